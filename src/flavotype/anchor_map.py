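"""Reference-anchored position mapping via pairwise global alignment.

The pipeline locates substrate-preference determining residues by their
coordinate in a family reference protein (AtDFR numbering: anchor 133;
AtFLS1 numbering: anchor 132) and projects that coordinate onto each
candidate through an optimal global alignment.  The aligner is a
Needleman-Wunsch/Gotoh dynamic program with affine gaps and BLOSUM62
scoring, with a fixed deterministic tie-break so runs are reproducible:
at equal score, a match/mismatch column is preferred over a gap in the
candidate, which is preferred over a gap in the reference.

Gap cost convention: a run of L gaps costs ``gap_open + (L-1)*gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "AlignmentPair",
    "PositionMap",
    "ReferenceAnchor",
    "AlignmentError",
    "default_scoring",
    "align_global",
    "build_position_map",
    "residue_at_anchor",
    "extract_region",
    "clean_columns",
    "reference_projected_msa",
    "position_map_to_tsv",
]

_NEG = -(10 ** 9)  # effective -inf for integer DP

AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: characters the aligner accepts; X and * score 0 against everything
ALIGN_ALPHABET = set(AA20) | {"X", "*"}


class AlignmentError(ValueError):
    """Raised for unalignable input (empty sequence, unknown characters)."""


def _blosum62_array() -> np.ndarray:
    """26x26 integer score array indexed by ord(ch)-65; X/'*' rows zeroed."""
    b62 = substitution_matrices.load("BLOSUM62")
    arr = np.zeros((27, 27), dtype=np.int64)  # index 26 used for '*'
    idx = {ch: ord(ch) - 65 for ch in AA20}
    idx["X"] = ord("X") - 65
    idx["*"] = 26
    for a in AA20:
        for b in AA20:
            arr[idx[a], idx[b]] = int(b62[a][b])
    # ambiguity (X) and stop (*) are scored neutrally against everything
    arr[idx["X"], :] = 0
    arr[:, idx["X"]] = 0
    arr[idx["*"], :] = 0
    arr[:, idx["*"]] = 0
    return arr


_B62 = _blosum62_array()


@dataclass
class ScoringScheme:
    """Substitution matrix plus positive affine gap penalties."""

    matrix: np.ndarray = field(default_factory=lambda: _B62.copy())
    gap_open: int = 10
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def score(self, a: str, b: str) -> int:
        return int(self.matrix[_aa_index(a), _aa_index(b)])


def default_scoring() -> ScoringScheme:
    return ScoringScheme()


def _aa_index(ch: str) -> int:
    return 26 if ch == "*" else ord(ch) - 65


def _encode(seq: str) -> np.ndarray:
    bad = set(seq) - ALIGN_ALPHABET
    if bad:
        raise AlignmentError(f"unknown residue characters: {sorted(bad)}")
    return np.fromiter((_aa_index(c) for c in seq), dtype=np.int64, count=len(seq))


@dataclass
class AlignmentPair:
    """A pairwise global alignment: two equal-length gapped strings."""

    ref_aligned: str
    cand_aligned: str
    score: int

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.cand_aligned):
            raise ValueError("aligned rows must have equal length")
        if any(a == "-" and b == "-"
               for a, b in zip(self.ref_aligned, self.cand_aligned)):
            raise ValueError("alignment contains an all-gap column")


def align_global(ref: str, cand: str,
                 scoring: ScoringScheme | None = None) -> AlignmentPair:
    """Optimal affine-gap global alignment of two protein strings.

    Tie-break at equal score: match/mismatch > gap-in-candidate >
    gap-in-reference (applied at the final cell and throughout traceback).
    """
    if scoring is None:
        scoring = default_scoring()
    if not ref or not cand:
        raise AlignmentError("cannot align an empty sequence")
    r = _encode(ref)
    c = _encode(cand)
    n, m = len(r), len(c)
    go, ge = scoring.gap_open, scoring.gap_extend

    # State matrices: M (ref i aligned to cand j), Ix (gap in candidate,
    # ref residue consumed), Iy (gap in reference, cand residue consumed).
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    for i in range(1, n + 1):
        Ix[i, 0] = -go - (i - 1) * ge
    for j in range(1, m + 1):
        Iy[0, j] = -go - (j - 1) * ge

    sub = scoring.matrix[np.ix_(r, c)]  # n x m substitution scores
    js = np.arange(m + 1)
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = prev_best[:-1] + sub[i - 1]
        Ix[i, :] = np.maximum(np.maximum(M[i - 1] - go, Iy[i - 1] - go),
                              Ix[i - 1] - ge)
        Ix[i, 0] = -go - (i - 1) * ge
        M[i, 0] = _NEG
        # Iy has an intra-row dependency; solve it with a prefix-max scan:
        # Iy[i,j] = max_{k<j}( max(M[i,k], Ix[i,k]) - go - (j-1-k)*ge )
        t = np.maximum(M[i], Ix[i]) + js * ge
        run = np.maximum.accumulate(t[:-1])
        Iy[i, 1:] = run - go - js[1:] * ge + ge
        Iy[i, 0] = _NEG

    # traceback; state preference M > Ix > Iy at every tie
    end_scores = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax([end_scores[0], end_scores[1], end_scores[2]]))
    # argmax returns the first maximum, which is the preferred state
    score = int(end_scores[state])

    ra: list[str] = []
    ca: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # M
            ra.append(ref[i - 1])
            ca.append(cand[j - 1])
            opts = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i, j = i - 1, j - 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(opts))
        elif state == 1:  # Ix: ref residue over a gap in candidate
            ra.append(ref[i - 1])
            ca.append("-")
            opts = (M[i - 1, j] - go, Ix[i - 1, j] - ge, Iy[i - 1, j] - go)
            i -= 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(opts))
        else:  # Iy: gap in reference over a candidate residue
            ra.append("-")
            ca.append(cand[j - 1])
            opts = (M[i, j - 1] - go, Ix[i, j - 1] - go, Iy[i, j - 1] - ge)
            j -= 1
            if i == 0 and j == 0:
                break
            state = int(np.argmax(opts))

    return AlignmentPair("".join(reversed(ra)), "".join(reversed(ca)), score)


# ---------------------------------------------------------------------------
# position mapping

@dataclass
class PositionMap:
    """Gap-aware map from 1-based reference positions to candidate positions.

    ``mapping[i]`` is the 1-based candidate position aligned to reference
    position ``i``, or ``None`` where the candidate has a gap (ABSENT).
    Restricted to defined entries the map is strictly increasing.
    """

    mapping: dict[int, Optional[int]]

    def __getitem__(self, ref_pos: int) -> Optional[int]:
        return self.mapping[ref_pos]

    def __len__(self) -> int:
        return len(self.mapping)


def build_position_map(a: AlignmentPair) -> PositionMap:
    mapping: dict[int, Optional[int]] = {}
    ri = ci = 0
    for rc, cc in zip(a.ref_aligned, a.cand_aligned):
        if cc != "-":
            ci += 1
        if rc != "-":
            ri += 1
            mapping[ri] = ci if cc != "-" else None
    return PositionMap(mapping)


@dataclass
class ReferenceAnchor:
    """A family reference protein and its anchor coordinate.

    The anchor is the substrate-preference determining position expressed
    in reference numbering (133 for DFR after AtDFR, 132 for FLS after
    AtFLS1; other numbering systems, e.g. Gerbera 134, are offset variants
    of the same column).
    """

    family: str  # 'FLS' | 'DFR'
    reference_id: str
    reference_protein: str
    anchor_position: int

    def __post_init__(self) -> None:
        if self.family not in ("FLS", "DFR"):
            raise ValueError(f"unknown family {self.family!r}")
        if not 1 <= self.anchor_position <= len(self.reference_protein):
            raise ValueError(
                f"anchor position {self.anchor_position} outside reference "
                f"length {len(self.reference_protein)}"
            )


def residue_at_anchor(cand: str, m: PositionMap,
                      anchor: ReferenceAnchor) -> Optional[str]:
    """Candidate residue aligned to the anchor column, or None if deleted."""
    pos = m[anchor.anchor_position]
    if pos is None:
        return None
    return cand[pos - 1]


def extract_region(cand: str, m: PositionMap, start_ref: int,
                   end_ref: int) -> str:
    """Candidate residues over reference positions start..end ('-' = absent).

    Used for the 26-residue substrate-binding region of DFR (reference
    positions anchor-2 .. anchor+23).
    """
    if start_ref > end_ref:
        raise ValueError(f"empty region {start_ref}..{end_ref}")
    if start_ref < 1 or end_ref > len(m):
        raise ValueError(
            f"region {start_ref}..{end_ref} outside reference 1..{len(m)}"
        )
    out = []
    for i in range(start_ref, end_ref + 1):
        pos = m[i]
        out.append("-" if pos is None else cand[pos - 1])
    return "".join(out)


def clean_columns(msa: Sequence[str],
                  min_occupancy: float) -> tuple[list[str], list[int]]:
    """Drop alignment columns whose non-gap fraction is below threshold.

    The boundary is strict ("less than"): a column with occupancy exactly
    equal to ``min_occupancy`` is kept.  Returns the reduced rows and the
    0-based indices of the kept columns so anchors can be re-located.
    """
    if not msa:
        raise ValueError("empty alignment")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("alignment rows have unequal lengths")
    if not 0 < min_occupancy <= 1:
        raise ValueError("min_occupancy must be in (0, 1]")
    arr = np.array([list(row) for row in msa])
    occupancy = (arr != "-").mean(axis=0)
    kept = [j for j in range(ncol) if occupancy[j] >= min_occupancy]
    reduced = ["".join(arr[i, kept]) for i in range(len(msa))]
    return reduced, kept


def reference_projected_msa(proteins: Sequence[tuple[str, str]],
                            anchor: ReferenceAnchor,
                            scoring: ScoringScheme | None = None,
                            ) -> tuple[list[str], list[str]]:
    """Build a pseudo-MSA by projecting candidates onto reference columns.

    Each candidate is aligned pairwise to the reference and its residues
    at reference positions 1..L are concatenated ('-' where absent);
    candidate insertions relative to the reference are discarded.  The
    result is a rectangular alignment in reference coordinates, suitable
    for p-distance/NJ when no external MSA is available.

    ``proteins`` is a sequence of (label, protein) pairs; returns
    (labels, aligned rows) with the reference itself as the first row.
    """
    if scoring is None:
        scoring = default_scoring()
    L = len(anchor.reference_protein)
    labels = [anchor.reference_id]
    rows = [anchor.reference_protein]
    for label, prot in proteins:
        pair = align_global(anchor.reference_protein, prot, scoring)
        m = build_position_map(pair)
        rows.append(extract_region(prot, m, 1, L))
        labels.append(label)
    return labels, rows


def position_map_to_tsv(m: PositionMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_pos\tcand_pos\n")
        for i in sorted(m.mapping):
            v = m.mapping[i]
            fh.write(f"{i}\t{'NA' if v is None else v}\n")
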