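"""Independent reference implementations used only to check the package.

These deliberately share no code with flavotype: the alignment oracle is a
plain recursive three-state dynamic program over the published BLOSUM62
matrix, and the motif oracles are hand-coded scans for the specific
patterns under test.
"""

from __future__ import annotations

from functools import lru_cache

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _score(a: str, b: str) -> int:
    if a in ("X", "*") or b in ("X", "*"):
        return 0
    return int(_B62[a][b])


def gotoh_score_oracle(ref: str, cand: str, gap_open: int = 10,
                       gap_extend: int = 1) -> int:
    """Optimal affine-gap global alignment score by memoized recursion.

    Gap of length L costs gap_open + (L-1)*gap_extend.  States: 0 = last
    column was a match/mismatch, 1 = gap in candidate, 2 = gap in reference.
    """
    NEG = -(10 ** 9)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> int:
        if i == 0 and j == 0:
            return 0 if state == 0 else NEG
        options = []
        if state == 0 and i > 0 and j > 0:
            sub = _score(ref[i - 1], cand[j - 1])
            options = [best(i - 1, j - 1, s) + sub for s in (0, 1, 2)]
        elif state == 1 and i > 0:  # cand gap consumes ref[i-1]
            options = [best(i - 1, j, 0) - gap_open,
                       best(i - 1, j, 1) - gap_extend,
                       best(i - 1, j, 2) - gap_open]
        elif state == 2 and j > 0:  # ref gap consumes cand[j-1]
            options = [best(i, j - 1, 0) - gap_open,
                       best(i, j - 1, 1) - gap_open,
                       best(i, j - 1, 2) - gap_extend]
        return max(options) if options else NEG

    n, m = len(ref), len(cand)
    return max(best(n, m, s) for s in (0, 1, 2))


def naive_fixed_motif_starts(seq: str, pattern: str) -> list[int]:
    """1-based starts of a wildcard ('x') pattern, position-by-position."""
    out = []
    for s in range(len(seq) - len(pattern) + 1):
        if all(p == "x" or seq[s + k] == p for k, p in enumerate(pattern)):
            out.append(s + 1)
    return out


def naive_fe_motif_starts(seq: str, n_min: int = 40,
                          n_max: int = 150) -> list[int]:
    """1-based starts of H-x-(D/E)-x{n}-H, hand-coded."""
    out = []
    for s in range(len(seq)):
        if s + 3 >= len(seq) or seq[s] != "H" or seq[s + 2] not in "DE":
            continue
        for n in range(n_min, n_max + 1):
            h = s + 3 + n
            if h >= len(seq):
                break
            if seq[h] == "H":
                out.append(s + 1)
                break
    return out


def quartet_ls_topology(labels, d) -> frozenset:
    """Best least-squares quartet topology for a 4x4 distance matrix.

    Enumerates the three unrooted quartet topologies ab|cd, ac|bd, ad|bc
    and fits the five edge lengths of each by ordinary least squares;
    returns the cherry {x, y} of the best-fitting topology.
    """
    import itertools

    import numpy as np

    a, b, c, d4 = range(4)
    pairs = list(itertools.combinations(range(4), 2))
    best = None
    for split in ((a, b), (a, c), (a, d4)):
        others = tuple(x for x in range(4) if x not in split)
        # edges: e0..e3 pendant for taxa 0..3, e4 internal
        rows = []
        y = []
        for (i, j) in pairs:
            row = [0.0] * 5
            row[i] += 1
            row[j] += 1
            same_side = ({i, j} == set(split)) or ({i, j} == set(others))
            if not same_side:
                row[4] = 1.0
            rows.append(row)
            y.append(d[i][j])
        X = np.array(rows)
        coef, res, *_ = np.linalg.lstsq(X, np.array(y), rcond=None)
        fit = X @ coef
        sse = float(np.sum((fit - np.array(y)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, split)
    return frozenset(labels[i] for i in best[1])
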