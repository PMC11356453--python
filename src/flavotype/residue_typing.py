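"""Functional screening and substrate-preference typing of FLS/DFR candidates.

A candidate is typed by the residue found at the family anchor column
(DFR 133 / FLS 132 in Arabidopsis reference numbering).  For DFR the
residue determines which dihydroflavonols (DHK, DHQ, DHM) the enzyme can
reduce; for FLS the association is hypothesized from the DHQ-binding
residue literature:

    DFR:  N -> all three substrates;  D -> DHQ+DHM;  A -> DHK (high
          affinity);  L -> DHK only (known restriction, reported as
          DFR_other with a note);  anything else -> DFR_other, unknown.
    FLS:  H -> DHK+DHQ;  F -> DHK;  Y -> DHQ;  anything else -> FLS_other.

Functionality screening checks the residues and motifs known to be
required for catalysis (2-ODD fold residues G68/H75/P207/G261, DHQ-binding
H132/F134/K202/F293/E295, the ferrous-iron motif HX(D/E)XnH, the
2-oxoglutarate-binding RXS, and the FLS-specific motifs PxxxIRxxxEQP and
SxxTxLVP; for DFR, presence of the 26-residue substrate-binding region).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .anchor_map import (
    PositionMap,
    ReferenceAnchor,
    ScoringScheme,
    align_global,
    build_position_map,
    default_scoring,
    extract_region,
    residue_at_anchor,
)
from .seqio import SequenceRecord, translate_cds

__all__ = [
    "ResidueRule",
    "MotifPattern",
    "TypingResult",
    "classify_anchor",
    "screen_rules",
    "find_motif",
    "type_sequences",
    "summarize_types",
    "default_rules",
    "default_motifs",
    "load_rules_tsv",
    "write_typing_tsv",
    "results_to_frame",
    "DFR_REGION_MAX_GAP_FRACTION",
    "TYPE_LABELS",
]

log = logging.getLogger(__name__)

TYPE_LABELS = (
    "DFR_N", "DFR_D", "DFR_A", "DFR_other",
    "FLS_H", "FLS_F", "FLS_Y", "FLS_other",
    "absent",
)

#: anchor residue -> (type label, substrate set, confidence, note)
DEFAULT_ANCHOR_TABLE: dict[tuple[str, str], tuple[str, frozenset, str, str]] = {
    ("DFR", "N"): ("DFR_N", frozenset({"DHK", "DHQ", "DHM"}), "reported", ""),
    ("DFR", "D"): ("DFR_D", frozenset({"DHQ", "DHM"}), "reported", ""),
    ("DFR", "A"): ("DFR_A", frozenset({"DHK"}), "reported", ""),
    ("DFR", "L"): ("DFR_other", frozenset({"DHK"}), "reported",
                   "L restricts the substrate to DHK"),
    ("FLS", "H"): ("FLS_H", frozenset({"DHK", "DHQ"}), "hypothesized", ""),
    ("FLS", "F"): ("FLS_F", frozenset({"DHK"}), "hypothesized", ""),
    ("FLS", "Y"): ("FLS_Y", frozenset({"DHQ"}), "hypothesized", ""),
}

#: maximum gap fraction tolerated in the DFR substrate-binding region
DFR_REGION_MAX_GAP_FRACTION = 0.30


@dataclass(frozen=True)
class ResidueRule:
    """One required residue at a reference-numbered position."""

    ref_position: int
    allowed: frozenset
    role: str = ""

    def __post_init__(self) -> None:
        if not self.allowed:
            raise ValueError("allowed residue set must be non-empty")


@dataclass(frozen=True)
class MotifPattern:
    """Wildcard protein motif.

    Syntax: upper-case residues are exact; ``x`` matches any residue;
    ``(A/B)`` matches any listed residue; one ``x{min,max}`` run matches a
    bounded-length stretch of arbitrary residues (used for the iron-binding
    motif ``Hx(D/E)x{n}H``).  ``restrict`` limits the scan window:
    'any' (whole sequence) or 'c_half' (C-terminal half).
    """

    pattern: str
    name: str = ""
    restrict: str = "any"  # 'any' | 'c_half'

    def __post_init__(self) -> None:
        if len(self.pattern) < 2:
            raise ValueError("pattern must have length >= 2")
        self.tokens  # validate eagerly

    @property
    def tokens(self) -> tuple:
        return _parse_pattern(self.pattern)


def _parse_pattern(pattern: str) -> tuple:
    """Tokenize into ('res', set), ('any',), or ('gap', min, max) tokens."""
    tokens: list[tuple] = []
    i = 0
    n = len(pattern)
    n_gap = 0
    while i < n:
        ch = pattern[i]
        if ch == "x":
            if i + 1 < n and pattern[i + 1] == "{":
                close = pattern.index("}", i + 1)
                lo_s, hi_s = pattern[i + 2:close].split(",")
                lo, hi = int(lo_s), int(hi_s)
                if lo < 0 or hi < lo:
                    raise ValueError(f"bad gap bounds in {pattern!r}")
                tokens.append(("gap", lo, hi))
                n_gap += 1
                i = close + 1
            else:
                tokens.append(("any",))
                i += 1
        elif ch == "(":
            close = pattern.index(")", i)
            allowed = frozenset(pattern[i + 1:close].split("/"))
            if not all(len(a) == 1 and a.isalpha() for a in allowed):
                raise ValueError(f"bad alternation in {pattern!r}")
            tokens.append(("res", allowed))
            i = close + 1
        elif ch.isalpha() and ch.isupper():
            tokens.append(("res", frozenset(ch)))
            i += 1
        else:
            raise ValueError(f"unexpected character {ch!r} in {pattern!r}")
    if n_gap > 1:
        raise ValueError("at most one bounded-gap run per pattern")
    return tuple(tokens)


def _match_at(seq: str, tokens: tuple, start: int) -> bool:
    """Does the token list match ``seq`` starting at 0-based ``start``?"""
    def rec(pos: int, ti: int) -> bool:
        if ti == len(tokens):
            return True
        tok = tokens[ti]
        if tok[0] == "gap":
            _, lo, hi = tok
            for g in range(lo, hi + 1):
                if pos + g > len(seq):
                    break
                if rec(pos + g, ti + 1):
                    return True
            return False
        if pos >= len(seq):
            return False
        if tok[0] == "any":
            return rec(pos + 1, ti + 1)
        return seq[pos] in tok[1] and rec(pos + 1, ti + 1)

    return rec(start, 0)


def find_motif(protein: str, p: MotifPattern) -> list[int]:
    """All (possibly overlapping) 1-based match start positions."""
    tokens = p.tokens
    start0 = len(protein) // 2 if p.restrict == "c_half" else 0
    min_len = sum(t[1] if t[0] == "gap" else 1 for t in tokens)
    out = []
    for s in range(start0, len(protein) - min_len + 1):
        if _match_at(protein, tokens, s):
            out.append(s + 1)
    return out


# ---------------------------------------------------------------------------
# classification

def classify_anchor(family: str, residue: Optional[str],
                    table: dict | None = None,
                    ) -> tuple[str, frozenset, str]:
    """Map an anchor residue to (type label, substrate set, confidence).

    ``residue`` None means the anchor column is deleted in the candidate
    (label 'absent' — a deletion is distinct from a substitution).
    Total over {A..Y, None} x {FLS, DFR}.
    """
    if family not in ("FLS", "DFR"):
        raise ValueError(f"unknown family {family!r}")
    if residue is None:
        return "absent", frozenset(), "none"
    if table is None:
        table = DEFAULT_ANCHOR_TABLE
    key = (family, residue.upper())
    if key in table:
        label, subs, conf, _note = table[key]
        return label, subs, conf
    return f"{family}_other", frozenset(), "none"


def default_rules(family: str) -> list[ResidueRule]:
    """Shipped residue rule set for a family, in reference numbering.

    FLS carries the residues named as required for 2-ODD folding and DHQ
    binding; position 132 admits the three known type residues H/F/Y.
    DFR positional requirements beyond the substrate-binding region are
    not fully published; the DFR list therefore holds only the anchor-region
    check, which is applied separately (see ``type_sequences``).
    """
    if family == "FLS":
        return [
            ResidueRule(68, frozenset("G"), "2-ODD fold"),
            ResidueRule(75, frozenset("H"), "2-ODD fold"),
            ResidueRule(207, frozenset("P"), "2-ODD fold"),
            ResidueRule(261, frozenset("G"), "2-ODD fold"),
            ResidueRule(132, frozenset("HFY"), "DHQ binding / type residue"),
            ResidueRule(134, frozenset("F"), "DHQ binding"),
            ResidueRule(202, frozenset("K"), "DHQ binding"),
            ResidueRule(293, frozenset("F"), "DHQ binding"),
            ResidueRule(295, frozenset("E"), "DHQ binding"),
        ]
    if family == "DFR":
        return []
    raise ValueError(f"unknown family {family!r}")


def default_motifs(family: str) -> list[MotifPattern]:
    if family == "FLS":
        return [
            MotifPattern("PxxxIRxxxEQP", name="FLS-specific motif 1"),
            MotifPattern("SxxTxLVP", name="FLS-specific motif 2"),
            MotifPattern("Hx(D/E)x{40,150}H", name="Fe(II) binding"),
            MotifPattern("RxS", name="2-oxoglutarate binding",
                         restrict="c_half"),
        ]
    if family == "DFR":
        return []
    raise ValueError(f"unknown family {family!r}")


def load_rules_tsv(path: str | Path) -> list[ResidueRule]:
    """Load residue rules from TSV (columns: ref_position, allowed, role)."""
    df = pd.read_csv(path, sep="\t")
    required = {"ref_position", "allowed"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: rule file needs columns {sorted(required)}")
    rules = []
    for _, row in df.iterrows():
        rules.append(ResidueRule(int(row["ref_position"]),
                                 frozenset(str(row["allowed"]).upper()),
                                 str(row.get("role", ""))))
    return rules


def screen_rules(cand: str, m: PositionMap,
                 rules: Iterable[ResidueRule]) -> tuple[bool, list]:
    """Check required residues; a rule fails on a disallowed or absent residue.

    Returns (functional, failures) where each failure is
    (rule, observed residue or None).
    """
    failures = []
    for rule in rules:
        pos = m[rule.ref_position]
        observed = None if pos is None else cand[pos - 1]
        if observed is None or observed not in rule.allowed:
            failures.append((rule, observed))
    return not failures, failures


@dataclass
class TypingResult:
    """Per-sequence outcome of the typing pipeline."""

    seq_id: str
    family: str
    anchor_residue: Optional[str]
    type_label: str
    substrate_set: frozenset
    confidence: str
    functional: bool
    failed_checks: list = field(default_factory=list)
    species: str = ""

    def __post_init__(self) -> None:
        if self.failed_checks and self.functional:
            raise ValueError(
                f"{self.seq_id}: functional=True with failed checks"
            )


def type_sequences(records: Sequence[SequenceRecord],
                   anchor: ReferenceAnchor,
                   rules: Sequence[ResidueRule] | None = None,
                   motifs: Sequence[MotifPattern] | None = None,
                   scoring: ScoringScheme | None = None,
                   ) -> list[TypingResult]:
    """Run the full per-sequence typing pipeline.

    CDS records are translated first (an internal stop is recorded as a
    failed check but the sequence is still aligned and typed, so
    pseudogene candidates come out as non-functional '-like' entries with
    a type label).  Each protein is globally aligned to the family
    reference, the anchor residue is read through the position map and
    classified, and the residue/motif screens decide the functional flag.
    """
    if rules is None:
        rules = default_rules(anchor.family)
    if motifs is None:
        motifs = default_motifs(anchor.family)
    if scoring is None:
        scoring = default_scoring()

    results = []
    for rec in records:
        failed: list = []
        if rec.molecule == "cds":
            protein, flags = translate_cds(rec)
            if flags.internal_stop:
                failed.append(("internal_stop", "*"))
        else:
            protein = rec
        pair = align_global(anchor.reference_protein, protein.residues, scoring)
        m = build_position_map(pair)
        residue = residue_at_anchor(protein.residues, m, anchor)
        label, substrates, confidence = classify_anchor(anchor.family, residue)
        ok, rule_failures = screen_rules(protein.residues, m, rules)
        failed.extend(rule_failures)
        for motif in motifs:
            if not find_motif(protein.residues, motif):
                failed.append((motif, None))
        if anchor.family == "DFR":
            start = anchor.anchor_position - 2
            end = anchor.anchor_position + 23
            region = extract_region(protein.residues, m, start, end)
            gap_frac = region.count("-") / len(region)
            if gap_frac > DFR_REGION_MAX_GAP_FRACTION:
                failed.append(("substrate_binding_region",
                               f"gap fraction {gap_frac:.2f}"))
        results.append(TypingResult(
            seq_id=rec.id,
            family=anchor.family,
            anchor_residue=residue,
            type_label=label,
            substrate_set=substrates,
            confidence=confidence,
            functional=not failed,
            failed_checks=failed,
            species=rec.species,
        ))
    return results


# ---------------------------------------------------------------------------
# summaries and export

def _failure_repr(failure) -> str:
    what, observed = failure
    obs = "ABSENT" if observed is None else str(observed)
    if isinstance(what, ResidueRule):
        return f"pos{what.ref_position}!={''.join(sorted(what.allowed))}:{obs}"
    if isinstance(what, MotifPattern):
        return f"motif:{what.name or what.pattern}:no_match"
    return f"{what}:{obs}"


def results_to_frame(results: Sequence[TypingResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "seq_id": r.seq_id,
            "species": r.species,
            "family": r.family,
            "anchor_residue": r.anchor_residue or "ABSENT",
            "type": r.type_label,
            "substrates": "+".join(sorted(r.substrate_set)) or "none",
            "confidence": r.confidence,
            "functional": r.functional,
            "failed_checks": ";".join(_failure_repr(f) for f in r.failed_checks),
        })
    return pd.DataFrame(rows, columns=[
        "seq_id", "species", "family", "anchor_residue", "type",
        "substrates", "confidence", "functional", "failed_checks"])


def write_typing_tsv(results: Sequence[TypingResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)


def summarize_types(results: Sequence[TypingResult],
                    grouping: dict[str, str] | None = None) -> pd.DataFrame:
    """Aggregate type labels per group (e.g. species -> taxonomic order).

    ``grouping`` maps each result's species to a group name; without it,
    species themselves are the groups.  For each group the table reports
    label counts, the modal residue(s), and a 'pattern' string of residues
    observed at the anchor ordered by frequency (e.g. "F/Y").  Groups with
    no results are omitted with a warning.  Output is sorted by group, so
    it is invariant to input order.
    """
    by_group: dict[str, list[TypingResult]] = {}
    for r in results:
        group = grouping.get(r.species, r.species) if grouping else r.species
        by_group.setdefault(group, []).append(r)
    if grouping:
        for group in set(grouping.values()) - set(by_group):
            log.warning("group %r has no typing results; omitted", group)
    rows = []
    for group in sorted(by_group):
        members = by_group[group]
        label_counts = Counter(r.type_label for r in members)
        residue_counts = Counter(r.anchor_residue or "ABSENT" for r in members)
        top = max(residue_counts.values())
        modal = sorted(res for res, c in residue_counts.items() if c == top)
        ordered = sorted(residue_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        rows.append({
            "group": group,
            "n": len(members),
            "labels": ";".join(f"{lab}:{c}" for lab, c
                               in sorted(label_counts.items())),
            "modal_residue": "/".join(modal),
            "pattern": "/".join(res for res, _ in ordered),
        })
    return pd.DataFrame(rows, columns=["group", "n", "labels",
                                       "modal_residue", "pattern"])
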