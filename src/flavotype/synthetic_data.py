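"""Synthetic sequence families and expression tables with known ground truth.

Every pipeline stage is testable without downloads: this module emulates
(a) a CDS family diverged from a reference by iid substitutions and
geometric-length indels, with a chosen residue planted at the anchor
column and back-translated to a synonymous codon, and (b) per-sample
kallisto-dialect abundance tables in which one of the two focal genes
(FLS or DFR) is expressed per sample with a tunable exclusivity
parameter rho.

The packaged reference proteins are SYNTHETIC stand-ins for the real
Arabidopsis references (AtDFR / AtFLS1), generated deterministically with
the field's required residues and motifs planted at the published
reference coordinates; they carry the coordinate system, not the real
sequences.  Divergence is iid from a star (no tree-structured evolution),
which is sufficient for exercising anchoring, typing, and distance-based
tree building, but does not emulate rate heterogeneity, domain-level
conservation structure, or codon usage bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .anchor_map import AA20, ReferenceAnchor
from .expression import SampleMeta, ORGANS
from .residue_typing import TypingResult, classify_anchor
from .seqio import ABUNDANCE_COLUMNS, SequenceRecord, write_fasta

__all__ = [
    "FamilySimConfig",
    "ExprSimConfig",
    "FamilySim",
    "ExpressionSim",
    "make_reference",
    "simulate_family",
    "simulate_expression",
    "score_recovery",
    "write_family",
    "write_expression",
]

_REFERENCE_SEED = 20240828  # fixed: the packaged references are constants

#: residue -> list of synonymous codons (standard code)
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()
_STOPS = sorted(standard_dna_table.stop_codons)


def make_reference(family: str) -> ReferenceAnchor:
    """Deterministic synthetic reference protein for a family.

    FLS (length 310, anchor 132): carries H132 plus the 2-ODD fold
    residues (G68, H75, P207, G261), the DHQ-binding residues (F134,
    K202, F293, E295), both FLS-specific motifs, an iron-binding
    Hx(D/E)x{n}H arrangement and a C-terminal RxS.  DFR (length 330,
    anchor 133): carries N133 inside a fully present 26-residue
    substrate-binding region.  Synthetic stand-ins for the Arabidopsis
    reference coordinates, not real sequences.
    """
    rng = np.random.default_rng(_REFERENCE_SEED + (0 if family == "DFR" else 1))
    if family == "FLS":
        length = 310
        planted = {
            68: "G", 75: "H", 132: "H", 134: "F", 202: "K", 207: "P",
            261: "G", 293: "F", 295: "E",
            # PxxxIRxxxEQP at 150
            150: "P", 154: "I", 155: "R", 159: "E", 160: "Q", 161: "P",
            # SxxTxLVP at 170
            170: "S", 173: "T", 175: "L", 176: "V", 177: "P",
            # Hx(D/E)x{n}H: H220 .. D222 .. H270 (n = 47)
            220: "H", 222: "D", 270: "H",
            # RxS in the C-terminal half
            300: "R", 302: "S",
        }
        anchor_pos = 132
        ref_id = "FLS_ref_synthetic"
    elif family == "DFR":
        length = 330
        planted = {133: "N"}
        anchor_pos = 133
        ref_id = "DFR_ref_synthetic"
    else:
        raise ValueError(f"unknown family {family!r}")
    residues = [AA20[i] for i in rng.integers(0, len(AA20), size=length)]
    for pos, aa in planted.items():
        residues[pos - 1] = aa
    return ReferenceAnchor(family=family, reference_id=ref_id,
                           reference_protein="".join(residues),
                           anchor_position=anchor_pos)


@dataclass
class FamilySimConfig:
    """Conditions for one simulated homolog family."""

    family: str = "DFR"
    n_sequences: int = 200
    substitution_rate: float = 0.10
    indel_rate: float = 0.02
    indel_length_p: float = 0.5  # geometric(p); mean length 1/p
    planted_anchor_residues: dict[str, float] = field(
        default_factory=lambda: {"N": 1 / 3, "D": 1 / 3, "A": 1 / 3})
    protect_anchor: bool = True
    seed: int = 0
    reference: Optional[ReferenceAnchor] = None

    def __post_init__(self) -> None:
        for rate in (self.substitution_rate, self.indel_rate):
            if not 0 <= rate < 1:
                raise ValueError("rates must lie in [0, 1)")
        if not 0 < self.indel_length_p <= 1:
            raise ValueError("indel_length_p must lie in (0, 1]")
        total = sum(self.planted_anchor_residues.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("planted residue probabilities must sum to 1")
        if self.reference is None:
            self.reference = make_reference(self.family)


@dataclass
class FamilySim:
    cds: list[SequenceRecord]
    proteins: list[SequenceRecord]
    truth: pd.DataFrame  # indexed by seq id
    anchor: ReferenceAnchor
    config: FamilySimConfig


def _random_other(rng: np.random.Generator, current: str) -> str:
    choices = [a for a in AA20 if a != current]
    return choices[rng.integers(0, len(choices))]


def simulate_family(cfg: FamilySimConfig) -> FamilySim:
    """Simulate a diverged homolog family with a planted anchor residue.

    Each homolog gets iid substitutions, a planted anchor residue
    (overwriting whatever the substitution step produced), and
    geometric-length indels; with ``protect_anchor`` no indel overlaps or
    abuts the anchor column, and indels avoid the terminal 3 columns to
    keep alignments well anchored.  Proteins are back-translated with
    uniformly chosen synonymous codons plus a random stop, so the truth
    table can record the exact anchor codon.  Deterministic given the
    config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    anchor = cfg.reference
    ref = anchor.reference_protein
    a_idx = anchor.anchor_position - 1
    residue_choices = sorted(cfg.planted_anchor_residues)
    residue_probs = [cfg.planted_anchor_residues[r] for r in residue_choices]

    cds_records: list[SequenceRecord] = []
    protein_records: list[SequenceRecord] = []
    truth_rows = []
    for i in range(cfg.n_sequences):
        seq_id = f"{cfg.family}_sim_{i:04d}"
        species = f"species_{i // 10:02d}"
        residues = list(ref)
        sub_mask = rng.random(len(residues)) < cfg.substitution_rate
        for j in np.flatnonzero(sub_mask):
            residues[j] = _random_other(rng, residues[j])
        planted = residue_choices[
            rng.choice(len(residue_choices), p=residue_probs)]
        residues[a_idx] = planted
        anchor_idx = a_idx

        # indel events, applied right-to-left so positions stay valid
        positions = np.flatnonzero(
            rng.random(len(residues)) < cfg.indel_rate)
        events = []
        for pos in positions:
            if pos < 3 or pos >= len(ref) - 3:
                continue
            is_del = rng.random() < 0.5
            length = int(rng.geometric(cfg.indel_length_p))
            if cfg.protect_anchor:
                # a gap near the anchor can slide over it at equal or
                # better alignment score (repeated residues), so "not
                # touching the anchor" means a small exclusion window
                lo, hi = anchor_idx - 3, anchor_idx + 3
                if is_del and pos <= hi and lo < pos + length:
                    continue
                if not is_del and lo < pos <= hi + 1:
                    continue
            events.append((int(pos), is_del, length))
        for pos, is_del, length in sorted(events, reverse=True):
            if is_del:
                if pos <= anchor_idx < pos + length:
                    continue  # earlier deletion may have shifted things
                del residues[pos:pos + length]
                if pos + length <= anchor_idx:
                    anchor_idx -= length
            else:
                ins = [AA20[k]
                       for k in rng.integers(0, len(AA20), size=length)]
                residues[pos:pos] = ins
                if pos <= anchor_idx:
                    anchor_idx += length
        protein = "".join(residues)
        assert protein[anchor_idx] == planted

        codons = [_CODONS[aa][rng.integers(0, len(_CODONS[aa]))]
                  for aa in residues]
        codons.append(_STOPS[rng.integers(0, len(_STOPS))])
        cds = "".join(codons)
        planted_codon = codons[anchor_idx]

        cds_records.append(SequenceRecord(id=seq_id, residues=cds,
                                          molecule="cds", species=species))
        protein_records.append(SequenceRecord(id=seq_id, residues=protein,
                                              molecule="protein",
                                              species=species))
        label, _subs, _conf = classify_anchor(cfg.family, planted)
        truth_rows.append({
            "seq_id": seq_id, "species": species,
            "planted_residue": planted, "planted_codon": planted_codon,
            "anchor_pos_protein": anchor_idx + 1,
            "expected_type": label,
        })
    truth = pd.DataFrame(truth_rows).set_index("seq_id")
    return FamilySim(cds=cds_records, proteins=protein_records, truth=truth,
                     anchor=anchor, config=cfg)


# ---------------------------------------------------------------------------
# expression simulation

@dataclass
class ExprSimConfig:
    """Conditions for the simulated cross-species expression study.

    With probability ``rho`` a sample expresses exactly one of FLS/DFR
    (the 'on' gene at lognormal TPM, the other at a uniform noise floor);
    with probability 1 - rho both are on.  ``on_mu``/``on_sigma`` are on
    the natural-log scale (defaults give a median of ~20 TPM).  Each
    family's TPM is split over its paralogs by a Dirichlet draw.
    """

    n_species: int = 10
    samples_per_species: int = 50
    rho: float = 0.9
    on_mu: float = 3.0
    on_sigma: float = 1.0
    noise_floor: float = 0.01
    paralogs_per_family: int = 2
    paralog_identity: float = 0.95
    n_noise_genes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.rho <= 1:
            raise ValueError("rho must lie in [0, 1]")
        if not self.noise_floor < np.exp(self.on_mu):
            raise ValueError("noise floor must sit below the on-expression scale")
        if self.paralogs_per_family < 1:
            raise ValueError("need at least one gene per family")


@dataclass
class ExpressionSim:
    tables: dict[str, pd.DataFrame]  # sample_id -> kallisto-dialect frame
    meta: list[SampleMeta]
    gene_truth: pd.DataFrame  # per gene: species, family, type, residue
    sample_truth: pd.DataFrame  # per sample: expressed call, true totals
    typing_results: list[TypingResult]
    proteins: dict[str, str]  # paralog proteins (for identity clustering)
    config: ExprSimConfig


_TYPE_COMBOS = [("FLS_H", "DFR_N"), ("FLS_H", "DFR_D"), ("FLS_H", "DFR_A"),
                ("FLS_F", "DFR_N"), ("FLS_Y", "DFR_N"), ("FLS_Y", "DFR_D")]
_TYPE_RESIDUE = {"FLS_H": "H", "FLS_F": "F", "FLS_Y": "Y",
                 "DFR_N": "N", "DFR_D": "D", "DFR_A": "A"}


def _paralog_protein(rng: np.random.Generator, base: str,
                     identity: float, keep_idx: int, keep_res: str) -> str:
    """Mutate ``base`` to roughly the requested identity, fixing one site."""
    residues = list(base)
    mask = rng.random(len(residues)) < (1 - identity)
    for j in np.flatnonzero(mask):
        residues[j] = _random_other(rng, residues[j])
    residues[keep_idx] = keep_res
    return "".join(residues)


def simulate_expression(cfg: ExprSimConfig) -> ExpressionSim:
    """Simulate per-sample abundance tables with planted exclusivity.

    Deterministic given the config seed; output tables are exactly the
    kallisto dialect (readable by :func:`flavotype.seqio.read_abundance_tsv`
    after writing).
    """
    rng = np.random.default_rng(cfg.seed)
    fls_ref = make_reference("FLS")
    dfr_ref = make_reference("DFR")

    tables: dict[str, pd.DataFrame] = {}
    meta: list[SampleMeta] = []
    gene_rows = []
    sample_rows = []
    typing_results: list[TypingResult] = []
    proteins: dict[str, str] = {}

    for s in range(cfg.n_species):
        species = f"species_{s:02d}"
        fls_type, dfr_type = _TYPE_COMBOS[s % len(_TYPE_COMBOS)]
        genes: dict[str, tuple[str, str]] = {}  # gene -> (family, type)
        for family, type_label, ref in (("FLS", fls_type, fls_ref),
                                        ("DFR", dfr_type, dfr_ref)):
            residue = _TYPE_RESIDUE[type_label]
            for k in range(cfg.paralogs_per_family):
                gid = f"{species}_{family}{k + 1}"
                genes[gid] = (family, type_label)
                proteins[gid] = _paralog_protein(
                    rng, ref.reference_protein, cfg.paralog_identity,
                    ref.anchor_position - 1, residue)
                gene_rows.append({"gene_id": gid, "species": species,
                                  "family": family, "type_label": type_label,
                                  "anchor_residue": residue})
                typing_results.append(TypingResult(
                    seq_id=gid, family=family, anchor_residue=residue,
                    type_label=type_label,
                    substrate_set=classify_anchor(family, residue)[1],
                    confidence=classify_anchor(family, residue)[2],
                    functional=True, species=species))
        noise_genes = [f"{species}_other{k + 1}"
                       for k in range(cfg.n_noise_genes)]
        for gid in noise_genes:
            gene_rows.append({"gene_id": gid, "species": species,
                              "family": "other", "type_label": "",
                              "anchor_residue": ""})
        universe = list(genes) + noise_genes

        for t in range(cfg.samples_per_species):
            sample_id = f"{species}_s{t:03d}"
            organ = ORGANS[t % len(ORGANS)]
            meta.append(SampleMeta(sample_id=sample_id, species=species,
                                   organ=organ))
            exclusive = rng.random() < cfg.rho
            if exclusive:
                on = "FLS" if rng.random() < 0.5 else "DFR"
                totals = {
                    "FLS": (float(rng.lognormal(cfg.on_mu, cfg.on_sigma))
                            if on == "FLS"
                            else float(rng.uniform(0, cfg.noise_floor))),
                    "DFR": (float(rng.lognormal(cfg.on_mu, cfg.on_sigma))
                            if on == "DFR"
                            else float(rng.uniform(0, cfg.noise_floor))),
                }
                call = on
            else:
                totals = {
                    "FLS": float(rng.lognormal(cfg.on_mu, cfg.on_sigma)),
                    "DFR": float(rng.lognormal(cfg.on_mu, cfg.on_sigma)),
                }
                call = "both"
            tpm: dict[str, float] = {}
            for family in ("FLS", "DFR"):
                members = [g for g, (fam, _t) in genes.items() if fam == family]
                split = rng.dirichlet(np.ones(len(members)))
                for gid, w in zip(members, split):
                    tpm[gid] = totals[family] * float(w)
            for gid in noise_genes:
                tpm[gid] = float(rng.uniform(0, cfg.noise_floor))
            frame = pd.DataFrame({
                "target_id": universe,
                "length": 1500,
                "eff_length": 1300.0,
                "est_counts": [tpm[g] * 10.0 for g in universe],
                "tpm": [tpm[g] for g in universe],
            }).set_index("target_id")
            tables[sample_id] = frame
            sample_rows.append({
                "sample_id": sample_id, "species": species, "organ": organ,
                "expressed": call,
                "fls_tpm_true": totals["FLS"], "dfr_tpm_true": totals["DFR"],
                "fls_type": fls_type, "dfr_type": dfr_type,
            })

    gene_truth = pd.DataFrame(gene_rows).set_index("gene_id")
    sample_truth = pd.DataFrame(sample_rows).set_index("sample_id")
    return ExpressionSim(tables=tables, meta=meta, gene_truth=gene_truth,
                         sample_truth=sample_truth,
                         typing_results=typing_results, proteins=proteins,
                         config=cfg)


# ---------------------------------------------------------------------------
# recovery scoring

def score_recovery(family_truth: pd.DataFrame | None = None,
                   typing_results: Sequence[TypingResult] | None = None,
                   sample_truth: pd.DataFrame | None = None,
                   pairs_df: pd.DataFrame | None = None,
                   call_floor: float = 1.0) -> dict:
    """Per-stage recovery accuracies against a simulation truth table.

    For the family stage: fraction of sequences whose recovered anchor
    residue / type label match the planted truth, with confusion counts.
    For the expression stage: per-sample expressed-gene call (FLS / DFR /
    both, using ``call_floor`` TPM as the detection threshold per gene)
    against the generator's record of which gene was on.
    """
    report: dict = {}
    if family_truth is not None:
        if typing_results is None or len(family_truth) == 0:
            raise ValueError("family scoring needs truth rows and results")
        by_id = {r.seq_id: r for r in typing_results}
        n = res_ok = type_ok = 0
        confusion: dict[tuple[str, str], int] = {}
        for seq_id, row in family_truth.iterrows():
            r = by_id.get(seq_id)
            if r is None:
                raise ValueError(f"no typing result for {seq_id!r}")
            n += 1
            observed = r.anchor_residue or "ABSENT"
            if observed == row["planted_residue"]:
                res_ok += 1
            if r.type_label == row["expected_type"]:
                type_ok += 1
            key = (row["expected_type"], r.type_label)
            confusion[key] = confusion.get(key, 0) + 1
        report["anchor_residue_accuracy"] = res_ok / n
        report["type_label_accuracy"] = type_ok / n
        report["type_confusion"] = {f"{a}->{b}": c
                                    for (a, b), c in sorted(confusion.items())}
    if sample_truth is not None:
        if pairs_df is None or len(sample_truth) == 0:
            raise ValueError("expression scoring needs truth rows and pairs")
        merged = pairs_df.set_index("sample_id").join(
            sample_truth[["expressed"]], how="inner")
        if merged.empty:
            raise ValueError("no overlapping samples between pairs and truth")
        calls = np.where(
            (merged["fls_tpm"] >= call_floor) & (merged["dfr_tpm"] >= call_floor),
            "both",
            np.where(merged["fls_tpm"] >= merged["dfr_tpm"], "FLS", "DFR"))
        report["expressed_call_accuracy"] = float(
            np.mean(calls == merged["expressed"].values))
        report["n_samples_scored"] = int(len(merged))
    if not report:
        raise ValueError("nothing to score: provide a truth table")
    return report


# ---------------------------------------------------------------------------
# writers

def write_family(sim: FamilySim, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cds": out / f"{sim.config.family.lower()}_family_cds.fasta",
        "protein": out / f"{sim.config.family.lower()}_family_protein.fasta",
        "truth": out / f"{sim.config.family.lower()}_family_truth.tsv",
        "reference": out / f"{sim.config.family.lower()}_reference.fasta",
    }
    write_fasta(sim.cds, paths["cds"])
    write_fasta(sim.proteins, paths["protein"])
    sim.truth.to_csv(paths["truth"], sep="\t")
    write_fasta([SequenceRecord(id=sim.anchor.reference_id,
                                residues=sim.anchor.reference_protein,
                                molecule="protein")], paths["reference"])
    return paths


def write_expression(sim: ExpressionSim, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    (out / "abundance").mkdir(parents=True, exist_ok=True)
    for sample_id, frame in sim.tables.items():
        frame.reset_index().to_csv(out / "abundance" / f"{sample_id}.tsv",
                                   sep="\t", index=False)
    meta_path = out / "samples.tsv"
    pd.DataFrame([{"sample_id": m.sample_id, "species": m.species,
                   "organ": m.organ} for m in sim.meta]).to_csv(
        meta_path, sep="\t", index=False)
    truth_path = out / "expression_truth.tsv"
    sim.sample_truth.to_csv(truth_path, sep="\t")
    # typing of the focal genes, in the same TSV the 'type' subcommand
    # writes, so the expression stage can consume simulated data directly
    from .residue_typing import write_typing_tsv
    typing_path = out / "typing_focal.tsv"
    write_typing_tsv(sim.typing_results, typing_path)
    proteins_path = out / "focal_proteins.fasta"
    write_fasta([SequenceRecord(id=gid, residues=prot, molecule="protein")
                 for gid, prot in sorted(sim.proteins.items())], proteins_path)
    return {"abundance_dir": out / "abundance", "meta": meta_path,
            "truth": truth_path, "typing": typing_path,
            "proteins": proteins_path}
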