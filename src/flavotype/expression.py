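"""Cross-species expression merging and FLS-vs-DFR exclusivity analysis.

Abundance tables in the kallisto dialect (one per RNA-seq sample) are
merged into a genes x samples matrix per the sample metadata.  Close
paralogs — same family, same anchor residue, protein identity at or above
a threshold — are summed into one row, mirroring how per-gene transcript
abundance is consolidated before cross-species comparison.  Each sample
then contributes one (FLS total TPM, DFR total TPM) pair; the package
quantifies the near-mutually-exclusive expression of the two genes with
an exclusivity index defined as

    index = median over samples of |F - D| / (F + D)

over samples whose total F + D passes a detection floor: 1 means each
sample expresses only one of the two genes, 0 means perfectly balanced
co-expression.  The index is an artifact-defined statistic that
operationalizes the qualitative "one or the other, almost never both"
pattern; outputs label it as such.  A 2D density grid over
log10(TPM + 1)-transformed axes with marginal histograms supports the
standard visualization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .anchor_map import ScoringScheme, align_global, default_scoring
from .residue_typing import TypingResult

__all__ = [
    "SampleMeta",
    "ExpressionTable",
    "ExclusivityResult",
    "merge_samples",
    "aggregate_paralogs",
    "pair_focal",
    "exclusivity_index",
    "density_grid",
    "analyze_exclusivity",
    "plot_density",
    "protein_identity",
    "ORGANS",
]

log = logging.getLogger(__name__)

ORGANS = ("leaf", "root", "stem", "flower", "seed", "fruit", "other")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    species: str
    organ: str = "other"

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")


@dataclass
class ExpressionTable:
    """Genes x samples TPM and count matrices plus annotations.

    ``annotations`` is indexed by gene id with columns species, family
    ('FLS'/'DFR'/'other'), type_label, anchor_residue, functional.
    """

    tpm: pd.DataFrame
    counts: pd.DataFrame
    meta: pd.DataFrame  # indexed by sample_id: species, organ
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.tpm.values < 0).any() or (self.counts.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if not self.tpm.columns.equals(self.counts.columns):
            raise ValueError("TPM and count matrices disagree on samples")


def merge_samples(tables: dict[str, pd.DataFrame],
                  meta: Sequence[SampleMeta]) -> ExpressionTable:
    """Merge per-sample abundance tables into one matrix.

    Within a species every sample must quantify the identical gene set
    (they come from one kallisto index).  Samples present in the data but
    missing from the metadata (or vice versa) are errors.  Columns are
    ordered by sample id, so merging is deterministic.
    """
    if not tables:
        raise ValueError("no samples to merge")
    meta_ids = {m.sample_id for m in meta}
    if len(meta_ids) != len(list(meta)):
        raise ValueError("duplicate sample_id in metadata")
    data_ids = set(tables)
    if data_ids - meta_ids:
        missing = sorted(data_ids - meta_ids)[0]
        raise ValueError(f"sample {missing!r} has no metadata entry")
    if meta_ids - data_ids:
        missing = sorted(meta_ids - data_ids)[0]
        raise ValueError(f"metadata sample {missing!r} has no abundance table")

    by_species: dict[str, list[str]] = {}
    for m in meta:
        by_species.setdefault(m.species, []).append(m.sample_id)
    for species, ids in by_species.items():
        universe = set(tables[ids[0]].index)
        for sid in ids[1:]:
            diff = universe ^ set(tables[sid].index)
            if diff:
                raise ValueError(
                    f"gene {sorted(diff)[0]!r} not shared by all samples of "
                    f"{species!r}"
                )

    order = sorted(tables)
    tpm = pd.DataFrame({sid: tables[sid]["tpm"] for sid in order}).fillna(0.0)
    counts = pd.DataFrame({sid: tables[sid]["est_counts"]
                           for sid in order}).fillna(0.0)
    meta_df = pd.DataFrame(
        [{"sample_id": m.sample_id, "species": m.species, "organ": m.organ}
         for m in meta]).set_index("sample_id").loc[order]
    annotations = pd.DataFrame(
        index=tpm.index,
        data={"species": "", "family": "other", "type_label": "",
              "anchor_residue": "", "functional": False})
    for species, ids in by_species.items():
        annotations.loc[tables[ids[0]].index, "species"] = species
    return ExpressionTable(tpm=tpm, counts=counts, meta=meta_df,
                           annotations=annotations)


def annotate_genes(table: ExpressionTable,
                   typing: Sequence[TypingResult]) -> ExpressionTable:
    """Attach family/type/functional labels from typing results."""
    for r in typing:
        if r.seq_id not in table.annotations.index:
            log.warning("typing result for %r matches no gene; ignored",
                        r.seq_id)
            continue
        table.annotations.loc[r.seq_id,
                              ["family", "type_label", "anchor_residue",
                               "functional"]] = [
            r.family, r.type_label, r.anchor_residue or "ABSENT", r.functional]
    return table


def protein_identity(a: str, b: str,
                     scoring: ScoringScheme | None = None) -> float:
    """Fraction of identical columns over the global alignment length."""
    pair = align_global(a, b, scoring or default_scoring())
    same = sum(x == y and x != "-"
               for x, y in zip(pair.ref_aligned, pair.cand_aligned))
    return same / len(pair.ref_aligned)


def aggregate_paralogs(table: ExpressionTable,
                       proteins: dict[str, str],
                       identity_threshold: float = 0.8,
                       scoring: ScoringScheme | None = None,
                       ) -> ExpressionTable:
    """Sum close paralogs into single rows.

    Within one species and family, genes are merged when they share the
    same substrate-preference determining (anchor) residue AND their
    pairwise protein identity is at or above the threshold; merging is by
    connected components of the qualifying-pair graph.  Genes with
    different anchor residues are never merged.  TPM and counts are both
    summed, so per-sample focal totals are conserved exactly.
    """
    ann = table.annotations
    focal = ann[ann["family"].isin(["FLS", "DFR"])]
    merged_tpm = table.tpm.copy()
    merged_counts = table.counts.copy()
    merged_ann = ann.copy()

    for (_species, _family, _residue), group in focal.groupby(
            ["species", "family", "anchor_residue"], sort=True):
        ids = sorted(group.index)
        if len(ids) < 2:
            continue
        # union-find over qualifying pairs
        parent = {g: g for g in ids}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, gi in enumerate(ids):
            for gj in ids[i + 1:]:
                if gi in proteins and gj in proteins:
                    ident = protein_identity(proteins[gi], proteins[gj],
                                             scoring)
                    if ident >= identity_threshold:
                        parent[find(gi)] = find(gj)
        clusters: dict[str, list[str]] = {}
        for g in ids:
            clusters.setdefault(find(g), []).append(g)
        for members in clusters.values():
            if len(members) < 2:
                continue
            members = sorted(members)
            new_id = "+".join(members)
            merged_tpm.loc[new_id] = merged_tpm.loc[members].sum(axis=0)
            merged_counts.loc[new_id] = merged_counts.loc[members].sum(axis=0)
            merged_ann.loc[new_id] = merged_ann.loc[members[0]]
            merged_ann.loc[new_id, "functional"] = bool(
                merged_ann.loc[members, "functional"].any())
            merged_tpm = merged_tpm.drop(index=members)
            merged_counts = merged_counts.drop(index=members)
            merged_ann = merged_ann.drop(index=members)
    return ExpressionTable(tpm=merged_tpm, counts=merged_counts,
                           meta=table.meta, annotations=merged_ann)


def pair_focal(table: ExpressionTable,
               combination: Optional[tuple[str, str]] = None) -> pd.DataFrame:
    """Per-sample (FLS total TPM, DFR total TPM) pairs with a type tag.

    Totals sum the TPM of functional FLS/DFR rows of the sample's species;
    with ``combination`` = (FLS type, DFR type) only rows of those types
    contribute, and species lacking the combination yield an empty result
    rather than an error.  Samples of species lacking a functional member
    of either family are excluded with a warning.
    """
    ann = table.annotations
    rows = []
    for sid in table.tpm.columns:
        species = table.meta.loc[sid, "species"]
        sel = ann[(ann["species"] == species) & ann["functional"]]
        fls = sel[sel["family"] == "FLS"]
        dfr = sel[sel["family"] == "DFR"]
        if combination is not None:
            fls = fls[fls["type_label"] == combination[0]]
            dfr = dfr[dfr["type_label"] == combination[1]]
        if fls.empty or dfr.empty:
            if combination is None:
                log.warning(
                    "sample %r (%s) lacks a functional FLS or DFR; excluded",
                    sid, species)
            continue
        f = float(table.tpm.loc[fls.index, sid].sum())
        d = float(table.tpm.loc[dfr.index, sid].sum())
        tag = ("/".join(sorted(set(fls["type_label"]))),
               "/".join(sorted(set(dfr["type_label"]))))
        rows.append({"sample_id": sid, "species": species,
                     "organ": table.meta.loc[sid, "organ"],
                     "fls_tpm": f, "dfr_tpm": d,
                     "fls_type": tag[0], "dfr_type": tag[1]})
    return pd.DataFrame(rows, columns=["sample_id", "species", "organ",
                                       "fls_tpm", "dfr_tpm",
                                       "fls_type", "dfr_type"])


def exclusivity_index(pairs: Sequence[tuple[float, float]],
                      min_total_tpm: float = 1.0) -> tuple[float, int]:
    """Median of |F - D| / (F + D) over samples passing the detection floor.

    Returns (index, n_used).  Invariant under swapping the two genes and
    under scaling all TPM by a positive constant (floor scaled likewise).
    Raises if no sample passes the filter.
    """
    if min_total_tpm <= 0:
        raise ValueError("min_total_tpm must be positive")
    ratios = []
    for f, d in pairs:
        if f < 0 or d < 0:
            raise ValueError("TPM values must be non-negative")
        if f + d >= min_total_tpm:
            ratios.append(abs(f - d) / (f + d))
    if not ratios:
        raise ValueError("no sample passes the expression filter")
    return float(np.median(ratios)), len(ratios)


def density_grid(pairs: Sequence[tuple[float, float]], bins: int = 30,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                            np.ndarray, np.ndarray]:
    """2D histogram over log10(TPM + 1) axes plus marginal histograms.

    FLS is the first (row) axis, DFR the second.  Returns
    (grid, f_edges, d_edges, f_marginal, d_marginal); the grid total
    equals the number of pairs and the marginals are its row/column sums.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    f = np.log10(np.asarray([p[0] for p in pairs], dtype=float) + 1.0)
    d = np.log10(np.asarray([p[1] for p in pairs], dtype=float) + 1.0)
    hi = max(f.max(initial=0.0), d.max(initial=0.0))
    edges = np.linspace(0.0, hi + 1e-9, bins + 1)
    grid, f_edges, d_edges = np.histogram2d(f, d, bins=[edges, edges])
    return grid, f_edges, d_edges, grid.sum(axis=1), grid.sum(axis=0)


@dataclass
class ExclusivityResult:
    """Exclusivity index plus the density grid behind the visualization."""

    pairs: pd.DataFrame
    index: float
    n_used: int
    grid: np.ndarray
    f_edges: np.ndarray
    d_edges: np.ndarray
    f_marginal: np.ndarray
    d_marginal: np.ndarray
    min_total_tpm: float

    def __post_init__(self) -> None:
        if not 0 <= self.index <= 1:
            raise ValueError("exclusivity index must lie in [0, 1]")


def analyze_exclusivity(pairs_df: pd.DataFrame, bins: int = 30,
                        min_total_tpm: float = 1.0) -> ExclusivityResult:
    pairs = list(zip(pairs_df["fls_tpm"], pairs_df["dfr_tpm"]))
    index, n_used = exclusivity_index(pairs, min_total_tpm)
    retained = [(f, d) for f, d in pairs if f + d >= min_total_tpm]
    grid, fe, de, fm, dm = density_grid(retained, bins)
    return ExclusivityResult(pairs=pairs_df, index=index, n_used=n_used,
                             grid=grid, f_edges=fe, d_edges=de,
                             f_marginal=fm, d_marginal=dm,
                             min_total_tpm=min_total_tpm)


def plot_density(result: ExclusivityResult, path: str | Path,
                 title: str = "") -> None:
    """Heatmap of the density grid with marginal histograms.

    Color is log-scaled with a pseudocount of 1 (log10(count + 1)).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 6))
    gs = fig.add_gridspec(2, 2, width_ratios=(4, 1), height_ratios=(1, 4),
                          hspace=0.05, wspace=0.05)
    ax = fig.add_subplot(gs[1, 0])
    ax_top = fig.add_subplot(gs[0, 0], sharex=ax)
    ax_right = fig.add_subplot(gs[1, 1], sharey=ax)

    img = np.log10(result.grid.T + 1.0)
    mesh = ax.pcolormesh(result.f_edges, result.d_edges, img, cmap="viridis")
    ax.set_xlabel("log10(FLS TPM + 1)")
    ax.set_ylabel("log10(DFR TPM + 1)")
    centers_f = 0.5 * (result.f_edges[:-1] + result.f_edges[1:])
    centers_d = 0.5 * (result.d_edges[:-1] + result.d_edges[1:])
    ax_top.bar(centers_f, result.f_marginal,
               width=np.diff(result.f_edges), color="#777777")
    ax_right.barh(centers_d, result.d_marginal,
                  height=np.diff(result.d_edges), color="#777777")
    ax_top.tick_params(labelbottom=False)
    ax_right.tick_params(labelleft=False)
    fig.colorbar(mesh, ax=ax_right, label="log10(count + 1)")
    label = title or (f"exclusivity index (artifact-defined) = "
                      f"{result.index:.3f}, n = {result.n_used}")
    ax_top.set_title(label, fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
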