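"""Neighbor-joining phylogenetics with bootstrap support and type annotation.

Distances are protein p-distances (proportion of differing residues over
compared columns, optionally with pairwise deletion of gapped columns).
Trees are built with the Saitou-Nei neighbor-joining agglomeration; ties
in the Q matrix are broken by the smallest (i, j) label-index pair and
negative branch lengths are clamped to zero with the deficit moved to the
sister edge, so results are fully deterministic.  Bootstrap support is the
percentage of column-resampled replicates whose NJ tree contains each
internal bipartition of the full-data tree.

Trees are dendropy objects throughout, so newick I/O and downstream
manipulation use the standard library for the format.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np

from .residue_typing import TYPE_LABELS, TypingResult

__all__ = [
    "DistanceMatrix",
    "pdistance",
    "neighbor_joining",
    "bootstrap_support",
    "annotate_tree",
    "clade_type_summary",
    "tree_bipartitions",
    "leaf_path_distance",
    "TYPE_COLORS",
    "write_distance_matrix",
]

log = logging.getLogger(__name__)

#: stable, injective color code per type label (iTOL strip colors)
TYPE_COLORS: dict[str, str] = {
    "DFR_N": "#b39ddb",
    "DFR_D": "#7986cb",
    "DFR_A": "#4a148c",
    "DFR_other": "#9e9e9e",
    "FLS_H": "#fff176",
    "FLS_F": "#ef6c00",
    "FLS_Y": "#c8a200",
    "FLS_other": "#757575",
    "absent": "#bdbdbd",
    "untyped": "#000000",
}


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("labels must be unique")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def pdistance(labels: Sequence[str], msa: Sequence[str],
              pairwise_deletion: bool = True) -> DistanceMatrix:
    """Proportion of differing residues between each pair of aligned rows.

    With ``pairwise_deletion`` a column is skipped for a pair when either
    row has a gap there.  A pair with no comparable columns is an error.
    """
    n = len(labels)
    if n != len(msa):
        raise ValueError("labels and alignment rows differ in number")
    ncol = len(msa[0])
    if any(len(row) != ncol for row in msa):
        raise ValueError("alignment rows have unequal lengths")
    arr = np.array([list(row) for row in msa])
    gaps = arr == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_deletion:
                keep = ~(gaps[i] | gaps[j])
            else:
                keep = np.ones(ncol, dtype=bool)
            if not keep.any():
                raise ValueError(
                    f"no comparable columns between {labels[i]!r} and "
                    f"{labels[j]!r}"
                )
            d[i, j] = d[j, i] = np.mean(arr[i, keep] != arr[j, keep])
    return DistanceMatrix(list(labels), d)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining over a distance matrix (>= 3 labels).

    The final three lineages are joined at an unresolved root with
    closed-form branch lengths, giving the conventional unrooted NJ tree.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 labels")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes.append(node)
    d = dm.d.copy()
    active = list(range(n))  # indices into d / nodes, in label order

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        row_sums = sub.sum(axis=1)
        q = (r - 2) * sub - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest (i, j) pair wins ties: scan in index order
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if best is None or q[a, b] < q[best[0], best[1]] - 1e-12:
                    best = (a, b)
        a, b = best
        ia, ib = active[a], active[b]
        dij = sub[a, b]
        va = 0.5 * dij + (row_sums[a] - row_sums[b]) / (2 * (r - 2))
        vb = dij - va
        # clamp negatives, transferring the deficit to the sister edge
        if va < 0:
            vb = dij
            va = 0.0
        elif vb < 0:
            va = dij
            vb = 0.0
        parent = dendropy.Node()
        na, nb = nodes[ia], nodes[ib]
        na.edge.length = va
        nb.edge.length = vb
        parent.add_child(na)
        parent.add_child(nb)
        # distances from the new node to the remaining taxa
        new_d = 0.5 * (d[ia, :] + d[ib, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        k = d.shape[0] - 1
        active = [x for x in active if x not in (ia, ib)] + [k]

    # closed-form star resolution of the last three lineages
    ia, ib, ic = active
    dab, dac, dbc = d[ia, ib], d[ia, ic], d[ib, ic]
    root = dendropy.Node()
    lengths = {
        ia: 0.5 * (dab + dac - dbc),
        ib: 0.5 * (dab + dbc - dac),
        ic: 0.5 * (dac + dbc - dab),
    }
    for idx in (ia, ib, ic):
        node = nodes[idx]
        node.edge.length = max(lengths[idx], 0.0)
        root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as canonical frozensets of leaf labels.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically first leaf is the canonical representation.
    """
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    first = min(leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(leaves) - len(side) < 2:
            continue
        if first in side:
            side = frozenset(leaves - side)
        out.add(side)
    return out


def leaf_path_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return pdm.patristic_distance(ta, tb)


def bootstrap_support(labels: Sequence[str], msa: Sequence[str],
                      n_reps: int, seed: int,
                      pairwise_deletion: bool = True,
                      ) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree on the full alignment plus bootstrap support per bipartition.

    Columns are resampled with replacement ``n_reps`` times; support is the
    percentage of replicate NJ trees containing each bipartition of the
    full-data tree.  Deterministic given ``seed``.  Supports are written
    onto the internal node labels of the returned tree.
    """
    if n_reps <= 0:
        raise ValueError("n_reps must be positive")
    ncol = len(msa[0])
    tree = neighbor_joining(pdistance(labels, msa, pairwise_deletion))
    target = tree_bipartitions(tree)
    counts: dict[frozenset, int] = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    rows = [np.array(list(r)) for r in msa]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_msa = ["".join(row[cols]) for row in rows]
        try:
            rep_tree = neighbor_joining(
                pdistance(labels, rep_msa, pairwise_deletion))
        except ValueError:
            continue  # replicate with no comparable columns for some pair
        rep_bps = tree_bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    support = {bp: 100.0 * c / n_reps for bp, c in counts.items()}

    leaves_all = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    first = min(leaves_all)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if first in side:
            side = frozenset(leaves_all - side)
        if side in support:
            node.label = f"{support[side]:g}"
    return tree, support


# ---------------------------------------------------------------------------
# annotation

def annotate_tree(tree: dendropy.Tree,
                  typing: Sequence[TypingResult],
                  ) -> tuple[dendropy.Tree, str]:
    """Label tree leaves with their type and emit an iTOL color-strip file.

    Returns a cloned tree whose leaf labels carry a ``|type`` suffix (the
    input tree, its topology and branch lengths are untouched) and the
    text of an iTOL COLORSTRIP dataset (leaf id, hex color, type label).
    Typing results for ids not present in the tree are ignored with a
    warning; leaves without a result are labeled 'untyped'.
    """
    by_id = {r.seq_id: r for r in typing}
    leaf_labels = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for seq_id in by_id:
        if seq_id not in leaf_labels:
            log.warning("typing result for %r matches no tree leaf; ignored",
                        seq_id)

    annotated = tree.clone(depth=1)
    annotated.taxon_namespace = dendropy.TaxonNamespace()
    strip_rows = []
    for leaf in annotated.leaf_node_iter():
        base = leaf.taxon.label
        label = by_id[base].type_label if base in by_id else "untyped"
        strip_rows.append((base, TYPE_COLORS[label], label))
        leaf.taxon = dendropy.Taxon(label=f"{base}|{label}")
        annotated.taxon_namespace.add_taxon(leaf.taxon)

    lines = [
        "DATASET_COLORSTRIP",
        "SEPARATOR TAB",
        "DATASET_LABEL\tsubstrate-preference type",
        "COLOR\t#888888",
        "DATA",
    ]
    lines += [f"{lid}\t{color}\t{lab}" for lid, color, lab in strip_rows]
    return annotated, "\n".join(lines) + "\n"


def clade_type_summary(tree: dendropy.Tree,
                       annotations: dict[str, str],
                       ) -> tuple[list[dict], dict[str, bool]]:
    """Per-clade type counts and a monophyly verdict per type.

    ``annotations`` maps leaf label -> type label.  A type is monophyletic
    iff some node's subtree contains exactly the leaves of that type
    (single-leaf types are monophyletic by definition).  Returns
    (clade rows, {type: monophyletic}).
    """
    type_leaves: dict[str, set[str]] = {}
    for leaf, label in annotations.items():
        type_leaves.setdefault(label, set()).add(leaf)

    clades = []
    subtree_sets = []
    for idx, node in enumerate(tree.preorder_internal_node_iter()):
        leaves = {l.taxon.label for l in node.leaf_iter()}
        subtree_sets.append(leaves)
        counts: dict[str, int] = {}
        for leaf in leaves:
            if leaf in annotations:
                lab = annotations[leaf]
                counts[lab] = counts.get(lab, 0) + 1
        clades.append({"clade": idx, "n_leaves": len(leaves),
                       "type_counts": counts})

    monophyly = {}
    for label, members in type_leaves.items():
        monophyly[label] = (len(members) == 1
                            or any(members == s for s in subtree_sets))
    return clades, monophyly


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """PHYLIP-style square distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.labels)}\n")
        for label, row in zip(dm.labels, dm.d):
            fh.write(label + "\t" + "\t".join(f"{x:.6f}" for x in row) + "\n")
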