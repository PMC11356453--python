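from __future__ import annotations

import dendropy
import numpy as np
import pytest

from flavotype.phylo import (TYPE_COLORS, DistanceMatrix, annotate_tree,
                             bootstrap_support, clade_type_summary,
                             leaf_path_distance, neighbor_joining, pdistance,
                             tree_bipartitions)
from flavotype.seqio import read_newick

from _oracles import quartet_ls_topology


def random_additive_tree(rng, n):
    """Random binary topology with uniform(0.1, 1) edges; returns
    (labels, distance matrix, bipartition set)."""
    labels = [f"t{i}" for i in range(n)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nd.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(nd)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.1, 1.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [nodes[k] for k in range(len(nodes))
                 if k not in (i, j)] + [parent]
    root = dendropy.Node()
    for nd in nodes:
        root.add_child(nd)
    tree.seed_node = root
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                d[a, b] = pdm.patristic_distance(tns.get_taxon(labels[a]),
                                                 tns.get_taxon(labels[b]))
    return labels, d, tree_bipartitions(tree)


# ---------------------------------------------------------------------------
# p-distance

def test_pdistance_basic_arithmetic():
    dm = pdistance(["a", "b"], ["AAAAAAAAAA", "AACCAAAAAA"])
    assert dm.d[0, 1] == pytest.approx(0.2)
    dm2 = pdistance(["a", "b"], ["AAAA", "AAAA"])
    assert dm2.d[0, 1] == 0


def test_pdistance_pairwise_deletion_skips_gaps():
    dm = pdistance(["a", "b"], ["AA--AA", "AACCCA"], pairwise_deletion=True)
    # compared columns: 0,1,4,5 -> one mismatch (col 4)
    assert dm.d[0, 1] == pytest.approx(0.25)


def test_pdistance_no_comparable_columns():
    with pytest.raises(ValueError, match="comparable"):
        pdistance(["a", "b"], ["A--", "-AA"])


# ---------------------------------------------------------------------------
# neighbor joining

def test_nj_requires_three_labels():
    with pytest.raises(ValueError):
        neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


def test_nj_three_taxa_closed_form():
    d = np.array([[0.0, 0.3, 0.5],
                  [0.3, 0.0, 0.6],
                  [0.5, 0.6, 0.0]])
    tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
    assert leaf_path_distance(tree, "a", "b") == pytest.approx(0.3)
    assert leaf_path_distance(tree, "a", "c") == pytest.approx(0.5)
    assert leaf_path_distance(tree, "b", "c") == pytest.approx(0.6)


def test_nj_quartet_matches_least_squares_oracle(rng):
    """On additive quartets NJ agrees with exhaustive least-squares fitting."""
    for _ in range(10):
        labels, d, _ = random_additive_tree(rng, 4)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        bps = tree_bipartitions(tree)
        assert len(bps) == 1
        cherry = next(iter(bps))
        oracle_cherry = quartet_ls_topology(labels, d)
        assert cherry in (oracle_cherry,
                          frozenset(labels) - oracle_cherry)


def test_nj_recovers_additive_six_taxon_topologies(rng):
    for _ in range(20):
        labels, d, true_bps = random_additive_tree(rng, 6)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        assert tree_bipartitions(tree) == true_bps
        for a in range(6):
            for b in range(a + 1, 6):
                assert leaf_path_distance(tree, labels[a], labels[b]) == \
                    pytest.approx(d[a, b], abs=1e-9)


def test_nj_agrees_with_skbio_on_topology(rng):
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    labels, d, _ = random_additive_tree(rng, 8)
    ours = tree_bipartitions(neighbor_joining(DistanceMatrix(labels, d)))
    sk_tree = skbio_nj(SkbioDM(d, ids=labels))
    sk_newick = sk_tree.__str__()
    import io
    dtree = dendropy.Tree.get(data=sk_newick, schema="newick")
    theirs = tree_bipartitions(dtree)
    assert ours == theirs


def test_nj_branch_lengths_non_negative(rng):
    # noisy (non-additive) matrices can produce negative NJ estimates,
    # which must be clamped
    for _ in range(10):
        labels, d, _ = random_additive_tree(rng, 6)
        noise = rng.uniform(0, 0.05, size=d.shape)
        noisy = d + noise + noise.T
        np.fill_diagonal(noisy, 0)
        tree = neighbor_joining(DistanceMatrix(labels, noisy))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


# ---------------------------------------------------------------------------
# bootstrap

def _two_block_msa(rng, n_per_block=5, n_diag=50, n_noise=30):
    base = rng.integers(0, 20, size=n_diag + n_noise)
    other = base.copy()
    other[:n_diag] = (other[:n_diag] + 10) % 20
    AA = "ACDEFGHIKLMNPQRSTVWY"
    labels, rows = [], []
    for blk, template in enumerate((base, other)):
        for k in range(n_per_block):
            r = template.copy()
            m = rng.random(len(r)) < 0.05
            r[m] = rng.integers(0, 20, size=m.sum())
            labels.append(f"b{blk}_{k}")
            rows.append("".join(AA[x] for x in r))
    return labels, rows


def test_bootstrap_support_of_diagnostic_split():
    for seed in range(5):
        labels, rows = _two_block_msa(np.random.default_rng(100 + seed))
        tree, support = bootstrap_support(labels, rows, 100, seed)
        split = frozenset(l for l in labels if l.startswith("b1"))
        assert support[split] >= 95


def test_bootstrap_deterministic_given_seed():
    labels, rows = _two_block_msa(np.random.default_rng(0))
    _, s1 = bootstrap_support(labels, rows, 50, seed=42)
    _, s2 = bootstrap_support(labels, rows, 50, seed=42)
    assert s1 == s2
    assert all(0 <= v <= 100 for v in s1.values())


def test_bootstrap_rejects_zero_reps():
    labels, rows = _two_block_msa(np.random.default_rng(0))
    with pytest.raises(ValueError):
        bootstrap_support(labels, rows, 0, seed=1)


# ---------------------------------------------------------------------------
# annotation

def _typed(seq_id, label):
    from flavotype.residue_typing import TypingResult
    residue = None if label == "absent" else label[-1]
    return TypingResult(seq_id=seq_id, family="DFR", anchor_residue=residue,
                        type_label=label, substrate_set=frozenset(),
                        confidence="none", functional=True)


def test_annotate_tree_labels_and_preserves_topology(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:2):1,(c:1,d:1):3);\n")
    tree = read_newick(p)
    before_bps = tree_bipartitions(tree)
    before_len = leaf_path_distance(tree, "a", "b")
    results = [_typed("a", "DFR_N"), _typed("b", "DFR_N"),
               _typed("c", "DFR_A"), _typed("x", "DFR_D")]
    annotated, itol = annotate_tree(tree, results)
    # original untouched
    assert tree_bipartitions(tree) == before_bps
    assert leaf_path_distance(tree, "a", "b") == before_len
    leaf_labels = {l.taxon.label for l in annotated.leaf_node_iter()}
    assert leaf_labels == {"a|DFR_N", "b|DFR_N", "c|DFR_A", "d|untyped"}
    assert "DATASET_COLORSTRIP" in itol
    assert f"c\t{TYPE_COLORS['DFR_A']}\tDFR_A" in itol


def test_type_color_map_is_injective():
    assert len(set(TYPE_COLORS.values())) == len(TYPE_COLORS)


def test_clade_type_summary_monophyly(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:1):1,(c:1,d:1):1);\n")
    tree = read_newick(p)
    _, mono = clade_type_summary(tree, {"a": "DFR_A", "b": "DFR_A",
                                        "c": "DFR_N", "d": "DFR_N"})
    assert mono == {"DFR_A": True, "DFR_N": True}

    p2 = tmp_path / "t2.nwk"
    p2.write_text("((a:1,c:1):1,(b:1,d:1):1);\n")
    tree2 = read_newick(p2)
    _, mono2 = clade_type_summary(tree2, {"a": "DFR_A", "b": "DFR_A",
                                          "c": "DFR_N", "d": "DFR_N"})
    assert mono2 == {"DFR_A": False, "DFR_N": False}


def test_clade_type_summary_singleton_monophyletic(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((a:1,b:1):1,c:1);\n")
    tree = read_newick(p)
    _, mono = clade_type_summary(tree, {"a": "DFR_N", "b": "DFR_N",
                                        "c": "DFR_A"})
    assert mono["DFR_A"] is True
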