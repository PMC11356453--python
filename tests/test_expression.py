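from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flavotype.expression import (SampleMeta, aggregate_paralogs,
                                  analyze_exclusivity, annotate_genes,
                                  density_grid, exclusivity_index,
                                  merge_samples, pair_focal, plot_density,
                                  protein_identity)
from flavotype.synthetic_data import (ExprSimConfig, simulate_expression)


def _table(genes, tpm):
    return pd.DataFrame({
        "target_id": genes,
        "length": 1500,
        "eff_length": 1300.0,
        "est_counts": [x * 10 for x in tpm],
        "tpm": tpm,
    }).set_index("target_id")


def _merged(sim):
    table = merge_samples(sim.tables, sim.meta)
    return annotate_genes(table, sim.typing_results)


# ---------------------------------------------------------------------------
# merging

def test_merge_samples_shape_and_order():
    genes = ["g1", "g2", "g3", "g4", "g5"]
    tables = {f"s{i}": _table(genes, [i, 0, 1, 2, 3]) for i in range(3)}
    meta = [SampleMeta(f"s{i}", "sp") for i in range(3)]
    merged = merge_samples(tables, meta)
    assert merged.tpm.shape == (5, 3)
    assert list(merged.tpm.columns) == ["s0", "s1", "s2"]


def test_merge_samples_gene_universe_mismatch():
    tables = {"s0": _table(["g1", "g2"], [1, 2]),
              "s1": _table(["g1", "g3"], [1, 2])}
    meta = [SampleMeta("s0", "sp"), SampleMeta("s1", "sp")]
    with pytest.raises(ValueError, match="g2|g3"):
        merge_samples(tables, meta)


def test_merge_samples_meta_mismatch_and_empty():
    tables = {"s0": _table(["g1"], [1.0])}
    with pytest.raises(ValueError, match="metadata"):
        merge_samples(tables, [])
    with pytest.raises(ValueError):
        merge_samples({}, [SampleMeta("s0", "sp")])


# ---------------------------------------------------------------------------
# paralog aggregation

def test_aggregate_paralogs_sums_close_same_residue(small_expression_sim):
    sim = small_expression_sim
    table = _merged(sim)
    before = table.tpm.loc[
        table.annotations["family"].isin(["FLS", "DFR"])].sum(axis=0)
    merged = aggregate_paralogs(table, sim.proteins, 0.8)
    after = merged.tpm.loc[
        merged.annotations["family"].isin(["FLS", "DFR"])].sum(axis=0)
    # conservation of per-sample focal totals, exactly
    pd.testing.assert_series_equal(before, after)
    # the simulated paralogs are ~95% identical with equal residues: merged
    assert (merged.annotations["family"] == "FLS").sum() == \
        sim.config.n_species


def test_aggregate_paralogs_impossible_threshold(small_expression_sim):
    sim = small_expression_sim
    table = _merged(sim)
    merged = aggregate_paralogs(table, sim.proteins, 1.01)
    assert merged.tpm.shape == table.tpm.shape


def test_aggregate_paralogs_never_merges_different_residues():
    genes = ["sp_FLS1", "sp_FLS2", "sp_other"]
    tables = {"s0": _table(genes, [10.0, 5.0, 1.0])}
    meta = [SampleMeta("s0", "sp")]
    table = merge_samples(tables, meta)
    from flavotype.residue_typing import TypingResult
    typing = [
        TypingResult("sp_FLS1", "FLS", "H", "FLS_H", frozenset(),
                     "hypothesized", True, species="sp"),
        TypingResult("sp_FLS2", "FLS", "Y", "FLS_Y", frozenset(),
                     "hypothesized", True, species="sp"),
    ]
    table = annotate_genes(table, typing)
    prot = "MKTAYHWLLNP" * 20
    merged = aggregate_paralogs(table, {"sp_FLS1": prot, "sp_FLS2": prot}, 0.8)
    assert set(merged.tpm.index) == set(genes)  # identical proteins, but
    # different anchor residues -> never merged


def test_protein_identity_bounds():
    assert protein_identity("MKTW" * 10, "MKTW" * 10) == 1.0
    assert protein_identity("MKTW" * 10, "MKTW" * 9 + "MKTA") < 1.0


# ---------------------------------------------------------------------------
# pairing and the exclusivity index

def test_pair_focal_tags_and_values(small_expression_sim):
    sim = small_expression_sim
    table = _merged(sim)
    pairs = pair_focal(table)
    assert set(pairs.columns) >= {"sample_id", "fls_tpm", "dfr_tpm",
                                  "fls_type", "dfr_type"}
    assert len(pairs) == len(sim.meta)
    truth = sim.sample_truth
    merged = pairs.set_index("sample_id").join(truth, rsuffix="_t")
    np.testing.assert_allclose(merged["fls_tpm"], merged["fls_tpm_true"],
                               rtol=1e-9)


def test_pair_focal_missing_combination_is_empty(small_expression_sim):
    table = _merged(small_expression_sim)
    pairs = pair_focal(table, combination=("FLS_F", "DFR_A"))
    assert pairs.empty


@pytest.mark.parametrize("pairs,expected", [
    ([(10, 0), (0, 7), (3, 0)], 1.0),
    ([(5, 5), (2, 2)], 0.0),
])
def test_exclusivity_index_limit_cases(pairs, expected):
    index, n = exclusivity_index(pairs, min_total_tpm=1.0)
    assert index == expected
    assert n == len(pairs)


def test_exclusivity_index_filter_and_errors():
    with pytest.raises(ValueError, match="filter"):
        exclusivity_index([(0.1, 0.2)], min_total_tpm=1.0)
    with pytest.raises(ValueError):
        exclusivity_index([(1, 1)], min_total_tpm=0)


def test_exclusivity_index_invariances(rng):
    pairs = [(float(f), float(d))
             for f, d in rng.uniform(0, 50, size=(40, 2))]
    idx, _ = exclusivity_index(pairs, 1.0)
    swapped, _ = exclusivity_index([(d, f) for f, d in pairs], 1.0)
    scaled, _ = exclusivity_index([(3 * f, 3 * d) for f, d in pairs], 3.0)
    assert idx == pytest.approx(swapped)
    assert idx == pytest.approx(scaled)


def test_exclusivity_monotone_in_rho():
    indices = []
    for rho in (0, 0.25, 0.5, 0.75, 1.0):
        sim = simulate_expression(ExprSimConfig(
            n_species=4, samples_per_species=25, rho=rho, seed=1))
        table = _merged(sim)
        pairs = pair_focal(table)
        idx, _ = exclusivity_index(
            list(zip(pairs["fls_tpm"], pairs["dfr_tpm"])), 1.0)
        indices.append(idx)
    assert indices == sorted(indices)
    assert indices[-1] >= 0.95


def test_exclusivity_rho_zero_matches_lognormal_oracle():
    """At rho=0 both genes are iid lognormal; the index must match a direct
    Monte-Carlo estimate of median |F-D|/(F+D) for two iid lognormals."""
    cfg = ExprSimConfig(n_species=10, samples_per_species=50, rho=0.0, seed=2)
    sim = simulate_expression(cfg)
    pairs = pair_focal(_merged(sim))
    idx, _ = exclusivity_index(list(zip(pairs["fls_tpm"],
                                        pairs["dfr_tpm"])), 1.0)
    oracle_rng = np.random.default_rng(123)
    f = oracle_rng.lognormal(cfg.on_mu, cfg.on_sigma, size=200_000)
    d = oracle_rng.lognormal(cfg.on_mu, cfg.on_sigma, size=200_000)
    keep = f + d >= 1.0
    oracle = np.median(np.abs(f - d)[keep] / (f + d)[keep])
    assert idx == pytest.approx(oracle, abs=0.06)


# ---------------------------------------------------------------------------
# density grid

def test_density_grid_conserves_counts(rng):
    pairs = [(float(f), float(d))
             for f, d in rng.lognormal(2, 1, size=(100, 2))]
    grid, fe, de, fm, dm = density_grid(pairs, bins=20)
    assert grid.sum() == 100
    np.testing.assert_array_equal(fm, grid.sum(axis=1))
    np.testing.assert_array_equal(dm, grid.sum(axis=0))


def test_density_grid_identical_pairs_single_cell():
    grid, *_ = density_grid([(5.0, 2.0)] * 7, bins=10)
    assert grid.sum() == 7
    assert (grid > 0).sum() == 1


def test_density_grid_swap_symmetry(rng):
    pairs = [(float(f), float(d))
             for f, d in rng.lognormal(2, 1, size=(60, 2))]
    g1, *_ = density_grid(pairs, bins=15)
    g2, *_ = density_grid([(d, f) for f, d in pairs], bins=15)
    np.testing.assert_array_equal(g2, g1.T)


def test_analyze_and_plot(tmp_path, small_expression_sim):
    pairs = pair_focal(_merged(small_expression_sim))
    result = analyze_exclusivity(pairs, bins=12)
    assert result.grid.sum() == result.n_used
    out = tmp_path / "density.png"
    plot_density(result, out)
    assert out.stat().st_size > 0
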