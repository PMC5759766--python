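"""Size factors, dispersion, NB Wald tests and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triadexpr as tx


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return tx.CountMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _triad_design(n_reps):
    genotype_of = {f"{g}_{r}": g for g in ("P1", "P2", "H")
                   for r in range(n_reps)}
    return tx.TriadDesign(genotype_of, {"P1": "parent1", "P2": "parent2",
                                        "H": "hybrid"})


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def test_size_factors_proportional_columns():
    # columns in ratio 1:2 -> factors (1/sqrt(2), sqrt(2))
    counts = _matrix([[10, 20], [35, 70], [4, 8]])
    f = tx.estimate_size_factors(counts)
    np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)


def test_size_factors_identical_columns_are_one():
    counts = _matrix(np.tile([[7], [3], [11]], (1, 4)))
    np.testing.assert_allclose(tx.estimate_size_factors(counts), 1.0)


def test_size_factors_column_scaling_equivariance():
    # scaling one column by c multiplies that factor, relative to any other
    # sample's, by exactly c (median-of-ratios equivariance)
    rng = np.random.default_rng(0)
    k = rng.poisson(50, size=(500, 6))
    f0 = tx.estimate_size_factors(_matrix(k))
    k2 = k.copy()
    k2[:, 2] *= 3
    f1 = tx.estimate_size_factors(_matrix(k2))
    ratios0 = f0.iloc[2] / f0.drop(f0.index[2])
    ratios1 = f1.iloc[2] / f1.drop(f1.index[2])
    np.testing.assert_allclose(ratios1, 3 * ratios0, rtol=1e-10)


def test_size_factors_require_all_positive_gene():
    counts = _matrix([[0, 5, 3], [4, 0, 1], [2, 7, 0]])
    with pytest.raises(tx.NormalizationError, match="pseudo_reference"):
        tx.estimate_size_factors(counts)
    f = tx.estimate_size_factors(counts, pseudo_reference=True)
    assert (f > 0).all()


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def test_dispersion_recovery_nb():
    params = tx.SimulationParams(n_genes=300, n_replicates=50, dispersion=0.1,
                                 class_fractions={"NoDiff": 1.0},
                                 baseline_mean_log_range=(3.0, 8.0), seed=17)
    counts, design, _ = tx.simulate_triad_counts(params)
    disp = tx.estimate_dispersion(counts, design)
    assert 0.08 <= disp.median() <= 0.12


def test_dispersion_recovery_poisson():
    params = tx.SimulationParams(n_genes=300, n_replicates=50, dispersion=0.0,
                                 class_fractions={"NoDiff": 1.0},
                                 baseline_mean_log_range=(3.0, 8.0), seed=19)
    counts, design, _ = tx.simulate_triad_counts(params)
    assert tx.estimate_dispersion(counts, design).median() <= 0.01


def test_dispersion_constant_gene_gets_floor():
    counts = _matrix(np.full((1, 6), 5),
                     samples=[f"{g}_{r}" for g in ("P1", "P2", "H")
                              for r in range(2)])
    disp = tx.estimate_dispersion(counts, _triad_design(2))
    assert disp.iloc[0] == pytest.approx(1e-8)


# ---------------------------------------------------------------------------
# Two-group Wald test
# ---------------------------------------------------------------------------

def test_wald_identical_groups_give_null_result():
    values = np.tile([[8, 12, 10]], (4, 1))
    counts = _matrix(np.hstack([values, values, values]),
                     samples=[f"{g}_{r}" for g in ("P1", "P2", "H")
                              for r in range(3)])
    res = tx.nb_wald_test(counts, _triad_design(3), "P1", "H")
    assert np.allclose(res["log2fc"], 0.0)
    assert (res["p_raw"] >= 0.99).all()
    assert not res["significant"].any()


def test_wald_antisymmetry_exact(strong_sim):
    _, counts, design, _ = strong_sim
    sf = tx.estimate_size_factors(counts)
    disp = tx.estimate_dispersion(counts, design, sf)
    ab = tx.nb_wald_test(counts, design, "P1", "H", sf, disp)
    ba = tx.nb_wald_test(counts, design, "H", "P1", sf, disp)
    np.testing.assert_array_equal(ab["log2fc"], -ba["log2fc"])
    np.testing.assert_array_equal(ab["stat"].dropna(), -ba["stat"].dropna())
    np.testing.assert_array_equal(ab["p_raw"], ba["p_raw"])
    np.testing.assert_array_equal(ab["p_adj"], ba["p_adj"])


def test_wald_power_fourfold_two_replicates():
    params = tx.SimulationParams(n_genes=2000, n_replicates=2,
                                 class_fractions={"HPD": 1.0},
                                 dispersion=0.05, seed=23)
    counts, design, _ = tx.simulate_triad_counts(params)
    res = tx.nb_wald_test(counts, design, "P1", "P2")
    # regression baseline: ~0.9 observed for 4-fold planted parent gaps
    assert res["significant"].mean() >= 0.80


def test_wald_unknown_genotype_is_design_error(strong_sim):
    _, counts, design, _ = strong_sim
    with pytest.raises(tx.DesignError):
        tx.nb_wald_test(counts, design, "P1", "nope")


def test_all_zero_genes_reported_untested():
    values = np.array([[0] * 6, [5, 6, 4, 7, 5, 6]])
    counts = _matrix(values,
                     samples=[f"{g}_{r}" for g in ("P1", "P2", "H")
                              for r in range(2)])
    res = tx.nb_wald_test(counts, _triad_design(2), "P1", "H")
    assert not res["tested"].iloc[0]
    assert np.isnan(res["p_adj"].iloc[0])
    assert res["tested"].iloc[1]


# ---------------------------------------------------------------------------
# Mid-parent contrast
# ---------------------------------------------------------------------------

def _unit_factors(counts):
    # the matrices below are single-class by construction, which violates
    # the non-DE-majority assumption of median-of-ratios; the simulation's
    # true factors are 1
    return pd.Series(1.0, index=counts.sample_ids)


def test_midparent_null_false_positive_rate():
    # hybrid planted exactly at mid-parent: padj calls are rare
    params = tx.SimulationParams(n_genes=2000, n_replicates=3,
                                 class_fractions={"AD": 1.0},
                                 baseline_mean_log_range=(4.0, 8.0), seed=29)
    counts, design, _ = tx.simulate_triad_counts(params)
    res = tx.midparent_test(counts, design, size_factors=_unit_factors(counts))
    assert res["significant"].mean() <= 0.05


def test_midparent_power_strong_signal():
    # overdominant hybrids sit 6.4-fold above the mid-parent value
    params = tx.SimulationParams(n_genes=1000, n_replicates=3,
                                 class_fractions={"OD": 1.0}, seed=31)
    counts, design, _ = tx.simulate_triad_counts(params)
    res = tx.midparent_test(counts, design, size_factors=_unit_factors(counts))
    assert res["significant"].mean() >= 0.80


def test_midparent_geometric_option(strong_sim):
    _, counts, design, _ = strong_sim
    res = tx.midparent_test(counts, design, midparent="geometric")
    assert res["p_raw"].dropna().between(0, 1).all()
    with pytest.raises(tx.ParameterError):
        tx.midparent_test(counts, design, midparent="harmonic")


# ---------------------------------------------------------------------------
# Null calibration of raw p-values (uniformity)
# ---------------------------------------------------------------------------

def test_null_p_uniform_for_well_expressed_genes(null_sim):
    _, counts, design, truth = null_sim
    contrasts = tx.triad_contrasts(counts, design)
    well = (truth.table["mu_p1"] > 50).to_numpy()
    for key in ("hp1", "mid"):
        p = contrasts[key]["p_raw"].to_numpy()[well]
        assert stats.kstest(p, "uniform").statistic < 0.02


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_stepup_bruteforce(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj


def test_bh_hand_example():
    np.testing.assert_allclose(tx.adjust_bh([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04], rtol=1e-12)


def test_bh_single_p_unchanged():
    np.testing.assert_allclose(tx.adjust_bh([0.37]), [0.37])


def test_bh_matches_bruteforce_and_is_monotone():
    rng = np.random.default_rng(12)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        p = rng.random(n)
        adj = tx.adjust_bh(p)
        np.testing.assert_allclose(adj, bh_stepup_bruteforce(list(p)),
                                   rtol=1e-12)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(adj[order]) >= -1e-15).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(tx.ParameterError):
        tx.adjust_bh([0.1, 1.2])
    with pytest.raises(tx.ParameterError):
        tx.adjust_bh([-0.1])
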