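"""Generator: planted structure, seeded determinism, moment behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import triadexpr as tx
from triadexpr.synthetic import CLASSES


def test_seeded_determinism():
    params = tx.SimulationParams(n_genes=300, n_replicates=3, seed=42)
    a = tx.simulate_triad_counts(params)
    b = tx.simulate_triad_counts(params)
    assert a[0].df.equals(b[0].df)
    assert a[2].table.equals(b[2].table)


def test_gene_streams_stable_under_growth():
    small = tx.SimulationParams(n_genes=50, seed=3)
    large = tx.SimulationParams(n_genes=120, seed=3)
    ca, _, ta = tx.simulate_triad_counts(small)
    cb, _, tb = tx.simulate_triad_counts(large)
    np.testing.assert_array_equal(ca.values, cb.values[:50])
    assert ta.table["planted_class"].tolist() == \
        tb.table["planted_class"].iloc[:50].tolist()


def test_poisson_limit_variance_mean_ratio():
    # dispersion 0 degenerates to Poisson: replicate var/mean ratio near 1
    params = tx.SimulationParams(n_genes=1000, n_replicates=10, dispersion=0.0,
                                 class_fractions={"NoDiff": 1.0}, seed=11)
    counts, design, _ = tx.simulate_triad_counts(params)
    cols = [counts.sample_ids.get_loc(s) for s in design.samples_of("P1")]
    sub = counts.values[:, cols].astype(float)
    ratio = sub.var(axis=1, ddof=1) / sub.mean(axis=1)
    assert abs(ratio.mean() - 1.0) < 0.05


def test_overdominance_construction():
    params = tx.SimulationParams(n_genes=100, class_fractions={"OD": 1.0},
                                 od_ud_log2fc=2.0, seed=5)
    _, _, truth = tx.simulate_triad_counts(params)
    t = truth.table
    np.testing.assert_allclose(
        t["mu_h"], 4.0 * np.maximum(t["mu_p1"], t["mu_p2"]), rtol=0)


@pytest.mark.parametrize("klass", CLASSES)
def test_planted_means_consistent_per_class(klass):
    params = tx.SimulationParams(n_genes=60, class_fractions={klass: 1.0},
                                 seed=8)
    _, _, truth = tx.simulate_triad_counts(params)
    assert (truth.table["planted_class"] == klass).all()
    truth.check_consistency()


def test_high_parent_assignment_balanced():
    # which parent is the high one must not depend on the label
    params = tx.SimulationParams(n_genes=800, class_fractions={"HPD": 1.0},
                                 seed=13)
    _, _, truth = tx.simulate_triad_counts(params)
    p1_high = (truth.table["mu_p1"] > truth.table["mu_p2"]).mean()
    assert 0.4 < p1_high < 0.6


def test_empirical_means_converge_with_replicates():
    sf = np.tile([0.5, 1.0, 2.0], 200)  # per-sample library factors
    params = tx.SimulationParams(n_genes=50, n_replicates=200,
                                 baseline_mean_log_range=(3.0, 8.0),
                                 library_size_factors=sf, seed=21)
    counts, design, truth = tx.simulate_triad_counts(params)
    sf_by_sample = pd.Series(sf, index=counts.sample_ids)
    for role, col in (("parent1", "mu_p1"), ("hybrid", "mu_h")):
        geno = design.genotype_for_role(role)
        samples = design.samples_of(geno)
        expected = np.outer(truth.table[col], sf_by_sample[samples])
        observed = counts.df[samples].to_numpy()
        rel = np.abs(observed.mean(axis=1) - expected.mean(axis=1)) \
            / expected.mean(axis=1)
        assert rel.max() < 0.05


def test_invalid_params_name_offending_field():
    with pytest.raises(tx.ParameterError, match="n_genes"):
        tx.SimulationParams(n_genes=0)
    with pytest.raises(tx.ParameterError, match="class_fractions"):
        tx.SimulationParams(class_fractions={"NoDiff": 0.5})
    with pytest.raises(tx.ParameterError, match="dispersion"):
        tx.SimulationParams(dispersion=-0.1)
    with pytest.raises(tx.ParameterError, match="library_size_factors"):
        tx.SimulationParams(n_replicates=2, library_size_factors=[1.0] * 5)


# ---------------------------------------------------------------------------
# Annotation simulation
# ---------------------------------------------------------------------------

def test_annotation_uniform_within_binomial_bounds():
    params = tx.SimulationParams(n_genes=2000, seed=2)
    _, _, truth = tx.simulate_triad_counts(params)
    pairs = tx.simulate_annotation(truth, n_terms=15, seed=9,
                                   background_prob=0.05)
    sizes = pairs["term"].value_counts()
    lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.05)
    for term in sizes.index:
        assert lo <= sizes[term] <= hi


def test_annotation_unplanted_fold_enrichment_near_one():
    params = tx.SimulationParams(n_genes=3000, seed=4)
    _, _, truth = tx.simulate_triad_counts(params)
    pairs = tx.simulate_annotation(
        truth, n_terms=10, enriched_term_spec=[("T_flat", "OD", 1.0)], seed=6)
    ann = tx.AnnotationMap.from_pairs(pairs, universe=truth.table.index)
    table = tx.enrich_terms(truth.genes_in_class("OD"), ann)
    fe = table.set_index("term").loc["T_flat", "fold_enrichment"]
    assert 0.6 < fe < 1.5


def test_annotation_rejects_bad_spec():
    params = tx.SimulationParams(n_genes=100, seed=1)
    _, _, truth = tx.simulate_triad_counts(params)
    with pytest.raises(tx.ParameterError, match="unknown class"):
        tx.simulate_annotation(truth, 5, [("T1", "XX", 2.0)])
    with pytest.raises(tx.ParameterError, match="factor"):
        tx.simulate_annotation(truth, 5, [("T1", "NoDiff", 0.5)])


# ---------------------------------------------------------------------------
# qPCR simulation
# ---------------------------------------------------------------------------

def test_qpcr_zero_cv_reproduces_planted_means():
    params = tx.SimulationParams(n_genes=50, class_fractions={"OD": 1.0},
                                 seed=3)
    _, _, truth = tx.simulate_triad_counts(params)
    genes = list(truth.table.index[:5])
    long = tx.simulate_qpcr(truth, genes, cv=0.0, n_replicates=3, seed=0)
    for gene in genes:
        mu = truth.table.loc[gene]
        expected = {"P1": 1.0,
                    "P2": mu["mu_p2"] / mu["mu_p1"],
                    "H": mu["mu_h"] / mu["mu_p1"]}
        sub = long[long["gene"] == gene]
        for geno, vals in sub.groupby("genotype"):
            np.testing.assert_allclose(vals["value"], expected[str(geno)])


def test_qpcr_seeded_determinism_and_cv():
    params = tx.SimulationParams(n_genes=20, class_fractions={"HPD": 1.0},
                                 seed=7)
    _, _, truth = tx.simulate_triad_counts(params)
    genes = list(truth.table.index[:3])
    a = tx.simulate_qpcr(truth, genes, cv=0.1, n_replicates=200, seed=5)
    b = tx.simulate_qpcr(truth, genes, cv=0.1, n_replicates=200, seed=5)
    assert a.equals(b)
    g = a[(a["gene"] == genes[0]) & (a["genotype"] == "H")]["value"]
    assert abs(g.std(ddof=1) / g.mean() - 0.1) < 0.03
    assert (a["value"] > 0).all()
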