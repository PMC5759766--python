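import numpy as np
import pandas as pd
import pytest

import triadexpr as tx


@pytest.fixture(scope="session")
def strong_sim():
    """Default strong-effect simulation: 4-fold parent gap, 4-fold OD/UD
    excess, dispersion 0.05, 3 replicates, 5000 genes, default seed."""
    params = tx.SimulationParams(n_genes=5000, n_replicates=3)
    counts, design, truth = tx.simulate_triad_counts(params)
    return params, counts, design, truth


@pytest.fixture(scope="session")
def strong_contrasts(strong_sim):
    _, counts, design, _ = strong_sim
    return tx.triad_contrasts(counts, design)


@pytest.fixture(scope="session")
def strong_calls(strong_sim, strong_contrasts):
    c = strong_contrasts
    return tx.classify_gene_action(c["p12"], c["hp1"], c["hp2"], c["mid"])


@pytest.fixture(scope="session")
def null_sim():
    """Planted null: all three genotypes share every gene's mean."""
    params = tx.SimulationParams(n_genes=10000, n_replicates=3,
                                 class_fractions={"NoDiff": 1.0}, seed=1)
    counts, design, truth = tx.simulate_triad_counts(params)
    return params, counts, design, truth


def noiseless_truth():
    """Integral planted means covering all classes, with a NoDiff majority
    so that median-of-ratios normalization is exactly neutral."""
    rows = []
    for b in (8, 40, 200, 1000):
        lo, hi = b, 4 * b
        rows += [("AD", lo, hi, (lo + hi) // 2), ("AD", hi, lo, (lo + hi) // 2),
                 ("HPD", lo, hi, hi), ("HPD", hi, lo, hi),
                 ("LPD", lo, hi, lo), ("LPD", hi, lo, lo),
                 ("OD", lo, hi, 4 * hi), ("OD", hi, lo, 4 * hi),
                 ("UD", lo, hi, lo // 4), ("UD", hi, lo, lo // 4)]
    for b in (5, 9, 17, 33, 65, 129, 257, 513, 1025, 2049):
        rows += [("NoDiff", b, b, b)] * 5
    table = pd.DataFrame(rows,
                         columns=["planted_class", "mu_p1", "mu_p2", "mu_h"],
                         index=pd.Index([f"g{i}" for i in range(len(rows))],
                                        name="gene_id"))
    table[["mu_p1", "mu_p2", "mu_h"]] = \
        table[["mu_p1", "mu_p2", "mu_h"]].astype(float)
    return tx.SyntheticTruth(table, seed=0)


def contrast_frame(genes, mean_a, mean_b, significant):
    """Fabricate a minimal contrast table for decision-table unit tests."""
    mean_a = np.asarray(mean_a, float)
    mean_b = np.asarray(mean_b, float)
    significant = np.asarray(significant, bool)
    log2fc = np.log2(mean_b + 0.5) - np.log2(mean_a + 0.5)
    return pd.DataFrame({
        "mean_A": mean_a,
        "mean_B": mean_b,
        "log2fc": log2fc,
        "stat": np.zeros(len(genes)),
        "p_raw": np.where(significant, 1e-6, 0.8),
        "p_adj": np.where(significant, 1e-5, 0.9),
        "significant": significant,
        "direction": np.where(~significant, "none",
                              np.where(log2fc > 0, "up", "down")),
        "tested": np.ones(len(genes), bool),
    }, index=pd.Index(genes, name="gene_id"))
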