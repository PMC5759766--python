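"""Normalization and per-gene negative-binomial differential testing.

The stage mirrors the classical count-based DE recipe: median-of-ratios
size factors, a pooled method-of-moments dispersion with shrinkage toward
the trimmed-mean dispersion, a per-gene Wald test on normalized group
means, and Benjamini-Hochberg adjustment across the genes actually tested.

Two contrasts are provided: a plain two-group comparison
(:func:`nb_wald_test`) and the mid-parent contrast
(:func:`midparent_test`), which tests whether the hybrid's mean equals the
average of the two parental means -- the quantity that separates additive
from non-additive gene action.

Numerical conventions
---------------------
* The NB variance function is var = mu + alpha*mu^2 on the normalized
  scale; the variance of a group mean of n replicates is (mu + alpha*mu^2)/n.
  Because the statistic depends on the data only through normalized counts,
  rescaling a sample's raw column together with its size factor leaves every
  result bit-identical.
* A zero group mean is replaced by the pseudo-count inside the Wald
  statistic; reported log2 fold changes always use the pseudo-count,
  computed as log2(mean_B + pc) - log2(mean_A + pc) so that swapping the
  groups negates the value exactly.
* Genes with all-zero counts in every group of a contrast are excluded from
  testing and from the BH denominator and reported with ``tested = False``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, NormalizationError, ParameterError
from .io import CountMatrix, TriadDesign

DISPERSION_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# Size factors
# ---------------------------------------------------------------------------

def estimate_size_factors(counts: CountMatrix,
                          pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each sample the factor is the median, over genes positive in all
    samples, of count / geometric-mean-across-samples.  If no gene is
    positive in every sample, a :class:`NormalizationError` is raised unless
    ``pseudo_reference=True``, in which case the per-gene reference is the
    geometric mean over the positive entries only (computed over genes with
    at least one positive count).
    """
    k = counts.values.astype(float)
    positive = k > 0
    if pseudo_reference:
        usable = positive.any(axis=1)
        if not usable.any():
            raise NormalizationError("all counts are zero")
        logk = np.where(positive, np.log(np.where(positive, k, 1.0)), 0.0)
        log_ref = logk[usable].sum(axis=1) / positive[usable].sum(axis=1)
        ratios = np.where(positive[usable],
                          k[usable] / np.exp(log_ref)[:, None], np.nan)
        factors = np.nanmedian(ratios, axis=0)
    else:
        usable = positive.all(axis=1)
        if not usable.any():
            raise NormalizationError(
                "no gene has positive counts in every sample; re-run with "
                "pseudo_reference=True to normalize against a pseudo-reference")
        logk = np.log(k[usable])
        log_ref = logk.mean(axis=1)
        factors = np.median(np.exp(logk - log_ref[:, None]), axis=0)
    if not np.all(np.isfinite(factors) & (factors > 0)):
        raise NormalizationError("estimated size factors are not all positive")
    return pd.Series(factors, index=counts.sample_ids, name="size_factor")


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(counts: CountMatrix, design: TriadDesign,
                        size_factors: pd.Series | None = None,
                        shrink_weight: float = 0.5,
                        trim: float = 0.125,
                        floor: float = DISPERSION_FLOOR) -> pd.Series:
    """Per-gene NB dispersion, pooled across genotypes and shrunk.

    For each genotype with a positive mean, the method-of-moments estimate
    max(0, (s^2 - m) / m^2) is computed on normalized counts; the per-gene
    value is the average over genotypes, then shrunk toward the trimmed-mean
    dispersion with weight ``shrink_weight`` and floored at ``floor``.
    Degenerate genes (no genotype with a positive mean) receive the floor.
    """
    if not (0 <= shrink_weight <= 1):
        raise ParameterError("shrink_weight: must be in [0, 1]")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    y = counts.values / size_factors.reindex(counts.sample_ids).to_numpy()
    per_geno = []
    for geno in design.genotypes:
        cols = [counts.sample_ids.get_loc(s) for s in design.samples_of(geno)]
        if len(cols) < 2:
            raise DesignError(f"genotype {geno!r}: need >= 2 replicates")
        sub = y[:, cols]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.maximum(0.0, (v - m) / (m * m))
        per_geno.append(np.where(m > 0, a, np.nan))
    stacked = np.column_stack(per_geno)
    valid = np.isfinite(stacked)
    n_valid = valid.sum(axis=1)
    a_gene = np.where(n_valid > 0,
                      np.where(valid, stacked, 0.0).sum(axis=1)
                      / np.maximum(n_valid, 1), np.nan)
    finite = np.isfinite(a_gene)
    if finite.any():
        center = stats.trim_mean(a_gene[finite], trim)
    else:
        center = 0.0
    a_shrunk = (1 - shrink_weight) * np.where(finite, a_gene, center) \
        + shrink_weight * center
    return pd.Series(np.maximum(floor, a_shrunk), index=counts.gene_ids,
                     name="dispersion")


# ---------------------------------------------------------------------------
# Wald tests
# ---------------------------------------------------------------------------

def _finish(df: pd.DataFrame, tested: np.ndarray, p_raw: np.ndarray,
            alpha: float) -> pd.DataFrame:
    p_raw = np.where(tested, p_raw, np.nan)
    p_adj = np.full(p_raw.shape, np.nan)
    if tested.any():
        p_adj[tested] = adjust_bh(p_raw[tested])
    significant = tested & (p_adj <= alpha)
    direction = np.where(significant & (df["log2fc"].to_numpy() > 0), "up",
                         np.where(significant & (df["log2fc"].to_numpy() < 0),
                                  "down", "none"))
    df["p_raw"] = p_raw
    df["p_adj"] = p_adj
    df["significant"] = significant
    df["direction"] = direction
    df["tested"] = tested
    return df


def _group_mean(y: np.ndarray, counts: CountMatrix, design: TriadDesign,
                genotype: str) -> tuple[np.ndarray, int]:
    samples = design.samples_of(genotype)
    cols = [counts.sample_ids.get_loc(s) for s in samples]
    if len(cols) < 2:
        raise DesignError(f"genotype {genotype!r}: need >= 2 replicates")
    return y[:, cols].mean(axis=1), len(cols)


def nb_wald_test(counts: CountMatrix, design: TriadDesign,
                 group_a: str, group_b: str,
                 size_factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None,
                 alpha: float = 0.05,
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Two-group NB Wald test of genotype ``group_b`` versus ``group_a``.

    Returns a DataFrame indexed by gene with columns ``mean_A``, ``mean_B``
    (normalized means), ``log2fc`` (B over A, pseudo-counted), ``stat``,
    ``p_raw``, ``p_adj`` (BH over tested genes), ``significant``
    (p_adj <= alpha), ``direction`` and ``tested``.
    """
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design, size_factors)
    disp = dispersions.reindex(counts.gene_ids).to_numpy()
    y = counts.values / size_factors.reindex(counts.sample_ids).to_numpy()
    mu_a, n_a = _group_mean(y, counts, design, group_a)
    mu_b, n_b = _group_mean(y, counts, design, group_b)
    tested = (mu_a > 0) | (mu_b > 0)

    ma = np.where(mu_a > 0, mu_a, pseudocount)
    mb = np.where(mu_b > 0, mu_b, pseudocount)
    var_a = (ma + disp * ma * ma) / n_a
    var_b = (mb + disp * mb * mb) / n_b
    se = np.sqrt(var_a / (ma * ma) + var_b / (mb * mb))
    with np.errstate(invalid="ignore"):
        stat = (np.log(mb) - np.log(ma)) / se
    p_raw = 2.0 * stats.norm.sf(np.abs(stat))

    df = pd.DataFrame({
        "mean_A": mu_a,
        "mean_B": mu_b,
        "log2fc": np.log2(mu_b + pseudocount) - np.log2(mu_a + pseudocount),
        "stat": np.where(tested, stat, np.nan),
    }, index=counts.gene_ids)
    df = _finish(df, tested, p_raw, alpha)
    df.attrs.update(group_A=group_a, group_B=group_b, alpha=alpha,
                    contrast=f"{group_b}_vs_{group_a}")
    return df


def midparent_test(counts: CountMatrix, design: TriadDesign,
                   size_factors: pd.Series | None = None,
                   dispersions: pd.Series | None = None,
                   alpha: float = 0.05,
                   pseudocount: float = 0.5,
                   midparent: str = "arithmetic") -> pd.DataFrame:
    """Test H0: hybrid mean equals the mid-parent value.

    With the default arithmetic mid-parent the Wald contrast is
    (mu_H - (mu_P1 + mu_P2)/2) / SE with
    SE^2 = Var(mu_H) + Var(mu_P1)/4 + Var(mu_P2)/4; the geometric option
    tests log mu_H against (log mu_P1 + log mu_P2)/2 by the delta method.
    ``mean_A`` is the mid-parent value and ``mean_B`` the hybrid mean.
    """
    if midparent not in ("arithmetic", "geometric"):
        raise ParameterError("midparent: must be 'arithmetic' or 'geometric'")
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design, size_factors)
    disp = dispersions.reindex(counts.gene_ids).to_numpy()
    y = counts.values / size_factors.reindex(counts.sample_ids).to_numpy()
    mu = {}
    n = {}
    for role in ("parent1", "parent2", "hybrid"):
        geno = design.genotype_for_role(role)
        mu[role], n[role] = _group_mean(y, counts, design, geno)

    def var_of_mean(m, role):
        return (m + disp * m * m) / n[role]

    p1, p2, h = mu["parent1"], mu["parent2"], mu["hybrid"]
    tested = (p1 > 0) | (p2 > 0) | (h > 0)
    if midparent == "arithmetic":
        mid = (p1 + p2) / 2.0
        num = h - mid
        se = np.sqrt(var_of_mean(h, "hybrid")
                     + 0.25 * var_of_mean(p1, "parent1")
                     + 0.25 * var_of_mean(p2, "parent2"))
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.where(se > 0, num / np.where(se > 0, se, 1.0), 0.0)
    else:
        p1_ = np.where(p1 > 0, p1, pseudocount)
        p2_ = np.where(p2 > 0, p2, pseudocount)
        h_ = np.where(h > 0, h, pseudocount)
        mid = np.sqrt(p1_ * p2_)
        num = np.log(h_) - 0.5 * (np.log(p1_) + np.log(p2_))
        se = np.sqrt(var_of_mean(h_, "hybrid") / (h_ * h_)
                     + 0.25 * var_of_mean(p1_, "parent1") / (p1_ * p1_)
                     + 0.25 * var_of_mean(p2_, "parent2") / (p2_ * p2_))
        stat = num / se
    p_raw = 2.0 * stats.norm.sf(np.abs(stat))

    df = pd.DataFrame({
        "mean_A": mid,
        "mean_B": h,
        "log2fc": np.log2(h + pseudocount) - np.log2(mid + pseudocount),
        "stat": np.where(tested, stat, np.nan),
    }, index=counts.gene_ids)
    df = _finish(df, tested, p_raw, alpha)
    df.attrs.update(group_A="midparent", group_B=design.genotype_for_role("hybrid"),
                    alpha=alpha, contrast="hybrid_vs_midparent",
                    midparent=midparent)
    return df


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p) | (p < 0) | (p > 1)):
        raise ParameterError("p_values: all values must be in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def adjust_bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); m defaults to len(p)."""
    p = np.asarray(p_values, dtype=float)
    if np.any(~np.isfinite(p) | (p < 0) | (p > 1)):
        raise ParameterError("p_values: all values must be in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, p * m)
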