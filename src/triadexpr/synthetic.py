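"""Synthetic triad data with known, planted gene-action structure.

Every downstream stage of the pipeline (normalization, negative-binomial
testing, gene-action classification, enrichment, qPCR-style validation) is
testable against ground truth generated here.  A gene's planted class fixes
the relationship between the expected expression of the two parents and the
hybrid:

========  =====================================================
class     planted means
========  =====================================================
NoDiff    mu_P1 = mu_P2 = mu_H
AD        mu_H = (mu_P1 + mu_P2) / 2   (arithmetic mid-parent)
HPD       mu_H = max(mu_P1, mu_P2)
LPD       mu_H = min(mu_P1, mu_P2)
OD        mu_H = max(mu_P1, mu_P2) * 2**od_ud_log2fc
UD        mu_H = min(mu_P1, mu_P2) / 2**od_ud_log2fc
========  =====================================================

For non-NoDiff genes the two parents differ by ``parent_log2fc`` (log2), the
lower parent sitting at the gene's baseline mean; which parent is the high
one is chosen uniformly at random so that classification cannot exploit
label order.  Counts are negative-binomial with variance mu + alpha*mu**2
(alpha = 0 degenerates to Poisson).

RNG contract: one root seed; an independent sub-stream is derived per gene,
so enlarging ``n_genes`` never perturbs the genes already generated.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CountMatrix, TriadDesign

#: canonical class labels, in the order used for planting
CLASSES = ("NoDiff", "AD", "HPD", "LPD", "OD", "UD")

#: default planted class spectrum: a large NoDiff majority, with the
#: differential genes split in proportions resembling observed hybrid-parent
#: triad spectra in which over/underdominance and dominance dwarf additivity
DEFAULT_CLASS_FRACTIONS: Mapping[str, float] = {
    "NoDiff": 0.80,
    "AD": 0.011,
    "HPD": 0.017,
    "LPD": 0.029,
    "OD": 0.072,
    "UD": 0.071,
}

GENOTYPES = {"parent1": "P1", "parent2": "P2", "hybrid": "H"}


@dataclasses.dataclass(frozen=True)
class SimulationParams:
    """Parameters of the triad count simulation.

    ``baseline_mean_log_range`` bounds the natural-log baseline mean, drawn
    log-uniformly (default e^1..e^8) to span low- and high-expression genes.
    ``dispersion`` is the NB overdispersion alpha in var = mu + alpha*mu^2.
    """

    n_genes: int = 5000
    n_replicates: int = 2
    class_fractions: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    baseline_mean_log_range: tuple[float, float] = (1.0, 8.0)
    parent_log2fc: float = 2.0
    od_ud_log2fc: float = 2.0
    dispersion: float = 0.05
    library_size_factors: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1:
            raise ParameterError("n_genes: must be a positive integer")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates: must be a positive integer")
        unknown = set(self.class_fractions) - set(CLASSES)
        if unknown:
            raise ParameterError(f"class_fractions: unknown classes {sorted(unknown)}")
        fracs = list(self.class_fractions.values())
        if any(f < 0 for f in fracs):
            raise ParameterError("class_fractions: fractions must be >= 0")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ParameterError(
                f"class_fractions: must sum to 1 (got {sum(fracs)!r})")
        lo, hi = self.baseline_mean_log_range
        if not (math.isfinite(lo) and math.isfinite(hi) and lo <= hi):
            raise ParameterError("baseline_mean_log_range: need finite lo <= hi")
        for name in ("parent_log2fc", "od_ud_log2fc"):
            if not math.isfinite(getattr(self, name)):
                raise ParameterError(f"{name}: must be finite")
        if not (math.isfinite(self.dispersion) and self.dispersion >= 0):
            raise ParameterError("dispersion: must be finite and >= 0")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, float)
            if sf.size != 3 * self.n_replicates:
                raise ParameterError(
                    "library_size_factors: need one factor per sample "
                    f"({3 * self.n_replicates}), got {sf.size}")
            if not np.all(np.isfinite(sf) & (sf > 0)):
                raise ParameterError("library_size_factors: must be positive and finite")


@dataclasses.dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-gene ground truth.

    ``table`` is indexed by gene id with columns ``planted_class``,
    ``mu_p1``, ``mu_p2`` and ``mu_h`` (expected normalized counts).
    """

    table: pd.DataFrame
    seed: int

    def classes_of(self, gene_ids: Iterable[str]) -> pd.Series:
        return self.table.loc[list(gene_ids), "planted_class"]

    def genes_in_class(self, klass: str) -> pd.Index:
        if klass not in CLASSES:
            raise ParameterError(f"class: unknown class {klass!r}")
        return self.table.index[self.table["planted_class"] == klass]

    def check_consistency(self, rtol: float = 1e-12) -> None:
        """Raise AssertionError if any planted means violate their class."""
        t = self.table
        p1, p2, h = (t[c].to_numpy() for c in ("mu_p1", "mu_p2", "mu_h"))
        hi, lo = np.maximum(p1, p2), np.minimum(p1, p2)
        klass = t["planted_class"].to_numpy()
        checks = {
            "NoDiff": (p1 == p2) & (p2 == h),
            "AD": np.isclose(h, (p1 + p2) / 2, rtol=rtol) & (p1 != p2),
            "HPD": np.isclose(h, hi, rtol=rtol) & (p1 != p2),
            "LPD": np.isclose(h, lo, rtol=rtol) & (p1 != p2),
            "OD": h > hi,
            "UD": h < lo,
        }
        for name, ok in checks.items():
            sel = klass == name
            assert ok[sel].all(), f"planted means inconsistent for class {name}"


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    # sub-stream per gene: stable under changes of n_genes
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, float)
    if dispersion == 0.0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def _planted_means(rng: np.random.Generator, klass: str,
                   params: SimulationParams) -> tuple[float, float, float]:
    lo_log, hi_log = params.baseline_mean_log_range
    base = math.exp(rng.uniform(lo_log, hi_log))
    swap = rng.random() < 0.5  # drawn for every gene to keep streams aligned
    if klass == "NoDiff":
        return base, base, base
    mu_lo, mu_hi = base, base * 2.0 ** params.parent_log2fc
    p1, p2 = (mu_hi, mu_lo) if swap else (mu_lo, mu_hi)
    if klass == "AD":
        h = (p1 + p2) / 2.0
    elif klass == "HPD":
        h = mu_hi
    elif klass == "LPD":
        h = mu_lo
    elif klass == "OD":
        h = mu_hi * 2.0 ** params.od_ud_log2fc
    else:  # UD
        h = mu_lo / 2.0 ** params.od_ud_log2fc
    return p1, p2, h


def _design(n_replicates: int) -> TriadDesign:
    genotype_of = {}
    for role in ("parent1", "parent2", "hybrid"):
        geno = GENOTYPES[role]
        for r in range(1, n_replicates + 1):
            genotype_of[f"{geno}_{r}"] = geno
    return TriadDesign(genotype_of, {g: r for r, g in GENOTYPES.items()})


def simulate_triad_counts(
    params: SimulationParams,
) -> tuple[CountMatrix, TriadDesign, SyntheticTruth]:
    """Simulate a parent1/parent2/hybrid count matrix with planted classes.

    Returns the count matrix (genes x 3*n_replicates samples), the matching
    design and the planted truth.  Identical params give identical output.
    """
    R = params.n_replicates
    design = _design(R)
    sf = (np.ones(3 * R) if params.library_size_factors is None
          else np.asarray(params.library_size_factors, float))
    cum = np.cumsum([params.class_fractions.get(c, 0.0) for c in CLASSES])
    width = max(5, len(str(params.n_genes)))
    gene_ids = [f"g{i:0{width}d}" for i in range(params.n_genes)]
    counts = np.empty((params.n_genes, 3 * R), dtype=np.int64)
    truth_rows = []
    for i in range(params.n_genes):
        rng = _gene_rng(params.seed, i)
        u = rng.random()
        klass = CLASSES[min(int(np.searchsorted(cum, u, side="right")),
                            len(CLASSES) - 1)]
        p1, p2, h = _planted_means(rng, klass, params)
        means = np.repeat([p1, p2, h], R) * sf
        counts[i] = _nb_draw(rng, means, params.dispersion)
        truth_rows.append((klass, p1, p2, h))
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids,
                                  columns=list(design.genotype_of)))
    truth = SyntheticTruth(
        pd.DataFrame(truth_rows, index=pd.Index(gene_ids, name="gene_id"),
                     columns=["planted_class", "mu_p1", "mu_p2", "mu_h"]),
        seed=params.seed)
    return cm, design, truth


def counts_from_truth(truth: SyntheticTruth, n_replicates: int = 3,
                      ) -> tuple[CountMatrix, TriadDesign]:
    """Noise-free count matrix: every replicate equals the planted mean.

    Planted means are rounded to the nearest integer, so the planted class
    structure is preserved exactly whenever the means are integral (e.g.
    integer baselines with integral fold changes).  Useful as the noiseless
    limit of the simulation.
    """
    design = _design(n_replicates)
    mus = truth.table[["mu_p1", "mu_p2", "mu_h"]].to_numpy()
    counts = np.repeat(np.rint(mus).astype(np.int64), n_replicates, axis=1)
    cm = CountMatrix(pd.DataFrame(counts, index=truth.table.index,
                                  columns=list(design.genotype_of)))
    return cm, design


def simulate_annotation(
    truth: SyntheticTruth,
    n_terms: int = 20,
    enriched_term_spec: Sequence[tuple[str, str, float]] = (),
    seed: int = 0,
    background_prob: float = 0.05,
) -> "pd.DataFrame":
    """Simulate a gene -> term annotation with planted over-representation.

    ``enriched_term_spec`` lists ``(term, class, enrichment_factor)``
    triples; genes of the named planted class join the named term with
    probability ``min(1, factor * background_prob)`` while all other
    memberships are uniform at ``background_prob``.  Returns a two-column
    DataFrame (gene, term); wrap it with
    :meth:`triadexpr.enrichment.AnnotationMap.from_pairs`.
    """
    if n_terms < 1:
        raise ParameterError("n_terms: must be a positive integer")
    if not (0 < background_prob <= 1):
        raise ParameterError("background_prob: must be in (0, 1]")
    present = set(truth.table["planted_class"].unique())
    for term, klass, factor in enriched_term_spec:
        if klass not in CLASSES:
            raise ParameterError(f"enriched_term_spec: unknown class {klass!r}")
        if klass not in present:
            raise ParameterError(
                f"enriched_term_spec: class {klass!r} absent from truth")
        if factor < 1:
            raise ParameterError(
                f"enriched_term_spec: enrichment_factor for {term!r} must be >= 1")
    planted = {term: (klass, factor) for term, klass, factor in enriched_term_spec}
    if len(planted) != len(enriched_term_spec):
        raise ParameterError("enriched_term_spec: duplicate term names")
    n_background = n_terms - len(planted)
    if n_background < 0:
        raise ParameterError("n_terms: fewer terms than enriched_term_spec entries")
    terms = list(planted) + [f"T{j + 1:03d}" for j in range(n_background)]
    rng = np.random.default_rng(seed)
    genes = truth.table.index.to_numpy()
    klass = truth.table["planted_class"].to_numpy()
    pairs: list[tuple[str, str]] = []
    for term in terms:
        prob = np.full(genes.size, background_prob)
        if term in planted:
            target, factor = planted[term]
            prob[klass == target] = min(1.0, factor * background_prob)
        member = rng.random(genes.size) < prob
        pairs.extend((g, term) for g in genes[member])
    return pd.DataFrame(pairs, columns=["gene", "term"])


def simulate_qpcr(
    truth: SyntheticTruth,
    gene_ids: Sequence[str],
    cv: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate replicate relative-abundance values for selected genes.

    Planted means are rescaled so parent1 sits at 1.0 (abundance relative to
    parent1); per genotype, ``n_replicates`` positive values are drawn from
    a mean-preserving lognormal with coefficient of variation ``cv``
    (``cv=0`` returns the planted means exactly).  Returns a long-format
    DataFrame (gene, genotype, replicate, value) readable by
    :func:`triadexpr.qpcr.triads_from_long`.
    """
    if cv < 0:
        raise ParameterError("cv: must be >= 0")
    if n_replicates < 2:
        raise ParameterError("n_replicates: must be >= 2")
    missing = [g for g in gene_ids if g not in truth.table.index]
    if missing:
        raise ParameterError(f"gene_ids: not in truth: {missing[:5]}")
    sigma2 = math.log1p(cv * cv)
    sigma = math.sqrt(sigma2)
    rows = []
    for k, gene in enumerate(gene_ids):
        rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(k,)))
        mu = truth.table.loc[gene, ["mu_p1", "mu_p2", "mu_h"]].to_numpy(float)
        mu = mu / mu[0]  # relative to parent1
        for geno, m in zip(("P1", "P2", "H"), mu):
            if cv == 0:
                vals = np.full(n_replicates, m)
            else:
                vals = rng.lognormal(math.log(m) - sigma2 / 2, sigma,
                                     n_replicates)
            rows.extend((gene, geno, r + 1, v)
                        for r, v in enumerate(vals))
    return pd.DataFrame(rows, columns=["gene", "genotype", "replicate", "value"])
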