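"""Replicate-level triad validation in the style of qRT-PCR panels.

For each gene, replicate relative-abundance values of the three genotypes
are compared with one-way ANOVA followed by Tukey's HSD across all genotype
pairs (Tukey-Kramer for unbalanced replication).  The pairwise outcomes are
then collapsed with the same gene-action decision table used for the count
pipeline, with two adaptations forced by having only three group means:

* "significant" means the Tukey pair comparison is significant at the
  family level, and
* additivity keeps its significance pattern but the mid-parent condition
  becomes the interval form: the hybrid mean lies within the closed
  interval between the parent means while differing from both parents.

Relative abundance is taken as given (e.g. instrument-software output); a
``2**-ddCt`` convenience converter is provided for raw Ct values.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, InputError, ParameterError

ROLES = ("parent1", "parent2", "hybrid")
DEFAULT_GENOTYPE_ROLES = {"P1": "parent1", "P2": "parent2", "H": "hybrid"}


@dataclasses.dataclass(frozen=True)
class QpcrTriad:
    """Replicate relative-abundance values for one gene across the triad."""

    gene_id: str
    parent1: np.ndarray
    parent2: np.ndarray
    hybrid: np.ndarray

    def __post_init__(self):
        for role in ROLES:
            vals = np.asarray(getattr(self, role), dtype=float)
            if vals.ndim != 1 or vals.size < 3:
                raise ParameterError(
                    f"{self.gene_id}/{role}: need >= 3 replicate values")
            if not np.all(np.isfinite(vals) & (vals > 0)):
                raise ParameterError(
                    f"{self.gene_id}/{role}: values must be positive and finite")
            object.__setattr__(self, role, vals)

    def groups(self) -> dict[str, np.ndarray]:
        return {role: getattr(self, role) for role in ROLES}

    def means(self) -> dict[str, float]:
        return {role: float(getattr(self, role).mean()) for role in ROLES}


@dataclasses.dataclass(frozen=True)
class TukeyOutcome:
    """One Tukey HSD pairwise comparison (diff = mean(b) - mean(a))."""

    pair: tuple[str, str]
    diff: float
    q: float
    p: float
    significant: bool


@dataclasses.dataclass(frozen=True)
class QpcrCall:
    """Gene-action call for one triad from replicate-level statistics."""

    gene_id: str
    klass: str
    high_parent: str
    means: Mapping[str, float]
    pair_significant: Mapping[tuple[str, str], bool]


def _within_var(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    dfw = sum(g.size - 1 for g in groups)
    return ssw, dfw


def anova_oneway(triad: QpcrTriad) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across the three genotypes."""
    groups = list(triad.groups().values())
    ssw, _ = _within_var(groups)
    if ssw == 0.0:
        raise DegenerateDataError(
            f"{triad.gene_id}: zero within-group variance; ANOVA undefined")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _tukey_arrays(arrays: Sequence[np.ndarray], alpha: float,
                  label: str) -> dict[tuple[str, str], TukeyOutcome]:
    ssw, dfw = _within_var(arrays)
    if ssw == 0.0:
        raise DegenerateDataError(
            f"{label}: zero within-group variance; Tukey HSD undefined")
    msw = ssw / dfw
    res = stats.tukey_hsd(*arrays)
    out: dict[tuple[str, str], TukeyOutcome] = {}
    for i, j in itertools.combinations(range(3), 2):
        a, b = ROLES[i], ROLES[j]
        diff = float(arrays[j].mean() - arrays[i].mean())
        q = abs(diff) / np.sqrt(msw / 2 * (1 / arrays[i].size + 1 / arrays[j].size))
        p = float(res.pvalue[i, j])
        out[(a, b)] = TukeyOutcome(pair=(a, b), diff=diff, q=float(q), p=p,
                                   significant=p < alpha)
    return out


def tukey_hsd(triad: QpcrTriad,
              alpha: float = 0.05) -> dict[tuple[str, str], TukeyOutcome]:
    """All pairwise Tukey HSD comparisons at family level ``alpha``.

    Returns a dict keyed by role pair in canonical order
    (parent1, parent2), (parent1, hybrid), (parent2, hybrid); ``diff`` is
    the mean of the second role minus the mean of the first.  ``q`` is the
    studentized-range statistic |diff| / sqrt(MSW/2 * (1/ni + 1/nj)).
    Tukey-Kramer standard errors are used for unbalanced replication.
    """
    return _tukey_arrays(list(triad.groups().values()), alpha, triad.gene_id)


def classify_qpcr_triad(triad: QpcrTriad,
                        tukey: Mapping[tuple[str, str], TukeyOutcome] | None = None,
                        alpha: float = 0.05,
                        log_scale: bool = True,
                        tie_tol: float = 1e-12) -> QpcrCall:
    """Collapse Tukey pairwise outcomes into a gene-action class.

    By default pairwise significance is judged on log-transformed
    abundances (the ddCt domain), which stabilizes the replicate variance
    of ratio-scale data whose noise is proportional to the mean; pass
    ``log_scale=False`` (or a precomputed ``tukey``) to test the raw
    values.  Mean ordering always uses the raw-scale group means.  When the
    replicate values are exactly noise-free (zero within-group variance),
    pairwise "significance" degenerates to exact inequality of the group
    means.
    """
    means = triad.means()
    if tukey is None:
        arrays = [getattr(triad, role) for role in ROLES]
        if log_scale:
            arrays = [np.log(a) for a in arrays]
        try:
            tukey = _tukey_arrays(arrays, alpha, triad.gene_id)
        except DegenerateDataError:
            tukey = None
    if tukey is None:  # noise-free limit: compare means directly
        sig = {(a, b): means[a] != means[b]
               for a, b in itertools.combinations(ROLES, 2)}
    else:
        sig = {pair: out.significant for pair, out in tukey.items()}

    m1, m2, mh = means["parent1"], means["parent2"], means["hybrid"]
    sp = sig[("parent1", "parent2")]
    s1 = sig[("parent1", "hybrid")]
    s2 = sig[("parent2", "hybrid")]
    tie = abs(m1 - m2) <= tie_tol
    hi, lo = max(m1, m2), min(m1, m2)
    sig_h_hp = s1 if m1 > m2 else s2
    sig_h_lp = s2 if m1 > m2 else s1
    high_parent = "tie" if tie else ("parent1" if m1 > m2 else "parent2")

    deg = s1 or s2
    if not deg:
        klass = "NoDiff"
    elif s1 and s2 and mh > m1 and mh > m2:
        klass = "OD"
    elif s1 and s2 and mh < m1 and mh < m2:
        klass = "UD"
    elif sp and not tie and not sig_h_hp and sig_h_lp and mh > lo:
        klass = "HPD"
    elif sp and not tie and not sig_h_lp and sig_h_hp and mh < hi:
        klass = "LPD"
    elif sp and s1 and s2 and lo <= mh <= hi:
        klass = "AD"
    else:
        klass = "Ambiguous"
    return QpcrCall(gene_id=triad.gene_id, klass=klass,
                    high_parent=high_parent, means=means,
                    pair_significant=sig)


# ---------------------------------------------------------------------------
# Concordance with the count-based calls
# ---------------------------------------------------------------------------

def _as_class_map(calls) -> dict[str, str]:
    if isinstance(calls, pd.DataFrame):
        return dict(calls["class"])
    if isinstance(calls, Mapping):
        return {g: (c.klass if isinstance(c, QpcrCall) else str(c))
                for g, c in calls.items()}
    return {c.gene_id: c.klass for c in calls}


def concordance(rnaseq_calls, qpcr_calls) -> pd.DataFrame:
    """Per-gene agreement between count-based and replicate-level calls.

    Accepts call tables (DataFrame with a ``class`` column), mappings
    gene -> class, or iterables of :class:`QpcrCall`.  Returns a DataFrame
    over the shared genes with columns class_rnaseq, class_qpcr and agree;
    the overall agreement fraction is stored in ``.attrs["agreement"]``.
    """
    a = _as_class_map(rnaseq_calls)
    b = _as_class_map(qpcr_calls)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise InputError("concordance: no shared gene ids")
    df = pd.DataFrame({
        "class_rnaseq": [a[g] for g in shared],
        "class_qpcr": [b[g] for g in shared],
    }, index=pd.Index(shared, name="gene_id"))
    df["agree"] = df["class_rnaseq"] == df["class_qpcr"]
    df.attrs["agreement"] = float(df["agree"].mean())
    return df


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def triads_from_long(table: pd.DataFrame | str | Path,
                     genotype_roles: Mapping[str, str] | None = None,
                     ) -> list[QpcrTriad]:
    """Build triads from a long-format table (gene, genotype, replicate, value).

    ``genotype_roles`` maps genotype labels to triad roles; by default the
    labels P1/P2/H are taken as parent1/parent2/hybrid.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    required = {"gene", "genotype", "value"}
    if not required.issubset(table.columns):
        raise InputError(f"long table needs columns {sorted(required)}")
    roles = dict(genotype_roles or DEFAULT_GENOTYPE_ROLES)
    triads = []
    for gene, sub in table.groupby("gene", sort=True):
        vals: dict[str, np.ndarray] = {}
        for geno, g in sub.groupby("genotype"):
            role = roles.get(str(geno))
            if role is None:
                raise InputError(f"genotype {geno!r} has no triad role")
            vals[role] = g["value"].to_numpy(float)
        missing = set(ROLES) - set(vals)
        if missing:
            raise InputError(f"gene {gene!r}: missing roles {sorted(missing)}")
        triads.append(QpcrTriad(gene_id=str(gene), **vals))
    return triads


def validation_table(triads: Iterable[QpcrTriad], alpha: float = 0.05,
                     log_scale: bool = True) -> pd.DataFrame:
    """Per-gene ANOVA, Tukey pairs and class for a set of triads.

    ``log_scale`` controls the scale of the replicate-level statistics (see
    :func:`classify_qpcr_triad`); the reported ANOVA F refers to the same
    scale as the Tukey comparisons.
    """
    rows = []
    for triad in triads:
        arrays = [getattr(triad, role) for role in ROLES]
        if log_scale:
            arrays = [np.log(a) for a in arrays]
        try:
            ssw, _ = _within_var(arrays)
            if ssw == 0.0:
                raise DegenerateDataError(triad.gene_id)
            f, p = (float(x) for x in stats.f_oneway(*arrays))
            tk = _tukey_arrays(arrays, alpha, triad.gene_id)
        except DegenerateDataError:
            f, p, tk = np.nan, np.nan, None
        call = classify_qpcr_triad(triad, tukey=tk, alpha=alpha,
                                   log_scale=log_scale)
        row = {"gene_id": triad.gene_id, "F": f, "p_anova": p,
               "class": call.klass, "high_parent": call.high_parent}
        for (a, b), s in call.pair_significant.items():
            row[f"sig_{a}_{b}"] = s
        if tk is not None:
            for (a, b), out in tk.items():
                row[f"p_{a}_{b}"] = out.p
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")


def relative_abundance_from_ct(ct_target: float, ct_reference: float,
                               calibrator_ct_target: float,
                               calibrator_ct_reference: float) -> float:
    """2^-ddCt relative abundance.

    dCt = Ct(target) - Ct(reference) within each sample; ddCt subtracts the
    calibrator sample's dCt, so the calibrator has relative abundance 1.
    """
    dct = ct_target - ct_reference
    dct_cal = calibrator_ct_target - calibrator_ct_reference
    return float(2.0 ** -(dct - dct_cal))
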