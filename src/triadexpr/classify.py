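"""Gene-action classification of hybrid-parent triads.

A gene is a DEG when its expression differs significantly between the
hybrid and at least one parent.  Each DEG is assigned one of five
gene-action classes from the pattern of four contrasts -- parent1 vs
parent2 (``p12``), hybrid vs parent1 (``hp1``), hybrid vs parent2
(``hp2``) and hybrid vs mid-parent (``mid``) -- together with the
normalized means.  Writing S(x) for "contrast x significant", HP/LP for the
parent with the larger/smaller normalized mean:

=========  ==============================================================
class      rule
=========  ==============================================================
OD         S(hp1) and S(hp2) and hybrid above both parents
UD         S(hp1) and S(hp2) and hybrid below both parents
HPD        S(p12) and not S(H vs HP) and S(H vs LP) and hybrid above LP
LPD        S(p12) and not S(H vs LP) and S(H vs HP) and hybrid below HP
AD         S(p12) and S(hp1) and S(hp2) and hybrid strictly between the
           parents and not S(mid)
Ambiguous  any other pattern within the DEG set
NoDiff     not a DEG
=========  ==============================================================

The decision table is this module's normative reading of the classical
five-class scheme (additivity, high/low-parent dominance, over- and
underdominance): each verbal class description maps to exactly one branch.
The mid-parent condition on AD can be relaxed
(``require_midparent_test=False``), in which case AD requires only the
significance pattern and strict betweenness.  Exact parental mean ties
(within ``tie_tol``) make the high parent undefined and force Ambiguous for
the dominance branches.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .io import CountMatrix, TriadDesign

CLASS_LABELS = ("AD", "HPD", "LPD", "OD", "UD")
ALL_CALLS = CLASS_LABELS + ("NoDiff", "Ambiguous")


def _check_universe(*contrasts: pd.DataFrame) -> pd.Index:
    first = contrasts[0].index
    for c in contrasts[1:]:
        if len(c.index) != len(first) or not first.equals(c.index):
            raise InputError("contrasts cover different gene universes")
    return first


def select_degs(c_hp1: pd.DataFrame, c_hp2: pd.DataFrame) -> pd.Index:
    """Genes significant in at least one hybrid-vs-parent contrast."""
    genes = _check_universe(c_hp1, c_hp2)
    keep = c_hp1["significant"].to_numpy() | c_hp2["significant"].to_numpy()
    return genes[keep]


def triad_contrasts(counts: CountMatrix, design: TriadDesign,
                    size_factors=None, dispersions=None,
                    alpha: float = 0.05, pseudocount: float = 0.5,
                    midparent: str = "arithmetic") -> dict[str, pd.DataFrame]:
    """Run the four contrasts feeding classification, in canonical order.

    Returns ``{"p12": parent2 vs parent1, "hp1": hybrid vs parent1,
    "hp2": hybrid vs parent2, "mid": hybrid vs mid-parent}``.
    """
    from .de import estimate_dispersion, estimate_size_factors, midparent_test, nb_wald_test

    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    if dispersions is None:
        dispersions = estimate_dispersion(counts, design, size_factors)
    p1 = design.genotype_for_role("parent1")
    p2 = design.genotype_for_role("parent2")
    h = design.genotype_for_role("hybrid")
    common = dict(size_factors=size_factors, dispersions=dispersions,
                  alpha=alpha, pseudocount=pseudocount)
    return {
        "p12": nb_wald_test(counts, design, p1, p2, **common),
        "hp1": nb_wald_test(counts, design, p1, h, **common),
        "hp2": nb_wald_test(counts, design, p2, h, **common),
        "mid": midparent_test(counts, design, midparent=midparent, **common),
    }


def classify_gene_action(c_p12: pd.DataFrame, c_hp1: pd.DataFrame,
                         c_hp2: pd.DataFrame, c_mid: pd.DataFrame | None = None,
                         require_midparent_test: bool = True,
                         tie_tol: float = 1e-12) -> pd.DataFrame:
    """Per-gene gene-action calls from the four triad contrasts.

    The contrasts must be oriented as produced by :func:`triad_contrasts`
    (``c_p12``: parent2 vs parent1; ``c_hp1``/``c_hp2``: hybrid vs that
    parent; ``c_mid``: hybrid vs mid-parent).  Returns a DataFrame indexed
    by gene with the class, the supporting significance/direction pattern,
    the data-driven high parent and the four adjusted p-values.
    """
    if require_midparent_test and c_mid is None:
        raise InputError("mid-parent contrast required "
                         "(pass c_mid or set require_midparent_test=False)")
    contrasts = [c_p12, c_hp1, c_hp2] + ([c_mid] if c_mid is not None else [])
    genes = _check_universe(*contrasts)

    mu_p1 = c_hp1["mean_A"].to_numpy(float)
    mu_p2 = c_hp2["mean_A"].to_numpy(float)
    mu_h = c_hp1["mean_B"].to_numpy(float)
    sp = c_p12["significant"].to_numpy()
    s1 = c_hp1["significant"].to_numpy()
    s2 = c_hp2["significant"].to_numpy()
    if c_mid is not None:
        sm = c_mid["significant"].to_numpy()
    else:
        sm = np.zeros(len(genes), dtype=bool)

    tie = np.abs(mu_p1 - mu_p2) <= tie_tol
    p1_high = mu_p1 > mu_p2
    sig_h_hp = np.where(p1_high, s1, s2)
    sig_h_lp = np.where(p1_high, s2, s1)
    mu_hp = np.maximum(mu_p1, mu_p2)
    mu_lp = np.minimum(mu_p1, mu_p2)

    deg = s1 | s2
    above = (mu_h > mu_p1) & (mu_h > mu_p2)
    below = (mu_h < mu_p1) & (mu_h < mu_p2)
    between = (mu_h > mu_lp) & (mu_h < mu_hp)

    od = deg & s1 & s2 & above
    ud = deg & s1 & s2 & below
    hpd = deg & sp & ~tie & ~sig_h_hp & sig_h_lp & (mu_h > mu_lp)
    lpd = deg & sp & ~tie & ~sig_h_lp & sig_h_hp & (mu_h < mu_hp)
    ad = deg & sp & s1 & s2 & between
    if require_midparent_test:
        ad &= ~sm

    klass = np.select([~deg, od, ud, hpd, lpd, ad],
                      ["NoDiff", "OD", "UD", "HPD", "LPD", "AD"],
                      default="Ambiguous")
    high_parent = np.where(tie, "tie", np.where(p1_high, "parent1", "parent2"))

    out = pd.DataFrame({
        "class": klass,
        "high_parent": high_parent,
        "sig_p12": sp, "dir_p12": c_p12["direction"].to_numpy(),
        "sig_hp1": s1, "dir_hp1": c_hp1["direction"].to_numpy(),
        "sig_hp2": s2, "dir_hp2": c_hp2["direction"].to_numpy(),
        "sig_mid": sm,
        "mu_p1": mu_p1, "mu_p2": mu_p2, "mu_h": mu_h,
        "p_adj_p12": c_p12["p_adj"].to_numpy(),
        "p_adj_hp1": c_hp1["p_adj"].to_numpy(),
        "p_adj_hp2": c_hp2["p_adj"].to_numpy(),
        "p_adj_mid": (c_mid["p_adj"].to_numpy() if c_mid is not None
                      else np.full(len(genes), np.nan)),
    }, index=genes)
    return out


# ---------------------------------------------------------------------------
# Class-spectrum summary
# ---------------------------------------------------------------------------

def round_percent(x: float, ndigits: int = 2) -> float:
    """Round half-up to ``ndigits`` decimals (matching printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(part: int | float, whole: int | float, ndigits: int = 2) -> float:
    """``part`` as a half-up rounded percentage of ``whole``."""
    if whole <= 0:
        raise InputError("percentage: whole must be positive")
    return round_percent(100.0 * part / whole, ndigits)


@dataclasses.dataclass(frozen=True)
class TriadSummary:
    """Class spectrum of a triad: counts, percentages and aggregates.

    Percentages are computed over the classified denominator (the five
    named classes, excluding NoDiff and Ambiguous) and rounded half-up to
    two decimals.  ``dominance`` aggregates HPD+LPD; ``nonadditive``
    aggregates HPD+LPD+OD+UD.
    """

    counts: Mapping[str, int]
    n_deg: int
    n_ambiguous: int

    @property
    def n_classified(self) -> int:
        return sum(self.counts.values())

    @property
    def percentages(self) -> dict[str, float]:
        denom = self.n_classified
        if denom == 0:
            return {c: 0.0 for c in CLASS_LABELS}
        return {c: percentage(self.counts[c], denom) for c in CLASS_LABELS}

    def _aggregate(self, classes: tuple[str, ...]) -> tuple[int, float]:
        count = sum(self.counts[c] for c in classes)
        denom = self.n_classified
        return count, (percentage(count, denom) if denom else 0.0)

    @property
    def dominance(self) -> tuple[int, float]:
        return self._aggregate(("HPD", "LPD"))

    @property
    def nonadditive(self) -> tuple[int, float]:
        return self._aggregate(("HPD", "LPD", "OD", "UD"))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int],
                    n_ambiguous: int = 0) -> "TriadSummary":
        unknown = set(counts) - set(CLASS_LABELS)
        if unknown:
            raise InputError(f"unknown classes {sorted(unknown)}")
        full = {c: int(counts.get(c, 0)) for c in CLASS_LABELS}
        if any(v < 0 for v in full.values()) or n_ambiguous < 0:
            raise InputError("counts must be non-negative")
        return cls(counts=full, n_deg=sum(full.values()) + n_ambiguous,
                   n_ambiguous=n_ambiguous)

    def to_dict(self) -> dict:
        dom_n, dom_pct = self.dominance
        non_n, non_pct = self.nonadditive
        return {
            "n_deg": self.n_deg,
            "n_classified": self.n_classified,
            "n_ambiguous": self.n_ambiguous,
            "counts": dict(self.counts),
            "percentages": self.percentages,
            "dominance": {"count": dom_n, "percent": dom_pct},
            "nonadditive": {"count": non_n, "percent": non_pct},
        }


def summarize_classes(calls: pd.DataFrame | Mapping[str, int]) -> TriadSummary:
    """Summarize gene-action calls (or a plain class->count mapping).

    When given the per-gene call table, NoDiff genes are outside the DEG
    set and Ambiguous genes are counted but excluded from the percentage
    denominator.
    """
    if isinstance(calls, pd.DataFrame):
        if calls.empty:
            raise InputError("summarize_classes: no calls")
        vc = calls["class"].value_counts()
        counts = {c: int(vc.get(c, 0)) for c in CLASS_LABELS}
        return TriadSummary.from_counts(counts,
                                        n_ambiguous=int(vc.get("Ambiguous", 0)))
    if not calls:
        raise InputError("summarize_classes: no counts")
    return TriadSummary.from_counts(calls)
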