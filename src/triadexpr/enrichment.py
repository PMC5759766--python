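"""Over-representation analysis of gene sets against an annotation map.

For a query set of n genes from a background universe of N genes, a term
annotating K universe genes and k query genes is scored by

* fold enrichment (k/n) / (K/N) -- the term's relative occurrence in the
  query set over its relative occurrence in the background, and
* the upper-tail hypergeometric probability P(X >= k).

Both a Bonferroni column (min(1, p*m), m = number of terms tested for this
query) and a Benjamini-Hochberg column are reported; significance is called
on the Bonferroni value at p < alpha (strict).  Terms with k = 0 are kept
with p = 1 so that m is stable across query sets of the same annotation.
The default background universe is the set of all annotated genes; pass an
explicit ``universe`` (e.g. all expressed genes) to widen it.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import adjust_bh, adjust_bonferroni
from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)


class AnnotationMap:
    """Gene -> annotation-term map with a derived term -> gene-set index.

    Terms with no genes inside the universe are dropped at indexing time.
    """

    def __init__(self, gene_to_terms: Mapping[str, Iterable[str]],
                 universe: Iterable[str] | None = None):
        if universe is None:
            universe = [g for g, ts in gene_to_terms.items() if ts]
        self.universe: frozenset[str] = frozenset(universe)
        if not self.universe:
            raise ParameterError("universe: empty")
        self.gene_to_terms: dict[str, frozenset[str]] = {
            g: frozenset(ts) for g, ts in gene_to_terms.items()
            if g in self.universe and ts}
        term_to_genes: dict[str, set[str]] = {}
        for g, ts in self.gene_to_terms.items():
            for t in ts:
                term_to_genes.setdefault(t, set()).add(g)
        self.term_to_genes: dict[str, frozenset[str]] = {
            t: frozenset(gs) for t, gs in term_to_genes.items() if gs}

    @property
    def terms(self) -> list[str]:
        return sorted(self.term_to_genes)

    @property
    def n_genes(self) -> int:
        return len(self.universe)

    def genes_with_term(self, term: str) -> frozenset[str]:
        return self.term_to_genes.get(term, frozenset())

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame | Iterable[tuple[str, str]],
                   universe: Iterable[str] | None = None) -> "AnnotationMap":
        """Build from (gene, term) pairs (two-column DataFrame or iterable)."""
        if isinstance(pairs, pd.DataFrame):
            pairs = pairs.iloc[:, :2].itertuples(index=False)
        g2t: dict[str, set[str]] = {}
        for gene, term in pairs:
            g2t.setdefault(str(gene), set()).add(str(term))
        return cls(g2t, universe=universe)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "AnnotationMap":
        """Read a headerless two-column gene<TAB>term file."""
        df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"],
                         dtype=str, comment="#")
        return cls.from_pairs(df, universe=universe)

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "AnnotationMap":
        """Read GMT: term<TAB>description<TAB>gene1<TAB>gene2..."""
        g2t: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                term = fields[0]
                for gene in fields[2:]:
                    if gene:
                        g2t.setdefault(gene, set()).add(term)
        return cls(g2t, universe=universe)

    def to_tsv(self, path: str | Path) -> None:
        rows = sorted((g, t) for g, ts in self.gene_to_terms.items() for t in ts)
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def _check_bounds(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N):
        raise ParameterError(f"require 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ParameterError(f"require 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ParameterError(f"require k <= K, got k={k}, K={K}")
    if n - k > N - K:
        raise ParameterError(
            f"impossible overlap: n-k={n - k} non-members exceed N-K={N - K}")


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_bounds(k, n, K, N)
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N); 0 when k = 0."""
    if n <= 0 or K <= 0:
        raise ParameterError(f"require n > 0 and K > 0, got n={n}, K={K}")
    _check_bounds(k, n, K, N)
    if k == 0:
        return 0.0
    return (k / n) / (K / N)


def enrich_terms(query_genes: Iterable[str], annotation: AnnotationMap,
                 alpha: float = 0.05, min_term_size: int = 1) -> pd.DataFrame:
    """Hypergeometric over-representation of every term in the query set.

    Returns one row per term with at least ``min_term_size`` universe genes,
    sorted by raw p then term id, with columns term, k, n, K, N,
    fold_enrichment, p_raw, p_bonferroni, p_bh and significant
    (Bonferroni < alpha).  An empty query/universe intersection yields an
    empty frame with a logged warning.
    """
    if min_term_size < 1:
        raise ParameterError("min_term_size: must be >= 1")
    query = set(query_genes) & annotation.universe
    cols = ["term", "k", "n", "K", "N", "fold_enrichment",
            "p_raw", "p_bonferroni", "p_bh", "significant"]
    if not query:
        logger.warning("enrich_terms: query does not intersect the universe")
        return pd.DataFrame(columns=cols)
    n = len(query)
    N = annotation.n_genes
    rows = []
    for term in annotation.terms:
        members = annotation.term_to_genes[term]
        K = len(members)
        if K < min_term_size:
            continue
        k = len(query & members)
        rows.append((term, k, n, K, N,
                     fold_enrichment(k, n, K, N),
                     hypergeom_pvalue(k, n, K, N)))
    df = pd.DataFrame(rows, columns=cols[:7])
    m = len(df)
    df["p_bonferroni"] = adjust_bonferroni(df["p_raw"].to_numpy(), m)
    df["p_bh"] = adjust_bh(df["p_raw"].to_numpy()) if m else np.array([])
    df["significant"] = df["p_bonferroni"] < alpha
    df = df.sort_values(["p_raw", "term"], kind="mergesort",
                        ignore_index=True)
    df.attrs.update(alpha=alpha, n_terms_tested=m)
    return df
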