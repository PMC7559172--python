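"""Over-representation analysis of a query gene list against GMT term sets.

For each term with ``K`` genes in a universe of ``N``, the overlap ``k``
with a query of ``n`` genes is tested with the hypergeometric upper tail
``p = P(X >= k)`` (equivalently a one-sided Fisher exact test).  Terms are
filtered on the raw p-value (conventional ``P < 0.05``); Benjamini–Hochberg
q-values are always reported alongside so FDR control remains available.

The default universe is the union of all genes in the collection; an
explicit background gene set can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "enrich", "bh_adjust", "top_terms"]


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation outcome."""

    term: str
    k: int  # overlap size
    n: int  # query size within the universe
    K: int  # term size within the universe
    N: int  # universe size
    p: float
    q: float
    overlap: tuple[str, ...]

    @property
    def fold(self) -> float:
        """Fold enrichment: (k/n) / (K/N)."""
        if self.K == 0 or self.n == 0:
            return 0.0
        return (self.k / self.n) / (self.K / self.N)


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values (monotone in p-rank, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="fdr_bh")[1])


def enrich(
    query: Iterable[str],
    collection: Mapping[str, set[str]],
    universe: Iterable[str] | str = "union",
    p_cutoff: float = 0.05,
    adjust: bool = True,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation test for every term.

    Gene symbols are upper-cased and deduplicated before intersection.
    Results with ``p < p_cutoff`` are returned sorted by p ascending, ties by
    overlap size descending, then term id.  ``adjust`` controls whether BH
    q-values are computed (over all tested terms, before the p filter).
    """
    query_set = {str(g).upper() for g in query}
    if isinstance(universe, str) and universe == "union":
        uni = set().union(*collection.values()) if collection else set()
    else:
        uni = {str(g).upper() for g in universe}
    q_in = query_set & uni
    if not q_in:
        missing = sorted(query_set)[:10]
        raise ValueError(
            "query has no genes in the universe; first unmatched symbols: "
            + ", ".join(missing)
        )
    N, n = len(uni), len(q_in)
    raw: list[tuple[str, int, int, tuple[str, ...], float]] = []
    for term in sorted(collection):
        genes = {g.upper() for g in collection[term]} & uni
        K = len(genes)
        overlap = tuple(sorted(genes & q_in))
        k = len(overlap)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        raw.append((term, k, K, overlap, p))
    qvals = bh_adjust([r[4] for r in raw]) if adjust else [float("nan")] * len(raw)
    results = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, p=p, q=q, overlap=ov)
        for (t, k, K, ov, p), q in zip(raw, qvals)
        if p < p_cutoff
    ]
    results.sort(key=lambda r: (r.p, -r.k, r.term))
    return results


def top_terms(results: Sequence[EnrichmentResult], n: int = 10) -> list[EnrichmentResult]:
    """Stable prefix of the sorted results (at most ``n`` entries)."""
    return list(results[:n])


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results for TSV export."""
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "overlap": r.k,
                "query_size": r.n,
                "term_size": r.K,
                "universe": r.N,
                "fold": r.fold,
                "p": r.p,
                "q": r.q,
                "genes": ";".join(r.overlap),
            }
            for r in results
        ]
    )
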