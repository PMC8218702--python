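"""Gene-list over-representation of a feature set (e.g. uORF-harboring genes).

For a gene list of size n drawn from a universe of N genes of which K carry
the feature, with k list genes carrying it, the upper-tail hypergeometric
probability is

    P(X >= k) = sum_{i=k}^{min(n,K)} C(K,i) C(N-K,n-i) / C(N,n)

and the sample (cross-product) odds ratio of the 2x2 table is
k(N-n-K+k) / ((n-k)(K-k)).  p-values across lists are adjusted with the
Benjamini-Hochberg step-up procedure; FDR < 0.05 is declared significant.
Both the list and the feature set are intersected with the universe before
any counting.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class EnrichmentResult:
    list_name: str
    universe_size: int       # N
    feature_set_size: int    # K, after universe intersection
    list_size: int           # n, after universe intersection
    intersection_size: int   # k
    p_value: float
    fdr: Optional[float] = None
    odds_ratio: float = float("nan")

    @property
    def significant(self) -> Optional[bool]:
        return None if self.fdr is None else self.fdr < FDR_SIGNIFICANCE_THRESHOLD


def hypergeometric_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k); computed on the log scale to survive magnitudes ~1e-61."""
    if k <= 0:
        return 1.0
    return float(math.exp(hypergeom.logsf(k - 1, N, K, n)))


def sample_odds_ratio(k: int, N: int, K: int, n: int) -> float:
    """Cross-product odds ratio of the 2x2 list-by-feature table."""
    num = k * (N - n - K + k)
    den = (n - k) * (K - k)
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def enrich_counts(list_name: str, k: int, N: int, K: int, n: int) -> EnrichmentResult:
    """Enrichment statistics from pre-tabulated 2x2 marginals."""
    if not 0 <= k <= min(n, K):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}")
    return EnrichmentResult(
        list_name=list_name,
        universe_size=N,
        feature_set_size=K,
        list_size=n,
        intersection_size=k,
        p_value=hypergeometric_upper_tail(k, N, K, n),
        odds_ratio=sample_odds_ratio(k, N, K, n),
    )


def enrich(gene_list: Iterable[str], feature_set: Iterable[str],
           universe: Iterable[str], list_name: str = "") -> EnrichmentResult:
    """Over-representation of ``feature_set`` genes within ``gene_list``.

    Genes absent from the universe are discarded from both sets before
    counting.  An empty filtered list yields k = 0 and p = 1 with a warning.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be non-empty")
    features = set(feature_set) & uni
    genes = set(gene_list) & uni
    if not genes:
        logger.warning("enrich(%s): gene list empty after universe filtering", list_name)
        return EnrichmentResult(
            list_name=list_name, universe_size=len(uni),
            feature_set_size=len(features), list_size=0, intersection_size=0,
            p_value=1.0, odds_ratio=float("nan"),
        )
    k = len(genes & features)
    return enrich_counts(list_name, k, len(uni), len(features), len(genes))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment; output order matches input order."""
    if len(p_values) == 0:
        return []
    _, adjusted, _, _ = multipletests(np.asarray(p_values, dtype=float),
                                      method="fdr_bh")
    return adjusted.tolist()


def enrich_many(results: list[EnrichmentResult]) -> list[EnrichmentResult]:
    """Fill the ``fdr`` field across a family of tests."""
    adjusted = bh_adjust([r.p_value for r in results])
    for res, fdr in zip(results, adjusted):
        res.fdr = fdr
    return results


def write_enrichment_csv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["list", "list_size", "feature_genes", "intersection",
                         "universe_size", "p_value", "fdr", "odds_ratio"])
        for r in results:
            writer.writerow([
                r.list_name, r.list_size, r.feature_set_size, r.intersection_size,
                r.universe_size, f"{r.p_value:.6g}",
                "" if r.fdr is None else f"{r.fdr:.6g}", f"{r.odds_ratio:.6g}",
            ])
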