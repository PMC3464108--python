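"""Gene-set overrepresentation of hit lists.

Given a hit list drawn from a universe of N scored genes and a gene set with
K members in that universe, the overlap k of the n hits with the set is
tested against the hypergeometric upper tail P(X >= k), X ~ Hypergeom(N, K,
n) — the classical one-sided overrepresentation test behind GO-term
analyses.  p-values are BH-adjusted across the tested sets.

The universe must be the genes that *could* have been hits — i.e. genes
scored after linkage filtering — not the whole genome; conditioning on the
wrong universe inflates enrichment.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import ConfigurationError
from .scoring import adjust_p

RESULT_COLUMNS = [
    "set_id", "universe_size", "set_size", "hits_size", "overlap",
    "p_hyper", "p_adjusted",
]


def hypergeometric_enrich(
    hits: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    min_set_size: int = 3,
    adjust_method: str = "BH",
) -> pd.DataFrame:
    """Upper-tail hypergeometric overrepresentation test per gene set.

    Set members are intersected with the universe before testing; sets with
    fewer than ``min_set_size`` members in the universe are skipped.  Raises
    if the hits are not a subset of the universe, naming the offenders.
    """
    universe = set(universe)
    hits = set(hits)
    stray = sorted(hits - universe)
    if stray:
        raise ConfigurationError(
            f"{len(stray)} hit(s) not in the universe: {stray[:10]}"
        )
    N, n = len(universe), len(hits)
    rows = []
    for set_id in sorted(gene_sets):
        members = set(gene_sets[set_id]) & universe
        K = len(members)
        if K < min_set_size:
            continue
        k = len(members & hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((set_id, N, K, n, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS[:-1])
    out["p_adjusted"] = adjust_p(out["p_hyper"].to_numpy(), adjust_method)
    return out.sort_values(["p_adjusted", "p_hyper", "set_id"],
                           kind="mergesort").reset_index(drop=True)


class GeneSetEnricher(BaseEstimator):
    """Estimator wrapper: fix the catalog and universe, then test hit lists.

    Parameters
    ----------
    min_set_size : smallest in-universe set size still tested (default 3).
    adjust_method : multiple-testing adjustment across sets (default BH).

    ``fit(gene_sets, universe)`` stores the catalog; ``transform(hits)``
    returns the enrichment table and stores it as ``results_``.
    """

    def __init__(self, min_set_size: int = 3, adjust_method: str = "BH"):
        self.min_set_size = min_set_size
        self.adjust_method = adjust_method

    def fit(self, X: Mapping[str, Iterable[str]], y: Iterable[str] = None
            ) -> "GeneSetEnricher":
        if y is None:
            raise ConfigurationError("fit requires the gene universe as y")
        self.gene_sets_ = {k: list(v) for k, v in X.items()}
        self.universe_ = list(y)
        return self

    def transform(self, hits: Iterable[str]) -> pd.DataFrame:
        if not hasattr(self, "gene_sets_"):
            raise ConfigurationError("GeneSetEnricher is not fitted")
        self.results_ = hypergeometric_enrich(
            hits, self.gene_sets_, self.universe_,
            min_set_size=self.min_set_size, adjust_method=self.adjust_method,
        )
        return self.results_
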