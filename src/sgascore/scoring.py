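"""Per-gene interaction statistics and hit calling.

The screen's statistic is deliberately simple: for each library gene, the
normalized colony sizes of the double mutant (test plates) are compared to
the position-matched single-mutant spots (control plates) with a paired
t-test.  When a screen was run twice, the two experiments' p-values are
combined with Fisher's method (−2·Σ ln p ~ χ² with 2k df).  Combined
p-values are adjusted for multiple testing over the post-linkage gene
universe, and a gene is called:

* **sick**   — adjusted p < alpha, mean size difference (control − test)
  greater than ``diff_threshold`` (default 25 area units), not linked;
* **rescue** — same, with the difference below ``−diff_threshold`` (the
  double mutant grows *better*, the pattern sought at the query's
  nonpermissive temperature).

Fisher combination additionally requires the per-experiment t-statistics to
agree in sign; two opposite-direction experiments can produce a small
combined p, and such genes are never called.

Pairing is by matched replicate grid position: control and test plates share
their spot layout, so (experiment, gene, replicate index) identifies a pair.
A spot of size 0 is a dead or failed pinning, not a measurement of growth, so
pairs with a dead spot on either side are invalid for the t-test; the
per-gene counts of dead control/test spots are reported alongside the
statistics so that fully lethal double mutants (all test spots dead, hence
too few valid pairs) remain visible rather than silently vanishing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from . import io as sio
from .errors import ConfigurationError

RESULT_COLUMNS = [
    "gene", "n_pairs", "n_dead_control", "n_dead_test",
    "mean_control", "mean_test", "diff",
    "t_stat", "p_raw", "x2", "p_combined", "p_adjusted",
    "sign_consistent", "status", "linked", "call",
]

STATUS_OK = "ok"
STATUS_DEGENERATE = "degenerate"
STATUS_INSUFFICIENT = "insufficient_data"


@dataclass(frozen=True)
class ScoringConfig:
    """Hit-calling thresholds and statistical options."""

    alpha: float = 0.05
    diff_threshold: float = 25.0
    adjust_method: str = "BH"       # BH | bonferroni | none
    combine: str = "fisher"         # fisher | none
    sided: str = "two"              # two | one (one = upper tail, sick side)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.diff_threshold <= 0:
            raise ConfigurationError("diff_threshold must be > 0")
        if self.adjust_method not in ("BH", "bonferroni", "none"):
            raise ConfigurationError(f"unknown adjust_method {self.adjust_method!r}")
        if self.combine not in ("fisher", "none"):
            raise ConfigurationError(f"unknown combine {self.combine!r}")
        if self.sided not in ("two", "one"):
            raise ConfigurationError(f"unknown sidedness {self.sided!r}")


@dataclass(frozen=True)
class PairedTResult:
    t_stat: float
    p_value: float
    diff: float
    n_pairs: int
    status: str
    mean_control: float = np.nan
    mean_test: float = np.nan


def paired_t(control, test, sided: str = "two") -> PairedTResult:
    """Paired t-test of position-matched control vs test colony sizes.

    ``d_i = control_i − test_i``; ``t = mean(d) / (sd(d)/√n)`` with ``n−1``
    degrees of freedom.  Two-sided by default; ``sided='one'`` is the upper
    tail (control larger, the sick direction).

    Degenerate inputs are flagged rather than raised: identical differences
    give ``status='degenerate'`` with p = 1 when the common difference is 0
    and p = 0 otherwise; fewer than 2 pairs give ``status='insufficient_data'``.
    """
    c = np.asarray(control, dtype=float)
    t = np.asarray(test, dtype=float)
    if c.shape != t.shape:
        raise ValueError("control and test must be position-matched")
    keep = np.isfinite(c) & np.isfinite(t)
    c, t = c[keep], t[keep]
    n = len(c)
    if n < 2:
        return PairedTResult(np.nan, np.nan, np.nan, n, STATUS_INSUFFICIENT)
    d = c - t
    dbar = float(np.mean(d))
    mc, mt = float(np.mean(c)), float(np.mean(t))
    if np.ptp(d) == 0.0:
        p = 1.0 if dbar == 0.0 else 0.0
        return PairedTResult(np.nan, p, dbar, n, STATUS_DEGENERATE, mc, mt)
    alternative = "two-sided" if sided == "two" else "greater"
    res = stats.ttest_rel(c, t, alternative=alternative)
    return PairedTResult(float(res.statistic), float(res.pvalue), dbar, n,
                         STATUS_OK, mc, mt)


def fisher_combine(p_values) -> tuple[float, int, float]:
    """Fisher's method: ``X² = −2·Σ ln pᵢ`` against χ² with 2k df.

    Returns (X², df, combined p).  A single p-value passes through unchanged
    (χ²₂ survival at −2·ln p is exactly p).  Zero p-values are clamped to the
    smallest positive float with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0.0):
        warnings.warn("p-value of 0 clamped to the smallest positive float",
                      stacklevel=2)
        p = np.maximum(p, np.finfo(float).tiny)
    x2, p_comb = stats.combine_pvalues(p, method="fisher")
    return float(x2), 2 * p.size, float(p_comb)


def adjust_p(p_values, method: str = "BH") -> np.ndarray:
    """Multiple-testing adjustment: BH step-up (default), Bonferroni, or none.

    Monotone by construction: adjusted ≥ raw, order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if method == "none":
        return p.copy()
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ConfigurationError(f"unknown adjust_method {method!r}")
    return multipletests(p, method=key)[1]


def _per_gene_stats(paired: pd.DataFrame, sided: str) -> pd.DataFrame:
    rows = []
    for (gene, exp), grp in paired.groupby(["gene", "experiment_id"], sort=True):
        r = paired_t(grp["size_control"], grp["size_test"], sided=sided)
        rows.append((gene, exp, r.n_pairs, r.mean_control, r.mean_test,
                     r.diff, r.t_stat, r.p_value, r.status))
    return pd.DataFrame(rows, columns=[
        "gene", "experiment_id", "n_pairs", "mean_control", "mean_test",
        "diff", "t_stat", "p_raw", "status",
    ])


def score_genes(X: pd.DataFrame, config: ScoringConfig = ScoringConfig()
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene statistics from a normalized colony table.

    Returns ``(results, per_experiment)``: the per-gene frame (one row per
    gene, experiments combined, calls not yet made) and the per-experiment
    statistics behind it.  Uses ``size_normalized`` when present, raw sizes
    otherwise (with a warning — the size-difference threshold presumes
    normalized units).
    """
    df = X[X["gene"] != sio.EMPTY_GENE]
    size_col = sio.NORMALIZED_COLUMN
    if size_col not in df.columns:
        warnings.warn("no size_normalized column; scoring raw sizes", stacklevel=2)
        size_col = "size"
    keys = ["experiment_id", "gene", "replicate"]
    ctrl = df[df["condition"] == "control"].loc[:, keys + [size_col]]
    test = df[df["condition"] == "test"].loc[:, keys + [size_col]]
    paired = ctrl.merge(test, on=keys, suffixes=("_control", "_test"))
    paired = paired.rename(columns={f"{size_col}_control": "size_control",
                                    f"{size_col}_test": "size_test"})
    # dead spots (size 0) are failed pinnings, not growth measurements:
    # count them per gene, then test only pairs alive on both sides
    dead = paired.groupby("gene").agg(
        n_dead_control=("size_control", lambda s: int((s == 0).sum())),
        n_dead_test=("size_test", lambda s: int((s == 0).sum())),
    )
    paired = paired[(paired["size_control"] > 0) & (paired["size_test"] > 0)]

    per_exp = _per_gene_stats(paired, config.sided)
    all_genes = sorted(df["gene"].unique())

    rows = []
    by_gene = dict(iter(per_exp.groupby("gene", sort=True)))
    for gene in all_genes:
        grp = by_gene.get(gene)
        if grp is None:
            rows.append((gene, 0, np.nan, np.nan, np.nan, np.nan, np.nan,
                         np.nan, np.nan, True, STATUS_INSUFFICIENT))
            continue
        usable = grp[grp["status"].isin([STATUS_OK, STATUS_DEGENERATE])]
        n_total = int(grp["n_pairs"].sum())
        first = grp.iloc[0]
        if usable.empty:
            rows.append((gene, n_total, np.nan, np.nan, np.nan,
                         first["t_stat"], first["p_raw"], np.nan, np.nan,
                         True, STATUS_INSUFFICIENT))
            continue
        w = usable["n_pairs"].to_numpy(dtype=float)
        mc = float(np.average(usable["mean_control"], weights=w))
        mt = float(np.average(usable["mean_test"], weights=w))
        diff = float(np.average(usable["diff"], weights=w))
        signs = np.sign(usable["diff"].to_numpy())
        sign_consistent = bool(len(set(signs[signs != 0])) <= 1)
        status = STATUS_OK if (usable["status"] == STATUS_OK).all() else STATUS_DEGENERATE
        ps = usable["p_raw"].to_numpy(dtype=float)
        if len(ps) == 1 or config.combine == "none":
            x2, p_comb = np.nan, float(ps[0])
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                x2, _, p_comb = fisher_combine(ps)
        rows.append((gene, n_total, mc, mt, diff, first["t_stat"],
                     first["p_raw"], x2, p_comb, sign_consistent, status))
    results = pd.DataFrame(rows, columns=[
        "gene", "n_pairs", "mean_control", "mean_test", "diff", "t_stat",
        "p_raw", "x2", "p_combined", "sign_consistent", "status",
    ])
    for col in ("n_dead_control", "n_dead_test"):
        results[col] = results["gene"].map(dead[col]).fillna(0).astype(int)
    results["linked"] = False
    results["p_adjusted"] = np.nan
    results["call"] = "none"
    return results.loc[:, RESULT_COLUMNS], per_exp


def call_hits(results: pd.DataFrame, config: ScoringConfig = ScoringConfig()
              ) -> pd.DataFrame:
    """Adjust combined p-values over the eligible universe and set calls.

    The universe is every scored, unlinked gene with a finite combined p
    (``status`` ok or degenerate); linked and coordinate-less genes keep
    their statistics but get ``p_adjusted = NaN`` and can never be called.
    """
    out = results.copy()
    eligible = (
        out["status"].isin([STATUS_OK, STATUS_DEGENERATE])
        & ~out["linked"].astype(bool)
        & out["p_combined"].notna()
    )
    out["p_adjusted"] = np.nan
    out.loc[eligible, "p_adjusted"] = adjust_p(
        out.loc[eligible, "p_combined"].to_numpy(), config.adjust_method
    )
    sick = (
        eligible
        & (out["p_adjusted"] < config.alpha)
        & (out["diff"] > config.diff_threshold)
        & out["sign_consistent"]
    )
    rescue = (
        eligible
        & (out["p_adjusted"] < config.alpha)
        & (out["diff"] < -config.diff_threshold)
        & out["sign_consistent"]
    )
    out["call"] = np.where(sick, "sick", np.where(rescue, "rescue", "none"))
    return out


def intersect_screens(results_a: pd.DataFrame, results_b: pd.DataFrame,
                      call: str = "sick") -> pd.DataFrame:
    """Genes called ``call`` in both screens, both screens' statistics attached."""
    shared_universe = set(results_a["gene"]) & set(results_b["gene"])
    if not shared_universe:
        warnings.warn("screens have disjoint gene universes", stacklevel=2)
    a = results_a[results_a["call"] == call]
    b = results_b[results_b["call"] == call]
    merged = a.merge(b, on="gene", suffixes=("_a", "_b"), how="inner")
    return merged.sort_values("gene", kind="mergesort").reset_index(drop=True)


class InteractionScorer(BaseEstimator):
    """Scikit-learn style estimator wrapping the per-gene scoring.

    ``fit`` consumes a normalized colony table (both conditions, one or two
    experiments) and populates:

    Attributes
    ----------
    stats_ : per-gene statistics before linkage/adjustment.
    per_experiment_ : per-(gene, experiment) paired-t results.
    results_ : ``stats_`` with p_adjusted and calls, assuming no linkage.
        For linkage-aware calls, flag ``stats_`` with a fitted
        :class:`~sgascore.linkage.LinkageFlagger` and re-run
        :func:`call_hits`.
    """

    def __init__(self, alpha: float = 0.05, diff_threshold: float = 25.0,
                 adjust_method: str = "BH", combine: str = "fisher",
                 sided: str = "two"):
        self.alpha = alpha
        self.diff_threshold = diff_threshold
        self.adjust_method = adjust_method
        self.combine = combine
        self.sided = sided

    def _config(self) -> ScoringConfig:
        return ScoringConfig(alpha=self.alpha, diff_threshold=self.diff_threshold,
                             adjust_method=self.adjust_method,
                             combine=self.combine, sided=self.sided)

    def fit(self, X: pd.DataFrame, y=None) -> "InteractionScorer":
        config = self._config()
        self.stats_, self.per_experiment_ = score_genes(X, config)
        self.results_ = call_hits(self.stats_, config)
        return self

    def hits(self, call: str = "sick") -> list[str]:
        return self.results_.loc[self.results_["call"] == call, "gene"].tolist()
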