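"""2x2 contingency statistics for cytological phenotype comparisons.

The screen's follow-up scores anaphases with lagging chromosomes per strain
(events out of totals) and compares strains against a reference with
Fisher's exact test — e.g. rescue of the query mutant's lagging-chromosome
frequency by a suppressor deletion.  Percentages come with exact
Clopper-Pearson 95% intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import FormatError


@dataclass(frozen=True)
class ContingencyTable:
    """Lagging-vs-normal anaphase counts for two strains."""

    strain_a: str
    strain_b: str
    a_event: int
    a_total: int
    b_event: int
    b_total: int

    def __post_init__(self):
        for ev, tot, name in ((self.a_event, self.a_total, self.strain_a),
                              (self.b_event, self.b_total, self.strain_b)):
            if tot < 1:
                raise ValueError(f"{name}: total must be >= 1")
            if not 0 <= ev <= tot:
                raise ValueError(f"{name}: need 0 <= events <= total")

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.a_event, self.a_total - self.a_event],
             [self.b_event, self.b_total - self.b_event]]
        )


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool


def fisher_exact(table: ContingencyTable, sided: str = "two") -> FisherResult:
    """Fisher's exact test on the 2x2 table.

    Exact hypergeometric-tail p over tables with the observed margins.  The
    two-sided p sums the probabilities of all tables no more likely than the
    observed one (minimum-likelihood convention).  Tables with a zero column
    margin (no events anywhere, or events everywhere) are degenerate: p = 1.
    """
    arr = table.as_array()
    degenerate = (arr.sum(axis=0) == 0).any()
    alternative = {"two": "two-sided", "less": "less", "greater": "greater"}.get(sided)
    if alternative is None:
        raise ValueError(f"sided must be two|less|greater, got {sided!r}")
    odds, p = stats.fisher_exact(arr, alternative=alternative)
    if degenerate:
        p = 1.0
    return FisherResult(p_value=float(p), odds_ratio=float(odds),
                        degenerate=bool(degenerate))


def rate_summary(counts: pd.DataFrame, confidence: float = 0.95) -> pd.DataFrame:
    """Per-strain event percentage with exact binomial CI.

    ``counts`` needs columns ``strain, events, total``.  Returns percent
    (100·events/total) and Clopper-Pearson interval bounds, all in percent.
    Strains with total 0 are flagged undefined rather than raised.
    """
    for col in ("strain", "events", "total"):
        if col not in counts.columns:
            raise FormatError(f"counts table missing column {col!r}")
    rows = []
    for _, rec in counts.iterrows():
        ev, tot = int(rec["events"]), int(rec["total"])
        if tot <= 0:
            rows.append((rec["strain"], ev, tot, np.nan, np.nan, np.nan, False))
            continue
        lo, hi = proportion_confint(ev, tot, alpha=1 - confidence, method="beta")
        rows.append((rec["strain"], ev, tot, 100.0 * ev / tot,
                     100.0 * lo, 100.0 * hi, True))
    return pd.DataFrame(rows, columns=[
        "strain", "events", "total", "percent", "ci_low", "ci_high", "defined",
    ])


def read_counts_table(path) -> pd.DataFrame:
    """Read a per-strain counts TSV with columns ``strain, events, total``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("strain", "events", "total"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    df["events"] = df["events"].astype(int)
    df["total"] = df["total"].astype(int)
    if ((df["events"] < 0) | (df["events"] > df["total"])).any():
        raise FormatError(f"{path}: need 0 <= events <= total")
    return df


def compare_to_reference(counts: pd.DataFrame, reference: str,
                         sided: str = "two") -> pd.DataFrame:
    """Fisher-exact p for every strain against the reference strain."""
    if reference not in set(counts["strain"]):
        raise FormatError(f"reference strain {reference!r} not in counts table")
    ref = counts[counts["strain"] == reference].iloc[0]
    rows = []
    for _, rec in counts.iterrows():
        if rec["strain"] == reference:
            continue
        tab = ContingencyTable(rec["strain"], reference,
                               int(rec["events"]), int(rec["total"]),
                               int(ref["events"]), int(ref["total"]))
        res = fisher_exact(tab, sided=sided)
        rows.append((rec["strain"], reference,
                     100.0 * rec["events"] / rec["total"],
                     100.0 * ref["events"] / ref["total"],
                     res.odds_ratio, res.p_value, res.degenerate))
    return pd.DataFrame(rows, columns=[
        "strain", "reference", "percent", "reference_percent",
        "odds_ratio", "p_value", "degenerate",
    ])
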