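"""Linkage-window filtering.

Genes physically near the query locus (or near a selection-marker locus)
cannot recombine away from it during the cross, so their double-mutant
recovery is biased regardless of any genetic interaction.  The screen
therefore excludes genes within a fixed physical window — 500 kb by default —
around each such locus from multiple-testing adjustment and hit calling.
Flagged genes keep their statistics (the record stays auditable); they are
simply removed from the adjustment universe and can never be called.

Distance is measured from the window center to the nearest base of the gene
interval (0 if the center falls inside the gene); the window boundary is
inclusive, so a gene at exactly ``half_width`` is linked.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError


@dataclass(frozen=True)
class LinkageWindow:
    """A symmetric exclusion window around one locus."""

    chromosome: str
    center: int
    half_width: int = 500_000

    def __post_init__(self):
        if self.half_width <= 0:
            raise ConfigurationError("half_width must be > 0")
        if self.center < 0:
            raise ConfigurationError("center must be >= 0")


_WINDOW_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<center>\d+)(?:±|\+-)(?P<hw>\d+)$")


def parse_window(spec: str) -> LinkageWindow:
    """Parse ``"chr2:2000000±500000"`` (ASCII ``+-`` also accepted)."""
    m = _WINDOW_RE.match(spec.strip())
    if not m:
        raise FormatError(
            f"bad window spec {spec!r}; expected chrom:center±half_width"
        )
    return LinkageWindow(m["chrom"], int(m["center"]), int(m["hw"]))


def interval_distance(center: int, start: int, end: int) -> int:
    """bp distance from a point to the nearest base of [start, end).

    0 when the center lies inside the interval; the last base is ``end - 1``.
    """
    if center < start:
        return start - center
    if center >= end:
        return center - (end - 1)
    return 0


def flag_linked(
    annotations: pd.DataFrame, windows: Sequence[LinkageWindow]
) -> pd.Series:
    """Flag genes linked to any window.

    Parameters
    ----------
    annotations : DataFrame with columns ``gene, chromosome, start, end``
        (0-based half-open).
    windows : the exclusion windows.

    Returns a boolean Series indexed by gene: True iff the gene lies on a
    window's chromosome with interval distance <= half_width (boundary
    inclusive).
    """
    chrom = annotations["chromosome"].to_numpy()
    start = annotations["start"].to_numpy(dtype=np.int64)
    end = annotations["end"].to_numpy(dtype=np.int64)
    linked = np.zeros(len(annotations), dtype=bool)
    for w in windows:
        on_chrom = chrom == w.chromosome
        below = w.center < start
        above = w.center >= end
        dist = np.where(below, start - w.center,
                        np.where(above, w.center - (end - 1), 0))
        linked |= on_chrom & (dist <= w.half_width)
    return pd.Series(linked, index=pd.Index(annotations["gene"], name="gene"),
                     name="linked")


class LinkageFlagger:
    """Estimator-style wrapper: learns the flag map from annotations, then
    annotates scored results.

    Parameters
    ----------
    windows : sequence of LinkageWindow (or parseable specs).

    Attributes
    ----------
    linked_ : pd.Series mapping gene -> bool, after :meth:`fit`.
    """

    def __init__(self, windows: Iterable[LinkageWindow | str] = ()):
        self.windows = list(windows)

    def get_params(self, deep: bool = True) -> dict:
        return {"windows": self.windows}

    def set_params(self, **params) -> "LinkageFlagger":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def _windows(self) -> list[LinkageWindow]:
        return [w if isinstance(w, LinkageWindow) else parse_window(w)
                for w in self.windows]

    def fit(self, annotations: pd.DataFrame, y=None) -> "LinkageFlagger":
        self.linked_ = flag_linked(annotations, self._windows())
        return self

    def transform(self, results: pd.DataFrame) -> pd.DataFrame:
        """Set the ``linked`` column on a per-gene results frame.

        Genes without coordinates are marked ``status='no_coordinates'`` and
        treated as linked for universe purposes (excluded from adjustment),
        with a warning.
        """
        if not hasattr(self, "linked_"):
            raise ConfigurationError("LinkageFlagger is not fitted")
        out = results.copy()
        known = out["gene"].isin(self.linked_.index)
        out["linked"] = (
            out["gene"].map(self.linked_).astype("boolean").fillna(False).astype(bool)
        )
        if (~known).any():
            import warnings

            missing = out.loc[~known, "gene"].tolist()
            warnings.warn(
                f"{len(missing)} gene(s) lack coordinates and are excluded "
                f"from the adjustment universe: {missing[:5]}...",
                stacklevel=2,
            )
            if "status" in out.columns:
                out.loc[~known, "status"] = "no_coordinates"
            else:
                out["status"] = np.where(known, "ok", "no_coordinates")
        return out

    def fit_transform(self, annotations: pd.DataFrame, results: pd.DataFrame
                      ) -> pd.DataFrame:
        return self.fit(annotations).transform(results)
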