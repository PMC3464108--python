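"""Two-step colony-size normalization.

Colonies on the outermost two rows and columns of an arrayed plate grow
larger than interior colonies (more nutrient access), and whole plates differ
in overall growth.  The correction is multiplicative, per plate:

1. **Edge step** — edge-spot sizes are scaled by ``f_p = m_p / e_p`` so the
   edge ring matches the plate middle mean ``m_p`` (mean size over spots not
   in the outermost two rows/columns).  Middle spots are untouched.
2. **Plate step** — every spot on plate ``p`` is scaled by ``g_p = M / m_p``
   where ``M`` is the median of the plate middle means across all plates, so
   every plate ends at the same middle mean ``M``.

Dead spots (size 0) participate in both means: a dead middle colony is a real
observation that legitimately lowers the plate's growth estimate.  Positions
that were never spotted with a library strain (sentinel gene ``EMPTY`` on a
partially filled plate) are different — they are structural, not biological —
so they are excluded from the plate statistics while still receiving the
plate's scale factors.  A plate whose middle spots are *all* zero cannot be
normalized; it is excluded from ``M`` and its spots are marked
unnormalizable (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from . import io as sio
from .errors import ConfigurationError, InsufficientDataError

REPORT_COLUMNS = [
    "experiment_id", "condition", "plate_id",
    "middle_mean", "edge_mean", "edge_factor", "plate_scale", "target",
    "normalizable",
]


def partition_edge_middle(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    """Boolean edge/middle masks for a ``rows x cols`` grid, row-major.

    Edge = outermost two rows and two columns; middle = complement.  Requires
    at least 5 rows and 5 columns so a middle exists.
    """
    if rows < 5 or cols < 5:
        raise ConfigurationError(
            f"grid {rows}x{cols} too small: need >= 5 rows and columns"
        )
    r = np.repeat(np.arange(1, rows + 1), cols)
    c = np.tile(np.arange(1, cols + 1), rows)
    edge = (r <= 2) | (r > rows - 2) | (c <= 2) | (c > cols - 2)
    return edge, ~edge


def edge_mask_for(plate: pd.DataFrame, geom: sio.PlateGeometry) -> np.ndarray:
    """Edge mask aligned with the rows of one plate frame."""
    if geom.rows < 5 or geom.cols < 5:
        raise ConfigurationError(
            f"grid {geom.rows}x{geom.cols} too small: need >= 5 rows and columns"
        )
    r = plate["row"].to_numpy()
    c = plate["col"].to_numpy()
    return (r <= 2) | (r > geom.rows - 2) | (c <= 2) | (c > geom.cols - 2)


def _ring_index(plate: pd.DataFrame, geom: sio.PlateGeometry) -> np.ndarray:
    """0 = middle, 1 = second ring, 2 = outermost ring."""
    r = plate["row"].to_numpy()
    c = plate["col"].to_numpy()
    depth = np.minimum.reduce([r - 1, geom.rows - r, c - 1, geom.cols - c])
    return np.where(depth == 0, 2, np.where(depth == 1, 1, 0))


class PlateNormalizer(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer applying the two-step normalization.

    Parameters
    ----------
    middle_stat : {"mean", "median"}, default "mean"
        Statistic summarizing middle (and edge) spot sizes per plate.  The
        procedure is defined on the mean; the median is a robustness option.
    per_ring : bool, default False
        If True, the outermost ring and the second ring each get their own
        factor instead of one factor for the whole two-deep edge.

    Attributes
    ----------
    report_ : DataFrame, one row per plate with ``m_p``, ``e_p``,
        ``f_p = m_p/e_p``, ``g_p = M/m_p`` and the normalizable flag.
    target_ : float
        The common middle mean ``M`` (median of plate middle means).

    ``fit`` learns the per-plate factors from a colony table; ``transform``
    applies them to the same plates, filling ``size_normalized``.  Sizes are
    read from ``size_normalized`` when present (so the transform is
    idempotent), else from ``size``.
    """

    def __init__(self, middle_stat: str = "mean", per_ring: bool = False):
        self.middle_stat = middle_stat
        self.per_ring = per_ring

    def _stat(self, x: np.ndarray) -> float:
        if self.middle_stat == "mean":
            return float(np.mean(x)) if len(x) else np.nan
        if self.middle_stat == "median":
            return float(np.median(x)) if len(x) else np.nan
        raise ConfigurationError(f"middle_stat must be mean|median, got {self.middle_stat!r}")

    @staticmethod
    def _sizes(plate: pd.DataFrame) -> np.ndarray:
        if sio.NORMALIZED_COLUMN in plate.columns and plate[sio.NORMALIZED_COLUMN].notna().all():
            return plate[sio.NORMALIZED_COLUMN].to_numpy(dtype=float)
        return plate["size"].to_numpy(dtype=float)

    def fit(self, X: pd.DataFrame, y=None) -> "PlateNormalizer":
        self._stat(np.zeros(1))  # validate middle_stat eagerly
        rows = []
        factors: dict[tuple, dict] = {}
        for key, plate in sio.iter_plates(X):
            geom = sio.plate_geometry(plate)
            sizes = self._sizes(plate)
            edge = edge_mask_for(plate, geom)
            spotted = (plate["gene"] != sio.EMPTY_GENE).to_numpy()
            m_p = self._stat(sizes[~edge & spotted])
            e_p = self._stat(sizes[edge & spotted])
            normalizable = m_p > 0
            f_p = m_p / e_p if (normalizable and e_p > 0) else 1.0
            entry = {"m": m_p, "e": e_p, "f": f_p, "ok": normalizable}
            if self.per_ring:
                ring = _ring_index(plate, geom)
                ring_f = {}
                for k in (1, 2):
                    rk = self._stat(sizes[(ring == k) & spotted])
                    ring_f[k] = m_p / rk if (normalizable and rk > 0) else 1.0
                entry["ring_f"] = ring_f
            factors[key] = entry
            rows.append(dict(zip(["experiment_id", "condition", "plate_id"], key),
                             middle_mean=m_p, edge_mean=e_p, edge_factor=f_p,
                             normalizable=normalizable))
        if not rows:
            raise InsufficientDataError("no plates to normalize")
        report = pd.DataFrame(rows)
        usable = report.loc[report["normalizable"], "middle_mean"]
        if usable.empty:
            raise InsufficientDataError("all plates have all-zero middle spots")
        M = float(np.median(usable))
        report["plate_scale"] = np.where(
            report["normalizable"], M / report["middle_mean"], np.nan
        )
        report["target"] = M
        self.report_ = report.loc[:, REPORT_COLUMNS]
        self.target_ = M
        for key, entry in factors.items():
            entry["g"] = M / entry["m"] if entry["ok"] else np.nan
        self._factors_ = factors
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "_factors_"):
            raise ConfigurationError("PlateNormalizer is not fitted")
        out = X.copy()
        normalized = np.full(len(out), np.nan)
        pos = {idx: i for i, idx in enumerate(out.index)}
        for key, plate in sio.iter_plates(out):
            if key not in self._factors_:
                raise ConfigurationError(f"plate {key} was not seen during fit")
            fac = self._factors_[key]
            geom = sio.plate_geometry(plate)
            sizes = self._sizes(plate)
            ix = [pos[i] for i in plate.index]
            if not fac["ok"]:
                continue  # unnormalizable: stays NaN
            if self.per_ring:
                ring = _ring_index(plate, geom)
                mult = np.where(ring == 2, fac["ring_f"][2],
                                np.where(ring == 1, fac["ring_f"][1], 1.0))
            else:
                edge = edge_mask_for(plate, geom)
                mult = np.where(edge, fac["f"], 1.0)
            normalized[ix] = sizes * mult * fac["g"]
        out[sio.NORMALIZED_COLUMN] = normalized
        return out


def normalize_plates(
    X: pd.DataFrame, middle_stat: str = "mean", per_ring: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Functional front end: returns (table with ``size_normalized``, report)."""
    norm = PlateNormalizer(middle_stat=middle_stat, per_ring=per_ring)
    out = norm.fit(X).transform(X)
    return out, norm.report_


@dataclass(frozen=True)
class NormalitySummary:
    """Advisory distribution check of the per-gene t-statistics."""

    n: int
    skewness: float
    excess_kurtosis: float
    shapiro_p: float


def qc_tstat_normality(t_statistics) -> NormalitySummary:
    """Summarize how normal a vector of t-statistics looks.

    A roughly normal t distribution after linkage exclusion is a sanity check
    that the screen's nulls dominate and the pairing is sound; the summary is
    advisory and never blocks the pipeline.  Requires >= 20 finite values.
    """
    t = np.asarray(t_statistics, dtype=float)
    t = t[np.isfinite(t)]
    if len(t) < 20:
        raise InsufficientDataError(
            f"need >= 20 finite t-statistics, got {len(t)}"
        )
    if np.ptp(t) == 0:
        raise ValueError("t-statistics are constant (zero variance)")
    return NormalitySummary(
        n=len(t),
        skewness=float(stats.skew(t)),
        excess_kurtosis=float(stats.kurtosis(t)),
        shapiro_p=float(stats.shapiro(t[:5000]).pvalue),
    )
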