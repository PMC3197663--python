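"""Spine-pair dominance dynamics.

The core statistic: for a spine pair tracked over hourly frames, the
difference index at each time point is

    DiffIndex(t) = (IntDen_Dom(t) − IntDen_Nondom(t))
                   / (IntDen_Dom(t) + IntDen_Nondom(t)),

where IntDen is each head's integrated density (a volume proxy) and the
dominant spine is preselected as the one with the higher average integrated
density over the analysis window. The slope of the least-squares linear
trend of DiffIndex against time is the dominance rate (ΔDiffIndex/h), with
R² measuring trend strength. Analysis uses the first 15 h of each series.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats
from .errors import ConfigError, DegenerateVarianceError, InsufficientDataError
from .records import SpineRecord

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_H = 15.0

__all__ = [
    "PairDynamics",
    "truncate_series",
    "preselect_dominant",
    "difference_index",
    "dominance_fit",
    "pair_dynamics",
    "pair_ssb_neighbors",
    "compare_classes",
    "comparison_table",
    "DEFAULT_WINDOW_H",
]


@dataclass
class PairDynamics:
    """Per-frame integrated densities and the fitted dominance trend of a pair."""

    pair_id: int
    pair_class: str  # msb | ssb
    times: np.ndarray  # h, strictly increasing
    intden_dom: np.ndarray
    intden_nondom: np.ndarray
    diff_index: np.ndarray  # NaN marks missing frames
    dominance_rate: float
    r_squared: float
    dom_id: int | None = None
    nondom_id: int | None = None
    truth_rate: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ConfigError("times: must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_h": self.times, "intden_dom": self.intden_dom,
            "intden_nondom": self.intden_nondom, "diff_index": self.diff_index})


def truncate_series(times: np.ndarray, *series: np.ndarray,
                    window_h: float = DEFAULT_WINDOW_H,
                    start_frame: int = 0) -> tuple[np.ndarray, ...]:
    """Keep frames within ``window_h`` hours of the start frame.

    ``start_frame`` is the first frame at which the synapse is discernable
    (an explicit per-pair judgment; default: the series start). With hourly
    frames and the default 15 h window this keeps 16 frames.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ConfigError("times: series must be nonempty")
    if not 0 <= start_frame < times.size:
        raise ConfigError(f"start_frame: {start_frame} out of range")
    if window_h < 0:
        raise ConfigError("window_h: must be >= 0")
    t0 = times[start_frame]
    keep = slice(start_frame, int(np.searchsorted(times, t0 + window_h, "right")))
    return (times[keep],) + tuple(np.asarray(s)[keep] for s in series)


def preselect_dominant(series_a: np.ndarray, series_b: np.ndarray,
                       id_a=0, id_b=1) -> tuple:
    """Preselect the dominant spine: the higher mean integrated density.

    Returns ``(dom_id, nondom_id)``. Ties go to the lexicographically
    smaller id, with a logged warning.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ConfigError("series: both series must have equal length >= 1")
    mean_a, mean_b = np.nanmean(a), np.nanmean(b)
    if mean_a > mean_b:
        return id_a, id_b
    if mean_b > mean_a:
        return id_b, id_a
    first, second = sorted((id_a, id_b), key=str)
    logger.warning("tied mean integrated densities; dominant defaults to %r", first)
    return first, second


def difference_index(intden_dom, intden_nondom):
    """DiffIndex = (Dom − Nondom) / (Dom + Nondom), elementwise.

    Frames where both densities are zero (e.g. bouton label absent) are
    undefined and returned as NaN with a warning.
    """
    dom = np.asarray(intden_dom, dtype=float)
    non = np.asarray(intden_nondom, dtype=float)
    scalar = dom.ndim == 0
    dom, non = np.atleast_1d(dom), np.atleast_1d(non)
    if (dom < 0).any() or (non < 0).any():
        raise ConfigError("integrated densities must be >= 0")
    total = dom + non
    undefined = total == 0
    if undefined.any():
        warnings.warn("DiffIndex undefined where both integrated densities are 0; "
                      "marked missing", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        di = np.where(undefined, np.nan, (dom - non) / np.where(undefined, 1, total))
    return float(di[0]) if scalar else di


def dominance_fit(times: np.ndarray, diff_index: np.ndarray
                  ) -> tuple[float, float]:
    """Ordinary least-squares linear trend of DiffIndex against time.

    Returns ``(dominance_rate, r_squared)``; the rate is the slope in
    ΔDiffIndex/h and R² the squared Pearson correlation. Missing (NaN)
    frames are skipped. A constant series has rate 0 and R² defined as 0
    (no trend explained).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(diff_index, dtype=float)
    if t.shape != y.shape:
        raise ConfigError("times and diff_index must have equal length")
    valid = ~np.isnan(y) & ~np.isnan(t)
    t, y = t[valid], y[valid]
    if t.size < 2:
        raise InsufficientDataError(
            f"need >= 2 non-missing frames for a trend fit, have {t.size}")
    st = t - t.mean()
    if np.allclose(st, 0):
        raise ConfigError("zero time variance: all frames at the same time")
    sy = y - y.mean()
    slope = float((st * sy).sum() / (st * st).sum())
    ss_y = float((sy * sy).sum())
    if ss_y == 0.0:
        return slope, 0.0
    r = float((st * sy).sum() / np.sqrt((st * st).sum() * ss_y))
    return slope, r * r


def pair_dynamics(pair_id: int, pair_class: str, times: np.ndarray,
                  intden_a: np.ndarray, intden_b: np.ndarray, *,
                  id_a=0, id_b=1, window_h: float = DEFAULT_WINDOW_H,
                  start_frame: int = 0, truth_rate: float | None = None
                  ) -> PairDynamics:
    """Full per-pair analysis: truncate, preselect, DiffIndex, trend fit."""
    t, a, b = truncate_series(times, intden_a, intden_b,
                              window_h=window_h, start_frame=start_frame)
    dom_id, _ = preselect_dominant(a, b, id_a, id_b)
    dom, non = (a, b) if dom_id == id_a else (b, a)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        di = difference_index(dom, non)
    rate, r2 = dominance_fit(t, di)
    return PairDynamics(
        pair_id=pair_id, pair_class=pair_class, times=t,
        intden_dom=dom, intden_nondom=non, diff_index=di,
        dominance_rate=rate, r_squared=r2,
        dom_id=dom_id, nondom_id=id_b if dom_id == id_a else id_a,
        truth_rate=truth_rate)


def pair_ssb_neighbors(ssb_spines: list[SpineRecord],
                       all_spines: list[SpineRecord]
                       ) -> list[tuple[SpineRecord, SpineRecord]]:
    """Pair each single-bouton spine with its nearest neighbor spine.

    Nearest by head distance at the first frame, among all other spines.
    Duplicate pairs (a,b)/(b,a) are emitted once; a spine with no candidate
    neighbor is skipped with a warning.
    """
    from .geometry import head_distance
    out = []
    seen: set[frozenset[int]] = set()
    for spine in ssb_spines:
        candidates = [s for s in all_spines if s.id != spine.id]
        if not candidates:
            warnings.warn(f"spine {spine.id}: no neighbor available; skipped",
                          stacklevel=2)
            continue
        nearest = min(candidates, key=lambda s: head_distance(spine, s))
        key = frozenset((spine.id, nearest.id))
        if key in seen:
            continue
        seen.add(key)
        out.append((spine, nearest))
    return out


def _class_stats(pairs: list[PairDynamics]) -> dict:
    rates = np.array([p.dominance_rate for p in pairs], dtype=float)
    r2s = np.array([p.r_squared for p in pairs], dtype=float)
    return {
        "n": len(pairs),
        "rate_mean": float(rates.mean()),
        "rate_sd": float(rates.std(ddof=1)) if len(pairs) > 1 else None,
        "r2_mean": float(r2s.mean()),
        "r2_sd": float(r2s.std(ddof=1)) if len(pairs) > 1 else None,
        "rates": rates,
        "r2s": r2s,
    }


def compare_classes(msb: list[PairDynamics], ssb: list[PairDynamics],
                    alpha: float = 0.05) -> dict:
    """Compare dominance statistics between MSB and single-bouton pairs.

    Reports per-class mean ± SD of the dominance rate and R², MSB:SSB fold
    ratios of the means, and one-tailed t-test p-values for the alternative
    that the MSB mean exceeds the SSB mean. A class with fewer than 2 pairs
    leaves the tests marked not-computable.
    """
    if not msb or not ssb:
        raise InsufficientDataError("both classes must be nonempty")
    cm, cs = _class_stats(msb), _class_stats(ssb)

    def fold(num, den):
        if den == 0:
            return float("inf") if num > 0 else float("nan")
        return num / den
    report = {
        "msb": {k: v for k, v in cm.items() if k not in ("rates", "r2s")},
        "ssb": {k: v for k, v in cs.items() if k not in ("rates", "r2s")},
        "rate_fold": fold(cm["rate_mean"], cs["rate_mean"]),
        "r2_fold": fold(cm["r2_mean"], cs["r2_mean"]),
        "alpha": alpha,
    }
    for key, attr in (("rate", "rates"), ("r2", "r2s")):
        if cm["n"] < 2 or cs["n"] < 2:
            report[f"{key}_p_one_tailed"] = None
            report[f"{key}_test"] = "not computable (class with < 2 pairs)"
            continue
        try:
            result = _stats.t_test_one_tailed(cm[attr], cs[attr],
                                              alternative="greater", alpha=alpha)
        except DegenerateVarianceError:
            report[f"{key}_p_one_tailed"] = None
            report[f"{key}_test"] = "not computable (zero variance in both classes)"
            continue
        report[f"{key}_p_one_tailed"] = result.p_value
        report[f"{key}_test"] = result.to_dict()
    return report


def comparison_table(report: dict) -> pd.DataFrame:
    """Render a class-comparison report as a two-row table."""
    rows = []
    for cls in ("msb", "ssb"):
        c = report[cls]
        rows.append({"class": cls, "n": c["n"],
                     "rate_mean": c["rate_mean"], "rate_sd": c["rate_sd"],
                     "r2_mean": c["r2_mean"], "r2_sd": c["r2_sd"]})
    return pd.DataFrame(rows)
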