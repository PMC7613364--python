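"""Season detection and phenology-indicator extraction.

From a reconstructed (regularly gridded) series, growing seasons are
segmented as prominent local maxima flanked by the deepest local minima,
and per season the standard threshold-based indicators are computed:

- SOS / EOS: day the curve crosses base_level + 20% of the seasonal
  amplitude on the rising / falling limb (percent-of-amplitude rule);
- DOM: day of maximum; LOS = EOS - SOS;
- amplitude: seasonal maximum minus the base level (mean of the flanking
  minimum values);
- green area: integral of the curve above the base level between SOS and
  EOS; blue area: integral of the curve above zero over the same window
  (the large/small seasonal integrals of the TIMESAT tradition).

Crossings are located by linear interpolation between grid points; on the
rising limb the *last* upward crossing before the peak is taken and on the
falling limb the *first* downward crossing after it, which is conservative
on noisy flanks with multiple crossings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core_gpr import PredictiveSeries
from .errors import InvalidInputError
from .gapfill import FLAG_OK, FLAG_FALLBACK, ReconstructionResult

DEFAULT_THRESHOLD_FRAC = 0.20
DEFAULT_MIN_PROMINENCE = 0.10  # fraction of the series' global range
DEFAULT_MIN_SEASON_LENGTH = 30.0  # days
_FLAT_TOL = 1e-12

METRIC_NAMES = ("sos", "eos", "los", "dom", "max_value", "amplitude",
                "blue_area", "green_area")


@dataclass
class SeasonSegment:
    """One detected season: peak and flanking minima (time, value) pairs."""

    left_min: tuple[float, float]
    peak: tuple[float, float]
    right_min: tuple[float, float]

    def __post_init__(self):
        if not (self.left_min[0] < self.peak[0] < self.right_min[0]):
            raise InvalidInputError("season extrema out of order")
        if self.peak[1] < max(self.left_min[1], self.right_min[1]):
            raise InvalidInputError("peak below a flanking minimum")

    @property
    def base_level(self) -> float:
        """Mean of the left and right minimum values."""
        return 0.5 * (self.left_min[1] + self.right_min[1])


@dataclass
class SeasonMetrics:
    """Phenology indicators for one season.

    Days are on the same day-since-epoch axis as the series; max_value and
    amplitude are in descriptor units, areas in descriptor-units x days.
    ``missing_reason`` is set (and day metrics are NaN) when a threshold
    level is never crossed on one side, e.g. for edge or plateau seasons.
    """

    sos: float
    eos: float
    los: float
    dom: float
    max_value: float
    amplitude: float
    blue_area: float
    green_area: float
    missing_reason: str | None = None

    def __post_init__(self):
        if self.missing_reason is None:
            if not (self.sos < self.dom < self.eos):
                raise InvalidInputError("SOS < DOM < EOS violated")
            assert abs(self.los - (self.eos - self.sos)) < 1e-9
            if not np.isfinite([self.sos, self.eos, self.los, self.dom,
                                self.max_value, self.amplitude,
                                self.blue_area, self.green_area]).all():
                raise InvalidInputError("non-finite phenology metric")


def detect_seasons(
    series: PredictiveSeries,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_season_length: float = DEFAULT_MIN_SEASON_LENGTH,
) -> list[SeasonSegment]:
    """Segment a regularly gridded series into seasons.

    Peaks are local maxima with prominence at least ``min_prominence`` times
    the series' global range; each peak is flanked by the deepest minimum
    between it and the neighbouring peak (series endpoints act as minima).
    Segments spanning less than ``min_season_length`` days are dropped.
    A flat series yields no seasons.
    """
    t = np.asarray(series.times, float)
    v = np.asarray(series.mean, float)
    if t.size < 3:
        raise InvalidInputError("need at least 3 grid points")
    rng = float(np.nanmax(v) - np.nanmin(v))
    if not np.isfinite(rng) or rng < _FLAT_TOL:
        return []
    peaks, _ = find_peaks(v, prominence=min_prominence * rng)
    if peaks.size == 0:
        return []
    segments = []
    bounds = np.concatenate([[0], peaks, [t.size - 1]])
    for i, p in enumerate(peaks):
        lo, hi = bounds[i], bounds[i + 2]
        li = lo + int(np.argmin(v[lo:p + 1]))
        ri = p + int(np.argmin(v[p:hi + 1]))
        if li == p or ri == p:
            continue
        seg = SeasonSegment((t[li], v[li]), (t[p], v[p]), (t[ri], v[ri]))
        if seg.right_min[0] - seg.left_min[0] < min_season_length:
            continue
        segments.append(seg)
    return segments


def _interp_crossing(t0, v0, t1, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) * (t1 - t0) / (v1 - v0)


def _integrate(t, v, a, b, baseline, clip):
    """Trapezoidal integral over [a, b] of (v - baseline), with interpolated
    endpoint values inserted at a and b; negative excursions clipped if asked."""
    va = np.interp(a, t, v)
    vb = np.interp(b, t, v)
    inside = (t > a) & (t < b)
    tt = np.concatenate([[a], t[inside], [b]])
    vv = np.concatenate([[va], v[inside], [vb]]) - baseline
    if clip:
        vv = np.maximum(vv, 0.0)
    return float(np.trapezoid(vv, tt))


def season_metrics(
    segment: SeasonSegment,
    series: PredictiveSeries,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> SeasonMetrics:
    """Compute the indicator set for one detected season.

    The threshold level is base_level + threshold_frac * amplitude; SOS is
    its last upward crossing between the left minimum and the peak, EOS the
    first downward crossing between the peak and the right minimum, both by
    linear interpolation on the grid.
    """
    t = np.asarray(series.times, float)
    v = np.asarray(series.mean, float)
    base = segment.base_level
    peak_t, peak_v = segment.peak
    amplitude = peak_v - base
    level = base + threshold_frac * amplitude

    li = int(np.searchsorted(t, segment.left_min[0]))
    pi = int(np.searchsorted(t, peak_t))
    ri = int(np.searchsorted(t, segment.right_min[0]))

    sos = eos = None
    for i in range(pi - 1, li - 1, -1):  # last upward crossing before peak
        if v[i] < level <= v[i + 1]:
            sos = _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], level)
            break
        if v[i] == level:
            sos = float(t[i])
            break
    for i in range(pi, ri):  # first downward crossing after peak
        if v[i] >= level > v[i + 1]:
            eos = _interp_crossing(t[i], v[i], t[i + 1], v[i + 1], level)
            break
        if v[i + 1] == level:
            eos = float(t[i + 1])
            break
    if threshold_frac == 0.0:
        # degenerate threshold: the season spans minimum to minimum
        sos, eos = segment.left_min[0], segment.right_min[0]
    if sos is None or eos is None:
        side = "rising" if sos is None else "falling"
        return SeasonMetrics(np.nan, np.nan, np.nan, peak_t, peak_v, amplitude,
                             np.nan, np.nan,
                             missing_reason=f"threshold never crossed on {side} limb")

    blue = _integrate(t, v, sos, eos, baseline=0.0, clip=False)
    green = _integrate(t, v, sos, eos, baseline=base, clip=True)
    return SeasonMetrics(
        sos=float(sos), eos=float(eos), los=float(eos - sos), dom=float(peak_t),
        max_value=float(peak_v), amplitude=float(amplitude),
        blue_area=blue, green_area=green,
    )


def extract_pixel_phenology(
    series: PredictiveSeries,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_season_length: float = DEFAULT_MIN_SEASON_LENGTH,
) -> list[SeasonMetrics]:
    """detect_seasons + season_metrics for one series, in time order."""
    return [
        season_metrics(seg, series, threshold_frac)
        for seg in detect_seasons(series, min_prominence, min_season_length)
    ]


def phenology_maps(
    recon: ReconstructionResult,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_season_length: float = DEFAULT_MIN_SEASON_LENGTH,
    slot_by: str = "index",
    days_per_year: float = 365.0,
) -> tuple[pd.DataFrame, dict[int, dict[str, np.ndarray]]]:
    """Per-pixel phenology records and per-metric raster layers.

    Seasons are assigned to slots either by detection index (``slot_by =
    'index'``) or by the calendar year containing the season's DOM
    (``'year'``, counted in ``days_per_year`` blocks from the epoch).
    Pixels that were flagged (cloud-starved or failed) or in which no season
    was detected are nodata (NaN) in every metric map.

    Returns
    -------
    (records, maps)
        records: DataFrame with row, col, season_index, slot and the metric
        columns. maps: {slot: {metric: H x W float array}}.
    """
    if slot_by not in ("index", "year"):
        raise InvalidInputError("slot_by must be 'index' or 'year'")
    _, H, W = recon.mean_stack.shape
    rows = []
    for r in range(H):
        for c in range(W):
            if recon.flags[r, c] not in (FLAG_OK, FLAG_FALLBACK):
                continue
            series = recon.pixel_series(r, c)
            if not np.all(np.isfinite(series.mean)):
                continue
            for k, m in enumerate(extract_pixel_phenology(
                    series, threshold_frac, min_prominence, min_season_length)):
                slot = k if slot_by == "index" else int(m.dom // days_per_year)
                rows.append({
                    "row": r, "col": c, "season_index": k, "slot": slot,
                    **{name: getattr(m, name) for name in METRIC_NAMES},
                    "missing_reason": m.missing_reason or "",
                })
    records = pd.DataFrame(
        rows, columns=["row", "col", "season_index", "slot", *METRIC_NAMES,
                       "missing_reason"])
    maps: dict[int, dict[str, np.ndarray]] = {}
    for slot, grp in records.groupby("slot"):
        layer = {name: np.full((H, W), np.nan) for name in METRIC_NAMES}
        for _, rec in grp.iterrows():
            for name in METRIC_NAMES:
                layer[name][int(rec["row"]), int(rec["col"])] = rec[name]
        maps[int(slot)] = layer
    return records, maps
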