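"""Comparison statistics between reconstructions and between phenology runs.

Four statistics quantify how much a pooled-hyperparameter reconstruction
deviates from the per-pixel reference:

- RMSE between paired series (descriptor units);
- variation-percent: RMSE divided by the reference reconstruction's dynamic
  range, x100 — a scale-free version of the same comparison;
- mean per-pixel Pearson correlation over time, averaged per crop class;
- MAD (mean absolute deviation) of paired phenology metrics.

Per-crop "mean RMSE" is the mean over pixels of per-pixel RMSE values (not
pooled residuals), which keeps classes with many pixels from dominating.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedResultError
from .phenology import METRIC_NAMES


def rmse(a, b) -> float:
    """Root-mean-square difference over jointly finite points."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise UndefinedResultError("series lengths differ")
    m = np.isfinite(a) & np.isfinite(b)
    if not m.any():
        raise UndefinedResultError("no overlapping finite values")
    d = a[m] - b[m]
    return float(np.sqrt(np.mean(d * d)))


def variation_percent(rmse_value: float, reference) -> float:
    """100 x RMSE / (max - min) of the reference series."""
    ref = np.asarray(reference, float).ravel()
    ref = ref[np.isfinite(ref)]
    if ref.size == 0:
        raise UndefinedResultError("empty reference series")
    rng = float(ref.max() - ref.min())
    if rng <= 0:
        raise UndefinedResultError("reference series has zero range")
    return 100.0 * rmse_value / rng


def pearson_r(a, b) -> float:
    """Pearson correlation of two 1-D series (NaN if either is constant)."""
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    m = np.isfinite(a) & np.isfinite(b)
    a, b = a[m], b[m]
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def mean_pixel_correlation(
    recon_a: np.ndarray,
    recon_b: np.ndarray,
    class_mask: np.ndarray | None = None,
) -> dict:
    """Per-pixel Pearson r over time, averaged per class.

    recon_a/recon_b are T x H x W cubes on the same grid. Constant-in-time
    pixels (r undefined) are excluded and counted.

    Returns {"per_class": {cid: mean r}, "overall": mean r,
    "n_excluded": int, "n_used": int}.
    """
    if recon_a.shape != recon_b.shape:
        raise UndefinedResultError("stacks not aligned")
    T, H, W = recon_a.shape
    rs = np.full((H, W), np.nan)
    for r in range(H):
        for c in range(W):
            rs[r, c] = pearson_r(recon_a[:, r, c], recon_b[:, r, c])
    usable = np.isfinite(rs)
    # pixels with data but undefined r (constant series) count as excluded
    had_data = np.isfinite(recon_a).any(axis=0) & np.isfinite(recon_b).any(axis=0)
    out = {
        "per_class": {},
        "overall": float(np.nanmean(rs)) if usable.any() else np.nan,
        "n_excluded": int((had_data & ~usable).sum()),
        "n_used": int(usable.sum()),
    }
    if class_mask is not None:
        for cid in sorted(set(np.unique(class_mask).tolist()) - {0}):
            sel = (class_mask == cid) & usable
            out["per_class"][int(cid)] = (
                float(rs[sel].mean()) if sel.any() else np.nan
            )
    return out


def match_seasons(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    max_dom_gap: float = 90.0,
    days_per_year: float = 365.0,
) -> pd.DataFrame:
    """Pair season records from two runs on (pixel, season slot).

    Seasons are matched greedily per pixel by nearest DOM within the same
    calendar year; pairs further apart than ``max_dom_gap`` days are dropped.
    Returns a frame with <metric>_a / <metric>_b columns.
    """
    pairs = []
    cols = ["row", "col", *METRIC_NAMES]
    a = metrics_a[cols].dropna(subset=["dom"]).copy()
    b = metrics_b[cols].dropna(subset=["dom"]).copy()
    a["year"] = (a["dom"] // days_per_year).astype(int)
    b["year"] = (b["dom"] // days_per_year).astype(int)
    b_groups = {k: g.copy() for k, g in b.groupby(["row", "col", "year"])}
    for key, ga in a.groupby(["row", "col", "year"]):
        gb = b_groups.get(key)
        if gb is None:
            continue
        taken = set()
        for _, rec_a in ga.sort_values("dom").iterrows():
            free = gb.loc[[i for i in gb.index if i not in taken]]
            if free.empty:
                break
            gaps = (free["dom"] - rec_a["dom"]).abs()
            j = gaps.idxmin()
            if gaps.loc[j] > max_dom_gap:
                continue
            taken.add(j)
            rec_b = gb.loc[j]
            pairs.append({
                "row": key[0], "col": key[1],
                **{f"{m}_a": rec_a[m] for m in METRIC_NAMES},
                **{f"{m}_b": rec_b[m] for m in METRIC_NAMES},
            })
    return pd.DataFrame(pairs)


def mad_phenology(
    metrics_a: pd.DataFrame,
    metrics_b: pd.DataFrame,
    max_dom_gap: float = 90.0,
) -> pd.DataFrame:
    """Mean absolute deviation (and its sd) per phenology metric.

    Records are matched with :func:`match_seasons`; unmatched records are
    excluded and counted in the frame's ``attrs``.
    """
    matched = match_seasons(metrics_a, metrics_b, max_dom_gap=max_dom_gap)
    if matched.empty:
        raise UndefinedResultError("no matched season pairs")
    rows = []
    for m in METRIC_NAMES:
        d = (matched[f"{m}_a"] - matched[f"{m}_b"]).abs().dropna()
        rows.append({"metric": m, "mad": float(d.mean()),
                     "sd": float(d.std(ddof=0)), "n": int(d.size)})
    out = pd.DataFrame(rows).set_index("metric")
    out.attrs["n_matched"] = len(matched)
    out.attrs["n_unmatched"] = (len(metrics_a) - len(matched)) + (
        len(metrics_b) - len(matched))
    return out


@dataclass
class ComparisonReport:
    """Per-class comparison of two reconstructions (crop rows x statistics)."""

    table: pd.DataFrame
    mode_a: str = "reference"
    mode_b: str = "candidate"
    notes: dict = field(default_factory=dict)

    def to_markdown(self) -> str:
        head = (f"# Reconstruction comparison: {self.mode_b} vs {self.mode_a}\n\n")
        return head + self.table.to_markdown()


def compare_reconstructions(
    recon_ref: np.ndarray,
    recon_alt: np.ndarray,
    class_mask: np.ndarray,
    legend: dict[int, str] | None = None,
    mode_ref: str = "per_pixel",
    mode_alt: str = "global",
) -> ComparisonReport:
    """Per-crop mean RMSE, variation-percent and mean correlation.

    RMSE and variation-percent are computed per pixel against the reference
    cube (the reference pixel's own dynamic range as denominator), then
    averaged within each class.
    """
    T, H, W = recon_ref.shape
    corr = mean_pixel_correlation(recon_ref, recon_alt, class_mask)
    rows = []
    for cid in sorted(set(np.unique(class_mask).tolist()) - {0}):
        sel = np.argwhere(class_mask == cid)
        rmses, vps = [], []
        for r, c in sel:
            a = recon_ref[:, r, c]
            b = recon_alt[:, r, c]
            if not (np.isfinite(a).any() and np.isfinite(b).any()):
                continue
            e = rmse(a, b)
            rmses.append(e)
            ref = a[np.isfinite(a)]
            if ref.max() > ref.min():
                vps.append(variation_percent(e, a))
        rows.append({
            "class": legend.get(cid, str(cid)) if legend else str(cid),
            "mean_rmse": float(np.mean(rmses)) if rmses else np.nan,
            "variation_percent": float(np.mean(vps)) if vps else np.nan,
            "mean_correlation": corr["per_class"].get(int(cid), np.nan),
            "n_pixels": len(rmses),
        })
    table = pd.DataFrame(rows).set_index("class")
    return ComparisonReport(table, mode_a=mode_ref, mode_b=mode_alt,
                            notes={"overall_correlation": corr["overall"],
                                   "n_excluded_constant": corr["n_excluded"]})
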