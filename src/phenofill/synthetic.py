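"""Synthetic multi-crop LAI scenes with known ground truth.

The generator emulates the setting the gap-filler is built for: a small
agricultural scene observed by a Sentinel-2-like sensor — a parcel mosaic of
crop classes with distinct double-logistic seasonal LAI curves, irregular
acquisition times, spatially correlated cloud gaps and additive Gaussian
noise. Everything is driven by one integer seed (numpy's PCG64 stream), so
scenes are bit-reproducible across platforms.

Truth tables carry the clean (noise-free) cube and the analytic
20%-amplitude season crossings per pixel and year, which makes phenology
extraction testable without any reference dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_gpr import Hyperparameters, TimeSeries, _chol_with_jitter, se_kernel
from .errors import ConfigError
from .gapfill import RasterStack
from .pooling import CropMap

_LN4 = math.log(4.0)
DAYS_PER_YEAR = 365.0

#: Threshold fraction at which sos_true / eos_true are defined (the same
#: percent-of-amplitude rule the phenology module applies).
TRUTH_THRESHOLD_FRAC = 0.20


@dataclass(frozen=True)
class CropCurveParams:
    """Double-logistic seasonal curve for one crop.

    sos_true / eos_true are days-of-year at which the rising / falling limb
    crosses base + 0.2 * amplitude (the curve is placed so these crossings
    hold in closed form). Rates are logistic slopes in 1/days.
    """

    base: float
    amplitude: float
    sos_true: float
    eos_true: float
    growth_rate: float = 0.10
    senescence_rate: float = 0.10
    seasons_per_year: int = 1

    def __post_init__(self):
        if self.amplitude <= 0 or self.sos_true >= self.eos_true:
            raise ConfigError("need amplitude > 0 and sos_true < eos_true")
        if self.growth_rate <= 0 or self.senescence_rate <= 0:
            raise ConfigError("rates must be positive")

    def inflection_times(self) -> tuple[float, float]:
        """(s1, s2): logistic midpoints implied by the 20% crossings.

        sigmoid(g (t - s1)) = 0.2 at t = sos_true gives s1 = sos + ln4/g;
        sigmoid(s (t - s2)) = 0.8 at t = eos_true gives s2 = eos - ln4/s.
        """
        s1 = self.sos_true + _LN4 / self.growth_rate
        s2 = self.eos_true - _LN4 / self.senescence_rate
        return s1, s2


def double_logistic(t, p: CropCurveParams, years: int = 1) -> np.ndarray:
    """Evaluate the (possibly multi-year) double-logistic curve at days t.

    value = base + amplitude * [sigmoid(g (t - s1)) - sigmoid(s (t - s2))],
    with the season repeated every year (and, for seasons_per_year = 2,
    a second season half a year later). Far from any season the two
    sigmoids cancel and the curve returns to base.
    """
    t = np.asarray(t, float)
    s1, s2 = p.inflection_times()
    out = np.zeros_like(t)
    sub_offsets = [k * DAYS_PER_YEAR / p.seasons_per_year
                   for k in range(p.seasons_per_year)]
    for year in range(years):
        for off in sub_offsets:
            shift = year * DAYS_PER_YEAR + off
            rise = _sigmoid(p.growth_rate * (t - (s1 + shift)))
            fall = _sigmoid(p.senescence_rate * (t - (s2 + shift)))
            out += rise - fall
    return p.base + p.amplitude * out


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


#: Nine crop archetypes with distinct seasonal windows and amplitudes:
#: winter cereals and rape peak in late spring; summer crops (corn,
#: sunflower, beet, potato) peak in late summer; alfalfa has a long season.
DEFAULT_CROPS: dict[str, CropCurveParams] = {
    "wheat": CropCurveParams(0.30, 2.6, 90, 200, 0.10, 0.12),
    "corn": CropCurveParams(0.25, 3.6, 160, 290, 0.11, 0.10),
    "barley": CropCurveParams(0.30, 2.4, 85, 195, 0.10, 0.12),
    "sunflower": CropCurveParams(0.20, 2.2, 150, 280, 0.09, 0.10),
    "rape": CropCurveParams(0.35, 2.9, 70, 190, 0.09, 0.11),
    "pea": CropCurveParams(0.25, 2.0, 95, 205, 0.11, 0.12),
    "alfalfa": CropCurveParams(0.40, 1.9, 80, 300, 0.08, 0.08),
    "beet": CropCurveParams(0.25, 3.8, 150, 300, 0.09, 0.11),
    "potato": CropCurveParams(0.25, 3.4, 150, 250, 0.11, 0.12),
}


@dataclass
class SceneConfig:
    """Configuration of a synthetic scene.

    The defaults give a 60x60 px, 9-class parcel mosaic observed every ~5
    days over two years with 25% spatially correlated cloud gaps — small
    enough for routine testing while structurally matching multi-year
    Sentinel-2 crop monitoring.
    """

    height: int = 60
    width: int = 60
    parcel_height: int = 10
    parcel_width: int = 10
    crops: dict[str, CropCurveParams] = field(
        default_factory=lambda: dict(DEFAULT_CROPS))
    start_day: float = 0.0
    end_day: float = 730.0
    revisit_days: float = 5.0
    jitter_days: float = 1.5
    cloud_prob: float = 0.25
    cloud_blob_radius: tuple[float, float] = (4.0, 10.0)
    noise_sd: float = 0.10
    perturb_base_sd: float = 0.03
    perturb_amplitude_frac: float = 0.05
    perturb_day_sd: float = 3.0
    epoch: str = "2016-01-01"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ConfigError("cloud_prob must be in [0, 1]")
        if self.end_day - self.start_day < DAYS_PER_YEAR / 2:
            raise ConfigError("schedule must span at least one full season")
        if self.revisit_days <= 0:
            raise ConfigError("revisit_days must be positive")
        if self.jitter_days >= self.revisit_days / 2:
            raise ConfigError("jitter must be below half the revisit interval")


def acquisition_times(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    base = np.arange(config.start_day, config.end_day, config.revisit_days)
    t = base + rng.uniform(-config.jitter_days, config.jitter_days, base.size)
    return np.sort(t)


def sentinel2_like_times(
    n_acquisitions: int = 127,
    span_days: float = 1400.0,
    slot_days: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Unevenly spaced acquisition days mimicking a multi-year Sentinel-2
    collection: a 5-day revisit grid over ~4 years thinned at random to the
    requested count (cloud-season gaps arise naturally from the thinning)."""
    rng = np.random.default_rng(seed)
    slots = np.arange(0.0, span_days, slot_days)
    if n_acquisitions > slots.size:
        raise ConfigError("more acquisitions than revisit slots")
    keep = np.sort(rng.choice(slots.size, size=n_acquisitions, replace=False))
    return slots[keep] + rng.uniform(-1.0, 1.0, n_acquisitions)


def _parcel_layout(config: SceneConfig, rng: np.random.Generator):
    """Rectangular parcel mosaic; every crop class appears at least once."""
    n_pr = config.height // config.parcel_height
    n_pc = config.width // config.parcel_width
    n_parcels = n_pr * n_pc
    class_ids = np.arange(1, len(config.crops) + 1)
    if n_parcels < class_ids.size:
        raise ConfigError("not enough parcels for the class list")
    # cycle through classes, then shuffle parcel order
    assign = class_ids[np.arange(n_parcels) % class_ids.size]
    rng.shuffle(assign)
    labels = np.zeros((config.height, config.width), int)
    parcel_ids = np.zeros((config.height, config.width), int)
    pid = 0
    for i in range(n_pr):
        for j in range(n_pc):
            pid += 1
            sl = (slice(i * config.parcel_height, (i + 1) * config.parcel_height),
                  slice(j * config.parcel_width, (j + 1) * config.parcel_width))
            labels[sl] = assign[pid - 1]
            parcel_ids[sl] = pid
    return labels, parcel_ids


def _cloud_masks(config: SceneConfig, n_times: int, rng: np.random.Generator):
    """Per-acquisition boolean cloud masks made of random disk blobs whose
    expected coverage equals cloud_prob."""
    H, W = config.height, config.width
    r_lo, r_hi = config.cloud_blob_radius
    mean_area = math.pi * ((r_lo**2 + r_lo * r_hi + r_hi**2) / 3.0)  # E[pi r^2]
    lam = config.cloud_prob * H * W / mean_area
    yy, xx = np.mgrid[0:H, 0:W]
    clouds = np.zeros((n_times, H, W), bool)
    for k in range(n_times):
        for _ in range(rng.poisson(lam)):
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            rad = rng.uniform(r_lo, r_hi)
            clouds[k] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    return clouds


def generate_scene(config: SceneConfig) -> tuple[RasterStack, CropMap, dict]:
    """Generate a scene: noisy gappy stack, crop map, and ground truth.

    Per pixel, the class curve is perturbed slightly (base, amplitude and
    season timing), evaluated at the acquisition times, degraded by additive
    Gaussian noise and masked by spatially correlated cloud blobs.

    Returns
    -------
    (stack, crop_map, truth) where truth holds:
        ``clean``: noise-free T x H x W cube;
        ``params``: per-pixel perturbed curve parameters;
        ``phenology``: per-pixel, per-year analytic SOS/EOS/amplitude.
    """
    rng = np.random.default_rng(config.seed)
    times = acquisition_times(config, rng)
    if times.size == 0:
        raise ConfigError("no valid acquisitions in the schedule")
    H, W = config.height, config.width
    labels, parcel_ids = _parcel_layout(config, rng)
    legend = {i + 1: name for i, name in enumerate(config.crops)}

    n_years = int(math.ceil((config.end_day - config.start_day) / DAYS_PER_YEAR))
    clean = np.zeros((times.size, H, W))
    params_rows = []
    pheno_rows = []
    for cid, name in legend.items():
        p0 = config.crops[name]
        sel = np.argwhere(labels == cid)
        n = len(sel)
        base = p0.base + rng.normal(0, config.perturb_base_sd, n)
        amp = p0.amplitude * (1 + rng.normal(0, config.perturb_amplitude_frac, n))
        sos = p0.sos_true + rng.normal(0, config.perturb_day_sd, n)
        eos = p0.eos_true + rng.normal(0, config.perturb_day_sd, n)
        for i, (r, c) in enumerate(sel):
            p = replace(p0, base=float(base[i]), amplitude=float(amp[i]),
                        sos_true=float(sos[i]), eos_true=float(eos[i]))
            clean[:, r, c] = double_logistic(times, p, years=n_years)
            params_rows.append({
                "row": r, "col": c, "class_id": cid, "class_name": name,
                "base": p.base, "amplitude": p.amplitude,
                "sos_doy": p.sos_true, "eos_doy": p.eos_true,
                "growth_rate": p.growth_rate,
                "senescence_rate": p.senescence_rate,
            })
            for year in range(n_years):
                pheno_rows.append({
                    "row": r, "col": c, "class_id": cid, "year": year,
                    "sos": p.sos_true + year * DAYS_PER_YEAR,
                    "eos": p.eos_true + year * DAYS_PER_YEAR,
                    "amplitude": p.amplitude, "base": p.base,
                })

    clouds = _cloud_masks(config, times.size, rng)
    valid = ~clouds
    noise = rng.normal(0.0, config.noise_sd, clean.shape) if config.noise_sd > 0 \
        else np.zeros_like(clean)
    data = clean + noise
    data[~valid] = np.nan

    stack = RasterStack(data=data, times=times, valid_mask=valid,
                        epoch=config.epoch, geo={"transform": None, "crs": None})
    crop_map = CropMap(labels=labels, legend=legend, parcel_ids=parcel_ids)
    truth = {
        "clean": clean,
        "params": pd.DataFrame(params_rows),
        "phenology": pd.DataFrame(pheno_rows),
        "times": times,
    }
    return stack, crop_map, truth


def generate_gp_series(
    theta: Hyperparameters, times, seed: int = 0
) -> TimeSeries:
    """Draw one series from the zero-mean GP: f ~ N(0, K), y = f + noise.

    An exact draw via the Cholesky factor of the noise-free kernel, plus
    i.i.d. N(0, sigma_n^2) observation noise. With sigma_f = 0 the series is
    pure noise.
    """
    times = np.asarray(times, float)
    rng = np.random.default_rng(seed)
    if theta.sigma_f2 == 0.0:
        f = np.zeros(times.size)
    else:
        K = se_kernel(times, times, theta)
        L, _ = _chol_with_jitter(K + 1e-12 * theta.sigma_f2 * np.eye(times.size))
        f = L @ rng.standard_normal(times.size)
    y = f + math.sqrt(theta.sigma_n2) * rng.standard_normal(times.size)
    return TimeSeries(times=times, values=y)
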