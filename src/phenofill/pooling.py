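"""Hyperparameter pooling: sample training pixels per crop class, train
per-pixel hyperparameters, and average them per crop and globally.

Scene-wide GP gap-filling does not require optimizing hyperparameters for
every pixel: hyperparameters trained on a stratified sample of crop parcels
can be averaged (on the log scale, where they are reported) and reused
unchanged across the whole class or scene. ``ThetaSet`` is the container for
the three parameterizations: per-pixel (theta_pp), per-crop (theta_pc) and
global (theta_gl).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy import ndimage

from .core_gpr import MIN_OBS, Hyperparameters, train_hyperparameters
from .errors import InvalidInputError

#: Parcel sampling defaults: parcels per class and minimum parcel size,
#: matching the stratified-sampling design pooling is meant for.
DEFAULT_N_PARCELS = 100
DEFAULT_MIN_PIXELS = 50


@dataclass
class CropMap:
    """Crop-class raster with a legend and optional parcel identifiers.

    Label 0 is reserved for unclassified / non-crop pixels.
    """

    labels: np.ndarray
    legend: dict[int, str]
    parcel_ids: np.ndarray | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.legend)
        if missing:
            raise InvalidInputError(f"legend does not cover labels {sorted(missing)}")
        if self.parcel_ids is not None:
            self.parcel_ids = np.asarray(self.parcel_ids)
            if self.parcel_ids.shape != self.labels.shape:
                raise InvalidInputError("parcel_ids shape must match labels")

    @property
    def class_ids(self) -> list[int]:
        return sorted(set(np.unique(self.labels).tolist()) - {0})


@dataclass
class PixelTheta:
    """One trained pixel: location, class, hyperparameters, converged LML."""

    row: int
    col: int
    class_id: int
    theta: Hyperparameters
    lml: float


@dataclass
class ThetaSet:
    """Per-pixel, per-crop and global hyperparameters.

    per_crop and global_theta are unweighted arithmetic means of the
    per-pixel log-triples over their groups; the global mean averages over
    pixels (not over crop means), so with unbalanced classes it differs from
    the mean of the per-crop rows.
    """

    per_pixel: list[PixelTheta] = field(default_factory=list)
    per_crop: dict[int | str, Hyperparameters] = field(default_factory=dict)
    global_theta: Hyperparameters | None = None
    epoch: str | None = None
    provenance: dict = field(default_factory=dict)

    def to_dict(self, legend: dict[int, str] | None = None) -> dict:
        def name(cid):
            return legend.get(cid, str(cid)) if legend else str(cid)

        return {
            "per_crop": {name(c): th.to_dict() for c, th in self.per_crop.items()},
            "global": self.global_theta.to_dict() if self.global_theta else None,
            "epoch": self.epoch,
            "provenance": self.provenance,
        }

    def to_json(self, path, legend=None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(legend), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "ThetaSet":
        per_crop = {
            k: Hyperparameters.from_dict(v) for k, v in (d.get("per_crop") or {}).items()
        }
        g = d.get("global")
        return cls(
            per_crop=per_crop,
            global_theta=Hyperparameters.from_dict(g) if g else None,
            epoch=d.get("epoch"),
            provenance=d.get("provenance", {}),
        )

    @classmethod
    def from_json(cls, path) -> "ThetaSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def reference_thetas() -> ThetaSet:
    """Packaged precalculated crop hyperparameters, usable as defaults.

    These were derived from per-pixel GP training on multi-year Sentinel-2
    LAI series over nine crop types; keys of ``per_crop`` are crop names.
    """
    text = resources.files("phenofill.data").joinpath("reference_thetas.json").read_text()
    return ThetaSet.from_dict(json.loads(text))


def sample_parcels(
    crop_map: CropMap,
    n_parcels: int = DEFAULT_N_PARCELS,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    seed: int = 0,
) -> dict[int, list[np.ndarray]]:
    """Randomly sample parcels per crop class.

    Parcels come from the ``parcel_ids`` raster when present, otherwise from
    4-connected components of same-class pixels. Per class, up to
    ``n_parcels`` parcels with at least ``min_pixels`` pixels are drawn
    without replacement; classes with too few eligible parcels return all of
    them with a warning.

    Returns
    -------
    dict mapping class id -> list of (rows, cols) index-array pairs, one per
    sampled parcel, stacked as an (n_pix, 2) int array.
    """
    rng = np.random.default_rng(seed)
    out: dict[int, list[np.ndarray]] = {}
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    for cid in crop_map.class_ids:
        mask = crop_map.labels == cid
        if crop_map.parcel_ids is not None:
            pid = np.where(mask, crop_map.parcel_ids, 0)
            ids = [p for p in np.unique(pid) if p != 0]
            components = [np.argwhere(pid == p) for p in ids]
        else:
            lab, n = ndimage.label(mask, structure=structure)
            components = [np.argwhere(lab == i) for i in range(1, n + 1)]
        eligible = [c for c in components if len(c) >= min_pixels]
        if not eligible:
            warnings.warn(
                f"class {cid}: no parcels with >= {min_pixels} pixels", stacklevel=2
            )
            out[cid] = []
            continue
        if len(eligible) < n_parcels:
            warnings.warn(
                f"class {cid}: only {len(eligible)} eligible parcels "
                f"(requested {n_parcels}); using all",
                stacklevel=2,
            )
            chosen = eligible
        else:
            idx = rng.choice(len(eligible), size=n_parcels, replace=False)
            chosen = [eligible[i] for i in sorted(idx)]
        out[cid] = chosen
    return out


def train_per_pixel(
    stack,
    pixels: dict[int, np.ndarray] | list[tuple[int, int, int]],
    seed: int = 0,
    n_restarts: int = 5,
    prior_box: dict | None = None,
    min_obs: int = MIN_OBS,
) -> list[PixelTheta]:
    """Train hyperparameters independently for each listed pixel.

    ``pixels`` maps class id -> (n, 2) array of (row, col), or is a flat list
    of (row, col, class_id). Pixels with too few valid acquisitions or failed
    training are recorded as skipped, never fatal; a warning is raised if
    more than half of the pixels fail.
    """
    flat: list[tuple[int, int, int]] = []
    if isinstance(pixels, dict):
        for cid, arr in pixels.items():
            for r, c in np.asarray(arr).reshape(-1, 2):
                flat.append((int(r), int(c), int(cid)))
    else:
        flat = [(int(r), int(c), int(cid)) for r, c, cid in pixels]

    results: list[PixelTheta] = []
    n_failed = 0
    for r, c, cid in flat:
        # seed keyed on location so duplicated pixels train identically
        pix_seed = np.random.SeedSequence([seed, r, c]).generate_state(1)[0] % (2**31)
        ts = stack.pixel_series(r, c)
        if ts.n_valid < min_obs:
            n_failed += 1
            continue
        try:
            theta, lml = train_hyperparameters(
                ts, n_restarts=n_restarts, prior_box=prior_box,
                seed=int(pix_seed), min_obs=min_obs,
            )
        except Exception:
            n_failed += 1
            continue
        results.append(PixelTheta(r, c, cid, theta, lml))
    if flat and n_failed / len(flat) > 0.5:
        warnings.warn(
            f"{n_failed}/{len(flat)} pixels failed training", stacklevel=2
        )
    return results


def average_hyperparameters(
    per_pixel: list[PixelTheta],
    epoch: str | None = None,
    provenance: dict | None = None,
) -> ThetaSet:
    """Average per-pixel hyperparameters per crop class and globally.

    Means are unweighted arithmetic means of the log-triples — the scale on
    which SE hyperparameters are customarily reported and on which averaging
    is invariant to the parameterization (1/l vs l). The global mean runs
    over all pixels, so it is pixel-weighted, not crop-weighted.
    """
    if not per_pixel:
        raise InvalidInputError("no trained pixels to average")
    by_class: dict[int, list[np.ndarray]] = {}
    all_arrs = []
    for p in per_pixel:
        arr = p.theta.as_array()
        by_class.setdefault(p.class_id, []).append(arr)
        all_arrs.append(arr)
    per_crop = {
        cid: Hyperparameters.from_array(np.mean(arrs, axis=0))
        for cid, arrs in sorted(by_class.items())
    }
    global_theta = Hyperparameters.from_array(np.mean(all_arrs, axis=0))
    return ThetaSet(
        per_pixel=list(per_pixel),
        per_crop=per_crop,
        global_theta=global_theta,
        epoch=epoch,
        provenance=provenance or {},
    )
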