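"""Readers and writers for the formats the tool exchanges.

Single-pixel series travel as CSV (date, value, optional qa), hyperparameter
sets as JSON, stacks either as NetCDF (via xarray, classic NetCDF3 format)
or as multi-page GeoTIFF with a dates sidecar CSV. Georeferencing metadata
(CRS string + affine transform) rides along in a JSON sidecar / NetCDF
attributes and is passed through untouched.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .core_gpr import Hyperparameters, TimeSeries
from .errors import InvalidInputError
from .gapfill import RasterStack, ReconstructionResult
from .pooling import CropMap

DEFAULT_EPOCH = "2016-01-01"


def days_since_epoch(dates, epoch: str = DEFAULT_EPOCH) -> np.ndarray:
    """Convert date-likes to float days since the epoch date."""
    d = pd.to_datetime(dates)
    delta = d - pd.Timestamp(epoch)
    return np.asarray(delta / pd.Timedelta(days=1), float)


def dates_from_days(days, epoch: str = DEFAULT_EPOCH) -> pd.DatetimeIndex:
    return pd.Timestamp(epoch) + pd.to_timedelta(np.asarray(days, float), unit="D")


# ---------------------------------------------------------------- pixel CSV

def read_pixel_csv(path, epoch: str = DEFAULT_EPOCH) -> TimeSeries:
    """Read a single-pixel series CSV: columns date (ISO-8601), value,
    optional qa (1 = good)."""
    df = pd.read_csv(path)
    if not {"date", "value"} <= set(df.columns):
        raise InvalidInputError("pixel CSV needs 'date' and 'value' columns")
    times = days_since_epoch(df["date"], epoch)
    valid = np.isfinite(df["value"].to_numpy(float))
    if "qa" in df.columns:
        valid &= df["qa"].to_numpy(float) > 0
    order = np.argsort(times)
    return TimeSeries(times[order], df["value"].to_numpy(float)[order],
                      valid[order])


def write_pixel_csv(path, ts: TimeSeries, epoch: str = DEFAULT_EPOCH) -> None:
    pd.DataFrame({
        # full ISO-8601 timestamps: sub-day acquisition times survive round-trip
        "date": dates_from_days(ts.times, epoch).strftime("%Y-%m-%dT%H:%M:%S"),
        "value": ts.values,
        "qa": ts.valid.astype(int),
    }).to_csv(path, index=False)


# ------------------------------------------------------------- theta JSON

def write_theta_json(path, theta: Hyperparameters, epoch: str = DEFAULT_EPOCH) -> None:
    with open(path, "w") as fh:
        json.dump({**theta.to_dict(), "epoch": epoch}, fh, indent=2)


def read_theta_json(path) -> tuple[Hyperparameters, str]:
    with open(path) as fh:
        d = json.load(fh)
    return Hyperparameters.from_dict(d), d.get("epoch", DEFAULT_EPOCH)


# ----------------------------------------------------------------- stacks

def write_stack_netcdf(path, stack: RasterStack) -> None:
    """Write a stack as classic NetCDF3 (scipy engine) with a time coord."""
    ds = xr.Dataset(
        {
            "value": (("time", "y", "x"), np.where(stack.valid_mask, stack.data, np.nan)),
            "valid": (("time", "y", "x"), stack.valid_mask.astype(np.int8)),
        },
        coords={"time": stack.times},
        attrs={"epoch": stack.epoch, "geo": json.dumps(stack.geo, default=str)},
    )
    ds.to_netcdf(path, engine="scipy")


def read_stack_netcdf(path) -> RasterStack:
    with xr.open_dataset(path, engine="scipy") as ds:
        data = ds["value"].to_numpy()
        valid = ds["valid"].to_numpy().astype(bool)
        times = ds["time"].to_numpy().astype(float)
        epoch = ds.attrs.get("epoch", DEFAULT_EPOCH)
        geo = json.loads(ds.attrs.get("geo", "{}"))
    data = np.where(valid, data, np.nan)
    return RasterStack(data=data, times=times, valid_mask=valid, epoch=epoch, geo=geo)


def write_stack_geotiff(path, stack: RasterStack, dates_csv=None) -> None:
    """Write a stack as a multi-page GeoTIFF (one page per acquisition) with
    NaN as nodata, plus a sidecar dates CSV and geo JSON."""
    path = Path(path)
    tifffile.imwrite(path, np.where(stack.valid_mask, stack.data, np.nan)
                     .astype(np.float32))
    dates_csv = Path(dates_csv) if dates_csv else path.with_suffix(".dates.csv")
    pd.DataFrame({
        "date": dates_from_days(stack.times, stack.epoch).strftime("%Y-%m-%d %H:%M:%S"),
        "days": stack.times,
    }).to_csv(dates_csv, index=False)
    with open(path.with_suffix(".geo.json"), "w") as fh:
        json.dump({"epoch": stack.epoch, "geo": stack.geo}, fh, default=str)


def read_stack_geotiff(path, dates_csv=None) -> RasterStack:
    path = Path(path)
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    dates_csv = Path(dates_csv) if dates_csv else path.with_suffix(".dates.csv")
    df = pd.read_csv(dates_csv)
    geo_path = path.with_suffix(".geo.json")
    epoch, geo = DEFAULT_EPOCH, {}
    if geo_path.exists():
        with open(geo_path) as fh:
            meta = json.load(fh)
        epoch, geo = meta.get("epoch", DEFAULT_EPOCH), meta.get("geo", {})
    times = (df["days"].to_numpy(float) if "days" in df.columns
             else days_since_epoch(df["date"], epoch))
    valid = np.isfinite(data)
    return RasterStack(data=data, times=times, valid_mask=valid, epoch=epoch, geo=geo)


def write_crop_map(tif_path, legend_path, crop_map: CropMap) -> None:
    tifffile.imwrite(tif_path, crop_map.labels.astype(np.int32))
    with open(legend_path, "w") as fh:
        json.dump({str(k): v for k, v in crop_map.legend.items()}, fh, indent=2)


def read_crop_map(tif_path, legend_path, parcel_tif=None) -> CropMap:
    labels = tifffile.imread(tif_path).astype(int)
    with open(legend_path) as fh:
        legend = {int(k): v for k, v in json.load(fh).items()}
    parcels = tifffile.imread(parcel_tif).astype(int) if parcel_tif else None
    return CropMap(labels=labels, legend=legend, parcel_ids=parcels)


# ---------------------------------------------------------- reconstruction

def write_reconstruction(out_dir, recon: ReconstructionResult) -> None:
    """Write mean/sd/flags GeoTIFFs, the grid-dates CSV and metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "mean.tif", recon.mean_stack.astype(np.float32))
    tifffile.imwrite(out / "sd.tif", recon.sd_stack.astype(np.float32))
    tifffile.imwrite(out / "flags.tif", recon.flags.astype(np.int16))
    pd.DataFrame({
        "date": dates_from_days(recon.grid_times, recon.epoch).strftime("%Y-%m-%d"),
        "days": recon.grid_times,
    }).to_csv(out / "grid_dates.csv", index=False)
    with open(out / "reconstruction.json", "w") as fh:
        json.dump({
            "epoch": recon.epoch, "theta_mode": recon.theta_mode,
            "geo": recon.geo,
            "n_optimizations": recon.n_optimizations,
            "n_factorizations": recon.n_factorizations,
        }, fh, indent=2, default=str)


def read_reconstruction(out_dir) -> ReconstructionResult:
    out = Path(out_dir)
    with open(out / "reconstruction.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(out / "grid_dates.csv")
    return ReconstructionResult(
        mean_stack=tifffile.imread(out / "mean.tif").astype(float),
        sd_stack=tifffile.imread(out / "sd.tif").astype(float),
        grid_times=df["days"].to_numpy(float),
        flags=tifffile.imread(out / "flags.tif").astype(int),
        theta_mode=meta["theta_mode"], epoch=meta["epoch"],
        geo=meta.get("geo", {}),
        n_optimizations=meta.get("n_optimizations", 0),
        n_factorizations=meta.get("n_factorizations", 0),
    )
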