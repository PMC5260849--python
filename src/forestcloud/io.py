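"""Readers and writers for the pipeline's on-disk formats.

Raster stacks and static rasters go to NetCDF (classic format via the
scipy engine, CF-style UTC time axis); series go to CSV; configuration
to YAML.  Cloud-mask flags are written as 16-bit integers with the
value convention 0 = clear, 1 = cloud, 255 = missing; digital counts as
int16 with missing_value −1.  A run manifest (JSON) records the
configuration, seed, package/library versions and SHA-256 hashes of all
outputs so a run can be reproduced and checked bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .containers import COUNT_FILL, Box, CloudMaskStack, CountStack, LandCoverMap
from .detect import BinScheme, ClearSkyClimatology
from .synthetic import SimConfig

_ENGINE = "scipy"  # NetCDF3 classic; no optional backend dependencies


# ---------------------------------------------------------------- rasters
def save_counts(stack: CountStack, path) -> None:
    ds = xr.Dataset(
        {"counts": (("time", "y", "x"), stack.counts)},
        coords={"time": stack.times},
        attrs={"convention": "10-bit digital counts"},
    )
    ds["counts"].attrs["missing_value"] = COUNT_FILL
    ds.to_netcdf(path, engine=_ENGINE)


def load_counts(path) -> CountStack:
    # mask_and_scale off: the fill sentinel stays an integer, not NaN
    with xr.open_dataset(path, engine=_ENGINE, mask_and_scale=False) as ds:
        return CountStack(
            times=pd.DatetimeIndex(ds["time"].values),
            counts=ds["counts"].values.astype(np.int16),
        )


def save_mask(mask: CloudMaskStack, path) -> None:
    ds = xr.Dataset(
        {"flags": (("time", "y", "x"), mask.flags.astype(np.int16))},
        coords={"time": mask.times},
    )
    ds["flags"].attrs.update(
        flag_values=[0, 1, 255], flag_meanings="clear cloud missing"
    )
    if mask.threshold_counts is not None:
        ds["flags"].attrs["threshold_counts"] = mask.threshold_counts
    ds.to_netcdf(path, engine=_ENGINE)


def load_mask(path) -> CloudMaskStack:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        thr = ds["flags"].attrs.get("threshold_counts")
        return CloudMaskStack(
            times=pd.DatetimeIndex(ds["time"].values),
            flags=ds["flags"].values.astype(np.uint8),
            threshold_counts=int(thr) if thr is not None else None,
        )


def save_climatology(clim: ClearSkyClimatology, path) -> None:
    h0, h1 = clim.scheme.daylight
    ds = xr.Dataset(
        {
            "clearsky": (("dekad", "hour", "y", "x"), clim.values),
            "sample_count": (("dekad", "hour", "y", "x"), clim.sample_count),
        },
        coords={"dekad": np.arange(1, 37), "hour": np.arange(h0, h1)},
        attrs={"window_w": clim.window_w, "min_samples": clim.min_samples},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_climatology(path) -> ClearSkyClimatology:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        hours = ds["hour"].values
        return ClearSkyClimatology(
            values=ds["clearsky"].values.astype(np.float32),
            sample_count=ds["sample_count"].values.astype(np.int32),
            scheme=BinScheme(daylight=(int(hours[0]), int(hours[-1]) + 1)),
            window_w=int(ds.attrs["window_w"]),
            min_samples=int(ds.attrs["min_samples"]),
        )


def save_landcover(lc: LandCoverMap, path) -> None:
    ds = xr.Dataset(
        {"classes": (("y", "x"), lc.classes.astype(np.int16))},
        attrs={
            "pixel_km": lc.pixel_km,
            "class_codes": "1=forest 2=nonforest 3=water",
            "boxes": json.dumps({k: list(v) for k, v in lc.boxes.items()}),
            "damage_zone": json.dumps(list(lc.damage_zone) if lc.damage_zone else None),
        },
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_landcover(path) -> LandCoverMap:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        dz = json.loads(ds.attrs["damage_zone"])
        return LandCoverMap(
            classes=ds["classes"].values.astype(np.uint8),
            boxes={k: Box(*v) for k, v in json.loads(ds.attrs["boxes"]).items()},
            damage_zone=Box(*dz) if dz else None,
            pixel_km=float(ds.attrs["pixel_km"]),
        )


# ----------------------------------------------------------------- series
def save_wind(wind: pd.DataFrame, path) -> None:
    out = wind.copy()
    out.index.name = "date"
    out.to_csv(path, columns=["u10", "v10"], date_format="%Y-%m-%d")


def load_wind(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"], index_col="date")
    return df[["u10", "v10"]]


def save_series(series: pd.DataFrame, path) -> None:
    out = series.copy()
    if out.index.name is None:
        out.index.name = "bin"
    out.to_csv(path)


def load_series(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    try:
        df.index = pd.to_datetime(df.index)
    except (ValueError, TypeError):
        pass
    return df


# ------------------------------------------------------------------ config
def config_to_dict(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for k, v in d.items():
        if isinstance(v, date):
            d[k] = v.isoformat()
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d


def config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    for k in ("start", "klaus_date"):
        if d.get(k):
            d[k] = date.fromisoformat(d[k]) if isinstance(d[k], str) else d[k]
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v)
    return SimConfig(**d)


def save_config(cfg: SimConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=False))


def load_config(path) -> SimConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------- manifest
def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for blk in iter(lambda: fh.read(1 << 20), b""):
            h.update(blk)
    return h.hexdigest()


def write_manifest(path, config: SimConfig, outputs: dict[str, str | Path], extra=None) -> dict:
    import scipy
    import xarray

    from . import __version__

    manifest = {
        "config": config_to_dict(config),
        "seed": config.seed,
        "versions": {
            "forestcloud": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "xarray": xarray.__version__,
        },
        "outputs": {k: {"path": str(p), "sha256": sha256_of(p)} for k, p in outputs.items()},
    }
    if extra:
        manifest["extra"] = extra
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
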