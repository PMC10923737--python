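"""Core data model and raster I/O.

The pipeline's universal currency is the :class:`RasterCube`: a
``(time, row, col)`` float32 array of one variable (NDVI, LST, VCI, TCI or
VHI) with an explicit boolean missing-data mask and a calendar time axis.
Missing data is always represented by the mask, never by a sentinel value
inside ``values``, so statistics can never be contaminated silently.

Two on-disk formats are supported:

* NetCDF — a single file with dims ``(time, y, x)``, the data variable named
  after the cube variable, a ``mask`` byte variable and a CF time coordinate.
* GeoTIFF stack — one single-band float32 file per date, named
  ``<var>_<YYYY-MM-DD>.tif``; masked cells are written as NaN with a
  ``GDAL_NODATA`` tag, and any georeferencing tags present on input files are
  carried through untouched.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import enum
import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
import xarray as xr

__all__ = [
    "Variable",
    "StepKind",
    "TimeAxis",
    "RasterCube",
    "RunConfig",
    "ValidationError",
    "FormatError",
    "read_cube",
    "write_cube",
    "get_logger",
]

logger = logging.getLogger("vhicast")


def get_logger() -> logging.Logger:
    return logger


class ValidationError(ValueError):
    """Input violates a documented precondition or invariant."""


class FormatError(IOError):
    """File exists but cannot be parsed in a supported format."""


class Variable(str, enum.Enum):
    NDVI = "NDVI"
    LST = "LST"
    VCI = "VCI"
    TCI = "TCI"
    VHI = "VHI"


#: default units per variable; NDVI and the condition indices are dimensionless
DEFAULT_UNITS = {
    Variable.NDVI: "1",
    Variable.LST: "K",
    Variable.VCI: "1",
    Variable.TCI: "1",
    Variable.VHI: "1",
}

#: day-of-year start grid of the MODIS 8-day compositing calendar
MODIS_DOY_STARTS = tuple(range(1, 362, 8))


class StepKind(str, enum.Enum):
    daily = "daily"
    composite_8day = "composite_8day"


@dataclasses.dataclass(frozen=True)
class TimeAxis:
    """Strictly increasing sequence of calendar dates."""

    timestamps: tuple[dt.date, ...]
    step_kind: StepKind = StepKind.daily

    def __post_init__(self) -> None:
        ts = tuple(self.timestamps)
        object.__setattr__(self, "timestamps", ts)
        if len(ts) == 0:
            raise ValidationError("time axis must contain at least one date")
        for a, b in zip(ts, ts[1:]):
            if not b > a:
                raise ValidationError(f"timestamps not strictly increasing at {a} -> {b}")
        if self.step_kind is StepKind.composite_8day:
            for d in ts:
                if d.timetuple().tm_yday not in MODIS_DOY_STARTS:
                    raise ValidationError(
                        f"{d} is not a MODIS composite start (day-of-year 1, 9, ..., 361)"
                    )

    def __len__(self) -> int:
        return len(self.timestamps)

    def __getitem__(self, i):
        return self.timestamps[i]


@dataclasses.dataclass
class RasterCube:
    """A (time, row, col) raster time series of one variable.

    Row 0 is the north edge; indices are 0-based. ``mask`` is True where the
    value is missing; ``values`` must be finite wherever the mask is False.
    """

    variable: Variable
    values: np.ndarray
    mask: np.ndarray
    time: TimeAxis
    units: str = ""
    attrs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.variable = Variable(self.variable)
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be (time, row, col), got shape {self.values.shape}")
        if self.mask.shape != self.values.shape:
            raise ValidationError("mask shape differs from values shape")
        if len(self.time) != self.values.shape[0]:
            raise ValidationError(
                f"time axis length {len(self.time)} != number of frames {self.values.shape[0]}"
            )
        if not self.units:
            self.units = DEFAULT_UNITS[self.variable]
        if not np.all(np.isfinite(self.values[~self.mask])):
            raise ValidationError("non-finite values present outside the mask")

    # -- conveniences -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def copy(self) -> "RasterCube":
        return RasterCube(
            variable=self.variable,
            values=self.values.copy(),
            mask=self.mask.copy(),
            time=self.time,
            units=self.units,
            attrs=dict(self.attrs),
        )

    def isel_time(self, indexer) -> "RasterCube":
        """Subset along the time dimension (slice or index array)."""
        idx = np.arange(len(self.time))[indexer]
        ts = tuple(self.time.timestamps[i] for i in np.atleast_1d(idx))
        return RasterCube(
            variable=self.variable,
            values=self.values[indexer],
            mask=self.mask[indexer],
            time=TimeAxis(ts, self.time.step_kind),
            units=self.units,
            attrs=dict(self.attrs),
        )


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults are the package's standard experimental setup: windows of L=6
    composites, horizons 1-3, 16 convolution filters of size 3, at most 100
    training epochs with early-stopping patience 20, a temporal 80/10/10
    split and VHI weight alpha=0.5.
    """

    grid_size: tuple[int, int] = (128, 128)
    window_length: int = 6
    horizons: tuple[int, ...] = (1, 2, 3)
    normalization_scope: str = "global"
    layers: int = 1
    filters: int = 16
    kernel_size: int = 3
    max_epochs: int = 100
    patience: int = 20
    batch_size: int = 8
    learning_rate: float = 1e-3
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    alpha: float = 0.5
    fill_mode: str = "spatial"
    strategies: tuple[str, ...] = ("iterative", "separate")

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValidationError("split fractions must sum to 1")
        if self.window_length < 1:
            raise ValidationError("window_length must be >= 1")
        if not self.horizons:
            raise ValidationError("at least one horizon required")
        if any(k < 1 for k in self.horizons):
            raise ValidationError("horizons must be positive")
        if self.layers not in (1, 2, 3):
            raise ValidationError("layers must be 1, 2 or 3")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ValidationError("kernel_size must be odd and positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.normalization_scope not in ("image", "global", "global_scalar"):
            raise ValidationError(f"unknown normalization scope {self.normalization_scope!r}")
        if self.patience >= self.max_epochs:
            raise ValidationError("patience must be smaller than max_epochs")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# NetCDF
# ---------------------------------------------------------------------------

def _cube_to_dataset(cube: RasterCube) -> xr.Dataset:
    times = np.array(
        [np.datetime64(d, "D") for d in cube.time.timestamps], dtype="datetime64[ns]"
    )
    ds = xr.Dataset(
        {
            cube.variable.value: (("time", "y", "x"), cube.values.astype(np.float32)),
            "mask": (("time", "y", "x"), cube.mask.astype(np.int8)),
        },
        coords={"time": times},
        attrs={"step_kind": cube.time.step_kind.value, **{
            k: v for k, v in cube.attrs.items() if isinstance(v, (str, int, float))
        }},
    )
    ds[cube.variable.value].attrs["units"] = cube.units
    ds[cube.variable.value].attrs["_FillValue"] = np.float32(np.nan)
    ds["mask"].attrs["flag_meanings"] = "0=observed 1=missing"
    return ds


def _write_netcdf(cube: RasterCube, path: Path) -> None:
    ds = _cube_to_dataset(cube)
    ds.to_netcdf(path, engine="scipy", format="NETCDF3_CLASSIC")


def _read_netcdf(path: Path, variable: Variable) -> RasterCube:
    try:
        ds = xr.open_dataset(path, engine="scipy")
    except Exception:
        try:
            ds = xr.open_dataset(path)
        except Exception as exc:  # pragma: no cover - depends on file contents
            raise FormatError(f"cannot read NetCDF file {path}: {exc}") from exc
    with ds:
        name = variable.value
        if name not in ds:
            # accept a file whose single data variable is the one requested
            data_vars = [v for v in ds.data_vars if v != "mask"]
            if len(data_vars) == 1:
                name = data_vars[0]
            else:
                raise FormatError(f"variable {variable.value!r} not found in {path}")
        ds_sorted = ds.sortby("time")
        times = ds_sorted["time"].values
        dates = [
            dt.date.fromisoformat(str(t)[:10]) for t in np.datetime_as_string(times, unit="D")
        ]
        if len(set(dates)) != len(dates):
            raise ValidationError(f"duplicate timestamps in {path}")
        values = np.asarray(ds_sorted[name].values, dtype=np.float32)
        if "mask" in ds_sorted:
            mask = np.asarray(ds_sorted["mask"].values) != 0
        else:
            mask = ~np.isfinite(values)
        values = np.where(mask & ~np.isfinite(values), 0.0, values).astype(np.float32)
        step_kind = StepKind(ds.attrs.get("step_kind", _infer_step_kind(dates)))
        units = ds_sorted[name].attrs.get("units", "") or DEFAULT_UNITS[variable]
        attrs = {
            k: v for k, v in ds.attrs.items() if k != "step_kind" and isinstance(v, (str, int, float))
        }
    return RasterCube(
        variable=variable,
        values=values,
        mask=mask,
        time=TimeAxis(tuple(dates), step_kind),
        units=units,
        attrs=attrs,
    )


def _infer_step_kind(dates: Sequence[dt.date]) -> str:
    ok = all(d.timetuple().tm_yday in MODIS_DOY_STARTS for d in dates)
    return StepKind.composite_8day.value if (ok and len(dates) > 1) else StepKind.daily.value


# ---------------------------------------------------------------------------
# GeoTIFF stacks
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(r"(\d{4}-\d{2}-\d{2})")

#: raw TIFF tag codes carried through untouched (GeoKey directory, pixel
#: scale, tiepoints, ascii params) so georeferencing survives a round trip
_GEO_TAGS = (33550, 33922, 34264, 34735, 34736, 34737)


def _write_geotiff_stack(cube: RasterCube, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    extratags = []
    for code, (dtype, value) in cube.attrs.get("geotiff_tags", {}).items():
        count = len(value) if isinstance(value, (tuple, list, str, bytes)) else 1
        extratags.append((int(code), dtype, count, value, True))
    extratags.append((42113, "s", 0, "nan", True))  # GDAL_NODATA
    for i, date in enumerate(cube.time.timestamps):
        frame = cube.values[i].astype(np.float32).copy()
        frame[cube.mask[i]] = np.nan
        name = f"{cube.variable.value}_{date.isoformat()}.tif"
        tifffile.imwrite(outdir / name, frame, extratags=extratags)


def _read_geotiff_stack(path: Path, variable: Variable) -> RasterCube:
    files = sorted(path.glob("*.tif")) + sorted(path.glob("*.tiff"))
    if not files:
        raise FormatError(f"no GeoTIFF files found in {path}")
    dated: list[tuple[dt.date, Path]] = []
    for f in files:
        m = _DATE_RE.search(f.name)
        if m is None:
            raise FormatError(f"no ISO date in filename {f.name}")
        dated.append((dt.date.fromisoformat(m.group(1)), f))
    dated.sort(key=lambda p: p[0])
    dates = [d for d, _ in dated]
    if len(set(dates)) != len(dates):
        raise ValidationError(f"duplicate timestamps among GeoTIFF files in {path}")

    frames, geo_tags = [], {}
    for _, f in dated:
        try:
            with tifffile.TiffFile(f) as tif:
                page = tif.pages[0]
                frame = page.asarray()
                if not geo_tags:
                    for code in _GEO_TAGS:
                        if code in page.tags:
                            tag = page.tags[code]
                            geo_tags[code] = (tag.dtype, tag.value)
        except Exception as exc:
            raise FormatError(f"cannot read GeoTIFF {f}: {exc}") from exc
        if frame.ndim != 2:
            raise FormatError(f"{f} is not single-band")
        frames.append(np.asarray(frame, dtype=np.float32))
    shapes = {fr.shape for fr in frames}
    if len(shapes) != 1:
        raise ValidationError(f"inconsistent grid shapes across frames: {sorted(shapes)}")
    values = np.stack(frames)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values).astype(np.float32)
    attrs = {"geotiff_tags": geo_tags} if geo_tags else {}
    return RasterCube(
        variable=variable,
        values=values,
        mask=mask,
        time=TimeAxis(tuple(dates), StepKind(_infer_step_kind(dates))),
        units=DEFAULT_UNITS[variable],
        attrs=attrs,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def read_cube(path: str | Path, variable: Variable | str) -> RasterCube:
    """Read a raster cube from a NetCDF file or a directory of GeoTIFFs.

    Frames are sorted by date regardless of on-disk order; no-data pixels are
    flagged in the mask.
    """
    path = Path(path)
    variable = Variable(variable)
    if path.is_dir():
        return _read_geotiff_stack(path, variable)
    if not path.exists():
        raise FormatError(f"{path} does not exist")
    return _read_netcdf(path, variable)


def write_cube(cube: RasterCube, path: str | Path, format: str = "netcdf") -> None:
    """Write a cube as NetCDF (single file) or a GeoTIFF stack (directory)."""
    path = Path(path)
    if format == "netcdf":
        path.parent.mkdir(parents=True, exist_ok=True)
        _write_netcdf(cube, path)
    elif format == "geotiff_stack":
        _write_geotiff_stack(cube, path)
    else:
        raise ValidationError(f"unknown format {format!r}")
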