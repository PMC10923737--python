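"""Vegetation health indices.

NDVI = (NIR - RED) / (NIR + RED) measures green-vegetation vigour; VCI and
TCI min-max rescale NDVI and LST against reference extremes, and
VHI = alpha * VCI + (1 - alpha) * TCI blends moisture and thermal stress
(alpha = 0.5 by default). Two normalization scopes are supported:

* ``image`` — min/max over all pixels of each single frame (the traditional
  calculation; every frame is re-anchored to its own extremes);
* ``global`` — min/max of each pixel taken across the whole time series,
  preserving frame-to-frame dynamics in the index. A ``global_scalar``
  variant (one scalar pair over all pixels and times) is provided as an
  experimental alternative reading of "global".

VHI classes: > 0.50 no drought, (0.35, 0.50] mild, (0.20, 0.35] moderate,
(0.10, 0.20] severe, <= 0.10 extreme.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np

from .core_io import RasterCube, ValidationError, Variable

__all__ = [
    "NormalizationStats",
    "DroughtClass",
    "compute_ndvi",
    "normalization_stats",
    "compute_vci",
    "compute_tci",
    "compute_vhi",
    "classify_drought",
]

SCOPES = ("image", "global", "global_scalar")


class DroughtClass(str, enum.Enum):
    none = "none"
    mild = "mild"
    moderate = "moderate"
    severe = "severe"
    extreme = "extreme"


#: (lower-exclusive, upper-inclusive) VHI bounds per class; 0.50 itself is mild
DROUGHT_BOUNDS = {
    DroughtClass.extreme: (-np.inf, 0.10),
    DroughtClass.severe: (0.10, 0.20),
    DroughtClass.moderate: (0.20, 0.35),
    DroughtClass.mild: (0.35, 0.50),
    DroughtClass.none: (0.50, np.inf),
}


@dataclasses.dataclass
class NormalizationStats:
    """Min/max reference fields for one variable under one scope.

    image scope: ``minimum``/``maximum`` have shape (T,) — one scalar pair
    per frame. global scope: shape (H, W) — one pair per pixel over time.
    global_scalar: shape () — one pair overall.
    """

    scope: str
    variable: Variable
    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValidationError(f"unknown scope {self.scope!r}")
        self.minimum = np.asarray(self.minimum, dtype=np.float32)
        self.maximum = np.asarray(self.maximum, dtype=np.float32)
        if self.minimum.shape != self.maximum.shape:
            raise ValidationError("minimum/maximum shape mismatch")
        if np.any(self.maximum < self.minimum):
            raise ValidationError("maximum < minimum somewhere")

    def broadcast(self, cube_shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (min, max) broadcastable against a (T, H, W) cube."""
        T, H, W = cube_shape
        if self.scope == "image":
            if self.minimum.shape != (T,):
                raise ValidationError(
                    f"image-scope stats for {self.minimum.shape[0] if self.minimum.ndim else '?'} "
                    f"frames applied to a {T}-frame cube"
                )
            return self.minimum[:, None, None], self.maximum[:, None, None]
        if self.scope == "global":
            if self.minimum.shape != (H, W):
                raise ValidationError("global-scope stats grid does not match cube grid")
            return self.minimum[None], self.maximum[None]
        if self.minimum.shape != ():
            raise ValidationError("global_scalar stats must be scalars")
        return self.minimum, self.maximum


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ma.MaskedArray:
    """NDVI from RED/NIR reflectance grids; masked where RED + NIR == 0."""
    red = np.asarray(red, dtype=np.float32)
    nir = np.asarray(nir, dtype=np.float32)
    if red.shape != nir.shape:
        raise ValidationError("red and nir grids must have the same shape")
    if np.any(red < 0) or np.any(nir < 0):
        raise ValidationError("reflectances must be nonnegative")
    denom = nir + red
    bad = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(bad, 0.0, (nir - red) / np.where(bad, 1.0, denom))
    return np.ma.MaskedArray(ndvi.astype(np.float32), mask=bad)


def normalization_stats(cube: RasterCube, scope: str) -> NormalizationStats:
    """Min/max reference fields of a gap-free cube under the given scope."""
    if scope not in SCOPES:
        raise ValidationError(f"unknown scope {scope!r}")
    if cube.mask.any():
        raise ValidationError("normalization_stats requires a gap-free cube (run fill_gaps first)")
    v = cube.values
    if scope == "image":
        mn, mx = v.min(axis=(1, 2)), v.max(axis=(1, 2))
    elif scope == "global":
        mn, mx = v.min(axis=0), v.max(axis=0)
    else:
        mn, mx = v.min(), v.max()
    return NormalizationStats(scope=scope, variable=cube.variable, minimum=mn, maximum=mx)


def _rescale(
    cube: RasterCube, stats: NormalizationStats, invert: bool, out_var: Variable
) -> RasterCube:
    mn, mx = stats.broadcast(cube.shape)
    rng = (mx - mn).astype(np.float32)
    degenerate = rng == 0
    safe = np.where(degenerate, 1.0, rng).astype(np.float32)
    if invert:
        scaled = (mx - cube.values) / safe
    else:
        scaled = (cube.values - mn) / safe
    scaled = np.where(np.broadcast_to(degenerate, cube.shape), np.float32(0.5), scaled)
    scaled = np.clip(scaled, 0.0, 1.0).astype(np.float32)
    return RasterCube(
        variable=out_var,
        values=scaled,
        mask=cube.mask.copy(),
        time=cube.time,
        units="1",
        attrs={**cube.attrs, "normalization_scope": stats.scope},
    )


def compute_vci(ndvi: RasterCube, stats: NormalizationStats) -> RasterCube:
    """VCI = (NDVI - NDVImin) / (NDVImax - NDVImin), clipped to [0, 1].

    Degenerate reference ranges (max == min) map to 0.5.
    """
    if stats.variable is not Variable.NDVI:
        raise ValidationError("VCI requires NDVI normalization stats")
    return _rescale(ndvi, stats, invert=False, out_var=Variable.VCI)


def compute_tci(lst: RasterCube, stats: NormalizationStats) -> RasterCube:
    """TCI = (LSTmax - LST) / (LSTmax - LSTmin), clipped to [0, 1]."""
    if stats.variable is not Variable.LST:
        raise ValidationError("TCI requires LST normalization stats")
    return _rescale(lst, stats, invert=True, out_var=Variable.TCI)


def compute_vhi(vci: RasterCube, tci: RasterCube, alpha: float = 0.5) -> RasterCube:
    """VHI = alpha * VCI + (1 - alpha) * TCI, elementwise."""
    if not 0.0 <= alpha <= 1.0:
        raise ValidationError("alpha must lie in [0, 1]")
    if vci.time.timestamps != tci.time.timestamps:
        raise ValidationError("VCI and TCI time axes are misaligned")
    if vci.shape != tci.shape:
        raise ValidationError("VCI and TCI shapes differ")
    if alpha == 1.0:
        values = vci.values.copy()
    elif alpha == 0.0:
        values = tci.values.copy()
    else:
        values = (np.float32(alpha) * vci.values + np.float32(1.0 - alpha) * tci.values).astype(
            np.float32
        )
    return RasterCube(
        variable=Variable.VHI,
        values=values,
        mask=vci.mask | tci.mask,
        time=vci.time,
        units="1",
        attrs={**vci.attrs, "alpha": alpha},
    )


def classify_drought(vhi_value: float) -> DroughtClass:
    """Drought severity class of a single VHI value in [0, 1]."""
    v = float(vhi_value)
    if not 0.0 <= v <= 1.0:
        raise ValidationError(f"VHI value {v} outside [0, 1]")
    for cls, (lo, hi) in DROUGHT_BOUNDS.items():
        if lo < v <= hi or (cls is DroughtClass.none and v > lo):
            return cls
    raise AssertionError("unreachable: drought classes partition [0, 1]")
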