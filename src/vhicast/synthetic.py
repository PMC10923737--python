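"""Synthetic NDVI/LST cube generator.

Emulates the statistical structure the forecasting method assumes in
satellite vegetation data: a smooth spatial baseline, an annual sinusoidal
cycle, pixelwise AR(1) noise, negative NDVI-LST coupling, and optionally
missing cells and per-frame range outliers (residual-contamination spikes
that jitter each frame's min/max, which is what distinguishes image-based
from global-scale normalization in practice).

Everything is driven by a single integer seed and is bitwise reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
from scipy import ndimage

from .core_io import RasterCube, StepKind, TimeAxis, ValidationError, Variable

__all__ = [
    "SimulationConfig",
    "generate_daily_cubes",
    "inject_missing",
    "inject_range_outliers",
]


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of the daily NDVI/LST simulator.

    Defaults emulate the reference study conditions: a 128x128 km grid in a
    semi-arid continental climate observed daily over 2012-2021 (annual mean
    ~284 K with a ~10.7 K seasonal swing; vegetated NDVI baseline 0.2-0.6
    with a 0.2 seasonal amplitude), moderate spatial correlation and a few
    percent of missing cells.
    """

    grid_size: tuple[int, int] = (128, 128)
    start_date: dt.date = dt.date(2012, 1, 1)
    end_date: dt.date = dt.date(2022, 1, 1)
    ndvi_baseline_range: tuple[float, float] = (0.2, 0.6)
    ndvi_seasonal_amplitude: float = 0.2
    lst_mean_K: float = 284.0
    lst_seasonal_amplitude_K: float = 10.7
    anticorrelation_strength: float = 0.8
    spatial_correlation_length: float = 8.0
    noise_sd: float = 0.02
    ar1_coefficient: float = 0.7
    missing_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.end_date <= self.start_date:
            raise ValidationError("end_date must be after start_date")
        if self.ndvi_seasonal_amplitude < 0 or self.lst_seasonal_amplitude_K < 0:
            raise ValidationError("seasonal amplitudes must be nonnegative")
        if not 0.0 <= self.anticorrelation_strength <= 1.0:
            raise ValidationError("anticorrelation_strength must lie in [0, 1]")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValidationError("ar1_coefficient must lie in [0, 1)")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValidationError("missing_fraction must lie in [0, 1)")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], length: float) -> np.ndarray:
    """Seeded white noise smoothed to correlation length ``length``, rescaled to [0, 1]."""
    field = rng.standard_normal(shape)
    if length > 0:
        field = ndimage.gaussian_filter(field, sigma=length, mode="wrap")
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.full(shape, 0.5)
    return (field - lo) / (hi - lo)


def _ar1_noise(
    rng: np.random.Generator, T: int, shape: tuple[int, int], rho: float, sd: float
) -> np.ndarray:
    """Pixelwise AR(1) series with innovation standard deviation ``sd``."""
    out = np.zeros((T,) + shape, dtype=np.float64)
    if sd == 0.0:
        return out
    innov = rng.standard_normal((T,) + shape) * sd
    # stationary start so early frames are not systematically quieter
    out[0] = innov[0] / np.sqrt(1.0 - rho**2) if rho > 0 else innov[0]
    for t in range(1, T):
        out[t] = rho * out[t - 1] + innov[t]
    return out


def generate_daily_cubes(config: SimulationConfig) -> tuple[RasterCube, RasterCube]:
    """Generate paired daily NDVI and LST cubes.

    NDVI(p, t) = base(p) + A(p) sin(2*pi*doy(t)/365 + phi(p)) + AR(1) noise,
    with base, A, phi smooth spatial fields. LST carries the opposite-phase
    seasonal cycle plus a term proportional to the negative NDVI anomaly, so
    warm anomalies coincide with vegetation stress. NDVI is clipped to
    [-1, 1]; LST stays positive for any physically sensible configuration.
    """
    rng = np.random.default_rng(config.seed)
    H, W = config.grid_size
    ndays = (config.end_date - config.start_date).days
    dates = tuple(config.start_date + dt.timedelta(days=i) for i in range(ndays))
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=np.float64)

    b_lo, b_hi = config.ndvi_baseline_range
    base = b_lo + (b_hi - b_lo) * _smooth_field(rng, (H, W), config.spatial_correlation_length)
    # amplitude varies smoothly within +/-25% of the configured level
    amp = config.ndvi_seasonal_amplitude * (
        0.75 + 0.5 * _smooth_field(rng, (H, W), config.spatial_correlation_length)
    )
    # mild spatial phase gradient (phenology shifts of up to ~2 weeks)
    phase = 0.25 * (2.0 * _smooth_field(rng, (H, W), config.spatial_correlation_length) - 1.0)

    season = np.sin(2.0 * np.pi * doy[:, None, None] / 365.0 + phase[None])
    ndvi = base[None] + amp[None] * season + _ar1_noise(
        rng, ndays, (H, W), config.ar1_coefficient, config.noise_sd
    )
    ndvi = np.clip(ndvi, -1.0, 1.0)

    # LST: opposite-phase seasonal cycle minus a coupling to the NDVI anomaly.
    # The coupling is scaled so NDVI-anomaly units map onto LST's dynamic range.
    if config.ndvi_seasonal_amplitude > 0:
        scale = config.lst_seasonal_amplitude_K / config.ndvi_seasonal_amplitude
    else:
        scale = config.lst_seasonal_amplitude_K / max(config.noise_sd, 1e-6)
    ndvi_anom = ndvi - ndvi.mean(axis=0, keepdims=True)
    lst_noise_sd = config.noise_sd * scale * 0.5
    lst = (
        config.lst_mean_K
        + config.lst_seasonal_amplitude_K * np.sin(2.0 * np.pi * doy[:, None, None] / 365.0 + np.pi)
        - config.anticorrelation_strength * scale * 0.5 * ndvi_anom
        + _ar1_noise(rng, ndays, (H, W), config.ar1_coefficient, lst_noise_sd)
    )
    lst = np.maximum(lst, 1.0)

    axis = TimeAxis(dates, StepKind.daily)
    ndvi_cube = RasterCube(Variable.NDVI, ndvi.astype(np.float32), None, axis)
    lst_cube = RasterCube(Variable.LST, lst.astype(np.float32), None, axis)
    if config.missing_fraction > 0:
        miss_seed = int(rng.integers(0, 2**31 - 1))
        ndvi_cube = inject_missing(ndvi_cube, config.missing_fraction, miss_seed)
        lst_cube = inject_missing(lst_cube, config.missing_fraction, miss_seed + 1)
    return ndvi_cube, lst_cube


def inject_missing(cube: RasterCube, fraction: float, seed: int) -> RasterCube:
    """Mask a uniform random ``fraction`` of cells.

    Never masks an entire frame or an entire pixel time series, so both
    spatial and temporal interpolation stay well-posed. Original values are
    retained under the mask for recovery testing.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValidationError("fraction must lie in [0, 1)")
    out = cube.copy()
    if fraction == 0.0:
        return out
    T, H, W = cube.shape
    n_cells = T * H * W
    n_mask = int(round(fraction * n_cells))
    if n_mask == 0:
        return out
    rng = np.random.default_rng(seed)
    for _ in range(20):
        flat = rng.choice(n_cells, size=n_mask, replace=False)
        mask = np.zeros(n_cells, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(T, H, W) | cube.mask
        frame_ok = ~mask.all(axis=(1, 2)).any()
        series_ok = ~mask.all(axis=0).any()
        if frame_ok and series_ok:
            out.mask = mask
            return out
    raise ValidationError(
        "could not sample a mask without fully covering a frame or pixel series; "
        "the cube is too small for this fraction"
    )


def inject_range_outliers(
    cube: RasterCube,
    pixel_fraction: float = 0.02,
    amplitude: float | None = None,
    sign: int = -1,
    seed: int = 0,
) -> RasterCube:
    """Add contamination spikes at a fixed set of pixels, resampled each frame.

    Emulates residual cloud/atmospheric contamination: a small fixed set of
    pixels takes a random spike of magnitude up to ``amplitude`` (default:
    the cube's global dynamic range) in every frame, with ``sign`` -1 for
    NDVI-like dropouts or +1 for LST-like hot pixels. Because the spike
    magnitude varies frame to frame, per-frame min/max statistics fluctuate
    while per-pixel-over-time statistics remain stable for the uncontaminated
    majority of pixels.
    """
    if not 0.0 < pixel_fraction < 1.0:
        raise ValidationError("pixel_fraction must lie in (0, 1)")
    if sign not in (-1, 1):
        raise ValidationError("sign must be -1 or +1")
    rng = np.random.default_rng(seed)
    out = cube.copy()
    T, H, W = cube.shape
    n_pix = max(1, int(round(pixel_fraction * H * W)))
    flat = rng.choice(H * W, size=n_pix, replace=False)
    rows, cols = np.unravel_index(flat, (H, W))
    if amplitude is None:
        obs = cube.values[~cube.mask]
        amplitude = float(obs.max() - obs.min())
    spikes = rng.uniform(0.0, amplitude, size=(T, n_pix)).astype(np.float32)
    out.values[:, rows, cols] += sign * spikes
    if cube.variable is Variable.NDVI:
        out.values = np.clip(out.values, -1.0, 1.0)
    out.attrs["range_outlier_pixels"] = n_pix
    return out
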