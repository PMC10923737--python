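"""Forecast scoring: RMSE, MAE, MAPE, per-pixel error maps and baselines.

Metrics are pooled over all scored time steps and pixels by default
(``per_image=True`` averages per-frame scores instead, which differs for
RMSE). MAPE divides by ``max(|y_true|, zero_floor)`` so the metric stays
finite on a [0, 1]-scaled index; the default floor is 0.01.

Two reference baselines are provided: persistence (repeat the last observed
frame) and climatology (per-pixel training-partition mean of frames sharing
the same within-year composite position).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import MODIS_DOY_STARTS, RasterCube, ValidationError
from .forecasting import WindowedDataset, temporal_split

__all__ = [
    "EvaluationReport",
    "rmse",
    "mae",
    "mape",
    "rmse_map",
    "evaluate_forecast",
    "baselines",
]


def _aligned(y_pred, y_true) -> tuple[np.ndarray, np.ndarray]:
    y_pred = np.asarray(y_pred, dtype=np.float64)
    y_true = np.asarray(y_true, dtype=np.float64)
    if y_pred.shape != y_true.shape:
        raise ValidationError(f"shape mismatch: {y_pred.shape} vs {y_true.shape}")
    if y_pred.size == 0:
        raise ValidationError("empty inputs")
    return y_pred, y_true


def rmse(y_pred, y_true, per_image: bool = False) -> float:
    """Root mean squared error, pooled over all values (or averaged per frame)."""
    y_pred, y_true = _aligned(y_pred, y_true)
    sq = (y_pred - y_true) ** 2
    if per_image and sq.ndim == 3:
        return float(np.mean(np.sqrt(sq.mean(axis=(1, 2)))))
    return float(np.sqrt(sq.mean()))


def mae(y_pred, y_true) -> float:
    """Mean absolute error."""
    y_pred, y_true = _aligned(y_pred, y_true)
    return float(np.abs(y_pred - y_true).mean())


def mape(y_pred, y_true, zero_floor: float = 0.01) -> float:
    """Mean absolute percentage error with a denominator floor.

    Cells where |y_true| < zero_floor use zero_floor as the denominator so
    the metric stays finite.
    """
    if zero_floor <= 0:
        raise ValidationError("zero_floor must be positive")
    y_pred, y_true = _aligned(y_pred, y_true)
    denom = np.maximum(np.abs(y_true), zero_floor)
    return float(100.0 * np.mean(np.abs(y_pred - y_true) / denom))


def rmse_map(y_pred, y_true, bin_width: float = 0.005):
    """Per-pixel RMSE over time plus its histogram.

    Returns (map, bin_edges, counts); bins cover [0, max] with the given
    width and the counts sum to the pixel count.
    """
    y_pred, y_true = _aligned(y_pred, y_true)
    if y_pred.ndim != 3:
        raise ValidationError("rmse_map expects (time, row, col) arrays")
    grid = np.sqrt(((y_pred - y_true) ** 2).mean(axis=0))
    top = float(grid.max())
    n_bins = max(1, int(np.ceil(top / bin_width)) if top > 0 else 1)
    edges = np.arange(0.0, (n_bins + 1) * bin_width, bin_width)[: n_bins + 1]
    if edges[-1] <= top:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(grid, bins=edges)
    return grid, edges, counts


@dataclasses.dataclass
class EvaluationReport:
    """Scalar metrics plus the per-pixel RMSE map for one forecast run."""

    rmse: float
    mae: float
    mape: float
    rmse_map: np.ndarray
    histogram_edges: np.ndarray
    histogram_counts: np.ndarray
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.rmse >= self.mae >= 0.0):  # power-mean inequality
            raise ValidationError("expected rmse >= mae >= 0")


def evaluate_forecast(result, metadata: dict | None = None,
                      per_image: bool = False) -> EvaluationReport:
    """Score a ForecastResult (prediction cube vs truth cube)."""
    y_pred, y_true = result.predicted.values, result.truth.values
    grid, edges, counts = rmse_map(y_pred, y_true)
    meta = {"strategy": result.strategy, "horizon": result.horizon}
    meta.update(metadata or {})
    return EvaluationReport(
        rmse=rmse(y_pred, y_true, per_image=per_image),
        mae=mae(y_pred, y_true),
        mape=mape(y_pred, y_true),
        rmse_map=grid,
        histogram_edges=edges,
        histogram_counts=counts,
        metadata=meta,
    )


class _PersistenceModel:
    """Predicts the last frame of the input window."""

    @staticmethod
    def predict(windows: np.ndarray) -> np.ndarray:
        return np.asarray(windows)[:, -1]


def baselines(
    vhi: RasterCube,
    split: dict[str, range],
    L: int,
    horizons: tuple[int, ...],
    part: str = "test",
) -> dict[str, dict[int, EvaluationReport]]:
    """Persistence and climatology reference scores per horizon.

    Persistence repeats the last observed window frame; climatology predicts
    the per-pixel mean of training frames at the same within-year composite
    position (requires at least one full year of training data).
    """
    from .forecasting import make_windows

    comp_of_year = np.array(
        [MODIS_DOY_STARTS.index(d.timetuple().tm_yday) for d in vhi.time.timestamps]
    )
    train_idx = np.array(split["train"])
    if len(np.unique(comp_of_year[train_idx])) < len(MODIS_DOY_STARTS):
        raise ValidationError("climatology needs at least one full year of training data")
    clim = np.zeros((len(MODIS_DOY_STARTS),) + vhi.grid_shape, dtype=np.float64)
    for c in range(len(MODIS_DOY_STARTS)):
        sel = train_idx[comp_of_year[train_idx] == c]
        clim[c] = vhi.values[sel].mean(axis=0)

    out: dict[str, dict[int, EvaluationReport]] = {"persistence": {}, "climatology": {}}
    for k in horizons:
        ds = make_windows(vhi, L, k, split)
        sel = ds._part(part)
        truth = ds.targets[sel]
        target_idx = ds.target_indices(part)
        pers_pred = _PersistenceModel.predict(ds.inputs[sel])
        clim_pred = clim[comp_of_year[target_idx]]
        for name, pred in (("persistence", pers_pred), ("climatology", clim_pred)):
            grid, edges, counts = rmse_map(pred, truth)
            out[name][k] = EvaluationReport(
                rmse=rmse(pred, truth),
                mae=mae(pred, truth),
                mape=mape(pred, truth),
                rmse_map=grid,
                histogram_edges=edges,
                histogram_counts=counts,
                metadata={"strategy": name, "horizon": k},
            )
    return out
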