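"""Windowed dataset construction and multi-step forecasting strategies.

The VHI series is split in the time domain into contiguous train /
validation / test partitions (80/10/10 by default; floor for train and
validation counts, remainder to test). Samples are sliding windows of L
consecutive frames paired with the frame k steps after the window; windows
never cross a partition boundary, so no test target ever leaks into a
training input.

Two multi-step strategies are provided:

* separate (direct): a dedicated model per horizon k maps observed windows
  straight to the k-step-ahead target;
* iterative: a 1-step model is applied repeatedly, dropping the oldest frame
  and appending its own (clipped) prediction.

At k=1 the two strategies coincide exactly when they share the model.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .core_io import RasterCube, TimeAxis, ValidationError, Variable

__all__ = [
    "temporal_split",
    "WindowedDataset",
    "make_windows",
    "ForecastResult",
    "forecast_separate",
    "forecast_iterative",
]

PARTITIONS = ("train", "val", "test")


def temporal_split(
    T: int, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> dict[str, range]:
    """Contiguous ordered index ranges: first 80% train, next 10% validation,
    last 10% test (floor arithmetic, remainder to test)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValidationError("split fractions must sum to 1")
    n_tr = int(np.floor(fractions[0] * T))
    n_va = int(np.floor(fractions[1] * T))
    n_te = T - n_tr - n_va
    if min(n_tr, n_va, n_te) < 1:
        raise ValidationError(
            f"T={T} with fractions {fractions} leaves an empty partition "
            f"(sizes {n_tr}/{n_va}/{n_te}); need every partition nonempty"
        )
    return {
        "train": range(0, n_tr),
        "val": range(n_tr, n_tr + n_va),
        "test": range(n_tr + n_va, T),
    }


@dataclasses.dataclass
class WindowedDataset:
    """Sliding-window samples for one horizon, partitioned in time.

    ``inputs[s]`` holds frames t .. t+L-1 and ``targets[s]`` frame t+L+k-1,
    where t = ``start_indices[s]`` on the source cube's time axis.
    """

    inputs: np.ndarray  # (N, L, H, W)
    targets: np.ndarray  # (N, H, W)
    horizon: int
    window_length: int
    partition: np.ndarray  # (N,) strings from PARTITIONS
    start_indices: np.ndarray  # (N,) window start on the source time axis
    source_time: TimeAxis

    def _part(self, name: str) -> np.ndarray:
        return self.partition == name

    @property
    def train_inputs(self):
        return self.inputs[self._part("train")]

    @property
    def train_targets(self):
        return self.targets[self._part("train")]

    @property
    def val_inputs(self):
        return self.inputs[self._part("val")]

    @property
    def val_targets(self):
        return self.targets[self._part("val")]

    @property
    def test_inputs(self):
        return self.inputs[self._part("test")]

    @property
    def test_targets(self):
        return self.targets[self._part("test")]

    def target_indices(self, part: str) -> np.ndarray:
        sel = self._part(part)
        return self.start_indices[sel] + self.window_length + self.horizon - 1


def make_windows(
    vhi: RasterCube,
    L: int,
    k: int,
    split: dict[str, range] | None = None,
) -> WindowedDataset:
    """Stride-1 sliding windows inside each partition of the VHI cube.

    Each partition of length n contributes n - L - k + 1 samples; a
    partition shorter than L + k is an error.
    """
    if L < 1 or k < 1:
        raise ValidationError("window length and horizon must be positive")
    if vhi.mask.any():
        raise ValidationError("windowing requires a gap-free cube")
    T = vhi.shape[0]
    if split is None:
        split = temporal_split(T)
    inputs, targets, parts, starts = [], [], [], []
    for name in PARTITIONS:
        rng = split[name]
        n = len(rng)
        if n < L + k:
            raise ValidationError(
                f"partition {name!r} has {n} frames; needs at least L + k = {L + k}"
            )
        for t in range(rng.start, rng.stop - L - k + 1):
            inputs.append(vhi.values[t : t + L])
            targets.append(vhi.values[t + L + k - 1])
            parts.append(name)
            starts.append(t)
    return WindowedDataset(
        inputs=np.stack(inputs),
        targets=np.stack(targets),
        horizon=k,
        window_length=L,
        partition=np.array(parts),
        start_indices=np.array(starts),
        source_time=vhi.time,
    )


@dataclasses.dataclass
class ForecastResult:
    """Aligned prediction/truth cubes for one (strategy, horizon) pair."""

    strategy: str
    horizon: int
    predicted: RasterCube
    truth: RasterCube

    def __post_init__(self) -> None:
        if self.predicted.time.timestamps != self.truth.time.timestamps:
            raise ValidationError("prediction and truth time axes differ")


def _result_from_arrays(
    strategy: str,
    k: int,
    preds: np.ndarray,
    dataset: WindowedDataset,
    truth_targets: np.ndarray,
    target_idx: np.ndarray,
) -> ForecastResult:
    ts = tuple(dataset.source_time.timestamps[i] for i in target_idx)
    axis = TimeAxis(ts, dataset.source_time.step_kind)
    predicted = RasterCube(Variable.VHI, preds, None, axis, attrs={"strategy": strategy})
    truth = RasterCube(Variable.VHI, truth_targets, None, axis)
    return ForecastResult(strategy=strategy, horizon=k, predicted=predicted, truth=truth)


def forecast_separate(models: dict[int, object], datasets: dict[int, WindowedDataset],
                      part: str = "test") -> dict[int, ForecastResult]:
    """Direct forecasts: each horizon uses its own model on observed windows."""
    results = {}
    for k, dataset in datasets.items():
        if k not in models:
            raise ValidationError(f"no model trained for horizon {k}")
        preds = models[k].predict(dataset.inputs[dataset._part(part)])
        results[k] = _result_from_arrays(
            "separate", k, preds, dataset,
            dataset.targets[dataset._part(part)], dataset.target_indices(part),
        )
    return results


def forecast_iterative(model_1step, dataset: WindowedDataset, max_horizon: int,
                       vhi: RasterCube, part: str = "test") -> dict[int, ForecastResult]:
    """Iterated 1-step forecasts up to ``max_horizon``.

    Horizon 1 applies the model to observed windows; horizon j > 1 drops the
    oldest frame and appends the horizon j-1 prediction (already clipped to
    [0, 1]) before applying the model again. Predictions for horizon j are
    kept only for windows whose j-step target still lies inside the
    partition, so every horizon is scored against observed truth.
    """
    if max_horizon < 1:
        raise ValidationError("max_horizon must be >= 1")
    if dataset.horizon != 1:
        raise ValidationError("iterative forecasting needs a 1-step windowed dataset")
    sel = dataset._part(part)
    windows = dataset.inputs[sel].copy()
    starts = dataset.start_indices[sel]
    if not sel.any():
        raise ValidationError(f"partition {part!r} contains no windows")
    # for k=1 windows the last target is the final frame of the partition
    part_stop = int(dataset.target_indices(part).max()) + 1
    L = dataset.window_length
    results: dict[int, ForecastResult] = {}
    for j in range(1, max_horizon + 1):
        preds = model_1step.predict(windows)  # clipped to [0, 1] by predict
        target_idx = starts + L + j - 1
        keep = target_idx < part_stop
        if not keep.any():
            raise ValidationError(
                f"horizon {j} has no in-partition targets; partition too short"
            )
        truth_vals = vhi.values[target_idx[keep]]
        results[j] = _result_from_arrays(
            "iterative", j, preds[keep], dataset, truth_vals, target_idx[keep]
        )
        windows = np.concatenate([windows[:, 1:], preds[:, None]], axis=1)
    return results
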