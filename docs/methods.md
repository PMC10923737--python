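# Methods

## Overview

`vhicast` forecasts the Vegetation Health Index (VHI) over a raster grid.
The VHI blends two min–max-rescaled satellite observables,

    VCI = (NDVI − NDVI_min) / (NDVI_max − NDVI_min)
    TCI = (LST_max − LST) / (LST_max − LST_min)
    VHI = α·VCI + (1 − α)·TCI,            α = 0.5 by default,

where NDVI = (NIR − RED)/(NIR + RED) measures vegetation vigour and LST is
land surface temperature in Kelvin. VHI ≤ 0.5 indicates increasing drought
severity (mild > 0.35, moderate > 0.20, severe > 0.10, extreme ≤ 0.10; the
printed class intervals overlap at their endpoints, so we close each interval
on its upper end — 0.50 itself classifies as mild).

The forecasting model is a convolutional LSTM: an LSTM cell whose gate
transformations are same-padded convolutions, so spatial and temporal
structure are learned jointly. Given a window of L = 6 consecutive VHI
frames, a network of 1–3 stacked cells (16 filters, 3×3 kernels, 1×1
convolution head) predicts the frame k composites ahead.

## Normalization scopes

The min/max reference values in VCI/TCI can be taken per frame
("image-based": one scalar pair over all pixels of a single image) or per
pixel across the whole time series ("global scale"). Image-based
normalization re-anchors every frame to its own extremes, which removes
frame-wide dynamics and couples every pixel's index value to whatever pixel
happens to be the frame extreme — a single contaminated observation perturbs
the entire frame. Global-scale normalization preserves each pixel's temporal
dynamics and is robust to per-frame extreme fluctuations, which is why it
forecasts better whenever frame extremes are noisy. A third reading of
"global" — one scalar pair over all pixels *and* times — is implemented as
the experimental `global_scalar` scope; the per-pixel-over-time reading
matches the original VCI definition and is the default meaning of `global`
throughout.

Degenerate reference ranges (max = min) carry no information and map to 0.5.
Indices are computed in float32 and clipped to [0, 1] after rescaling to
guard against floating-point overshoot.

## Compositing calendar and gap filling

The 8-day compositing calendar restarts every January 1: periods start on
day-of-year 1, 9, …, 361, so the last period of each year is truncated to 5
days (6 in leap years) and every year contributes exactly 46 composites —
460 over 2012-01-01 … 2022-01-01. Composites are per-pixel arithmetic means
of unmasked daily values; a pixel observed on no day of a period stays
masked.

Missing cells are filled by 1-D linear interpolation. The default mode is
spatial (each image row scanned left→right, masked runs interpolated between
the nearest observed neighbours; fully masked rows fall back to column-wise
interpolation, then the frame mean); a temporal mode applies the same rule
along each pixel's series. Gaps touching a line edge are filled by
nearest-neighbour extension rather than linear extrapolation, which could
leave the physical range. Observed cells are never altered (bitwise).
Whether a practitioner interpolates spatially or temporally is largely a
matter of the gap structure; both are exposed and the recovery test in the
suite exercises the temporal mode on synthetic gaps.

## ConvLSTM implementation

The cell follows the peephole formulation (gates i, f, o; candidate tanh;
`*` a convolution, `∘` the Hadamard product):

    i_t = σ(W_xi * x_t + W_hi * h_{t−1} + W_ci ∘ c_{t−1} + b_i)
    f_t = σ(W_xf * x_t + W_hf * h_{t−1} + W_cf ∘ c_{t−1} + b_f)
    c_t = f_t ∘ c_{t−1} + i_t ∘ tanh(W_xc * x_t + W_hc * h_{t−1} + b_c)
    o_t = σ(W_xo * x_t + W_ho * h_{t−1} + W_co ∘ c_t + b_o)
    h_t = o_t ∘ tanh(c_t)

Peephole weights are elementwise (state-shaped) and default **off**, because
mainstream ConvLSTM layers omit them; a flag restores the exact form above.
The implementation is pure NumPy: convolutions are evaluated as im2col
matrix products with the four gates fused into a single weight matrix, and
gradients are hand-derived backpropagation through time (verified against
central finite differences and an explicit-loop convolution oracle in the
test suite). Forward math runs in float32; losses accumulate in float64.

Networks stack 1–3 cells (intermediate layers pass their full hidden
sequence upward) and finish with a 1×1 convolution mapping the last hidden
state to one frame, so a 1-layer model with F filters and k×k kernels has
4·(k²·(1+F)·F + F) + F + 1 parameters. Predictions are clipped to [0, 1] at
inference; training operates on raw outputs.

Training choices (exposed in `TrainingProtocol`): pixelwise MSE loss, Adam
with learning rate 1e-3, batch size 8, Glorot-style uniform init with the
forget-gate bias started at 1, at most 100 epochs, early stopping when the
validation loss has not improved (strictly, by any amount) for 20
consecutive epochs, best-validation weights restored. Given a seed, runs are
bitwise reproducible.

## Dataset construction and strategies

The composite time axis is split 80/10/10 into contiguous train/validation/
test blocks *before* windowing (floor for train and validation counts,
remainder to test; 460 → 368/46/46), and windows never cross a partition
boundary, so no test-period frame can appear in any training input. Each
partition of length n yields n − L − k + 1 stride-1 samples for horizon k.

Multi-step forecasts use two strategies. *Separate* (direct): a dedicated
model per horizon maps observed windows straight to the k-step target.
*Iterative*: the 1-step model is applied repeatedly, dropping the oldest
frame and appending its own clipped prediction. At k = 1 the two coincide
bitwise when they share a model. Iterative predictions at horizon j are
scored only for windows whose j-step target is still observed inside the
partition.

## Synthetic data generator

The generator emulates the statistical structure of a decade of daily
semi-arid vegetation observations on a small grid:

- NDVI(p, t) = base(p) + A(p)·sin(2π·doy(t)/365 + φ(p)) + AR(1) noise, with
  base, A, φ smooth random fields (seeded white noise smoothed with a
  Gaussian kernel of the configured correlation length, default 8 px). The
  annual period becomes ≈46 steps after 8-day compositing.
- LST carries the opposite-phase annual cycle plus a term proportional to
  the negative NDVI anomaly, so vegetation stress and warm anomalies
  coincide; its noise is scaled to its own dynamic range.
- Defaults: baseline NDVI 0.2–0.6 with seasonal amplitude 0.2; LST mean
  284 K with amplitude 10.7 K (an annual-mean ≈ 11 °C continental climate
  with ≈ 21 K peak-to-trough swing); AR(1) coefficient 0.7 and innovation
  s.d. 0.02 NDVI units; anticorrelation strength 0.8; 5 % of cells missing
  uniformly at random (never a whole frame or a whole pixel series; truth is
  retained under the mask for recovery tests).
- `inject_range_outliers` adds contamination spikes (NDVI dropouts / LST hot
  pixels) at a fixed 2 % of pixels with a fresh random magnitude every
  frame. This jitters per-frame extremes — exactly the condition that
  separates image-based from global-scale normalization — while leaving the
  other 98 % of pixels untouched.

What the generator does **not** emulate: cloud-shaped (spatially clustered)
missingness, sensor viewing geometry, mixed land cover, trends or regime
shifts, and real MODIS scale/QA conventions. Passing tests therefore
demonstrate correctness of the pipeline and the qualitative behaviour of the
method (forecast skill over persistence, scope ranking, horizon
degradation), not absolute error levels on real archives.

## Benchmark problem sizes

The repository's end-to-end checks and `scripts/acceptance.py` run on a
16×16 grid over 2012–2021 (3653 daily frames → 460 composites; split
368/46/46; L = 6; horizons 1–3; 1-layer, 16-filter models trained with the
full 100-epoch/patience-20 protocol). The skill and scope comparisons are
evaluated over training seeds {0, 1, 2} by majority. On this benchmark the
trained 1-step model reaches test RMSE ≈ 0.03–0.04, below the persistence
reference (≈ 0.05–0.06), with the global scope outperforming the image-based
scope; all of these numbers are recomputed at run time by the tests and the
acceptance script, never stored.

## Numerical and design notes

- Missing data lives in a boolean mask, never a sentinel value; NetCDF files
  store an explicit mask variable (values under the mask survive a round
  trip), GeoTIFF stacks store NaN with a `GDAL_NODATA` tag (they do not).
- Dates are calendar dates (no time of day); GeoTIFF stacks use
  `<VAR>_<YYYY-MM-DD>.tif` filenames; frames are sorted by date on read and
  duplicate dates are an error.
- Grids are (row, col) with row 0 at the north edge, 0-based.
- Values are float32 end-to-end; test comparisons use 1e-5 tolerances unless
  an operation is contractually bitwise.
- MAPE is undefined at y_true = 0; the denominator is floored at 0.01 (VHI
  scale) so the metric stays finite. RMSE/MAE/MAPE pool over all scored
  time×pixel values; a per-image-then-average variant exists behind a flag
  because the two differ for RMSE.
- The per-pixel RMSE histogram uses 0.005-wide bins from 0, which resolves
  the 0.02–0.04 band where well-trained models concentrate.
- Every output artifact carries a hash of the run configuration.

## Known limitations

- The NumPy ConvLSTM is CPU-only and sized for small grids (≈128×128 and
  below); there is no GPU path, no hyperparameter search, and no attention
  or transformer variant.
- Only the VHI cube (1 channel) is fed to the network; NDVI/LST are not
  additional input channels.
- Probabilistic/ensemble forecasting and exogenous covariates are out of
  scope; horizons beyond those configured reuse the same code path but are
  not exercised by the benchmark.
- Kriging/inpainting and maximum-value compositing are deliberately not
  implemented; the compositing is plain averaging.
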