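# vhicast

Vegetation health monitoring and short-range forecasting for raster time
series. `vhicast` computes the Vegetation Health Index (VHI) from NDVI and
land-surface-temperature (LST) cubes and forecasts it 1–k composites ahead
with convolutional LSTM networks — the kind of pipeline used to anticipate
agricultural drought from MODIS-class satellite archives. It is aimed at
remote-sensing and agro-hydrology practitioners who want a reproducible,
dependency-light implementation they can run on their own rasters or on the
built-in synthetic benchmark.

## The indices and the model

With NDVI = (NIR − RED)/(NIR + RED) and LST in Kelvin,

```
VCI = (NDVI − NDVI_min) / (NDVI_max − NDVI_min)        # moisture condition
TCI = (LST_max − LST)   / (LST_max − LST_min)          # thermal condition
VHI = α·VCI + (1 − α)·TCI,  α = 0.5
```

VHI > 0.50 means no drought; (0.35, 0.50] mild, (0.20, 0.35] moderate,
(0.10, 0.20] severe, ≤ 0.10 extreme drought.

The min/max references can be taken per frame (**image-based**, the
traditional calculation) or per pixel over the whole series (**global
scale**), and the two scopes behave very differently under noisy frame
extremes — the package implements both and lets you compare them.

Forecasting uses ConvLSTM cells — LSTM gates whose transformations are
same-padded convolutions (i, f, o gates, Hadamard peepholes optional):

```
i_t = σ(W_xi * x_t + W_hi * h_{t−1} + b_i)
f_t = σ(W_xf * x_t + W_hf * h_{t−1} + b_f)
c_t = f_t ∘ c_{t−1} + i_t ∘ tanh(W_xc * x_t + W_hc * h_{t−1} + b_c)
o_t = σ(W_xo * x_t + W_ho * h_{t−1} + b_o)
h_t = o_t ∘ tanh(c_t)
```

stacked 1–3 layers deep (16 filters, 3×3 kernels by default), trained with
Adam on pixelwise MSE with early stopping, entirely in NumPy — including the
backpropagation-through-time gradients. Multi-step forecasts come in two
flavours: **iterative** (re-feed the 1-step model its own predictions) and
**separate** (a direct model per horizon). See `docs/methods.md` for the
full account.

## Worked example

Simulate four years of daily NDVI/LST on a 12×12 grid, composite to the
8-day calendar, fill gaps, build global-scale VHI, train a 1-layer model and
evaluate both strategies:

```python
import datetime as dt
from vhicast import RunConfig, run_pipeline
from vhicast.synthetic import SimulationConfig

config = RunConfig(grid_size=(12, 12), horizons=(1, 2), filters=8,
                   max_epochs=30, patience=10, seed=7)
sim = SimulationConfig(grid_size=(12, 12), start_date=dt.date(2012, 1, 1),
                       end_date=dt.date(2016, 1, 1), seed=7)
reports = run_pipeline(config, simulate=True, sim_config=sim, outdir="demo")
for rep in reports:
    m = rep.metadata
    print(f"{m['strategy']:>9}  k={m['horizon']}  rmse={rep.rmse:.4f}  "
          f"mae={rep.mae:.4f}  mape={rep.mape:.2f}%")
```

prints

```
iterative  k=1  rmse=0.0490  mae=0.0381  mape=51.44%
iterative  k=2  rmse=0.0550  mae=0.0428  mape=50.01%
 separate  k=1  rmse=0.0490  mae=0.0381  mape=51.44%
 separate  k=2  rmse=0.0600  mae=0.0466  mape=56.07%
```

Read: 1-step forecasts err by ≈0.05 VHI units on the test year and degrade
as the horizon grows; the two strategies coincide exactly at k = 1 because
they share the same 1-step model. MAPE is large here because this test
window covers the season where true VHI approaches zero and percentage
errors blow up — RMSE/MAE are the robust numbers on the VHI scale.
`demo/metrics.csv` holds the same table; prediction and VHI cubes land next
to it as NetCDF.

The same pipeline is scriptable from a shell:

```
vhicast simulate --outdir data/ --seed 42 --grid-size 16
vhicast run-all --simulate --scope global --layers 1 --outdir run/ --seed 42
```

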