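# yieldnet

Hybrid CNN–LSTM prediction of county-level crop yield from weekly weather,
depth-profiled soil, planting progress and the historical yield trend —
with guided-backpropagation feature importance, classical baselines,
location-holdout cross-validation, and a synthetic county-year data
generator with known ground truth.

## Who this is for

Agro-environmental modellers who want a self-contained, inspectable
implementation of the hybrid convolutional–recurrent approach to
county-yield forecasting: 1-D CNN encoders over the weekly weather axis
(W-CNN) and the soil depth axis (S-CNN) feed a k-year LSTM whose final
step predicts the target-year yield in bushels/acre. Everything — the
model, its training loop, and guided backpropagation — runs on a small
numpy reverse-mode autodiff engine bundled with the package, so there is
no deep-learning framework dependency and the gradient rules (including
the guided ReLU rule) are plain, testable code.

## The model

For a county and target year *t*, each step *t′* ∈ {t−k+1 … t} (k = 5)
assembles

- `W_CNN(weather_t′)` — 4 conv layers (ReLU, same padding, average pooling
  stride 2) over 6 × 52 weekly weather, then an FC layer (60 units corn /
  40 soybean);
- `S_CNN(soil)` — 4 conv layers over the 10 × 9 depth profile, FC to 40
  units; the 4 surface soil variables bypass directly;
- `M_t′` — 16 weeks of cumulative planting progress;
- `Ȳ_t′` — the cross-county mean yield of year t′ (the trend signal),

and feeds the concatenation to an LSTM cell (64 hidden units); a shared
linear head maps each hidden state to a yield prediction. At test time the
unknown `Ȳ_t` is substituted with `Ȳ_{t−1}`, and target-year weather
weeks beyond a forecast cutoff can be substituted with proxy weather
(previous year's, by default).

Feature importance follows guided backpropagation: seed the final-step
LSTM output gradient with 1 on positively (mean-)activated neurons,
backpropagate zeroing negative gradients at every ReLU, average absolute
input gradients over samples, and max-normalize within each input group.

See `docs/methods.md` for assumptions, parameter defaults, and what the
synthetic generator does and does not emulate.

## Worked example

Generate a synthetic Corn-Belt-like dataset (20 counties × 8 years,
drivers in all input groups), train a reduced model, and evaluate on the
final year:

```bash
yieldnet simulate --counties 20 --states 4 --start 2000 --end 2007 \
    --seed 1 --out data/
yieldnet train --data data/ --val-year 2007 --k 3 --small \
    --iterations 800 --checkpoint model.npz
```

which logs the learning-rate schedule and train/validation RMSE and ends
with (numbers from this exact invocation):

```
iter     500  lr 3.00e-04  train RMSE    9.708  val RMSE   18.892
iter     800  lr 3.00e-04  train RMSE    6.925  val RMSE   19.722
{
  "train_rmse": 6.92546058100529,
  "train_corr_pct": 94.02991673658197,
  "val_rmse": 19.722080076993922,
  "val_corr_pct": 49.878206075669304
}
```

Train RMSE ≈ 6.9 bu/acre with 94% correlation means the model has
captured most of the in-sample systematic signal; on the held-out year it
reaches RMSE ≈ 19.7 against the Average baseline's ≈ 23.8 with 0.0
correlation (run `yieldnet evaluate` to print both) — real but modest
skill, as expected from a 480-sample training set. Guided-backprop
importances per feature group:

```bash
yieldnet importance --data data/ --checkpoint model.npz --val-year 2007 \
    --out importance.csv --plots plots/
```

Full experiment pipelines (`yieldnet ablate`, `yieldnet cv`,
`yieldnet weather-update`, and YAML-configured `yieldnet run`) are thin
wrappers over `yieldnet.experiments` and `yieldnet.studies`.

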