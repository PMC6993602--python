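# Methods

## The model

`yieldnet` predicts county-level crop yield (bushels/acre) from weekly
weather, a depth-profiled soil description, state-level planting progress,
and the historical yield trend. The architecture is a hybrid of
convolutional encoders and a recurrent backbone:

- **W-CNN** — four 1-D convolutional layers (ReLU, same padding) over the
  52-week axis with the six weather variables as input channels
  (precipitation, solar radiation, snow water equivalent, max/min
  temperature, vapor pressure), average-pooled with stride 2, followed by a
  fully connected layer (60 units for corn, 40 for soybean).
- **S-CNN** — four 1-D convolutional layers over the nine-depth axis
  (0–5 … 100–120 cm) with the ten soil variables as channels, pooled only
  while the depth axis permits (9→4→2), followed by a 40-unit FC layer.
  The four surface-only soil variables (slope, NCCPI-corn, NCCPI-all, root
  zone depth) bypass the encoder and enter the recurrent cell directly.
- **LSTM** — k = 5 yearly steps with 64 hidden units. The step-t input
  concatenates the two encoder outputs, the surface bypass, the weekly
  cumulative planting-progress vector (16 weeks from the start of April),
  and Ȳ_t, the cross-county mean yield of year t. A linear head shared
  across steps maps each hidden state to a yield prediction; the last step
  is the target-year forecast.

Because Ȳ_t alone tracks the technology trend, the model degrades
gracefully when weather/soil/management branches are removed; the ablation
variants CNN-RNN(W/S/M) drop the other branches structurally.

At prediction time for a future year, Ȳ_t is unknown and is substituted
with Ȳ_{t−1}; unobserved target-year weather weeks can be substituted with
proxy values (by default the same county's previous-year weather), which is
the basis of the progressive weekly weather-update experiment.

## Training protocol

Weights are Xavier-initialized (variance 2/(fan_in+fan_out), zero biases)
and optimized with Adam, mini-batches of 25, learning rate 3e-4 halved
every 60,000 iterations, loss = MSE of the final-step prediction
(optionally averaged over all k steps). The reference budget is 350,000
iterations; the bundled synthetic studies use 5,000–6,000, which reaches a
stable validation RMSE at their problem sizes.

Two numerical choices deserve note:

- **Output scale.** The linear head predicts on the standardized-yield
  scale and a fixed affine transform (mean/sd of the training targets,
  recorded with the parameters, never trained) maps predictions back to
  bushels/acre. Without this, Adam — whose per-parameter step is bounded by
  the learning rate — would need hundreds of thousands of iterations just
  to move the output bias to the yield level; with it, desk-scale budgets
  converge. Reported RMSE is always in natural units.
- **Weight decay.** Off by default, matching the reference protocol. The
  importance-recovery study enables a small decoupled shrinkage (3e-4 per
  iteration) because saliency quality degrades sharply once the network
  starts memorizing the training counties; the decay closes the train/val
  gap at those study sizes.

All randomness is seeded: initialization and batch shuffling derive from
the training seed, the generator from the dataset seed, and identical seeds
reproduce loss histories bit-for-bit (single-threaded numpy arithmetic).

## Feature importance

Guided backpropagation: forward the evaluation samples, compute each
final-step LSTM output neuron's mean activation, seed the output gradient
with 1 for positively activated neurons and 0 otherwise, and backpropagate
with the guided ReLU rule (zero the gradient where the forward input was
non-positive and where the incoming gradient is negative). A feature's raw
importance is the mean absolute input-space gradient across samples,
aggregated at the final step's inputs by default (per-step aggregation is
available). Scores are max-normalized within four groups — weather, soil at
depth, surface soil, management — so each group spans (0, 1].

Subset retraining keeps the top fraction of features (by normalized score,
ties broken by fixed feature order), zeroes the rest at the standardized
input (zero = the feature's training mean, and shapes stay fixed across
masks), and retrains from scratch. Following the selection protocol,
importance is computed on the penultimate year and the masked models are
evaluated on the final year.

Two practical notes from the synthetic studies:

- A single trained replicate's saliency is noisy at desk scale: each
  replicate learns some injected drivers strongly and others weakly.
  The recovery study therefore averages raw importances over five seeded
  replicates before ranking; the ensemble recovers the union.
- Gradient attribution through a pooled CNN has limited positional
  resolution: with the weather axis pooled 52→3, every week in a pooled
  region inherits a similar gradient. The importance studies use a weather
  encoder pooled to 13 positions; the full-pooling default remains for
  prediction-only runs.

## Synthetic data generator

The generator emulates the structure the model assumes, with a documented
response so recovery tests have an unambiguous answer:

- **Weather**: channel-specific seasonal templates (snow only in winter,
  max ≥ min temperature) plus county- and year-level offsets and weekly
  noise. Offset scales are kept near a quarter of the weekly noise so that
  week-specific variation dominates: if a channel's county/year level is
  large, any week of the channel proxies it and week-level attribution
  becomes unidentifiable by construction.
- **Soil**: static per county; depth profiles combine a monotone trend with
  a random walk along depth (adjacent depths correlate more than distant
  ones). Four surface variables.
- **Management**: a logistic cumulative planting curve per state-year
  (16 weeks from April), non-decreasing in [0, 100].
- **Yield**: baseline (100 bu/acre) + trend (2 bu/acre/year, the
  long-run genetic/agronomic improvement) + documented driver effects +
  a quadratic planting-date penalty around the optimal 50%-planted week +
  county random effect (sd 6) + Gaussian noise (sd 8), truncated at 1.0.
  Driver effects are linear or saturating functions of a single designated
  feature, `size·z` or `size·(1−exp(−max(z,0)))` with `z=(x−loc)/scale`.
  The default set spans all input groups, and effect sizes are calibrated
  so each driver's marginal effect is ~4–6 bu/acre — detectable in
  principle (verified against an ordinary-least-squares oracle on the
  flattened features); weaker drivers would make recovery tests vacuous.
  A broader "growing-season" driver set (34 features across consecutive
  weeks, depths and planting weeks) backs the subset-retraining study,
  where the informative set should not be a handful of isolated columns.
- **Missingness**: injected completely at random into soil (6.7%, per
  county cell) and management (6.3%, per state-year week), matching the
  imputation rules' assumptions.

What the generator does *not* emulate: spatial autocorrelation between
counties beyond state/county random effects, realistic meteorology
(storm systems, droughts spanning weeks), genotype information, and
measurement error in reported yields. Passing recovery tests therefore
shows the pipeline is correct and the method behaves as designed under its
own assumptions — not that real-data accuracy matches any published level.

## Preprocessing conventions

Weeks are consecutive 7-day blocks from January 1; days 365/366 fold into
week 52. Missing soil values are imputed with the cross-county mean of the
same feature (training-period reference when a split is declared); missing
management values with the same-year cross-county mean, then re-clipped to
a non-decreasing curve in [0, 100] — contemporaneous planting progress of
other counties is observable at prediction time, so using the validation
year's own cross-county mean is not target leakage. Inputs are z-scored
with training-set statistics (sd = 0 features map to 0); the target stays
in bushels/acre. Ȳ is z-scored with the training-yield statistics. The
sequence builder emits one sample per (county, target year) whose k
consecutive years are all present with the target yield observed.

## Evaluation

RMSE in bushels/acre and Pearson correlation in percent, reported as 0.0
when either vector is constant — which is how the no-information *Average*
baseline (predicting the previous year's cross-county mean everywhere)
shows up. Location-holdout cross-validation partitions the counties with
target-year truth into seeded disjoint folds and removes each held-out
fold from *all* training years. Baselines: random forest (50 trees, depth
10), LASSO (α between 0.3 and 0.5, default 0.4), and a 9×50 DFNN with
batch normalization and residual shortcuts; all consume flattened
target-year features plus the previous-year average yield and a year index
so they can express the trend.

## Bundled study sizes

The reference study uses 200 counties × 15 years with a reduced
architecture (`ModelConfig.medium`: 16-filter encoders, the weather axis
pooled to 13 positions, 24/16-unit FC layers, 24 LSTM units), weight decay
3e-4 and 5,000 iterations; the focused studies use 50–300 counties over
10–11 years with the 8-filter `small` configuration. These sizes were
chosen so each study's qualitative conclusion is stable across seeds while
a full run of every study completes on a single CPU in well under an
hour.

## Known limitations

- The conv-layer filter counts of the original design are not public; the
  defaults here (16/32/64/128, kernel 3) are configurable stand-ins.
- Guided backpropagation is the only saliency method; its positional
  resolution is bounded by the encoder's pooling, and attribution smears
  across features correlated with a true driver (adjacent depths,
  collinear planting weeks).
- The exact-column recovery of management drivers is ill-posed: all 16
  weekly values of a planting curve are deterministic functions of the
  same two latent parameters.
- Training is plain single-threaded numpy; fine at desk scale, not for
  the full 350,000-iteration protocol on real Corn Belt data.
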