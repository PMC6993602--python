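"""Evaluation metrics, baseline models, ablations, location-holdout
cross-validation and the progressive weather-update experiment.

Performance is reported as RMSE (bushels/acre) and Pearson correlation in
percent, for both the training and the validation split, plus per-county
absolute errors.  Baselines: the *Average* model (predicts the previous
year's cross-county mean yield for every county — the no-information
floor, whose correlation is 0.0 by constancy), random forest, LASSO, and a
deep fully connected network with batch normalization and residual
shortcuts; the latter three consume flattened per-county-year features plus
a year index so they can express the technology trend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso

from . import autodiff as ad
from .model import Batch, ModelConfig, samples_to_batch
from .preprocess import (
    CountyYearRecord,
    SequenceSample,
    Standardizer,
    build_sequences,
    impute_management,
    impute_soil,
    standardize,
    yearly_average_yield,
)
from .training import Adam, TrainConfig, predict, train


@dataclass
class EvalReport:
    """Train/validation RMSE and correlation (%), with per-county absolute
    errors on the validation split."""

    train_rmse: float
    train_corr_pct: float
    val_rmse: float
    val_corr_pct: float
    per_county_abs_error: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "train_rmse": self.train_rmse,
            "train_corr_pct": self.train_corr_pct,
            "val_rmse": self.val_rmse,
            "val_corr_pct": self.val_corr_pct,
        }


def evaluate(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """Root-mean-square error and Pearson correlation in percent.

    Correlation is reported as 0.0 when either vector has zero variance
    (e.g. a constant predictor).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size < 1:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
    # ptp is exact for constant arrays where a computed sd may be ~1e-14
    if np.ptp(pred) == 0.0 or np.ptp(truth) == 0.0:
        return rmse, 0.0
    corr = float(np.corrcoef(pred, truth)[0, 1])
    return rmse, 100.0 * corr


def report_from_predictions(
    train_pred, train_batch: Batch, val_pred, val_batch: Batch,
    val_counties: list[str] | None = None,
) -> EvalReport:
    train_rmse, train_corr = evaluate(train_pred, train_batch.target)
    val_rmse, val_corr = evaluate(val_pred, val_batch.target)
    per_county = {}
    if val_counties is not None:
        for county, p, t in zip(val_counties, val_pred, val_batch.target):
            per_county[county] = float(abs(p - t))
    return EvalReport(train_rmse, train_corr, val_rmse, val_corr, per_county)


# ---------------------------------------------------------------------------
# data pipeline helper
# ---------------------------------------------------------------------------


@dataclass
class Split:
    """Preprocessed train/validation sequence samples and the statistics
    used to standardize them."""

    train_samples: list[SequenceSample]
    val_samples: list[SequenceSample]
    stats: Standardizer
    records: list[CountyYearRecord]  # imputed, standardized


def make_split(
    records: list[CountyYearRecord],
    k: int,
    val_year: int,
    exclude_counties: set[str] = frozenset(),
) -> Split:
    """Impute, standardize and assemble sequences for one train/val split.

    Training targets are all years before ``val_year``; validation targets
    are ``val_year``.  Imputation and standardization statistics come from
    pre-``val_year`` records only, so nothing leaks from the validation
    year.  ``exclude_counties`` are removed from every training year (used
    by the location-holdout CV) and become the validation counties.
    """
    train_ref = [r for r in records if r.year < val_year]
    imputed = impute_soil(records, reference=train_ref)
    # management means are per-year by definition, so the validation year's
    # gaps are filled from that same year's other counties (contemporaneous
    # planting progress, not target-year yield information)
    imputed = impute_management(imputed)
    avg_yield = yearly_average_yield(imputed)
    stats_recs = [
        r
        for r in imputed
        if r.year < val_year and r.county_id not in exclude_counties
    ]
    _, stats = standardize(stats_recs)
    std_records, _ = standardize(imputed, stats)

    train_pool = [r for r in std_records if r.county_id not in exclude_counties]
    train_years = {r.year for r in train_pool if r.year < val_year}
    train_samples = build_sequences(
        train_pool, k, target_years=train_years, avg_yield_by_year=avg_yield, stats=stats
    )
    val_pool = (
        [r for r in std_records if r.county_id in exclude_counties]
        if exclude_counties
        else std_records
    )
    val_samples = build_sequences(
        val_pool, k, target_years={val_year}, avg_yield_by_year=avg_yield, stats=stats
    )
    return Split(train_samples, val_samples, stats, std_records)


def run_cnn_rnn(
    split: Split,
    config: ModelConfig,
    tconfig: TrainConfig,
) -> tuple[EvalReport, dict[str, ad.Tensor], object]:
    """Train the hybrid model on a split and evaluate it (test-mode
    substitution on the validation year)."""
    train_batch = samples_to_batch(split.train_samples)
    val_batch = samples_to_batch(split.val_samples)
    params, history = train(config, train_batch, val_batch, tconfig)
    train_pred = predict(params, train_batch, config, mode="train")
    val_pred = predict(params, val_batch, config, mode="test")
    report = report_from_predictions(
        train_pred,
        train_batch,
        val_pred,
        val_batch,
        [s.county_id for s in split.val_samples],
    )
    return report, params, history


# ---------------------------------------------------------------------------
# Average baseline and ablations
# ---------------------------------------------------------------------------


def average_baseline(
    records: list[CountyYearRecord], target_year: int
) -> float:
    """The constant prediction of the Average model: the cross-county mean
    observed yield of ``target_year - 1``."""
    prior = [
        r.yield_value
        for r in records
        if r.year == target_year - 1 and not math.isnan(r.yield_value)
    ]
    if not prior:
        raise ValueError(f"no observed yields in year {target_year - 1}")
    return float(np.mean(prior))


def evaluate_average_baseline(
    records: list[CountyYearRecord],
    val_samples: list[SequenceSample],
    train_samples: list[SequenceSample] | None = None,
) -> EvalReport:
    """Score the constant prior-year-mean prediction; its correlation is
    0.0 by constancy.  The same constant scores the training samples when
    they are provided."""
    target_year = val_samples[0].target_year
    const = average_baseline(records, target_year)
    truth = np.array([s.target for s in val_samples])
    rmse, corr = evaluate(np.full_like(truth, const), truth)
    train_rmse = train_corr = 0.0
    if train_samples:
        t_truth = np.array([s.target for s in train_samples])
        train_rmse, train_corr = evaluate(np.full_like(t_truth, const), t_truth)
    return EvalReport(
        train_rmse=train_rmse,
        train_corr_pct=train_corr,
        val_rmse=rmse,
        val_corr_pct=corr,
        per_county_abs_error={
            s.county_id: float(abs(const - s.target)) for s in val_samples
        },
    )


def ablation_variant(config: ModelConfig, which: str) -> ModelConfig:
    """Model specification using only one input branch ('W', 'S' or 'M')
    beside the average-yield backbone; the other branches are removed
    structurally, not zero-masked."""
    return config.variant(which)


# ---------------------------------------------------------------------------
# flattened-feature baselines
# ---------------------------------------------------------------------------


def flatten_features(samples: list[SequenceSample]) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample flat feature vector from the target-year step: weather
    (312) + soil depth (90) + surface (4) + management (W_m) + previous
    average yield + a year index."""
    year0 = min(s.target_year for s in samples)
    X = np.stack(
        [
            np.concatenate(
                [
                    s.weather[-1].ravel(),
                    s.soil[-1].ravel(),
                    s.surface[-1],
                    s.management[-1],
                    [s.avg_yield[-2] if s.k >= 2 else s.avg_yield[-1]],
                    [s.target_year - year0],
                ]
            )
            for s in samples
        ]
    )
    y = np.array([s.target for s in samples])
    return X, y


def _baseline_report(model_predict, Xtr, ytr, Xval, yval, counties) -> EvalReport:
    ptr = model_predict(Xtr)
    pval = model_predict(Xval)
    tr_rmse, tr_corr = evaluate(ptr, ytr)
    v_rmse, v_corr = evaluate(pval, yval)
    per_county = {c: float(abs(p - t)) for c, p, t in zip(counties, pval, yval)}
    return EvalReport(tr_rmse, tr_corr, v_rmse, v_corr, per_county)


def baseline_rf(
    train_samples, val_samples, n_trees: int = 50, max_depth: int = 10, seed: int = 0
) -> EvalReport:
    """Random forest: 50 trees, max depth 10."""
    Xtr, ytr = flatten_features(list(train_samples))
    Xval, yval = flatten_features(list(val_samples))
    if Xtr.size == 0:
        raise ValueError("empty feature table")
    rf = RandomForestRegressor(
        n_estimators=n_trees, max_depth=max_depth, random_state=seed
    )
    rf.fit(Xtr, ytr)
    return _baseline_report(
        rf.predict, Xtr, ytr, Xval, yval, [s.county_id for s in val_samples]
    )


def baseline_lasso(train_samples, val_samples, alpha: float = 0.4) -> EvalReport:
    """LASSO with L1 coefficient in the 0.3-0.5 range (default 0.4)."""
    Xtr, ytr = flatten_features(list(train_samples))
    Xval, yval = flatten_features(list(val_samples))
    if Xtr.size == 0:
        raise ValueError("empty feature table")
    model = Lasso(alpha=alpha, max_iter=20000)
    model.fit(Xtr, ytr)
    return _baseline_report(
        model.predict, Xtr, ytr, Xval, yval, [s.county_id for s in val_samples]
    )


class _BatchNormLayer:
    """1-D batch normalization with running statistics for evaluation."""

    def __init__(self, width: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = ad.parameter(np.ones(width))
        self.beta = ad.parameter(np.zeros(width))
        self.running_mean = np.zeros(width)
        self.running_var = np.ones(width)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: ad.Tensor, training: bool) -> ad.Tensor:
        if training:
            mu = ad.mean(x, axis=0, keepdims=True)
            xc = x - mu
            var = ad.mean(ad.square(xc), axis=0, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean
                + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var
                + (1 - self.momentum) * var.data.ravel()
            )
            xhat = xc / ad.sqrt(var + ad.tensor(self.eps))
        else:
            xhat = (x - ad.tensor(self.running_mean)) / ad.tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    @property
    def params(self) -> list[ad.Tensor]:
        return [self.gamma, self.beta]


class DFNN:
    """Deep fully connected regression network: 9 hidden layers of 50 ReLU
    neurons each with batch normalization, residual shortcuts between
    equal-width layers, and a linear output."""

    def __init__(self, n_features: int, n_layers: int = 9, width: int = 50, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_layers = n_layers
        self.weights: list[ad.Tensor] = []
        self.biases: list[ad.Tensor] = []
        self.bns: list[_BatchNormLayer] = []
        fan_in = n_features
        for _ in range(n_layers):
            sd = math.sqrt(2.0 / (fan_in + width))
            self.weights.append(ad.parameter(rng.normal(0, sd, size=(fan_in, width))))
            self.biases.append(ad.parameter(np.zeros(width)))
            self.bns.append(_BatchNormLayer(width))
            fan_in = width
        sd = math.sqrt(2.0 / (width + 1))
        self.w_out = ad.parameter(rng.normal(0, sd, size=(width, 1)))
        self.b_out = ad.parameter(np.zeros(1))

    @property
    def params(self) -> dict[str, ad.Tensor]:
        out = {}
        for i, (w, b, bn) in enumerate(zip(self.weights, self.biases, self.bns)):
            out[f"dense{i}.w"] = w
            out[f"dense{i}.b"] = b
            out[f"bn{i}.gamma"] = bn.gamma
            out[f"bn{i}.beta"] = bn.beta
        out["out.w"] = self.w_out
        out["out.b"] = self.b_out
        return out

    def count_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params.values()))

    def forward(self, x: np.ndarray | ad.Tensor, training: bool = False) -> ad.Tensor:
        h = x if isinstance(x, ad.Tensor) else ad.tensor(x)
        for i in range(self.n_layers):
            z = ad.matmul(h, self.weights[i]) + self.biases[i]
            z = ad.relu(self.bns[i](z, training))
            # residual shortcut once widths agree (after the first layer)
            h = z + h if h.shape[-1] == z.shape[-1] else z
        return ad.matmul(h, self.w_out) + self.b_out

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        iterations: int = 2000,
        batch_size: int = 25,
        lr: float = 3e-4,
        seed: int = 0,
    ) -> "DFNN":
        opt = Adam(self.params)
        rng = np.random.default_rng(seed)
        n = X.shape[0]
        order = rng.permutation(n)
        pos = 0
        for _ in range(iterations):
            if pos + batch_size > n:
                order = rng.permutation(n)
                pos = 0
            idx = order[pos : pos + batch_size]
            pos += batch_size
            opt.zero_grad()
            pred = self.forward(X[idx], training=True)
            loss = ad.mean(ad.square(pred - ad.tensor(y[idx, None])))
            loss.backward()
            opt.step(lr)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).data[:, 0]


def baseline_dfnn(
    train_samples, val_samples, iterations: int = 2000, seed: int = 0
) -> EvalReport:
    Xtr, ytr = flatten_features(list(train_samples))
    Xval, yval = flatten_features(list(val_samples))
    if Xtr.size == 0:
        raise ValueError("empty feature table")
    # standardize the year/avg-yield columns the flattener adds raw
    mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    net = DFNN(Xtr.shape[1], seed=seed)
    net.fit((Xtr - mu) / sd, ytr, iterations=iterations, seed=seed)
    return _baseline_report(
        lambda X: net.predict((X - mu) / sd),
        Xtr,
        ytr,
        Xval,
        yval,
        [s.county_id for s in val_samples],
    )


# ---------------------------------------------------------------------------
# location-holdout cross-validation
# ---------------------------------------------------------------------------


def location_folds(
    records: list[CountyYearRecord], target_year: int, folds: int, seed: int
) -> list[list[str]]:
    """Seeded disjoint partition of the counties that have an observed
    target-year yield."""
    eligible = sorted(
        {
            r.county_id
            for r in records
            if r.year == target_year and not math.isnan(r.yield_value)
        }
    )
    if len(eligible) < folds:
        raise ValueError(f"only {len(eligible)} eligible counties for {folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    return [
        [eligible[j] for j in sorted(order[i::folds])] for i in range(folds)
    ]


def location_kfold(
    records: list[CountyYearRecord],
    config: ModelConfig,
    tconfig: TrainConfig,
    target_year: int,
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[EvalReport], EvalReport]:
    """Hold out each fold's counties from *all* training years, train on the
    remaining counties' history, and evaluate on the held-out counties'
    target-year yields.  Returns per-fold reports and a pooled report."""
    fold_counties = location_folds(records, target_year, folds, seed)
    reports: list[EvalReport] = []
    pooled_pred: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    pooled_errors: dict[str, float] = {}
    for held_out in fold_counties:
        split = make_split(records, config.k, target_year, exclude_counties=set(held_out))
        for s in split.train_samples:
            assert s.county_id not in set(held_out), "held-out county leaked into training"
        report, params, _ = run_cnn_rnn(split, config, tconfig)
        reports.append(report)
        val_batch = samples_to_batch(split.val_samples)
        pred = predict(params, val_batch, config, mode="test")
        pooled_pred.append(pred)
        pooled_truth.append(val_batch.target)
        pooled_errors.update(report.per_county_abs_error)
    pred = np.concatenate(pooled_pred)
    truth = np.concatenate(pooled_truth)
    rmse, corr = evaluate(pred, truth)
    pooled = EvalReport(
        train_rmse=float(np.mean([r.train_rmse for r in reports])),
        train_corr_pct=float(np.mean([r.train_corr_pct for r in reports])),
        val_rmse=rmse,
        val_corr_pct=corr,
        per_county_abs_error=pooled_errors,
    )
    return reports, pooled


# ---------------------------------------------------------------------------
# progressive weather-update experiment
# ---------------------------------------------------------------------------


def default_cutoff_schedule() -> list[int]:
    """Weekly cutoffs from the start of June (week 22) through the end of
    September (week 39), then the full-information cutoff."""
    return list(range(22, 40)) + [52]


def weather_update_experiment(
    params: dict[str, ad.Tensor],
    samples,
    config: ModelConfig,
    cutoff_schedule: list[int] | None = None,
    proxy_weather: np.ndarray | None = None,
) -> list[dict]:
    """Predict the target year repeatedly as forecast weather is replaced by
    observed weather week by week.

    At cutoff week c, target-year weather weeks <= c keep their true values
    and weeks after c come from ``proxy_weather`` (default: the previous
    year's weather of the same county).  Returns one row per cutoff with the
    validation RMSE and the mean predicted yield; the last cutoff (week 52)
    is bit-identical to a plain test-mode prediction.
    """
    batch = samples if isinstance(samples, Batch) else samples_to_batch(samples)
    if cutoff_schedule is None:
        cutoff_schedule = default_cutoff_schedule()
    if proxy_weather is None:
        if batch.weather.shape[1] < 2:
            raise ValueError("need k >= 2 to default the proxy to last year's weather")
        proxy_weather = batch.weather[:, -2].copy()
    rows = []
    for cutoff in cutoff_schedule:
        pred = predict(
            params,
            batch,
            config,
            mode="test",
            predicted_weather=proxy_weather,
            cutoff_week=cutoff,
        )
        rmse, _ = evaluate(pred, batch.target)
        rows.append(
            {
                "cutoff_week": int(cutoff),
                "rmse": rmse,
                "mean_predicted_yield": float(pred.mean()),
            }
        )
    return rows
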