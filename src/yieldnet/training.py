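"""Training loop and prediction-time substitution rules.

Weights are Xavier/Glorot-initialized (variance 2/(fan_in+fan_out), biases
zero) and optimized with Adam on mini-batches of 25, minimizing mean squared
error of the final-step prediction (optionally averaged over all k steps).
The learning rate starts at 3e-4 and is halved every ``lr_decay_every``
iterations.  At prediction time for an unseen target year, the target-year
average yield — unknown before harvest — is substituted with the previous
year's average, and unobserved target-year weather weeks can be substituted
with proxy values (e.g. the previous year's weather).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .model import Batch, ModelConfig, check_params, model_forward, parameter_shapes, samples_to_batch
from .preprocess import SequenceSample


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    The reference protocol is 350,000 iterations; the default here is a
    desk-scale 5,000, which suffices on the package's synthetic studies.
    """

    iterations: int = 5000
    batch_size: int = 25
    learning_rate: float = 3e-4
    lr_decay_every: int = 60000
    lr_decay_factor: float = 0.5
    seed: int = 0
    log_every: int = 500
    all_steps_loss: bool = False
    patience: int | None = None
    max_eval_samples: int = 2000
    scale_targets: bool = True
    #: per-iteration multiplicative shrinkage of weight matrices (decoupled
    #: weight decay); 0 reproduces the reference protocol, small values
    #: (~3e-4) suppress memorization on small synthetic studies
    weight_decay: float = 0.0


@dataclass
class History:
    iterations: list[int] = field(default_factory=list)
    learning_rates: list[float] = field(default_factory=list)
    train_rmse: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)


def learning_rate_at(iteration: int, tconfig: TrainConfig) -> float:
    """Step-decayed learning rate for a 1-based iteration index; each
    halving takes effect after a full decay block completes."""
    steps = (iteration - 1) // tconfig.lr_decay_every
    return tconfig.learning_rate * tconfig.lr_decay_factor**steps


def init_params(config: ModelConfig, seed: int) -> dict[str, ad.Tensor]:
    """Xavier-initialized weights (variance 2/(fan_in+fan_out)); zero biases.

    For conv kernels fan counts include the kernel width; for the LSTM input
    matrix the fan-out of one gate block is the hidden size.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, ad.Tensor] = {}
    for name, shape in parameter_shapes(config).items():
        if name == "target.scale":
            params[name] = ad.tensor(np.array([1.0, 0.0]))
            continue
        if name.endswith(".b"):
            params[name] = ad.parameter(np.zeros(shape))
            continue
        if len(shape) == 3:  # conv: (out, in, k)
            fan_in = shape[1] * shape[2]
            fan_out = shape[0] * shape[2]
        elif name.startswith("lstm."):
            fan_in = shape[0]
            fan_out = shape[1] // 4
        else:  # dense: (in, out)
            fan_in, fan_out = shape
        sd = math.sqrt(2.0 / (fan_in + fan_out))
        params[name] = ad.parameter(rng.normal(0.0, sd, size=shape))
    return params


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: dict[str, ad.Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / (1 - self.beta1**self.t)
            vhat = self.v[k] / (1 - self.beta2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _as_batch(samples) -> Batch:
    return samples if isinstance(samples, Batch) else samples_to_batch(samples)


def substitute_test_inputs(
    batch: Batch,
    predicted_weather: np.ndarray | None = None,
    cutoff_week: int | None = None,
) -> Batch:
    """Apply the test-time substitutions to the final (target-year) step.

    The target-year average yield is unknown at prediction time, so it is
    replaced by the previous step's average yield (requires k >= 2).  If a
    proxy-weather array (B, 6, 52) and a cutoff week are given, target-year
    weather weeks strictly after the cutoff are replaced by the proxy.
    """
    out = batch.copy()
    if out.avg_yield.shape[1] < 2:
        raise TrainingError(
            "test-time substitution needs the previous year's average yield; "
            "k must be >= 2"
        )
    out.avg_yield[:, -1] = out.avg_yield[:, -2]
    if predicted_weather is not None:
        if cutoff_week is None:
            raise TrainingError("predicted weather requires a cutoff week")
        if not 0 <= cutoff_week <= out.weather.shape[-1]:
            raise TrainingError(f"cutoff week {cutoff_week} out of range")
        if cutoff_week < out.weather.shape[-1]:
            out.weather[:, -1, :, cutoff_week:] = predicted_weather[
                :, :, cutoff_week:
            ]
    return out


def predict(
    params: dict[str, ad.Tensor],
    samples,
    config: ModelConfig,
    mode: str = "test",
    predicted_weather: np.ndarray | None = None,
    cutoff_week: int | None = None,
) -> np.ndarray:
    """Final-step yield prediction per sample.

    ``mode='train'`` uses the inputs as given (all data observed);
    ``mode='test'`` applies the substitution rules above first.
    """
    if mode not in ("train", "test"):
        raise ValueError("mode must be 'train' or 'test'")
    batch = _as_batch(samples)
    if mode == "test":
        batch = substitute_test_inputs(batch, predicted_weather, cutoff_week)
    elif predicted_weather is not None:
        raise ValueError("predicted weather only applies in test mode")
    preds = model_forward(batch, params, config)
    return preds.data[:, -1].copy()


def _rmse_on(params, batch: Batch, config, mode: str, limit: int) -> float:
    if batch.size > limit:
        batch = Batch(
            weather=batch.weather[:limit],
            soil=batch.soil[:limit],
            surface=batch.surface[:limit],
            management=batch.management[:limit],
            avg_yield=batch.avg_yield[:limit],
            target=batch.target[:limit],
        )
    p = predict(params, batch, config, mode=mode)
    return float(np.sqrt(np.mean((p - batch.target) ** 2)))


def train(
    config: ModelConfig,
    train_samples,
    val_samples=None,
    tconfig: TrainConfig | None = None,
    params: dict[str, ad.Tensor] | None = None,
) -> tuple[dict[str, ad.Tensor], History]:
    """Mini-batch Adam training; returns parameters and the logged history.

    Samples are shuffled each epoch; one iteration is one mini-batch update.
    Validation RMSE (test-mode prediction with the substitution rules) is
    logged every ``log_every`` iterations and drives optional early stopping.
    """
    tconfig = tconfig or TrainConfig()
    train_batch = _as_batch(train_samples)
    if train_batch.size == 0:
        raise TrainingError("empty training set")
    val_batch = _as_batch(val_samples) if val_samples else None

    if params is None:
        params = init_params(config, tconfig.seed)
    else:
        check_params(config, params)
    if tconfig.scale_targets:
        sd = float(train_batch.target.std())
        params["target.scale"].data = np.array(
            [sd if sd > 0 else 1.0, float(train_batch.target.mean())]
        )
    opt = Adam(params)
    rng = np.random.default_rng(tconfig.seed + 1)
    history = History()

    n = train_batch.size
    order = rng.permutation(n)
    pos = 0
    best_val = math.inf
    stale = 0
    for it in range(1, tconfig.iterations + 1):
        if pos + tconfig.batch_size > n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos : pos + tconfig.batch_size]
        pos += tconfig.batch_size

        mb = Batch(
            weather=train_batch.weather[idx],
            soil=train_batch.soil[idx],
            surface=train_batch.surface[idx],
            management=train_batch.management[idx],
            avg_yield=train_batch.avg_yield[idx],
            target=train_batch.target[idx],
        )
        opt.zero_grad()
        preds = model_forward(mb, params, config)
        target = ad.tensor(mb.target[:, None])
        if tconfig.all_steps_loss:
            err = preds - ad.tensor(np.repeat(mb.target[:, None], config.k, axis=1))
            loss = ad.mean(ad.square(err))
        else:
            err = preds[:, -1:] - target
            loss = ad.mean(ad.square(err))
        if not np.isfinite(loss.data):
            raise TrainingError(
                f"non-finite loss at iteration {it}; try a lower learning rate"
            )
        loss.backward()
        opt.step(learning_rate_at(it, tconfig))
        if tconfig.weight_decay:
            shrink = 1.0 - tconfig.weight_decay
            for name, p in params.items():
                if not name.endswith(".b") and not name.startswith("target."):
                    p.data *= shrink

        if it % tconfig.log_every == 0 or it == tconfig.iterations:
            tr = _rmse_on(params, train_batch, config, "train", tconfig.max_eval_samples)
            history.iterations.append(it)
            history.learning_rates.append(learning_rate_at(it, tconfig))
            history.train_rmse.append(tr)
            if val_batch is not None:
                vr = _rmse_on(params, val_batch, config, "test", tconfig.max_eval_samples)
                history.val_rmse.append(vr)
                if tconfig.patience is not None:
                    if vr < best_val - 1e-9:
                        best_val = vr
                        stale = 0
                    else:
                        stale += 1
                        if stale >= tconfig.patience:
                            break
    return params, history
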