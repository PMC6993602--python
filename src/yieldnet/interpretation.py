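"""Guided-backpropagation feature importance and subset retraining.

Importance of an input feature is the mean absolute input-space gradient
obtained by: (1) forwarding a sample set (typically the validation set)
through the trained model; (2) computing the mean activation of each neuron
of the final-step LSTM output; (3) seeding the output gradient with 1 for
neurons whose mean activation is positive and 0 otherwise; (4)
backpropagating under the guided rule — at every ReLU, gradients are zeroed
both where the forward input was non-positive and where the incoming
gradient is negative.  Scores are then max-normalized within four groups
(weather, soil at depth, surface soil, management) so the groups are
comparable, and the top fraction of features can be kept for a masked
retraining run that measures how much predictive skill the discarded
features carried.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import autodiff as ad
from .model import (
    Batch,
    FeatureSpace,
    ModelConfig,
    apply_feature_mask,
    model_forward,
    samples_to_batch,
)
from .training import TrainConfig, predict, train

GROUPS = ("weather", "soil_depth", "soil_surface", "management")


@dataclass
class ImportanceReport:
    """Tidy per-feature importance table.

    ``raw`` is the mean absolute guided gradient; ``normalized`` divides raw
    by the maximum within the feature's group, so each group spans (0, 1]
    (all-zero groups stay 0).
    """

    table: pd.DataFrame  # columns: group, variable, index, raw, normalized

    def flat_scores(self, column: str = "normalized") -> np.ndarray:
        return self.table[column].to_numpy()

    def group_scores(self, group: str, column: str = "normalized") -> np.ndarray:
        return self.table.loc[self.table["group"] == group, column].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def guided_backprop(
    params: dict[str, ad.Tensor],
    samples,
    config: ModelConfig,
    per_step: bool = False,
) -> ImportanceReport:
    """Mean absolute guided gradient of each input feature.

    Gradients flow through the whole unrolled network; by default they are
    aggregated over the final (target-year) step's inputs.  With
    ``per_step`` the per-step weather/management gradients are averaged over
    all k steps instead.
    """
    batch = samples if isinstance(samples, Batch) else samples_to_batch(samples)
    for name, p in params.items():
        if not np.all(np.isfinite(p.data)):
            raise ValueError(f"parameter {name} contains non-finite values")

    inputs: dict[str, ad.Tensor] = {
        "weather": ad.tensor(batch.weather, requires_grad=True),
        "soil": ad.tensor(batch.soil, requires_grad=True),
        "surface": ad.tensor(batch.surface, requires_grad=True),
        "management": ad.tensor(batch.management, requires_grad=True),
        "avg_yield": ad.tensor(batch.avg_yield, requires_grad=True),
    }
    if not config.use_weather:
        inputs.pop("weather")
    if not config.use_soil:
        inputs.pop("soil")
        inputs.pop("surface")
    if not config.use_management:
        inputs.pop("management")

    _, hiddens = model_forward(
        batch, params, config, inputs=inputs, return_hidden=True
    )
    h_final = hiddens[-1]
    mean_act = h_final.data.mean(axis=0)
    seed_row = (mean_act > 0).astype(np.float64)
    seed = np.broadcast_to(seed_row, h_final.shape).copy()
    with ad.guided_gradients():
        h_final.backward(seed)

    space = FeatureSpace(n_mgmt_weeks=config.n_mgmt_weeks)

    def agg(name: str, shape: tuple[int, ...]) -> np.ndarray:
        t = inputs.get(name)
        if t is None or t.grad is None:
            return np.zeros(shape)
        g = np.abs(t.grad)  # (B, k, ...)
        g = g.mean(axis=(0, 1)) if per_step else g[:, -1].mean(axis=0)
        return g

    from .preprocess import N_DEPTHS, N_SOIL_VARS, N_SURFACE, N_WEATHER_VARS, N_WEEKS

    raw = np.concatenate(
        [
            agg("weather", (N_WEATHER_VARS, N_WEEKS)).ravel(),
            agg("soil", (N_SOIL_VARS, N_DEPTHS)).ravel(),
            agg("surface", (N_SURFACE,)).ravel(),
            agg("management", (config.n_mgmt_weeks,)).ravel(),
        ]
    )
    labels = space.labels()
    table = pd.DataFrame(
        {
            "group": [l[0] for l in labels],
            "variable": [l[1] for l in labels],
            "index": [l[2] for l in labels],
            "raw": raw,
        }
    )
    table["normalized"] = 0.0
    return normalize_by_group(ImportanceReport(table))


def normalize_by_group(report: ImportanceReport) -> ImportanceReport:
    """Divide each feature's raw score by its group's maximum raw score."""
    table = report.table.copy()
    norm = np.zeros(len(table))
    for group in GROUPS:
        sel = (table["group"] == group).to_numpy()
        if not sel.any():
            continue
        mx = table.loc[sel, "raw"].max()
        if mx > 0:
            norm[sel] = table.loc[sel, "raw"].to_numpy() / mx
    table["normalized"] = norm
    return ImportanceReport(table)


def select_top_features(report: ImportanceReport, fraction: float) -> np.ndarray:
    """Boolean mask keeping the ceil(fraction * F) highest-importance
    features across all groups (by normalized score so groups are
    comparable); ties broken by fixed feature order."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    scores = report.flat_scores("normalized")
    n = len(scores)
    keep = int(np.ceil(fraction * n))
    # stable sort on (-score, position) => ties keep the earlier feature
    order = np.lexsort((np.arange(n), -scores))
    mask = np.zeros(n, dtype=bool)
    mask[order[:keep]] = True
    return mask


def masked_retrain(
    config: ModelConfig,
    train_samples,
    val_samples,
    mask: np.ndarray,
    tconfig: TrainConfig | None = None,
) -> dict:
    """Retrain with masked-out features zeroed everywhere (train and
    predict) and evaluate on the validation samples.

    Returns train/validation RMSE and correlation under the mask, following
    the select-on-one-year, evaluate-on-the-next protocol of the caller.
    """
    from .experiments import evaluate

    space = FeatureSpace(n_mgmt_weeks=config.n_mgmt_weeks)
    train_batch = apply_feature_mask(samples_to_batch(list(train_samples)), mask, space)
    val_batch = apply_feature_mask(samples_to_batch(list(val_samples)), mask, space)
    params, history = train(config, train_batch, val_batch, tconfig)
    train_pred = predict(params, train_batch, config, mode="train")
    val_pred = predict(params, val_batch, config, mode="test")
    train_rmse, train_corr = evaluate(train_pred, train_batch.target)
    val_rmse, val_corr = evaluate(val_pred, val_batch.target)
    return {
        "n_features_kept": int(mask.sum()),
        "train_rmse": train_rmse,
        "train_corr_pct": train_corr,
        "val_rmse": val_rmse,
        "val_corr_pct": val_corr,
        "params": params,
        "history": history,
    }
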