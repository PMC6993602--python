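"""The hybrid CNN-LSTM yield model.

Two 1-D convolutional encoders feed a k-step LSTM: the weather encoder
(W-CNN) convolves over the 52-week axis with the six weather variables as
channels; the soil encoder (S-CNN) convolves over the nine-depth axis with
the ten soil variables as channels.  Each encoder is four conv layers with
ReLU activations and average pooling (stride 2) where the axis length
permits, followed by a fully connected layer.  Per year-step, the LSTM cell
receives the concatenation of the two encoder outputs, the four surface
soil variables passed through directly, the cross-county average yield of
that year (the trend signal), and the weekly planting-progress vector.  A
single linear head shared across steps maps each hidden state to a yield
prediction; the last step's prediction is the target-year forecast.

Because the average-yield input alone can carry the prediction, the model
degrades gracefully when weather/soil/management branches are removed —
the basis of the ablation variants in :mod:`yieldnet.experiments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from .preprocess import (
    N_DEPTHS,
    N_MGMT_WEEKS,
    N_SOIL_VARS,
    N_SURFACE,
    N_WEATHER_VARS,
    N_WEEKS,
    DimensionError,
    SequenceSample,
    SoilProfile,
    WeatherSeries,
)


class ConfigurationError(ValueError):
    """Parameters do not match the model configuration."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and input-wiring hyperparameters.

    Defaults are the corn configuration: four conv layers per encoder with
    average pooling of stride 2 (pooling on the soil branch only while the
    depth axis is long enough), 60/40-unit fully connected layers, and a
    5-step LSTM with 64 hidden units.
    """

    crop: str = "corn"
    k: int = 5
    lstm_units: int = 64
    fc_weather_units: int = 60
    fc_soil_units: int = 40
    wcnn_filters: tuple[int, ...] = (16, 32, 64, 128)
    wcnn_kernel: int = 3
    wcnn_pool: tuple[bool, ...] = (True, True, True, True)
    scnn_filters: tuple[int, ...] = (16, 32, 64, 128)
    scnn_kernel: int = 3
    scnn_pool: tuple[bool, ...] = (True, True, False, False)
    use_weather: bool = True
    use_soil: bool = True
    use_management: bool = True
    n_mgmt_weeks: int = N_MGMT_WEEKS

    def __post_init__(self):
        if len(self.wcnn_filters) != 4 or len(self.scnn_filters) != 4:
            raise ConfigurationError("each encoder uses exactly four conv layers")
        if min(self.wcnn_filters + self.scnn_filters) < 1:
            raise ConfigurationError("filter counts must be positive")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        if min(self.lstm_units, self.fc_weather_units, self.fc_soil_units) < 1:
            raise ConfigurationError("layer widths must be positive")

    @classmethod
    def for_crop(cls, crop: str, **overrides) -> "ModelConfig":
        """Corn uses a 60-unit weather FC layer; soybean uses 40."""
        if crop not in ("corn", "soybean"):
            raise ConfigurationError(f"unknown crop {crop!r}")
        fcw = 60 if crop == "corn" else 40
        return cls(crop=crop, fc_weather_units=overrides.pop("fc_weather_units", fcw), **overrides)

    @classmethod
    def small(cls, **overrides) -> "ModelConfig":
        """A reduced configuration for quick experiments and tests."""
        defaults = dict(
            lstm_units=16,
            fc_weather_units=16,
            fc_soil_units=12,
            wcnn_filters=(8, 8, 8, 8),
            scnn_filters=(8, 8, 8, 8),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def medium(cls, **overrides) -> "ModelConfig":
        """Desk-scale reference configuration for the bundled synthetic
        studies: 16-filter encoders, weather axis pooled to 13 positions
        (better positional resolution for saliency), 24/16-unit FC layers,
        24 LSTM units."""
        defaults = dict(
            lstm_units=24,
            fc_weather_units=24,
            fc_soil_units=16,
            wcnn_filters=(16, 16, 16, 16),
            scnn_filters=(16, 16, 16, 16),
            wcnn_pool=(True, True, False, False),
        )
        defaults.update(overrides)
        return cls(**defaults)

    def variant(self, which: str) -> "ModelConfig":
        """Structural ablation keeping the LSTM/average-yield backbone:
        'W' = weather only, 'S' = soil only, 'M' = management only."""
        if which not in ("W", "S", "M"):
            raise ConfigurationError("ablation variant must be 'W', 'S' or 'M'")
        return replace(
            self,
            use_weather=which == "W",
            use_soil=which == "S",
            use_management=which == "M",
        )

    @property
    def step_input_size(self) -> int:
        n = 1  # average yield
        if self.use_weather:
            n += self.fc_weather_units
        if self.use_soil:
            n += self.fc_soil_units + N_SURFACE
        if self.use_management:
            n += self.n_mgmt_weeks
        return n

    def conv_output_length(self, branch: str) -> int:
        """Length of the conv stack's output axis (before flattening)."""
        if branch == "weather":
            length, pools = N_WEEKS, self.wcnn_pool
        else:
            length, pools = N_DEPTHS, self.scnn_pool
        for pool in pools:
            if pool:
                if length < 2:
                    raise ConfigurationError(
                        f"{branch} axis vanishes under the configured pooling"
                    )
                length //= 2
        return length


@dataclass
class Batch:
    """Dense arrays for a batch of sequence samples (oldest step first)."""

    weather: np.ndarray     # (B, k, 6, 52)
    soil: np.ndarray        # (B, k, 10, 9)
    surface: np.ndarray     # (B, k, 4)
    management: np.ndarray  # (B, k, W_m)
    avg_yield: np.ndarray   # (B, k)
    target: np.ndarray      # (B,)

    @property
    def size(self) -> int:
        return self.weather.shape[0]

    def copy(self) -> "Batch":
        return Batch(
            weather=self.weather.copy(),
            soil=self.soil.copy(),
            surface=self.surface.copy(),
            management=self.management.copy(),
            avg_yield=self.avg_yield.copy(),
            target=self.target.copy(),
        )


def samples_to_batch(samples: list[SequenceSample]) -> Batch:
    if not samples:
        raise ValueError("empty sample list")
    return Batch(
        weather=np.stack([s.weather for s in samples]),
        soil=np.stack([s.soil for s in samples]),
        surface=np.stack([s.surface for s in samples]),
        management=np.stack([s.management for s in samples]),
        avg_yield=np.stack([s.avg_yield for s in samples]),
        target=np.array([s.target for s in samples], dtype=np.float64),
    )


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------


def _conv_branch_shapes(
    in_channels: int, filters: tuple[int, ...], kernel: int, prefix: str
) -> dict[str, tuple[int, ...]]:
    shapes = {}
    c = in_channels
    for i, f in enumerate(filters):
        shapes[f"{prefix}.conv{i}.w"] = (f, c, kernel)
        shapes[f"{prefix}.conv{i}.b"] = (f,)
        c = f
    return shapes


def parameter_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Name -> shape for every trainable array of the configured model."""
    shapes: dict[str, tuple[int, ...]] = {}
    if config.use_weather:
        shapes |= _conv_branch_shapes(
            N_WEATHER_VARS, config.wcnn_filters, config.wcnn_kernel, "wcnn"
        )
        flat = config.wcnn_filters[-1] * config.conv_output_length("weather")
        shapes["wfc.w"] = (flat, config.fc_weather_units)
        shapes["wfc.b"] = (config.fc_weather_units,)
    if config.use_soil:
        shapes |= _conv_branch_shapes(
            N_SOIL_VARS, config.scnn_filters, config.scnn_kernel, "scnn"
        )
        flat = config.scnn_filters[-1] * config.conv_output_length("soil")
        shapes["sfc.w"] = (flat, config.fc_soil_units)
        shapes["sfc.b"] = (config.fc_soil_units,)
    H = config.lstm_units
    shapes["lstm.wx"] = (config.step_input_size, 4 * H)
    shapes["lstm.wh"] = (H, 4 * H)
    shapes["lstm.b"] = (4 * H,)
    shapes["head.w"] = (H, 1)
    shapes["head.b"] = (1,)
    # fixed affine back-transform (sd, mean) from the standardized-yield
    # scale the head predicts on to bushels/acre; set from training targets,
    # not trained
    shapes["target.scale"] = (2,)
    return shapes


def count_parameters(params: dict[str, ad.Tensor]) -> int:
    """Total number of trainable scalars (fixed statistics excluded)."""
    return int(
        sum(p.data.size for k, p in params.items() if not k.startswith("target."))
    )


def check_params(config: ModelConfig, params: dict[str, ad.Tensor]) -> None:
    expected = parameter_shapes(config)
    got = {k: tuple(v.shape) for k, v in params.items()}
    if got != expected:
        raise ConfigurationError(
            "parameters do not match the configuration; first mismatch: "
            + next(
                f"{k}: expected {expected.get(k)}, got {got.get(k)}"
                for k in sorted(set(expected) | set(got))
                if expected.get(k) != got.get(k)
            )
        )


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------


def _conv_stack(
    x: ad.Tensor,
    params: dict[str, ad.Tensor],
    prefix: str,
    pools: tuple[bool, ...],
) -> ad.Tensor:
    length = x.shape[-1]
    for i in range(4):
        x = ad.conv1d(x, params[f"{prefix}.conv{i}.w"], params[f"{prefix}.conv{i}.b"])
        x = ad.relu(x)
        if pools[i]:
            if length < 2:
                raise ConfigurationError("pooling on a length-1 axis")
            x = ad.avg_pool1d(x, 2, 2)
            length //= 2
    return x


def _fc(x: ad.Tensor, w: ad.Tensor, b: ad.Tensor, activation: bool = True) -> ad.Tensor:
    out = ad.matmul(x, w) + b
    return ad.relu(out) if activation else out


def wcnn_forward(
    weather: np.ndarray | WeatherSeries | ad.Tensor,
    params: dict[str, ad.Tensor],
    config: ModelConfig,
) -> ad.Tensor:
    """Weather encoder: (B, 6, 52) -> (B, fc_weather_units)."""
    if isinstance(weather, WeatherSeries):
        weather = weather.values[None]
    x = weather if isinstance(weather, ad.Tensor) else ad.tensor(np.asarray(weather))
    if x.shape[-2:] != (N_WEATHER_VARS, N_WEEKS):
        raise DimensionError(f"weather input must end in (6, 52), got {x.shape}")
    if x.data.ndim == 2:
        x = ad.reshape(x, (1,) + x.shape)
    h = _conv_stack(x, params, "wcnn", config.wcnn_pool)
    h = ad.reshape(h, (h.shape[0], h.shape[1] * h.shape[2]))
    return _fc(h, params["wfc.w"], params["wfc.b"])


def scnn_forward(
    soil: np.ndarray | SoilProfile | ad.Tensor,
    params: dict[str, ad.Tensor],
    config: ModelConfig,
) -> ad.Tensor:
    """Soil-depth encoder: (B, 10, 9) -> (B, fc_soil_units).  The four
    surface variables are not part of this branch; they bypass to the LSTM."""
    if isinstance(soil, SoilProfile):
        soil = soil.depth_values[None]
    x = soil if isinstance(soil, ad.Tensor) else ad.tensor(np.asarray(soil))
    if x.shape[-2:] != (N_SOIL_VARS, N_DEPTHS):
        raise DimensionError(f"soil input must end in (10, 9), got {x.shape}")
    if x.data.ndim == 2:
        x = ad.reshape(x, (1,) + x.shape)
    h = _conv_stack(x, params, "scnn", config.scnn_pool)
    h = ad.reshape(h, (h.shape[0], h.shape[1] * h.shape[2]))
    return _fc(h, params["sfc.w"], params["sfc.b"])


def _lstm_step(
    x: ad.Tensor,
    h: ad.Tensor,
    c: ad.Tensor,
    params: dict[str, ad.Tensor],
    H: int,
) -> tuple[ad.Tensor, ad.Tensor]:
    return ad.lstm_cell(x, h, c, params["lstm.wx"], params["lstm.wh"], params["lstm.b"])


def model_forward(
    batch: Batch | SequenceSample,
    params: dict[str, ad.Tensor],
    config: ModelConfig,
    inputs: dict[str, ad.Tensor] | None = None,
    return_hidden: bool = False,
):
    """Run the unrolled model.

    Returns a (B, k) tensor of per-step yield predictions; the final column
    is the target-year forecast.  Passing a dict via ``inputs`` lets callers
    supply their own leaf tensors (with ``requires_grad``) for saliency; the
    dict is filled with the tensors actually used.
    """
    if isinstance(batch, SequenceSample):
        batch = samples_to_batch([batch])
    check_params(config, params)
    B, k = batch.avg_yield.shape
    if k != config.k:
        raise ConfigurationError(f"batch has k={k}, config expects k={config.k}")

    if inputs is None:
        inputs = {}

    def leaf(name: str, data: np.ndarray) -> ad.Tensor:
        if name not in inputs:
            inputs[name] = ad.tensor(data)
        return inputs[name]

    w_feats = s_feats = None
    if config.use_weather:
        w_in = leaf("weather", batch.weather)
        flat = ad.reshape(w_in, (B * k, N_WEATHER_VARS, N_WEEKS))
        w_feats = ad.reshape(
            wcnn_forward(flat, params, config), (B, k, config.fc_weather_units)
        )
    if config.use_soil:
        s_in = leaf("soil", batch.soil)
        flat = ad.reshape(s_in, (B * k, N_SOIL_VARS, N_DEPTHS))
        s_feats = ad.reshape(
            scnn_forward(flat, params, config), (B, k, config.fc_soil_units)
        )
        u_in = leaf("surface", batch.surface)
    if config.use_management:
        m_in = leaf("management", batch.management)
    ybar_in = leaf("avg_yield", batch.avg_yield)

    H = config.lstm_units
    h = ad.tensor(np.zeros((B, H)))
    c = ad.tensor(np.zeros((B, H)))
    preds = []
    hiddens = []
    for t in range(k):
        parts = []
        if config.use_weather:
            parts.append(w_feats[:, t, :])
        if config.use_soil:
            parts.append(s_feats[:, t, :])
            parts.append(u_in[:, t, :])
        parts.append(ad.reshape(ybar_in[:, t], (B, 1)))
        if config.use_management:
            parts.append(m_in[:, t, :])
        x = ad.concat(parts, axis=1)
        h, c = _lstm_step(x, h, c, params, H)
        hiddens.append(h)
        preds.append(ad.matmul(h, params["head.w"]) + params["head.b"])
    out = ad.concat(preds, axis=1)
    scale = params["target.scale"].data
    out = out * ad.tensor(scale[0]) + ad.tensor(scale[1])
    if return_hidden:
        return out, hiddens
    return out


# ---------------------------------------------------------------------------
# feature index space (shared by interpretation & masking)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureSpace:
    """Flat enumeration of all scalar input features of one year-step, in
    fixed order: weather (variable-major over weeks), soil depth
    (variable-major over depths), surface soil, management weeks."""

    n_mgmt_weeks: int = N_MGMT_WEEKS

    @property
    def n_weather(self) -> int:
        return N_WEATHER_VARS * N_WEEKS

    @property
    def n_soil(self) -> int:
        return N_SOIL_VARS * N_DEPTHS

    @property
    def total(self) -> int:
        return self.n_weather + self.n_soil + N_SURFACE + self.n_mgmt_weeks

    def labels(self) -> list[tuple[str, int, int]]:
        out = [
            ("weather", v, w)
            for v in range(N_WEATHER_VARS)
            for w in range(N_WEEKS)
        ]
        out += [("soil_depth", v, d) for v in range(N_SOIL_VARS) for d in range(N_DEPTHS)]
        out += [("soil_surface", 0, i) for i in range(N_SURFACE)]
        out += [("management", 0, w) for w in range(self.n_mgmt_weeks)]
        return out

    def split(self, flat: np.ndarray) -> dict[str, np.ndarray]:
        """Split a flat feature vector into per-group arrays."""
        a = self.n_weather
        b = a + self.n_soil
        c = b + N_SURFACE
        return {
            "weather": flat[:a].reshape(N_WEATHER_VARS, N_WEEKS),
            "soil_depth": flat[a:b].reshape(N_SOIL_VARS, N_DEPTHS),
            "soil_surface": flat[b:c],
            "management": flat[c:],
        }


def apply_feature_mask(batch: Batch, mask: np.ndarray, space: FeatureSpace | None = None) -> Batch:
    """Zero masked-out features in every step of every sample (inputs are
    standardized, so zero is the feature's training mean)."""
    space = space or FeatureSpace()
    if mask.shape != (space.total,):
        raise DimensionError(f"mask must have {space.total} entries, got {mask.shape}")
    parts = space.split(mask.astype(np.float64))
    out = batch.copy()
    out.weather *= parts["weather"][None, None]
    out.soil *= parts["soil_depth"][None, None]
    out.surface *= parts["soil_surface"][None, None]
    out.management *= parts["management"][None, None]
    return out
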