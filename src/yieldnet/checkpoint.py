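"""Versioned model checkpoints.

One ``.npz`` file holds every parameter array plus a JSON header with the
model configuration, the preprocessing statistics and a schema version;
loading validates that the stored arrays match the configuration's shapes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .model import ModelConfig, check_params
from .preprocess import Standardizer

SCHEMA_VERSION = 1


def save_checkpoint(
    path: str | Path,
    config: ModelConfig,
    params: dict[str, ad.Tensor],
    stats: Standardizer | None = None,
) -> None:
    check_params(config, params)
    header = {
        "schema_version": SCHEMA_VERSION,
        "config": dataclasses.asdict(config),
        "stats": stats.to_dict() if stats is not None else None,
    }
    arrays = {f"param/{k}": p.data for k, p in params.items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(
    path: str | Path,
) -> tuple[ModelConfig, dict[str, ad.Tensor], Standardizer | None]:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported checkpoint schema {header.get('schema_version')}"
            )
        cfg_dict = header["config"]
        for key in ("wcnn_filters", "wcnn_pool", "scnn_filters", "scnn_pool"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        params = {
            k[len("param/") :]: ad.parameter(data[k])
            for k in data.files
            if k.startswith("param/")
        }
    check_params(config, params)
    stats = (
        Standardizer.from_dict(header["stats"]) if header["stats"] is not None else None
    )
    return config, params, stats
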