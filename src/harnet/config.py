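"""Configuration profiles and YAML loading for the CLI.

The ``reference_defaults`` profile collects the reference training protocol:
window length 100 with 50% overlap, learning rate 1e-4, batch size 128,
40 epochs, 70% of attention pairs masked, class-weighted loss.
"""

from __future__ import annotations

import yaml

from .attention import EncoderConfig
from .embedding import SEConfig
from .model import TrainConfig

__all__ = ["PROFILES", "default_config", "load_config", "build_configs"]

PROFILES: dict[str, dict] = {
    "reference_defaults": {
        "segmentation": {"window_length": 100, "overlap": 0.5},
        "se": {"reduction_ratio": 2, "conv_kernel_sizes": [7, 5],
               "conv_out_channels": [32, 64], "use_se": True},
        "encoder": {"d_model": 64, "n_heads": 4, "n_layers": 2,
                    "dropout": 0.1, "slide_radius": 5,
                    "mask_fraction": 0.7, "mask_is_keep_fraction": False,
                    "use_sparse_mask": True},
        "train": {"learning_rate": 1.0e-4, "lr_decay": 0.95,
                  "batch_size": 128, "epochs": 40, "seed": 0,
                  "use_class_weights": True},
    },
}


def default_config() -> dict:
    import copy

    return copy.deepcopy(PROFILES["reference_defaults"])


def load_config(path=None, profile: str = "reference_defaults") -> dict:
    """Load a YAML config, filling unspecified sections from a profile."""
    import copy

    cfg = copy.deepcopy(PROFILES[profile])
    if path is not None:
        with open(path) as f:
            user = yaml.safe_load(f) or {}
        for section, values in user.items():
            cfg.setdefault(section, {}).update(values or {})
    return cfg


def build_configs(cfg: dict):
    """Materialise the dataclass configs from a config dictionary."""
    se_raw = dict(cfg.get("se", {}))
    for key in ("conv_kernel_sizes", "conv_out_channels"):
        if key in se_raw:
            se_raw[key] = tuple(se_raw[key])
    se = SEConfig(**se_raw)
    enc = EncoderConfig(**cfg.get("encoder", {}))
    train = TrainConfig(**cfg.get("train", {}))
    return se, enc, train
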