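"""Run configuration: defaults, YAML loading, strict merging.

Defaults follow the training recipe of the algorithm: SGD with momentum
0.9, initial learning rate 1e-5, weight decay 1e-7, batch size 1, loss
mix alpha = 0.9 / beta = 0.4, schedule S/I/J = 2/4/50 epochs.  Unknown
keys in a YAML file or override set raise (typo protection).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, is_dataclass
from pathlib import Path

import yaml

from .cascade import CascadeConfig
from .phantom import PhantomConfig


@dataclass
class RunConfig:
    seed: int = 0
    train_fraction: float = 0.8
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    cascade: CascadeConfig = field(default_factory=CascadeConfig)

    def resolved(self) -> "RunConfig":
        """Propagate the top-level seed into sub-configs."""
        self.phantom.seed = self.seed
        self.cascade.seed = self.seed
        return self


def _coerce(value, current):
    if isinstance(current, tuple) and isinstance(value, (list, tuple)):
        return tuple(value)
    if isinstance(current, bool):
        return bool(value)
    if isinstance(current, int) and not isinstance(value, bool) and isinstance(value, (int, float)):
        return int(value) if float(value).is_integer() else value
    if isinstance(current, float) and isinstance(value, (int, float)):
        return float(value)
    return value


def _merge(obj, data: dict, path: str = "") -> None:
    names = {f.name for f in dataclasses.fields(obj)}
    for key, value in data.items():
        where = f"{path}{key}"
        if key not in names:
            raise KeyError(f"unknown config key: {where!r}")
        current = getattr(obj, key)
        if is_dataclass(current) and isinstance(value, dict):
            _merge(current, value, path=where + ".")
        else:
            setattr(obj, key, _coerce(value, current))


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a RunConfig from defaults <- YAML file <- dotted overrides."""
    cfg = RunConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        _merge(cfg, raw)
    for dotted, value in (overrides or {}).items():
        node = cfg
        *parents, last = dotted.split(".")
        for p in parents:
            if not hasattr(node, p):
                raise KeyError(f"unknown config key: {dotted!r}")
            node = getattr(node, p)
        if not hasattr(node, last):
            raise KeyError(f"unknown config key: {dotted!r}")
        setattr(node, last, _coerce(value, getattr(node, last)))
    # re-run validation hooks with the merged values
    cfg.phantom.__post_init__()
    cfg.cascade.weights.__post_init__()
    return cfg.resolved()


def config_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_dict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_dict(cfg), sort_keys=False))
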