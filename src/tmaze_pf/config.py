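"""Experiment configuration: defaults, file parsing, validation.

The defaults reproduce the full study: the 5x5 (lambda, alpha_r) grid, 100
runs of 100 episodes, goal relocation every 20 episodes, observation noise
sigma = 0.05, alpha_W = 0.1, gamma = 0.95, and the epsilon schedule
0.9 * 0.8**k + 0.1.  Config files are flat YAML or JSON mappings; explicit
overrides win over the file, which wins over the defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .experiment import DEFAULT_ALPHA_RS, DEFAULT_LAMS


@dataclass(frozen=True)
class ExperimentConfig:
    lams: tuple[float, ...] = DEFAULT_LAMS
    alpha_rs: tuple[float, ...] = DEFAULT_ALPHA_RS
    n_runs: int = 100
    n_episodes: int = 100
    switch_period: int = 20
    sigma: float = 0.05
    max_steps: int = 500
    alpha_W: float = 0.1
    gamma: float = 0.95
    eps_a: float = 0.9
    eps_b: float = 0.8
    eps_floor: float = 0.1
    feature_space: str = "corridor"
    initial_side: str = "left"
    base_seed: int = 0
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if not self.lams or not self.alpha_rs:
            raise ValueError("hyperparameter grids must be non-empty")
        for lam in self.lams:
            if not 0.0 <= lam < 1.0:
                raise ValueError(f"lam={lam} outside [0, 1)")
        for a in self.alpha_rs:
            if not 0.0 < a <= 1.0:
                raise ValueError(f"alpha_r={a} outside (0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.alpha_W <= 0:
            raise ValueError("alpha_W must be positive")
        if min(self.n_runs, self.n_episodes, self.switch_period, self.max_steps) < 1:
            raise ValueError("counts must be >= 1")
        if self.feature_space not in ("corridor", "full"):
            raise ValueError(f"unknown feature_space {self.feature_space!r}")
        if self.initial_side not in ("left", "right"):
            raise ValueError(f"unknown initial_side {self.initial_side!r}")


_FIELDS = {f.name for f in dataclasses.fields(ExperimentConfig)}
_LIST_FIELDS = ("lams", "alpha_rs")


def parse_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> ExperimentConfig:
    """Merge defaults <- config file <- overrides into a validated config.

    Unknown keys raise a ValueError naming the key; out-of-range values
    raise from the dataclass validation.
    """
    merged: dict[str, Any] = {}
    for source in (_load_file(path), dict(overrides or {})):
        for key, value in source.items():
            if value is None:
                continue
            if key not in _FIELDS:
                raise ValueError(f"unknown configuration key {key!r}")
            if key in _LIST_FIELDS:
                value = tuple(float(v) for v in value)
            merged[key] = value
    return ExperimentConfig(**merged)


def _load_file(path: str | Path | None) -> dict[str, Any]:
    if path is None:
        return {}
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
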