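"""Run configuration: YAML loading, validation, defaults, serialization.

An empty configuration file reproduces the reference two-group experiment
(10 subjects per group, 1,000 training epochs, 100 test stimuli).  Unknown
keys are rejected so typos fail loudly before any simulation starts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Optional

import yaml

from .dopamine import DAParams
from .network import NetworkParams
from .plasticity import LearningParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Settings for a full cohort experiment."""

    n_per_group: int = 10
    n_epochs: int = 1000
    base_seed: int = 0
    test_stimuli: int = 100
    test_noise_sd: float = 0.1
    trial_duration: float = 0.8        # training stimulus presentation (s)
    test_duration: float = 1.8         # test stimulus presentation (s)
    response_threshold: float = 0.9
    dt: float = 1e-3
    sweep_sd_grid: list = field(default_factory=lambda:
                                [0.0, 0.2, 0.4, 0.6, 0.8, 1.0])
    gain_amplitudes: list = field(default_factory=lambda:
                                  [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7,
                                   0.8, 0.9, 1.0])
    vmax_control: float = 1.2
    vmax_imbalance: float = 1.8
    da_overrides: dict = field(default_factory=dict)
    network_overrides: dict = field(default_factory=dict)
    learning_overrides: dict = field(default_factory=dict)
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.n_epochs < 4 or self.n_epochs % 4:
            raise ValueError("n_epochs must be a positive multiple of 4")
        if self.test_noise_sd < 0:
            raise ValueError("test_noise_sd must be >= 0")
        if not 0 < self.response_threshold < 1:
            raise ValueError("response_threshold must lie in (0, 1)")
        if not 0 < self.dt <= 1e-3:
            raise ValueError("dt must lie in (0, 1 ms]")
        for name, cls in (("da_overrides", DAParams),
                          ("network_overrides", NetworkParams),
                          ("learning_overrides", LearningParams)):
            known = {f.name for f in fields(cls)}
            bad = set(getattr(self, name)) - known
            if bad:
                raise ValueError(f"unknown {name} keys: {sorted(bad)}")
        # constructing the parameter objects validates the override values
        self.da_params("control")
        self.network_params()
        self.learning_params()

    def da_params(self, group: str) -> DAParams:
        vmax = {"control": self.vmax_control,
                "imbalance": self.vmax_imbalance}[group]
        return DAParams(**{"Vmax": vmax, **self.da_overrides})

    def network_params(self) -> NetworkParams:
        return NetworkParams(**self.network_overrides)

    def learning_params(self) -> LearningParams:
        return LearningParams(**self.learning_overrides)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def load_config(path: Optional[str | Path] = None, **overrides) -> RunConfig:
    """Load a YAML config file; an empty/missing mapping means full defaults.

    Unknown top-level keys raise ``ValueError`` naming the offending field.
    Keyword arguments override file values (used by the CLI flags).
    """
    data: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got "
                             f"{type(loaded).__name__}")
        data = loaded
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    bad = set(data) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    return RunConfig(**data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully-defaulted config back out (round-trips with load)."""
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
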