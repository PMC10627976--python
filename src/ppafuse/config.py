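"""Structured run configuration for the command-line entry point.

A :class:`RunConfig` is a validated, YAML/JSON-serialisable description of
one evaluation run: which cohort to simulate (or load), which feature
kinds and fusion modes to evaluate, the selection and fusion grids, the
network hyperparameters, and the cross-validation setup.  Every report the
run produces embeds the config's content digest, so outputs are traceable
to the exact configuration that generated them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ann import AnnConfig
from .evaluation import DEFAULT_P_GRID, ExperimentConfig
from .fusion import DEFAULT_WEIGHT_GRID

__all__ = ["RunConfig", "load_config"]

_VALID_KINDS = {"PSD", "PPA"}
_VALID_FUSION = {"feature", "score"}
_VALID_PRESETS = {"null", "phase-only", "power-only", "both"}


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end evaluation run."""

    preset: str = "both"
    data_dir: str | None = None  # load recordings instead of simulating
    n_per_class: int = 30
    duration: float = 30.0
    fs: float = 250.0
    kinds: tuple[str, ...] = ("PSD", "PPA")
    fusion: tuple[str, ...] = ("feature", "score")
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    weight_grid: tuple[float, ...] = DEFAULT_WEIGHT_GRID
    k: int = 5
    hidden_units: int = 10
    max_epochs: int = 10_000
    goal_mse: float = 1e-5
    patience: int = 6
    seed: int = 0
    out_dir: str = "ppafuse_out"

    def __post_init__(self) -> None:
        errors = []
        if self.data_dir is None and self.preset not in _VALID_PRESETS:
            errors.append(f"preset: {self.preset!r} not in {sorted(_VALID_PRESETS)}")
        bad = set(self.kinds) - _VALID_KINDS
        if bad:
            errors.append(f"kinds: unknown {sorted(bad)}")
        bad = set(self.fusion) - _VALID_FUSION
        if bad:
            errors.append(f"fusion: unknown {sorted(bad)}")
        if self.n_per_class < 1:
            errors.append("n_per_class: must be >= 1")
        if self.k < 2:
            errors.append("k: must be >= 2")
        if any(not 0 < p < 1 for p in self.p_grid):
            errors.append("p_grid: thresholds must lie in (0, 1)")
        if any(not 0 < w < 1 for w in self.weight_grid):
            errors.append("weight_grid: weights must lie in (0, 1)")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
        self.kinds = tuple(self.kinds)
        self.fusion = tuple(self.fusion)
        self.p_grid = tuple(float(p) for p in self.p_grid)
        self.weight_grid = tuple(float(w) for w in self.weight_grid)

    @property
    def digest(self) -> str:
        """Content digest of the computation-relevant configuration.

        ``out_dir`` is excluded: where a run writes does not change what it
        computes.
        """
        payload = asdict(self)
        payload.pop("out_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def experiment_config(self, seed: int | None = None) -> ExperimentConfig:
        return ExperimentConfig(
            kinds=self.kinds,
            fusion=self.fusion,
            p_grid=self.p_grid,
            weight_grid=self.weight_grid,
            k=self.k,
            ann=AnnConfig(
                hidden_units=self.hidden_units,
                max_epochs=self.max_epochs,
                goal_mse=self.goal_mse,
                patience=self.patience,
            ),
            seed=self.seed if seed is None else seed,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration file must hold a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration fields: {sorted(unknown)}")
    for key in ("kinds", "fusion", "p_grid", "weight_grid"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
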