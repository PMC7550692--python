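"""Run configuration: analysis thresholds and generator parameters.

A single YAML file (or defaults) drives the full pipeline; all randomness
flows from one root seed that is split deterministically per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from pdacdriver.synthetic_data import CohortParams, ExpressionSimParams

MIN_PERMUTATION_REPS = 1000


@dataclass(frozen=True)
class RunConfig:
    """Thresholds and simulation parameters for a full pipeline run."""

    deg_p: float = 0.05
    deg_abs_log2fc: float = 1.0
    expressed_frac: float = 0.20
    min_level: float = 5.0
    reps: int = 1_000_000
    seed: int = 0
    cohort: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("deg_p", "deg_abs_log2fc", "expressed_frac", "min_level"):
            if not getattr(self, name) > 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.reps < MIN_PERMUTATION_REPS:
            raise ValueError(
                f"reps must be >= {MIN_PERMUTATION_REPS}, got {self.reps}"
            )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        stages = ("cohort", "expression", "qpcr", "enrichment")
        offset = stages.index(stage) if stage in stages else len(stages)
        return int(np.random.SeedSequence((self.seed, offset)).generate_state(1)[0] % (2**31))

    def cohort_params(self) -> CohortParams:
        return CohortParams(**{**self.cohort, "seed": self.stage_seed("cohort")})

    def expression_params(self) -> ExpressionSimParams:
        return ExpressionSimParams(**{**self.expression, "seed": self.stage_seed("expression")})

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if seed is not None:
            raw["seed"] = seed
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
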