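"""Run configuration and seeded random-stream management.

All analysis constants live in :class:`RunConfig`; all randomness flows
from one root seed through :func:`stage_rng`, which derives an independent
child stream per named pipeline stage so stages can be re-run or reordered
without perturbing each other.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import numpy as np


class ConfigError(ValueError):
    """Raised for out-of-contract configuration values."""


@dataclass(frozen=True)
class RunConfig:
    """Pipeline constants.

    Fractions are probability/volume fractions in (0, 1); lengths are in
    meters; areas in square meters.
    """

    mcp_percent: float = 0.95        # MCP peel fraction
    core_isopleth: float = 0.30      # UD volume contour defining "core" use
    outer_isopleth: float = 0.95     # contour matched to the MCP area
    bandwidth_step: float = 1.0      # KDE bandwidth increment, m
    pop_ud_iterations: int = 1000    # season-resampling iterations
    min_obs_per_season: int = 20     # season retention threshold
    grid_cell: float = 2.0           # raster cell size, m
    grid_margin: float = 50.0        # raster margin beyond data extent, m
    delta_aic_cut: float = 2.0       # model-averaging candidate-set cut
    vif_max: float = 2.0             # collinearity screening threshold
    bootstrap_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mcp_percent", "core_isopleth", "outer_isopleth"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name}={v} not in (0, 1)")
        if self.core_isopleth >= self.outer_isopleth:
            raise ConfigError("core_isopleth must be < outer_isopleth")
        for name in ("pop_ud_iterations", "min_obs_per_season",
                     "bootstrap_iterations"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("bandwidth_step", "grid_cell", "grid_margin"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible generator for one named pipeline stage.

    The stage name is hashed into a spawn key so the child streams are
    statistically independent of each other and of the root, and adding a
    new stage never shifts the draws of existing ones.
    """
    digest = hashlib.sha256(stage.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                        spawn_key=(key,)))
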