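"""Telemetry data container and shared constants.

A relocation dataset is one row per observation: animal id, season id,
reproductive class, timestamp, planar x/y (meters), and the five habitat
covariates measured in a 1-m^2 quadrat at the snake's position (percent
cover, 0-100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Habitat covariates, in canonical column order.
COVARIATES = ("canopy", "cwd", "ground_veg", "rock", "woody_veg")

#: Reproductive classes (per animal-season; females may switch between years).
CLASSES = ("male", "nongravid_female", "gravid_female")

#: Required columns of a telemetry table.
COLUMNS = ("obs_id", "animal_id", "season_id", "repro_class", "timestamp",
           "x", "y") + COVARIATES


class ValidationError(ValueError):
    """Raised when telemetry rows violate the dataset contract."""


@dataclass
class TelemetryDataset:
    """Relocations grouped into animal-seasons.

    ``obs`` holds one row per observation with the columns in
    :data:`COLUMNS`.  ``rejected`` (possibly empty) is the row-level report
    of observations dropped on read because of missing coordinates or
    covariates.
    """

    obs: pd.DataFrame
    rejected: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.obs.columns]
        if missing:
            raise ValidationError(f"missing columns: {missing}")
        bad_class = set(self.obs["repro_class"]) - set(CLASSES)
        if bad_class:
            raise ValidationError(
                f"repro_class outside {CLASSES}: {sorted(bad_class)}")
        xy = self.obs[["x", "y"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite coordinates")
        cov = self.obs[list(COVARIATES)].to_numpy(float)
        bad = ~((cov >= 0) & (cov <= 100)).all(axis=1) | ~np.isfinite(cov).all(axis=1)
        if bad.any():
            rows = self.obs.index[bad].tolist()
            raise ValidationError(
                f"covariates outside [0, 100] in rows {rows[:20]}")
        dup = self.obs["obs_id"].duplicated()
        if dup.any():
            raise ValidationError("duplicate obs_id values")

    # -- accessors -------------------------------------------------------

    def __len__(self) -> int:
        return len(self.obs)

    @property
    def n_seasons(self) -> int:
        return len(self.obs.groupby(["animal_id", "season_id"], sort=False))

    def season_keys(self) -> list[tuple[str, str]]:
        """(animal_id, season_id) pairs in first-appearance order."""
        seen = self.obs.drop_duplicates(["animal_id", "season_id"])
        return list(zip(seen["animal_id"], seen["season_id"]))

    def season_points(self, animal_id, season_id) -> np.ndarray:
        """(n, 2) array of x/y for one animal-season."""
        m = (self.obs["animal_id"] == animal_id) & (self.obs["season_id"] == season_id)
        return self.obs.loc[m, ["x", "y"]].to_numpy(float)

    def points(self) -> np.ndarray:
        return self.obs[["x", "y"]].to_numpy(float)

    def season_column(self) -> pd.Series:
        """Globally unique animal-season key per row."""
        return (self.obs["animal_id"].astype(str) + "/"
                + self.obs["season_id"].astype(str))

    def subset(self, mask) -> "TelemetryDataset":
        return TelemetryDataset(self.obs.loc[mask].reset_index(drop=True))
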