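"""Dual core/noncore labeling of relocations.

Each retained observation receives two binary use-intensity labels: inside
(1) or outside (0) the 30% volume contour of its own season's UD
(``core_ind``), and of the population UD (``core_pop``).  Membership is
decided by cell index, not by polygonized contours, so points can never
sit ambiguously on a contour boundary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import RunConfig, stage_rng
from .data import COVARIATES, TelemetryDataset
from .utilization import UDRaster, volume_contour


class LabelError(ValueError):
    pass


LABEL_COLUMNS = ["obs_id", "animal_id", "season_id", "repro_class",
                 *COVARIATES, "core_ind", "core_pop"]


def label_observations(data: TelemetryDataset,
                       ind_uds: dict, pop_ud: UDRaster,
                       cfg: RunConfig) -> pd.DataFrame:
    """Attach core_ind / core_pop labels to every observation's covariates."""
    pop_mask = volume_contour(pop_ud, cfg.core_isopleth).mask()
    ind_masks = {key: volume_contour(ud, cfg.core_isopleth).mask()
                 for key, ud in ind_uds.items()}
    core_ind = np.empty(len(data.obs), dtype=int)
    core_pop = np.empty(len(data.obs), dtype=int)
    for i, row in enumerate(data.obs.itertuples(index=False)):
        key = (row.animal_id, row.season_id)
        if key not in ind_uds:
            raise LabelError(f"no individual UD for season {key}")
        try:
            r, c = ind_uds[key].grid.point_to_cell(row.x, row.y)
            core_ind[i] = int(ind_masks[key][int(r), int(c)])
            r, c = pop_ud.grid.point_to_cell(row.x, row.y)
            core_pop[i] = int(pop_mask[int(r), int(c)])
        except Exception as exc:
            raise LabelError(
                f"observation {row.obs_id} outside a UD grid") from exc
    table = data.obs[["obs_id", "animal_id", "season_id", "repro_class",
                      *COVARIATES]].copy()
    table["core_ind"] = core_ind
    table["core_pop"] = core_pop
    return table.reset_index(drop=True)


def bootstrap_mean_ci(values: np.ndarray, n_iter: int,
                      rng: np.random.Generator) -> tuple[float, float, float, float]:
    """Bootstrap mean, SE and 95% percentile CI of a 1-D sample."""
    values = np.asarray(values, float)
    idx = rng.integers(0, len(values), size=(n_iter, len(values)))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), float(means.std(ddof=1)), float(lo), float(hi)


def core_summaries(table: pd.DataFrame, cfg: RunConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Bootstrap mean and 95% CI of each covariate among core observations,
    per level.  A level with no core rows is marked unavailable (NaN)."""
    if len(table) == 0:
        raise LabelError("empty label table")
    if rng is None:
        rng = stage_rng(cfg.seed, "core_summaries")
    rows = []
    for level, col in (("individual", "core_ind"), ("population", "core_pop")):
        core = table[table[col] == 1]
        for cov in COVARIATES:
            if len(core) == 0:
                rows.append({"level": level, "covariate": cov,
                             "mean": np.nan, "se": np.nan,
                             "ci_lo": np.nan, "ci_hi": np.nan,
                             "n": 0, "available": False})
                continue
            m, se, lo, hi = bootstrap_mean_ci(
                core[cov].to_numpy(float), cfg.bootstrap_iterations, rng)
            rows.append({"level": level, "covariate": cov, "mean": m,
                         "se": se, "ci_lo": lo, "ci_hi": hi,
                         "n": len(core), "available": True})
    return pd.DataFrame(rows)
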