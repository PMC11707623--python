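"""Synthetic landscapes and episodically gregarious telemetry.

The generator plants known, level-dependent habitat effects so every
downstream stage of the pipeline has ground truth:

* a covariate landscape of five spatially autocorrelated percent-cover
  surfaces (stationary Gaussian random fields, exponential covariance,
  mapped to [0, 100] by a scaled logistic), with a rocky, forested
  hibernaculum zone (elevated rock and canopy, depressed ground-layer
  vegetation) and open meadow patches (elevated ground vegetation,
  depressed canopy);
* animal-seasons that alternate between communal phases (relocations
  clustered around the shared hibernaculum — spring emergence/basking and
  fall return) and a solitary summer phase (relocations around 1-3
  individually chosen summer core sites, drawn preferentially by
  reproductive-class covariate weights), joined by a short dispersal
  phase.

Because the communal zone is forested while class preferences favor open,
debris- or vegetation-rich cells, the planted canopy effect is negative at
the individual level and positive at the population level — the
level-dependent signature the analysis is built to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import stage_rng
from .data import CLASSES, COVARIATES, TelemetryDataset
from .grid import GridSpec


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class SimConfig:
    """Study-scale defaults: ~16 animals, ~27 animal-seasons, ~32
    relocations per season (mean 32, sd 7, truncated to [20, 49])."""

    n_animals: int = 16
    season_count_probs: tuple = (0.45, 0.40, 0.15)   # P(1, 2, 3 seasons)
    male_fraction: float = 5 / 16
    gravid_prob: float = 8 / 18        # per female-season
    relocs_mean: float = 32.0
    relocs_sd: float = 7.0
    relocs_range: tuple = (20, 49)
    # fractions of a season in (communal spring, dispersal, summer,
    # communal fall); dispersal is split around the summer phase
    phase_schedule: tuple = (0.15, 0.10, 0.60, 0.15)
    sigma_communal: float = 35.0       # m, spread around the hibernaculum
    sigma_core: float = 12.0           # m, spread around a summer core
    dispersal_jitter: float = 25.0     # m
    n_summer_cores: tuple = (1, 3)
    #: class-specific preference weights on standardized covariates
    #: (canopy, cwd, ground_veg, rock, woody_veg); summer core centers are
    #: drawn with probability proportional to exp(w . z).
    #: contrasts are sized so the planted class pattern (gravid: woody
    #: debris; male: open, grassy, canopy-poor) stays identifiable from
    #: the ~40 core sites a study of this scale yields, despite the
    #: canopy/ground-vegetation collinearity that meadows induce
    preference_weights: dict = field(default_factory=lambda: {
        "male": (-2.0, 0.0, 1.0, 0.0, 0.0),
        "nongravid_female": (-0.5, 0.0, 0.3, 0.0, 0.0),
        "gravid_female": (-0.4, 1.8, 0.0, 0.0, 0.0),
    })
    #: summer cores per class (males range widely; gravid females gestate
    #: at a single site)
    cores_by_class: dict = field(default_factory=lambda: {
        "male": (2, 3), "nongravid_female": (1, 2), "gravid_female": (1, 1)})
    measurement_noise_sd: float = 6.0  # percent points
    field_range: float = 40.0          # m, practical autocorrelation range
    # landscape geometry
    grid_cell: float = 2.0
    grid_shape: tuple = (300, 300)     # rows, cols
    hibernaculum_center: tuple = (180.0, 420.0)
    hibernaculum_radius: float = 80.0
    meadow_centers: tuple = ((430.0, 150.0), (150.0, 120.0), (470.0, 460.0))
    meadow_radius: float = 60.0
    #: additive offsets on the standardized (z) scale inside zones
    hibernaculum_offsets: dict = field(default_factory=lambda: {
        "rock": 1.6, "canopy": 1.2, "ground_veg": -1.3})
    meadow_offsets: dict = field(default_factory=lambda: {
        "ground_veg": 1.3, "canopy": -1.6})
    #: baseline shift of each surface on the z scale (site-wide mean cover)
    baselines: dict = field(default_factory=lambda: {
        "canopy": 0.3, "cwd": -0.6, "ground_veg": 0.0,
        "rock": -0.4, "woody_veg": -0.3})
    logistic_scale: float = 0.9        # z -> percent slope
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.phase_schedule) - 1.0) > 1e-9:
            raise SyntheticError("phase_schedule fractions must sum to 1")
        if abs(sum(self.season_count_probs) - 1.0) > 1e-9:
            raise SyntheticError("season_count_probs must sum to 1")
        if self.sigma_communal <= 0 or self.sigma_core < 0:
            raise SyntheticError("sigmas must be positive")

    def replace(self, **kw) -> "SimConfig":
        import dataclasses
        return dataclasses.replace(self, **kw)


@dataclass
class Landscape:
    grid: GridSpec
    surfaces: dict                      # name -> (nrows, ncols) percent
    hibernaculum_center: tuple
    hibernaculum_radius: float
    meadow_centers: tuple
    meadow_radius: float

    def sample(self, name: str, x, y) -> np.ndarray:
        """Bilinear sample of one surface at points (clamped to edges)."""
        g = self.grid
        fx = np.clip((np.asarray(x, float) - g.x0) / g.cellsize - 0.5,
                     0, g.ncols - 1)
        fy = np.clip((np.asarray(y, float) - g.y0) / g.cellsize - 0.5,
                     0, g.nrows - 1)
        j0 = np.clip(np.floor(fx).astype(int), 0, g.ncols - 2)
        i0 = np.clip(np.floor(fy).astype(int), 0, g.nrows - 2)
        tx, ty = fx - j0, fy - i0
        s = self.surfaces[name]
        return ((1 - ty) * ((1 - tx) * s[i0, j0] + tx * s[i0, j0 + 1])
                + ty * ((1 - tx) * s[i0 + 1, j0] + tx * s[i0 + 1, j0 + 1]))

    def in_hibernaculum(self, x, y) -> np.ndarray:
        cx, cy = self.hibernaculum_center
        return (np.hypot(np.asarray(x, float) - cx,
                         np.asarray(y, float) - cy)
                <= self.hibernaculum_radius)

    def standardized_surfaces(self) -> dict:
        return {n: (s - s.mean()) / s.std() for n, s in self.surfaces.items()}


# ---------------------------------------------------------------------------
# Gaussian random fields (circulant embedding / FFT)

def gaussian_random_field(shape: tuple[int, int], cellsize: float,
                          practical_range: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Stationary unit-variance GRF with exponential covariance.

    Covariance exp(-d / rho) with rho = practical_range / 3 (the lag at
    which correlation drops to ~0.05 is ~3 rho).  Sampled exactly on the
    torus by circulant embedding on a doubled grid: eigenvalues of the
    embedded covariance come from its 2-D FFT; tiny negative eigenvalues
    from imperfect embedding are clipped.
    """
    nr, nc = shape
    rho = practical_range / 3.0
    M, N = 2 * nr, 2 * nc
    iy = np.minimum(np.arange(M), M - np.arange(M)) * cellsize
    ix = np.minimum(np.arange(N), N - np.arange(N)) * cellsize
    d = np.hypot(iy[:, None], ix[None, :])
    cov = np.exp(-d / rho)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    noise = rng.normal(size=(M, N)) + 1j * rng.normal(size=(M, N))
    f = np.fft.fft2(noise * np.sqrt(lam / (M * N)))
    return f.real[:nr, :nc]


def _zone_bump(grid: GridSpec, center: tuple, radius: float) -> np.ndarray:
    """Gaussian-shaped bump, ~1 at the center, exp(-2) at the radius."""
    xc, yc = np.meshgrid(grid.x_centers(), grid.y_centers())
    d2 = (xc - center[0]) ** 2 + (yc - center[1]) ** 2
    return np.exp(-2.0 * d2 / radius**2)


def generate_landscape(cfg: SimConfig,
                       rng: np.random.Generator | None = None) -> Landscape:
    """Five percent-cover surfaces with planted zone structure."""
    if rng is None:
        rng = stage_rng(cfg.seed, "landscape")
    nr, nc = cfg.grid_shape
    if nr < 100 or nc < 100:
        raise SyntheticError("landscape grid must be at least 100x100 cells")
    extent = min(nr, nc) * cfg.grid_cell
    if cfg.field_range >= extent:
        raise SyntheticError(
            "field_range must be smaller than the grid extent "
            "(no semivariogram plateau would be observable)")
    grid = GridSpec(x0=0.0, y0=0.0, cellsize=cfg.grid_cell,
                    nrows=nr, ncols=nc)
    hib = _zone_bump(grid, cfg.hibernaculum_center, cfg.hibernaculum_radius)
    meadow = np.zeros(grid.shape)
    for c in cfg.meadow_centers:
        meadow = np.maximum(meadow, _zone_bump(grid, c, cfg.meadow_radius))
    surfaces = {}
    for name in COVARIATES:
        z = gaussian_random_field(cfg.grid_shape, cfg.grid_cell,
                                  cfg.field_range, rng)
        z = z + cfg.baselines.get(name, 0.0)
        z = z + cfg.hibernaculum_offsets.get(name, 0.0) * hib
        z = z + cfg.meadow_offsets.get(name, 0.0) * meadow
        surfaces[name] = 100.0 / (1.0 + np.exp(-cfg.logistic_scale * z))
    return Landscape(grid=grid, surfaces=surfaces,
                     hibernaculum_center=cfg.hibernaculum_center,
                     hibernaculum_radius=cfg.hibernaculum_radius,
                     meadow_centers=cfg.meadow_centers,
                     meadow_radius=cfg.meadow_radius)


# ---------------------------------------------------------------------------
# telemetry simulation

def _draw_core_centers(cfg: SimConfig, land: Landscape, repro_class: str,
                       k: int, rng: np.random.Generator) -> np.ndarray:
    """Summer core sites: cells drawn with P proportional to exp(w . z)."""
    zsurf = land.standardized_surfaces()
    w = np.asarray(cfg.preference_weights[repro_class], float)
    logit = sum(w[i] * zsurf[name] for i, name in enumerate(COVARIATES))
    p = np.exp(logit - logit.max()).ravel()
    total = p.sum()
    if not np.isfinite(total) or total <= 0:
        raise SyntheticError("no cell carries positive preference mass")
    idx = rng.choice(p.size, size=k, replace=False, p=p / total)
    rows, cols = np.unravel_index(idx, land.grid.shape)
    g = land.grid
    return np.column_stack([g.x0 + (cols + 0.5) * g.cellsize,
                            g.y0 + (rows + 0.5) * g.cellsize])


def _clip_to_grid(pts: np.ndarray, grid: GridSpec, pad: float = 1.0
                  ) -> np.ndarray:
    pts[:, 0] = np.clip(pts[:, 0], grid.x0 + pad, grid.xmax - pad)
    pts[:, 1] = np.clip(pts[:, 1], grid.y0 + pad, grid.ymax - pad)
    return pts


def _phase_counts(n: int, schedule: tuple) -> list[int]:
    counts = [int(np.floor(f * n)) for f in schedule]
    # hand leftovers to the summer phase (index 2)
    counts[2] += n - sum(counts)
    return counts


def simulate_telemetry(cfg: SimConfig, land: Landscape,
                       rng: np.random.Generator | None = None,
                       ) -> TelemetryDataset:
    """Phase-switched Gaussian relocation sampling over the landscape.

    Not a continuous-time movement model: at 48-72 h relocation intervals
    step autocorrelation is weak, and the downstream pipeline consumes
    point patterns only.
    """
    if rng is None:
        rng = stage_rng(cfg.seed, "telemetry")
    hib = np.asarray(cfg.hibernaculum_center, float)
    rows = []
    obs_id = 0
    for a in range(cfg.n_animals):
        animal = f"A{a:02d}"
        sex_male = rng.random() < cfg.male_fraction
        n_seasons = 1 + rng.choice(len(cfg.season_count_probs),
                                   p=cfg.season_count_probs)
        for s in range(n_seasons):
            season = f"Y{2016 + s}"
            if sex_male:
                rclass = "male"
            else:
                rclass = ("gravid_female" if rng.random() < cfg.gravid_prob
                          else "nongravid_female")
            lo, hi = cfg.relocs_range
            n = int(np.clip(np.round(rng.normal(cfg.relocs_mean,
                                                cfg.relocs_sd)), lo, hi))
            kc_lo, kc_hi = cfg.cores_by_class.get(rclass, cfg.n_summer_cores)
            k = int(rng.integers(kc_lo, kc_hi + 1))
            cores = _draw_core_centers(cfg, land, rclass, k, rng)
            n_spring, n_disp, n_summer, n_fall = _phase_counts(
                n, cfg.phase_schedule)
            pts = []
            # communal spring: clustered on the shared hibernaculum
            pts.append(hib + rng.normal(0, cfg.sigma_communal,
                                        size=(n_spring, 2)))
            # dispersal: interpolated along hibernaculum -> first core
            if n_disp > 0:
                t = rng.random(n_disp)[:, None]
                pts.append(hib + t * (cores[0] - hib)
                           + rng.normal(0, cfg.dispersal_jitter,
                                        size=(n_disp, 2)))
            # summer: mixture of Gaussians around this season's cores
            which = rng.integers(0, k, size=n_summer)
            pts.append(cores[which]
                       + rng.normal(0, max(cfg.sigma_core, 1e-9),
                                    size=(n_summer, 2)))
            # communal fall: return to the hibernaculum
            pts.append(hib + rng.normal(0, cfg.sigma_communal,
                                        size=(n_fall, 2)))
            pts = _clip_to_grid(np.vstack(pts), land.grid)
            t0 = np.datetime64(f"{2016 + s}-04-05")
            times = t0 + np.round(np.arange(n) * 2.5
                                  + rng.uniform(-0.5, 0.5, n)).astype(int)
            for i in range(n):
                row = {"obs_id": obs_id, "animal_id": animal,
                       "season_id": season, "repro_class": rclass,
                       "timestamp": pd.Timestamp(times[i]),
                       "x": pts[i, 0], "y": pts[i, 1]}
                for name in COVARIATES:
                    v = land.sample(name, pts[i, 0], pts[i, 1])
                    v = v + rng.normal(0, cfg.measurement_noise_sd)
                    row[name] = float(np.clip(v, 0, 100))
                rows.append(row)
                obs_id += 1
    return TelemetryDataset(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# planted truth

@dataclass
class TruthRecord:
    """Ground truth the simulation plants, for downstream recovery checks.

    ``expected_sign_ind`` / ``expected_sign_pop`` give, per covariate, the
    expected direction of the core-vs-noncore effect at each level
    ("+", "-", or "none"): population core use concentrates in the
    hibernaculum zone, individual core use at the preference-drawn summer
    sites.
    """

    zone_contrast_z: dict           # covariate -> hibernaculum-minus-mean, z
    summer_contrast_z: dict         # covariate -> expected core-site z
    class_weights: dict
    expected_sign_ind: dict
    expected_sign_pop: dict
    class_core_mean: dict           # class -> covariate -> expected percent


def _sign(v: float, threshold: float) -> str:
    if v > threshold:
        return "+"
    if v < -threshold:
        return "-"
    return "none"


def planted_truth(cfg: SimConfig, land: Landscape,
                  sign_threshold: float = 0.15) -> TruthRecord:
    """Derive expected effect directions from the landscape and weights.

    Population-level signs come from the covariate contrast between the
    hibernaculum zone and the landscape mean; individual-level signs from
    the class-mixture average covariate contrast at preference-weighted
    summer core cells.  Contrasts are on the standardized (z) landscape
    scale; |z| below ``sign_threshold`` is recorded as "none".
    """
    zsurf = land.standardized_surfaces()
    xc, yc = np.meshgrid(land.grid.x_centers(), land.grid.y_centers())
    in_hib = land.in_hibernaculum(xc, yc)
    zone_contrast = {n: float(zsurf[n][in_hib].mean()) for n in COVARIATES}

    # class mixture over animal-seasons
    p_male = cfg.male_fraction
    mix = {"male": p_male,
           "gravid_female": (1 - p_male) * cfg.gravid_prob,
           "nongravid_female": (1 - p_male) * (1 - cfg.gravid_prob)}

    summer_contrast = {n: 0.0 for n in COVARIATES}
    class_core_mean: dict = {}
    for rclass in CLASSES:
        w = np.asarray(cfg.preference_weights[rclass], float)
        logit = sum(w[i] * zsurf[n] for i, n in enumerate(COVARIATES))
        p = np.exp(logit - logit.max())
        p /= p.sum()
        class_core_mean[rclass] = {
            n: float((land.surfaces[n] * p).sum()) for n in COVARIATES}
        for n in COVARIATES:
            summer_contrast[n] += mix[rclass] * float((zsurf[n] * p).sum())

    sign_ind = {n: _sign(summer_contrast[n], sign_threshold)
                for n in COVARIATES}
    sign_pop = {n: _sign(zone_contrast[n], sign_threshold)
                for n in COVARIATES}
    return TruthRecord(zone_contrast_z=zone_contrast,
                       summer_contrast_z=summer_contrast,
                       class_weights=dict(cfg.preference_weights),
                       expected_sign_ind=sign_ind,
                       expected_sign_pop=sign_pop,
                       class_core_mean=class_core_mean)
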