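"""Core-habitat composition by reproductive class and ecological level.

Two multinomial logistic models over core observations: Model 1 predicts
reproductive class (reference: gravid female) from the standardized
habitat covariates; Model 2 predicts ecological level (reference:
individual), each core observation contributing one row per level at
which it is core.  Pairwise group contrasts come from estimated marginal
means of the multinomial linear predictors at the grand covariate mean
(all zeros under standardization).  PCA on the covariate correlation
matrix (with Bartlett's sphericity check) summarizes the group separation
in two components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .config import RunConfig, stage_rng
from .data import CLASSES, COVARIATES
from .labeling import bootstrap_mean_ci


class ClassError(ValueError):
    pass


# ---------------------------------------------------------------------------
# multinomial logit

@dataclass
class MultinomFit:
    reference: str
    groups: tuple                  # reference first
    coef: np.ndarray               # (p + 1, G - 1); row 0 = intercepts
    cov_params: np.ndarray         # covariance of vec(coef), column-major
    llf: float
    names: tuple

    def linear_predictors(self, X: np.ndarray) -> np.ndarray:
        """(n, G) linear predictors; reference column is 0."""
        Xc = np.column_stack([np.ones(len(X)), X])
        eta = Xc @ self.coef
        return np.column_stack([np.zeros(len(X)), eta])

    def probabilities(self, X: np.ndarray) -> np.ndarray:
        eta = self.linear_predictors(X)
        e = np.exp(eta - eta.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)


def fit_multinomial(rows: pd.DataFrame, grouping: str, reference: str,
                    min_group: int = 10) -> MultinomFit:
    """Maximum-likelihood multinomial logit of group membership on the
    standardized covariates.  ``grouping`` names the response column."""
    counts = rows[grouping].value_counts()
    if len(counts) < 2:
        raise ClassError("need >= 2 groups")
    if reference not in counts.index:
        raise ClassError(f"reference group {reference!r} absent")
    small = counts[counts < min_group]
    if len(small):
        raise ClassError(f"groups with < {min_group} rows: {dict(small)}")
    groups = (reference,) + tuple(g for g in sorted(counts.index)
                                  if g != reference)
    codes = rows[grouping].map({g: i for i, g in enumerate(groups)}).to_numpy()
    X = rows[list(COVARIATES)].to_numpy(float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    exog = np.column_stack([np.ones(len(Z)), Z])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes, exog).fit(disp=0, method="newton",
                                              maxiter=200)
    except np.linalg.LinAlgError as exc:
        raise ClassError("singular multinomial fit (separation?)") from exc
    if not np.all(np.isfinite(res.params.to_numpy()
                              if hasattr(res.params, "to_numpy")
                              else res.params)):
        raise ClassError("divergent multinomial fit (separation?)")
    coef = np.asarray(res.params)
    if np.abs(coef).max() > 50:
        raise ClassError("separation: unbounded multinomial coefficients")
    return MultinomFit(reference=reference, groups=groups, coef=coef,
                       cov_params=np.asarray(res.cov_params()),
                       llf=float(res.llf), names=COVARIATES)


def multinomial_coef_table(fit: MultinomFit) -> pd.DataFrame:
    """Coefficients and SEs per non-reference group (log-odds vs reference)."""
    p1 = fit.coef.shape[0]
    se = np.sqrt(np.diag(fit.cov_params)).reshape(-1, p1).T  # (p+1, G-1)
    rows = []
    for gi, group in enumerate(fit.groups[1:]):
        for ti, term in enumerate(("intercept",) + fit.names):
            b, s = fit.coef[ti, gi], se[ti, gi]
            rows.append({"group": group, "reference": fit.reference,
                         "term": term, "estimate": b, "se": s,
                         "z": b / s, "p": 2 * norm.sf(abs(b / s))})
    return pd.DataFrame(rows)


def emm_pairwise(fit: MultinomFit) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Estimated marginal means at the covariate mean vector (all zeros).

    The EMM of each group is its multinomial linear predictor there (the
    reference's is 0), reported centered; pairwise differences are
    log-odds of membership in one group versus another at average habitat,
    with delta-method SEs and normal-approximation ratios.
    """
    Gm1 = len(fit.groups) - 1
    p1 = fit.coef.shape[0]
    eta = np.r_[0.0, fit.coef[0, :]]                      # intercepts at x=0
    # covariance of the intercepts: vec(coef) is stacked per group-column
    icov = np.zeros((Gm1 + 1, Gm1 + 1))
    for a in range(Gm1):
        for b in range(Gm1):
            icov[a + 1, b + 1] = fit.cov_params[a * p1, b * p1]
    emms = pd.DataFrame({"group": fit.groups,
                         "emm": eta - eta.mean(),
                         "linear_predictor": eta})
    rows = []
    for a in range(len(fit.groups)):
        for b in range(len(fit.groups)):
            if a >= b:
                continue
            d = eta[a] - eta[b]
            var = icov[a, a] + icov[b, b] - 2 * icov[a, b]
            if var <= 0:
                raise ClassError("singular information for EMM contrast")
            se = float(np.sqrt(var))
            rows.append({"group_a": fit.groups[a], "group_b": fit.groups[b],
                         "difference": d, "se": se, "t_ratio": d / se,
                         "p": 2 * norm.sf(abs(d / se)),
                         "significant": 2 * norm.sf(abs(d / se)) < 0.05})
    return emms, pd.DataFrame(rows)


def level_rows(labels: pd.DataFrame) -> pd.DataFrame:
    """Rows for the level model: each observation contributes once per
    level at which it is core (possibly twice)."""
    ind = labels[labels["core_ind"] == 1].copy()
    ind["level"] = "individual"
    pop = labels[labels["core_pop"] == 1].copy()
    pop["level"] = "population"
    return pd.concat([ind, pop], ignore_index=True)


# ---------------------------------------------------------------------------
# PCA with sphericity check

def bartlett_sphericity(X: np.ndarray) -> tuple[float, int, float]:
    """Bartlett's test of sphericity on the correlation matrix:
    chi2 = -(n - 1 - (2p + 5) / 6) * ln|R|, df = p(p - 1)/2."""
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ClassError("need n > p for Bartlett's test")
    R = np.corrcoef(X, rowvar=False)
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        raise ClassError("correlation matrix is numerically singular")
    stat = -(n - 1 - (2 * p + 5) / 6.0) * logdet
    df = p * (p - 1) // 2
    return float(stat), int(df), float(chi2.sf(stat, df))


@dataclass
class PCAResult:
    loadings: np.ndarray           # (p, p) orthonormal columns
    variance_explained: np.ndarray  # percent, sums to 100
    scores: np.ndarray             # (n, p)
    pc_correlations: np.ndarray    # (p, p): covariate-PC correlations
    bartlett: tuple                # (chi2, df, p)
    group_scores: pd.DataFrame     # per group x PC: mean, SE, 95% CI
    names: tuple
    strong_loading: float = 0.5
    strong_correlation: float = 0.40

    def loading_table(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(self.names):
            for k in range(len(self.names)):
                rows.append({"covariate": name, "pc": k + 1,
                             "loading": self.loadings[i, k],
                             "correlation": self.pc_correlations[i, k],
                             "strong_loading":
                                 abs(self.loadings[i, k]) >= self.strong_loading,
                             "strong_correlation":
                                 abs(self.pc_correlations[i, k])
                                 > self.strong_correlation})
        return pd.DataFrame(rows)


def pca_core(X: np.ndarray, groups: np.ndarray,
             names: tuple = COVARIATES) -> PCAResult:
    """PCA of the covariate correlation matrix over core observations.

    Loadings are sign-normalized (largest-magnitude element of each
    component positive) so output is deterministic across linear-algebra
    backends.  Scores are the z-scored covariates projected on the
    loadings; group means/SEs/CIs of PC scores summarize separation.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if n <= p:
        raise ClassError("need n > p observations for PCA")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ClassError("rank-deficient covariate matrix")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(X, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0, None), evecs[:, order]
    for k in range(p):
        i = np.argmax(np.abs(evecs[:, k]))
        if evecs[i, k] < 0:
            evecs[:, k] = -evecs[:, k]
    scores = Z @ evecs
    var_pct = 100.0 * evals / evals.sum()
    pc_corr = evecs * np.sqrt(evals)[None, :]
    chi2_stat, df, pval = bartlett_sphericity(X)
    rows = []
    for g in pd.unique(groups):
        sub = scores[np.asarray(groups) == g]
        for k in range(min(p, 2)):
            m = sub[:, k].mean()
            se = sub[:, k].std(ddof=1) / np.sqrt(len(sub))
            rows.append({"group": g, "pc": k + 1, "mean": m, "se": se,
                         "ci_lo": m - 1.96 * se, "ci_hi": m + 1.96 * se,
                         "n": len(sub)})
    return PCAResult(loadings=evecs, variance_explained=var_pct,
                     scores=scores, pc_correlations=pc_corr,
                     bartlett=(chi2_stat, df, pval),
                     group_scores=pd.DataFrame(rows), names=tuple(names))


# ---------------------------------------------------------------------------
# bootstrap class summaries

def class_core_means(rows: pd.DataFrame, cfg: RunConfig,
                     class_col: str = "repro_class",
                     rng: np.random.Generator | None = None,
                     min_per_class: int = 5) -> pd.DataFrame:
    """Bootstrap mean, SE and 95% percentile CI of each covariate within
    each reproductive class's core observations."""
    if rng is None:
        rng = stage_rng(cfg.seed, "class_core_means")
    out = []
    classes = sorted(set(rows[class_col].unique()) | set(CLASSES))
    for rclass in classes:
        sub = rows[rows[class_col] == rclass]
        for cov in COVARIATES:
            if len(sub) < min_per_class:
                out.append({"repro_class": rclass, "covariate": cov,
                            "mean": np.nan, "se": np.nan, "ci_lo": np.nan,
                            "ci_hi": np.nan, "n": len(sub),
                            "available": False})
                continue
            m, se, lo, hi = bootstrap_mean_ci(
                sub[cov].to_numpy(float), cfg.bootstrap_iterations, rng)
            out.append({"repro_class": rclass, "covariate": cov, "mean": m,
                        "se": se, "ci_lo": lo, "ci_hi": hi, "n": len(sub),
                        "available": True})
    return pd.DataFrame(out)
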