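"""Level-contrasted resource-utilization models.

Both levels regress a binary core/noncore label on the five z-score
standardized habitat covariates with a logit link.  The individual-level
model is a single pooled logistic regression (labels are season-relative,
so a per-season random effect would carry no information); the
population-level model adds a Gaussian random intercept per animal-season
to absorb repeated sampling of individuals.  Every covariate subset (32
models, intercept always included) is fit; candidates within a Delta-AIC
cut of the best are full-model-averaged with Akaike weights, a covariate
absent from a candidate contributing a zero coefficient, and unconditional
standard errors combine within-model variance with between-model spread
(Burnham-Anderson).  Level dissimilarity per covariate is tested with a
Wald chi-square on the difference of the two averaged coefficients,
treating the levels as independent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm

from .config import RunConfig
from .data import COVARIATES


class ModelError(ValueError):
    pass


class SeparationError(ModelError):
    pass


# ---------------------------------------------------------------------------
# design construction

@dataclass
class DesignMatrix:
    """Standardized design: binary response, n x p covariate matrix with
    column mean 0 / sd 1, and optional grouping for the random intercept."""

    y: np.ndarray
    X: np.ndarray
    names: tuple
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.X = np.asarray(self.X, float)
        if self.X.ndim != 2 or len(self.y) != len(self.X):
            raise ModelError("response/covariate shape mismatch")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ModelError("missing values in design")

    @property
    def n(self) -> int:
        return len(self.y)


def standardize(table: pd.DataFrame) -> tuple[DesignMatrix, DesignMatrix]:
    """Two designs sharing one standardized covariate matrix: individual
    (response core_ind, ungrouped) and population (core_pop, grouped by
    animal-season)."""
    if len(table) < 50:
        raise ModelError(f"need >= 50 observations, got {len(table)}")
    X = table[list(COVARIATES)].to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    for name, s in zip(COVARIATES, sd):
        if s == 0:
            raise ModelError(f"zero-variance covariate: {name}")
    Z = (X - X.mean(axis=0)) / sd
    groups = (table["animal_id"].astype(str) + "/"
              + table["season_id"].astype(str)).to_numpy()
    ind = DesignMatrix(y=table["core_ind"].to_numpy(float), X=Z,
                       names=COVARIATES, groups=None)
    pop = DesignMatrix(y=table["core_pop"].to_numpy(float), X=Z,
                       names=COVARIATES, groups=groups)
    return ind, pop


def vif(design: DesignMatrix, vif_max: float = 2.0) -> pd.DataFrame:
    """Variance inflation factors 1 / (1 - R^2_j) from OLS of each column
    on the others; infinite under perfect collinearity (warned, not fatal)."""
    X = design.X
    if X.shape[1] < 2:
        raise ModelError("VIF needs >= 2 covariates")
    rows = []
    for j, name in enumerate(design.names):
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        target = X[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        v = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        if np.isinf(v):
            warnings.warn(f"perfect collinearity: {name}")
        rows.append({"covariate": name, "vif": v, "flagged": v >= vif_max})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitted models

@dataclass
class FittedModel:
    """One candidate fit: included terms, coefficients, SEs, likelihood."""

    terms: tuple                  # covariate indices included
    names: tuple                  # their names
    params: np.ndarray            # intercept first, then included terms
    llf: float
    k: int                        # parameter count entering AIC
    se: np.ndarray | None = None
    sigma_u: float | None = None  # random-intercept sd (mixed only)
    boundary: bool = False        # variance estimate hit the 0 boundary
    _se_fn: object = field(default=None, repr=False)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.llf

    def ensure_se(self) -> np.ndarray:
        if self.se is None:
            self.se = self._se_fn()
        return self.se

    def coef_by_index(self) -> dict:
        """covariate index -> (beta, se); absent covariates omitted."""
        se = self.ensure_se()
        return {j: (float(self.params[i + 1]), float(se[i + 1]))
                for i, j in enumerate(self.terms)}


def fit_logistic(design: DesignMatrix, terms=None,
                 compute_se: bool = True) -> FittedModel:
    """Pooled maximum-likelihood logit (Newton/IRLS via statsmodels)."""
    terms = tuple(range(design.X.shape[1])) if terms is None else tuple(terms)
    y = design.y
    if y.min() == y.max():
        raise ModelError("response does not vary")
    exog = np.column_stack([np.ones(design.n), design.X[:, terms]])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0, method="newton", maxiter=100)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(
            f"separation or singular fit for terms {terms}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ModelError(f"logit did not converge in 100 iterations ({terms})")
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise SeparationError(f"divergent coefficients for terms {terms}")
    se = res.bse if compute_se else None
    model = FittedModel(terms=terms,
                        names=tuple(design.names[j] for j in terms),
                        params=np.asarray(res.params), llf=float(res.llf),
                        k=len(terms) + 1, se=np.asarray(se) if se is not None else None)
    model._se_fn = lambda: np.asarray(res.bse)
    return model


# -- random-intercept logistic (adaptive Gauss-Hermite) ---------------------

def _group_index(groups: np.ndarray):
    """Sort order, per-row group codes (already in sorted order), and the
    start offset of each group block."""
    codes, _ = pd.factorize(groups, sort=True)
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.flatnonzero(np.r_[True, np.diff(sorted_codes) > 0])
    return order, sorted_codes, starts


def _agq_negloglik_grad(theta, X, y, gidx, starts, t_nodes, log_w, t_sq):
    """Negative marginal log-likelihood and gradient.

    The random-intercept integral per group is evaluated by adaptive
    Gauss-Hermite quadrature: nodes centered at each group's conditional
    mode (found by Newton; the integrand is log-concave) and scaled by the
    conditional curvature.  The gradient is the exact score integrated on
    the same fixed grid.
    """
    p = X.shape[1]
    beta, log_sigma = theta[:p], theta[p]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    G = len(starts)
    m = np.zeros(G)
    inv_s2 = 1.0 / sigma**2
    for _ in range(60):
        mu = expit(eta + m[gidx])
        grad = np.add.reduceat(y - mu, starts) - m * inv_s2
        hess = -np.add.reduceat(mu * (1.0 - mu), starts) - inv_s2
        m = m - grad / hess
        if np.abs(grad).max() < 1e-10:
            break
    mu = expit(eta + m[gidx])
    hess = -np.add.reduceat(mu * (1.0 - mu), starts) - inv_s2
    s = 1.0 / np.sqrt(-hess)

    U = m[:, None] + np.sqrt(2.0) * s[:, None] * t_nodes[None, :]   # (G, K)
    lin = eta[:, None] + U[gidx]                                    # (n, K)
    ll_obs = y[:, None] * lin - np.logaddexp(0.0, lin)
    f = np.add.reduceat(ll_obs, starts, axis=0)
    f += (-0.5 * U**2 * inv_s2
          - log_sigma - 0.5 * np.log(2.0 * np.pi))
    a = f + t_sq[None, :] + log_w[None, :]
    lse = logsumexp(a, axis=1)
    ll = float(np.sum(lse + 0.5 * np.log(2.0) + np.log(s)))

    pk = np.exp(a - lse[:, None])                                   # (G, K)
    muk = expit(lin)
    r = ((y[:, None] - muk) * pk[gidx]).sum(axis=1)
    g_beta = X.T @ r
    g_logsig = float(((U**2 * inv_s2 - 1.0) * pk).sum())
    return -ll, -np.r_[g_beta, g_logsig]


def fit_mixed_logistic(design: DesignMatrix, terms=None, nodes: int = 9,
                       compute_se: bool = True,
                       start_params: np.ndarray | None = None) -> FittedModel:
    """Logistic regression with a Gaussian random intercept per group,
    fit by maximum marginal likelihood (adaptive Gauss-Hermite, default 9
    nodes).  A variance estimate collapsing to zero is returned as the
    plain pooled logit with a boundary flag.
    """
    if design.groups is None:
        raise ModelError("design has no grouping for the random intercept")
    terms = tuple(range(design.X.shape[1])) if terms is None else tuple(terms)
    order, gidx, starts = _group_index(design.groups)
    if len(starts) < 5:
        raise ModelError("need >= 5 groups")
    y = design.y[order]
    if y.min() == y.max():
        raise ModelError("response does not vary")
    X = np.column_stack([np.ones(design.n), design.X[:, terms]])[order]
    t_nodes, w = hermgauss(nodes)
    log_w, t_sq = np.log(w), t_nodes**2
    args = (X, y, gidx, starts, t_nodes, log_w, t_sq)

    if start_params is None:
        pooled = fit_logistic(design, terms, compute_se=False)
        start_params = np.r_[pooled.params, np.log(0.5)]
    lo = np.log(1e-4)
    bounds = [(None, None)] * X.shape[1] + [(lo, np.log(20.0))]
    res = minimize(_agq_negloglik_grad, start_params, args=args, jac=True,
                   method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7})
    theta = res.x
    sigma = float(np.exp(theta[-1]))
    k = len(terms) + 2          # fixed effects + intercept + variance

    if sigma < 5e-3:            # boundary: marginal model degenerates to GLM
        pooled = fit_logistic(design, terms, compute_se=compute_se)
        model = FittedModel(terms=terms, names=pooled.names,
                            params=pooled.params, llf=pooled.llf, k=k,
                            se=pooled.se, sigma_u=0.0, boundary=True)
        model._se_fn = pooled._se_fn
        return model

    llf = -float(res.fun)

    def se_fn(theta=theta):
        # observed information: central differences of the analytic score
        npar = len(theta)
        H = np.empty((npar, npar))
        for j in range(npar):
            h = 1e-5 * (1.0 + abs(theta[j]))
            tp, tm = theta.copy(), theta.copy()
            tp[j] += h
            tm[j] -= h
            _, gp = _agq_negloglik_grad(tp, *args)
            _, gm = _agq_negloglik_grad(tm, *args)
            H[:, j] = (gp - gm) / (2.0 * h)
        H = 0.5 * (H + H.T)
        cov = np.linalg.inv(H)
        return np.sqrt(np.clip(np.diag(cov)[:-1], 0.0, None))

    model = FittedModel(terms=terms,
                        names=tuple(design.names[j] for j in terms),
                        params=theta[:-1].copy(), llf=llf, k=k,
                        se=se_fn() if compute_se else None, sigma_u=sigma)
    model._se_fn = se_fn
    return model


def mixed_loglik(design: DesignMatrix, params: np.ndarray, sigma_u: float,
                 terms=None, nodes: int = 9) -> float:
    """Marginal log-likelihood at fixed parameters (quadrature check)."""
    terms = tuple(range(design.X.shape[1])) if terms is None else tuple(terms)
    order, gidx, starts = _group_index(design.groups)
    X = np.column_stack([np.ones(design.n), design.X[:, terms]])[order]
    t_nodes, w = hermgauss(nodes)
    nll, _ = _agq_negloglik_grad(
        np.r_[params, np.log(sigma_u)], X, design.y[order], gidx,
        starts, t_nodes, np.log(w), t_nodes**2)
    return -nll


# ---------------------------------------------------------------------------
# all-subsets model averaging

@dataclass
class AveragedModel:
    """Full model average over the Delta-AIC candidate set."""

    names: tuple
    beta: dict                    # covariate -> averaged coefficient
    se: dict                      # covariate -> unconditional SE
    ci: dict                      # covariate -> (lo, hi)
    intercept: float
    intercept_se: float
    ledger: pd.DataFrame          # all candidates: terms, k, llf, AIC, ...
    level: str = ""
    models: list = field(default_factory=list, repr=False)  # the candidate fits

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"covariate": n, "estimate": self.beta[n], "se": self.se[n],
             "ci_lo": self.ci[n][0], "ci_hi": self.ci[n][1]}
            for n in self.names])


def all_subsets_average(design: DesignMatrix, mixed: bool,
                        cfg: RunConfig, level: str = "") -> AveragedModel:
    """Fit every covariate subset and full-average within Delta-AIC < cut.

    Akaike weights are renormalized over the candidate set; a covariate
    absent from a candidate contributes beta = 0 and SE = 0; the
    unconditional SE is sum_m w_m * sqrt(se_m^2 + (beta_m - beta_bar)^2).
    """
    p = design.X.shape[1]
    fits: list[FittedModel] = []
    failures = []
    start = None
    for size in range(p, -1, -1):           # full model first (warm start)
        for terms in itertools.combinations(range(p), size):
            try:
                if mixed:
                    sp = None
                    if start is not None:
                        sp = np.r_[start[0][[0, *[1 + j for j in terms]]],
                                   start[1]]
                    fit = fit_mixed_logistic(design, terms, compute_se=False,
                                             start_params=sp)
                    if size == p and not fit.boundary:
                        start = (np.r_[fit.params], np.log(max(fit.sigma_u, 1e-3)))
                else:
                    fit = fit_logistic(design, terms, compute_se=False)
                fits.append(fit)
            except ModelError as exc:
                failures.append((terms, str(exc)))
                warnings.warn(f"subset {terms} failed: {exc}")
    if not fits:
        raise ModelError(f"all candidate fits failed: {failures}")

    aics = np.array([f.aic for f in fits])
    delta = aics - aics.min()
    in_set = delta < cfg.delta_aic_cut
    rel = np.where(in_set, np.exp(-0.5 * delta), 0.0)
    weights = rel / rel.sum()

    beta, se, ci = {}, {}, {}
    for j, name in enumerate(design.names):
        b_m = np.zeros(len(fits))
        s_m = np.zeros(len(fits))
        for i, f in enumerate(fits):
            if weights[i] > 0 and j in f.terms:
                b_m[i], s_m[i] = f.coef_by_index()[j]
        b_bar = float(np.sum(weights * b_m))
        s_bar = float(np.sum(weights * np.sqrt(s_m**2 + (b_m - b_bar)**2)))
        beta[name] = b_bar
        se[name] = s_bar
        ci[name] = (b_bar - 1.96 * s_bar, b_bar + 1.96 * s_bar)

    b0 = np.array([f.params[0] for f in fits])
    s0 = np.array([f.ensure_se()[0] if weights[i] > 0 else 0.0
                   for i, f in enumerate(fits)])
    b0_bar = float(np.sum(weights * b0))
    s0_bar = float(np.sum(weights * np.sqrt(s0**2 + (b0 - b0_bar)**2)))

    ledger = pd.DataFrame([
        {"terms": "+".join(f.names) or "(intercept)", "k": f.k,
         "logLik": f.llf, "AIC": f.aic, "deltaAIC": delta[i],
         "weight": weights[i], "in_set": bool(in_set[i]),
         "sigma_u": f.sigma_u, "boundary": f.boundary}
        for i, f in enumerate(fits)]).sort_values("AIC").reset_index(drop=True)

    return AveragedModel(names=design.names, beta=beta, se=se, ci=ci,
                         intercept=b0_bar, intercept_se=s0_bar,
                         ledger=ledger, level=level, models=fits)


# ---------------------------------------------------------------------------
# level contrast and marginal effects

def wald_level_test(ind: AveragedModel, pop: AveragedModel) -> pd.DataFrame:
    """Wald chi-square (df = 1) per covariate on the difference between the
    individual- and population-level averaged coefficients, treating the
    two levels as independent."""
    if ind.names != pop.names:
        raise ModelError("averaged models cover different covariates")
    rows = []
    for name in ind.names:
        se2 = ind.se[name] ** 2 + pop.se[name] ** 2
        if se2 <= 0:
            raise ModelError(f"zero standard errors for {name}")
        W = (ind.beta[name] - pop.beta[name]) ** 2 / se2
        rows.append({"covariate": name,
                     "beta_ind": ind.beta[name],
                     "ci_ind_lo": ind.ci[name][0], "ci_ind_hi": ind.ci[name][1],
                     "beta_pop": pop.beta[name],
                     "ci_pop_lo": pop.ci[name][0], "ci_pop_hi": pop.ci[name][1],
                     "W": W, "df": 1, "p": float(chi2.sf(W, 1))})
    return pd.DataFrame(rows)


def marginal_effects(avg: AveragedModel, covariate: str,
                     grid: np.ndarray) -> pd.DataFrame:
    """Predicted core probability along one standardized covariate, others
    held at their mean (0), with delta-method 95% CI on the linear
    predictor mapped through the inverse logit."""
    if covariate not in avg.names:
        raise ModelError(f"{covariate} not in averaged model")
    grid = np.asarray(grid, float)
    if np.any(np.abs(grid) > 3.0):
        warnings.warn("grid extends beyond +-3 standardized units")
    eta = avg.intercept + avg.beta[covariate] * grid
    se_eta = np.sqrt(avg.intercept_se**2 + grid**2 * avg.se[covariate]**2)
    z = norm.ppf(0.975)
    return pd.DataFrame({
        "x": grid, "prob": expit(eta), "eta": eta, "se_eta": se_eta,
        "ci_lo": expit(eta - z * se_eta), "ci_hi": expit(eta + z * se_eta)})
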