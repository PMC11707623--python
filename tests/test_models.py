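"""Logistic and mixed-logistic fits, AIC averaging, the Wald level test."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import chi2

import levelcore as lc
from levelcore.data import COVARIATES
from levelcore.models import (DesignMatrix, ModelError, fit_logistic,
                              fit_mixed_logistic, mixed_loglik)

NAMES = tuple(COVARIATES)


def make_design(rng, n=800, beta=(0.5, -0.5, 0, 0, 0), b0=0.0,
                sigma_u=0.0, n_groups=25):
    X = rng.normal(size=(n, 5))
    groups = rng.integers(0, n_groups, size=n)
    u = rng.normal(0, sigma_u, n_groups) if sigma_u > 0 else np.zeros(n_groups)
    p = expit(b0 + X @ np.asarray(beta, float) + u[groups])
    y = (rng.random(n) < p).astype(float)
    return DesignMatrix(y=y, X=X, names=NAMES, groups=groups)


def label_table(rng, n=300):
    t = pd.DataFrame(rng.uniform(0, 100, size=(n, 5)), columns=COVARIATES)
    t.insert(0, "obs_id", range(n))
    t.insert(1, "animal_id", rng.choice(["A", "B", "C"], n))
    t.insert(2, "season_id", rng.choice(["S0", "S1"], n))
    t.insert(3, "repro_class", "male")
    t["core_ind"] = rng.integers(0, 2, n)
    t["core_pop"] = rng.integers(0, 2, n)
    return t


class TestStandardize:
    def test_columns_standardized_and_shared(self, rng):
        ind, pop = lc.standardize(label_table(rng))
        for d in (ind, pop):
            assert np.abs(d.X.mean(axis=0)).max() < 1e-10
            assert np.abs(d.X.std(axis=0) - 1).max() < 1e-10
        assert np.array_equal(ind.X, pop.X)
        assert ind.groups is None and pop.groups is not None

    def test_idempotent_on_standardized_input(self, rng):
        t = label_table(rng)
        ind1, _ = lc.standardize(t)
        t2 = t.copy()
        t2[list(COVARIATES)] = ind1.X
        ind2, _ = lc.standardize(t2)
        assert np.abs(ind1.X - ind2.X).max() < 1e-10

    def test_zero_variance_named(self, rng):
        t = label_table(rng)
        t["rock"] = 5.0
        with pytest.raises(ModelError, match="rock"):
            lc.standardize(t)

    def test_minimum_n(self, rng):
        with pytest.raises(ModelError, match="50"):
            lc.standardize(label_table(rng, n=40))


class TestVif:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        raw = np.random.default_rng(0).normal(size=(n, 5))
        X = np.linalg.qr(raw - raw.mean(axis=0))[0]   # also orthogonal to 1
        d = DesignMatrix(y=np.zeros(n), X=X, names=NAMES)
        out = lc.vif(d)
        assert np.abs(out["vif"] - 1.0).max() < 1e-8

    def test_duplicate_column_infinite(self, rng):
        X = rng.normal(size=(100, 5))
        X[:, 4] = X[:, 0]
        d = DesignMatrix(y=np.zeros(100), X=X, names=NAMES)
        with pytest.warns(UserWarning, match="collinear"):
            out = lc.vif(d)
        assert np.isinf(out["vif"]).sum() >= 2

    def test_matches_direct_ols_oracle(self, rng):
        # equicorrelated design: VIF_j = 1/(1 - R2_j) with R2 from lstsq
        L = np.linalg.cholesky(0.5 + 0.5 * np.eye(5))
        X = rng.normal(size=(4000, 5)) @ L.T
        d = DesignMatrix(y=np.zeros(4000), X=X, names=NAMES)
        out = lc.vif(d)
        for j in range(5):
            others = np.column_stack([np.ones(4000), np.delete(X, j, 1)])
            pred = others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            r2 = 1 - ((X[:, j] - pred) ** 2).sum() \
                / ((X[:, j] - X[:, j].mean()) ** 2).sum()
            assert out["vif"][j] == pytest.approx(1 / (1 - r2), rel=1e-8)


class TestLogit:
    def test_null_model_closed_form_intercept(self, rng):
        d = make_design(rng, b0=0.7)
        fit = fit_logistic(d, terms=())
        assert fit.params[0] == pytest.approx(logit(d.y.mean()), abs=1e-8)

    def test_recovery_within_3_se(self, rng):
        beta = (0.5, -0.5, 0, 0, 0)
        d = make_design(rng, n=5000, beta=beta)
        fit = fit_logistic(d)
        for b_hat, se, b in zip(fit.params[1:], fit.se[1:], beta):
            assert abs(b_hat - b) < 3 * se

    def test_aic_identity(self, rng):
        fit = fit_logistic(make_design(rng), terms=(0, 2))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.llf, abs=1e-12)
        assert fit.k == 3


class TestMixedLogit:
    def test_zero_group_variance_boundary_matches_glm(self, rng):
        d = make_design(rng, n=900, sigma_u=0.0, n_groups=30)
        mixed = fit_mixed_logistic(d)
        plain = fit_logistic(d)
        assert mixed.boundary
        assert mixed.sigma_u == 0.0
        assert np.abs(mixed.params - plain.params).max() < 1e-3

    def test_parameter_recovery_over_seeds(self):
        # sigma_u = 1, 30 groups x 30 obs, beta = (1, -1, 0, 0, 0)
        beta = np.array([1.0, -1.0, 0, 0, 0])
        sigmas, covered = [], []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            d = make_design(rng, n=900, beta=beta, sigma_u=1.0, n_groups=30)
            fit = fit_mixed_logistic(d)
            sigmas.append(fit.sigma_u)
            covered += [abs(b_hat - b) < 3 * se for b_hat, se, b
                        in zip(fit.params[1:], fit.se[1:], beta)]
        assert abs(np.mean(sigmas) - 1.0) < 0.30
        assert np.mean(covered) >= 0.95

    def test_quadrature_convergence(self, rng):
        d = make_design(rng, n=600, sigma_u=1.0, n_groups=20)
        fit = fit_mixed_logistic(d, nodes=9)
        ll9 = mixed_loglik(d, fit.params, fit.sigma_u, nodes=9)
        ll25 = mixed_loglik(d, fit.params, fit.sigma_u, nodes=25)
        assert abs(ll9 - ll25) < 1e-4

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_against_lme4_glmer(self, tmp_path, rng):
        d = make_design(rng, n=450, beta=(1, -1, 0, 0, 0), sigma_u=1.0,
                        n_groups=15)
        fit = fit_mixed_logistic(d, nodes=9)
        df = pd.DataFrame(d.X, columns=list("abcde"))
        df["y"], df["g"] = d.y, d.groups
        df.to_csv(tmp_path / "d.csv", index=False)
        script = (
            f"d <- read.csv('{tmp_path}/d.csv')\n"
            "suppressMessages(library(lme4))\n"
            "f <- glmer(y ~ a+b+c+d+e + (1|g), data=d, family=binomial,"
            " nAGQ=9)\n"
            "cat(as.numeric(logLik(f)), fixef(f),"
            " sqrt(unlist(VarCorr(f))), '\\n')")
        (tmp_path / "m.R").write_text(script)
        out = subprocess.run(["Rscript", str(tmp_path / "m.R")],
                             capture_output=True, text=True, check=True)
        vals = np.array([float(v) for v in out.stdout.split()])
        assert fit.llf == pytest.approx(vals[0], abs=1e-3)
        assert np.abs(fit.params - vals[1:7]).max() < 1e-2
        assert fit.sigma_u == pytest.approx(vals[7], abs=2e-2)


def reaverage_oracle(fits, cut):
    """Independent reimplementation of the averaging formulas."""
    aic = np.array([2 * f.k - 2 * f.llf for f in fits])
    delta = aic - aic.min()
    w = np.where(delta < cut, np.exp(-0.5 * delta), 0.0)
    w = w / w.sum()
    beta, se = {}, {}
    for j in range(5):
        bs, ss = [], []
        for f, wi in zip(fits, w):
            if j in f.terms:
                i = f.terms.index(j)
                bs.append(f.params[i + 1])
                ss.append(f.ensure_se()[i + 1])
            else:
                bs.append(0.0)
                ss.append(0.0)
        bs, ss = np.array(bs), np.array(ss)
        bbar = float((w * bs).sum())
        beta[j] = bbar
        se[j] = float((w * np.sqrt(ss**2 + (bs - bbar) ** 2)).sum())
    return w, beta, se


class TestModelAveraging:
    def test_single_strong_covariate_singleton_set(self, rng):
        X = rng.normal(size=(2000, 1))
        y = (rng.random(2000) < expit(2.0 * X[:, 0])).astype(float)
        d = DesignMatrix(y=y, X=X, names=("canopy",))
        avg = lc.all_subsets_average(d, mixed=False, cfg=lc.RunConfig(seed=0))
        assert avg.ledger["in_set"].sum() == 1
        full = fit_logistic(d, terms=(0,))
        assert avg.beta["canopy"] == pytest.approx(full.params[1], abs=1e-12)
        assert avg.se["canopy"] == pytest.approx(full.se[1], abs=1e-12)

    def test_equal_weight_average_halves_beta(self):
        # two hand-built candidates tied in AIC, beta present in only one
        from levelcore.models import FittedModel
        f1 = FittedModel(terms=(0,), names=("canopy",),
                         params=np.array([0.0, 0.8]), llf=-100.0, k=2,
                         se=np.array([0.1, 0.2]))
        f2 = FittedModel(terms=(), names=(), params=np.array([0.0]),
                         llf=-101.0, k=1, se=np.array([0.1]))
        w, beta, se = reaverage_oracle([f1, f2], cut=2.0)
        assert np.allclose(w, 0.5)
        assert beta[0] == pytest.approx(0.4)
        # unconditional SE mixes within-model and between-model spread
        assert se[0] == pytest.approx(
            0.5 * np.sqrt(0.2**2 + 0.4**2) + 0.5 * 0.4)

    @pytest.mark.parametrize("mixed", [False, True])
    def test_matches_reimplementation_oracle(self, rng, mixed):
        d = make_design(rng, n=700, beta=(0.6, -0.4, 0.1, 0, 0),
                        sigma_u=0.5 if mixed else 0.0, n_groups=20)
        cfg = lc.RunConfig(seed=0)
        avg = lc.all_subsets_average(d, mixed=mixed, cfg=cfg)
        assert len(avg.ledger) == 32
        assert avg.ledger.loc[avg.ledger["in_set"], "weight"].sum() \
            == pytest.approx(1.0, abs=1e-12)
        # reapply the weight/average formulas to the same 32 fits
        _, beta, se = reaverage_oracle(avg.models, cfg.delta_aic_cut)
        for j, name in enumerate(NAMES):
            assert avg.beta[name] == pytest.approx(beta[j], abs=1e-10)
            assert avg.se[name] == pytest.approx(se[j], abs=1e-10)

    def test_plain_logit_refit_reproduces_average(self, rng):
        # independent refits (not the stored models) give the same answer
        d = make_design(rng, n=700, beta=(0.6, -0.4, 0.1, 0, 0))
        cfg = lc.RunConfig(seed=0)
        avg = lc.all_subsets_average(d, mixed=False, cfg=cfg)
        import itertools
        fits = [fit_logistic(d, terms=t) for size in range(6)
                for t in itertools.combinations(range(5), size)]
        _, beta, se = reaverage_oracle(fits, cfg.delta_aic_cut)
        for j, name in enumerate(NAMES):
            assert avg.beta[name] == pytest.approx(beta[j], abs=1e-7)
            assert avg.se[name] == pytest.approx(se[j], abs=1e-7)


class TestWaldAndMarginal:
    def _avg(self, beta, se, names=NAMES):
        from levelcore.models import AveragedModel
        return AveragedModel(
            names=names, beta=dict(zip(names, beta)),
            se=dict(zip(names, se)),
            ci={n: (b - 1.96 * s, b + 1.96 * s)
                for n, b, s in zip(names, beta, se)},
            intercept=0.2, intercept_se=0.1, ledger=pd.DataFrame())

    def test_equal_betas_give_w_zero_p_one(self):
        a = self._avg([0.5] * 5, [0.1] * 5)
        out = lc.wald_level_test(a, a)
        assert (out["W"] == 0).all()
        assert (out["p"] == 1).all()

    def test_closed_form_example(self):
        a = self._avg([3.0, 0, 0, 0, 0], [1.0] * 5)
        b = self._avg([0.0] * 5, [1.0] * 5)
        out = lc.wald_level_test(a, b)
        assert out["W"][0] == pytest.approx(4.5)
        assert out["p"][0] == pytest.approx(chi2.sf(4.5, 1), abs=1e-10)
        assert out["p"][0] == pytest.approx(0.0339, abs=2e-4)

    def test_flat_curve_at_zero_betas(self):
        a = self._avg([0.0] * 5, [0.1] * 5)
        curve = lc.marginal_effects(a, "canopy", np.linspace(-2, 2, 9))
        assert np.allclose(curve["prob"], expit(0.2))

    def test_positive_beta_monotone_curve(self):
        a = self._avg([0.8, 0, 0, 0, 0], [0.1] * 5)
        curve = lc.marginal_effects(a, "canopy", np.linspace(-2, 2, 21))
        assert np.all(np.diff(curve["prob"]) > 0)

    def test_ci_width_matches_delta_method_oracle(self):
        a = self._avg([0.8, 0, 0, 0, 0], [0.25] * 5)
        curve = lc.marginal_effects(a, "canopy", np.array([0.0, 1.5]))
        # at x=0 the linear-predictor SE is the intercept SE alone
        from scipy.stats import norm
        z = norm.ppf(0.975)
        at0 = curve.iloc[0]
        assert at0["ci_hi"] == pytest.approx(expit(0.2 + z * 0.1), abs=1e-12)
        at15 = curve.iloc[1]
        se = np.sqrt(0.1**2 + 1.5**2 * 0.25**2)
        assert at15["ci_lo"] == pytest.approx(
            expit(0.2 + 1.5 * 0.8 - z * se), abs=1e-12)
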