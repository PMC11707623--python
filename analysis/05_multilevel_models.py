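"""Level-contrasted resource-utilization models.

Pooled logistic regression (individual level) and random-intercept
logistic regression (population level, season intercept) of core use on
the z-scored covariates; all 32 covariate subsets fit per level and
full-model-averaged within Delta-AIC < 2; per-covariate Wald chi-square
contrast between the levels; marginal-effect curves for plotting.
"""

import json

import numpy as np
import pandas as pd

import levelcore as lc

from common import RUN, outdir


def main() -> None:
    out = outdir()
    labels = pd.read_csv(out / "core_labels.csv")
    ind_design, pop_design = lc.standardize(labels)

    vifs = lc.vif(ind_design, RUN.vif_max)
    vifs.to_csv(out / "vif.csv", index=False)
    print("collinearity screen (VIF):",
          {r.covariate: round(r.vif, 2) for r in vifs.itertuples()},
          "— all <", RUN.vif_max if not vifs.flagged.any() else "FLAGGED")

    avg_ind = lc.all_subsets_average(ind_design, mixed=False, cfg=RUN,
                                     level="individual")
    avg_pop = lc.all_subsets_average(pop_design, mixed=True, cfg=RUN,
                                     level="population")
    for avg, name in ((avg_ind, "individual"), (avg_pop, "population")):
        avg.ledger.to_json(out / f"model_ledger_{name}.json", orient="records",
                           indent=2)
        n_set = int(avg.ledger.in_set.sum())
        print(f"{name}: {len(avg.ledger)} candidate models, "
              f"{n_set} within dAIC<{RUN.delta_aic_cut} averaged")

    contrast = lc.wald_level_test(avg_ind, avg_pop)
    contrast.to_csv(out / "level_contrast.csv", index=False)
    print("\nmodel-averaged effects on the log-odds of core use:")
    print("covariate    beta_ind [95% CI]        beta_pop [95% CI]"
          "        Wald W      p")
    for r in contrast.itertuples():
        star = "*" if r.p < 0.05 else " "
        print(f"{r.covariate:11s} {r.beta_ind:6.2f} "
              f"[{r.ci_ind_lo:5.2f},{r.ci_ind_hi:5.2f}]   "
              f"{r.beta_pop:6.2f} [{r.ci_pop_lo:5.2f},{r.ci_pop_hi:5.2f}]   "
              f"{r.W:7.2f}  {r.p:.4f}{star}")

    grid = np.linspace(-2.5, 2.5, 41)
    curves = []
    for cov in lc.COVARIATES:
        for avg, level in ((avg_ind, "individual"), (avg_pop, "population")):
            c = lc.marginal_effects(avg, cov, grid)
            c.insert(0, "covariate", cov)
            c.insert(1, "level", level)
            curves.append(c)
    pd.concat(curves, ignore_index=True).to_csv(
        out / "marginal_effects.csv", index=False)

    sigma = avg_pop.ledger.iloc[0]["sigma_u"]
    print(f"\npopulation-model random-intercept sd (top model): {sigma:.2f}")
    with open(out / "averaged_models.json", "w") as fh:
        json.dump({lvl: {"beta": a.beta, "se": a.se,
                         "intercept": a.intercept}
                   for lvl, a in (("individual", avg_ind),
                                  ("population", avg_pop))}, fh, indent=2)


if __name__ == "__main__":
    main()
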