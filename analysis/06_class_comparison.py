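"""Core-habitat composition by reproductive class and by level.

Model 1: multinomial logit of reproductive class (reference gravid
female) on the covariates over individual-core observations.  Model 2:
multinomial logit of ecological level (reference individual), each
observation contributing once per level at which it is core.  Pairwise
estimated-marginal-mean contrasts at average habitat, Bartlett-checked
PCA of core covariates, and bootstrap class summaries.
"""

import pandas as pd

import levelcore as lc
from levelcore.classes import level_rows, multinomial_coef_table

from common import RUN, SEED, outdir


def main() -> None:
    out = outdir()
    labels = pd.read_csv(out / "core_labels.csv")
    ind_core = labels[labels["core_ind"] == 1].reset_index(drop=True)

    # Model 1: class composition of individual core habitats
    m1 = lc.fit_multinomial(ind_core, "repro_class", "gravid_female")
    tab1 = multinomial_coef_table(m1)
    tab1.to_csv(out / "multinomial_class.csv", index=False)
    print(f"Model 1 (n={len(ind_core)} individual-core observations, "
          "reference gravid_female):")
    for r in tab1[tab1.term != "intercept"].itertuples():
        if r.p < 0.05:
            print(f"  {r.group:17s} {r.term:11s} beta={r.estimate:6.2f} "
                  f"+- {r.se:.2f}  p={r.p:.4f}")
    emm1, pw1 = lc.emm_pairwise(m1)
    pw1.to_csv(out / "emm_pairwise_class.csv", index=False)
    print("  pairwise EMM contrasts:",
          [(r.group_a, r.group_b, round(r.difference, 2),
            "sig" if r.significant else "ns") for r in pw1.itertuples()])

    # Model 2: individual vs population core habitats
    lvl = level_rows(labels)
    m2 = lc.fit_multinomial(lvl, "level", "individual")
    multinomial_coef_table(m2).to_csv(out / "multinomial_level.csv",
                                      index=False)
    emm2, pw2 = lc.emm_pairwise(m2)
    pw2.to_csv(out / "emm_pairwise_level.csv", index=False)

    # PCA over individual-core covariates, grouped by class
    X = ind_core[list(lc.COVARIATES)].to_numpy(float)
    pca = lc.pca_core(X, ind_core["repro_class"].to_numpy())
    chi2_stat, df, p = pca.bartlett
    print(f"Bartlett sphericity: chi2={chi2_stat:.1f}, df={df}, p={p:.2g}")
    print(f"PC1+PC2 explain "
          f"{pca.variance_explained[:2].sum():.1f}% of core-habitat "
          f"variance ({pca.variance_explained[0]:.1f} + "
          f"{pca.variance_explained[1]:.1f})")
    pca.loading_table().to_csv(out / "pca_loadings.csv", index=False)
    pca.group_scores.to_csv(out / "pca_group_scores.csv", index=False)
    strong = pca.loading_table().query("pc <= 2 and strong_loading")
    print("  strong loadings (|loading| >= 0.5):",
          [(r.covariate, r.pc, round(r.loading, 2))
           for r in strong.itertuples()])

    means = lc.class_core_means(ind_core, RUN,
                                rng=lc.stage_rng(SEED, "class_core_means"))
    means.to_csv(out / "class_core_means.csv", index=False)
    wide = means[means.available].pivot(index="covariate",
                                        columns="repro_class",
                                        values="mean").round(1)
    print("bootstrap mean covariate (percent) in class core areas:")
    print(wide.to_string())


if __name__ == "__main__":
    main()
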