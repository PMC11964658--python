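"""Associate predicted brain features with a trait, both from individual
data and from GWAS summary statistics plus a banded LD reference.

Weights are trained on one cohort; the trait, its GWAS, and the LD
reference come from a second, disjoint cohort. The summary-level z-score
(an LD-weighted combination of per-SNP GWAS z-scores) should match the
individual-level regression z.
"""

import numpy as np

import featurexcan as fx

cfg = fx.SimConfig(n=2000, P=1500, K=3, seed=9)
g_all = fx.simulate_genotypes(cfg)
idps, L, R = fx.simulate_idps(g_all, cfg)
train = g_all.subset_samples(np.arange(1000))
cohort = g_all.subset_samples(np.arange(1000, 2000))

X = fx.standardize(train)
db = fx.WeightsDB(variants=list(train.variants))
for k in range(3):
    b = idps[:1000, k] - idps[:1000, k].mean()
    db.add(f"idp_{k}", fx.fit_ridge(b, X, theta=0.2))

y = 0.3 * L[1000:] + np.random.default_rng(1).standard_normal(1000) * np.sqrt(0.91)
y = (y - y.mean()) / y.std()

pred = fx.predict_features(cohort, db)
gwas = fx.run_gwas(y, cohort)
cov = fx.build_banded_cov(cohort, bandwidth=200)

print(f"{'feature':8s} {'z (individual)':>15s} {'z (summary)':>12s}")
summary = fx.associate_summary(gwas, db, cov)
for res in summary:
    ind = fx.associate_individual(pred[res.feature_id].to_numpy(), y,
                                  feature_id=res.feature_id)
    print(f"{res.feature_id:8s} {ind.z:15.3f} {res.z:12.3f}")
# The two columns should agree closely: the summary route needs only GWAS
# statistics and the LD reference, not individual genotypes.

flags, fdr = fx.adjust_multiple(np.array([r.p_raw for r in summary]), "bh", 0.05)
print("BH-significant features:", [r.feature_id for r, f in zip(summary, flags) if f])
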