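"""Train and evaluate one polygenic score end to end.

GWAS on a training split -> LD estimation -> clumping + thresholding with
the threshold tuned on a validation split -> R^2 on a held-out test split.
"""

import prsup as P

model = P.PopulationModel(n_pops=1, m_variants=500, seed=7)
geno = P.simulate_genotypes(model, n_per_pop=2000)
pheno, _ = P.simulate_phenotype(geno, P.SimPhenotypeSpec(h2=0.5, seed=7))

train, test, val = P.split_data(geno, pheno, P.SplitSpec(seed=7))
g_train, g_test, g_val = (geno.subset_samples(ids) for ids in (train, test, val))
y_train, y_test, y_val = (pheno.subset(ids) for ids in (train, test, val))

ss = P.marginal_gwas(g_train, y_train)
ld = P.estimate_ld(g_train)

grid = P.adjust_pt(ss, ld)                      # one effect set per threshold
prs_val = {t: P.score(g_val, eff) for t, eff in grid.items()}
best, val_scores = P.tune(prs_val, y_val)

r2 = P.r2_metric(P.score(g_test, grid[best]), y_test)
print(f"tuned p-value threshold: {best:g} "
      f"(validation R^2 {val_scores[best]:.3f})")
print(f"test R^2: {r2:.3f}")
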