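"""Multiple-population strategy: combine per-population predictors with NNLS.

Each source population contributes its own summary statistics; predictors
are adjusted and tuned on the target's validation split, combined with
non-negative least-squares weights fit on the same split, and the combined
score is evaluated on the held-out test split.
"""

import prsup as P

model = P.PopulationModel(n_pops=3, fst=0.1, m_variants=300, seed=5)
geno = P.simulate_genotypes(model, n_per_pop=800)
genos = {p: geno.subset_samples(
            [s for s, q in zip(geno.samples, geno.population) if q == p])
         for p in dict.fromkeys(geno.population)}
phenos, _ = P.simulate_phenotype_multi(genos, P.SimPhenotypeSpec(h2=0.5, seed=5))

target, aux1, aux2 = genos  # AFR is the under-represented target
aux_ss = {p: P.marginal_gwas(genos[p], phenos[p]) for p in (aux1, aux2)}

recipes = [
    [(target, "pt")],                                  # target-only baseline
    [(target, "pt"), (aux1, "pt"), (aux2, "pt")],      # 3-population combination
]
records = P.run_multi_population(
    target, genos[target], aux_ss, recipes,
    P.SplitSpec(n_folds=5, seed=5), target_pheno=phenos[target])

summary = P.summarize_multi(records, baseline_labels=[f"pt_{target}"])
print(summary.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
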