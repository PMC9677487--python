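"""Simulate a two-population cohort and inspect its structure.

The generator draws ancestral allele frequencies, diversifies them per
population under a Balding-Nichols model at the requested F_ST, lays down
local LD in blocks, and pairs the genotypes with a quantitative phenotype
whose genetic share of variance equals the requested heritability.
"""

import numpy as np

import prsup as P

model = P.PopulationModel(n_pops=2, fst=0.1, m_variants=500,
                          ld_block_len=20, ld_rho=0.9, seed=42)
geno = P.simulate_genotypes(model, n_per_pop=1000)
pheno, effects = P.simulate_phenotype(geno, P.SimPhenotypeSpec(h2=0.5, seed=42))

print(f"cohort: {geno.n_samples} samples x {geno.n_variants} variants")
print(f"populations: {sorted(set(geno.population))}")
print(f"causal variants: {effects.n_causal} "
      f"({effects.n_causal / geno.n_variants:.0%} of the panel)")

# a single replicate is noisy; average a few to see the calibration
z = geno.standardized()
ratios, totals = [], []
for seed in range(10):
    p, e = P.simulate_phenotype(geno, P.SimPhenotypeSpec(h2=0.5, seed=seed))
    y = p.values.to_numpy()
    ratios.append(np.var(z @ e.beta) / np.var(y))
    totals.append(np.var(y))
print(f"over 10 replicates: mean Var(y) = {np.mean(totals):.3f}   "
      f"mean Var(g)/Var(y) = {np.mean(ratios):.3f}")

# the fixture writer produces the same data as PLINK + TSV files:
#   P.make_fixture("two_pop_meta", "fixtures/", seed=42)
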