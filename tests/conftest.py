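import numpy as np
import pandas as pd
import pytest

import prsup as P


def make_geno(dosages, chrom="1", pos=None, ids=None, samples=None,
              eff="A", oth="G", population=None):
    """Small hand-built GenotypeMatrix helper."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame({
        "id": ids or [f"v{j}" for j in range(m)],
        "chrom": chrom,
        "pos": pos if pos is not None else 1 + np.arange(m) * 1000,
        "effect_allele": eff if isinstance(eff, list) else [eff] * m,
        "other_allele": oth if isinstance(oth, list) else [oth] * m,
    })
    samples = samples or [f"s{i}" for i in range(n)]
    return P.GenotypeMatrix(d, variants, samples, population)


def make_pheno(values, samples=None):
    samples = samples or [f"s{i}" for i in range(len(values))]
    return P.PhenotypeTable(pd.Series(np.asarray(values, dtype=float),
                                      index=pd.Index(samples)))


@pytest.fixture(scope="session")
def sim_cohort():
    """One simulated 2-population cohort reused across method tests."""
    model = P.PopulationModel(n_pops=2, m_variants=400, ld_block_len=20,
                              ld_rho=0.9, fst=0.1, seed=1)
    geno = P.simulate_genotypes(model, 500)
    pheno, effects = P.simulate_phenotype(geno, P.SimPhenotypeSpec(seed=2))
    ss = P.marginal_gwas(geno, pheno)
    ld = P.estimate_ld(geno, window_kb=50)
    return {"geno": geno, "pheno": pheno, "effects": effects, "ss": ss, "ld": ld}
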