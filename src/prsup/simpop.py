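"""Multi-population genotype simulation and the quantitative-trait simulator.

Genotypes follow a Balding–Nichols construction: each variant has a shared
ancestral allele frequency, and each population draws its own frequency from
a Beta distribution whose spread is governed by the differentiation parameter
``fst``.  Local linkage disequilibrium is induced by a latent Gaussian AR(1)
process within fixed-length blocks, thresholded per haplotype at the
population allele frequency; an individual's dosage is the sum of two
independent haploid draws.

Phenotypes follow the additive model: a fraction of variants (default 10%)
is causal, each causal effect is drawn from N(0, h²/M) on the
column-standardized genotype scale (M = number of causal variants), and the
residual is N(0, 1−h²), so the total phenotypic variance is 1 in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .genodata import GenotypeMatrix, PhenotypeTable, write_phenotype, write_plink

_POP_NAMES = ["AFR", "EAS", "EUR", "SAS", "VN"]


@dataclass
class PopulationModel:
    """Parameters of the multi-population genotype generator."""

    n_pops: int = 2
    fst: float = 0.1
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_len: int = 20
    ld_rho: float = 0.9
    m_variants: int = 1000
    spacing_bp: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must be in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if self.m_variants < self.ld_block_len:
            raise ValueError("m_variants must be >= ld_block_len")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must lie within (0, 0.5]")


@dataclass
class SimPhenotypeSpec:
    """Heritability model of the simulated quantitative trait."""

    h2: float = 0.5
    causal_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError("h2 must be in [0, 1]")
        if not 0 < self.causal_fraction <= 1:
            raise ValueError("causal_fraction must be in (0, 1]")


@dataclass
class TrueEffects:
    """Causal variant indices and their standardized-scale effects."""

    causal_idx: np.ndarray
    beta: np.ndarray  # length m_variants; zero off the causal set

    @property
    def n_causal(self) -> int:
        return len(self.causal_idx)


def _haplotypes(rng, n_hap: int, thresholds: np.ndarray, block_len: int,
                rho: float) -> np.ndarray:
    """Threshold a blockwise-AR(1) latent Gaussian into 0/1 haploid alleles."""
    m = len(thresholds)
    z = np.empty((n_hap, m))
    start = 0
    while start < m:
        stop = min(start + block_len, m)
        z[:, start] = rng.standard_normal(n_hap)
        for j in range(start + 1, stop):
            z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * rng.standard_normal(n_hap)
        start = stop
    return (z < thresholds).astype(float)


def simulate_genotypes(model: PopulationModel, n_per_pop: int) -> GenotypeMatrix:
    """Simulate diploid hard-call genotypes for ``model.n_pops`` populations.

    Deterministic given ``model.seed``.  Population labels are AFR/EAS/EUR/
    SAS/VN in order (``popK`` beyond five).
    """
    if n_per_pop < 2:
        raise ValueError("n_per_pop must be >= 2")
    rng = np.random.default_rng(model.seed)
    m = model.m_variants
    lo, hi = model.ancestral_maf_range
    p_anc = rng.uniform(lo, hi, size=m)

    dosage_blocks, samples, pops = [], [], []
    for k in range(model.n_pops):
        name = _POP_NAMES[k] if k < len(_POP_NAMES) else f"pop{k}"
        if model.fst > 0:
            a = p_anc * (1 - model.fst) / model.fst
            b = (1 - p_anc) * (1 - model.fst) / model.fst
            p_pop = rng.beta(a, b)
        else:
            p_pop = p_anc.copy()
        p_pop = np.clip(p_pop, 1e-3, 1 - 1e-3)
        thresh = norm.ppf(p_pop)
        h1 = _haplotypes(rng, n_per_pop, thresh, model.ld_block_len, model.ld_rho)
        h2 = _haplotypes(rng, n_per_pop, thresh, model.ld_block_len, model.ld_rho)
        dosage_blocks.append(h1 + h2)
        samples += [f"{name}_{i}" for i in range(n_per_pop)]
        pops += [name] * n_per_pop

    variants = pd.DataFrame({
        "id": [f"snp{j}" for j in range(m)],
        "chrom": "1",
        "pos": 1 + np.arange(m) * model.spacing_bp,
        "effect_allele": "A",
        "other_allele": "G",
    })
    return GenotypeMatrix(np.vstack(dosage_blocks), variants, samples,
                          np.array(pops, dtype=object))


def draw_true_effects(m_variants: int, spec: SimPhenotypeSpec,
                      rng: np.random.Generator) -> TrueEffects:
    """Draw the causal set (uniform) and N(0, h²/M) standardized effects."""
    n_causal = int(round(spec.causal_fraction * m_variants))
    causal = np.sort(rng.choice(m_variants, size=n_causal, replace=False))
    beta = np.zeros(m_variants)
    if spec.h2 > 0 and n_causal > 0:
        beta[causal] = rng.normal(0.0, np.sqrt(spec.h2 / n_causal), size=n_causal)
    return TrueEffects(causal, beta)


def simulate_phenotype(geno: GenotypeMatrix, spec: SimPhenotypeSpec,
                       effects: TrueEffects | None = None):
    """Simulate a quantitative trait on ``geno`` under the additive model.

    ``y_i = Σ_c z_ic β_c + e_i`` with ``z`` the column-standardized dosages,
    ``β_c ~ N(0, h²/M)`` over a uniformly drawn 10% (default) causal set and
    ``e ~ N(0, 1−h²)``.  Pass ``effects`` to reuse a causal architecture
    across cohorts (shared causal variants between populations).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sd = np.nanstd(geno.imputed(), axis=0)
    if spec.h2 > 0 and not (sd > 0).any():
        raise ValueError("h2 > 0 but every variant is monomorphic")
    if effects is None:
        effects = draw_true_effects(geno.n_variants, spec, rng)
    z = geno.standardized()
    g = z @ effects.beta
    e = rng.normal(0.0, np.sqrt(1 - spec.h2), size=geno.n_samples)
    values = pd.Series(g + e, index=pd.Index(geno.samples), name="phenotype")
    return PhenotypeTable(values), effects


def simulate_phenotype_multi(genos: dict[str, GenotypeMatrix],
                             spec: SimPhenotypeSpec):
    """Shared-architecture phenotypes for several cohorts on one panel.

    Causal variants and true effects are drawn once and applied to every
    cohort (standardizing within cohort); residuals are independent.  All
    cohorts must share the variant count.
    """
    sizes = {g.n_variants for g in genos.values()}
    if len(sizes) != 1:
        raise ValueError("cohorts must share a variant panel")
    rng = np.random.default_rng(spec.seed)
    effects = draw_true_effects(sizes.pop(), spec, rng)
    phenos = {}
    for name, geno in genos.items():
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub = SimPhenotypeSpec(spec.h2, spec.causal_fraction, seed=sub_seed)
        phenos[name], _ = simulate_phenotype(geno, sub, effects=effects)
    return phenos, effects


def make_fixture(scenario: str, outdir, seed: int = 0, n_per_pop: int = 300,
                 m_variants: int = 300) -> dict:
    """Write a small on-disk benchmark fixture (PLINK + phenotype + sumstats).

    Scenarios: ``single_pop`` (one cohort), ``two_pop_meta`` (two cohorts on a
    shared panel), ``three_pop_multi`` (three cohorts plus per-population
    summary statistics from the GWAS engine).  A YAML manifest records seeds
    and parameters.
    """
    from .gwas import GwasConfig, marginal_gwas  # deferred: avoids cycle
    from .genodata import write_sumstats

    n_pops = {"single_pop": 1, "two_pop_meta": 2, "three_pop_multi": 3}.get(scenario)
    if n_pops is None:
        raise ValueError(f"unknown scenario {scenario!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = PopulationModel(n_pops=n_pops, m_variants=m_variants, seed=seed)
    geno = simulate_genotypes(model, n_per_pop)
    spec = SimPhenotypeSpec(seed=seed + 1)
    pop_names = list(dict.fromkeys(geno.population))
    genos = {p: geno.subset_samples([s for s, q in zip(geno.samples, geno.population)
                                     if q == p]) for p in pop_names}
    phenos, effects = simulate_phenotype_multi(genos, spec)

    manifest = {"scenario": scenario, "seed": seed, "n_per_pop": n_per_pop,
                "m_variants": m_variants, "h2": spec.h2,
                "causal_fraction": spec.causal_fraction, "populations": pop_names,
                "files": {}}
    for p in pop_names:
        write_plink(genos[p], outdir / p)
        write_phenotype(phenos[p], outdir / f"{p}.pheno", population=genos[p].population)
        manifest["files"][p] = {"plink": f"{p}.bed/.bim/.fam", "pheno": f"{p}.pheno"}
        if scenario == "three_pop_multi":
            ss = marginal_gwas(genos[p], phenos[p], GwasConfig())
            write_sumstats(ss, outdir / f"{p}.sumstats.tsv")
            manifest["files"][p]["sumstats"] = f"{p}.sumstats.tsv"
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return manifest
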