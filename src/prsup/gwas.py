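"""Marginal per-variant association: the step that turns a training cohort
into GWAS summary statistics.

Each variant is fit by ordinary least squares of the phenotype on the
(standardized, mean-imputed) dosage plus an intercept; optional covariates
are projected out of both phenotype and genotype first, with the residual
degrees of freedom adjusted accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import (GenotypeMatrix, PhenotypeTable, SUMSTATS_COLUMNS,
                       ConsistencyError, merge_populations)


@dataclass
class GwasConfig:
    """Association-model options.

    ``standardize`` reports effects on the standardized-genotype scale
    (scale-free in the raw dosage units); ``covariates`` names phenotype-table
    columns to residualize out.
    """

    standardize: bool = True
    covariates: list[str] = field(default_factory=list)


def marginal_gwas(geno: GenotypeMatrix, pheno: PhenotypeTable,
                  cfg: GwasConfig | None = None) -> pd.DataFrame:
    """Per-variant OLS association scan; returns the internal sumstats schema.

    Monomorphic variants are emitted with beta 0, infinite SE and p = 1.
    """
    cfg = cfg or GwasConfig()
    shared = [s for s in geno.samples if s in pheno.values.index]
    if len(shared) < 3:
        raise ConsistencyError("need at least 3 samples shared by genotype and phenotype")
    sub = geno.subset_samples(shared) if len(shared) != geno.n_samples else geno
    y = pheno.aligned(sub.samples)
    if np.std(y) == 0:
        raise ValueError("phenotype is constant")

    x = sub.imputed()
    eaf = sub.eaf()
    n = sub.n_samples
    df_resid = n - 2

    if cfg.covariates:
        if pheno.covariates is None:
            raise ConsistencyError("covariates requested but none in phenotype table")
        missing = [c for c in cfg.covariates if c not in pheno.covariates.columns]
        if missing:
            raise ConsistencyError(f"covariate columns absent: {missing}")
        c = pheno.covariates.loc[sub.samples, cfg.covariates].to_numpy(dtype=float)
        design = np.column_stack([np.ones(n), c])
        proj, *_ = np.linalg.lstsq(design, np.column_stack([y, x]), rcond=None)
        resid = np.column_stack([y, x]) - design @ proj
        y, x = resid[:, 0], resid[:, 1:]
        df_resid = n - 2 - c.shape[1]

    mu = x.mean(axis=0)
    xc = x - mu
    sd = xc.std(axis=0)
    poly = sd > 0
    if cfg.standardize:
        xc[:, poly] = xc[:, poly] / sd[poly]

    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxy = xc.T @ yc
    beta = np.zeros(len(sxx))
    beta[poly] = sxy[poly] / sxx[poly]
    rss = (yc @ yc) - beta * sxy
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(np.maximum(rss, 0.0) / df_resid / sxx)
        tval = beta / se
    p = 2.0 * stats.t.sf(np.abs(tval), df_resid)
    beta[~poly], p[~poly] = 0.0, 1.0
    se[~poly] = np.inf
    p = np.clip(np.where(np.isnan(p), 1.0, p), np.finfo(float).tiny, 1.0)

    out = sub.variants.copy()
    out["eaf"] = eaf
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["n"] = n
    return out[SUMSTATS_COLUMNS]


def meta_population_gwas(geno_a, geno_b, pheno_a, pheno_b,
                         cfg: GwasConfig | None = None) -> pd.DataFrame:
    """Association scan on the pooled (meta-population) individual-level data.

    Equivalent to :func:`marginal_gwas` on the output of
    :func:`~prsup.genodata.merge_populations`; the ``n`` column reflects the
    combined sample count.
    """
    merged, pheno = merge_populations(geno_a, geno_b, pheno_a, pheno_b)
    return marginal_gwas(merged, pheno, cfg)
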