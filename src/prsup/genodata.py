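"""Genotype/summary-statistic data model, PLINK I/O, QC, harmonization and merging.

The central container is :class:`GenotypeMatrix`: an ``n_samples x n_variants``
dosage matrix counting copies of the effect allele (``0/1/2``, ``NaN`` for
missing hard calls) together with variant metadata and per-sample population
labels.  Summary statistics are carried as a plain :class:`pandas.DataFrame`
with a fixed internal schema (see :data:`SUMSTATS_COLUMNS`).

Individual-level data from several populations can be pooled into a
"meta-population" with :func:`merge_populations`: variants are intersected on
(chromosome, position, unordered allele pair), allele orientation is
harmonized to the first cohort, and samples are concatenated.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele"]
SUMSTATS_COLUMNS = ["id", "chrom", "pos", "effect_allele", "other_allele",
                    "eaf", "beta", "se", "p", "n"]

#: complementary bases; a variant whose two alleles are complements (A/T, C/G)
#: cannot be strand-resolved from alleles alone.
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


class ConsistencyError(ValueError):
    """Mutually inconsistent inputs (counts, ids, panels)."""


@dataclass
class GenotypeMatrix:
    """Samples x variants effect-allele dosage matrix with metadata.

    Attributes
    ----------
    dosages : ndarray of float, shape (n_samples, n_variants)
        Counts of the effect allele in {0, 1, 2}; ``NaN`` marks a missing call.
    variants : DataFrame
        One row per variant with columns ``id, chrom, pos, effect_allele,
        other_allele``, ordered by (chromosome, position).
    samples : list of str
        Unique sample identifiers.
    population : ndarray of str
        Per-sample population label, aligned with ``samples``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]
    population: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.variants = self.variants.reset_index(drop=True)
        self.samples = list(self.samples)
        if self.population is None:
            self.population = np.array(["pop0"] * len(self.samples))
        else:
            self.population = np.asarray(self.population, dtype=object)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.dosages.shape
        if len(self.samples) != n:
            raise ConsistencyError(f"{len(self.samples)} sample ids for {n} dosage rows")
        if len(self.variants) != m:
            raise ConsistencyError(f"{len(self.variants)} variant rows for {m} dosage columns")
        if len(self.population) != n:
            raise ConsistencyError("population labels do not match sample count")
        if len(set(self.samples)) != n:
            raise ConsistencyError("duplicate sample ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ConsistencyError("dosages must be 0/1/2 or missing")
        v = self.variants
        if (v["effect_allele"] == v["other_allele"]).any():
            raise ConsistencyError("effect allele equals other allele")
        if (v["pos"] < 1).any():
            raise ConsistencyError("positions must be >= 1")
        key = list(zip(v["chrom"].astype(str), v["pos"].astype(int)))
        if key != sorted(key, key=lambda t: (_chrom_sort_key(t[0]), t[1])):
            raise ConsistencyError("variants not ordered by (chromosome, position)")

    # -- convenience ------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        """Effect-allele frequency per variant, over non-missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def imputed(self) -> np.ndarray:
        """Dosages with missing calls replaced by the per-variant mean."""
        x = self.dosages.copy()
        if np.isnan(x).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                col_mean = np.nanmean(x, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.where(np.isnan(x))
            x[idx] = col_mean[idx[1]]
        return x

    def standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized dosages (sd-0 columns set to 0)."""
        x = self.imputed()
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
        z = np.zeros_like(x)
        ok = sd > 0
        z[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
        return z

    def subset_samples(self, ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        rows = [index[s] for s in ids]
        return GenotypeMatrix(self.dosages[rows], self.variants.copy(),
                              list(ids), self.population[rows])

    def subset_variants(self, cols) -> "GenotypeMatrix":
        cols = np.asarray(cols)
        return GenotypeMatrix(self.dosages[:, cols],
                              self.variants.iloc[cols].reset_index(drop=True),
                              list(self.samples), self.population.copy())


def _chrom_sort_key(c: str):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass
class PhenotypeTable:
    """Quantitative phenotype (and optional covariates) keyed by sample id."""

    values: pd.Series  # index: sample id
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ConsistencyError("duplicate sample ids in phenotype table")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ConsistencyError("non-finite phenotype values")

    def aligned(self, sample_ids) -> np.ndarray:
        return self.values.reindex(sample_ids).to_numpy(dtype=float)

    def subset(self, ids) -> "PhenotypeTable":
        cov = self.covariates.loc[list(ids)] if self.covariates is not None else None
        return PhenotypeTable(self.values.loc[list(ids)], cov)


@dataclass
class DataBundle:
    """Pipeline state: the five input layers and five processed layers.

    Input layers hold the raw material of one benchmarking run (training
    summary statistics, test/validation genotypes and their phenotypes);
    processed layers are populated as the pipeline stages run.
    """

    sumstats: pd.DataFrame | None = None
    test: GenotypeMatrix | None = None
    validation: GenotypeMatrix | None = None
    phenotype: PhenotypeTable | None = None
    phenotype_val: PhenotypeTable | None = None
    # processed layers
    adjusted_ss: dict = field(default_factory=dict)
    prs_validation: dict = field(default_factory=dict)
    prs_test: dict = field(default_factory=dict)
    tuning: dict = field(default_factory=dict)
    performance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PLINK 1 BED/BIM/FAM I/O
# ---------------------------------------------------------------------------

def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK 1 ``.bed/.bim/.fam`` triplet (SNP-major hard calls).

    Dosages count the BIM A1 allele.  The FAM family id column is used as the
    population label.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "pheno"],
                      dtype={"fid": str, "iid": str})
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:3].hex()}")
    n, m = len(fam), len(bim)
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_variant * m:
        raise ConsistencyError(
            f"{prefix}.bed: {body.size} payload bytes, expected {bytes_per_variant * m}")
    codes = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    two_bit = two_bit.reshape(m, -1)[:, :n]  # variants x samples
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[two_bit].T  # samples x variants
    variants = pd.DataFrame({
        "id": bim["id"], "chrom": bim["chrom"], "pos": bim["pos"].astype(int),
        "effect_allele": bim["a1"], "other_allele": bim["a2"],
    })
    return GenotypeMatrix(dosages, variants, list(fam["iid"]),
                          fam["fid"].to_numpy(dtype=object))


def write_plink(geno: GenotypeMatrix, prefix) -> None:
    """Write ``geno`` as a PLINK 1 SNP-major BED/BIM/FAM triplet."""
    if geno.n_variants == 0:
        raise ValueError("refusing to write a PLINK fileset with zero variants")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    v = geno.variants
    bim = pd.DataFrame({"chrom": v["chrom"], "id": v["id"], "cm": 0,
                        "pos": v["pos"], "a1": v["effect_allele"],
                        "a2": v["other_allele"]})
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": geno.population, "iid": geno.samples,
                        "pat": 0, "mat": 0, "sex": 0, "pheno": -9})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n, m = geno.n_samples, geno.n_variants
    d = geno.dosages.T  # variants x samples
    two_bit = np.full(d.shape, 1, dtype=np.uint8)  # 01 = missing
    two_bit[d == 2] = 0b00
    two_bit[d == 1] = 0b10
    two_bit[d == 0] = 0b11
    pad = (-n) % 4
    if pad:
        two_bit = np.concatenate(
            [two_bit, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    two_bit = two_bit.reshape(m, -1, 4)
    packed = (two_bit[:, :, 0] | (two_bit[:, :, 1] << 2)
              | (two_bit[:, :, 2] << 4) | (two_bit[:, :, 3] << 6)).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Summary statistics I/O
# ---------------------------------------------------------------------------

_DEFAULT_COLUMN_MAP = {
    "id": ["SNP", "ID", "RSID", "MARKERNAME", "VARIANT_ID"],
    "chrom": ["CHR", "CHROM", "CHROMOSOME"],
    "pos": ["BP", "POS", "POSITION"],
    "effect_allele": ["A1", "ALT", "EFFECT_ALLELE", "EA"],
    "other_allele": ["A2", "REF", "OTHER_ALLELE", "OA", "NEA"],
    "eaf": ["FRQ", "EAF", "FREQ", "AF", "MAF"],
    "beta": ["BETA", "B", "EFFECT", "OR"],
    "se": ["SE", "STDERR"],
    "p": ["P", "PVAL", "P_VALUE", "PVALUE"],
    "n": ["N", "NMISS", "N_SAMPLES"],
}


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistics table into the internal schema.

    ``column_map`` optionally maps internal names (``beta``, ``p`` ...) to the
    file's header names; common dialects (A1/ALT, BETA/OR) resolve
    automatically.  An ``OR`` effect column is converted to the log scale.
    Rows with non-positive SE are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    upper = {c.upper(): c for c in df.columns}
    resolved: dict[str, str] = {}
    or_scale = False
    for internal, candidates in _DEFAULT_COLUMN_MAP.items():
        if column_map and internal in column_map:
            cand = [str(column_map[internal]).upper()]
        else:
            cand = candidates
        for c in cand:
            if c in upper:
                resolved[internal] = upper[c]
                if internal == "beta" and c == "OR":
                    or_scale = True
                break
    missing = [k for k in SUMSTATS_COLUMNS if k not in resolved]
    if missing:
        raise FormatError(f"{path}: cannot resolve mandatory columns {missing}")
    out = pd.DataFrame({k: df[v] for k, v in resolved.items()})
    out["chrom"] = out["chrom"].astype(str)
    out["pos"] = out["pos"].astype(int)
    out["id"] = out["id"].astype(str)
    for c in ("eaf", "beta", "se", "p"):
        out[c] = out[c].astype(float)
    out["n"] = out["n"].astype(float).round().astype(int)
    if or_scale:
        out["beta"] = np.log(out["beta"])
    bad = ~(out["se"] > 0)
    if bad.any():
        logger.warning("%s: dropped %d rows with non-positive SE", path, int(bad.sum()))
        out = out[~bad]
    return out[SUMSTATS_COLUMNS].reset_index(drop=True)


def write_sumstats(ss: pd.DataFrame, path) -> None:
    """Write summary statistics as tab-separated text with standard headers."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = ss.rename(columns={"id": "SNP", "chrom": "CHR", "pos": "BP",
                             "effect_allele": "A1", "other_allele": "A2",
                             "eaf": "FRQ", "beta": "BETA", "se": "SE",
                             "p": "P", "n": "N"})
    out.to_csv(path, sep="\t", index=False)


def read_phenotype(path) -> PhenotypeTable:
    """Read a PLINK-dialect whitespace FID/IID/value phenotype file."""
    df = pd.read_csv(path, sep=r"\s+")
    iid = df.columns[1]
    value_col = df.columns[2]
    values = pd.Series(df[value_col].to_numpy(dtype=float),
                       index=df[iid].astype(str), name="phenotype")
    cov = None
    if df.shape[1] > 3:
        cov = df.set_index(df[iid].astype(str)).iloc[:, 3:]
    return PhenotypeTable(values, cov)


def write_phenotype(pheno: PhenotypeTable, path, population=None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fid = population if population is not None else ["0"] * len(pheno.values)
    df = pd.DataFrame({"FID": fid, "IID": pheno.values.index,
                       "PHENO": pheno.values.to_numpy()})
    if pheno.covariates is not None:
        for c in pheno.covariates.columns:
            df[c] = pheno.covariates[c].to_numpy()
    df.to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg p-value for one biallelic variant.

    The test conditions on the observed allele counts and sums, over all
    heterozygote counts of matching parity, the probabilities of
    configurations no more likely than the observed one.  Symmetric in the
    two homozygote labels.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("negative genotype count")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("no genotyped samples")
    n_a = 2 * n_hom1 + n_het          # copies of allele A
    rare = min(n_a, 2 * n - n_a)
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(h | n, allele counts) up to a shared constant
    logp = (hets * np.log(2.0) - gammaln(hom_r + 1) - gammaln(hets + 1)
            - gammaln(hom_c + 1))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[hets == n_het][0]
    # tolerance guards float ties in the "as or less probable" comparison
    return float(min(1.0, prob[prob <= observed * (1 + 1e-12)].sum()))


def qc_filter(geno: GenotypeMatrix, maf_min: float = 0.01,
              hwe_p_min: float = 1e-7, miss_max: float = 0.05) -> GenotypeMatrix:
    """Variant QC: MAF, Hardy-Weinberg and per-variant missingness filters.

    Duplicated variant ids are resolved by keeping the first occurrence.
    Surviving variants satisfy MAF >= ``maf_min``, HWE exact p >= ``hwe_p_min``
    and missing fraction <= ``miss_max``.  Raises if nothing survives.
    """
    if geno.n_variants == 0:
        raise ValueError("empty genotype panel")
    d = geno.dosages
    n = geno.n_samples

    first = ~geno.variants["id"].duplicated(keep="first").to_numpy()
    miss_frac = np.isnan(d).mean(axis=0)
    eaf = geno.eaf()
    maf = np.where(np.isnan(eaf), 0.0, np.minimum(eaf, 1 - eaf))
    hwe = np.ones(geno.n_variants)
    for j in range(geno.n_variants):
        col = d[:, j]
        counts = (int(np.nansum(col == 2)), int(np.nansum(col == 1)),
                  int(np.nansum(col == 0)))
        if sum(counts) >= 1:
            hwe[j] = hwe_exact_p(*counts)
        else:
            hwe[j] = 0.0

    keep = first & (maf >= maf_min) & (hwe >= hwe_p_min) & (miss_frac <= miss_max)
    logger.info("qc_filter: %d/%d variants kept (dup=%d maf=%d hwe=%d miss=%d removed)",
                int(keep.sum()), geno.n_variants, int((~first).sum()),
                int((maf < maf_min).sum()), int((hwe < hwe_p_min).sum()),
                int((miss_frac > miss_max).sum()))
    if not keep.any():
        raise ValueError("QC removed every variant from the panel")
    return geno.subset_variants(np.where(keep)[0])


# ---------------------------------------------------------------------------
# Allele harmonization and merging
# ---------------------------------------------------------------------------

def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(ss: pd.DataFrame, panel: pd.DataFrame) -> pd.DataFrame:
    """Restrict summary statistics to a variant panel, aligning alleles.

    Variants are matched on (chromosome, position).  Where the effect/other
    alleles are swapped relative to the panel, the beta sign is flipped and
    the frequency complemented.  Strand-ambiguous (A/T, C/G) variants and
    variants with irreconcilable alleles are dropped; all drop counts are
    logged.  Output rows follow panel order.
    """
    pan = panel.copy()
    pan["_key"] = list(zip(pan["chrom"].astype(str), pan["pos"].astype(int)))
    lookup = {k: i for i, k in enumerate(pan["_key"])}

    rows, n_absent, n_ambig, n_mismatch, n_flip = [], 0, 0, 0, 0
    for rec in ss.itertuples(index=False):
        key = (str(rec.chrom), int(rec.pos))
        idx = lookup.get(key)
        if idx is None:
            n_absent += 1
            continue
        if _is_ambiguous(rec.effect_allele, rec.other_allele):
            n_ambig += 1
            continue
        p = pan.iloc[idx]
        if (rec.effect_allele, rec.other_allele) == (p["effect_allele"], p["other_allele"]):
            rows.append((idx, rec, False))
        elif (rec.other_allele, rec.effect_allele) == (p["effect_allele"], p["other_allele"]):
            rows.append((idx, rec, True))
            n_flip += 1
        else:
            n_mismatch += 1
    if not rows:
        raise ConsistencyError("no variants shared between sumstats and panel")
    logger.info("harmonize: kept %d (%d sign-flipped); dropped absent=%d "
                "ambiguous=%d allele-mismatch=%d",
                len(rows), n_flip, n_absent, n_ambig, n_mismatch)

    rows.sort(key=lambda t: t[0])
    out = []
    for idx, rec, flip in rows:
        p = pan.iloc[idx]
        out.append({
            "id": p["id"], "chrom": p["chrom"], "pos": int(p["pos"]),
            "effect_allele": p["effect_allele"], "other_allele": p["other_allele"],
            "eaf": 1 - rec.eaf if flip else rec.eaf,
            "beta": -rec.beta if flip else rec.beta,
            "se": rec.se, "p": rec.p, "n": rec.n,
        })
    return pd.DataFrame(out, columns=SUMSTATS_COLUMNS)


def merge_populations(geno_a: GenotypeMatrix, geno_b: GenotypeMatrix,
                      pheno_a: PhenotypeTable | None = None,
                      pheno_b: PhenotypeTable | None = None):
    """Pool two cohorts into a meta-population on their shared variants.

    Variants are intersected on (chromosome, position, unordered allele
    pair); where ``geno_b``'s allele orientation is swapped its dosages are
    recoded (``2 - d``) to count ``geno_a``'s effect allele.  Samples are
    concatenated with population labels preserved.  Returns the merged
    genotypes, and the concatenated phenotype table when phenotypes are given.
    """
    overlap = set(geno_a.samples) & set(geno_b.samples)
    if overlap:
        raise ConsistencyError(f"duplicate sample ids across cohorts: {sorted(overlap)[:5]}")

    def keyed(v):
        return {(str(r.chrom), int(r.pos), frozenset((r.effect_allele, r.other_allele))): i
                for i, r in enumerate(v.itertuples(index=False))}

    ka, kb = keyed(geno_a.variants), keyed(geno_b.variants)
    shared = [k for k in ka if k in kb]
    if not shared:
        raise ConsistencyError("no shared variants between cohorts")
    ia = sorted((ka[k] for k in shared))
    cols_a = np.array(ia)
    cols_b = np.array([kb[k] for k in shared])[np.argsort([ka[k] for k in shared])]

    va = geno_a.variants.iloc[cols_a].reset_index(drop=True)
    vb = geno_b.variants.iloc[cols_b].reset_index(drop=True)
    db = geno_b.dosages[:, cols_b].copy()
    swapped = (vb["effect_allele"].to_numpy() == va["other_allele"].to_numpy())
    if swapped.any():
        db[:, swapped] = 2.0 - db[:, swapped]

    merged = GenotypeMatrix(
        np.vstack([geno_a.dosages[:, cols_a], db]), va,
        list(geno_a.samples) + list(geno_b.samples),
        np.concatenate([geno_a.population, geno_b.population]))
    if pheno_a is None and pheno_b is None:
        return merged, None
    values = pd.concat([pheno_a.values, pheno_b.values])
    cov = None
    if pheno_a.covariates is not None and pheno_b.covariates is not None:
        cov = pd.concat([pheno_a.covariates, pheno_b.covariates])
    return merged, PhenotypeTable(values, cov)
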