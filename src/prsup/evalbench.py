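"""Benchmarking harness: splits, hyper-parameter tuning, R², and the two
population-combination study designs.

Meta-population design: for each target population, individual-level data
from the target's training split alone and pooled pairwise with each other
population are used to generate summary statistics and train each PRS
method; hyper-parameters are tuned on the target's test split, and the
final R² is reported on the target's validation split, replicated over
fresh phenotype simulations (the tune-on-test / report-on-validation order
follows the benchmarked protocol; see docs/methods.md).

Multiple-population design: per seeded re-split of the target cohort
(7:1.5:1.5 by default, 20 splits), per-population predictors are adjusted,
tuned on validation, combined with non-negative least-squares weights fit on
validation, and scored on the held-out test split.

Sample-id disjointness between training, tuning and reporting splits is
asserted at every stage boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, PhenotypeTable, harmonize, merge_populations
from .gwas import GwasConfig, marginal_gwas
from .prscore import (AdjustedEffects, DWConfig, LDpredConfig, MixtureConfig,
                      PTConfig, SBayesSConfig, adjust_dw, adjust_ldpred_gibbs,
                      adjust_ldpred_inf, adjust_mixture, adjust_pt,
                      adjust_sbayes_s, estimate_ld, score)
from .combine import MixWeights, PredictorSet, combine_effects, fit_mix_weights
from .simpop import SimPhenotypeSpec, simulate_phenotype, simulate_phenotype_multi

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["strategy", "label", "training", "target", "replicate",
                  "r2", "hyperparameter"]


@dataclass
class SplitSpec:
    """Train/test/validation protocol constants."""

    ratio: tuple = (7.0, 1.5, 1.5)
    n_folds: int = 20
    n_replications: int = 100
    seed: int = 0

    def __post_init__(self):
        if any(r <= 0 for r in self.ratio) or len(self.ratio) != 3:
            raise ValueError("ratio must be three positive parts")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass
class MethodSettings:
    """Per-method hyper-parameter bundles used by the benchmark drivers."""

    h2: float = 0.5
    pt: PTConfig = field(default_factory=PTConfig)
    dw: DWConfig = field(default_factory=DWConfig)
    ldpred: LDpredConfig = field(default_factory=LDpredConfig)
    mixture: MixtureConfig = field(default_factory=MixtureConfig)
    sbayes_s: SBayesSConfig = field(default_factory=SBayesSConfig)
    ld_window_kb: float = 1000.0
    ld_ridge: float = 0.05


KNOWN_METHODS = ("pt", "dw", "ldpred_inf", "ldpred", "mixture", "sbayes_s")


# ---------------------------------------------------------------------------
# Splits and metrics
# ---------------------------------------------------------------------------

def _shares(n: int, ratio) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n samples into the ratio parts."""
    total = sum(ratio)
    raw = [n * r / total for r in ratio]
    sizes = [int(np.floor(x)) for x in raw]
    for _ in range(n - sum(sizes)):
        j = int(np.argmax([x - s for x, s in zip(raw, sizes)]))
        sizes[j] += 1
    return tuple(sizes)


def split_data(geno: GenotypeMatrix, pheno: PhenotypeTable | None,
               spec: SplitSpec, seed: int | None = None):
    """Disjoint, exhaustive train/test/validation partition of sample ids.

    Shuffled deterministically by seed and stratified by population label.
    Raises if any share of any stratum rounds to zero.
    """
    if geno.n_samples < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    train, test, val = [], [], []
    pops = list(dict.fromkeys(geno.population))
    for p in pops:
        ids = [s for s, q in zip(geno.samples, geno.population) if q == p]
        ids = [ids[i] for i in rng.permutation(len(ids))]
        a, b, c = _shares(len(ids), spec.ratio)
        if min(a, b, c) == 0:
            raise ValueError(f"a split share rounds to 0 for population {p}")
        train += ids[:a]
        test += ids[a:a + b]
        val += ids[a + b:]
    return train, test, val


def r2_metric(prs: pd.Series, pheno: PhenotypeTable) -> float:
    """Squared Pearson correlation between PRS and phenotype.

    A constant PRS has undefined correlation and is scored 0 with a warning.
    """
    shared = [s for s in prs.index if s in pheno.values.index]
    if len(shared) < 3:
        raise ValueError("need at least 3 overlapping samples")
    x = prs.loc[shared].to_numpy(dtype=float)
    y = pheno.values.loc[shared].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("constant PRS or phenotype; R2 defined as 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def tune(prs_by_param: dict, pheno_val: PhenotypeTable):
    """Pick the hyper-parameter with the highest validation R².

    Ties break toward the smaller (more conservative) parameter value.
    Returns ``(winning_parameter, {parameter: R²})``.
    """
    if not prs_by_param:
        raise ValueError("no candidates to tune over")
    scores = {param: r2_metric(prs, pheno_val) for param, prs in prs_by_param.items()}
    def sort_key(param):
        try:
            return (float(param),)
        except (TypeError, ValueError):
            return (float("inf"),)
    best = min(scores, key=lambda p: (-scores[p],) + sort_key(p))
    return best, scores


def _assert_no_leak(train_ids, *eval_id_sets) -> None:
    t = set(train_ids)
    for ids in eval_id_sets:
        leaked = t & set(ids)
        if leaked:
            raise AssertionError(f"information leak: {sorted(leaked)[:5]} in both "
                                 "training and evaluation splits")


# ---------------------------------------------------------------------------
# Method dispatch
# ---------------------------------------------------------------------------

def run_adjustment(method: str, ss: pd.DataFrame, ld, settings: MethodSettings,
                   seed: int = 0) -> dict:
    """Run one adjustment method; returns {hyper-parameter: AdjustedEffects}.

    Methods without a tuned grid return a single-entry mapping keyed by a
    descriptive constant.
    """
    if method == "pt":
        return adjust_pt(ss, ld, settings.pt)
    if method == "dw":
        cfg = replace(settings.dw, top_z=min(settings.dw.top_z, len(ss)), seed=seed)
        return {"top_z=%d" % cfg.top_z: adjust_dw(ss, cfg)}
    if method == "ldpred_inf":
        return {"inf": adjust_ldpred_inf(ss, ld, settings.h2)}
    if method == "ldpred":
        cfg = replace(settings.ldpred, h2=settings.h2, seed=seed)
        return adjust_ldpred_gibbs(ss, ld, cfg)
    if method == "mixture":
        cfg = replace(settings.mixture, seed=seed)
        return {"gammas=%s" % (cfg.gammas,): adjust_mixture(ss, ld, cfg)}
    if method == "sbayes_s":
        cfg = replace(settings.sbayes_s, seed=seed)
        return {"S=%g" % cfg.S: adjust_sbayes_s(ss, ld, cfg)}
    raise ValueError(f"unknown method {method!r}; known: {KNOWN_METHODS}")


# ---------------------------------------------------------------------------
# Meta-population benchmark
# ---------------------------------------------------------------------------

def run_meta_population(genos: dict[str, GenotypeMatrix], methods: list[str],
                        spec: SplitSpec,
                        pheno_spec: SimPhenotypeSpec | None = None,
                        settings: MethodSettings | None = None) -> pd.DataFrame:
    """Meta-population benchmark over fresh phenotype replications.

    For every target population, evaluates the single-population baseline and
    each pairwise pooled training set.  Per replication: simulate shared-
    architecture phenotypes, split each cohort, run GWAS and LD estimation on
    the pooled training split, adjust effects per method, tune on the
    target's test split and report R² on its validation split.
    """
    if spec.n_replications < 1:
        raise ValueError("n_replications must be >= 1")
    if len(genos) < 1:
        raise ValueError("need at least one population")
    pheno_spec = pheno_spec or SimPhenotypeSpec()
    settings = settings or MethodSettings(h2=pheno_spec.h2)
    pops = list(genos)
    records = []
    for rep in range(spec.n_replications):
        rep_seed = (spec.seed * 100003 + rep) % (2**31 - 1)
        phenos, _ = simulate_phenotype_multi(
            genos, replace(pheno_spec, seed=rep_seed))
        splits = {p: split_data(genos[p], phenos[p], spec, seed=rep_seed + i)
                  for i, p in enumerate(pops)}
        for target in pops:
            tr_ids, te_ids, va_ids = splits[target]
            geno_te = genos[target].subset_samples(te_ids)
            geno_va = genos[target].subset_samples(va_ids)
            pheno_te = phenos[target].subset(te_ids)
            pheno_va = phenos[target].subset(va_ids)
            configs = [(target,)] + [(target, o) for o in pops if o != target]
            for cfg_pops in configs:
                if len(cfg_pops) == 1:
                    g_tr = genos[target].subset_samples(tr_ids)
                    y_tr = phenos[target].subset(tr_ids)
                else:
                    other = cfg_pops[1]
                    o_tr = splits[other][0]
                    g_tr, y_tr = merge_populations(
                        genos[target].subset_samples(tr_ids),
                        genos[other].subset_samples(o_tr),
                        phenos[target].subset(tr_ids),
                        phenos[other].subset(o_tr))
                _assert_no_leak(g_tr.samples, te_ids, va_ids)
                ss = marginal_gwas(g_tr, y_tr, GwasConfig())
                ld = estimate_ld(g_tr, settings.ld_window_kb, settings.ld_ridge)
                for method in methods:
                    grid = run_adjustment(method, ss, ld, settings, seed=rep_seed)
                    prs_tune = {k: score(geno_te, eff) for k, eff in grid.items()}
                    best, _scores = tune(prs_tune, pheno_te)
                    r2 = r2_metric(score(geno_va, grid[best]), pheno_va)
                    records.append({
                        "strategy": "meta", "label": method,
                        "training": "_".join(cfg_pops), "target": target,
                        "replicate": rep, "r2": r2, "hyperparameter": str(best)})
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def summarize_meta(records: pd.DataFrame) -> pd.DataFrame:
    """Mean R² with a 95% normal-approximation CI over replications."""
    def agg(g):
        n = len(g)
        mean = g["r2"].mean()
        half = 1.96 * g["r2"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series({"mean_r2": mean, "ci95_half": half, "n": n})
    return (records.groupby(["label", "training", "target"])
            .apply(agg, include_groups=False).reset_index())


# ---------------------------------------------------------------------------
# Multiple-population benchmark
# ---------------------------------------------------------------------------

def run_multi_population(target: str, target_geno: GenotypeMatrix,
                         aux_sumstats: dict[str, pd.DataFrame],
                         recipes: list[list[tuple[str, str]]],
                         spec: SplitSpec,
                         target_pheno: PhenotypeTable | None = None,
                         pheno_spec: SimPhenotypeSpec | None = None,
                         settings: MethodSettings | None = None) -> pd.DataFrame:
    """Multiple-population benchmark over seeded target re-splits.

    Per fold: the target cohort is split 7:1.5:1.5; its own summary
    statistics and LD come from the fold's training split, auxiliary
    populations contribute fixed external summary statistics harmonized to
    the target panel.  Per-method hyper-parameters and the NNLS mixing
    weights are fit on the validation split; R² is reported on the test
    split.  ``target_pheno`` may be fixed, or resimulated per fold from
    ``pheno_spec``.
    """
    settings = settings or MethodSettings()
    if target_pheno is None and pheno_spec is None:
        raise ValueError("either target_pheno or pheno_spec is required")
    for recipe in recipes:
        for pop, _m in recipe:
            if pop != target and pop not in aux_sumstats:
                raise ValueError(f"recipe references unknown population {pop!r}")
    needed = sorted({pm for recipe in recipes for pm in recipe})
    records = []
    for fold in range(spec.n_folds):
        fold_seed = (spec.seed * 100003 + fold) % (2**31 - 1)
        if target_pheno is not None:
            pheno = target_pheno
        else:
            pheno, _ = simulate_phenotype(target_geno,
                                          replace(pheno_spec, seed=fold_seed))
        tr_ids, te_ids, va_ids = split_data(target_geno, pheno, spec, seed=fold_seed)
        _assert_no_leak(tr_ids, te_ids, va_ids)
        g_tr = target_geno.subset_samples(tr_ids)
        g_te = target_geno.subset_samples(te_ids)
        g_va = target_geno.subset_samples(va_ids)
        y_tr, y_te, y_va = (pheno.subset(ids) for ids in (tr_ids, te_ids, va_ids))

        target_ss = marginal_gwas(g_tr, y_tr, GwasConfig())
        ld = estimate_ld(g_tr, settings.ld_window_kb, settings.ld_ridge)
        chosen: dict[tuple[str, str], AdjustedEffects] = {}
        for pop, method in needed:
            if pop == target:
                ss = target_ss
            else:
                ss = harmonize(aux_sumstats[pop], target_geno.variants)
            grid = run_adjustment(method, ss, ld, settings, seed=fold_seed)
            prs_val = {k: score(g_va, eff) for k, eff in grid.items()}
            best, _ = tune(prs_val, y_va)
            chosen[(pop, method)] = grid[best]

        for recipe in recipes:
            pset = PredictorSet([(f"{m}_{p}", chosen[(p, m)]) for p, m in recipe])
            weights = fit_mix_weights(pset, g_va, y_va)
            comb = combine_effects(pset, weights)
            prs_test = score(g_te, comb)
            records.append({
                "strategy": "multi", "label": "+".join(pset.labels),
                "training": "+".join(p for p, _ in recipe), "target": target,
                "replicate": fold, "r2": r2_metric(prs_test, y_te),
                "hyperparameter": ";".join(f"{k}={v:.4g}" for k, v in weights.items())})
    return pd.DataFrame(records, columns=RECORD_COLUMNS)


def summarize_multi(records: pd.DataFrame,
                    baseline_labels: list[str] | None = None) -> pd.DataFrame:
    """Per-recipe mean and SD of R² across folds, plus relative accuracy.

    Relative accuracy is each recipe's mean R² divided by the mean R² of the
    baseline models (the benchmark convention: the average of the target
    population's PT and DW models).
    """
    out = (records.groupby("label")["r2"].agg(mean_r2="mean", sd_r2="std", n="count")
           .reset_index())
    if baseline_labels:
        base = out[out["label"].isin(baseline_labels)]["mean_r2"].mean()
        out["relative_accuracy"] = out["mean_r2"] / base if base > 0 else np.nan
    return out


def report(records: pd.DataFrame, outdir, summary: pd.DataFrame | None = None,
           plot: bool = False) -> dict:
    """Write tidy performance records (and optional summary/bar chart) to disk."""
    if records.empty:
        raise ValueError("empty performance table")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"records": outdir / "performance.csv"}
    records.to_csv(paths["records"], index=False)
    if summary is not None:
        paths["summary"] = outdir / "summary.csv"
        summary.to_csv(paths["summary"], index=False)
    if plot and summary is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(summary)), 4))
        ax.bar(summary["label"], summary["mean_r2"],
               yerr=summary.get("sd_r2", summary.get("ci95_half")))
        ax.set_ylabel("$R^2$")
        ax.tick_params(axis="x", rotation=90)
        fig.tight_layout()
        paths["figure"] = outdir / "performance.png"
        fig.savefig(paths["figure"], dpi=150)
        plt.close(fig)
    return paths
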