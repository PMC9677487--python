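"""Cross-population predictor combination with non-negative mixing weights.

The multiple-population strategy trains one predictor per source population
(any adjustment method), then learns a non-negative linear combination of
the predictors on validation data:

    minimize ||y − Σ_j w_j · PRS_j||²   subject to  w_j ≥ 0,

solved by Lawson–Hanson NNLS after centering y and each PRS column (PRS
location is arbitrary, so no intercept enters the weight vector).  Because
scoring is linear in the effect sizes, combining at the effect level
(``β^comb = Σ_j w_j β_j``) and combining the scores themselves are
interchangeable.
"""

from __future__ import annotations

import itertools
import logging
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .genodata import GenotypeMatrix, PhenotypeTable
from .prscore import AdjustedEffects, score

logger = logging.getLogger(__name__)


class PredictorSet:
    """Ordered, uniquely labelled collection of constituent predictors."""

    def __init__(self, members: list[tuple[str, AdjustedEffects]]):
        if not members:
            raise ValueError("predictor set must have at least one member")
        labels = [lab for lab, _ in members]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate predictor labels")
        self.members = list(members)

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)


class MixWeights(dict):
    """Per-label non-negative mixing weight."""

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        for lab, w in self.items():
            if w < 0:
                raise ValueError(f"negative weight for {lab}")


def fit_mix_weights(predictors: PredictorSet, geno_val: GenotypeMatrix,
                    pheno_val: PhenotypeTable) -> MixWeights:
    """Learn non-negative mixing weights on validation data.

    Each predictor is scored on ``geno_val``; y and the PRS columns are
    centered, columns standardized for conditioning (weights are transformed
    back to the raw-PRS scale), and the non-negative least-squares problem is
    solved exactly.  A constant PRS column receives weight 0 with a warning.
    """
    if geno_val.n_samples < 2 * len(predictors):
        raise ValueError("need at least 2x more validation samples than predictors")
    y = pheno_val.aligned(geno_val.samples)
    cols = np.column_stack([score(geno_val, eff).to_numpy()
                            for _, eff in predictors])
    yc = y - y.mean()
    xc = cols - cols.mean(axis=0)
    sd = xc.std(axis=0)
    const = sd == 0
    if const.any():
        bad = [predictors.labels[j] for j in np.where(const)[0]]
        warnings.warn(f"constant PRS column(s) {bad}; weight forced to 0")
    scale = np.where(const, 1.0, sd)
    w_std, _ = nnls(xc / scale, yc)
    w = np.where(const, 0.0, w_std / scale)
    w = np.maximum(w, 0.0)  # clamp any -0.0
    return MixWeights(zip(predictors.labels, w))


def combine_effects(predictors: PredictorSet, weights: MixWeights) -> AdjustedEffects:
    """Per-variant weighted sum of constituent effect sizes.

    Predictors are joined on the union of their variants keyed by
    (chromosome, position); a variant absent from a predictor contributes 0.
    Allele orientation is harmonized to the first predictor carrying each
    variant; an irreconcilable allele pair raises, naming the variants.
    """
    panel: dict[tuple, dict] = {}
    acc: dict[tuple, float] = {}
    conflicts = []
    for lab, eff in predictors:
        w = weights.get(lab, 0.0)
        for rec in eff.table.itertuples(index=False):
            key = (str(rec.chrom), int(rec.pos))
            if key not in panel:
                panel[key] = {"id": rec.id, "chrom": rec.chrom, "pos": int(rec.pos),
                              "effect_allele": rec.effect_allele,
                              "other_allele": rec.other_allele}
                acc[key] = 0.0
            ref = panel[key]
            if (rec.effect_allele, rec.other_allele) == (ref["effect_allele"],
                                                         ref["other_allele"]):
                acc[key] += w * rec.beta
            elif (rec.other_allele, rec.effect_allele) == (ref["effect_allele"],
                                                           ref["other_allele"]):
                acc[key] += -w * rec.beta
            else:
                conflicts.append(rec.id)
    if conflicts:
        raise ValueError(f"unresolvable allele orientation for variants: {conflicts[:10]}")
    keys = sorted(panel, key=lambda k: ((0, int(k[0])) if k[0].isdigit()
                                        else (1, k[0]), k[1]))
    table = pd.DataFrame([{**panel[k], "beta": acc[k]} for k in keys],
                         columns=["id", "chrom", "pos", "effect_allele",
                                  "other_allele", "beta"])
    label = "+".join(predictors.labels)
    return AdjustedEffects(table, method=f"combination({label})",
                           params={"weights": dict(weights)})


def enumerate_combinations(methods_per_population: dict[str, list[str]],
                           scheme: str = "multi") -> list[list[tuple[str, str]]]:
    """Cross-product combination recipes: one method per population.

    Returns a deterministic list of recipes, each a list of
    ``(population, method)`` pairs in population order.  Population order
    follows the mapping's insertion order.
    """
    if not methods_per_population:
        raise ValueError("no populations given")
    for pop, methods in methods_per_population.items():
        if not methods:
            raise ValueError(f"no methods listed for population {pop}")
        if len(set(methods)) != len(methods):
            raise ValueError(f"duplicate method label for population {pop}")
    pops = list(methods_per_population)
    out = []
    for combo in itertools.product(*(methods_per_population[p] for p in pops)):
        out.append(list(zip(pops, combo)))
    return out
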