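"""PRS effect-size adjustment methods, LD estimation and genotype scoring.

Implemented adjusters, all operating on GWAS summary statistics harmonized
to a reference panel:

* ``adjust_pt`` — LD clumping (greedy by p-value, r² and distance bounded)
  followed by p-value thresholding over a grid.
* ``adjust_dw`` — "double weight": each marginal effect is down-weighted by
  the Monte-Carlo probability that its resampled effect, drawn from
  N(β̂, SE²), ranks among the top-Z absolute effects.
* ``adjust_ldpred_inf`` — infinitesimal-model posterior mean,
  ``(D + (M/(N h²)) I)⁻¹ β̂`` solved per chromosome on the banded LD matrix.
* ``adjust_ldpred_gibbs`` — point-normal (spike-and-slab) Gibbs sampler over
  a grid of causal proportions π; at π = 1 it converges to the
  infinitesimal closed form.
* ``adjust_mixture`` — finite mixture of C zero-mean normals with scale
  grid γ (SBayesR-style when fed summary-level banded LD; BayesR-style when
  fed a dense LD computed from individual-level genotypes).
* ``adjust_sbayes_s`` — point-normal prior whose per-variant variance scales
  with heterozygosity, ``[2p(1−p)]^S σ_β²``; S may be fixed (default 0) or
  sampled by random-walk Metropolis.

All samplers are deterministic given their seed.  Betas are carried on the
standardized-genotype scale; :func:`score` applies them to column-standardized
target dosages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genodata import GenotypeMatrix, ConsistencyError, _is_ambiguous

logger = logging.getLogger(__name__)

DEFAULT_P_THRESHOLDS = (1e-8, 1e-7, 1e-6, 1e-5, 3e-5, 1e-4, 3e-4,
                        0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)
DEFAULT_PI_GRID = (1e-5, 3e-5, 1e-4, 3e-4, 0.001, 0.003, 0.01, 0.03, 0.1, 0.3, 1.0)


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass
class PTConfig:
    p_thresholds: tuple = DEFAULT_P_THRESHOLDS
    clump_r2: float = 0.1
    clump_kb: float = 250.0

    def __post_init__(self):
        if not all(0 < t <= 1 for t in self.p_thresholds):
            raise ValueError("p thresholds must be in (0, 1]")
        if not 0 < self.clump_r2 <= 1:
            raise ValueError("clump_r2 must be in (0, 1]")


@dataclass
class DWConfig:
    top_z: int = 100
    n_draws: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.top_z < 1 or self.n_draws < 1:
            raise ValueError("top_z and n_draws must be >= 1")


@dataclass
class LDpredConfig:
    pi_grid: tuple = DEFAULT_PI_GRID
    h2: float = 0.5
    n_iter: int = 1000
    n_burnin: int = 200
    seed: int = 0

    def __post_init__(self):
        if not all(0 < p <= 1 for p in self.pi_grid):
            raise ValueError("pi values must be in (0, 1]")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")


#: summary-level scale grid (SBayesR) vs individual-level grid (BayesR)
GAMMA_SUMMARY = (0.0, 0.01, 0.1, 1.0)
GAMMA_INDIVIDUAL = (0.0, 0.0001, 0.001, 0.01)


@dataclass
class MixtureConfig:
    gammas: tuple = GAMMA_SUMMARY
    pi_init: tuple | None = None
    sigma_beta2: float = 0.01
    n_iter: int = 1000
    n_burnin: int = 200
    seed: int = 0
    learn_pi: bool = True      # Dirichlet update of component probabilities
    learn_sigma: bool = True   # scaled-inv-chi-square update of sigma_beta2

    def __post_init__(self):
        if self.gammas[0] != 0.0:
            raise ValueError("first mixture component must be the null (gamma=0)")
        if self.pi_init is None:
            c = len(self.gammas)
            self.pi_init = tuple([0.9] + [0.1 / (c - 1)] * (c - 1))
        if abs(sum(self.pi_init) - 1) > 1e-9:
            raise ValueError("pi_init must sum to 1")


@dataclass
class SBayesSConfig:
    S: float = 0.0
    sigma_s2: float = 1.0
    estimate_S: bool = False
    pi_init: float = 0.1
    sigma_beta2: float = 0.01
    n_iter: int = 1000
    n_burnin: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.sigma_s2 <= 0:
            raise ValueError("sigma_s2 must be > 0")


@dataclass
class AdjustedEffects:
    """Per-variant adjusted effect sizes produced by one PRS method."""

    table: pd.DataFrame  # id, chrom, pos, effect_allele, other_allele, beta
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.table["beta"].to_numpy()).all():
            raise ValueError("non-finite adjusted betas")

    @property
    def betas(self) -> np.ndarray:
        return self.table["beta"].to_numpy()

    def with_betas(self, beta, method=None, **params) -> "AdjustedEffects":
        t = self.table.copy()
        t["beta"] = beta
        return AdjustedEffects(t, method or self.method, params or dict(self.params))


def effects_from_sumstats(ss: pd.DataFrame, method: str = "marginal",
                          **params) -> AdjustedEffects:
    t = ss[["id", "chrom", "pos", "effect_allele", "other_allele", "beta"]].copy()
    return AdjustedEffects(t.reset_index(drop=True), method, params)


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------

@dataclass
class LDMatrix:
    """Windowed (banded) variant-correlation structure per chromosome.

    ``raw[chrom]`` holds the dense within-chromosome Pearson correlations
    with entries beyond ``window_kb`` zeroed (used for clumping r²);
    ``matrices[chrom]`` holds the solver matrix: the same band with the
    ridge regularization ``(1−ridge)·R + ridge·I`` applied and negative
    eigenvalues (an artifact of hard band truncation) clipped so the matrix
    is positive definite.  ``lo``/``hi`` give each variant's window bounds
    as local indices.
    """

    variants: pd.DataFrame
    window_kb: float
    ridge: float
    matrices: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    chrom_start: dict = field(default_factory=dict)

    def chrom_of(self, j: int) -> str:
        return str(self.variants["chrom"].iloc[j])

    def r(self, i: int, j: int) -> float:
        """Raw correlation between global variant indices i and j (0 outside band)."""
        ci, cj = self.chrom_of(i), self.chrom_of(j)
        if ci != cj:
            return 0.0
        s = self.chrom_start[ci]
        return float(self.raw[ci][i - s, j - s])

    def r2(self, i: int, j: int) -> float:
        return self.r(i, j) ** 2


def estimate_ld(geno_ref: GenotypeMatrix, window_kb: float = 1000.0,
                ridge: float = 0.05) -> LDMatrix:
    """Pearson correlations of standardized dosages within a physical window.

    Monomorphic variants get an identity row/column (logged).  The returned
    band is regularized as ``(1−ridge)·R + ridge·I``.
    """
    if geno_ref.n_samples < 2:
        raise ValueError("need >= 2 reference samples to estimate LD")
    z = geno_ref.standardized()
    v = geno_ref.variants
    ld = LDMatrix(v[["id", "chrom", "pos"]].copy(), window_kb, ridge)
    m = geno_ref.n_variants
    ld.lo = np.zeros(m, dtype=int)
    ld.hi = np.zeros(m, dtype=int)
    n_mono = 0
    for chrom, idx in v.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(idx)
        start = int(idx[0])
        ld.chrom_start[str(chrom)] = start
        zc = z[:, idx]
        sd0 = zc.std(axis=0) == 0
        n_mono += int(sd0.sum())
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(zc, rowvar=False)
        if r.ndim == 0:
            r = np.array([[1.0]])
        r[np.isnan(r)] = 0.0
        r[sd0, :] = 0.0
        r[:, sd0] = 0.0
        pos = v["pos"].iloc[idx].to_numpy()
        dist = np.abs(pos[:, None] - pos[None, :])
        r[dist > window_kb * 1000.0] = 0.0
        np.fill_diagonal(r, 1.0)
        ld.raw[str(chrom)] = r
        reg = (1 - ridge) * r + ridge * np.eye(len(idx))
        # hard band truncation can make the matrix indefinite; clip spectrum
        floor = max(ridge, 1e-4)
        w, vecs = np.linalg.eigh(reg)
        if w.min() < floor:
            reg = (vecs * np.clip(w, floor, None)) @ vecs.T
            reg = (reg + reg.T) / 2.0
            d = np.sqrt(np.diag(reg))
            reg = reg / np.outer(d, d)  # back to unit diagonal, stays PD
        ld.matrices[str(chrom)] = reg
        for k, g in enumerate(idx):
            inb = np.abs(pos - pos[k]) <= window_kb * 1000.0
            ld.lo[g] = int(np.argmax(inb))
            ld.hi[g] = len(inb) - int(np.argmax(inb[::-1]))
    if n_mono:
        logger.info("estimate_ld: %d monomorphic variants set to identity rows", n_mono)
    return ld


def _check_aligned(ss: pd.DataFrame, ld: LDMatrix) -> None:
    if len(ss) != len(ld.variants) or not (ss["id"].to_numpy() ==
                                           ld.variants["id"].to_numpy()).all():
        raise ConsistencyError("sumstats are not harmonized to the LD panel")


# ---------------------------------------------------------------------------
# P + T
# ---------------------------------------------------------------------------

def clump(ss: pd.DataFrame, ld: LDMatrix, cfg: PTConfig | None = None) -> list[str]:
    """Greedy LD clumping: index variants by ascending p-value.

    A variant is kept iff its r² with every already-kept variant within
    ``clump_kb`` is below ``clump_r2``.  Ties in p break by (chromosome,
    position).
    """
    cfg = cfg or PTConfig()
    if len(ss) == 0:
        return []
    _check_aligned(ss, ld)
    order = sorted(range(len(ss)),
                   key=lambda j: (ss["p"].iloc[j], str(ss["chrom"].iloc[j]),
                                  int(ss["pos"].iloc[j])))
    kept: list[int] = []
    pos = ss["pos"].to_numpy()
    chrom = ss["chrom"].astype(str).to_numpy()
    for j in order:
        ok = True
        for k in kept:
            if chrom[k] == chrom[j] and abs(pos[k] - pos[j]) <= cfg.clump_kb * 1000.0:
                if ld.r2(j, k) >= cfg.clump_r2:
                    ok = False
                    break
        if ok:
            kept.append(j)
    kept.sort()
    return list(ss["id"].iloc[kept])


def adjust_pt(ss: pd.DataFrame, ld: LDMatrix,
              cfg: PTConfig | None = None) -> dict[float, AdjustedEffects]:
    """Clumping + thresholding: one effect set per p-value threshold.

    Retained variants keep their marginal beta; all others are zeroed.
    Threshold selection happens downstream on validation data.
    """
    cfg = cfg or PTConfig()
    kept = set(clump(ss, ld, cfg))
    base = effects_from_sumstats(ss)
    in_clump = ss["id"].isin(kept).to_numpy()
    out = {}
    for thr in cfg.p_thresholds:
        sel = in_clump & (ss["p"].to_numpy() <= thr)
        out[thr] = base.with_betas(np.where(sel, ss["beta"].to_numpy(), 0.0),
                                   method="pt", p_threshold=thr,
                                   clump_r2=cfg.clump_r2, clump_kb=cfg.clump_kb)
    return out


# ---------------------------------------------------------------------------
# Double weight
# ---------------------------------------------------------------------------

def adjust_dw(ss: pd.DataFrame, cfg: DWConfig | None = None) -> AdjustedEffects:
    """Double weight: β̂ down-weighted by its top-Z inclusion probability.

    For each Monte-Carlo draw, every effect is resampled from N(β̂, SE²) and
    π̂_j is the fraction of draws in which |β*_j| ranks in the top ``top_z``;
    the adjusted effect is π̂_j · β̂_j.
    """
    cfg = cfg or DWConfig()
    m = len(ss)
    if cfg.top_z > m:
        raise ValueError(f"top_z={cfg.top_z} exceeds {m} variants")
    rng = np.random.default_rng(cfg.seed)
    beta = ss["beta"].to_numpy()
    se = ss["se"].to_numpy()
    if not np.all(np.isfinite(se) & (se > 0)):
        raise ValueError("double weight requires finite positive SE for every variant")
    hits = np.zeros(m)
    for _ in range(cfg.n_draws):
        draw = np.abs(beta + se * rng.standard_normal(m))
        top = np.argpartition(draw, m - cfg.top_z)[m - cfg.top_z:]
        hits[top] += 1
    pi_hat = hits / cfg.n_draws
    return effects_from_sumstats(ss).with_betas(
        pi_hat * beta, method="dw", top_z=cfg.top_z, n_draws=cfg.n_draws)


# ---------------------------------------------------------------------------
# LDpred (infinitesimal and point-normal Gibbs)
# ---------------------------------------------------------------------------

def _median_n(ss: pd.DataFrame) -> float:
    return float(np.median(ss["n"].to_numpy()))


def adjust_ldpred_inf(ss: pd.DataFrame, ld: LDMatrix, h2: float,
                      M: int | None = None, N: float | None = None) -> AdjustedEffects:
    """Infinitesimal-model posterior mean ``(D + (M/(N h²)) I)⁻¹ β̂``.

    Solved per chromosome on the regularized banded LD matrix; with identity
    LD this reduces to uniform shrinkage by ``1/(1 + M/(N h²))``.
    """
    _check_aligned(ss, ld)
    M = M if M is not None else len(ss)
    N = N if N is not None else _median_n(ss)
    lam = M / (N * h2)
    beta = ss["beta"].to_numpy()
    out = np.empty_like(beta)
    for chrom, r in ld.matrices.items():
        s = ld.chrom_start[chrom]
        sl = slice(s, s + r.shape[0])
        a = r + lam * np.eye(r.shape[0])
        try:
            out[sl] = np.linalg.solve(a, beta[sl])
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular LD system on chromosome {chrom}") from exc
    return effects_from_sumstats(ss).with_betas(
        out, method="ldpred_inf", h2=h2, M=M, N=N)


def _point_normal_sweeps(beta_hat, R, lo, hi, N, pi, sigma2, n_iter, burnin, rng):
    """Single-site point-normal Gibbs on one chromosome.

    Returns the Rao-Blackwellized posterior-mean effects (average over
    post-burn-in sweeps of inclusion probability x conditional mean).
    """
    m = len(beta_hat)
    b = np.zeros(m)
    acc = np.zeros(m)
    lik_var = 1.0 / N
    post_var = 1.0 / (N + 1.0 / sigma2)
    shrink = post_var * N
    # log-density constants for the inclusion odds
    c1 = -0.5 * np.log(2 * np.pi * (sigma2 + lik_var))
    c0 = -0.5 * np.log(2 * np.pi * lik_var)
    sd_post = np.sqrt(post_var)
    for it in range(n_iter):
        u = rng.random(m)
        eps = rng.standard_normal(m)
        for j in range(m):
            r = beta_hat[j] - (R[j] @ b - R[j, j] * b[j])
            if pi >= 1.0:
                p_incl = 1.0
            else:
                l1 = c1 - r * r / (2 * (sigma2 + lik_var))
                l0 = c0 - r * r / (2 * lik_var)
                logit = np.log(pi) + l1 - np.log1p(-pi) - l0
                p_incl = 1.0 / (1.0 + np.exp(-logit)) if logit < 35 else 1.0
            mean_j = shrink * r
            b[j] = mean_j + sd_post * eps[j] if u[j] < p_incl else 0.0
            if it >= burnin:
                acc[j] += p_incl * mean_j
    return acc / max(n_iter - burnin, 1)


def adjust_ldpred_gibbs(ss: pd.DataFrame, ld: LDMatrix,
                        cfg: LDpredConfig | None = None,
                        N: float | None = None) -> dict[float, AdjustedEffects]:
    """Point-normal (spike-and-slab) Gibbs sampler, one run per π in the grid.

    Prior: β_j ~ N(0, h²/(πM)) with probability π, else exactly 0.  Output
    is the posterior-mean effect per variant, averaged over post-burn-in
    sweeps; deterministic given ``cfg.seed``.
    """
    cfg = cfg or LDpredConfig()
    _check_aligned(ss, ld)
    M = len(ss)
    N = N if N is not None else _median_n(ss)
    beta = ss["beta"].to_numpy()
    base = effects_from_sumstats(ss)
    out: dict[float, AdjustedEffects] = {}
    for pi in cfg.pi_grid:
        rng = np.random.default_rng(cfg.seed)
        sigma2 = cfg.h2 / (pi * M)
        post = np.empty_like(beta)
        for chrom, r in ld.matrices.items():
            s = ld.chrom_start[chrom]
            sl = slice(s, s + r.shape[0])
            post[sl] = _point_normal_sweeps(
                beta[sl], r, ld.lo[sl], ld.hi[sl], N, pi, sigma2,
                cfg.n_iter, cfg.n_burnin, rng)
        out[pi] = base.with_betas(post, method="ldpred",
                                  pi=pi, h2=cfg.h2, N=N, seed=cfg.seed)
    return out


# ---------------------------------------------------------------------------
# Finite-mixture Gibbs (BayesR / SBayesR / SBayesS core)
# ---------------------------------------------------------------------------

def _mixture_gibbs(beta_hat, R, lo, hi, N, gammas, pi0, sigma_beta2, n_iter,
                   burnin, rng, var_mult=None, S=0.0, sigma_s2=1.0,
                   estimate_S=False, het=None, learn_pi=True, learn_sigma=True):
    """Shared Gibbs core for the finite-mixture shrinkage priors.

    ``var_mult`` scales each variant's non-null prior variance (the
    heterozygosity term of the MAF-dependent prior); when ``estimate_S`` is
    on, ``het`` must hold 2p(1−p) and S is updated by random-walk Metropolis
    under an N(0, σ_s²) prior.  Returns (posterior-mean betas, posterior-mean
    S, mean null-component occupancy).
    """
    m = len(beta_hat)
    C = len(gammas)
    gam = np.asarray(gammas, dtype=float)
    pi = np.asarray(pi0, dtype=float).copy()
    mult = np.ones(m) if var_mult is None else np.asarray(var_mult, dtype=float)
    lik_var = 1.0 / N
    b = np.zeros(m)
    comp = np.zeros(m, dtype=int)
    acc = np.zeros(m)
    s_acc = 0.0
    null_occ = 0.0
    kept = max(n_iter - burnin, 1)
    s_prior = sigma_beta2  # prior scale of the scaled-inv-chi-square update
    log_het = np.log(het) if het is not None else None
    for it in range(n_iter):
        u_comp = rng.random(m)
        eps = rng.standard_normal(m)
        counts = np.zeros(C)
        ss_by_comp = 0.0
        k_nonzero = 0
        for j in range(m):
            r = beta_hat[j] - (R[j] @ b - R[j, j] * b[j])
            v = gam * sigma_beta2 * mult[j]  # v[0] = 0
            tot = v + lik_var
            logl = -0.5 * np.log(tot) - r * r / (2 * tot) + np.log(pi)
            logl -= logl.max()
            prob = np.exp(logl)
            prob /= prob.sum()
            c = int(np.searchsorted(np.cumsum(prob), u_comp[j]))
            c = min(c, C - 1)
            counts[c] += 1
            if c == 0:
                b[j] = 0.0
            else:
                post_var = 1.0 / (N + 1.0 / v[c])
                mean_j = post_var * N * r
                b[j] = mean_j + np.sqrt(post_var) * eps[j]
                ss_by_comp += b[j] ** 2 / (gam[c] * mult[j])
                k_nonzero += 1
            comp[j] = c
            if it >= burnin:
                nz = slice(1, C)
                pv = 1.0 / (N + 1.0 / v[nz])
                acc[j] += float(prob[nz] @ (pv * N * r))
        if learn_pi:
            # component probabilities: Dirichlet(1 + counts)
            pi = rng.dirichlet(1.0 + counts)
        if learn_sigma:
            # effect-variance scale: scaled inverse chi-square update
            nu0 = 4.0
            sigma_beta2 = (ss_by_comp + nu0 * s_prior) / rng.chisquare(nu0 + k_nonzero)
        if estimate_S:
            s_new = S + 0.1 * rng.standard_normal()
            nz_idx = comp > 0
            if nz_idx.any():
                def logp(s):
                    vj = gam[comp[nz_idx]] * sigma_beta2 * np.exp(s * log_het[nz_idx])
                    return (-0.5 * np.sum(np.log(vj) + b[nz_idx] ** 2 / vj)
                            - s * s / (2 * sigma_s2))
                if np.log(rng.random()) < logp(s_new) - logp(S):
                    S = s_new
                mult = np.exp(S * log_het)
        if it >= burnin:
            s_acc += S
            null_occ += counts[0] / m
    return acc / kept, s_acc / kept, null_occ / kept


def adjust_mixture(ss: pd.DataFrame, ld: LDMatrix,
                   cfg: MixtureConfig | None = None,
                   N: float | None = None) -> AdjustedEffects:
    """Finite-mixture shrinkage (C zero-mean normals with scale grid γ).

    Summary-level (SBayesR-style) when ``ld`` is a banded reference-panel
    matrix; the individual-level (BayesR) variant is the same sampler fed a
    dense LD matrix computed from the training genotypes and the
    individual-level γ grid.
    """
    cfg = cfg or MixtureConfig()
    _check_aligned(ss, ld)
    N = N if N is not None else _median_n(ss)
    beta = ss["beta"].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    post = np.empty_like(beta)
    occ = []
    for chrom, r in ld.matrices.items():
        s = ld.chrom_start[chrom]
        sl = slice(s, s + r.shape[0])
        post[sl], _, null_occ = _mixture_gibbs(
            beta[sl], r, ld.lo[sl], ld.hi[sl], N, cfg.gammas, cfg.pi_init,
            cfg.sigma_beta2, cfg.n_iter, cfg.n_burnin, rng,
            learn_pi=cfg.learn_pi, learn_sigma=cfg.learn_sigma)
        occ.append(null_occ)
    return effects_from_sumstats(ss).with_betas(
        post, method="mixture", gammas=tuple(cfg.gammas), N=N,
        seed=cfg.seed, null_occupancy=float(np.mean(occ)))


def adjust_sbayes_s(ss: pd.DataFrame, ld: LDMatrix,
                    cfg: SBayesSConfig | None = None,
                    N: float | None = None) -> AdjustedEffects:
    """Point-normal prior with MAF-dependent variance ``[2p(1−p)]^S σ_β²``.

    At S = 0 (the default) this is exactly the MAF-free point-normal special
    case of :func:`adjust_mixture`.  With ``estimate_S`` the selection
    parameter is sampled by random-walk Metropolis under N(0, σ_s²).
    """
    cfg = cfg or SBayesSConfig()
    _check_aligned(ss, ld)
    eaf = ss["eaf"].to_numpy()
    if np.isnan(eaf).any():
        raise ValueError("SBayesS requires an effect-allele frequency for every variant")
    het = np.clip(2 * eaf * (1 - eaf), 1e-6, None)
    N = N if N is not None else _median_n(ss)
    beta = ss["beta"].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    pi0 = (1 - cfg.pi_init, cfg.pi_init)
    post = np.empty_like(beta)
    s_means = []
    for chrom, r in ld.matrices.items():
        s = ld.chrom_start[chrom]
        sl = slice(s, s + r.shape[0])
        post[sl], s_mean, _ = _mixture_gibbs(
            beta[sl], r, ld.lo[sl], ld.hi[sl], N, (0.0, 1.0), pi0,
            cfg.sigma_beta2, cfg.n_iter, cfg.n_burnin, rng,
            var_mult=het[sl] ** cfg.S, S=cfg.S, sigma_s2=cfg.sigma_s2,
            estimate_S=cfg.estimate_S, het=het[sl])
        s_means.append(s_mean)
    return effects_from_sumstats(ss).with_betas(
        post, method="sbayes_s", S=cfg.S, estimate_S=cfg.estimate_S,
        S_posterior_mean=float(np.mean(s_means)), seed=cfg.seed)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score(geno: GenotypeMatrix, eff: AdjustedEffects) -> pd.Series:
    """Polygenic score: standardized dosages dotted with adjusted betas.

    Effects are matched to the target panel on (chromosome, position); sign
    flips are applied where the effect allele is the panel's other allele,
    strand-ambiguous or irreconcilable variants are dropped (logged).
    Missing dosages are mean-imputed.
    """
    v = geno.variants
    lookup = {(str(r.chrom), int(r.pos)): i for i, r in
              enumerate(v.itertuples(index=False))}
    idx, w = [], []
    n_drop = 0
    for rec in eff.table.itertuples(index=False):
        j = lookup.get((str(rec.chrom), int(rec.pos)))
        if j is None:
            n_drop += 1
            continue
        pa, po = v["effect_allele"].iloc[j], v["other_allele"].iloc[j]
        if (rec.effect_allele, rec.other_allele) == (pa, po):
            idx.append(j)
            w.append(rec.beta)
        elif (rec.effect_allele, rec.other_allele) == (po, pa) and not _is_ambiguous(pa, po):
            idx.append(j)
            w.append(-rec.beta)
        else:
            n_drop += 1
    if not idx:
        raise ConsistencyError("no effect variants overlap the target panel")
    if n_drop:
        logger.info("score: dropped %d effect variants absent/unresolvable in panel", n_drop)
    z = geno.standardized()[:, idx]
    return pd.Series(z @ np.asarray(w), index=pd.Index(geno.samples), name="prs")
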