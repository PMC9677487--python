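"""PRS effect-adjustment methods, LD estimation and scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import prsup as P
from prsup.genodata import ConsistencyError
from prsup.prscore import LDMatrix, effects_from_sumstats

from conftest import make_geno, make_pheno


def make_ss(betas, se=0.05, p=None, pos=None, eaf=0.3, n=1000, chrom="1"):
    m = len(betas)
    return pd.DataFrame({
        "id": [f"v{j}" for j in range(m)], "chrom": chrom,
        "pos": pos if pos is not None else 1 + np.arange(m) * 1000,
        "effect_allele": "A", "other_allele": "G",
        "eaf": np.broadcast_to(np.asarray(eaf, dtype=float), m).copy(),
        "beta": np.asarray(betas, dtype=float),
        "se": np.broadcast_to(np.asarray(se, dtype=float), m).copy(),
        "p": p if p is not None else np.full(m, 0.5),
        "n": n})


def ld_from_matrix(ss, r, ridge=0.0, window_kb=1e6):
    """LDMatrix wrapping an explicit correlation matrix (no estimation)."""
    r = np.asarray(r, dtype=float)
    m = len(ss)
    ld = LDMatrix(ss[["id", "chrom", "pos"]].copy(), window_kb, ridge)
    ld.raw = {"1": r.copy()}
    ld.matrices = {"1": (1 - ridge) * r + ridge * np.eye(m)}
    ld.chrom_start = {"1": 0}
    ld.lo = np.zeros(m, dtype=int)
    ld.hi = np.full(m, m, dtype=int)
    return ld


def identity_ld(ss):
    return ld_from_matrix(ss, np.eye(len(ss)))


# ---------------------------------------------------------------------------
# LD estimation
# ---------------------------------------------------------------------------

class TestEstimateLd:
    def test_duplicated_columns_have_unit_correlation(self):
        rng = np.random.default_rng(0)
        col = rng.binomial(2, 0.4, 100).astype(float)
        g = make_geno(np.column_stack([col, col]))
        ld = P.estimate_ld(g)
        assert ld.r(0, 1) == pytest.approx(1.0)

    def test_independent_variants_near_zero(self):
        rng = np.random.default_rng(1)
        g = make_geno(rng.binomial(2, 0.4, (5000, 10)).astype(float))
        ld = P.estimate_ld(g)
        off = [ld.r(i, j) for i in range(10) for j in range(i + 1, 10)]
        assert np.max(np.abs(off)) < 0.06

    def test_band_matches_dense_correlation_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.4, (200, 10)).astype(float)
        g = make_geno(d, pos=1 + np.arange(10) * 100_000)  # 100 kb spacing
        ld = P.estimate_ld(g, window_kb=250, ridge=0.0)
        dense = np.corrcoef(g.standardized(), rowvar=False)
        for i in range(10):
            for j in range(10):
                expected = dense[i, j] if abs(i - j) * 100 <= 250 else 0.0
                assert ld.r(i, j) == pytest.approx(expected, abs=1e-12)

    def test_monomorphic_variant_gets_identity_row(self):
        rng = np.random.default_rng(3)
        d = rng.binomial(2, 0.4, (50, 3)).astype(float)
        d[:, 1] = 2.0
        ld = P.estimate_ld(make_geno(d))
        assert ld.r(1, 1) == 1.0
        assert ld.r(0, 1) == 0.0

    def test_solver_matrix_is_positive_definite(self, sim_cohort):
        for r in sim_cohort["ld"].matrices.values():
            assert np.linalg.eigvalsh(r).min() > 0


# ---------------------------------------------------------------------------
# Clumping and thresholding
# ---------------------------------------------------------------------------

def clump_oracle(ss, r2mat, clump_r2, clump_kb):
    """Independent reimplementation of greedy clumping over a dense r2 matrix."""
    order = sorted(range(len(ss)), key=lambda j: (ss["p"].iloc[j],
                                                  str(ss["chrom"].iloc[j]),
                                                  int(ss["pos"].iloc[j])))
    kept = []
    for j in order:
        if all(not (abs(ss["pos"].iloc[j] - ss["pos"].iloc[k]) <= clump_kb * 1000
                    and r2mat[j, k] >= clump_r2) for k in kept):
            kept.append(j)
    return sorted(ss["id"].iloc[k] for k in kept)


class TestClump:
    def test_perfect_ld_trio_keeps_smallest_p(self):
        ss = make_ss([0.3, 0.3, 0.3], p=[1e-9, 1e-8, 1e-7], pos=[100, 200, 300])
        ld = ld_from_matrix(ss, np.ones((3, 3)))
        assert P.clump(ss, ld) == ["v0"]

    def test_unlinked_variants_all_kept(self):
        ss = make_ss([0.1] * 5, p=[0.01, 0.02, 0.03, 0.04, 0.05])
        assert P.clump(ss, identity_ld(ss)) == [f"v{j}" for j in range(5)]

    def test_distance_window_limits_pruning(self):
        # r2 = 1 but 400 kb apart: both kept under a 250 kb window
        ss = make_ss([0.3, 0.3], p=[1e-9, 1e-8], pos=[100, 400_100])
        ld = ld_from_matrix(ss, np.ones((2, 2)))
        assert P.clump(ss, ld, P.PTConfig(clump_kb=250)) == ["v0", "v1"]

    def test_matches_independent_oracle_on_random_instances(self, sim_cohort):
        ss, ld = sim_cohort["ss"], sim_cohort["ld"]
        sub = ss.iloc[:50].reset_index(drop=True)
        rmat = np.array([[ld.r(i, j) for j in range(50)] for i in range(50)])
        got = sorted(P.clump(sub, ld_from_matrix(sub, rmat), P.PTConfig()))
        assert got == clump_oracle(sub, rmat ** 2, 0.1, 250)

    def test_kept_set_is_maximal(self, sim_cohort):
        ss, ld = sim_cohort["ss"], sim_cohort["ld"]
        cfg = P.PTConfig()
        kept = set(P.clump(ss, ld, cfg))
        idx = {v: j for j, v in enumerate(ss["id"])}
        for v in ss["id"]:
            if v in kept:
                continue
            j = idx[v]
            violates = any(
                ld.r2(j, idx[k]) >= cfg.clump_r2
                and str(ss["chrom"].iloc[j]) == str(ss["chrom"].iloc[idx[k]])
                and abs(ss["pos"].iloc[j] - ss["pos"].iloc[idx[k]]) <= cfg.clump_kb * 1000
                for k in kept)
            assert violates, f"{v} could have been added"

    def test_empty_sumstats_empty_selection(self):
        ss = make_ss([])
        assert P.clump(ss, identity_ld(ss)) == []


class TestAdjustPT:
    def test_vacuous_threshold_keeps_all_clumped(self):
        ss = make_ss([0.1, -0.2, 0.3], p=[0.5, 0.01, 0.9])
        out = P.adjust_pt(ss, identity_ld(ss), P.PTConfig(p_thresholds=(1.0,)))
        np.testing.assert_allclose(out[1.0].betas, ss["beta"])

    def test_threshold_below_min_p_empties_effects(self):
        ss = make_ss([0.1, -0.2], p=[0.5, 0.01])
        out = P.adjust_pt(ss, identity_ld(ss), P.PTConfig(p_thresholds=(1e-9,)))
        np.testing.assert_array_equal(out[1e-9].betas, 0.0)

    def test_worked_instance_set_arithmetic(self):
        ss = make_ss([0.1, 0.2, 0.3, 0.4, 0.5],
                     p=[1e-6, 1e-3, 0.05, 1e-7, 0.5],
                     pos=[100, 200, 300, 400, 500])
        r = np.eye(5)
        r[0, 3] = r[3, 0] = 0.9  # v0 clumped away by stronger v3
        out = P.adjust_pt(ss, ld_from_matrix(ss, r),
                          P.PTConfig(p_thresholds=(0.01, 0.1)))
        # clumped set = {v1, v2, v3, v4}; p <= 0.01 keeps {v1, v3}
        assert set(np.nonzero(out[0.01].betas)[0]) == {1, 3}
        assert set(np.nonzero(out[0.1].betas)[0]) == {1, 2, 3}


# ---------------------------------------------------------------------------
# Double weight
# ---------------------------------------------------------------------------

class TestAdjustDW:
    def test_zero_se_degenerates_to_top_z_indicator(self):
        ss = make_ss([3.0, 0.1, -2.0, 0.2], se=1e-12)
        out = P.adjust_dw(ss, P.DWConfig(top_z=2, n_draws=50, seed=0))
        np.testing.assert_allclose(out.betas, [3.0, 0.0, -2.0, 0.0], atol=1e-9)

    def test_top_z_all_returns_marginal_betas(self):
        ss = make_ss([0.5, -0.3, 0.1])
        out = P.adjust_dw(ss, P.DWConfig(top_z=3, n_draws=20, seed=0))
        np.testing.assert_allclose(out.betas, ss["beta"])

    def test_inclusion_probability_matches_brute_force(self):
        # 3 variants, betas (3, 0, -3), SE 1, top_z=1: pi for the middle
        # variant is P(|N(0,1)| > max(|N(3,1)|, |N(-3,1)|)), estimated by an
        # independent high-draw Monte-Carlo oracle
        rng = np.random.default_rng(123)
        n_oracle = 400_000
        draws = rng.standard_normal((n_oracle, 3)) + np.array([3.0, 0.0, -3.0])
        top = np.argmax(np.abs(draws), axis=1)
        pi_oracle = np.bincount(top, minlength=3) / n_oracle

        ss = make_ss([3.0, 0.0, -3.0], se=1.0)
        out = P.adjust_dw(ss, P.DWConfig(top_z=1, n_draws=20_000, seed=7))
        pi_hat = np.divide(out.betas, ss["beta"],
                           out=np.zeros(3), where=ss["beta"] != 0)
        assert pi_hat[0] == pytest.approx(pi_oracle[0], abs=0.02)
        assert pi_hat[2] == pytest.approx(pi_oracle[2], abs=0.02)
        assert pi_oracle[1] < 0.01  # middle variant essentially never wins

    def test_top_z_exceeding_panel_raises(self):
        ss = make_ss([0.1, 0.2])
        with pytest.raises(ValueError):
            P.adjust_dw(ss, P.DWConfig(top_z=3))

    def test_deterministic_given_seed(self):
        ss = make_ss(np.linspace(-1, 1, 20))
        a = P.adjust_dw(ss, P.DWConfig(top_z=5, n_draws=100, seed=3))
        b = P.adjust_dw(ss, P.DWConfig(top_z=5, n_draws=100, seed=3))
        np.testing.assert_array_equal(a.betas, b.betas)


# ---------------------------------------------------------------------------
# LDpred
# ---------------------------------------------------------------------------

class TestLDpredInf:
    def test_identity_ld_uniform_shrinkage(self):
        ss = make_ss([0.3, -0.2, 0.1, 0.05], n=1000)
        out = P.adjust_ldpred_inf(ss, identity_ld(ss), h2=0.5, M=1000, N=1000)
        np.testing.assert_allclose(out.betas, ss["beta"] / 3.0, rtol=1e-12)

    def test_no_shrinkage_limit(self):
        ss = make_ss([0.3, -0.2], n=1000)
        out = P.adjust_ldpred_inf(ss, identity_ld(ss), h2=1.0, M=2, N=1e12)
        np.testing.assert_allclose(out.betas, ss["beta"], rtol=1e-9)

    def test_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.standard_normal((20, 8))
        r = np.corrcoef(a, rowvar=False)
        ss = make_ss(rng.normal(0, 0.1, 8))
        ld = ld_from_matrix(ss, r, ridge=0.05)
        out = P.adjust_ldpred_inf(ss, ld, h2=0.5, M=8, N=500)
        lam = 8 / (500 * 0.5)
        expected = np.linalg.inv(ld.matrices["1"] + lam * np.eye(8)) @ ss["beta"]
        np.testing.assert_allclose(out.betas, expected, atol=1e-10)


class TestLDpredGibbs:
    def test_pi_one_matches_infinitesimal_closed_form(self, sim_cohort):
        ss, ld = sim_cohort["ss"], sim_cohort["ld"]
        inf = P.adjust_ldpred_inf(ss, ld, h2=0.5)
        gibbs = P.adjust_ldpred_gibbs(
            ss, ld, P.LDpredConfig(pi_grid=(1.0,), h2=0.5, n_iter=1500,
                                   n_burnin=300, seed=1))[1.0]
        rel_rms = (np.sqrt(np.mean((gibbs.betas - inf.betas) ** 2))
                   / np.sqrt(np.mean(inf.betas ** 2)))
        assert rel_rms < 0.02

    def test_zero_signal_posterior_near_zero(self):
        ss = make_ss(np.zeros(30), n=1000)
        out = P.adjust_ldpred_gibbs(
            ss, identity_ld(ss),
            P.LDpredConfig(pi_grid=(0.1,), n_iter=400, n_burnin=100, seed=2))[0.1]
        assert np.max(np.abs(out.betas)) < 1e-3

    def test_sparse_prior_two_variant_exact_posterior(self):
        """2-variant spike-and-slab posterior by exact enumeration over
        inclusion configurations (numerical integration oracle)."""
        rho, N, pi, sigma2 = 0.3, 10_000.0, 1e-2, 0.05
        bh = np.array([0.20, 0.002])  # one huge signal, one null
        r = np.array([[1.0, rho], [rho, 1.0]])

        # oracle: model beta_hat ~ N(R b, R/N); enumerate configs
        configs = [(False, False), (True, False), (False, True), (True, True)]
        weights, means = [], []
        for cfg in configs:
            s = [j for j in range(2) if cfg[j]]
            prior_w = np.prod([pi if c else 1 - pi for c in cfg])
            cov = r / N
            if s:
                rs = r[:, s]
                cov = cov + sigma2 * (rs @ rs.T)
            weights.append(prior_w * multivariate_normal.pdf(bh, mean=[0, 0], cov=cov))
            mu = np.zeros(2)
            if s:
                prec = N * r[np.ix_(s, s)] + np.eye(len(s)) / sigma2
                mu[s] = np.linalg.solve(prec, N * bh[s])
            means.append(mu)
        weights = np.array(weights) / np.sum(weights)
        oracle = np.array(means).T @ weights

        ss = make_ss(bh, n=int(N))
        ld = ld_from_matrix(ss, r)
        # the sampler's slab variance is h2/(pi*M) with M = panel size (2),
        # so match the oracle's sigma2 by setting h2 = pi * 2 * sigma2
        cfg = P.LDpredConfig(pi_grid=(pi,), h2=pi * 2 * sigma2,
                             n_iter=6000, n_burnin=1000, seed=3)
        got = P.adjust_ldpred_gibbs(ss, ld, cfg)[pi].betas
        np.testing.assert_allclose(got, oracle, atol=0.01)
        assert abs(got[0]) > 0.5 * abs(bh[0])  # big signal retained

    def test_deterministic_given_seed(self):
        ss = make_ss(np.linspace(-0.2, 0.2, 20), n=500)
        cfg = P.LDpredConfig(pi_grid=(0.1,), n_iter=100, n_burnin=20, seed=9)
        a = P.adjust_ldpred_gibbs(ss, identity_ld(ss), cfg)[0.1]
        b = P.adjust_ldpred_gibbs(ss, identity_ld(ss), cfg)[0.1]
        np.testing.assert_array_equal(a.betas, b.betas)


# ---------------------------------------------------------------------------
# Finite mixture and MAF-dependent priors
# ---------------------------------------------------------------------------

class TestMixture:
    def test_equal_components_reduce_to_point_normal(self):
        """gamma = (0, g, g, g) with frozen hyper-parameters is the
        point-normal model at the matched slab variance and pi."""
        rng = np.random.default_rng(11)
        bh = rng.normal(0, 0.05, 100)
        bh[:10] += 0.3
        ss = make_ss(bh, n=2000)
        ld = identity_ld(ss)
        g = 1.0
        sigma_b2 = 0.01
        pi_nonnull = 0.3
        mix = P.adjust_mixture(ss, ld, P.MixtureConfig(
            gammas=(0.0, g, g, g), pi_init=(0.7, 0.1, 0.1, 0.1),
            sigma_beta2=sigma_b2, n_iter=1500, n_burnin=300, seed=4,
            learn_pi=False, learn_sigma=False))
        pn = P.adjust_ldpred_gibbs(ss, ld, P.LDpredConfig(
            pi_grid=(pi_nonnull,), h2=pi_nonnull * 100 * g * sigma_b2,
            n_iter=1500, n_burnin=300, seed=5))[pi_nonnull]
        rel_rms = (np.sqrt(np.mean((mix.betas - pn.betas) ** 2))
                   / np.sqrt(np.mean(pn.betas ** 2)))
        assert rel_rms < 0.05

    def test_pure_noise_occupies_null_component(self):
        rng = np.random.default_rng(12)
        n_eff = 100_000
        ss = make_ss(rng.normal(0, 1 / np.sqrt(n_eff), 200), n=n_eff)
        out = P.adjust_mixture(ss, identity_ld(ss),
                               P.MixtureConfig(n_iter=400, n_burnin=100, seed=6))
        assert out.params["null_occupancy"] > 0.9
        assert np.mean(np.abs(out.betas)) < np.mean(np.abs(ss["beta"]))

    def test_recovers_true_effects_better_than_marginal(self, sim_cohort):
        ss, ld, eff = sim_cohort["ss"], sim_cohort["ld"], sim_cohort["effects"]
        out = P.adjust_mixture(ss, ld, P.MixtureConfig(n_iter=400, n_burnin=100,
                                                       seed=7))
        corr_adj = np.corrcoef(out.betas, eff.beta)[0, 1]
        corr_marg = np.corrcoef(ss["beta"], eff.beta)[0, 1]
        assert corr_adj > corr_marg


class TestSBayesS:
    def test_s_zero_identical_to_point_normal_mixture(self, sim_cohort):
        ss, ld = sim_cohort["ss"], sim_cohort["ld"]
        sb = P.adjust_sbayes_s(ss, ld, P.SBayesSConfig(
            S=0.0, n_iter=150, n_burnin=30, seed=8))
        mx = P.adjust_mixture(ss, ld, P.MixtureConfig(
            gammas=(0.0, 1.0), pi_init=(0.9, 0.1), n_iter=150, n_burnin=30,
            seed=8))
        np.testing.assert_array_equal(sb.betas, mx.betas)

    def test_negative_s_shrinks_rare_variants_less(self):
        # same marginal signal at a rare and a common variant
        ss = make_ss([0.15, 0.15], eaf=0.3, n=5000)
        ss.loc[0, "eaf"] = 0.05
        ss.loc[1, "eaf"] = 0.50
        out = P.adjust_sbayes_s(ss, identity_ld(ss), P.SBayesSConfig(
            S=-1.0, pi_init=0.5, n_iter=2000, n_burnin=400, seed=9))
        assert abs(out.betas[0]) > abs(out.betas[1])

    def test_estimate_s_recovers_negative_selection_sign(self):
        rng = np.random.default_rng(13)
        m, n_eff, s_true = 400, 50_000, -0.5
        eaf = rng.uniform(0.02, 0.5, m)
        het = 2 * eaf * (1 - eaf)
        beta_true = rng.normal(0, np.sqrt(0.002 * het ** s_true))
        bh = beta_true + rng.normal(0, 1 / np.sqrt(n_eff), m)
        ss = make_ss(bh, eaf=0.3, n=n_eff)
        ss["eaf"] = eaf
        out = P.adjust_sbayes_s(ss, identity_ld(ss), P.SBayesSConfig(
            estimate_S=True, pi_init=0.9, n_iter=600, n_burnin=150, seed=10))
        assert out.params["S_posterior_mean"] < 0

    def test_missing_eaf_raises(self):
        ss = make_ss([0.1, 0.2])
        ss.loc[0, "eaf"] = np.nan
        with pytest.raises(ValueError):
            P.adjust_sbayes_s(ss, identity_ld(ss))


# ---------------------------------------------------------------------------
# Shrinkage sanity across every adjuster
# ---------------------------------------------------------------------------

def test_all_adjusters_shrink_pure_noise():
    rng = np.random.default_rng(14)
    n_eff = 10_000
    ss = make_ss(rng.normal(0, 1 / np.sqrt(n_eff), 100),
                 se=1 / np.sqrt(n_eff),
                 p=rng.uniform(0.05, 1.0, 100), n=n_eff)
    ld = identity_ld(ss)
    marg = np.mean(np.abs(ss["beta"]))
    outs = {
        "pt": P.adjust_pt(ss, ld, P.PTConfig(p_thresholds=(0.05,)))[0.05],
        "dw": P.adjust_dw(ss, P.DWConfig(top_z=10, n_draws=300, seed=0)),
        "inf": P.adjust_ldpred_inf(ss, ld, h2=0.1),
        "gibbs": P.adjust_ldpred_gibbs(ss, ld, P.LDpredConfig(
            pi_grid=(0.01,), h2=0.1, n_iter=300, n_burnin=60, seed=1))[0.01],
        "mixture": P.adjust_mixture(ss, ld, P.MixtureConfig(
            n_iter=300, n_burnin=60, seed=2)),
        "sbayes_s": P.adjust_sbayes_s(ss, ld, P.SBayesSConfig(
            n_iter=300, n_burnin=60, seed=3)),
    }
    for name, eff in outs.items():
        assert np.mean(np.abs(eff.betas)) <= marg, name


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

class TestScore:
    def test_null_effects_null_scores(self):
        g = make_geno([[0, 1], [2, 0], [1, 1]])
        eff = effects_from_sumstats(make_ss([0.0, 0.0]))
        assert (P.score(g, eff) == 0).all()

    def test_single_variant_hand_arithmetic(self):
        g = make_geno([[0], [1], [2]])
        eff = effects_from_sumstats(make_ss([0.5]))
        prs = P.score(g, eff).to_numpy()
        # standardized dosages of (0,1,2) are (-sqrt(3/2), 0, +sqrt(3/2))
        z = (np.array([0.0, 1.0, 2.0]) - 1.0) / np.std([0.0, 1.0, 2.0])
        np.testing.assert_allclose(prs, 0.5 * z, atol=1e-12)

    def test_linearity_in_effects(self, sim_cohort):
        geno, ss = sim_cohort["geno"], sim_cohort["ss"]
        rng = np.random.default_rng(15)
        ea = effects_from_sumstats(ss).with_betas(rng.normal(size=len(ss)))
        eb = effects_from_sumstats(ss).with_betas(rng.normal(size=len(ss)))
        combo = effects_from_sumstats(ss).with_betas(2.0 * ea.betas - 0.5 * eb.betas)
        lhs = P.score(geno, combo)
        rhs = 2.0 * P.score(geno, ea) - 0.5 * P.score(geno, eb)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_swapped_alleles_flip_contribution(self):
        g = make_geno([[0], [1], [2]])
        fwd = effects_from_sumstats(make_ss([0.5]))
        t = fwd.table.copy()
        t.loc[0, ["effect_allele", "other_allele"]] = ["G", "A"]
        rev = P.AdjustedEffects(t, "flipped")
        np.testing.assert_allclose(P.score(g, fwd), -P.score(g, rev), atol=1e-12)

    def test_zero_overlap_raises(self):
        g = make_geno([[0], [1], [2]])
        eff = effects_from_sumstats(make_ss([0.5], pos=[999_999]))
        with pytest.raises(ConsistencyError):
            P.score(g, eff)
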