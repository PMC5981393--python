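"""Colocalization machinery: Wakefield ABF, posteriors, SMR, HEIDI, tiers."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gwascoloc.coloc import (
    ColocPriors,
    ColocResult,
    abf_from_pvalue,
    align_stats,
    classify,
    coloc_abf,
    heidi_test,
    smr_test,
    wakefield_abf,
    weighted_chi2_sf,
)


def naive_coloc_oracle(l1, l2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Plain-probability enumeration over causal configurations."""
    abf1, abf2 = np.exp(l1), np.exp(l2)
    h0 = 1.0
    h1 = p1 * abf1.sum()
    h2 = p2 * abf2.sum()
    h3 = p1 * p2 * (abf1.sum() * abf2.sum() - (abf1 * abf2).sum())
    h4 = p12 * (abf1 * abf2).sum()
    tot = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / tot


def _table(betas, ses, ids=None, ea="G", oa="A", n=1000):
    betas = np.asarray(betas, float)
    ses = np.asarray(ses, float)
    z = betas / ses
    return pd.DataFrame({
        "chrom": "1", "pos": np.arange(len(betas)),
        "id": ids or [f"s{k}" for k in range(len(betas))],
        "ea": ea, "oa": oa, "eaf": 0.3, "beta": betas, "se": ses,
        "z": z, "p": 2 * stats.norm.sf(np.abs(z)), "n": n,
    })


class TestWakefieldAbf:
    def test_null_effect_is_negative(self):
        lab = wakefield_abf(0.0, 0.1, 0.15**2)
        assert lab == pytest.approx(0.5 * math.log(0.01 / (0.01 + 0.0225)))
        assert lab < 0

    def test_closed_form_scalar(self):
        beta, se, W = 0.5, 0.1, 0.15**2
        V = se**2
        expected = 0.5 * math.log(V / (V + W)) + (beta / se) ** 2 * W / (2 * (V + W))
        assert wakefield_abf(beta, se, W) == pytest.approx(expected, rel=1e-12)

    def test_degenerate_prior_limit(self):
        assert wakefield_abf(0.5, 0.1, 0.0) == pytest.approx(0.0)

    def test_monotone_in_abs_beta(self):
        labs = [wakefield_abf(b, 0.1, 0.15**2) for b in (0.0, 0.1, 0.2, 0.4)]
        assert labs == sorted(labs)

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_abf(0.1, 0.0, 0.0225)


class TestAbfFromPvalue:
    def test_p_one_matches_null_beta_path(self):
        lab_p = abf_from_pvalue(1.0, 0.3, 1000)
        V = 1.0 / (2 * 1000 * 0.3 * 0.7)
        assert lab_p == pytest.approx(wakefield_abf(0.0, math.sqrt(V), 0.15**2))

    def test_variance_halves_when_n_doubles(self):
        # compare implied V through the null ABF value
        l1 = abf_from_pvalue(1.0, 0.5, 1000)
        V1 = 1.0 / (2 * 1000 * 0.25)
        V2 = 1.0 / (2 * 2000 * 0.25)
        assert V2 == V1 / 2
        l2 = abf_from_pvalue(1.0, 0.5, 2000)
        assert l2 < l1  # smaller V -> stronger null shrinkage term

    def test_internal_consistency_with_beta_se_path(self):
        """Matched (beta,se) and (p,maf,n) from one simulated SNP agree."""
        from gwascoloc.association import single_variant_assoc
        from gwascoloc.synthetic import LdBlockSpec, simulate_genotypes

        G = simulate_genotypes(4000, LdBlockSpec(block_sizes=(2,), rho=0.0), seed=51)
        x = G.column("var0").astype(float)
        rng = np.random.default_rng(52)
        y = 0.08 * x + rng.standard_normal(4000)
        y = (y - y.mean()) / y.std()  # sdY = 1 convention
        row = single_variant_assoc(x, y)
        lab_bse = wakefield_abf(row["beta"], row["se"], 0.15**2)
        maf = min(row["eaf"], 1 - row["eaf"])
        lab_p = abf_from_pvalue(row["p"], maf, row["n"])
        assert lab_p == pytest.approx(lab_bse, rel=0.05)

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            abf_from_pvalue(0.5, 0.7, 100)


class TestColocAbf:
    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(53)
        t1 = _table(rng.normal(0, 0.05, 50), np.full(50, 0.05))
        t2 = _table(rng.normal(0, 0.05, 50), np.full(50, 0.05))
        res = coloc_abf(t1, t2)
        assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_naive_enumeration_oracle(self):
        rng = np.random.default_rng(54)
        b1 = rng.normal(0, 0.08, 30)
        b1[7] = 0.6
        b2 = rng.normal(0, 0.08, 30)
        b2[7] = 0.5
        t1 = _table(b1, np.full(30, 0.07))
        t2 = _table(b2, np.full(30, 0.07))
        res = coloc_abf(t1, t2)
        l1 = wakefield_abf(b1, np.full(30, 0.07), 0.15**2)
        l2 = wakefield_abf(b2, np.full(30, 0.07), 0.15**2)
        oracle = naive_coloc_oracle(l1, l2)
        for k in range(5):
            assert res.pp[f"PP_H{k}"] == pytest.approx(oracle[k], abs=1e-8)

    def test_shared_strong_causal_gives_high_h4(self):
        rng = np.random.default_rng(55)
        n_snps = 200
        se = np.full(n_snps, 0.05)
        b1 = rng.normal(0, 0.05, n_snps)
        b2 = rng.normal(0, 0.05, n_snps)
        b1[11] = 12 * 0.05  # z ~ 12 in both traits
        b2[11] = 12 * 0.05
        res = coloc_abf(_table(b1, se), _table(b2, se))
        assert res.pp["PP_H4"] > 0.9

    def test_distinct_causals_favour_h3(self):
        rng = np.random.default_rng(56)
        n_snps = 200
        se = np.full(n_snps, 0.05)
        b1 = rng.normal(0, 0.02, n_snps)
        b2 = rng.normal(0, 0.02, n_snps)
        b1[11] = 10 * 0.05
        b2[120] = 10 * 0.05
        res = coloc_abf(_table(b1, se), _table(b2, se))
        assert res.pp["PP_H3"] > 0.7

    def test_trait_swap_symmetry(self):
        rng = np.random.default_rng(57)
        t1 = _table(rng.normal(0.1, 0.1, 40), np.full(40, 0.06))
        t2 = _table(rng.normal(0, 0.1, 40), np.full(40, 0.06))
        a = coloc_abf(t1, t2)
        b = coloc_abf(t2, t1)
        assert a.pp["PP_H1"] == pytest.approx(b.pp["PP_H2"], abs=1e-10)
        assert a.pp["PP_H2"] == pytest.approx(b.pp["PP_H1"], abs=1e-10)
        for h in ("PP_H0", "PP_H3", "PP_H4"):
            assert a.pp[h] == pytest.approx(b.pp[h], abs=1e-10)

    def test_h4_monotone_in_p12(self):
        rng = np.random.default_rng(58)
        se = np.full(60, 0.05)
        b1 = rng.normal(0, 0.03, 60)
        b2 = rng.normal(0, 0.03, 60)
        b1[5] = b2[5] = 0.35
        t1, t2 = _table(b1, se), _table(b2, se)
        h4 = [
            coloc_abf(t1, t2, priors=ColocPriors(p12=p12)).pp["PP_H4"]
            for p12 in (1e-6, 1e-5, 1e-4)
        ]
        assert h4 == sorted(h4)

    def test_empty_intersection_is_error(self):
        t1 = _table([0.1], [0.05], ids=["a"])
        t2 = _table([0.1], [0.05], ids=["b"])
        with pytest.raises(ValueError):
            coloc_abf(t1, t2)


class TestAlignStats:
    def test_swapped_alleles_flip_beta(self):
        t1 = _table([0.2, 0.1], [0.05, 0.05])
        t2 = _table([-0.2, 0.1], [0.05, 0.05], ea="A", oa="G")
        a1, a2 = align_stats(t1, t2)
        assert a2.loc[0, "beta"] == pytest.approx(0.2)
        assert (a2["ea"] == "G").all()

    def test_strand_ambiguous_mismatch_dropped(self):
        t1 = _table([0.2], [0.05], ea="A", oa="T")
        t2 = _table([0.2], [0.05], ea="C", oa="G")
        with pytest.warns(UserWarning, match="ambiguous|mismatch"):
            a1, a2 = align_stats(t1, t2)
        assert len(a1) == 0


class TestSmr:
    def test_arithmetic_and_tail(self):
        t, p = smr_test(4.0, 4.0)
        assert t == pytest.approx(8.0)
        assert p == pytest.approx(stats.chi2.sf(8.0, 1), rel=1e-12)

    def test_limit_large_eqtl_z(self):
        t, _ = smr_test(3.0, 1e8)
        assert t == pytest.approx(9.0, rel=1e-6)

    def test_null_gwas(self):
        assert smr_test(0.0, 5.0) == (0.0, 1.0)

    def test_both_zero(self):
        assert smr_test(0.0, 0.0) == (0.0, 1.0)

    def test_symmetry_and_bound(self):
        t_ab, p_ab = smr_test(2.5, 6.0)
        t_ba, p_ba = smr_test(6.0, 2.5)
        assert t_ab == pytest.approx(t_ba)
        assert p_ab == pytest.approx(p_ba)
        assert t_ab <= 2.5**2


class TestWeightedChi2:
    def test_single_weight_matches_chi2(self):
        for x in (0.5, 2.0, 6.0):
            assert weighted_chi2_sf(x, np.array([1.0])) == pytest.approx(
                stats.chi2.sf(x, 1), abs=1e-6
            )

    def test_equal_weights_match_scaled_chi2(self):
        # sum of k chi2_1 scaled by w ~ w * chi2_k
        for x in (1.0, 5.0, 12.0):
            assert weighted_chi2_sf(x, np.array([0.5] * 4)) == pytest.approx(
                stats.chi2.sf(x / 0.5, 4), abs=1e-6
            )

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(59)
        w = np.array([2.0, 1.0, 0.5, 0.25])
        draws = (w[None, :] * rng.chisquare(1, size=(200_000, 4))).sum(axis=1)
        x = 6.0
        mc = (draws > x).mean()
        assert weighted_chi2_sf(x, w) == pytest.approx(mc, abs=0.01)

    def test_nonpositive_statistic_returns_one(self):
        assert weighted_chi2_sf(0.0, np.array([1.0, 2.0])) == 1.0


def _heidi_inputs(bxy, be, se_g, se_e, r):
    ids = [f"s{k}" for k in range(len(be))]
    return pd.DataFrame({
        "id": ids,
        "beta_gwas": bxy * be,
        "se_gwas": se_g,
        "beta_eqtl": be,
        "se_eqtl": se_e,
        "p_eqtl": 2 * stats.norm.sf(np.abs(be / se_e)),
    }), pd.DataFrame(r, index=ids, columns=ids)


def _ar_corr(k, rho=0.85):
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_heidi_summary(rng, shared=True, k=8, n_g=20000, n_e=1000,
                           rho=0.85, be_top=0.35, bxy=0.17):
    """Summary-level locus simulation for HEIDI: marginal effects are the
    causal effect propagated through LD, estimates drawn MVN(b, se^2 R)."""
    R = _ar_corr(k, rho)
    L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
    se_e = np.full(k, 1 / math.sqrt(n_e))
    se_g = np.full(k, 1 / math.sqrt(n_g))
    be_causal = np.zeros(k)
    be_causal[0] = be_top
    be = R @ be_causal  # marginal eQTL effects
    if shared:
        bg = bxy * be  # GWAS effect mediated by expression: bxy constant
    else:
        bg_causal = np.zeros(k)
        bg_causal[k - 1] = bxy * be_top
        bg = R @ bg_causal
    be_hat = be + se_e * (L @ rng.standard_normal(k))
    bg_hat = bg + se_g * (L @ rng.standard_normal(k))
    ids = [f"s{j}" for j in range(k)]
    df = pd.DataFrame({
        "id": ids, "beta_gwas": bg_hat, "se_gwas": se_g,
        "beta_eqtl": be_hat, "se_eqtl": se_e,
        "p_eqtl": 2 * stats.norm.sf(np.abs(be_hat / se_e)),
    })
    return df, pd.DataFrame(R, index=ids, columns=ids)


class TestHeidi:
    def test_exactly_proportional_betas_give_p_one(self):
        k = 6
        be = np.linspace(0.8, 0.3, k)
        df, R = _heidi_inputs(np.full(k, 0.5), be, np.full(k, 0.02),
                              np.full(k, 0.02), _ar_corr(k))
        p, n_used, flag = heidi_test("s0", df, R)
        assert flag == ""
        assert p == pytest.approx(1.0)

    def test_too_few_neighbors_flagged_not_computed(self):
        k = 3
        be = np.array([0.8, 0.7, 0.6])
        df, R = _heidi_inputs(np.full(k, 0.5), be, np.full(k, 0.02),
                              np.full(k, 0.02), _ar_corr(k, rho=0.6))
        p, n_used, flag = heidi_test("s0", df, R)
        assert flag == "not-computed"
        assert math.isnan(p)

    def test_null_calibration_under_pleiotropy(self):
        """One shared causal variant: HEIDI rejects at ~ the nominal rate."""
        rng = np.random.default_rng(60)
        n_reps, rejections, computed = 400, 0, 0
        for _ in range(n_reps):
            df, R = simulate_heidi_summary(rng, shared=True)
            p, _, flag = heidi_test("s0", df, R)
            if flag:
                continue
            computed += 1
            rejections += p < 0.05
        assert computed > 0.9 * n_reps
        rate = rejections / computed
        assert 0.02 <= rate <= 0.08

    def test_power_against_linkage(self):
        """Two distinct causal variants: HEIDI should usually reject."""
        rng = np.random.default_rng(61)
        n_reps, rejections, computed = 100, 0, 0
        for _ in range(n_reps):
            df, R = simulate_heidi_summary(rng, shared=False)
            p, _, flag = heidi_test("s0", df, R)
            if flag:
                continue
            computed += 1
            rejections += p < 0.05
        assert rejections / max(computed, 1) > 0.5


class TestClassify:
    def _res(self, pp_h4, p_smr=float("nan"), p_heidi=float("nan")):
        pp = {f"PP_H{k}": 0.0 for k in range(5)}
        pp["PP_H4"] = pp_h4
        pp["PP_H0"] = 1 - pp_h4
        return ColocResult(pp=pp, p_smr=p_smr, p_heidi=p_heidi)

    def test_high_h4_is_strong(self):
        assert classify(self._res(0.95)).tier == "strong"

    def test_mid_h4_is_nominal(self):
        r = classify(self._res(0.4, p_smr=0.2))
        assert r.tier == "nominal" and not r.pleiotropy

    def test_smr_heidi_clause_is_strong_pleiotropy(self):
        r = classify(self._res(0.2, p_smr=0.01, p_heidi=0.3))
        assert r.tier == "strong" and r.pleiotropy

    def test_moderate_band(self):
        assert classify(self._res(0.6)).tier == "moderate"

    def test_missing_heidi_disables_pleiotropy_clause(self):
        r = classify(self._res(0.2, p_smr=0.01))
        assert not r.pleiotropy and r.tier == "nominal"

    def test_none_tier(self):
        assert classify(self._res(0.1, p_smr=0.5)).tier == "none"
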