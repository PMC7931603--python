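"""Mendelian-randomization suite: harmonization, pruning, the three
estimators against independent oracles, multivariable and bidirectional
MR, and the causal decision rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urateaf import (SummaryStatConfig, bidirectional_mr, causal_decision,
                     compare_runs, egger, generate_mediation_stats,
                     generate_summary_stats, harmonize, is_palindromic, ivw,
                     multivariable_mr, prune_by_distance, select_instruments,
                     weighted_median)
from urateaf.mr import MREstimate, flag_palindromic

from conftest import make_instruments


class TestPalindromic:
    @pytest.mark.parametrize("ea,oa,expected", [
        ("A", "T", True), ("T", "A", True), ("G", "C", True), ("C", "G", True),
        ("A", "G", False), ("A", "C", False), ("G", "T", False),
    ])
    def test_examples(self, ea, oa, expected):
        assert is_palindromic(ea, oa) is expected

    def test_case_insensitive(self):
        assert is_palindromic("a", "t")

    def test_invalid_allele(self):
        with pytest.raises(ValueError):
            is_palindromic("A", "N")


def gwas_frame(rows):
    return pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA",
                                       "EAF", "BETA", "SE", "P"])


class TestHarmonize:
    def exposure(self):
        return gwas_frame([
            ("rs1", 1, 1_000_000, "A", "G", 0.3, 0.05, 0.005, 1e-20),
            ("rs2", 1, 3_000_000, "C", "T", 0.4, -0.04, 0.005, 1e-15),
            ("rs3", 1, 5_000_000, "A", "T", 0.5, 0.03, 0.005, 1e-10),
        ])

    def test_swapped_alleles_flip_outcome_beta(self):
        out = gwas_frame([
            ("rs1", 1, 1_000_000, "G", "A", 0.7, -0.02, 0.003, 1e-8),
        ])
        inst = harmonize(self.exposure(), out)
        row = inst.table.iloc[0]
        assert row["flipped"]
        assert row["beta_out"] == pytest.approx(0.02)
        assert row["beta_exp"] == pytest.approx(0.05)

    def test_strand_complement_resolved(self):
        # outcome reports rs1 on the other strand: A/G -> T/C
        out = gwas_frame([
            ("rs1", 1, 1_000_000, "T", "C", 0.3, 0.02, 0.003, 1e-8),
        ])
        inst = harmonize(self.exposure(), out)
        assert inst.table.iloc[0]["beta_out"] == pytest.approx(0.02)

    def test_orientation_makes_exposure_beta_positive(self):
        out = gwas_frame([
            ("rs2", 1, 3_000_000, "C", "T", 0.4, -0.01, 0.003, 1e-8),
        ])
        inst = harmonize(self.exposure(), out)
        row = inst.table.iloc[0]
        assert row["beta_exp"] == pytest.approx(0.04)  # re-oriented
        assert row["beta_out"] == pytest.approx(0.01)

    def test_palindromic_dropped_by_default(self):
        out = gwas_frame([
            ("rs3", 1, 5_000_000, "A", "T", 0.5, 0.01, 0.003, 1e-8),
            ("rs1", 1, 1_000_000, "A", "G", 0.3, 0.02, 0.003, 1e-8),
        ])
        inst = harmonize(self.exposure(), out)
        assert list(inst.table["SNP"]) == ["rs1"]
        assert list(inst.dropped["reason"]) == ["palindromic"]
        kept = harmonize(self.exposure(), out, drop_ambiguous=False)
        assert set(kept.table["SNP"]) == {"rs1", "rs3"}

    def test_all_palindromic_set_errors(self):
        exp = gwas_frame([("rs9", 1, 1, "A", "T", 0.5, 0.05, 0.005, 1e-10)])
        out = gwas_frame([("rs9", 1, 1, "A", "T", 0.5, 0.01, 0.003, 1e-8)])
        with pytest.raises(ValueError):
            harmonize(exp, out)

    def test_mismatched_alleles_dropped_with_reason(self):
        out = gwas_frame([
            ("rs1", 1, 1_000_000, "A", "C", 0.3, 0.02, 0.003, 1e-8),
            ("rs2", 1, 3_000_000, "C", "T", 0.4, 0.01, 0.003, 1e-8),
        ])
        inst = harmonize(self.exposure(), out)
        assert list(inst.table["SNP"]) == ["rs2"]
        assert list(inst.dropped["reason"]) == ["allele_mismatch"]

    def test_empty_intersection_errors(self):
        out = gwas_frame([("rsX", 1, 1, "A", "G", 0.3, 0.02, 0.003, 1e-8)])
        with pytest.raises(ValueError, match="shared"):
            harmonize(self.exposure(), out)

    def test_label_randomization_leaves_ivw_invariant(self):
        """Randomly swapping EA/OA in the outcome file (negating beta,
        complementing EAF) must not change the harmonized IVW estimate."""
        e, o = generate_summary_stats(
            SummaryStatConfig(n_snps_exposure=30, true_causal_effect=0.05,
                              seed=55))
        base = ivw(harmonize(e, o))
        rng = np.random.default_rng(0)
        o2 = o.copy()
        swap = rng.random(len(o2)) < 0.5
        o2.loc[swap, ["EA", "OA"]] = o2.loc[swap, ["OA", "EA"]].to_numpy()
        o2.loc[swap, "BETA"] *= -1
        o2.loc[swap, "EAF"] = 1 - o2.loc[swap, "EAF"]
        swapped = ivw(harmonize(e, o2))
        assert swapped.theta == pytest.approx(base.theta, abs=1e-12)


class TestPrune:
    def frame(self, positions, pvalues):
        return pd.DataFrame({
            "SNP": [f"rs{i}" for i in range(len(positions))],
            "CHR": 1, "POS": positions, "p_exp": pvalues,
        })

    def test_two_close_snps_keep_smaller_p(self):
        out = prune_by_distance(self.frame([1_000_000, 1_400_000],
                                           [1e-8, 1e-12]))
        assert list(out["SNP"]) == ["rs1"]

    def test_far_apart_identity(self):
        t = self.frame([1_000_000, 2_100_000, 3_200_000], [1e-8, 1e-9, 1e-10])
        assert len(prune_by_distance(t)) == 3

    def test_three_snp_greedy_hand_trace(self):
        # positions 0 / 450 kb / 900 kb with p descending: the smallest-p
        # third SNP is kept, the second falls inside its window, the first
        # survives (900 kb from the third)
        out = prune_by_distance(self.frame([0, 450_000, 900_000],
                                           [1e-8, 1e-9, 1e-10]))
        assert list(out["SNP"]) == ["rs0", "rs2"]

    def test_chromosomes_pruned_independently(self):
        t = self.frame([1_000_000, 1_100_000], [1e-8, 1e-9])
        t.loc[1, "CHR"] = 2
        assert len(prune_by_distance(t)) == 2


class TestIVW:
    def test_single_snp_wald_ratio(self):
        inst = make_instruments([0.05], [0.005], [0.002], [0.003])
        est = ivw(inst)
        assert est.theta == pytest.approx(0.002 / 0.05)
        assert est.n_snps == 1

    def test_identical_snps_no_heterogeneity(self):
        inst = make_instruments([0.05] * 4, [0.005] * 4, [0.0025] * 4,
                                [0.003] * 4)
        est = ivw(inst)
        assert est.theta == pytest.approx(0.05)
        assert est.Q == pytest.approx(0.0, abs=1e-20)
        assert est.p_het == pytest.approx(1.0)

    def test_three_snp_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            bx = rng.uniform(0.01, 0.1, 3)
            by = rng.normal(0.05 * bx, 0.01)
            sy = rng.uniform(0.002, 0.01, 3)
            inst = make_instruments(bx, np.full(3, 0.005), by, sy)
            est = ivw(inst)
            # independent oracle: weighted least squares through the origin
            # via the design-matrix route
            w = 1 / sy**2
            theta_or = np.linalg.lstsq(
                (np.sqrt(w) * bx)[:, None], np.sqrt(w) * by, rcond=None)[0][0]
            assert est.theta == pytest.approx(theta_or, abs=1e-10)

    def test_random_effects_never_shrink_se(self):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.02, 0.08, 20)
        by = 0.05 * bx + rng.normal(0, 0.02, 20)  # overdispersed
        inst = make_instruments(bx, np.full(20, 0.005), by, np.full(20, 0.003))
        assert ivw(inst).se >= ivw(inst, random_effects=False).se

    def test_empty_set_errors(self):
        inst = make_instruments([], [], [], [])
        with pytest.raises(ValueError):
            ivw(inst)


class TestEgger:
    def test_two_snps_underdetermined(self):
        inst = make_instruments([0.05, 0.06], [0.005] * 2, [0.002, 0.003],
                                [0.003] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            egger(inst)

    def test_exact_line_recovered(self):
        bx = np.array([0.02, 0.05, 0.08, 0.03])
        inst = make_instruments(bx, np.full(4, 0.005), 0.05 * bx,
                                np.full(4, 0.003))
        est = egger(inst)
        assert est.theta == pytest.approx(0.05, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_statsmodels_wls_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        bx = rng.uniform(0.01, 0.1, 12)
        by = 0.002 + 0.04 * bx + rng.normal(0, 0.003, 12)
        sy = rng.uniform(0.002, 0.006, 12)
        inst = make_instruments(bx, np.full(12, 0.005), by, sy)
        est = egger(inst)
        ref = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert est.intercept == pytest.approx(ref.params[0], abs=1e-10)
        assert est.theta == pytest.approx(ref.params[1], abs=1e-10)

    def test_pleiotropy_simulation_recovery(self):
        e, o = generate_summary_stats(
            SummaryStatConfig(n_snps_exposure=50, true_causal_effect=0.02,
                              pleiotropy_intercept=0.01, seed=42))
        est = egger(select_instruments(e, o))
        assert abs(est.intercept - 0.01) < 3 * est.intercept_se
        assert abs(est.theta - 0.02) < 3 * est.se

    def test_intercept_type_i_error_under_no_pleiotropy(self):
        hits = 0
        n_sim = 200
        for s in range(n_sim):
            e, o = generate_summary_stats(
                SummaryStatConfig(n_snps_exposure=30, true_causal_effect=0.05,
                                  seed=3000 + s))
            hits += egger(select_instruments(e, o)).intercept_p < 0.05
        # nominal 5% within 4 binomial SEs
        assert hits / n_sim < 0.05 + 4 * np.sqrt(0.05 * 0.95 / n_sim)

    def test_requires_positive_orientation(self):
        inst = make_instruments([0.05, -0.06, 0.07], [0.005] * 3,
                                [0.002, 0.003, 0.004], [0.003] * 3)
        with pytest.raises(ValueError, match="orient"):
            egger(inst)


class TestWeightedMedian:
    def test_equal_weights_odd_is_middle_ratio(self):
        bx = np.full(5, 0.05)
        ratios = np.array([0.01, 0.03, 0.05, 0.07, 0.2])
        inst = make_instruments(bx, np.full(5, 0.005), ratios * bx,
                                np.full(5, 0.003))
        est = weighted_median(inst, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.05)

    @pytest.mark.parametrize("J", [5, 6, 9, 10])
    def test_equal_weights_equals_plain_median(self, J):
        rng = np.random.default_rng(J)
        ratios = rng.normal(0.05, 0.03, J)
        bx = np.full(J, 0.05)
        inst = make_instruments(bx, np.full(J, 0.005), ratios * bx,
                                np.full(J, 0.003))
        est = weighted_median(inst, n_boot=50, seed=0)
        assert est.theta == pytest.approx(np.median(ratios), abs=1e-12)

    def test_constant_ratio_and_vanishing_se(self):
        """All ratios equal c -> estimate c; the bootstrap SE shrinks in
        proportion as the sampling errors vanish."""
        bx = np.array([0.02, 0.05, 0.08])
        ses = []
        for se in (1e-5, 1e-7):
            inst = make_instruments(bx, np.full(3, se), 0.04 * bx,
                                    np.full(3, se))
            est = weighted_median(inst, n_boot=200, seed=1)
            assert est.theta == pytest.approx(0.04)
            ses.append(est.se)
        assert ses[0] < 1e-3
        assert ses[1] < ses[0] / 50

    def test_robust_to_forty_percent_invalid(self):
        """With 40% of instruments (the weaker ones) carrying a directional
        pleiotropic offset, valid instruments keep the majority of the
        weight: the weighted median stays near the true effect while the
        IVW point estimate is dragged far beyond its fixed-effects SE."""
        rng = np.random.default_rng(21)
        J, n_inv = 30, 12
        bx = np.empty(J)
        bx[:n_inv] = rng.uniform(0.02, 0.04, n_inv)
        bx[n_inv:] = rng.uniform(0.04, 0.09, J - n_inv)
        sy = np.full(J, 0.003)
        by = 0.05 * bx + rng.normal(0, sy)
        by[:n_inv] += 0.01  # directional pleiotropy on the invalid 40%
        inst = make_instruments(bx, np.full(J, 0.004), by, sy)
        wm = weighted_median(inst, n_boot=500, seed=2)
        iv = ivw(inst, random_effects=False)
        assert abs(wm.theta - 0.05) < 3 * wm.se
        assert abs(iv.theta - 0.05) > 2 * iv.se


class TestEstimatorAlgebra:
    @settings(derandomize=True, max_examples=50)
    @given(scale=st.floats(0.1, 10.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        J = 8
        bx = rng.uniform(0.02, 0.1, J)
        by = 0.05 * bx + rng.normal(0, 0.004, J)
        sy = rng.uniform(0.002, 0.006, J)
        a = make_instruments(bx, np.full(J, 0.005), by, sy)
        b = make_instruments(scale * bx, np.full(J, 0.005), by, sy)
        assert ivw(b).theta == pytest.approx(ivw(a).theta / scale, rel=1e-9)
        assert egger(b).theta == pytest.approx(egger(a).theta / scale,
                                               rel=1e-9)
        wm_a = weighted_median(a, n_boot=50, seed=1).theta
        wm_b = weighted_median(b, n_boot=50, seed=1).theta
        assert wm_b == pytest.approx(wm_a / scale, rel=1e-9)

    def test_ivw_equals_egger_with_intercept_forced_zero(self):
        rng = np.random.default_rng(5)
        J = 10
        bx = rng.uniform(0.02, 0.1, J)
        by = 0.05 * bx + rng.normal(0, 0.004, J)
        sy = rng.uniform(0.002, 0.006, J)
        inst = make_instruments(bx, np.full(J, 0.005), by, sy)
        w = 1 / sy**2
        # Egger normal equations with the intercept row deleted == IVW
        theta_no_int = np.sum(w * bx * by) / np.sum(w * bx * bx)
        assert ivw(inst).theta == pytest.approx(theta_no_int, abs=1e-14)


class TestMVMR:
    def trio(self, seed=0):
        return generate_mediation_stats(SummaryStatConfig(
            n_snps_exposure=30, true_causal_effect=0.0,
            mediator_effect_on_exposure=1.0, mediator_effect_on_outcome=0.08,
            instrument_strength_range=(0.015, 0.05),
            mediator_strength_range=(0.03, 0.10), seed=seed))

    @staticmethod
    def merged(d, m, u):
        mm = d.merge(m, on="SNP", suffixes=("_d", "_m")).merge(u, on="SNP")
        return (np.column_stack([mm["BETA_d"], mm["BETA_m"]]),
                np.column_stack([mm["SE_d"], mm["SE_m"]]),
                mm["BETA"].to_numpy(), mm["SE"].to_numpy())

    def test_null_second_exposure_reduces_to_univariate(self):
        rng = np.random.default_rng(8)
        J = 20
        bx1 = rng.uniform(0.02, 0.08, J)
        bx2 = np.zeros(J)
        sy = np.full(J, 0.003)
        by = 0.05 * bx1 + rng.normal(0, sy)
        res = multivariable_mr(np.column_stack([bx1, bx2]),
                               np.full((J, 2), 0.004), by, sy)
        w = 1 / sy**2
        uni = np.sum(w * bx1 * by) / np.sum(w * bx1 * bx1)
        assert res.theta[0] == pytest.approx(uni, abs=2e-3)
        assert abs(res.theta[1]) < 3 * res.se[1]

    def test_full_mediation_recovers_null_direct_diet_effect(self):
        d, m, u = self.trio(seed=101)
        res = multivariable_mr(*self.merged(d, m, u), exposures=("diet", "bmi"))
        assert abs(res.theta[0]) < 3 * res.se[0]          # diet direct ~ 0
        assert abs(res.theta[1] - 0.08) < 3 * res.se[1]   # bmi recovered
        # while the univariate route is confounded
        uni = ivw(select_instruments(d, u))
        assert uni.p < 0.05

    def test_likelihood_and_wls_routes_agree(self):
        d, m, u = self.trio(seed=7)
        bx, sx, by, sy = self.merged(d, m, u)
        lik = multivariable_mr(bx, sx, by, sy)
        assert lik.converged
        for k in range(2):
            assert lik.theta[k] == pytest.approx(lik.theta_wls[k],
                                                 abs=4 * lik.se[k])

    def test_duplicate_exposures_warn(self):
        rng = np.random.default_rng(2)
        J = 15
        bx = rng.uniform(0.02, 0.08, J)
        by = 0.05 * bx + rng.normal(0, 0.003, J)
        with pytest.warns(UserWarning, match="collinear"):
            multivariable_mr(np.column_stack([bx, bx]),
                             np.full((J, 2), 0.004), by, np.full(J, 0.003))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            multivariable_mr(np.zeros((5, 1)), np.ones((5, 1)),
                             np.zeros(5), np.ones(5))
        with pytest.raises(ValueError):
            multivariable_mr(np.ones((2, 2)), np.ones((2, 2)),
                             np.zeros(2), np.ones(2))


class TestBidirectional:
    def test_causal_direction_detected_reverse_null(self):
        cfg_fwd = SummaryStatConfig(n_snps_exposure=20, true_causal_effect=0.05,
                                    seed=61)
        a, b = generate_summary_stats(cfg_fwd)
        # instruments for the reverse direction: b's own hits are a's
        # downstream consequences only through noise here, so simulate an
        # independent b-GWAS with null effect on a
        cfg_rev = SummaryStatConfig(n_snps_exposure=20, true_causal_effect=0.0,
                                    seed=62)
        b2, a2 = generate_summary_stats(cfg_rev)
        b_full = pd.concat([b, b2], ignore_index=True)
        a_full = pd.concat([a, a2], ignore_index=True)
        b_full["SNP"] = [f"rs{i}" for i in range(len(b_full))]
        a_full["SNP"] = b_full["SNP"]
        pos = (np.arange(len(b_full)) + 1) * 2_000_000
        b_full["POS"] = a_full["POS"] = pos
        est_ab, est_ba, both = bidirectional_mr(a_full, b_full)
        assert est_ab.p < 0.05

    def test_swapping_arguments_swaps_estimates(self):
        e, o = generate_summary_stats(
            SummaryStatConfig(n_snps_exposure=25, true_causal_effect=0.05,
                              seed=33))
        # make the outcome trait instrumentable too
        o = o.copy()
        o["P"] = 1e-10
        ab1, ba1, _ = bidirectional_mr(e, o)
        ab2, ba2, _ = bidirectional_mr(o, e)
        assert ab1.theta == pytest.approx(ba2.theta)
        assert ba1.theta == pytest.approx(ab2.theta)

    def test_symmetric_null_type_i_error(self):
        sig = 0
        n_sim = 100
        for s in range(n_sim):
            e, o = generate_summary_stats(
                SummaryStatConfig(n_snps_exposure=20, true_causal_effect=0.0,
                                  seed=5000 + s))
            sig += ivw(select_instruments(e, o)).p < 0.05
        assert sig <= 10  # ~5% nominal, binomial slack


class TestCausalDecision:
    @staticmethod
    def est(p, intercept_p=None):
        return MREstimate("m", 0.05, 0.01, (0.03, 0.07), p, 10,
                          intercept=0.0, intercept_p=intercept_p)

    def test_skim_milk_pattern_called_causal(self):
        call = causal_decision(self.est(3.8e-8), self.est(3.8e-5),
                               self.est(0.9, intercept_p=0.26), n_tests=87)
        assert call.causal

    def test_egger_intercept_veto(self):
        call = causal_decision(self.est(1e-8), self.est(0.03),
                               self.est(0.9, intercept_p=0.01), n_tests=87)
        assert not call.causal and call.ivw_pass and call.wm_pass

    def test_single_test_threshold_is_nominal(self):
        call = causal_decision(self.est(0.04), self.est(0.03),
                               self.est(0.9, intercept_p=0.5), n_tests=1)
        assert call.ivw_pass and call.causal

    def test_bonferroni_boundary(self):
        thr = 0.05 / 87
        assert causal_decision(self.est(thr * 0.99), self.est(0.01),
                               self.est(0.5, intercept_p=0.5)).ivw_pass
        assert not causal_decision(self.est(thr * 1.01), self.est(0.01),
                                   self.est(0.5, intercept_p=0.5)).ivw_pass


class TestCompareRuns:
    def test_identical_runs_full_concordance(self):
        run = {f"e{i}": 0.01 * (i + 1) for i in range(5)}
        _, summary = compare_runs(run, dict(run))
        assert summary["sign_concordance"] == 1.0

    def test_one_flip_reduces_concordance(self):
        a = {f"e{i}": 0.01 * (i + 1) for i in range(5)}
        b = dict(a)
        b["e0"] = -a["e0"]
        _, summary = compare_runs(a, b)
        assert summary["sign_concordance"] == pytest.approx(4 / 5)

    def test_no_strand_error_high_concordance(self):
        """Palindromic SNPs generated without strand error: strict and
        ambiguous-included runs agree in sign for nearly every exposure."""
        strict, loose = {}, {}
        for i in range(20):
            cfg = SummaryStatConfig(n_snps_exposure=25, true_causal_effect=0.05,
                                    frac_palindromic=0.3, seed=800 + i)
            e, o = generate_summary_stats(cfg)
            strict[f"exp{i}"] = ivw(select_instruments(e, o)).theta
            loose[f"exp{i}"] = ivw(
                select_instruments(e, o, drop_ambiguous=False)).theta
        df, summary = compare_runs(strict, loose)
        assert summary["sign_concordance"] >= 0.95
        assert summary["spearman_rho"] > 0.8
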