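"""Two-sample Mendelian randomization estimators and sensitivity suite."""

import warnings

import numpy as np
import pandas as pd
import pytest

import crosstrait as ct
from crosstrait.mr import run_estimators
from crosstrait.simulate import SimMRConfig, mr_tables_from_dataset, simulate_mr

from conftest import make_sumstats


def _mr_frame(bx, by, sx=0.01, sy=0.01):
    n = len(bx)
    return pd.DataFrame({
        "SNP": [f"iv{i}" for i in range(n)],
        "beta_exp": bx, "se_exp": sx, "beta_out": by, "se_out": sy,
    })


class TestHarmonize:
    def _exposure(self):
        return make_sumstats([
            dict(SNP="rs1", CHR=1, BP=100, A1="A", A2="G", BETA=0.10,
                 SE=0.02, N=1e5, EAF=0.3),
            dict(SNP="rs2", CHR=1, BP=200, A1="A", A2="T", BETA=0.08,
                 SE=0.02, N=1e5, EAF=0.1),
            dict(SNP="rs3", CHR=1, BP=300, A1="C", A2="G", BETA=0.07,
                 SE=0.02, N=1e5, EAF=0.2),
            dict(SNP="rs4", CHR=1, BP=400, A1="A", A2="G", BETA=0.06,
                 SE=0.02, N=1e5, EAF=0.4),
            dict(SNP="rs5", CHR=1, BP=500, A1="A", A2="G", BETA=0.05,
                 SE=0.02, N=1e5, EAF=0.5),
        ])

    def _outcome(self):
        rows = []
        for snp, bp, a1, a2, beta in [
            ("rs1", 100, "G", "A", 0.05), ("rs2", 200, "A", "T", 0.02),
            ("rs3", 300, "C", "G", 0.01), ("rs4", 400, "A", "G", 0.03),
        ]:
            rows.append(dict(SNP=snp, CHR=1, BP=bp, A1=a1, A2=a2, BETA=beta,
                             SE=0.02, N=5e4, EAF=0.3))
        return make_sumstats(rows)

    def test_allele_flip_negates_outcome_beta(self):
        ds = ct.harmonize_mr(self._exposure(), self._outcome())
        row = ds[ds["SNP"] == "rs1"].iloc[0]
        assert row["beta_out"] == pytest.approx(-0.05)

    def test_drop_palindromic_flag(self):
        ds = ct.harmonize_mr(self._exposure(), self._outcome(),
                             drop_palindromic=True)
        assert set(ds["SNP"]) == {"rs1", "rs4"}
        assert ds.attrs["n_palindromic_dropped"] == 2

    def test_missing_in_outcome_dropped_and_counted(self):
        ds = ct.harmonize_mr(self._exposure(), self._outcome())
        assert "rs5" not in set(ds["SNP"])
        assert ds.attrs["n_missing_in_outcome"] == 1

    def test_pleiotropy_list_excluded(self):
        ds = ct.harmonize_mr(self._exposure(), self._outcome(),
                             pleiotropy_list=["rs1"])
        assert "rs1" not in set(ds["SNP"])
        assert ds.attrs["n_pleiotropic_dropped"] == 1

    def test_ambiguous_frequency_palindromic_dropped(self):
        exp = make_sumstats([
            dict(SNP="rs1", CHR=1, BP=100, A1="A", A2="T", BETA=0.1, SE=0.02,
                 N=1e5, EAF=0.5),   # ambiguous band
            dict(SNP="rs2", CHR=1, BP=200, A1="A", A2="G", BETA=0.1, SE=0.02,
                 N=1e5, EAF=0.3),
            dict(SNP="rs3", CHR=1, BP=300, A1="A", A2="G", BETA=0.1, SE=0.02,
                 N=1e5, EAF=0.3),
        ])
        out = make_sumstats([
            dict(SNP="rs1", CHR=1, BP=100, A1="A", A2="T", BETA=0.1, SE=0.02,
                 N=1e5, EAF=0.5),
            dict(SNP="rs2", CHR=1, BP=200, A1="A", A2="G", BETA=0.1, SE=0.02,
                 N=1e5, EAF=0.3),
            dict(SNP="rs3", CHR=1, BP=300, A1="A", A2="G", BETA=0.1, SE=0.02,
                 N=1e5, EAF=0.3),
        ])
        ds = ct.harmonize_mr(exp, out, drop_palindromic=False)
        assert "rs1" not in set(ds["SNP"])


class TestIvw:
    def test_equal_ratios_recovered_exactly(self):
        d = _mr_frame([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        assert ct.ivw(d).theta == pytest.approx(0.5, rel=1e-12)

    def test_closed_form_weighted_ratio(self):
        d = _mr_frame([0.1, 0.1], [0.02, 0.04])
        assert ct.ivw(d).theta == pytest.approx(0.3, rel=1e-12)

    def test_single_pair_equals_wald_ratio(self):
        d = _mr_frame([0.1, 0.1], [0.05, 0.05])
        assert ct.ivw(d).theta == pytest.approx(0.5)

    def test_fixed_se_never_exceeds_random_se(self):
        for seed in range(10):
            ds, _ = simulate_mr(SimMRConfig(n_iv=50, var_gamma=0.01,
                                            theta_true=0.2, seed=seed))
            assert ct.ivw(ds, model="fixed").se <= ct.ivw(ds, model="random").se + 1e-15

    def test_recovers_simulated_effect(self):
        ds, truth = simulate_mr(SimMRConfig(
            n_iv=278, var_gamma=0.003, theta_true=np.log(2.92), seed=0))
        est = ct.ivw(ds)
        assert abs(est.theta - truth["theta"]) < 2 * est.se

    def test_all_zero_exposure_fatal(self):
        d = _mr_frame([0.0, 0.0], [0.1, 0.1])
        with pytest.raises(ct.SumStatsError):
            ct.ivw(d)

    def test_ci_and_or_transformations(self):
        d = _mr_frame([0.1, 0.2, 0.4], [0.05, 0.10, 0.20])
        e = ct.ivw(d)
        assert e.ci_low == pytest.approx(e.theta - 1.96 * e.se, rel=1e-3)
        assert e.or_ == pytest.approx(np.exp(e.theta))


class TestEgger:
    def test_underidentified_with_two_ivs(self):
        with pytest.raises(ct.SumStatsError):
            ct.egger(_mr_frame([0.1, 0.2], [0.05, 0.1]))

    def test_collinear_exposure_fatal(self):
        with pytest.raises(ct.SumStatsError, match="spread"):
            ct.egger(_mr_frame([0.1, 0.1, 0.1], [0.05, 0.06, 0.04]))

    def test_clean_data_null_intercept_and_ivw_like_slope(self):
        ds, _ = simulate_mr(SimMRConfig(n_iv=150, var_gamma=0.01,
                                        theta_true=0.3, se_exp=0.003,
                                        seed=0))
        e = ct.egger(ds)
        assert abs(e.intercept) < 2 * e.intercept_se
        assert e.theta == pytest.approx(ct.ivw(ds).theta, abs=0.1)

    def test_recovers_planted_directional_pleiotropy(self):
        ds, truth = simulate_mr(SimMRConfig(
            n_iv=150, var_gamma=0.01, theta_true=0.3, se_exp=0.003,
            pleiotropy="directional", pleiotropy_mean=0.02,
            pleiotropy_sd=0.01, seed=1))
        e = ct.egger(ds)
        assert abs(e.intercept - truth["pleiotropy_mean"]) < 2 * e.intercept_se

    def test_invariant_to_joint_sign_orientation(self):
        ds, _ = simulate_mr(SimMRConfig(n_iv=50, var_gamma=0.01,
                                        theta_true=0.3, seed=3))
        flipped = ds.copy()
        flip = np.arange(len(ds)) % 2 == 0
        flipped.loc[flip, "beta_exp"] *= -1
        flipped.loc[flip, "beta_out"] *= -1
        a, b = ct.egger(ds), ct.egger(flipped)
        assert a.theta == pytest.approx(b.theta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)


class TestWeightedMedian:
    def test_middle_ratio_with_equal_weights(self):
        d = _mr_frame([0.1, 0.1, 0.1], [0.04, 0.05, 0.06])
        est = ct.weighted_median(d, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.5, abs=0.02)

    def test_dominant_weight_pulls_to_that_ratio(self):
        d = pd.DataFrame({
            "SNP": ["a", "b", "c"],
            "beta_exp": [0.5, 0.1, 0.1], "se_exp": [1e-5, 0.1, 0.1],
            "beta_out": [0.1, 0.09, 0.11], "se_out": [1e-5, 0.2, 0.2],
        })
        est = ct.weighted_median(d, n_boot=50, seed=0)
        assert est.theta == pytest.approx(0.2, abs=0.01)

    def test_robust_to_forty_percent_invalid_instruments(self):
        # invalid instruments with grossly inflated ratios get tiny
        # delta-method weights, so the valid majority keeps the median
        ds, _ = simulate_mr(SimMRConfig(n_iv=100, var_gamma=0.01,
                                        se_exp=0.005, theta_true=0.3, seed=2))
        rng = np.random.default_rng(1002)
        bad = rng.choice(len(ds), size=40, replace=False)
        ds = ds.copy()
        ds.loc[bad, "beta_out"] += 0.5
        est = ct.weighted_median(ds, n_boot=500, seed=0)
        assert abs(est.theta - 0.3) < 2 * est.se
        # the invalid instruments pull IVW far off; the median resists
        assert abs(ct.ivw(ds).theta - 0.3) > abs(est.theta - 0.3)

    def test_bootstrap_seeded(self):
        ds, _ = simulate_mr(SimMRConfig(n_iv=30, var_gamma=0.01,
                                        theta_true=0.2, seed=4))
        a = ct.weighted_median(ds, n_boot=100, seed=9).se
        b = ct.weighted_median(ds, n_boot=100, seed=9).se
        assert a == b


def test_estimators_negate_with_outcome():
    ds, _ = simulate_mr(SimMRConfig(n_iv=60, var_gamma=0.01, theta_true=0.4,
                                    seed=6))
    neg = ds.copy()
    neg["beta_out"] = -neg["beta_out"]
    assert ct.ivw(neg).theta == pytest.approx(-ct.ivw(ds).theta, rel=1e-12)
    assert ct.egger(neg).theta == pytest.approx(-ct.egger(ds).theta, rel=1e-12)
    assert ct.egger(neg).intercept == pytest.approx(
        -ct.egger(ds).intercept, rel=1e-12)
    wm_pos = ct.weighted_median(ds, n_boot=50, seed=0).theta
    wm_neg = ct.weighted_median(neg, n_boot=50, seed=0).theta
    assert wm_neg == pytest.approx(-wm_pos, rel=1e-9)


class TestLeaveOneOut:
    def test_one_row_per_omitted_iv(self):
        ds, _ = simulate_mr(SimMRConfig(n_iv=25, var_gamma=0.01,
                                        theta_true=0.3, seed=0))
        out = ct.leave_one_out(ds)
        assert len(out) == 25

    def test_homogeneous_instruments_stay_in_band(self):
        # equal-strength instruments: no single omission can move the
        # estimate by a full standard error
        rng = np.random.default_rng(1)
        ds = _mr_frame(np.full(50, 0.1), 0.03 + 0.005 * rng.standard_normal(50))
        out = ct.leave_one_out(ds)
        assert not out["outlier_flag"].any()

    def test_planted_outlier_is_extreme_shift(self):
        ds, _ = simulate_mr(SimMRConfig(n_iv=30, var_gamma=0.01,
                                        theta_true=0.3, seed=2))
        ds = ds.copy()
        ds.loc[0, "beta_out"] += 0.3  # gross outlier
        out = ct.leave_one_out(ds)
        extreme = out.loc[out["shift"].abs().idxmax(), "omitted"]
        assert extreme == ds["SNP"].iloc[0]


class TestClusteredMr:
    def test_null_instruments_assigned_to_null_cluster(self):
        ds, _ = simulate_mr(SimMRConfig(n_iv=40, var_gamma=0.01,
                                        theta_true=0.0, seed=9))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ct.clustered_mr(ds, max_k=3, seed=0)
        assert (res.assignments["cluster"] == "null").all()

    def test_two_planted_clusters_recovered(self):
        d1, _ = simulate_mr(SimMRConfig(n_iv=40, var_gamma=0.01,
                                        theta_true=0.5, seed=1))
        d2, _ = simulate_mr(SimMRConfig(n_iv=40, var_gamma=0.01,
                                        theta_true=-0.3, seed=2))
        d2 = d2.copy()
        d2["SNP"] = "x" + d2["SNP"]
        both = pd.concat([d1, d2], ignore_index=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = ct.clustered_mr(both, max_k=3, seed=0)
        means = sorted(m for k, m in res.cluster_means.items()
                       if k.startswith("cluster"))
        assert res.n_clusters == 2
        assert means[0] == pytest.approx(-0.3, abs=0.1)
        assert means[1] == pytest.approx(0.5, abs=0.1)

    def test_single_cluster_selected_by_bic(self):
        good = 0
        for seed in range(10):
            ds, _ = simulate_mr(SimMRConfig(n_iv=40, var_gamma=0.01,
                                            theta_true=0.5, seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ct.clustered_mr(ds, max_k=3, seed=seed)
            good += res.n_clusters == 1
        assert good >= 9


class TestPower:
    def test_reference_scenario_near_eighty_percent(self):
        p = ct.mr_power_binary(113_238, 0.09, 0.04, 1.15, 0.05)
        assert 0.78 < p < 0.85

    def test_null_odds_ratio_gives_alpha(self):
        p = ct.mr_power_binary(113_238, 0.09, 0.04, 1.0, 0.05)
        assert p == pytest.approx(0.05, abs=1e-9)

    def test_monotone_in_sample_size(self):
        grid = [1e4, 1e5, 1e6, 1e8]
        powers = [ct.mr_power_binary(n, 0.09, 0.04, 1.1, 0.05) for n in grid]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        assert powers[-1] > 0.999

    def test_invalid_arguments_fatal(self):
        with pytest.raises(ValueError):
            ct.mr_power_binary(1e5, 0.09, 0.0, 1.1)
        with pytest.raises(ValueError):
            ct.mr_power_binary(1e5, 1.5, 0.04, 1.1)


class TestBidirectional:
    def _tables(self, seed, theta_fwd):
        fwd, _ = simulate_mr(SimMRConfig(n_iv=80, var_gamma=0.005,
                                         theta_true=theta_fwd, seed=seed))
        rev, _ = simulate_mr(SimMRConfig(n_iv=14, var_gamma=0.005,
                                         theta_true=0.0, seed=seed + 5000))
        exp_ivs, out_stats = mr_tables_from_dataset(fwd)
        out_ivs, exp_stats = mr_tables_from_dataset(rev)
        return exp_stats, out_stats, exp_ivs, out_ivs

    def test_forward_detected_reverse_null(self):
        ok_fwd = ok_rev = 0
        n_rep = 100
        for seed in range(n_rep):
            exp_stats, out_stats, exp_ivs, out_ivs = self._tables(seed, 0.5)
            res = ct.bidirectional(exp_stats, out_stats, exp_ivs, out_ivs,
                                   seed=seed, n_boot=50)
            fwd = res["forward"]["estimates"][0]
            rev = res["reverse"]["estimates"][0]
            ok_fwd += fwd.ci_low > 0
            ok_rev += rev.ci_low <= 0 <= rev.ci_high
        assert ok_fwd >= int(0.9 * n_rep)
        assert ok_rev >= int(0.9 * n_rep)

    def test_swapping_roles_swaps_bundles(self):
        exp_stats, out_stats, exp_ivs, out_ivs = self._tables(3, 0.4)
        a = ct.bidirectional(exp_stats, out_stats, exp_ivs, out_ivs, seed=1)
        b = ct.bidirectional(out_stats, exp_stats, out_ivs, exp_ivs, seed=1)
        assert a["forward"]["estimates"][0].theta == pytest.approx(
            b["reverse"]["estimates"][0].theta)

    def test_reverse_uses_exactly_fourteen_instruments(self):
        exp_stats, out_stats, exp_ivs, out_ivs = self._tables(0, 0.5)
        res = ct.bidirectional(exp_stats, out_stats, exp_ivs, out_ivs)
        assert res["reverse"]["estimates"][0].n_iv == 14


def test_run_estimators_returns_all_methods():
    ds, _ = simulate_mr(SimMRConfig(n_iv=50, var_gamma=0.01, theta_true=0.2,
                                    seed=0))
    methods = {e.method for e in run_estimators(ds, n_boot=50)}
    assert {"ivw_random", "ivw_fixed", "egger", "weighted_median"} <= methods
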