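"""Two-sample MR: harmonization, estimators, sensitivity, bidirectional scan."""

import warnings

import numpy as np
import pandas as pd
import pytest

from prsbrain import (
    MendelianRandomization,
    egger,
    gsmr,
    harmonize,
    ivw,
    run_bidirectional,
    select_instruments,
    sensitivity,
    weighted_median,
    weighted_mode,
)
from prsbrain.mr import HarmonizedSet, mr_tier_thresholds


def _sumstats(snps, a1, a2, b, se=0.01, freq=0.3, p=1e-9, n=100_000, **extra):
    k = len(snps)
    tab = pd.DataFrame({
        "SNP": snps, "A1": a1, "A2": a2,
        "freq": np.full(k, freq), "b": b, "se": np.full(k, se),
        "p": np.full(k, p), "N": np.full(k, n),
    })
    for key, val in extra.items():
        tab[key] = val
    return tab


def _hset(b_x, b_y, se_x=0.01, se_y=0.01):
    k = len(b_x)
    return HarmonizedSet(data=pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(k)],
        "b_x": b_x, "se_x": np.full(k, se_x), "p_x": np.full(k, 1e-9),
        "b_y": b_y, "se_y": np.full(k, se_y), "p_y": np.full(k, 0.5),
        "freq": np.full(k, 0.3),
    }))


class TestHarmonize:
    def test_swapped_alleles_negate_outcome_beta(self):
        exp = _sumstats(["rs1"], ["A"], ["G"], [0.1])
        out = _sumstats(["rs1"], ["G"], ["A"], [0.2])
        h = harmonize(exp, out)
        assert h.b_y[0] == pytest.approx(-0.2)
        assert h.flipped == ["rs1"]

    def test_strand_flip_resolved(self):
        exp = _sumstats(["rs1"], ["A"], ["G"], [0.1])
        out = _sumstats(["rs1"], ["T"], ["C"], [0.2])  # complement of A/G
        h = harmonize(exp, out)
        assert h.b_y[0] == pytest.approx(0.2)
        assert not h.flipped

    def test_palindromic_removed_and_flagged(self):
        exp = _sumstats(["rs1", "rs2"], ["A", "C"], ["T", "T"], [0.1, 0.2])
        out = exp.copy()
        h = harmonize(exp, out)
        assert h.snps == ["rs2"]
        assert h.removed_palindromic == ["rs1"]

    def test_identical_tables_pass_through(self):
        exp = _sumstats(["rs1", "rs2", "rs3"], ["A", "C", "G"],
                        ["G", "T", "T"], [0.1, 0.2, 0.3])
        h = harmonize(exp, exp.copy())
        assert h.snps == ["rs1", "rs2", "rs3"]
        np.testing.assert_allclose(h.b_y, [0.1, 0.2, 0.3])

    def test_mismatched_alleles_dropped(self):
        exp = _sumstats(["rs1"], ["A"], ["G"], [0.1])
        out = _sumstats(["rs1"], ["A"], ["C"], [0.2])
        h = harmonize(exp, out)
        assert len(h) == 0 and h.removed_mismatch == ["rs1"]

    def test_empty_intersection_rejected(self):
        exp = _sumstats(["rs1"], ["A"], ["G"], [0.1])
        out = _sumstats(["rs2"], ["A"], ["G"], [0.1])
        with pytest.raises(ValueError, match="share no SNPs"):
            harmonize(exp, out)

    def test_positional_exclusion_regions(self):
        exp = _sumstats(["rs1", "rs2"], ["A", "C"], ["G", "A"], [0.1, 0.2],
                        chr=["17", "2"], bp=[45_000_000, 100])
        out = _sumstats(["rs1", "rs2"], ["A", "C"], ["G", "A"], [0.1, 0.2],
                        chr=["17", "2"], bp=[45_000_000, 100])
        regions = pd.DataFrame(
            {"chrom": ["17"], "start": [43_000_000], "end": [46_000_000]})
        h = harmonize(exp, out, exclude_regions=regions)
        assert h.snps == ["rs2"]
        assert h.removed_region == ["rs1"]


class TestSelectInstruments:
    def test_threshold_one_retains_all(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(seed=1)
        h = harmonize(exp, out)
        assert len(select_instruments(h, 1 - 1e-12)) == len(h)

    def test_no_passing_snp_warns(self):
        h = _hset(np.array([0.1]), np.array([0.0]))
        h.data["p_x"] = 0.5
        with pytest.warns(UserWarning, match="no SNP"):
            kept = select_instruments(h, 5e-8)
        assert len(kept) == 0

    def test_true_instruments_mostly_retained(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(seed=2, n_snps=100, n_instruments=50)
        h = select_instruments(harmonize(exp, out))
        assert len(h) >= 45


class TestIVW:
    def test_single_snp_is_wald_ratio(self):
        h = _hset(np.array([0.1]), np.array([0.05]))
        assert ivw(h).beta_hat == pytest.approx(0.5)

    def test_all_zero_outcome_gives_zero(self):
        h = _hset(np.array([0.1, 0.2, 0.3]), np.zeros(3))
        assert ivw(h).beta_hat == 0.0

    def test_recovers_simulated_effect(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.3, seed=3)
        m = MendelianRandomization(exp, out)
        est = ivw(m.instruments)
        assert abs(est.beta_hat - 0.3) < 1.96 * est.se_hat + 0.01

    def test_order_and_duplication_invariance(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.1, 0.02, 20)
        by = 0.2 * bx + rng.normal(0, 0.005, 20)
        h = _hset(bx, by)
        shuffled = _hset(bx[::-1], by[::-1])
        doubled = _hset(np.r_[bx, bx], np.r_[by, by])
        assert ivw(h).beta_hat == pytest.approx(ivw(shuffled).beta_hat)
        assert ivw(h).beta_hat == pytest.approx(ivw(doubled).beta_hat)

    def test_zero_exposure_effect_dropped_with_warning(self):
        h = _hset(np.array([0.0, 0.1]), np.array([0.1, 0.05]))
        with pytest.warns(UserWarning, match="zero exposure"):
            est = ivw(h)
        assert est.n_iv_used == 1


class TestEgger:
    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError, match="3 instruments"):
            egger(_hset(np.array([0.1, 0.2]), np.array([0.0, 0.1])))

    def test_matches_ivw_on_intercept_free_data(self):
        rng = np.random.default_rng(5)
        bx = rng.normal(0.1, 0.03, 40)
        by = 0.25 * bx  # exact, no intercept, no noise
        h = _hset(bx, by)
        assert egger(h).beta_hat == pytest.approx(ivw(h).beta_hat, abs=1e-9)
        assert egger(h).intercept == pytest.approx(0.0, abs=1e-12)

    def test_directional_pleiotropy_lands_in_intercept(self):
        rng = np.random.default_rng(6)
        c = 0.02
        bx = rng.normal(0.1, 0.03, 200)
        by = 0.25 * bx + c + rng.normal(0, 0.002, 200)
        est = egger(_hset(bx, by, se_y=0.002))
        assert est.intercept == pytest.approx(c, abs=0.005)
        assert est.beta_hat == pytest.approx(0.25, abs=0.05)
        assert est.intercept_p < 1e-6

    def test_directional_pleiotropy_from_simulator(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(
            causal_effect=0.0, seed=7, pleiotropy_fraction=1.0,
            pleiotropy_sd=0.001, pleiotropy_mean=0.01,
        )
        est = egger(MendelianRandomization(exp, out).instruments)
        assert est.intercept_p < 0.01
        assert est.intercept > 0


class TestWeightedMedian:
    def test_odd_equal_weight_middle_ratio(self):
        h = _hset(np.array([0.1, 0.1, 0.1]), np.array([0.01, 0.02, 0.05]))
        est = weighted_median(h, n_boot=50, seed=0)
        assert est.beta_hat == pytest.approx(0.2)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(8)
        bx = rng.normal(0.1, 0.02, 11)
        by = 0.3 * bx + rng.normal(0, 0.01, 11)
        h = _hset(bx, by)
        doubled = _hset(np.r_[bx, bx], np.r_[by, by])
        # interpolation between weight atoms moves the crossing by at most
        # half an atom when every atom is duplicated
        assert weighted_median(h, n_boot=10, seed=1).beta_hat == pytest.approx(
            weighted_median(doubled, n_boot=10, seed=1).beta_hat, abs=2e-3)

    def test_robust_to_half_invalid_instruments(self):
        rng = np.random.default_rng(9)
        k = 40
        bx = rng.normal(0.12, 0.01, k)
        by = 0.2 * bx + rng.normal(0, 0.002, k)
        by[: k // 2 - 1] += 0.05  # just under half get large pleiotropy
        h = _hset(bx, by, se_y=0.002)
        med = weighted_median(h, n_boot=100, seed=2).beta_hat
        naive = ivw(h).beta_hat
        assert abs(med - 0.2) < abs(naive - 0.2)


class TestWeightedMode:
    def test_identical_ratios_returned_exactly(self):
        h = _hset(np.array([0.1, 0.2, 0.4]), np.array([0.05, 0.1, 0.2]))
        est = weighted_mode(h, n_boot=10, seed=0)
        assert est.beta_hat == pytest.approx(0.5)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(10)
        bx = rng.normal(0.1, 0.02, 15)
        by = 0.3 * bx + rng.normal(0, 0.01, 15)
        h1 = _hset(bx, by, se_y=0.01)
        h2 = _hset(bx, by, se_y=0.02)  # scales all weights by 1/4
        assert weighted_mode(h1, n_boot=10, seed=3).beta_hat == pytest.approx(
            weighted_mode(h2, n_boot=10, seed=3).beta_hat, abs=1e-9)

    def test_majority_valid_recovers_truth(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.3, seed=11)
        est = weighted_mode(MendelianRandomization(exp, out).instruments,
                            n_boot=200, seed=4)
        assert abs(est.beta_hat - 0.3) < 2 * est.se_hat + 0.01


class TestGSMR:
    def test_clean_ratios_no_removals_equal_ivw(self):
        rng = np.random.default_rng(12)
        bx = rng.normal(0.1, 0.02, 30)
        h = _hset(bx, 0.25 * bx)  # exact ratios, zero heterogeneity
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = gsmr(h)
        assert est.removed_snps == []
        assert est.beta_hat == pytest.approx(ivw(h).beta_hat, abs=1e-6)

    def test_zero_threshold_disables_heidi(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.2, seed=13)
        h = MendelianRandomization(exp, out).instruments
        est = gsmr(h, heidi_p_threshold=0.0)
        assert est.removed_snps == []
        assert est.beta_hat == pytest.approx(ivw(h).beta_hat, abs=1e-12)

    def test_spike_in_outlier_removed_and_estimate_restored(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.3, seed=14)
        out = out.copy()
        # plant 10-sigma pleiotropy on the first instrument
        out.loc[0, "b"] += 10 * out.loc[0, "se"]
        h = MendelianRandomization(exp, out).instruments
        est = gsmr(h)
        assert "rs000001" in est.removed_snps
        assert abs(est.beta_hat - 0.3) < 2 * est.se_hat + 0.01

    def test_all_removed_rejected(self):
        h = _hset(np.array([0.1, 0.1]), np.array([1.0, -1.0]),
                  se_x=1e-4, se_y=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            with pytest.raises(ValueError, match="every instrument"):
                gsmr(h)


class TestSensitivity:
    def test_leave_one_out_counts(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.2, seed=15)
        h = MendelianRandomization(exp, out).instruments
        rep = sensitivity(h, ivw(h))
        assert len(rep.loo_estimates) == len(h)

    def test_dominant_outlier_flagged(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.2, seed=16)
        out = out.copy()
        out.loc[2, "b"] += 15 * out.loc[2, "se"]
        h = MendelianRandomization(exp, out).instruments
        rep = sensitivity(h, ivw(h))
        assert rep.max_deviation_snp == "rs000003"
        assert rep.q_p < 0.01


class TestModelAndBidirectional:
    def test_fit_all_methods_agree_on_clean_data(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=0.25, seed=17)
        res = MendelianRandomization(exp, out).fit(method="all", seed=5)
        betas = {m: e.beta_hat for m, e in res.estimates.items()}
        ses = {m: e.se_hat for m, e in res.estimates.items()}
        for m, b in betas.items():
            assert abs(b - 0.25) < 2 * ses[m] + 0.02, m
        assert "OR" in res.summary()

    def test_or_ci_transform(self, gwas_pair_factory):
        exp, out = gwas_pair_factory(causal_effect=-0.2, seed=18)
        est = MendelianRandomization(exp, out).fit(method="IVW")["IVW"]
        lo, hi = est.ci
        assert lo < est.or_hat < hi
        assert est.or_hat == pytest.approx(np.exp(est.beta_hat))

    def test_bidirectional_forward_only_effect(self, gwas_pair_factory):
        pairs = {("total_sa", "SZ"): {
            "forward": gwas_pair_factory(causal_effect=-0.2, seed=19),
            "reverse": gwas_pair_factory(causal_effect=0.0, seed=20),
        }}
        tab = run_bidirectional(pairs, method="IVW", n_measures=3,
                                n_diseases=13)
        fwd = tab[tab["direction"] == "forward"].iloc[0]
        rev = tab[tab["direction"] == "reverse"].iloc[0]
        assert fwd["p"] < 0.05 / 39  # study-wise
        assert rev["p"] > 0.05
        assert fwd["OR"] < 1
        assert np.isnan(rev["OR"])  # reverse reported on beta scale

    def test_missing_direction_marked_unavailable(self, gwas_pair_factory):
        pairs = {("icv", "ADHD"): {
            "forward": gwas_pair_factory(causal_effect=0.1, seed=21)}}
        tab = run_bidirectional(pairs, method="IVW")
        rev = tab[tab["direction"] == "reverse"].iloc[0]
        assert not rev["available"]
        assert rev["tier"] == "unavailable"

    def test_mr_tier_thresholds(self):
        thr = mr_tier_thresholds(3, 13)
        assert f"{thr['disease_wise']:.1e}" == "1.7e-02"
        assert round(thr["disease_wise"], 3) == pytest.approx(0.017)
        assert thr["disease_wise"] == pytest.approx(0.05 / 3)
        assert f"{thr['study_wise']:.1e}" == "1.3e-03"
        assert thr["study_wise"] == pytest.approx(0.05 / 39)
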