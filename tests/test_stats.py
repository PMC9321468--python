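"""Statistics layer: Holm correction, causal power, simulated nulls, sliding
ledger probabilities, cluster permutation, KS on MIP types, interaction
models and spike rates."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vpckit import (CausalTable, causal_power, cluster_permutation,
                    fit_interaction_model, holm_bonferroni, ks_compare_mip,
                    lep_lsp_correlation, simulated_null_test,
                    sliding_probability, spike_rate_summary)
from vpckit.config import SimulationConfig
from vpckit.simulate import simulate_ledger


class TestHolm:
    def test_hand_computed_stepdown(self):
        p_corr, reject = holm_bonferroni(np.array([0.01, 0.04]))
        assert np.allclose(p_corr, [0.02, 0.04])
        assert reject.all()

    def test_single_p_unchanged_and_all_ones(self):
        p_corr, reject = holm_bonferroni(np.array([0.03]))
        assert p_corr[0] == pytest.approx(0.03)
        assert reject[0]
        _, rej = holm_bonferroni(np.ones(5))
        assert not rej.any()

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20))
    @settings(deadline=None, max_examples=50)
    def test_corrected_never_below_raw_and_monotone(self, ps):
        ps = np.array(ps)
        p_corr, _ = holm_bonferroni(ps)
        assert np.all(p_corr >= ps - 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(p_corr[order]) >= -1e-12)


class TestCausalPower:
    def test_spec_examples(self):
        assert causal_power((0.3, 0.3)) == pytest.approx(0.0)
        assert causal_power((1.0, 0.7)) == pytest.approx(1.0)
        assert causal_power((0.300, 0.129)) == pytest.approx(0.171 / 0.871,
                                                             abs=1e-12)

    def test_undefined_when_alternatives_guarantee_event(self):
        with pytest.raises(ZeroDivisionError):
            causal_power(CausalTable(0.5, 1.0))

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.98), st.floats(0.001, 0.01))
    @settings(deadline=None, max_examples=100)
    def test_monotone_in_both_arguments(self, pc, pnc, eps):
        base = causal_power((pc, pnc))
        if pc + eps <= 1.0:
            assert causal_power((pc + eps, pnc)) > base
        if pnc + eps < 1.0 and pc < 1.0:
            assert causal_power((pc, pnc + eps)) < base


class TestSimulatedNull:
    POP = {"NS": 80, "10Hz": 80, "50Hz": 80, "200Hz": 80}

    def test_draw_from_null_is_calibrated(self, rng):
        hits = 0
        for _ in range(20):
            counts = rng.multinomial(40, np.ones(4) / 4)
            obs = dict(zip(sorted(self.POP), counts))
            res = simulated_null_test(self.POP, obs, nboot=400, rng=rng)
            hits += all(abs(r.z) < 2.5 for r in res.values())
        assert hits >= 17

    def test_enriched_category_detected(self, rng):
        obs = {"NS": 10, "10Hz": 10, "50Hz": 10, "200Hz": 34}
        res = simulated_null_test(self.POP, obs, nboot=4000, rng=rng)
        assert res["200Hz"].z > 2
        assert res["200Hz"].p_corrected < 0.05

    def test_null_sd_stable_in_nboot(self, rng):
        obs = {"NS": 15, "10Hz": 15, "50Hz": 15, "200Hz": 15}
        sd_small = simulated_null_test(self.POP, obs, nboot=200,
                                       rng=rng)["NS"].samples.std()
        sd_big = simulated_null_test(self.POP, obs, nboot=20_000,
                                     rng=rng)["NS"].samples.std()
        assert sd_small == pytest.approx(sd_big, rel=0.25)

    def test_proportion_statistic_and_replacement(self, rng):
        obs = {"NS": 5, "10Hz": 5, "50Hz": 5, "200Hz": 25}
        res = simulated_null_test(self.POP, obs, nboot=2000, replace=True,
                                  statistic="proportion", rng=rng)
        assert res["200Hz"].observed == pytest.approx(25 / 40)
        assert res["200Hz"].z > 2


class TestSlidingProbability:
    def _ledger(self, kindling, seed=0, blocks=360):
        cfg = SimulationConfig(n_blocks_rest=0, n_blocks_fix=0,
                               kindling_slope=kindling, seed=seed,
                               str_prob=0.19)
        return simulate_ledger(cfg, series_schedule=[("Stim", blocks // 2),
                                                     ("No-Stim", blocks // 2)])

    def test_kindling_induces_positive_correlation(self):
        sl = sliding_probability(self._ledger(0.35, seed=1))
        r, p = lep_lsp_correlation(sl)
        assert r > 0 and p < 0.01

    def test_all_stim_ledger_has_constant_lsp(self):
        cfg = SimulationConfig(n_blocks_rest=40, n_blocks_fix=0, seed=2,
                               conditions=("10Hz", "50Hz", "200Hz"))
        sl = sliding_probability(simulate_ledger(cfg))
        assert np.allclose(sl.lsp, 1.0)

    def test_too_few_blocks_rejected(self):
        cfg = SimulationConfig(n_blocks_rest=8, n_blocks_fix=0, seed=3)
        with pytest.raises(ValueError, match="at least 32"):
            sliding_probability(simulate_ledger(cfg))


class TestClusterPermutation:
    def test_injected_effect_recovered(self, rng):
        a = rng.standard_normal((12, 20, 15))
        b = rng.standard_normal((12, 20, 15))
        a[:, 5:12, 3:8] += 1.5
        clusters = cluster_permutation(a, b, nboot=500, rng=rng)
        assert clusters
        best = clusters[0]
        inject = np.zeros((20, 15), bool)
        inject[5:12, 3:8] = True
        overlap = (best.mask & inject).sum() / inject.sum()
        assert best.sign == 1 and overlap > 0.5

    def test_empty_group_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_permutation(np.empty((0, 4, 4)),
                                rng.standard_normal((5, 4, 4)))

    def test_sign_convention(self, rng):
        a = rng.standard_normal((10, 10, 10))
        b = rng.standard_normal((10, 10, 10))
        b[:, :5, :5] += 2.0
        clusters = cluster_permutation(a, b, nboot=500, rng=rng)
        assert clusters and clusters[0].sign == -1


class TestKsMip:
    def test_identical_and_disjoint(self, rng):
        a = rng.integers(0, 5, 40)
        ks, _ = ks_compare_mip(a, a.copy())
        assert ks == pytest.approx(0.0, abs=1e-9)
        ks, p = ks_compare_mip(np.zeros(30) + rng.integers(0, 3, 30),
                               np.full(30, 40.0) + rng.integers(0, 3, 30))
        assert ks == pytest.approx(1.0, abs=0.05)
        assert p < 0.001

    def test_smoothed_close_to_empirical_cdf(self, rng):
        a = rng.choice([0, 1, 2, 3], 60, p=[0.4, 0.3, 0.2, 0.1])
        b = rng.choice([0, 1, 2, 3], 60, p=[0.1, 0.2, 0.3, 0.4])
        ks_smooth, _ = ks_compare_mip(a, b, smooth=True)
        ks_emp, _ = ks_compare_mip(a, b, smooth=False)
        assert ks_smooth == pytest.approx(ks_emp, abs=0.05)

    def test_few_samples_falls_back_with_warning(self, rng):
        with pytest.warns(UserWarning, match="fewer than 5"):
            ks_compare_mip(np.array([0, 1, 2]), np.array([2, 3, 4, 5, 6]))


class TestInteractionModels:
    def _data(self, rng, beta3=0.5, n=300):
        c = rng.choice(["pre", "during"], n)
        e = rng.choice(["VPC", "STR"], n)
        a = rng.choice(["R", "W"], n)
        cc = np.where(c == "pre", 0.5, -0.5)
        ce = np.where(e == "VPC", 0.5, -0.5)
        yv = 1.0 + 0.3 * cc - 0.2 * ce + beta3 * cc * ce + rng.normal(0, 1, n)
        return pd.DataFrame({"C": c, "E": e, "A": a, "y": yv})

    def test_interaction_coefficient_recovered(self, rng):
        fit = fit_interaction_model(self._data(rng, n=1000), "y", ["C", "E"],
                                    covariates=["A"], interactions=[("C", "E")])
        est = fit.params["C:E"]
        se = fit.result.bse["C:E"]
        assert abs(est - 0.5) < 3 * se
        # oracle: identical to a hand-coded statsmodels OLS fit
        import statsmodels.api as sm
        d = self._data(np.random.default_rng(0), n=1000)
        cc = np.where(d.C == sorted(d.C.unique())[1], 0.5, -0.5)
        ce = np.where(d.E == sorted(d.E.unique())[1], 0.5, -0.5)
        ca = np.where(d.A == sorted(d.A.unique())[1], 0.5, -0.5)
        X = sm.add_constant(pd.DataFrame({"C": cc, "E": ce, "A": ca,
                                          "C:E": cc * ce}))
        ref = sm.OLS(d.y.to_numpy(), X).fit()
        fit0 = fit_interaction_model(d, "y", ["C", "E"], covariates=["A"],
                                     interactions=[("C", "E")])
        assert fit0.params["C:E"] == pytest.approx(ref.params["C:E"], abs=1e-10)

    def test_null_interaction_type_i(self, rng):
        rejections = 0
        for _ in range(40):
            fit = fit_interaction_model(self._data(rng, beta3=0.0, n=120), "y",
                                        ["C", "E"], interactions=[("C", "E")])
            rejections += fit.interaction_tests.p.iloc[0] < 0.05
        assert rejections <= 7     # nominal 5 % of 40, binomial slack

    def test_swapping_levels_flips_only_that_sign(self, rng):
        data = self._data(rng)
        fit1 = fit_interaction_model(data, "y", ["C", "E"],
                                     interactions=[("C", "E")])
        flipped = data.copy()
        flipped["E"] = flipped.E.map({"VPC": "a_STR", "STR": "b_VPC"})
        fit2 = fit_interaction_model(flipped, "y", ["C", "E"],
                                     interactions=[("C", "E")])
        assert fit2.params["E"] == pytest.approx(-fit1.params["E"], abs=1e-9)
        assert fit2.params["C"] == pytest.approx(fit1.params["C"], abs=1e-9)

    def test_rank_deficiency_detected(self, rng):
        data = self._data(rng)
        data["C2"] = data.C
        with pytest.raises(ValueError, match="rank"):
            fit_interaction_model(data, "y", ["C", "C2"])


class TestSpikeRates:
    def test_homogeneous_unit_normalizes_to_one(self, rng):
        times = np.sort(rng.uniform(0, 600, 6000))
        spikes = [{"unit": "u0", "area": "CN", "times": times},
                  {"unit": "u1", "area": "CN",
                   "times": np.sort(rng.uniform(0, 600, 6000))}]
        epochs = {"pre": [(float(t), float(t + 1)) for t in range(0, 100)],
                  "vpc": [(float(t), float(t + 1)) for t in range(300, 400)]}
        out = spike_rate_summary(spikes, epochs)
        vpc = out[out.condition == "vpc"]
        assert vpc.mean_rate.iloc[0] == pytest.approx(1.0, abs=0.1)

    def test_halved_rate_recovered(self, rng):
        pre_times = rng.uniform(0, 100, 1000)
        vpc_times = rng.uniform(300, 400, 500)
        spikes = [{"unit": "u0", "area": "CN",
                   "times": np.sort(np.concatenate([pre_times, vpc_times]))}]
        epochs = {"pre": [(float(t), float(t + 1)) for t in range(0, 100)],
                  "vpc": [(float(t), float(t + 1)) for t in range(300, 400)]}
        out = spike_rate_summary(spikes, epochs)
        assert out[out.condition == "vpc"].mean_rate.iloc[0] == \
            pytest.approx(0.5, abs=0.1)

    def test_effective_window_divisor(self, rng):
        times = np.arange(0.005, 10.0, 0.01)     # exactly 100 Hz
        spikes = [{"unit": "u0", "area": "CN", "times": times}]
        eff = {"pre": np.full(5, 1.0), "stim": np.full(5, 0.99)}
        epochs = {"pre": [(float(t), float(t + 1)) for t in range(5)],
                  "stim": [(float(t), float(t + 1)) for t in range(5, 10)]}
        out = spike_rate_summary(spikes, epochs, effective_lengths=eff)
        stim = out[out.condition == "stim"].mean_rate.iloc[0]
        assert stim == pytest.approx((100 / 0.99) / 100, abs=1e-6)

    def test_unit_missing_pre_excluded(self):
        spikes = [{"unit": "u0", "area": "CN", "times": np.array([500.0])}]
        epochs = {"pre": [(0.0, 1.0)], "vpc": [(500.0, 501.0)]}
        out = spike_rate_summary(spikes, epochs)
        assert out.empty
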