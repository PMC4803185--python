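"""Successive-cycle correlations, randomized controls, KS, sweeps."""
import math

import numpy as np
import pytest

from slclock import (SLParams, analyze_cohort, cohort_cycles,
                     correlation_summary, ks_compare,
                     period_amplitude_correlation, randomized_control,
                     successive_pairs, sweep_additive_noise,
                     sweep_colored_noise)
from tests.conftest import ensemble_traces


class TestSuccessivePairs:
    def test_pairs_formed_within_cells_only(self):
        pairs = successive_pairs({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0]},
                                 normalize=False)
        assert len(pairs) == 3  # (1,2), (2,3), (4,5)
        assert set(map(tuple, pairs.table[["v1", "v2"]].values)) == {
            (1.0, 2.0), (2.0, 3.0), (4.0, 5.0)}

    def test_single_cycle_cells_contribute_nothing(self):
        pairs = successive_pairs({"a": [1.0], "b": [], "c": [2.0, 3.0]})
        assert len(pairs) == 1

    def test_normalization_by_dataset_mean_recorded(self):
        pairs = successive_pairs({"a": [2.0, 4.0]})
        assert pairs.normalizer == pytest.approx(3.0)
        np.testing.assert_allclose([pairs.v1[0], pairs.v2[0]], [2 / 3, 4 / 3])

    def test_pair_count_conservation(self):
        # sum over cells of (n_cycles - 1)+ exactly
        rng = np.random.default_rng(3)
        cells = {f"c{i}": rng.uniform(1, 2, rng.integers(0, 8))
                 for i in range(40)}
        pairs = successive_pairs(cells)
        expected = sum(max(0, len(v) - 1) for v in cells.values())
        assert len(pairs) == expected

    def test_constant_values_sit_on_identity(self):
        pairs = successive_pairs({"a": [5.0] * 6}, normalize=False)
        assert np.all(pairs.distance_to_identity == 0.0)


class TestRandomizedControl:
    def test_same_seed_reproduces_control(self):
        pairs = successive_pairs({"a": np.arange(1.0, 9.0)})
        c1 = randomized_control(pairs, seed=11)
        c2 = randomized_control(pairs, seed=11)
        np.testing.assert_array_equal(c1.v1, c2.v1)

    def test_control_destroys_correlation(self, rng):
        # strongly autocorrelated per-cell values -> control ~ 0
        cells = {}
        for i in range(60):
            base = rng.uniform(0.5, 1.5)
            cells[f"c{i}"] = base + rng.normal(0, 0.05, 6)
        pairs = successive_pairs(cells)
        r_data = correlation_summary(pairs)["r"]
        r_ctrl = np.mean([correlation_summary(
            randomized_control(pairs, seed=s))["r"] for s in range(100)])
        assert r_data > 0.5
        assert abs(r_ctrl) < 0.1

    def test_sl_cohort_amplitudes_beat_control(self, full_noise_params):
        traces = ensemble_traces(full_noise_params, 60, seed=19)
        cycles = analyze_cohort(traces)
        table = cohort_cycles(cycles)
        table = table[table.accepted & np.isfinite(table.amplitude)]
        per_cell = {c: g["amplitude"].to_numpy()
                    for c, g in table.groupby("cell")}
        pairs = successive_pairs(per_cell)
        r_data = correlation_summary(pairs)["r"]
        r_ctrl = [correlation_summary(randomized_control(pairs, seed=s))["r"]
                  for s in range(99)]
        # one-sided permutation test at p < 0.05
        assert np.mean([rc >= r_data for rc in r_ctrl]) < 0.05

    def test_amplitude_memory_exceeds_period_memory(self, full_noise_params):
        # slow mu fluctuations correlate consecutive amplitudes but the
        # white frequency noise leaves periods uncorrelated
        traces = ensemble_traces(full_noise_params, 80, seed=23)
        table = cohort_cycles(analyze_cohort(traces))
        table = table[table.accepted & np.isfinite(table.amplitude)]
        groups = table.groupby("cell")
        r_amp = correlation_summary(successive_pairs(
            {c: g["amplitude"].to_numpy() for c, g in groups}))["r"]
        r_per = correlation_summary(successive_pairs(
            {c: g["period"].to_numpy() for c, g in groups}))["r"]
        assert r_amp > r_per + 0.1
        assert abs(r_per) < 0.25


class TestCorrelationSummary:
    def test_identity_pairs_have_unit_correlation(self):
        pairs = successive_pairs(
            {"a": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0]}, normalize=False)
        on_identity = pairs.table[pairs.table.v1 == pairs.table.v2]
        sub = successive_pairs({"a": []}, normalize=False)
        sub.table = on_identity
        res = correlation_summary(sub)
        assert res["r"] == pytest.approx(1.0)
        assert np.all(sub.distance_to_identity == 0.0)

    def test_independent_draws_decorrelated(self, rng):
        pairs = successive_pairs({"a": rng.uniform(0, 1, 400)},
                                 normalize=False)
        assert abs(correlation_summary(pairs)["r"]) < 0.15

    def test_d_statistic_is_perpendicular_distance(self):
        pairs = successive_pairs({"a": [1.0, 3.0]}, normalize=False)
        assert pairs.distance_to_identity[0] == pytest.approx(2 / math.sqrt(2))
        assert pairs.v_star[0] == pytest.approx(2.0)


class TestPeriodAmplitudeCorrelation:
    def test_isochronous_cohort_shows_no_correlation(self, full_noise_params):
        traces = ensemble_traces(full_noise_params, 80, seed=31)
        table = cohort_cycles(analyze_cohort(traces))
        table = table[table.accepted & np.isfinite(table.amplitude)]
        res = period_amplitude_correlation(table["period"], table["amplitude"],
                                           seed=1)
        assert abs(res["r"]) < 0.15

    def test_non_isochronous_cohort_couples_period_to_amplitude(self):
        # q > 0: larger amplitude -> lower instantaneous frequency, so the
        # correlation is positive and detectable at several hundred cycles
        params = SLParams(omega=2 * math.pi / 65.5, q=0.005, sigma_z2=0.486,
                          sigma_mu2=6.84, tau_mu=476.0)
        traces = ensemble_traces(params, 120, seed=37)
        table = cohort_cycles(analyze_cohort(traces))
        table = table[table.accepted & np.isfinite(table.amplitude)]
        assert len(table) >= 400
        res = period_amplitude_correlation(table["period"], table["amplitude"],
                                           seed=2)
        assert res["r"] > 0.2
        assert res["p"] < 0.01

    def test_permutation_p_uniform_under_null(self, rng):
        # p-values of pre-shuffled pairs are uniform
        ps = []
        for s in range(40):
            T = rng.normal(78, 10, 40)
            A = rng.normal(2, 0.3, 40)
            ps.append(period_amplitude_correlation(T, A, n_permutations=199,
                                                   seed=s)["p"])
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestKSCompare:
    def test_identical_samples_give_statistic_zero(self):
        a = np.linspace(1, 10, 50)
        res = ks_compare(a, a)
        assert res["statistic"] == 0.0
        assert res["p"] == pytest.approx(1.0)

    def test_separated_distributions_rejected(self, rng):
        res = ks_compare(rng.normal(0, 1, 100), rng.normal(3, 1, 100))
        assert res["p"] < 1e-6

    def test_tiny_samples_flagged(self):
        res = ks_compare([1.0, 2.0, 3.0], [1.5, 2.5, 3.5])
        assert res["small_sample"]


class TestSweeps:
    def test_colored_noise_fraction_decreases_with_variance(self, paper_params):
        res = sweep_colored_noise([0.0, 2.0, 6.84], [476.0],
                                  paper_params.with_(sigma_z2=0.486),
                                  n_sims=40, seed=3)
        t = res.table.sort_values("sigma_mu2")
        fr = t["oscillating_fraction"].to_numpy()
        assert fr[0] > 0.85          # never crosses the bifurcation
        assert fr[0] > fr[1] > fr[2]  # more variance -> less time oscillating

    def test_fraction_tracks_time_above_bifurcation(self, paper_params):
        # direct oracle: measured fraction correlates with the fraction of
        # time mu(t) > 0 in the same simulations
        from slclock import classify_persistence, render_trace, simulate_ensemble

        params = paper_params.with_(sigma_z2=0.486, sigma_mu2=6.84,
                                    tau_mu=476.0)
        trajs = simulate_ensemble(params, 60, seed=41)
        above = np.mean([np.mean(tr.mu_t > 0) for tr in trajs])
        traces = [render_trace(tr, 2.0) for tr in trajs]
        cycles = analyze_cohort(traces)
        med = np.median(np.concatenate([c.accepted_periods for c in cycles]))
        fr = np.mean([classify_persistence(c, dataset_median_period=med)[1]
                      for c in cycles])
        assert fr == pytest.approx(above, abs=0.15)

    def test_additive_sweep_q_decreases_and_ks_reference(self, paper_params):
        ref = np.random.default_rng(5).lognormal(math.log(4.6), 0.6, 54)
        res = sweep_additive_noise([0.25, 0.486, 1.0], paper_params,
                                   n_sims=40, seed=7, reference_q=ref)
        t = res.table.sort_values("sigma_z2")
        q = t["q_median"].to_numpy()
        assert q[0] > q[1] > q[2]
        assert np.all((t["ks_p"] >= 0) & (t["ks_p"] <= 1))
        assert np.all(t["q_lo68"] <= t["q_median"])
        assert np.all(t["q_median"] <= t["q_hi68"])
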