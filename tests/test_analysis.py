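"""Rates, correlations, CV ISI, PSTH peaks and normalized response tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barrelcircuit.analysis import (
    PSTHResult,
    compute_cv_isi,
    compute_pairwise_correlation,
    compute_peak_rmse,
    compute_population_rates,
    compute_psth_and_peaks,
    normalize_responses_and_test,
    percent_change,
)
from barrelcircuit.dynamics import SpikeTrainSet
from barrelcircuit.params import ParameterError


def _spikeset(times, senders, n, pops=None, pop_names=("L2/3 Exc",), t_stop=10_000.0):
    return SpikeTrainSet(
        times=np.asarray(times, float),
        senders=np.asarray(senders, int),
        n_neurons=n,
        pop_of=np.asarray(pops if pops is not None else np.zeros(n), int),
        pop_names=pop_names,
        t_start=0.0,
        t_stop=t_stop,
    )


def _poisson_set(rate, n, duration, seed, **kw):
    rng = np.random.default_rng(seed)
    times, senders = [], []
    for i in range(n):
        k = rng.poisson(rate * duration / 1000.0)
        times.append(np.sort(rng.random(k) * duration))
        senders.append(np.full(k, i))
    return _spikeset(np.concatenate(times), np.concatenate(senders), n,
                     t_stop=duration, **kw)


class TestRates:
    def test_silent_all_zero(self):
        s = _spikeset([], [], 5)
        df = compute_population_rates(s, 0.0, 1000.0)
        assert df["mean"].iloc[0] == 0.0

    def test_simple_count(self):
        s = _spikeset(np.linspace(0, 4999, 10), np.zeros(10), 1)
        df = compute_population_rates(s, 0.0, 5000.0)
        assert df["mean"].iloc[0] == pytest.approx(2.0)

    def test_poisson_mean_within_three_se(self):
        rate, n, dur = 8.0, 200, 10_000.0
        s = _poisson_set(rate, n, dur, seed=0)
        df = compute_population_rates(s, 0.0, dur)
        se = np.sqrt(rate / (dur / 1000.0) / n)
        assert abs(df["mean"].iloc[0] - rate) < 3 * se

    def test_empty_window_rejected(self):
        with pytest.raises(ParameterError):
            compute_population_rates(_spikeset([], [], 1), 5.0, 5.0)


class TestCorrelation:
    def test_duplicated_trains_correlate_fully(self):
        t = np.sort(np.random.default_rng(1).random(200) * 5000.0)
        s = _spikeset(np.concatenate([t, t]), np.r_[np.zeros(200), np.ones(200)], 2)
        assert compute_pairwise_correlation(s, "L2/3", 0, 5000.0) == pytest.approx(1.0)

    def test_independent_poisson_near_zero(self):
        s = _poisson_set(10.0, 100, 20_000.0, seed=2)
        c = compute_pairwise_correlation(s, "L2/3", 0, 20_000.0, seed=0)
        # single-pair correlation SE is ~1/sqrt(n_bins); the mean over pairs
        # is tighter, so this is a conservative three-sigma bound
        assert abs(c) < 3.0 / np.sqrt(2000.0)

    def test_silent_neurons_excluded(self):
        t = np.sort(np.random.default_rng(3).random(100) * 5000.0)
        s = _spikeset(np.concatenate([t, t]), np.r_[np.zeros(100), np.ones(100)], 3)
        # neuron 2 silent; correlation still defined from the two active ones
        assert compute_pairwise_correlation(s, "L2/3", 0, 5000.0) == pytest.approx(1.0)


class TestCvIsi:
    def test_regular_train_zero(self):
        t = np.arange(0.0, 5000.0, 100.0)
        s = _spikeset(t, np.zeros(t.size), 1)
        assert compute_cv_isi(s, "L2/3", 0, 5000.0) == pytest.approx(0.0)

    def test_poisson_near_one(self):
        s = _poisson_set(20.0, 100, 60_000.0, seed=4)
        cv = compute_cv_isi(s, "L2/3", 0, 60_000.0)
        assert abs(cv - 1.0) < 0.05

    def test_low_rate_neurons_excluded(self):
        slow = np.array([100.0, 2100.0])  # 0.4 spikes/s over 5 s
        fast = np.arange(0.0, 5000.0, 100.0)
        s = _spikeset(np.concatenate([slow, fast]),
                      np.r_[np.zeros(2), np.ones(fast.size)], 2)
        assert compute_cv_isi(s, "L2/3", 0, 5000.0) == pytest.approx(0.0)


class TestPsth:
    def test_silent_flat_zero(self):
        s = _spikeset([], [], 10)
        res = compute_psth_and_peaks(s, np.array([100.0]))
        assert res["L2/3 Exc"].a_peak == 0.0
        assert np.all(res["L2/3 Exc"].rates == 0.0)

    def test_doubling_repeats_leaves_psth_unchanged(self):
        onsets = np.array([100.0, 300.0])
        times = np.concatenate([onsets + 10.0, onsets + 10.2])
        s = _spikeset(times, np.zeros(times.size), 1, t_stop=1000.0)
        r1 = compute_psth_and_peaks(s, onsets)["L2/3 Exc"]
        onsets4 = np.array([100.0, 300.0, 500.0, 700.0])
        times4 = np.concatenate([onsets4 + 10.0, onsets4 + 10.2])
        s4 = _spikeset(times4, np.zeros(times4.size), 1, t_stop=1000.0)
        r4 = compute_psth_and_peaks(s4, onsets4)["L2/3 Exc"]
        assert np.allclose(r1.rates, r4.rates)
        assert r1.t_peak == r4.t_peak

    def test_spike_count_conservation(self):
        s = _poisson_set(50.0, 20, 1000.0, seed=5)
        onsets = np.array([0.0, 500.0])
        res = compute_psth_and_peaks(s, onsets, window_ms=500.0)["L2/3 Exc"]
        total = np.sum(res.rates * 0.5 / 1000.0) * 20 * onsets.size
        in_windows = np.sum((s.times % 500.0) < 500.0)  # all spikes
        assert total == pytest.approx(in_windows)

    def test_peak_in_search_window_with_tie_toward_earliest(self):
        onsets = np.array([0.0])
        times = np.array([10.1, 20.1])  # equal-height bins
        s = _spikeset(times, np.zeros(2), 1, t_stop=100.0)
        res = compute_psth_and_peaks(s, onsets)["L2/3 Exc"]
        assert res.t_peak == pytest.approx(10.25)


class TestPeakRmse:
    def _mk(self, peaks):
        return {
            name: PSTHResult(name, 0.5, np.arange(3), np.zeros(3), a, t)
            for name, (a, t) in peaks.items()
        }

    def test_exact_match_zero(self):
        sim = self._mk({"L4 Exc": (10.0, 5.0), "L4 PV": (20.0, 4.0)})
        ref = pd.DataFrame([
            {"population": "L4 Exc", "a_peak": 10.0, "t_peak": 5.0},
            {"population": "L4 PV", "a_peak": 20.0, "t_peak": 4.0},
        ])
        assert compute_peak_rmse(sim, ref) == (0.0, 0.0)

    def test_single_offset_formula(self):
        sim = self._mk({f"P{i}": (10.0, 5.0) for i in range(4)})
        sim["P0"] = PSTHResult("P0", 0.5, np.arange(3), np.zeros(3), 20.0, 5.0)
        ref = pd.DataFrame([
            {"population": f"P{i}", "a_peak": 10.0, "t_peak": 5.0} for i in range(4)
        ])
        a, t = compute_peak_rmse(sim, ref)
        assert a == pytest.approx(5.0) and t == 0.0

    def test_vip_zero_criterion_and_time_exclusion(self):
        peaks = {f"P{i}": (10.0, 5.0) for i in range(7)}
        sim = self._mk(peaks)
        sim["L2/3 VIP"] = PSTHResult("L2/3 VIP", 0.5, np.arange(3), np.zeros(3),
                                     12.0, 99.0)
        ref = pd.DataFrame([
            {"population": f"P{i}", "a_peak": 10.0, "t_peak": 5.0} for i in range(7)
        ])
        a, t = compute_peak_rmse(sim, ref)
        assert a == pytest.approx(np.sqrt(144.0 / 8.0))
        assert t == 0.0  # VIP time ignored

    def test_missing_reference_row(self):
        sim = self._mk({"L4 Exc": (10.0, 5.0)})
        with pytest.raises(ParameterError):
            compute_peak_rmse(sim, pd.DataFrame([{"population": "L4 PV",
                                                  "a_peak": 1.0, "t_peak": 1.0}]))


class TestResponseNormalization:
    def _frame(self, rates_by_level, n_inst=20):
        rows = []
        for level, vals in rates_by_level.items():
            for i in range(n_inst):
                rows.append({"population": "L4 Exc", "level": level,
                             "instance": i, "rate": vals[i]})
        return pd.DataFrame(rows)

    def test_identical_to_baseline_gives_one_and_p_one(self):
        df = self._frame({0.0: [2.0] * 20, 100.0: [2.0] * 20})
        res = normalize_responses_and_test(df)["L4 Exc"]
        assert res.r_norm == (1.0, 1.0)
        assert res.p_values[1] == 1.0
        assert any("zero variance" in f for f in res.flags)

    def test_t_statistic_matches_closed_form(self):
        rng = np.random.default_rng(6)
        vals = 1.1 + 0.05 * rng.standard_normal(20)
        df = self._frame({0.0: [1.0] * 20, 50.0: vals})
        res = normalize_responses_and_test(df)["L4 Exc"]
        t_closed = (vals.mean() - 1.0) / (vals.std(ddof=1) / np.sqrt(20))
        p_closed = 2 * stats.t.sf(abs(t_closed), 19)
        assert res.p_values[1] == pytest.approx(p_closed, rel=1e-9)

    def test_zero_baseline_instances_excluded(self):
        df = self._frame({0.0: [0.0] + [2.0] * 19, 100.0: [5.0] * 20})
        res = normalize_responses_and_test(df)["L4 Exc"]
        assert res.per_instance.shape[1] == 19
        assert any("zero-baseline" in f for f in res.flags)

    def test_percent_change_convention(self):
        assert percent_change(0.5) == -50.0
        assert percent_change(1.104) == pytest.approx(10.4)
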