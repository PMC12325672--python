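import numpy as np
import pandas as pd
import pytest

from m1beta import spike_analysis as sa


def _df(times, pop="PT5B", nid=0):
    return pd.DataFrame(
        {
            "neuron_id": nid,
            "population": pop,
            "spike_time_ms": np.asarray(times, dtype=float),
        }
    )


def _sch_from_counts(counts, bin_ms=2.0):
    counts = np.asarray(counts, dtype=float)
    edges = np.arange(0, (len(counts) + 0.5) * bin_ms, bin_ms)
    return sa.SCH(population="synthetic", bin_edges_ms=edges, counts=counts)


class TestSCH:
    def test_three_spikes_three_bins(self):
        sch = sa.spike_count_histogram(_df([1, 3, 5]), "PT5B", (0, 6))
        np.testing.assert_array_equal(sch.counts, [1, 1, 1])

    def test_empty_population_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            sch = sa.spike_count_histogram(_df([]), "PT5B", (0, 10))
        assert sch.counts.sum() == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 2300, 500)
        sch = sa.spike_count_histogram(_df(t), "PT5B", (0, 2300))
        assert sch.counts.sum() == 500


class TestDutyCycle:
    def test_square_wave_30pct(self):
        period, n = 100, 20  # bins
        counts = np.tile([10] * 6 + [0] * 14, 10)  # 30% high
        duty = sa.duty_cycle(_sch_from_counts(counts), smooth_bins=1)
        assert duty.duty_pct == pytest.approx(30.0, abs=2.0)

    def test_sinusoid_50pct(self):
        t = np.arange(2000)
        counts = 50 * (1 + np.sin(2 * np.pi * t / 40.0))
        duty = sa.duty_cycle(_sch_from_counts(counts), smooth_bins=1)
        assert duty.duty_pct == pytest.approx(50.0, abs=2.0)
        assert duty.mean_period_freq_hz == pytest.approx(1e3 / 80.0, rel=0.02)

    def test_sawtooth_37_5pct(self):
        """Linear rise over 75% of the period, instantaneous fall: the
        half-height is crossed halfway up the rise, so ON spans
        75% - 37.5% = 37.5% of the period."""
        rise, low = 75, 25
        one = np.concatenate([np.linspace(0, 1, rise, endpoint=False), np.zeros(low)])
        duty = sa.duty_cycle(_sch_from_counts(np.tile(one, 12)), smooth_bins=1)
        assert duty.duty_pct == pytest.approx(37.5, abs=1.5)

    def test_invariant_to_count_rescaling(self):
        t = np.arange(1000)
        counts = 20 * (1 + 0.8 * np.sin(2 * np.pi * t / 32.0))
        d1 = sa.duty_cycle(_sch_from_counts(counts))
        d2 = sa.duty_cycle(_sch_from_counts(counts * 7.3))
        assert d1.duty_pct == pytest.approx(d2.duty_pct, abs=1e-9)

    def test_flat_histogram_rejected(self):
        with pytest.raises(sa.FlatHistogramError):
            sa.duty_cycle(_sch_from_counts(np.full(100, 5.0)))


class TestISICV:
    def test_periodic_train_is_regular(self):
        df = _df(np.arange(0, 2000, 50.0))
        res = sa.isi_cv(df, None, "PT5B", (0, 2000))
        assert res.per_neuron[0] == pytest.approx(0.0, abs=1e-12)
        assert res.frac_regular == 1.0

    def test_poisson_cv_near_one(self):
        rng = np.random.default_rng(7)
        t = np.cumsum(rng.exponential(50.0, 400))  # 20 Hz for ~20 s
        res = sa.isi_cv(_df(t), None, "PT5B", (0, t[-1]))
        assert res.per_neuron[0] == pytest.approx(1.0, abs=0.15)

    def test_cv_exactly_half_is_regular(self):
        # alternating ISIs 0.5u and 1.5u give sd/mean = 0.5 exactly
        isi = np.tile([5.0, 15.0], 100)
        df = _df(np.concatenate([[0], np.cumsum(isi)]))
        res = sa.isi_cv(df, None, "PT5B", (0, 1e9))
        assert res.per_neuron[0] == pytest.approx(0.5, abs=1e-12)
        assert res.frac_regular == 1.0

    def test_sparse_neurons_excluded(self):
        df = _df([100.0, 200.0])
        res = sa.isi_cv(df, None, "PT5B", (0, 1000))
        assert res.n_excluded == 1
        assert res.per_neuron == {}

    def test_population_mean_cv_of_poisson_ensemble(self):
        rng = np.random.default_rng(11)
        frames = [
            _df(np.cumsum(rng.exponential(100.0, 120)), nid=i) for i in range(100)
        ]
        res = sa.isi_cv(pd.concat(frames), None, "PT5B", (0, 1e9))
        assert res.mean == pytest.approx(1.0, abs=0.05)


class TestRateStats:
    def _neurons(self, n, pop="PT5B"):
        return pd.DataFrame({"id": range(n), "pop": pop, "cell_class": pop})

    def test_rate_arithmetic(self):
        df = _df(np.linspace(2000, 4299, 23))
        stats = sa.rate_stats(df, self._neurons(1), (2000, 4300))
        assert stats.table["mean"].iloc[0] == pytest.approx(10.0)

    def test_silent_neurons_count_as_zero(self):
        df = _df(np.linspace(0, 999, 10))
        stats = sa.rate_stats(df, self._neurons(2), (0, 1000))
        assert stats.per_neuron["PT5B"].tolist() == [10.0, 0.0]

    def test_identical_groups_not_significant(self):
        r = np.arange(50, dtype=float)
        assert sa.compare_rates(r, r) > 0.5

    def test_programmed_effect_detected(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(10 * 2.3, 100) / 2.3
        b = rng.poisson(30 * 2.3, 100) / 2.3
        assert sa.compare_rates(a, b) < 1e-3

    def test_empty_group_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            p = sa.compare_rates(np.array([]), np.arange(5.0))
        assert np.isnan(p)
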