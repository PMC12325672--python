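import numpy as np
import pytest

from m1beta import synchrony as sy
from m1beta.synthetic_data import (
    InjectionSpec,
    OscillatorySpikeSpec,
    gen_oscillatory_trains,
    inject_coincidences,
)


class TestDetect:
    def test_two_neurons_within_window(self):
        ev, pct = sy.detect_coincidences({0: [10.0], 1: [10.5]})
        assert len(ev) == 1
        assert pct == 100.0

    def test_same_neuron_pair_not_an_event(self):
        ev, pct = sy.detect_coincidences({0: [10.0, 10.5], 1: [50.0]})
        assert len(ev) == 0

    def test_spikes_too_far_apart(self):
        ev, _ = sy.detect_coincidences({0: [10.0], 1: [12.0]})
        assert len(ev) == 0

    def test_pct_invariant_under_relabeling(self):
        rng = np.random.default_rng(0)
        trains = {i: np.sort(rng.uniform(0, 4000, 40)) for i in range(10)}
        _, pct1 = sy.detect_coincidences(trains)
        relabeled = {100 - k: v for k, v in trains.items()}
        _, pct2 = sy.detect_coincidences(relabeled)
        assert pct1 == pct2


class TestExpected:
    def test_pairwise_formula_two_neurons(self):
        """Two 10 Hz neurons over 1 s in 1 ms bins: n_exp sums to
        N_bins * p1 * p2 = 1000 * 0.01 * 0.01 = 0.1."""
        # exactly one spike per 100 ms per neuron (rates exact)
        t = np.arange(50.0, 1000.0, 100.0)
        cfg = sy.CoincidenceConfig(step_ms=100.0)
        df = sy.expected_coincidences({0: t, 1: t + 3.0}, (0, 1000), cfg)
        assert df["n_exp"].sum() == pytest.approx(0.1)

    def test_silent_neuron_contributes_nothing(self):
        t = np.arange(50.0, 1000.0, 100.0)
        cfg = sy.CoincidenceConfig(step_ms=100.0)
        a = sy.expected_coincidences({0: t, 1: t + 3}, (0, 1000), cfg)
        b = sy.expected_coincidences(
            {0: t, 1: t + 3, 2: np.array([])}, (0, 1000), cfg
        )
        assert a["n_exp"].sum() == pytest.approx(b["n_exp"].sum())

    def test_doubling_rates_quadruples(self):
        t = np.arange(50.0, 1000.0, 100.0)
        t2 = np.sort(np.concatenate([t, t + 41.0]))
        cfg = sy.CoincidenceConfig(step_ms=100.0)
        a = sy.expected_coincidences({0: t, 1: t + 3}, (0, 1000), cfg)
        b = sy.expected_coincidences({0: t2, 1: t2 + 3}, (0, 1000), cfg)
        assert b["n_exp"].sum() == pytest.approx(4 * a["n_exp"].sum())


class TestJointSurprise:
    def test_zero_count_is_certain(self):
        assert sy.joint_surprise(0, 5.0) == 1.0
        assert sy.joint_surprise(0, 0.0) == 1.0

    def test_poisson_tail_value(self):
        assert sy.joint_surprise(10, 5.0) == pytest.approx(0.0318, abs=2e-4)


class TestEpochs:
    def _windows(self, pvals, start=0.0, step=20.0):
        import pandas as pd

        centers = start + step * np.arange(len(pvals))
        return pd.DataFrame({"window_center_ms": centers, "p": pvals})

    def test_no_significant_windows(self):
        w = self._windows(np.ones(20))
        epochs, tot, pct = sy.significant_epochs(w, np.array([]), (0, 1000))
        assert len(epochs) == 0 and tot == 0 and pct == 0

    def test_single_epoch_duration(self):
        p = np.ones(100)
        centers = 20.0 * np.arange(100)
        sel = (centers >= 1000) & (centers <= 1200)
        p[sel] = 0.001
        w = self._windows(p)
        epochs, tot, _ = sy.significant_epochs(w, np.array([]), (0, 2100))
        assert len(epochs) == 1
        assert tot == pytest.approx(0.2, abs=0.02)

    def test_injected_15hz_recovered(self):
        """Ground-truth injection at 15 Hz over [0, 2] s: epochs recover
        the oscillation frequency within 1 Hz and ~2 s of significant
        time."""
        base = gen_oscillatory_trains(
            OscillatorySpikeSpec(
                n_neurons=20, duration_ms=4000, base_rate_hz=2.0,
                mod_depth=0.0, seed=21,
            )
        )
        times = tuple(np.arange(0.0, 2000.0, 1000.0 / 15.0))
        trains, truth = inject_coincidences(
            base, InjectionSpec(times, neurons_per_event=6, jitter_ms=0.3), seed=4
        )
        ue = sy.unitary_events(trains, (0, 4000))
        assert len(ue.epochs)
        longest = ue.epochs.iloc[
            (ue.epochs["end_ms"] - ue.epochs["start_ms"]).argmax()
        ]
        assert longest["freq_hz"] == pytest.approx(15.0, abs=1.0)
        assert ue.total_significant_s == pytest.approx(2.0, abs=0.5)

    def test_detection_monotone_in_injection_rate(self):
        base_spec = OscillatorySpikeSpec(
            n_neurons=20, duration_ms=4000, base_rate_hz=2.0, mod_depth=0.0,
            seed=33,
        )
        sig_time = []
        for freq in (2.0, 8.0, 15.0):
            trains, _ = inject_coincidences(
                gen_oscillatory_trains(base_spec),
                InjectionSpec(
                    tuple(np.arange(0.0, 4000.0, 1000.0 / freq)),
                    neurons_per_event=6,
                ),
                seed=5,
            )
            ue = sy.unitary_events(trains, (0, 4000))
            sig_time.append(ue.total_significant_s)
        assert sig_time[0] <= sig_time[1] <= sig_time[2]
        assert sig_time[-1] > 0


class TestTypeIError:
    def test_independent_poisson_false_positive_rate(self):
        """200 replicates of 20 independent 10 Hz Poisson neurons, 4 s:
        the fraction of analysis windows with p < 0.05 stays below 0.07."""
        n_sig = 0
        n_tot = 0
        for rep in range(200):
            trains = gen_oscillatory_trains(
                OscillatorySpikeSpec(
                    n_neurons=20, duration_ms=4000, base_rate_hz=10.0,
                    mod_depth=0.0, seed=1000 + rep,
                )
            )
            ue = sy.unitary_events(trains, (0, 4000))
            n_sig += int((ue.windows["p"] < 0.05).sum())
            n_tot += len(ue.windows)
        assert n_sig / n_tot <= 0.07
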