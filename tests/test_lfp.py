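import numpy as np
import pytest
from scipy import signal as ss

from m1beta import lfp
from m1beta.synthetic_data import gen_test_currents


def _point(x, z):
    """Potential of a 1 nA point source at horizontal offset x, depth z,
    electrode on the axis at 700 um."""
    return lfp.line_source_potential(
        np.array([[x, 0.0]]),
        np.array([z]),
        np.array([z]),
        np.array([1.0]),
        np.array([0.0, 0.0, 700.0]),
    )


class TestLineSource:
    def test_point_source_value(self):
        # 1 nA at 1 mm in sigma = 0.3 mS/mm -> 2.653e-7 V
        phi_mv = _point(1000.0, 700.0)
        assert phi_mv * 1e-3 == pytest.approx(2.653e-7, rel=1e-3)

    def test_short_segment_converges_to_point(self):
        errs = []
        for L in (100.0, 10.0, 1.0):
            seg = lfp.line_source_potential(
                np.array([[100.0, 0.0]]),
                np.array([700.0 - L / 2]),
                np.array([700.0 + L / 2]),
                np.array([1.0]),
                np.array([0.0, 0.0, 700.0]),
            )
            errs.append(abs(seg / _point(100.0, 700.0) - 1.0))
        assert errs[0] > errs[1] > errs[2]  # documented convergence
        assert errs[2] < 1e-3  # 0.1% in the short-segment limit

    def test_linear_in_current(self):
        one = lfp.line_source_potential(
            np.array([[50.0, 0.0]]),
            np.array([600.0]),
            np.array([800.0]),
            np.array([1.0]),
            np.array([0.0, 0.0, 700.0]),
        )
        two = lfp.line_source_potential(
            np.array([[50.0, 0.0]]),
            np.array([600.0]),
            np.array([800.0]),
            np.array([2.0]),
            np.array([0.0, 0.0, 700.0]),
        )
        assert two == pytest.approx(2 * one)

    def test_radial_symmetry(self):
        a = lfp.line_source_potential(
            np.array([[120.0, 0.0]]),
            np.array([650.0]),
            np.array([750.0]),
            np.array([1.0]),
            np.array([0.0, 0.0, 700.0]),
        )
        b = lfp.line_source_potential(
            np.array([[-120.0, 0.0]]),
            np.array([650.0]),
            np.array([750.0]),
            np.array([1.0]),
            np.array([0.0, 0.0, 700.0]),
        )
        assert a == pytest.approx(b)

    def test_dipole_oracle_within_1pct(self):
        """Two short segments vs the closed-form two-point solution."""
        elec = np.array([[250.0, 0.0, 700.0]])
        pos, cur, t, phi_true = gen_test_currents("dipole", elec)
        L = 1.0
        phi = sum(
            lfp.line_source_potential(
                pos[k : k + 1, :2],
                np.array([pos[k, 2] - L / 2]),
                np.array([pos[k, 2] + L / 2]),
                cur[k, :1],
                elec[0],
            )
            for k in range(2)
        )
        assert phi == pytest.approx(phi_true[0, 0], rel=0.01)


class TestSpectrogram:
    fs = 2000.0

    def _sine(self, f, dur=2.0, amp=1.0):
        t = np.arange(0, dur, 1 / self.fs)
        return t, amp * np.sin(2 * np.pi * f * t)

    def test_pure_tone_argmax(self):
        _, sig = self._sine(15.0)
        sp = lfp.spectrogram(sig, self.fs)
        interior = sp.power[:, 800:-800]
        assert np.all(sp.f_hz[np.argmax(interior, axis=0)] == 15.0)

    def test_two_tone_ridges(self):
        t, _ = self._sine(2.0)
        sig = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 20 * t)
        sp = lfp.spectrogram(sig, self.fs)
        prof = sp.power[:, 800:-800].mean(axis=1)
        lo = sp.f_hz[np.argmax(prof * (sp.f_hz < 10))]
        hi = sp.f_hz[np.argmax(prof * (sp.f_hz > 10))]
        assert lo == pytest.approx(2.0, abs=0.5)
        assert hi == pytest.approx(20.0, abs=1.0)

    def test_amplitude_step_quadruples_power(self):
        t = np.arange(0, 4.0, 1 / self.fs)
        sig = np.sin(2 * np.pi * 15 * t) * np.where(t < 2.0, 1.0, 2.0)
        sp = lfp.spectrogram(sig, self.fs)
        i15 = int(np.argmin(np.abs(sp.f_hz - 15)))
        first = sp.power[i15, 1000:3000].mean()
        second = sp.power[i15, 5000:7000].mean()
        assert second / first == pytest.approx(4.0, rel=0.05)

    def test_unit_tone_power_flat_over_time(self):
        _, sig = self._sine(15.0, dur=3.0)
        sp = lfp.spectrogram(sig, self.fs)
        i15 = int(np.argmin(np.abs(sp.f_hz - 15)))
        interior = sp.power[i15, 1200:-1200]
        assert interior.std() / interior.mean() < 0.05

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            lfp.spectrogram(np.zeros(100), self.fs)


class TestBandPower:
    def test_zero_signal(self):
        sp = lfp.spectrogram(np.zeros(4000), 2000.0)
        assert lfp.band_power(sp, (13, 30)) == 0.0

    def test_tone_band_dominates(self):
        t = np.arange(0, 2.0, 1 / 2000.0)
        sp = lfp.spectrogram(np.sin(2 * np.pi * 15 * t), 2000.0)
        assert lfp.band_power(sp, (13, 17)) > 100 * lfp.band_power(sp, (35, 45))

    def test_white_noise_flat_across_bands(self):
        rng = np.random.default_rng(0)
        sp = lfp.spectrogram(rng.standard_normal(40_000), 2000.0)
        a = lfp.band_power(sp, (13, 21), (2000, 18_000))
        b = lfp.band_power(sp, (31, 39), (2000, 18_000))
        assert a / b == pytest.approx(1.0, rel=0.35)

    def test_band_outside_range_rejected(self):
        sp = lfp.spectrogram(np.zeros(4000), 2000.0)
        with pytest.raises(ValueError):
            lfp.band_power(sp, (60, 80))
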