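"""Population spike-count histograms, duty cycle, ISI-CV, rate statistics.

Conventions follow the simulation protocol: analyses run on the last
2.3 s of a 4.3 s simulation (the first 2 s discard initialization
transients), spike-count histograms (SCH) use 2 ms bins, oscillation
duty cycles are measured against the half-height between trough and
peak of the SCH, and neurons are classified regular (ISI CV <= 0.5) or
irregular (CV > 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_BIN_MS = 2.0


class FlatHistogramError(ValueError):
    """Duty cycle is undefined on a flat histogram."""


@dataclass
class SCH:
    population: str
    bin_edges_ms: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ms[:-1] + self.bin_edges_ms[1:])

    @property
    def bin_width_ms(self) -> float:
        return float(self.bin_edges_ms[1] - self.bin_edges_ms[0])


@dataclass
class DutyCycleResult:
    threshold: float
    rising_ms: np.ndarray
    falling_ms: np.ndarray
    duty_pct: float
    mean_period_freq_hz: float


@dataclass
class CVResult:
    per_neuron: dict  # neuron id -> CV (neurons with >= 3 spikes)
    mean: float
    sd: float
    frac_regular: float  # CV <= 0.5
    frac_irregular: float
    n_excluded: int


@dataclass
class RateStats:
    table: pd.DataFrame  # population, mean, sd, min, max, n
    per_neuron: dict  # population -> array of per-neuron rates (incl. silent)


def _spike_array(spikes, population: str | None) -> np.ndarray:
    if isinstance(spikes, pd.DataFrame):
        if population is not None:
            spikes = spikes[spikes["population"] == population]
        return spikes["spike_time_ms"].to_numpy()
    # dict of trains
    return np.concatenate([np.asarray(v) for v in spikes.values()]) if spikes else np.array([])


def spike_count_histogram(
    spikes,
    population: str | None,
    window_ms: tuple[float, float],
    bin_ms: float = DEFAULT_BIN_MS,
) -> SCH:
    """Pooled spike counts of a population in fixed-width bins."""
    t = _spike_array(spikes, population)
    t = t[(t >= window_ms[0]) & (t < window_ms[1])]
    edges = np.arange(window_ms[0], window_ms[1] + bin_ms / 2, bin_ms)
    counts, _ = np.histogram(t, bins=edges)
    if t.size == 0:
        warnings.warn(f"no spikes for population {population!r} in window")
    return SCH(population=str(population), bin_edges_ms=edges, counts=counts)


def _interp_crossings(t: np.ndarray, y: np.ndarray, thr: float):
    """Rising and falling threshold crossings of the piecewise-linear
    signal through (t, y), linearly interpolated."""
    above = y >= thr
    rise, fall = [], []
    for i in range(len(y) - 1):
        if not above[i] and above[i + 1]:
            fr = (thr - y[i]) / (y[i + 1] - y[i])
            rise.append(t[i] + fr * (t[i + 1] - t[i]))
        elif above[i] and not above[i + 1]:
            fr = (y[i] - thr) / (y[i] - y[i + 1])
            fall.append(t[i] + fr * (t[i + 1] - t[i]))
    return np.array(rise), np.array(fall)


def duty_cycle(sch: SCH, smooth_bins: int = 3) -> DutyCycleResult:
    """Fraction of each oscillation period spent above half height.

    The threshold is (min + max)/2 of the (moving-average smoothed)
    histogram.  A period runs from one rising crossing to the next; the
    ON span runs from the rising crossing to the following falling
    crossing; the duty cycle is the mean of ON/period, in percent.
    """
    y = sch.counts.astype(float)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        y = np.convolve(y, kernel, mode="same")
    if np.ptp(y) == 0:
        raise FlatHistogramError("histogram is flat; duty cycle undefined")
    thr = 0.5 * (y.min() + y.max())
    t = sch.bin_centers_ms
    rise, fall = _interp_crossings(t, y, thr)
    if rise.size < 2:
        raise FlatHistogramError("fewer than two rising crossings")
    ratios = []
    for r0, r1 in zip(rise[:-1], rise[1:]):
        f = fall[(fall > r0) & (fall <= r1)]
        if f.size:
            ratios.append((f[0] - r0) / (r1 - r0))
    if not ratios:
        raise FlatHistogramError("no complete on/off period")
    period = np.diff(rise).mean()
    return DutyCycleResult(
        threshold=thr,
        rising_ms=rise,
        falling_ms=fall,
        duty_pct=float(np.mean(ratios) * 100.0),
        mean_period_freq_hz=float(1e3 / period),
    )


def isi_cv(
    spikes,
    neurons: pd.DataFrame | None,
    population: str | None,
    window_ms: tuple[float, float],
) -> CVResult:
    """Coefficient of variation of interspike intervals per neuron.

    Neurons with fewer than 3 spikes in the window are excluded (and
    counted).  Classification threshold: regular iff CV <= 0.5.
    """
    if isinstance(spikes, pd.DataFrame):
        sel = spikes
        if population is not None:
            sel = sel[sel["population"] == population]
        trains = {
            nid: g["spike_time_ms"].to_numpy() for nid, g in sel.groupby("neuron_id")
        }
    else:
        trains = spikes
    per = {}
    excluded = 0
    for nid, t in trains.items():
        t = np.asarray(t)
        t = t[(t >= window_ms[0]) & (t < window_ms[1])]
        if t.size < 3:
            excluded += 1
            continue
        isi = np.diff(np.sort(t))
        per[nid] = float(isi.std() / isi.mean())
    if per:
        vals = np.array(list(per.values()))
        reg = float(np.mean(vals <= 0.5))
        return CVResult(
            per_neuron=per,
            mean=float(vals.mean()),
            sd=float(vals.std()),
            frac_regular=reg,
            frac_irregular=1.0 - reg,
            n_excluded=excluded,
        )
    return CVResult(
        per_neuron={},
        mean=float("nan"),
        sd=float("nan"),
        frac_regular=float("nan"),
        frac_irregular=float("nan"),
        n_excluded=excluded,
    )


def rate_stats(
    spikes: pd.DataFrame,
    neurons: pd.DataFrame,
    window_ms: tuple[float, float],
) -> RateStats:
    """Per-population firing-rate statistics over the analysis window.

    Every placed neuron contributes a rate (0 for silent neurons).
    """
    t0, t1 = window_ms
    dur_s = (t1 - t0) / 1e3
    sel = spikes[(spikes["spike_time_ms"] >= t0) & (spikes["spike_time_ms"] < t1)]
    counts = sel.groupby("neuron_id").size()
    rows = []
    per = {}
    for pop, grp in neurons.groupby("pop"):
        ids = grp["id"].to_numpy()
        r = counts.reindex(ids).fillna(0).to_numpy() / dur_s
        per[pop] = r
        rows.append((pop, r.mean(), r.std(), r.min(), r.max(), len(ids)))
    table = pd.DataFrame(
        rows, columns=["population", "mean", "sd", "min", "max", "n"]
    )
    return RateStats(table=table, per_neuron=per)


def compare_rates(rates_a: np.ndarray, rates_b: np.ndarray) -> float:
    """Two-sided Mann-Whitney rank-sum p-value between per-neuron rates."""
    a = np.asarray(rates_a)
    b = np.asarray(rates_b)
    if a.size == 0 or b.size == 0:
        warnings.warn("empty group; comparison skipped")
        return float("nan")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
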