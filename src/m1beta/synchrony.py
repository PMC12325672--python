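"""Population coincidence detection and unitary-event significance.

A coincidence event is two or more spikes from distinct neurons falling
within a 1 ms sliding window; overlapping windows merge into maximal
clusters.  Events are reported once each (the % of coincident spikes
counts spikes belonging to any event).  For significance, the empirical
statistic inside each sliding 100 ms analysis window is the number of
distinct-neuron spike *pairs* falling in the same disjoint 1 ms bin,
whose expectation under frequency-matched independent Poisson firing is
the pairwise rate-product formula over the same bins -- the two moments
match, so the upper Poisson tail of the expectation (joint surprise) is
a calibrated test that still gains power when many neurons join a
volley.  Maximal
runs of significant windows form synchrony epochs, each annotated with
the oscillation frequency of its event train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CoincidenceConfig:
    window_ms: float = 1.0
    rate_window_ms: float = 100.0
    step_ms: float = 20.0
    alpha: float = 0.05

    def __post_init__(self):
        if self.window_ms <= 0 or self.rate_window_ms <= 0 or self.step_ms <= 0:
            raise ValueError("windows must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class UEResult:
    windows: pd.DataFrame  # window_center_ms, n_emp, n_exp, p
    events: pd.DataFrame  # time_ms, n_spikes, n_neurons
    pct_coincident: float  # % of population spikes inside events
    epochs: pd.DataFrame  # start_ms, end_ms, freq_hz
    total_significant_s: float
    pct_significant_time: float


def detect_coincidences(
    trains: dict, window_ms: float = 1.0
) -> tuple[pd.DataFrame, float]:
    """Coincidence events and the % of spikes participating in one.

    Spikes from all neurons are pooled and chained into maximal clusters
    (consecutive gap <= window); a cluster is an event iff it contains
    spikes from at least two distinct neurons.
    """
    cols = ["time_ms", "n_spikes", "n_neurons", "n_pairs"]
    if len(trains) < 2:
        return pd.DataFrame(columns=cols), 0.0
    times = []
    owners = []
    for nid, t in trains.items():
        t = np.asarray(t, dtype=float)
        times.append(t)
        owners.append(np.full(t.size, nid, dtype=object))
    t_all = np.concatenate(times)
    o_all = np.concatenate(owners)
    if t_all.size == 0:
        return pd.DataFrame(columns=cols), 0.0
    order = np.argsort(t_all, kind="stable")
    t_all, o_all = t_all[order], o_all[order]
    breaks = np.flatnonzero(np.diff(t_all) > window_ms) + 1
    clusters = np.split(np.arange(t_all.size), breaks)
    rows = []
    n_coincident = 0
    for cl in clusters:
        counts = {}
        for o in o_all[cl]:
            counts[o] = counts.get(o, 0) + 1
        uniq = len(counts)
        if cl.size >= 2 and uniq >= 2:
            s = cl.size
            pairs = (s * s - sum(c * c for c in counts.values())) // 2
            rows.append((float(t_all[cl].mean()), int(s), uniq, int(pairs)))
            n_coincident += s
    events = pd.DataFrame(rows, columns=cols)
    pct = 100.0 * n_coincident / t_all.size
    return events, pct


def expected_coincidences(
    trains: dict,
    window_ms: tuple[float, float],
    config: CoincidenceConfig = CoincidenceConfig(),
) -> pd.DataFrame:
    """Per analysis window: expected coincidence count for independent
    Poisson neurons with the window's empirical rates.

    With per-neuron bin probabilities p_i = r_i * (coincidence window),
    the expected number of >= 2-spike (pairwise-dominant) coincidences
    over N bins is N * sum_{i<j} p_i p_j.
    """
    t0, t1 = window_ms
    centers = np.arange(
        t0 + config.rate_window_ms / 2,
        t1 - config.rate_window_ms / 2 + 1e-9,
        config.step_ms,
    )
    arrs = [np.asarray(t, dtype=float) for t in trains.values()]
    n_bins = config.rate_window_ms / config.window_ms
    rows = []
    for c in centers:
        lo, hi = c - config.rate_window_ms / 2, c + config.rate_window_ms / 2
        p = np.array(
            [
                ((t >= lo) & (t < hi)).sum() / n_bins  # spikes per 1 ms bin
                for t in arrs
            ]
        )
        s1 = p.sum()
        s2 = (p**2).sum()
        n_exp = n_bins * 0.5 * (s1**2 - s2)
        rows.append((c, n_exp))
    return pd.DataFrame(rows, columns=["window_center_ms", "n_exp"])


def joint_surprise(n_emp: int, n_exp: float) -> float:
    """Upper-tail Poisson probability P(X >= n_emp), X ~ Poisson(n_exp)."""
    if n_exp < 0:
        raise ValueError("n_exp must be >= 0")
    if n_emp <= 0:
        return 1.0
    return float(stats.poisson.sf(n_emp - 1, n_exp))


def unitary_events(
    trains: dict,
    window_ms: tuple[float, float],
    config: CoincidenceConfig = CoincidenceConfig(),
) -> UEResult:
    """Full unitary-event battery over an analysis window."""
    events, pct = detect_coincidences(trains, config.window_ms)
    exp_df = expected_coincidences(trains, window_ms, config)
    ev_t = events["time_ms"].to_numpy() if len(events) else np.array([])
    # empirical statistic: cross-neuron spike pairs per disjoint 1 ms bin
    t0, t1 = window_ms
    edges = np.arange(t0, t1 + config.window_ms / 2, config.window_ms)
    total = np.zeros(edges.size - 1)
    sumsq = np.zeros(edges.size - 1)
    for t in trains.values():
        c, _ = np.histogram(np.asarray(t, dtype=float), edges)
        total += c
        sumsq += c.astype(float) ** 2
    pairs_per_bin = (total**2 - sumsq) / 2.0
    bin_centers = 0.5 * (edges[:-1] + edges[1:])
    n_events = np.empty(len(exp_df), dtype=int)
    n_emp = np.empty(len(exp_df), dtype=int)
    for i, c in enumerate(exp_df["window_center_ms"]):
        lo, hi = c - config.rate_window_ms / 2, c + config.rate_window_ms / 2
        n_events[i] = int(((ev_t >= lo) & (ev_t < hi)).sum())
        m = (bin_centers >= lo) & (bin_centers < hi)
        n_emp[i] = int(pairs_per_bin[m].sum())
    pvals = np.array(
        [joint_surprise(int(e), x) for e, x in zip(n_emp, exp_df["n_exp"])]
    )
    windows = exp_df.assign(n_emp=n_emp, n_events=n_events, p=pvals)[
        ["window_center_ms", "n_emp", "n_events", "n_exp", "p"]
    ]
    epochs, tot_s, pct_t = significant_epochs(
        windows, ev_t, window_ms, config.alpha, config.step_ms
    )
    return UEResult(
        windows=windows,
        events=events,
        pct_coincident=pct,
        epochs=epochs,
        total_significant_s=tot_s,
        pct_significant_time=pct_t,
    )


def significant_epochs(
    windows: pd.DataFrame,
    event_times_ms: np.ndarray,
    window_ms: tuple[float, float],
    alpha: float = 0.05,
    step_ms: float = 20.0,
):
    """Maximal runs of significant windows -> epochs with within-epoch
    oscillation frequency (reciprocal median inter-event interval)."""
    sig = (windows["p"] < alpha).to_numpy()
    centers = windows["window_center_ms"].to_numpy()
    rows = []
    total_ms = 0.0
    idx = np.flatnonzero(sig)
    if idx.size:
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in splits:
            start, end = centers[run[0]], centers[run[-1]]
            dur = end - start if run.size > 1 else step_ms
            total_ms += dur
            inside = event_times_ms[
                (event_times_ms >= start) & (event_times_ms <= end)
            ]
            if inside.size >= 2:
                # median inter-event interval: robust against sporadic
                # chance coincidences interleaved with the periodic train
                freq = 1e3 / np.median(np.diff(np.sort(inside)))
            else:
                freq = float("nan")
            rows.append((start, end, freq))
    epochs = pd.DataFrame(rows, columns=["start_ms", "end_ms", "freq_hz"])
    span = window_ms[1] - window_ms[0]
    return epochs, total_ms / 1e3, 100.0 * total_ms / span
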