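"""Ground-truth generators for testing the analysis stack in isolation.

Three families: (1) populations of independent inhomogeneous Poisson
spike trains with sinusoidally modulated rate (beta-band population
oscillations with known frequency and depth), sampled exactly by
thinning; (2) injected cross-neuron coincidences with a returned
ground-truth event list, for synchrony-recovery tests; (3) compartmental
current patterns (point source, static and oscillating dipoles) paired
with their closed-form extracellular potentials, as oracles for the
line-source LFP forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OscillatorySpikeSpec:
    n_neurons: int = 50
    duration_ms: float = 4000.0
    base_rate_hz: float = 10.0
    mod_depth: float = 1.0  # m in r0 (1 + m sin(2 pi f t))
    mod_freq_hz: float = 15.0
    seed: int = 0

    def __post_init__(self):
        if self.base_rate_hz < 0:
            raise ValueError("base rate must be >= 0")
        if not 0 <= self.mod_depth <= 1:
            raise ValueError(
                "modulation depth must be in [0, 1] (rate must stay >= 0)"
            )


@dataclass(frozen=True)
class InjectionSpec:
    event_times_ms: tuple  # coincidence times
    neurons_per_event: int = 5
    jitter_ms: float = 0.0

    def __post_init__(self):
        if self.jitter_ms > 0.5:
            raise ValueError("jitter must keep events within the 1 ms window")


def gen_oscillatory_trains(spec: OscillatorySpikeSpec) -> dict[int, np.ndarray]:
    """Independent inhomogeneous Poisson trains by thinning.

    Candidate spikes are drawn homogeneously at the peak rate
    r0 (1 + m) and kept with probability r(t)/r_max (exact thinning).
    """
    rng = np.random.default_rng(spec.seed)
    out = {}
    r_max = spec.base_rate_hz * (1.0 + spec.mod_depth)
    dur_s = spec.duration_ms / 1e3
    for nid in range(spec.n_neurons):
        if r_max == 0 or spec.duration_ms == 0:
            out[nid] = np.array([])
            continue
        n_cand = rng.poisson(r_max * dur_s)
        t = np.sort(rng.uniform(0.0, spec.duration_ms, n_cand))
        rate = spec.base_rate_hz * (
            1.0 + spec.mod_depth * np.sin(2 * np.pi * spec.mod_freq_hz * t / 1e3)
        )
        keep = rng.random(n_cand) < rate / r_max
        out[nid] = t[keep]
    return out


def inject_coincidences(
    trains: dict[int, np.ndarray], spec: InjectionSpec, seed: int = 0
) -> tuple[dict[int, np.ndarray], pd.DataFrame]:
    """Add one spike per participating neuron at each event time.

    Returns the augmented trains and a ground-truth table
    (time_ms, neuron_id) of the injected spikes.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(list(trains))
    out = {k: np.asarray(v, dtype=float) for k, v in trains.items()}
    truth = []
    for t0 in spec.event_times_ms:
        chosen = rng.choice(ids, size=min(spec.neurons_per_event, ids.size),
                            replace=False)
        for nid in chosen:
            t = t0 + (
                rng.uniform(-spec.jitter_ms, spec.jitter_ms)
                if spec.jitter_ms > 0
                else 0.0
            )
            out[nid] = np.sort(np.append(out[nid], t))
            truth.append((t0, nid))
    return out, pd.DataFrame(truth, columns=["time_ms", "neuron_id"])


def gen_test_currents(
    pattern: str,
    electrode_um: np.ndarray,
    duration_ms: float = 200.0,
    dt_ms: float = 0.5,
    amplitude_nA: float = 1.0,
    separation_um: float = 100.0,
    freq_hz: float = 15.0,
    source_um: np.ndarray | None = None,
    sigma_mS_per_mm: float = 0.3,
):
    """Compartmental current traces plus closed-form potentials.

    pattern: ``point`` (single monopole; physically a far-field check),
    ``dipole`` (two opposite point currents separated vertically), or
    ``oscillating-dipole`` (dipole with sinusoidal amplitude).

    Returns (positions (n, 3), currents (n, n_t) nA, t_ms,
    phi_analytic_mV (n_elec, n_t)) where the analytic potential is the
    sum of point-source terms I/(4 pi sigma d).
    """
    if source_um is None:
        source_um = np.array([0.0, 0.0, 700.0])
    t = np.arange(0.0, duration_ms, dt_ms)
    elec = np.atleast_2d(np.asarray(electrode_um, dtype=float))
    if pattern == "point":
        pos = source_um[None, :]
        amp = np.array([amplitude_nA])
        modulation = np.ones_like(t)
    elif pattern in ("dipole", "oscillating-dipole"):
        off = np.array([0.0, 0.0, separation_um / 2.0])
        pos = np.vstack([source_um - off, source_um + off])
        amp = np.array([amplitude_nA, -amplitude_nA])
        modulation = (
            np.sin(2 * np.pi * freq_hz * t / 1e3)
            if pattern == "oscillating-dipole"
            else np.ones_like(t)
        )
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    currents = amp[:, None] * modulation[None, :]
    d = np.linalg.norm(elec[:, None, :] - pos[None, :, :], axis=2)  # (ne, ns)
    # phi_mV = I_nA / (4 pi sigma d_um)  (sigma in mS/mm == S/m)
    geom = 1.0 / (4.0 * np.pi * sigma_mS_per_mm * d)
    phi = geom @ currents
    return pos, currents, t, phi
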