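"""Line-source extracellular potentials, spectrograms and band power.

The extracellular potential at an electrode is the superposition over
all neurite segments of the line-source solution: a segment carrying
membrane current ``I`` uniformly along its length ``L`` in a homogeneous
ohmic medium of conductivity ``sigma`` contributes

    phi = I / (4 pi sigma L) * [asinh((L - s0)/r) - asinh(-s0/r)]

where ``r`` is the perpendicular distance from the electrode to the
segment axis and ``s0`` the axial coordinate of the electrode's
projection measured from the segment start.  As ``L -> 0`` this reduces
to the point-source potential ``I / (4 pi sigma d)``.

Default conductivity is 0.3 mS/mm (0.3 S/m).  Electrodes sit on the
cylinder axis at seven depths (layer midpoints and boundaries).

Time-resolved spectra use complex Morlet wavelets (PyWavelets ``cmor``)
with a 6-cycle envelope over 1-50 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt

from .cells import CellModel, ConfigurationError
from .circuit import Geometry
from .engine import CompartmentLayout, SimResult

SIGMA_DEFAULT = 0.3  # mS/mm == S/m

# wavelet bandwidth giving a 6-cycle Gaussian envelope:
# sigma_t = n_cycles/(2 pi f) with cmor sigma_t = sqrt(B/2) * scale
N_CYCLES = 6.0
_CMOR_B = 2.0 * (N_CYCLES / (2.0 * np.pi)) ** 2
WAVELET = f"cmor{_CMOR_B:.4f}-1.0"

# orientation of each compartment zone along the depth axis
# (+1 deeper, -1 toward the pia, 0 centered on the soma)
_ZONE_DIRECTION = {"soma": 0, "axon": +1, "basal": +1, "apical": -1, "dend": -1}


@dataclass(frozen=True)
class LFPConfig:
    sigma_mS_per_mm: float = SIGMA_DEFAULT
    electrode_depths_um: tuple[float, ...] | None = None  # None -> layer grid
    min_distance_um: float = 10.0

    def __post_init__(self):
        if self.sigma_mS_per_mm <= 0:
            raise ConfigurationError("sigma must be > 0")


@dataclass
class LFPSignal:
    t_ms: np.ndarray
    potentials_mv: np.ndarray  # (n_electrodes, n_samples)
    electrode_depths_um: np.ndarray

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.potentials_mv.T,
            columns=[f"e{int(round(d))}um" for d in self.electrode_depths_um],
        )
        df.insert(0, "time_ms", self.t_ms)
        df.to_csv(path, index=False)


@dataclass
class Spectrogram:
    t_ms: np.ndarray
    f_hz: np.ndarray
    power: np.ndarray  # (n_freqs, n_times), >= 0


def default_electrode_depths(geometry: Geometry) -> np.ndarray:
    """Seven axial electrodes: midpoints of L2/3..L6 plus L5B boundaries."""
    d = geometry.depth_um
    mids = [
        0.5 * (a + b) * d
        for name, (a, b) in geometry.layers.items()
        if name != "L1"
    ]
    l5b = geometry.layers["L5B"]
    return np.array(sorted(mids + [l5b[0] * d, l5b[1] * d]))


def line_source_potential(
    seg_xy: np.ndarray,
    seg_z0: np.ndarray,
    seg_z1: np.ndarray,
    current_nA: np.ndarray,
    electrode_um: np.ndarray,
    sigma_mS_per_mm: float = SIGMA_DEFAULT,
    min_distance_um: float = 10.0,
) -> float:
    """Potential (mV) at one electrode from vertical line segments.

    seg_xy: (n, 2) horizontal positions; seg_z0/z1: segment depth
    extents (um); current_nA: membrane current per segment.
    """
    r = np.hypot(seg_xy[:, 0] - electrode_um[0], seg_xy[:, 1] - electrode_um[1])
    r = np.maximum(r, min_distance_um)
    L = np.abs(seg_z1 - seg_z0)
    s0 = electrode_um[2] - np.minimum(seg_z0, seg_z1)
    # units: nA, um -> SI; output mV
    scale = 1e-9 / (4.0 * np.pi * sigma_mS_per_mm) * 1e6 * 1e3  # per-um geometry
    point = L < 1e-9
    out = np.empty_like(r)
    with np.errstate(divide="ignore"):
        out[point] = 1.0 / np.hypot(r[point], s0[point])
        Ln = L[~point]
        out[~point] = (
            np.arcsinh((Ln - s0[~point]) / r[~point])
            - np.arcsinh(-s0[~point] / r[~point])
        ) / Ln
    return float(np.sum(current_nA * out) * scale)


def segment_geometry(
    neurons: pd.DataFrame,
    models: dict[str, CellModel],
    layout: CompartmentLayout,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical segment extents for every compartment in layout order.

    Returns (xy (n_comp, 2), z0, z1) in um.  Apical compartments extend
    toward the pia, axon/basal deeper, the soma straddles the cell body;
    chained compartments continue from their parent's far end.
    """
    rel = {}
    for cls, m in models.items():
        z0 = np.zeros(m.n_comp)
        z1 = np.zeros(m.n_comp)
        for i, c in enumerate(m.compartments):
            dr = _ZONE_DIRECTION[c.zone]
            if c.parent < 0:
                z0[i], z1[i] = -c.length_um / 2.0, c.length_um / 2.0
            else:
                p = m.compartments[c.parent]
                if dr == 0:
                    dr = +1
                if p.zone == "soma":
                    start = (c.length_um / 2.0) * 0 + (
                        p.length_um / 2.0 if dr > 0 else -p.length_um / 2.0
                    )
                else:
                    start = z1[c.parent]
                z0[i] = start
                z1[i] = start + dr * c.length_um
        rel[cls] = (z0, z1)
    n = layout.n_comp
    xy = np.empty((n, 2))
    z0g = np.empty(n)
    z1g = np.empty(n)
    x = neurons["x"].to_numpy()
    y = neurons["y"].to_numpy()
    z = neurons["z"].to_numpy()
    for i, cls in enumerate(layout.cell_class):
        o = layout.offsets[i]
        m = models[cls]
        z0, z1 = rel[cls]
        xy[o : o + m.n_comp, 0] = x[i]
        xy[o : o + m.n_comp, 1] = y[i]
        z0g[o : o + m.n_comp] = z[i] + z0
        z1g[o : o + m.n_comp] = z[i] + z1
    return xy, z0g, z1g


def transfer_matrix(
    neurons: pd.DataFrame,
    models: dict[str, CellModel],
    layout: CompartmentLayout,
    geometry: Geometry,
    config: LFPConfig = LFPConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """(n_electrodes, n_comp) map from membrane currents (nA) to mV."""
    depths = (
        np.asarray(config.electrode_depths_um)
        if config.electrode_depths_um is not None
        else default_electrode_depths(geometry)
    )
    xy, z0, z1 = segment_geometry(neurons, models, layout)
    T = np.empty((depths.size, layout.n_comp))
    for e, d in enumerate(depths):
        elec = np.array([0.0, 0.0, d])
        for c in range(layout.n_comp):
            T[e, c] = line_source_potential(
                xy[c : c + 1],
                z0[c : c + 1],
                z1[c : c + 1],
                np.ones(1),
                elec,
                config.sigma_mS_per_mm,
                config.min_distance_um,
            )
    return T, depths


def compute_lfp(
    result: SimResult,
    neurons: pd.DataFrame,
    models: dict[str, CellModel],
    geometry: Geometry,
    config: LFPConfig = LFPConfig(),
) -> LFPSignal:
    """LFP from recorded membrane currents (linear superposition)."""
    if result.imem_nA is None:
        raise ConfigurationError(
            "membrane currents were not recorded; enable record_currents "
            "or pass a transfer matrix to engine.run"
        )
    T, depths = transfer_matrix(neurons, models, result.layout, geometry, config)
    return LFPSignal(
        t_ms=result.t_record_ms,
        potentials_mv=T @ result.imem_nA,
        electrode_depths_um=depths,
    )


def spectrogram(
    signal: np.ndarray,
    fs_hz: float,
    f_hz: np.ndarray | None = None,
    t_ms: np.ndarray | None = None,
) -> Spectrogram:
    """Morlet-wavelet power of a 1-D signal; frequencies 1-50 Hz default."""
    sig = np.asarray(signal, dtype=float)
    if f_hz is None:
        f_hz = np.arange(1.0, 50.5, 0.5)
    fc = pywt.central_frequency(WAVELET)
    scales = fc * fs_hz / np.asarray(f_hz)
    # need at least ~two periods of the slowest requested frequency
    if sig.size < int(2 * fs_hz / np.min(f_hz)):
        raise ValueError("signal too short for the requested frequencies")
    coef, _ = pywt.cwt(sig - sig.mean(), scales, WAVELET, sampling_period=1.0 / fs_hz)
    power = np.abs(coef) ** 2
    if t_ms is None:
        t_ms = np.arange(sig.size) / fs_hz * 1e3
    return Spectrogram(t_ms=t_ms, f_hz=np.asarray(f_hz), power=power)


def band_power(
    spec: Spectrogram,
    band_hz: tuple[float, float],
    t_interval_ms: tuple[float, float] | None = None,
) -> float:
    """Mean power over a frequency band x time rectangle."""
    fm = (spec.f_hz >= band_hz[0]) & (spec.f_hz <= band_hz[1])
    if not np.any(fm):
        raise ValueError("band outside the spectrogram frequency range")
    if t_interval_ms is None:
        tm = np.ones(spec.t_ms.size, dtype=bool)
    else:
        tm = (spec.t_ms >= t_interval_ms[0]) & (spec.t_ms <= t_interval_ms[1])
    if not np.any(tm):
        raise ValueError("empty time selection")
    return float(spec.power[np.ix_(fm, tm)].mean())


@dataclass(frozen=True)
class Burst:
    f_hz: float
    t_start_ms: float
    t_end_ms: float


def detect_bursts(
    spec: Spectrogram, threshold_factor: float = 2.0, min_cycles: float = 2.0
) -> list[Burst]:
    """Beta-burst style events: per-frequency runs exceeding
    ``threshold_factor`` x that frequency's median power for at least
    ``min_cycles`` oscillation cycles."""
    out = []
    dt_ms = float(np.median(np.diff(spec.t_ms)))
    for i, f in enumerate(spec.f_hz):
        thr = threshold_factor * np.median(spec.power[i])
        above = spec.power[i] > thr
        idx = np.flatnonzero(above)
        if idx.size == 0:
            continue
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        min_len_ms = min_cycles / f * 1e3
        for run in splits:
            dur = (run[-1] - run[0] + 1) * dt_ms
            if dur >= min_len_ms:
                out.append(
                    Burst(
                        f_hz=float(f),
                        t_start_ms=float(spec.t_ms[run[0]]),
                        t_end_ms=float(spec.t_ms[run[-1]]),
                    )
                )
    return out
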