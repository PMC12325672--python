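"""External Poisson drive and rest/activated state switching.

Seven afferent regions (motor thalamus VM/VL, somatosensory S1/S2,
contralateral M1, ipsilateral M2, orbital cortex) each contribute a bank
of independent Poisson spike generators; every generator's rate is drawn
uniformly from the region's background range.  The activated (movement)
state raises the motor-thalamic range to 0-10 Hz and reduces the PT5B
hyperpolarization-activated (Ih) conductance to 25%, emulating
noradrenergic modulation; everything else is untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cells import CellModel
from .circuit import RECEPTOR_INDEX, SYNAPSE_KINDS, _synapse_target_compartments

DRIVE_DELAY_MS = 2.0


@dataclass(frozen=True)
class DriveSpec:
    region: str
    rate_range_hz: tuple[float, float]
    targets: tuple[str, ...]
    n_generators: int = 1000
    p_connect: float = 0.05
    unitary_epsp_mv: float = 0.5
    motor_thalamus: bool = False

    def __post_init__(self):
        if self.rate_range_hz[0] < 0 or self.rate_range_hz[1] < 0:
            raise ValueError("rates must be >= 0")


@dataclass(frozen=True)
class StateConfig:
    state: str = "rest"  # rest | activated
    motor_thalamus_range_hz: tuple[float, float] = (0.0, 10.0)
    ih_multiplier: float = 0.25

    def __post_init__(self):
        if self.state not in ("rest", "activated"):
            raise ValueError(f"unknown state {self.state!r}")
        if not 0 < self.ih_multiplier <= 1:
            raise ValueError("Ih multiplier must be in (0, 1]")


def default_drive_specs() -> list[DriveSpec]:
    cfg = json.loads((resources.files("m1beta") / "data" / "drive.json").read_text())
    specs = []
    for name, rc in cfg["regions"].items():
        specs.append(
            DriveSpec(
                region=name,
                rate_range_hz=tuple(rc["rate_range_hz"]),
                targets=tuple(rc["targets"]),
                n_generators=cfg["n_generators"],
                p_connect=cfg["p_connect"],
                unitary_epsp_mv=cfg["unitary_epsp_mv"],
                motor_thalamus=rc["motor_thalamus"],
            )
        )
    return specs


def effective_rate_range(spec: DriveSpec, state: StateConfig) -> tuple[float, float]:
    """Activated state overrides the motor-thalamic (VM+VL) range."""
    if state.state == "activated" and spec.motor_thalamus:
        return state.motor_thalamus_range_hz
    return spec.rate_range_hz


def generate_drive_spikes(
    spec: DriveSpec,
    state: StateConfig,
    duration_ms: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Independent homogeneous Poisson trains, one per generator.

    Returns a table (generator_id, region, spike_time_ms), times sorted
    per generator.  Each generator's rate is a uniform draw from the
    state's rate range.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = effective_rate_range(spec, state)
    rates = rng.uniform(lo, hi, spec.n_generators)
    counts = rng.poisson(rates * duration_ms / 1e3)
    gid = np.repeat(np.arange(spec.n_generators), counts)
    times = rng.uniform(0.0, duration_ms, counts.sum())
    order = np.lexsort((times, gid))
    return pd.DataFrame(
        {
            "generator_id": gid[order],
            "region": spec.region,
            "spike_time_ms": times[order],
        }
    )


def apply_state(models: dict[str, CellModel], state: StateConfig) -> dict[str, CellModel]:
    """Return models with the state's PT5B Ih scaling applied (idempotent).

    Scaling is tracked against the model's baseline via the
    ``ih_state_factor`` attribute so repeated application cannot
    compound.
    """
    out = dict(models)
    if state.state == "rest":
        return out
    for key, model in models.items():
        if model.cell_class != "PT5B":
            continue
        applied = getattr(model, "_ih_state_factor", 1.0)
        target = state.ih_multiplier
        scaled = model.scale_channel("ih", target / applied)
        object.__setattr__(scaled, "_ih_state_factor", target)
        out[key] = scaled
    return out


def drive_to_events(
    drive_spikes: pd.DataFrame,
    spec: DriveSpec,
    neurons: pd.DataFrame,
    models: dict[str, CellModel],
    layout_offsets: np.ndarray,
    weight_uS: dict[str, float],
    dt: float,
    seed: int = 0,
):
    """Map generator spikes to per-compartment synaptic events.

    Each generator connects once (probability ``p_connect``) to each cell
    of its target populations; spikes arrive after the 2 ms base delay as
    AMPA+NMDA deposits on a dendritic compartment.  ``weight_uS`` maps
    population name -> peak conductance of the unitary drive synapse.

    Returns (step, comp, receptor, weight) arrays sorted by step.
    """
    rng = np.random.default_rng(seed)
    pops_arr = neurons["pop"].to_numpy()
    rows = np.where(np.isin(pops_arr, spec.targets))[0]
    if rows.size == 0 or not len(drive_spikes):
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, np.zeros(0)
    classes = neurons["cell_class"].to_numpy()[rows]
    # fan-out: generator -> subset of target cells
    fan = rng.random((spec.n_generators, rows.size)) < spec.p_connect
    gen_ids = drive_spikes["generator_id"].to_numpy()
    times = drive_spikes["spike_time_ms"].to_numpy()
    ev_step, ev_comp, ev_rec, ev_w = [], [], [], []
    # pre-draw a target compartment per (generator, cell) pair
    for j, row in enumerate(rows):
        gens = np.where(fan[:, j])[0]
        if gens.size == 0:
            continue
        model = models[classes[j]]
        comps = _synapse_target_compartments("E", model, gens.size, rng)
        comp_of_gen = dict(zip(gens, layout_offsets[row] + comps))
        sel = np.isin(gen_ids, gens)
        g = gen_ids[sel]
        t = times[sel]
        step = np.round((t + DRIVE_DELAY_MS) / dt).astype(np.int64)
        comp = np.array([comp_of_gen[x] for x in g], dtype=np.int64)
        w = weight_uS[pops_arr[row]]
        for rec_name, share in SYNAPSE_KINDS["E"]:
            ev_step.append(step)
            ev_comp.append(comp)
            ev_rec.append(
                np.full(step.size, RECEPTOR_INDEX[rec_name], dtype=np.int64)
            )
            ev_w.append(np.full(step.size, w * share))
    if not ev_step:
        z = np.zeros(0, dtype=np.int64)
        return z, z, z, np.zeros(0)
    step = np.concatenate(ev_step)
    comp = np.concatenate(ev_comp)
    rec = np.concatenate(ev_rec)
    w = np.concatenate(ev_w)
    order = np.argsort(step, kind="stable")
    return step[order], comp[order], rec[order], w[order]
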