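"""Network integration: spikes, somatic voltages, membrane currents, LFP.

The engine flattens every neuron's compartments into global state arrays
and advances them with the same exponential-Euler scheme as the
single-cell integrator (default dt = 0.025 ms).  Synapses are
double-exponential conductances (AMPA, NMDA with magnesium unblock,
fast/slow GABAA, GABAB) driven by an exact delay queue: presynaptic
spikes deposit conductance increments into a circular per-compartment
buffer indexed by arrival step.

Per-compartment transmembrane currents are recovered from the axial
currents (Kirchhoff closure: membrane current out of a compartment
equals the axial current flowing in plus any injected current), which
makes the per-cell current sum vanish identically -- the property the
line-source LFP forward model relies on.  When an electrode transfer
matrix is supplied, the LFP is accumulated on the fly on the recording
grid instead of storing full current traces.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from . import channels
from .cells import (
    DEFAULT_DT,
    REFRACTORY_MS,
    SPIKE_THRESHOLD_MV,
    CellModel,
    ConfigurationError,
    NumericalError,
)
from .circuit import RECEPTOR_INDEX, RECEPTORS, SYNAPSE_KINDS, NetworkInstance

N_RECEPTORS = len(RECEPTORS)
NMDA_IDX = RECEPTOR_INDEX["NMDA"]


@dataclass(frozen=True)
class SimConfig:
    duration_ms: float = 4300.0
    dt: float = DEFAULT_DT
    record_dt: float = 0.5
    analysis_start_ms: float = 2000.0  # discard initialization transients
    record_spikes: bool = True
    n_v_record: int = 5  # somatic voltage traces per population
    record_currents: bool = False
    v_init_jitter_mv: float = 2.0
    seed_init: int = 0  # initial-condition jitter stream

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.analysis_start_ms > self.duration_ms:
            raise ValueError("analysis window exceeds duration")


@dataclass
class SimResult:
    spikes: pd.DataFrame  # neuron_id, population, spike_time_ms
    t_record_ms: np.ndarray
    v_soma: dict  # neuron_id -> trace (mV)
    lfp_mv: np.ndarray | None  # (n_electrodes, n_record)
    imem_nA: np.ndarray | None  # (n_comp, n_record)
    config: SimConfig
    layout: "CompartmentLayout"

    def spike_trains(self) -> dict[int, np.ndarray]:
        out = {}
        for nid, grp in self.spikes.groupby("neuron_id"):
            out[int(nid)] = grp["spike_time_ms"].to_numpy()
        return out

    def save_spikes(self, path: str | Path) -> None:
        self.spikes.to_csv(path, index=False)

    def save_currents(self, path: str | Path) -> None:
        """Flat binary container (.npz) plus implicit index via layout."""
        if self.imem_nA is None:
            raise ConfigurationError("membrane currents were not recorded")
        np.savez_compressed(
            path, imem_nA=self.imem_nA, t_ms=self.t_record_ms
        )


@dataclass
class CompartmentLayout:
    """Mapping between neurons and rows of the flat compartment arrays."""

    neuron_ids: np.ndarray  # (n_cells,)
    populations: np.ndarray  # (n_cells,) str
    cell_class: np.ndarray  # (n_cells,) str
    offsets: np.ndarray  # (n_cells + 1,)
    soma_comp: np.ndarray  # (n_cells,) global index of the soma
    comp_cell: np.ndarray  # (n_comp,) owning cell row
    comp_name: np.ndarray  # (n_comp,) compartment name

    @property
    def n_comp(self) -> int:
        return len(self.comp_cell)

    def global_comp(self, cell_row: int, local_comp: int) -> int:
        return int(self.offsets[cell_row] + local_comp)


def build_layout(
    neurons: pd.DataFrame, models: dict[str, CellModel]
) -> CompartmentLayout:
    ncomp_of = {cls: m.n_comp for cls, m in models.items()}
    classes = neurons["cell_class"].to_numpy()
    counts = np.array([ncomp_of[c] for c in classes])
    offsets = np.concatenate([[0], np.cumsum(counts)])
    soma_local = {cls: m.soma_index for cls, m in models.items()}
    soma_comp = offsets[:-1] + np.array([soma_local[c] for c in classes])
    comp_cell = np.repeat(np.arange(len(classes)), counts)
    comp_name = np.concatenate(
        [[c.name for c in models[cls].compartments] for cls in classes]
    )
    return CompartmentLayout(
        neuron_ids=neurons["id"].to_numpy(),
        populations=neurons["pop"].to_numpy(),
        cell_class=classes,
        offsets=offsets,
        soma_comp=soma_comp,
        comp_cell=comp_cell,
        comp_name=comp_name,
    )


def _receptor_constants(dt: float):
    """Per-receptor decay factors and peak-normalization constants."""
    rise_fac = np.empty(N_RECEPTORS)
    decay_fac = np.empty(N_RECEPTORS)
    norm = np.empty(N_RECEPTORS)
    erev = np.empty(N_RECEPTORS)
    for name, (tr, td, e) in RECEPTORS.items():
        i = RECEPTOR_INDEX[name]
        rise_fac[i] = np.exp(-dt / tr)
        decay_fac[i] = np.exp(-dt / td)
        tp = tr * td / (td - tr) * np.log(td / tr)
        norm[i] = 1.0 / (np.exp(-tp / td) - np.exp(-tp / tr))
        erev[i] = e
    return rise_fac, decay_fac, norm, erev


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _run_kernel(
    v,
    gates,  # (5, ncomp)
    gna,
    gk,
    gbk,
    gih,
    gl,
    el,
    cm,
    iinj,
    parent,  # global parent index, -1 root
    gax,
    gax_sum,
    cls_idx,  # (ncomp,) table row per compartment
    tables,  # (nclass, 10, nv)
    dt,
    nsteps,
    soma_comp,  # (ncell,)
    refrac_steps,
    # synapses
    syn_rise,
    syn_decay,  # (ncomp, nrec)
    rise_fac,
    decay_fac,
    norm,
    erev,
    pending,  # (L, ncomp, nrec) ring buffer
    edge_ptr,  # (ncell+1,) CSR over presynaptic cells
    edge_comp,
    edge_rec,
    edge_w,
    edge_delay,
    ev_step,
    ev_comp,
    ev_rec,
    ev_w,  # external events, sorted by step
    # recording
    rec_every,
    vrec_cells,  # rows of cells whose soma V is recorded
    vrec_out,  # (nvrec, nrecsteps)
    transfer,  # (nelec, ncomp) or (0, 0)
    lfp_out,  # (nelec, nrecsteps)
    imem_out,  # (ncomp, nrecsteps) or (0, 0)
    spike_cell,
    spike_step,  # preallocated output
):
    ncomp = v.shape[0]
    ncell = soma_comp.shape[0]
    L = pending.shape[0]
    nrec = syn_rise.shape[1]
    nv = tables.shape[2]
    inv_dv = 1.0 / channels.DV
    vmin = channels.V_MIN
    e_na = channels.E_NA
    e_k = channels.E_K
    e_h = channels.E_H
    nmda_a = 0.28
    nmda_b = 0.062

    vold = v.copy()
    child_drive = np.zeros(ncomp)
    refrac = np.zeros(ncell, dtype=np.int64)
    above = np.zeros(ncell, dtype=np.int64)
    for ci in range(ncell):
        above[ci] = 1 if v[soma_comp[ci]] > SPIKE_THRESHOLD_MV else 0
    n_spikes = 0
    ev_i = 0
    nev = ev_step.shape[0]
    do_lfp = transfer.shape[0] > 0
    do_imem = imem_out.shape[0] > 0
    record_axial = do_lfp or do_imem
    imem = np.zeros(ncomp)

    for t in range(nsteps):
        slot = t % L
        # deliver queued synaptic events and decay receptor states
        for c in range(ncomp):
            for r in range(nrec):
                w = pending[slot, c, r]
                if w != 0.0:
                    syn_rise[c, r] += w
                    syn_decay[c, r] += w
                    pending[slot, c, r] = 0.0
                syn_rise[c, r] *= rise_fac[r]
                syn_decay[c, r] *= decay_fac[r]
        # external drive events scheduled for this step
        while ev_i < nev and ev_step[ev_i] == t:
            c = ev_comp[ev_i]
            r = ev_rec[ev_i]
            syn_rise[c, r] += ev_w[ev_i]
            syn_decay[c, r] += ev_w[ev_i]
            ev_i += 1

        for c in range(ncomp):
            vold[c] = v[c]
            child_drive[c] = 0.0
        for c in range(ncomp):
            p = parent[c]
            if p >= 0:
                child_drive[p] += gax[c] * vold[c]
        if record_axial:
            for c in range(ncomp):
                imem[c] = iinj[c]
            for c in range(ncomp):
                p = parent[c]
                if p >= 0:
                    ia = gax[c] * (vold[p] - vold[c])
                    imem[c] += ia
                    imem[p] -= ia

        for c in range(ncomp):
            vc = vold[c]
            k = cls_idx[c]
            x = (vc - vmin) * inv_dv
            i0 = int(x)
            if i0 < 0:
                i0 = 0
            if i0 > nv - 2:
                i0 = nv - 2
            fr = x - i0
            for g in range(5):
                xinf = (
                    tables[k, 2 * g, i0] * (1 - fr) + tables[k, 2 * g, i0 + 1] * fr
                )
                ef = (
                    tables[k, 2 * g + 1, i0] * (1 - fr)
                    + tables[k, 2 * g + 1, i0 + 1] * fr
                )
                gates[g, c] = xinf + (gates[g, c] - xinf) * ef
            m = gates[0, c]
            hh = gates[1, c]
            nn = gates[2, c]
            g_na = gna[c] * m * m * m * hh
            g_kdr = gk[c] * nn * nn * nn * nn
            g_bk = gbk[c] * gates[3, c]
            g_ih = gih[c] * gates[4, c]
            gtot = g_na + g_kdr + g_bk + g_ih + gl[c] + gax_sum[c]
            num = (
                g_na * e_na
                + (g_kdr + g_bk) * e_k
                + g_ih * e_h
                + gl[c] * el[c]
                + iinj[c]
            )
            for r in range(nrec):
                gs = (syn_decay[c, r] - syn_rise[c, r])
                if gs != 0.0:
                    if r == NMDA_IDX:
                        gs *= 1.0 / (1.0 + nmda_a * np.exp(-nmda_b * vc))
                    gtot += gs
                    num += gs * erev[r]
            p = parent[c]
            if p >= 0:
                num += gax[c] * vold[p]
            num += child_drive[c]
            vinf = num / gtot
            v[c] = vinf + (vc - vinf) * np.exp(-dt * gtot / cm[c])
        for c in range(ncomp):
            if not np.isfinite(v[c]):
                return -(c + 1), n_spikes  # numerical failure marker

        # spike detection & event scheduling
        for ci in range(ncell):
            vs = v[soma_comp[ci]]
            if refrac[ci] > 0:
                refrac[ci] -= 1
            if vs > SPIKE_THRESHOLD_MV and above[ci] == 0 and refrac[ci] == 0:
                if n_spikes < spike_cell.shape[0]:
                    spike_cell[n_spikes] = ci
                    spike_step[n_spikes] = t + 1
                    n_spikes += 1
                refrac[ci] = refrac_steps
                for e in range(edge_ptr[ci], edge_ptr[ci + 1]):
                    slot2 = (t + edge_delay[e]) % L
                    pending[slot2, edge_comp[e], edge_rec[e]] += edge_w[e]
            above[ci] = 1 if vs > SPIKE_THRESHOLD_MV else 0

        if (t + 1) % rec_every == 0:
            tr = (t + 1) // rec_every - 1
            for j in range(vrec_cells.shape[0]):
                vrec_out[j, tr] = v[soma_comp[vrec_cells[j]]]
            if do_lfp:
                for e in range(transfer.shape[0]):
                    acc = 0.0
                    for c in range(ncomp):
                        acc += transfer[e, c] * imem[c]
                    lfp_out[e, tr] = acc
            if do_imem:
                for c in range(ncomp):
                    imem_out[c, tr] = imem[c]
    return 0, n_spikes


def run(
    network: NetworkInstance,
    models: dict[str, CellModel],
    drive_events: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None,
    config: SimConfig = SimConfig(),
    transfer: np.ndarray | None = None,
    iinj_nA: np.ndarray | None = None,
) -> SimResult:
    """Integrate the network and return spikes/voltages/LFP.

    drive_events: (step, comp, receptor, weight) arrays sorted by step
    (as produced by :func:`m1beta.drive.drive_to_events`), or None.
    transfer: optional (n_electrodes, n_comp) line-source matrix; if
    given, LFP is accumulated on the recording grid.
    iinj_nA: optional constant per-compartment injected current.
    """
    neurons = network.neurons
    layout = build_layout(neurons, models)
    ncomp = layout.n_comp
    ncell = len(neurons)
    dt = config.dt
    nsteps = int(round(config.duration_ms / dt))
    rec_every = max(1, int(round(config.record_dt / dt)))
    nrecsteps = nsteps // rec_every

    # ---- flatten per-class arrays -------------------------------------
    class_list = sorted(models)
    class_row = {c: i for i, c in enumerate(class_list)}
    tables = np.stack(
        [channels.build_tables(dt, models[c].vt) for c in class_list]
    )
    per_class = {c: models[c].to_arrays() for c in class_list}
    keys = ("g_na", "g_kdr", "g_bk", "g_ih", "g_leak", "e_leak", "cm", "gax")
    flat = {k: np.empty(ncomp) for k in keys}
    parent = np.full(ncomp, -1, dtype=np.int64)
    cls_idx = np.empty(ncomp, dtype=np.int64)
    v0 = np.empty(ncomp)
    rng_init = np.random.default_rng(config.seed_init)
    jitter = config.v_init_jitter_mv * rng_init.standard_normal(ncell)
    for i in range(ncell):
        cls = layout.cell_class[i]
        a = per_class[cls]
        o = layout.offsets[i]
        n = models[cls].n_comp
        for k in keys:
            flat[k][o : o + n] = a[k]
        loc_parent = a["parent"]
        parent[o : o + n] = np.where(loc_parent >= 0, loc_parent + o, -1)
        cls_idx[o : o + n] = class_row[cls]
        v0[o : o + n] = models[cls].v_init + jitter[i]
    gax_sum = np.zeros(ncomp)
    for c in range(ncomp):
        p = parent[c]
        if p >= 0:
            gax_sum[c] += flat["gax"][c]
            gax_sum[p] += flat["gax"][c]

    # ---- synaptic edges -> per-receptor CSR ---------------------------
    id_row = {int(nid): i for i, nid in enumerate(layout.neuron_ids)}
    edges = network.edges
    max_delay_steps = 1
    if len(edges):
        pre_rows = np.array([id_row[p] for p in edges["pre"]])
        post_rows = np.array([id_row[p] for p in edges["post"]])
        delays = np.maximum(1, np.round(edges["delay_ms"].to_numpy() / dt)).astype(
            np.int64
        )
        max_delay_steps = int(delays.max())
        # expand each edge into its receptor components
        exp_pre, exp_comp, exp_rec, exp_w, exp_delay = [], [], [], [], []
        weights = edges["weight"].to_numpy() * edges["nsyn"].to_numpy()
        comps = edges["comp"].to_numpy()
        kinds = edges["receptor"].to_numpy()
        for kind in np.unique(kinds):
            sel = kinds == kind
            for rec_name, share in SYNAPSE_KINDS[kind]:
                exp_pre.append(pre_rows[sel])
                exp_comp.append(layout.offsets[post_rows[sel]] + comps[sel])
                exp_rec.append(
                    np.full(sel.sum(), RECEPTOR_INDEX[rec_name], dtype=np.int64)
                )
                exp_w.append(weights[sel] * share)
                exp_delay.append(delays[sel])
        exp_pre = np.concatenate(exp_pre)
        order = np.argsort(exp_pre, kind="stable")
        exp_pre = exp_pre[order]
        edge_comp = np.concatenate(exp_comp)[order].astype(np.int64)
        edge_rec = np.concatenate(exp_rec)[order]
        edge_w = np.concatenate(exp_w)[order]
        edge_delay = np.concatenate(exp_delay)[order]
        edge_ptr = np.searchsorted(exp_pre, np.arange(ncell + 1)).astype(np.int64)
    else:
        edge_ptr = np.zeros(ncell + 1, dtype=np.int64)
        edge_comp = np.zeros(0, dtype=np.int64)
        edge_rec = np.zeros(0, dtype=np.int64)
        edge_w = np.zeros(0)
        edge_delay = np.zeros(0, dtype=np.int64)

    if drive_events is not None:
        ev_step, ev_comp, ev_rec, ev_w = drive_events
        ev_step = ev_step.astype(np.int64)
        ev_comp = ev_comp.astype(np.int64)
        ev_rec = ev_rec.astype(np.int64)
        ev_w = ev_w.astype(float)
    else:
        ev_step = np.zeros(0, dtype=np.int64)
        ev_comp = np.zeros(0, dtype=np.int64)
        ev_rec = np.zeros(0, dtype=np.int64)
        ev_w = np.zeros(0)

    rise_fac, decay_fac, norm, erev = _receptor_constants(dt)
    # fold the peak normalization into deposited weights
    edge_w = edge_w * norm[edge_rec] if edge_w.size else edge_w
    ev_w = ev_w * norm[ev_rec] if ev_w.size else ev_w

    L = max_delay_steps + 1
    pending = np.zeros((L, ncomp, N_RECEPTORS))
    syn_rise = np.zeros((ncomp, N_RECEPTORS))
    syn_decay = np.zeros((ncomp, N_RECEPTORS))

    # ---- recording targets --------------------------------------------
    vrec_rows = []
    rng_rec = np.random.default_rng(12345)
    for pop in pd.unique(layout.populations):
        rows = np.where(layout.populations == pop)[0]
        take = min(config.n_v_record, rows.size)
        vrec_rows.extend(rng_rec.choice(rows, take, replace=False))
    vrec_rows = np.array(sorted(vrec_rows), dtype=np.int64)
    vrec_out = np.zeros((vrec_rows.size, nrecsteps))
    if transfer is not None:
        if transfer.shape[1] != ncomp:
            raise ConfigurationError("transfer matrix does not match layout")
        lfp_out = np.zeros((transfer.shape[0], nrecsteps))
    else:
        transfer = np.zeros((0, 0))
        lfp_out = np.zeros((0, nrecsteps))
    imem_out = (
        np.zeros((ncomp, nrecsteps)) if config.record_currents else np.zeros((0, 0))
    )
    iinj = np.zeros(ncomp) if iinj_nA is None else np.asarray(iinj_nA, dtype=float)

    # steady-state gate init at v0
    gates = np.zeros((5, ncomp))
    for c in range(ncomp):
        tab = tables[cls_idx[c]]
        x = np.clip((v0[c] - channels.V_MIN) / channels.DV, 0, tab.shape[1] - 2)
        i0 = int(x)
        frx = x - i0
        for g in range(5):
            gates[g, c] = tab[2 * g, i0] * (1 - frx) + tab[2 * g, i0 + 1] * frx

    cap = max(100_000, ncell * 400)
    spike_cell = np.zeros(cap, dtype=np.int64)
    spike_step = np.zeros(cap, dtype=np.int64)
    status, n_spikes = _run_kernel(
        v0.copy(),
        gates,
        flat["g_na"],
        flat["g_kdr"],
        flat["g_bk"],
        flat["g_ih"],
        flat["g_leak"],
        flat["e_leak"],
        flat["cm"],
        iinj,
        parent,
        flat["gax"],
        gax_sum,
        cls_idx,
        tables,
        dt,
        nsteps,
        layout.soma_comp.astype(np.int64),
        int(round(REFRACTORY_MS / dt)),
        syn_rise,
        syn_decay,
        rise_fac,
        decay_fac,
        norm,
        erev,
        pending,
        edge_ptr,
        edge_comp,
        edge_rec,
        edge_w,
        edge_delay,
        ev_step,
        ev_comp,
        ev_rec,
        ev_w,
        rec_every,
        vrec_rows,
        vrec_out,
        transfer,
        lfp_out,
        imem_out,
        spike_cell,
        spike_step,
    )
    if status < 0:
        c = -status - 1
        raise NumericalError(
            f"divergence at compartment {c} "
            f"(cell id {layout.neuron_ids[layout.comp_cell[c]]})"
        )

    t_rec = (np.arange(nrecsteps) + 1) * rec_every * dt
    cells_rows = spike_cell[:n_spikes]
    spikes = pd.DataFrame(
        {
            "neuron_id": layout.neuron_ids[cells_rows],
            "population": layout.populations[cells_rows],
            "spike_time_ms": spike_step[:n_spikes] * dt,
        }
    )
    v_soma = {
        int(layout.neuron_ids[row]): vrec_out[j]
        for j, row in enumerate(vrec_rows)
    }
    return SimResult(
        spikes=spikes,
        t_record_ms=t_rec,
        v_soma=v_soma,
        lfp_mv=lfp_out if lfp_out.shape[0] else None,
        imem_nA=imem_out if imem_out.shape[0] else None,
        config=config,
        layout=layout,
    )


# ---------------------------------------------------------------------------
# unitary-PSP weight normalization
# ---------------------------------------------------------------------------


def _single_cell_network(model: CellModel) -> NetworkInstance:
    from .circuit import Geometry

    neurons = pd.DataFrame(
        {
            "id": [0],
            "pop": ["probe"],
            "cell_class": [model.cell_class],
            "x": [0.0],
            "y": [0.0],
            "z": [700.0],
        }
    )
    edges = pd.DataFrame(
        columns=["pre", "post", "comp", "weight", "delay_ms", "receptor", "nsyn"]
    )
    return NetworkInstance(
        neurons=neurons, edges=edges, geometry=Geometry(), scale=1.0, seed=0
    )


def measure_psp(
    model: CellModel,
    local_comp: int,
    kind: str,
    weight_uS: float,
    vhold_mv: float | None = None,
    settle_ms: float = 400.0,
    probe_ms: float = 400.0,
    dt: float = DEFAULT_DT,
) -> float:
    """Peak somatic PSP magnitude (mV) of one synaptic activation.

    The cell sits unperturbed for ``settle_ms`` (optionally held near
    ``vhold_mv`` by a constant somatic current), then a single synapse of
    the given kind and weight fires on ``local_comp``.
    """
    from .cells import input_resistance, resting_potential

    net = _single_cell_network(model)
    cfg = SimConfig(
        duration_ms=settle_ms + probe_ms,
        dt=dt,
        record_dt=0.5,
        analysis_start_ms=0.0,
        v_init_jitter_mv=0.0,
        n_v_record=1,
    )
    layout = build_layout(net.neurons, {model.cell_class: model})
    iinj = np.zeros(layout.n_comp)
    if vhold_mv is not None:
        vrest = resting_potential(model)
        rin = input_resistance(model)
        iinj[layout.soma_comp[0]] = (vhold_mv - vrest) / rin
    step = int(round(settle_ms / dt))
    ev_step, ev_comp, ev_rec, ev_w = [], [], [], []
    comp = layout.offsets[0] + local_comp
    for rec_name, share in SYNAPSE_KINDS[kind]:
        ev_step.append(step)
        ev_comp.append(comp)
        ev_rec.append(RECEPTOR_INDEX[rec_name])
        ev_w.append(weight_uS * share)
    events = (
        np.array(ev_step, dtype=np.int64),
        np.array(ev_comp, dtype=np.int64),
        np.array(ev_rec, dtype=np.int64),
        np.array(ev_w),
    )
    res = run(net, {model.cell_class: model}, events, cfg, iinj_nA=iinj)
    trace = next(iter(res.v_soma.values()))
    i_on = int(settle_ms / cfg.record_dt) - 1
    baseline = trace[i_on]
    return float(np.max(np.abs(trace[i_on:] - baseline)))


def calibrate_unitary_weight(
    model: CellModel,
    local_comp: int,
    kind: str,
    target_mv: float = 0.5,
    vhold_mv: float | None = None,
) -> float:
    """Weight (uS) whose unitary PSP at the soma has the target amplitude.

    PSPs are close to linear in weight at these amplitudes, so two
    secant refinements suffice.
    """
    w = 1e-3
    for _ in range(3):
        amp = measure_psp(model, local_comp, kind, w, vhold_mv)
        if amp <= 0:
            raise NumericalError("PSP probe produced no deflection")
        err = abs(amp - target_mv) / target_mv
        if err < 0.02:
            break
        w *= target_mv / amp
    return w
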