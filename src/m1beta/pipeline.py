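"""Experiment orchestration: build -> simulate -> analyze for the
condition x state grid, with deterministic seed streams.

A single master seed derives three independent streams (connectivity,
stimulation, location), mirroring the simulation protocol's seed
separation; all randomness in a run is a pure function of
(master seed, condition, state).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cells, circuit, drive, engine, lfp, spike_analysis, synchrony

BETA_BAND_HZ = (13.0, 30.0)
LOW_BETA_BAND_HZ = (13.0, 17.0)


@dataclass(frozen=True)
class ExperimentConfig:
    condition: str = "control"
    state: str = "rest"
    scale: float = 0.1
    duration_ms: float = 4300.0
    analysis_start_ms: float = 2000.0
    seed: int = 0
    seed_connectivity: int | None = None
    seed_stimulation: int | None = None
    seed_location: int | None = None
    excitability_reduction: float | None = None  # None -> per condition
    dt: float = cells.DEFAULT_DT
    record_dt: float = 0.5

    def seeds(self) -> tuple[int, int, int]:
        if None not in (
            self.seed_connectivity,
            self.seed_stimulation,
            self.seed_location,
        ):
            return (
                self.seed_connectivity,
                self.seed_stimulation,
                self.seed_location,
            )
        ss = np.random.SeedSequence(self.seed)
        conn, stim, loc = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
        )
        return (
            self.seed_connectivity if self.seed_connectivity is not None else conn,
            self.seed_stimulation if self.seed_stimulation is not None else stim,
            self.seed_location if self.seed_location is not None else loc,
        )


_weight_cache: dict = {}


def unitary_weight_lookup(models: dict[str, cells.CellModel]):
    """Cached v_con -> peak-conductance conversion per (class, zone, kind).

    Weights are anchored at a 0.5 mV unitary somatic PSP (inhibitory
    kinds measured at a -55 mV holding potential) and scaled linearly to
    each rule's v_con.
    """

    def lookup(post_class: str, zone: str, kind: str) -> float:
        model = models[post_class]
        key = (
            post_class,
            model.condition if post_class == "PT5B" else "control",
            getattr(model, "_ih_state_factor", 1.0),
            zone,
            kind,
        )
        if key not in _weight_cache:
            comp = next(
                i for i, c in enumerate(model.compartments) if c.zone == zone
            )
            vhold = None if kind == "E" else -55.0
            _weight_cache[key] = engine.calibrate_unitary_weight(
                model, comp, kind, 0.5, vhold
            )
        return _weight_cache[key]

    return lookup


def build_models(
    condition: str,
    state: drive.StateConfig,
    excitability_reduction: float | None = None,
) -> dict[str, cells.CellModel]:
    """Cell models for every class under a condition and state.

    ``excitability_reduction`` overrides the shipped parkinsonian PT5B
    with a freshly calibrated variant at the given target (0 -> control
    PT5B); used for the dose-response sweep.
    """
    models = {c: cells.build_cell(c, condition) for c in cells.CELL_CLASSES}
    if excitability_reduction is not None:
        if excitability_reduction == 0.0:
            models["PT5B"] = cells.build_cell("PT5B", "control")
        else:
            spec = cells.CalibrationSpec(target_reduction=excitability_reduction)
            models["PT5B"] = cells.calibrate_parkinsonian(
                cells.build_cell("PT5B", "control"), spec
            )
    return drive.apply_state(models, state)


def build_network(
    config: ExperimentConfig,
    models: dict[str, cells.CellModel],
) -> circuit.NetworkInstance:
    seed_conn, _, seed_loc = config.seeds()
    geo = circuit.Geometry()
    pops = circuit.default_populations()
    rules = circuit.default_rules()
    neurons = circuit.place_neurons(geo, pops, config.scale, seed=seed_loc)
    cls_of_pop = {p.name: p.cell_class for p in pops}
    lookup = unitary_weight_lookup(models)

    def unitary_weight(rule, zone):
        return lookup(cls_of_pop[rule.post], zone, rule.kind) * (
            rule.v_con_mv / 0.5
        )

    edges = circuit.build_edges(
        neurons,
        rules,
        models,
        seed=seed_conn,
        scale=config.scale,
        unitary_weight=unitary_weight,
    )
    return circuit.NetworkInstance(neurons, edges, geo, config.scale, seed_conn)


def build_drive_events(
    config: ExperimentConfig,
    network: circuit.NetworkInstance,
    models: dict[str, cells.CellModel],
    state: drive.StateConfig,
):
    _, seed_stim, _ = config.seeds()
    layout = engine.build_layout(network.neurons, models)
    specs = drive.default_drive_specs()
    cfg = json.loads(
        (__import__("importlib.resources", fromlist=["files"]).files("m1beta")
         / "data" / "drive.json").read_text()
    )
    class_factor = cfg.get("class_weight_factor", {})
    pop_factor = cfg.get("pop_weight_factor", {})
    lookup = unitary_weight_lookup(models)
    pops_in_net = pd.unique(network.neurons["pop"])
    cls_of_pop = dict(
        zip(network.neurons["pop"], network.neurons["cell_class"])
    )
    weight_by_pop = {}
    for pop in pops_in_net:
        cls = cls_of_pop[pop]
        model = models[cls]
        zones = [c.zone for c in model.compartments]
        zone = "basal" if "basal" in zones else "dend"
        w = lookup(cls, zone, "E")
        w *= class_factor.get(cls, 1.0) * pop_factor.get(pop, 1.0)
        weight_by_pop[pop] = w
    parts = [[], [], [], []]
    for k, spec in enumerate(specs):
        sp = drive.generate_drive_spikes(
            spec, state, config.duration_ms, seed=seed_stim + 17 * k
        )
        ev = drive.drive_to_events(
            sp,
            spec,
            network.neurons,
            models,
            layout.offsets,
            weight_by_pop,
            config.dt,
            seed=seed_stim + 17 * k + 1,
        )
        for i in range(4):
            parts[i].append(ev[i])
    merged = [np.concatenate(p) for p in parts]
    order = np.argsort(merged[0], kind="stable")
    return tuple(m[order] for m in merged)


@dataclass
class RunOutput:
    config: ExperimentConfig
    network: circuit.NetworkInstance
    models: dict
    result: engine.SimResult
    lfp_signal: lfp.LFPSignal
    electrode_depths_um: np.ndarray


def simulate(config: ExperimentConfig, record_currents: bool = False) -> RunOutput:
    """Run one (condition, state) simulation with LFP accumulation."""
    state = drive.StateConfig(state=config.state)
    models = build_models(config.condition, state, config.excitability_reduction)
    network = build_network(config, models)
    events = build_drive_events(config, network, models, state)
    layout = engine.build_layout(network.neurons, models)
    T, depths = lfp.transfer_matrix(
        network.neurons, models, layout, network.geometry
    )
    _, seed_stim, _ = config.seeds()
    sim_cfg = engine.SimConfig(
        duration_ms=config.duration_ms,
        dt=config.dt,
        record_dt=config.record_dt,
        analysis_start_ms=config.analysis_start_ms,
        record_currents=record_currents,
        seed_init=seed_stim + 9999,
    )
    result = engine.run(network, models, events, sim_cfg, transfer=T)
    sig = lfp.LFPSignal(
        t_ms=result.t_record_ms,
        potentials_mv=result.lfp_mv,
        electrode_depths_um=depths,
    )
    return RunOutput(config, network, models, result, sig, depths)


def l5b_electrode_index(run: RunOutput) -> int:
    geo = run.network.geometry
    lo, hi = geo.layers["L5B"]
    mid = 0.5 * (lo + hi) * geo.depth_um
    return int(np.argmin(np.abs(run.electrode_depths_um - mid)))


def analyze(run: RunOutput) -> dict:
    """Standard analysis battery over the post-transient window."""
    cfg = run.config
    window = (cfg.analysis_start_ms, cfg.duration_ms)
    spikes = run.result.spikes
    neurons = run.network.neurons

    rates = spike_analysis.rate_stats(spikes, neurons, window)
    cv = spike_analysis.isi_cv(spikes, neurons, "PT5B", window)
    sch = spike_analysis.spike_count_histogram(spikes, "PT5B", window)
    try:
        duty = spike_analysis.duty_cycle(sch)
        duty_out = {
            "duty_pct": duty.duty_pct,
            "period_freq_hz": duty.mean_period_freq_hz,
        }
    except spike_analysis.FlatHistogramError:
        duty_out = {"duty_pct": float("nan"), "period_freq_hz": float("nan")}

    fs = 1e3 / cfg.record_dt
    ei = l5b_electrode_index(run)
    sel = (run.lfp_signal.t_ms >= window[0]) & (run.lfp_signal.t_ms <= window[1])
    sig = run.lfp_signal.potentials_mv[ei, sel]
    window_s = (window[1] - window[0]) / 1e3
    f_min = max(1.0, np.ceil(2.0 / window_s))
    spec = lfp.spectrogram(
        sig, fs, f_hz=np.arange(f_min, 50.5, 0.5), t_ms=run.lfp_signal.t_ms[sel]
    )
    bp_beta = lfp.band_power(spec, BETA_BAND_HZ)
    bp_low = lfp.band_power(spec, LOW_BETA_BAND_HZ)

    # unitary events on a fixed-size PT5B ensemble: the joint-surprise
    # framework targets small ensembles; pooling hundreds of cells
    # saturates the 1 ms coincidence windows
    pt_ids = neurons.loc[neurons["pop"] == "PT5B", "id"].to_numpy()
    sub = np.random.default_rng(777).choice(
        pt_ids, size=min(20, pt_ids.size), replace=False
    )
    pt_spikes = spikes[spikes["neuron_id"].isin(sub)]
    trains = {
        int(nid): g["spike_time_ms"].to_numpy()
        for nid, g in pt_spikes.groupby("neuron_id")
    }
    for nid in sub:  # silent cells still belong to the ensemble
        trains.setdefault(int(nid), np.array([]))
    ue = synchrony.unitary_events(trains, window)
    return {
        "rates": rates,
        "cv": cv,
        "duty": duty_out,
        "band_power_beta": bp_beta,
        "band_power_low_beta": bp_low,
        "ue": ue,
        "spectrogram": spec,
    }


# ---------------------------------------------------------------------------
# full experiment grid + manifest
# ---------------------------------------------------------------------------


def _write_analysis(outdir: Path, run: RunOutput, ana: dict) -> dict:
    """Write the analysis battery to tidy files; return path map."""
    paths = {}

    def p(name):
        paths[name] = str(outdir / name)
        return outdir / name

    run.result.save_spikes(p("spikes.csv"))
    run.lfp_signal.to_csv(p("lfp.csv"))
    ana["rates"].table.to_csv(p("rates.csv"), index=False)
    cv = ana["cv"]
    pd.DataFrame(
        {"neuron_id": list(cv.per_neuron), "isi_cv": list(cv.per_neuron.values())}
    ).to_csv(p("isi_cv.csv"), index=False)
    ue = ana["ue"]
    ue.windows.to_csv(p("ue_windows.csv"), index=False)
    ue.epochs.to_csv(p("ue_epochs.csv"), index=False)
    spec = ana["spectrogram"]
    np.savez_compressed(
        p("spectrogram.npz"), t_ms=spec.t_ms, f_hz=spec.f_hz, power=spec.power
    )
    summary = {
        "duty_pct": ana["duty"]["duty_pct"],
        "duty_period_freq_hz": ana["duty"]["period_freq_hz"],
        "band_power_beta": ana["band_power_beta"],
        "band_power_low_beta": ana["band_power_low_beta"],
        "pt5b_cv_mean": cv.mean,
        "pt5b_frac_regular": cv.frac_regular,
        "pct_coincident": ue.pct_coincident,
        "pct_significant_time": ue.pct_significant_time,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    paths["summary.json"] = str(outdir / "summary.json")
    return paths


def run_experiment(
    outdir: str | Path,
    base: ExperimentConfig = ExperimentConfig(),
    conditions=("control", "parkinsonian"),
    states=("rest", "activated"),
) -> dict:
    """Run the condition x state grid; write per-run outputs, a manifest
    and a cross-condition comparison table.  Returns the manifest."""
    from dataclasses import replace as _replace

    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": base.seed,
        "seeds": dict(
            zip(("connectivity", "stimulation", "location"), base.seeds())
        ),
        "scale": base.scale,
        "duration_ms": base.duration_ms,
        "runs": {},
    }
    summaries = {}
    for cond in conditions:
        for state in states:
            name = f"{cond}_{state}"
            rundir = outdir / name
            rundir.mkdir(exist_ok=True)
            entry = {"status": "ok", "outputs": {}}
            try:
                cfg = _replace(base, condition=cond, state=state)
                run = simulate(cfg)
                ana = analyze(run)
                entry["outputs"] = _write_analysis(rundir, run, ana)
                summaries[name] = json.loads(
                    (rundir / "summary.json").read_text()
                )
                rates = ana["rates"].table.set_index("population")
                summaries[name]["pt5b_rate_mean"] = float(
                    rates.loc["PT5B", "mean"]
                )
            except Exception as exc:  # stage failure -> marked, not fatal
                entry["status"] = f"failed: {exc}"
            manifest["runs"][name] = entry
    if "control_rest" in summaries and "parkinsonian_rest" in summaries:
        c, p = summaries["control_rest"], summaries["parkinsonian_rest"]
        manifest["comparison"] = {
            "beta_power_ratio_rest": p["band_power_beta"] / c["band_power_beta"],
            "low_beta_power_ratio_rest": p["band_power_low_beta"]
            / c["band_power_low_beta"],
            "pt5b_rate_delta_rest": p["pt5b_rate_mean"] - c["pt5b_rate_mean"],
            "pt5b_cv_delta_rest": p["pt5b_cv_mean"] - c["pt5b_cv_mean"],
            "pct_coincident": {
                k: s["pct_coincident"] for k, s in summaries.items()
            },
            "pct_significant_time": {
                k: s["pct_significant_time"] for k, s in summaries.items()
            },
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def analyze_files(
    spikes_csv: str | Path,
    outdir: str | Path,
    lfp_csv: str | Path | None = None,
    window_ms: tuple[float, float] | None = None,
    record_dt: float = 0.5,
) -> dict:
    """Analysis-only path over externally supplied spike trains (CSV with
    neuron_id, population, spike_time_ms) and optional LFP traces (CSV,
    time_ms + one column per electrode)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spikes = pd.read_csv(spikes_csv)
    if window_ms is None:
        window_ms = (
            float(spikes["spike_time_ms"].min()),
            float(spikes["spike_time_ms"].max()) + 1e-9,
        )
    neurons = (
        spikes[["neuron_id", "population"]]
        .drop_duplicates()
        .rename(columns={"neuron_id": "id", "population": "pop"})
    )
    rates = spike_analysis.rate_stats(spikes, neurons, window_ms)
    rates.table.to_csv(outdir / "rates.csv", index=False)
    out = {"rates": rates}
    pops = neurons["pop"].unique()
    pop = "PT5B" if "PT5B" in pops else pops[0]
    cv = spike_analysis.isi_cv(spikes, neurons, pop, window_ms)
    pd.DataFrame(
        {"neuron_id": list(cv.per_neuron), "isi_cv": list(cv.per_neuron.values())}
    ).to_csv(outdir / "isi_cv.csv", index=False)
    sch = spike_analysis.spike_count_histogram(spikes, pop, window_ms)
    pd.DataFrame(
        {"bin_start_ms": sch.bin_edges_ms[:-1], "count": sch.counts}
    ).to_csv(outdir / "sch.csv", index=False)
    trains = {
        int(nid): g["spike_time_ms"].to_numpy()
        for nid, g in spikes[spikes["population"] == pop].groupby("neuron_id")
    }
    ue = synchrony.unitary_events(trains, window_ms)
    ue.windows.to_csv(outdir / "ue_windows.csv", index=False)
    ue.epochs.to_csv(outdir / "ue_epochs.csv", index=False)
    out.update({"cv": cv, "sch": sch, "ue": ue})
    if lfp_csv is not None:
        df = pd.read_csv(lfp_csv)
        t = df["time_ms"].to_numpy()
        fs = 1e3 / float(np.median(np.diff(t)))
        col = df.columns[1]
        spec = lfp.spectrogram(df[col].to_numpy(), fs, t_ms=t)
        np.savez_compressed(
            outdir / "spectrogram.npz",
            t_ms=spec.t_ms,
            f_hz=spec.f_hz,
            power=spec.power,
        )
        out["spectrogram"] = spec
    return out
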