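"""Cylindrical layered M1 microcircuit: placement, wiring, kinetics.

The modeled volume is a cylinder (default 300 um diameter, 1350 um deep)
spanning layers 2/3 through 6.  Neurons are placed uniformly within
their layer's slab; connection probability between two cells decays
exponentially with 3-D somatic distance (length constant 100 um) from a
per-pair zero-distance probability ``p_con``, and connection strength is
expressed as ``S_con = p_con * v_con`` with ``v_con`` the unitary somatic
PSP amplitude.  A border-correction factor keeps the expected in-degree
independent of a cell's radial position inside the finite cylinder.

Coordinates: depth axis ``z`` positive downward with origin at the pia;
``x``/``y`` horizontal; all distances Euclidean in 3-D.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import CellModel, ConfigurationError

LAMBDA_UM = 100.0
BASE_DELAY_MS = 2.0
PROPAGATION_SPEED_UM_PER_MS = 500.0  # 0.5 m/s

# receptor kinds: (rise tau ms, decay tau ms, reversal mV)
RECEPTORS = {
    "AMPA": (0.05, 5.3, 0.0),
    "NMDA": (15.0, 150.0, 0.0),
    "GABAA_fast": (0.07, 18.2, -80.0),
    "GABAA_slow": (2.0, 100.0, -80.0),
    # GABAB reduced to a slow double-exponential K+ conductance in place
    # of the second-messenger GIRK cascade
    "GABAB": (50.0, 200.0, -95.0),
}
RECEPTOR_INDEX = {name: i for i, name in enumerate(RECEPTORS)}

# synapse kind of an edge -> list of (receptor, weight share)
SYNAPSE_KINDS = {
    "E": [("AMPA", 0.5), ("NMDA", 0.5)],  # colocalized 1:1
    "PV": [("GABAA_fast", 1.0)],
    "SOM_E": [("GABAA_slow", 0.9), ("GABAB", 0.1)],
    "SOM_I": [("GABAA_slow", 1.0)],
}

NMDA_A = 0.28
NMDA_B = 0.062  # 1/mV, [Mg] = 1 mM


def nmda_voltage_factor(v_mv):
    """Magnesium unblock factor 1 / (1 + 0.28 exp(-0.062 V))."""
    return 1.0 / (1.0 + NMDA_A * np.exp(-NMDA_B * np.asarray(v_mv, dtype=float)))


def compute_delay(distance_um):
    """Conduction delay: 2 ms plus distance at 0.5 m/s (= 500 um/ms)."""
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return BASE_DELAY_MS + d / PROPAGATION_SPEED_UM_PER_MS


@dataclass(frozen=True)
class Geometry:
    diameter_um: float = 300.0
    depth_um: float = 1350.0
    # normalized depth fractions; L1 contains no somata
    layers: dict = field(
        default_factory=lambda: {
            "L1": (0.0, 0.1),
            "L2/3": (0.1, 0.29),
            "L4": (0.29, 0.37),
            "L5A": (0.37, 0.47),
            "L5B": (0.47, 0.8),
            "L6": (0.8, 1.0),
        }
    )

    def __post_init__(self):
        if self.diameter_um <= 0:
            raise ConfigurationError("diameter must be > 0")
        bounds = sorted(self.layers.values())
        for (a0, a1), (b0, b1) in zip(bounds, bounds[1:]):
            if a1 > b0 + 1e-12:
                raise ConfigurationError("layer boundaries overlap")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    def layer_depth_um(self, layer: str) -> tuple[float, float]:
        """Depth range in um of a layer label; 'L4+L5A' style unions allowed."""
        parts = layer.split("+")
        lo = min(self.layers[p][0] for p in parts)
        hi = max(self.layers[p][1] for p in parts)
        return lo * self.depth_um, hi * self.depth_um


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    cell_class: str  # PT5B | IT | CT | PV | SOM
    layer: str  # e.g. "L5B" or "L4+L5A"
    full_count: int  # count at scale = 1

    def __post_init__(self):
        if self.full_count < 0:
            raise ConfigurationError("population count must be >= 0")
        if self.cell_class == "PT5B" and self.layer != "L5B":
            raise ConfigurationError("PT5B is confined to L5B")
        if self.cell_class == "CT" and self.layer != "L6":
            raise ConfigurationError("CT is confined to L6")


@dataclass(frozen=True)
class ConnectionRule:
    pre: str
    post: str
    p_con: float  # zero-distance connection probability
    v_con_mv: float  # unitary somatic PSP amplitude (mV, magnitude)
    kind: str  # E | PV | SOM_E | SOM_I
    lambda_um: float = LAMBDA_UM
    nsyn: int = 1

    def __post_init__(self):
        if not 0.0 <= self.p_con <= 1.0:
            raise ConfigurationError("p_con must be in [0, 1]")
        if self.lambda_um <= 0:
            raise ConfigurationError("lambda must be > 0")
        if self.nsyn not in (1, 5):
            raise ConfigurationError("synapses per connection must be 1 or 5")
        if self.kind not in SYNAPSE_KINDS:
            raise ConfigurationError(f"unknown synapse kind {self.kind!r}")

    @property
    def s_con(self) -> float:
        return self.p_con * self.v_con_mv


def connection_probability(
    rule: ConnectionRule, distance_um, correction: float = 1.0
) -> np.ndarray:
    """Distance kernel p_con * exp(-d / lambda), border-corrected, clipped."""
    d = np.asarray(distance_um, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    return np.clip(rule.p_con * np.exp(-d / rule.lambda_um) * correction, 0.0, 1.0)


def default_populations() -> list[PopulationSpec]:
    cfg = json.loads(
        (resources.files("m1beta") / "data" / "network.json").read_text()
    )
    return [PopulationSpec(**p) for p in cfg["populations"]]


def default_rules() -> list[ConnectionRule]:
    cfg = json.loads(
        (resources.files("m1beta") / "data" / "network.json").read_text()
    )
    return [ConnectionRule(**r) for r in cfg["rules"]]


def place_neurons(
    geometry: Geometry,
    pops: list[PopulationSpec],
    scale: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Place neurons uniformly in each population's annular layer slab.

    Returns a table with columns id, pop, cell_class, x, y, z (um).
    Counts are round(scale * full_count), at least 1 per population.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    next_id = 0
    for pop in pops:
        n = int(round(scale * pop.full_count))
        if n == 0:
            warnings.warn(f"scale {scale} empties population {pop.name}; keeping 1")
            n = 1
        z0, z1 = geometry.layer_depth_um(pop.layer)
        r = geometry.radius_um * np.sqrt(rng.random(n))
        th = 2 * np.pi * rng.random(n)
        z = rng.uniform(z0, z1, n)
        for i in range(n):
            rows.append(
                (
                    next_id,
                    pop.name,
                    pop.cell_class,
                    r[i] * np.cos(th[i]),
                    r[i] * np.sin(th[i]),
                    z[i],
                )
            )
            next_id += 1
    return pd.DataFrame(rows, columns=["id", "pop", "cell_class", "x", "y", "z"])


def _synapse_target_compartments(
    kind: str, post_model: CellModel, n: int, rng
) -> np.ndarray:
    """Dendritic placement: PV->E perisomatic (<=50 um path), SOM->E apical,
    any->PV/SOM dendrite, E->E uniform over dendritic length."""
    zones = np.array([c.zone for c in post_model.compartments])
    if post_model.cell_class in ("PV", "SOM"):
        cand = np.where(zones == "dend")[0]
        return rng.choice(cand, n)
    if kind == "PV":
        path = post_model.path_distance_to_soma()
        cand = np.where((path <= 50.0) & (zones != "axon"))[0]
        return rng.choice(cand, n)
    if kind in ("SOM_E", "SOM_I"):
        cand = np.where(zones == "apical")[0]
        return rng.choice(cand, n)
    # excitatory onto pyramidal: uniform over dendritic length
    cand = np.where((zones == "basal") | (zones == "apical"))[0]
    lengths = np.array([post_model.compartments[i].length_um for i in cand])
    return rng.choice(cand, n, p=lengths / lengths.sum())


def build_edges(
    neurons: pd.DataFrame,
    rules: list[ConnectionRule],
    cell_models: dict[str, CellModel],
    seed: int = 0,
    scale: float = 1.0,
    border_correction: bool = True,
    unitary_weight=None,
) -> pd.DataFrame:
    """Draw the synaptic edge list.

    For every rule, each ordered (pre, post) pair connects with
    probability ``p_con exp(-d/lambda) * c(post) / scale`` (clipped to 1),
    where the border factor ``c`` is the ratio of the distance-kernel mass
    seen by a cell on the cylinder axis at the post cell's depth to the
    mass seen at the cell's actual position, evaluated against the
    realized presynaptic ensemble.  Dividing the probability by ``scale``
    preserves the expected in-degree of the full-density circuit.

    ``unitary_weight(rule, zone) -> uS`` converts the rule's v_con into a
    peak-conductance weight; if omitted, weights are left as v_con (mV).
    """
    pops = set(neurons["pop"])
    for rule in rules:
        if rule.pre not in pops or rule.post not in pops:
            raise ConfigurationError(
                f"rule references unknown population {rule.pre}->{rule.post}"
            )
    rng = np.random.default_rng(seed)
    xyz = neurons[["x", "y", "z"]].to_numpy()
    ids = neurons["id"].to_numpy()
    by_pop = {p: np.where((neurons["pop"] == p).to_numpy())[0] for p in pops}
    cls_of_pop = dict(zip(neurons["pop"], neurons["cell_class"]))

    out = {
        "pre": [],
        "post": [],
        "comp": [],
        "weight": [],
        "delay_ms": [],
        "receptor": [],
        "nsyn": [],
    }
    for rule in rules:
        pre_idx = by_pop[rule.pre]
        post_idx = by_pop[rule.post]
        if pre_idx.size == 0 or post_idx.size == 0:
            continue
        pre_xyz = xyz[pre_idx]
        post_xyz = xyz[post_idx]
        d = np.sqrt(
            ((post_xyz[:, None, :] - pre_xyz[None, :, :]) ** 2).sum(axis=2)
        )  # (npost, npre)
        kern = np.exp(-d / rule.lambda_um)
        self_mask = post_idx[:, None] == pre_idx[None, :]
        kern[self_mask] = 0.0
        if border_correction:
            axis_xyz = post_xyz.copy()
            axis_xyz[:, 0] = 0.0
            axis_xyz[:, 1] = 0.0
            d_axis = np.sqrt(
                ((axis_xyz[:, None, :] - pre_xyz[None, :, :]) ** 2).sum(axis=2)
            )
            mass_axis = np.exp(-d_axis / rule.lambda_um).sum(axis=1)
            mass_here = kern.sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                corr = np.where(mass_here > 0, mass_axis / mass_here, 1.0)
        else:
            corr = np.ones(post_idx.size)
        p = np.clip(rule.p_con * kern * corr[:, None] / scale, 0.0, 1.0)
        p[self_mask] = 0.0
        draw = rng.random(p.shape) < p
        post_i, pre_i = np.nonzero(draw)
        n_edges = post_i.size
        if n_edges == 0:
            continue
        dist = d[post_i, pre_i]
        post_model = cell_models[cls_of_pop[rule.post]]
        comps = _synapse_target_compartments(rule.kind, post_model, n_edges, rng)
        if unitary_weight is None:
            w = np.full(n_edges, rule.v_con_mv)
        else:
            uw = {
                z: unitary_weight(rule, post_model.compartments[z].zone)
                for z in np.unique(comps)
            }
            w = np.array([uw[z] for z in comps])
        out["pre"].append(ids[pre_idx[pre_i]])
        out["post"].append(ids[post_idx[post_i]])
        out["comp"].append(comps)
        out["weight"].append(w)
        out["delay_ms"].append(compute_delay(dist))
        out["receptor"].append(np.full(n_edges, rule.kind, dtype=object))
        out["nsyn"].append(np.full(n_edges, rule.nsyn))
    if not out["pre"]:
        return pd.DataFrame(
            columns=["pre", "post", "comp", "weight", "delay_ms", "receptor", "nsyn"]
        )
    return pd.DataFrame({k: np.concatenate(v) for k, v in out.items()})


@dataclass
class NetworkInstance:
    neurons: pd.DataFrame
    edges: pd.DataFrame
    geometry: Geometry
    scale: float
    seed: int

    def __post_init__(self):
        r = np.sqrt(self.neurons["x"] ** 2 + self.neurons["y"] ** 2)
        if np.any(r > self.geometry.radius_um + 1e-9):
            raise ConfigurationError("neuron outside cylinder")
        if len(self.edges):
            if np.any(self.edges["delay_ms"] < BASE_DELAY_MS - 1e-12):
                raise ConfigurationError("delay below base delay")
            if np.any(self.edges["pre"].to_numpy() == self.edges["post"].to_numpy()):
                raise ConfigurationError("self edge present")

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.neurons.to_csv(outdir / "neurons.csv", index=False)
        self.edges.to_csv(outdir / "edges.csv", index=False)
        hdr = {
            "diameter_um": self.geometry.diameter_um,
            "depth_um": self.geometry.depth_um,
            "layers": {k: list(v) for k, v in self.geometry.layers.items()},
            "scale": self.scale,
            "seed": self.seed,
        }
        (outdir / "network.json").write_text(json.dumps(hdr, indent=1))

    @staticmethod
    def load(outdir: str | Path) -> "NetworkInstance":
        outdir = Path(outdir)
        hdr = json.loads((outdir / "network.json").read_text())
        geo = Geometry(
            diameter_um=hdr["diameter_um"],
            depth_um=hdr["depth_um"],
            layers={k: tuple(v) for k, v in hdr["layers"].items()},
        )
        return NetworkInstance(
            neurons=pd.read_csv(outdir / "neurons.csv"),
            edges=pd.read_csv(outdir / "edges.csv"),
            geometry=geo,
            scale=hdr["scale"],
            seed=hdr["seed"],
        )
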