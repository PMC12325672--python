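"""Voltage-gated channel kinetics and lookup tables.

All cell classes share a compact Hodgkin-Huxley channel repertoire:

* ``NaT``  -- transient sodium (activation ``m``, inactivation ``h``)
* ``Kdr``  -- delayed-rectifier potassium (activation ``n``)
* ``BK``   -- large-conductance Ca-activated potassium, reduced here to a
  fast high-threshold voltage-dependent gate ``b`` (no explicit calcium
  pool); its small resting window current hyperpolarizes the cell when the
  maximal conductance is raised, and it speeds spike repolarization.
* ``Ih``   -- hyperpolarization-activated cation current (gate ``q``).
* passive leak.

NaT/Kdr rate functions follow the standard cortical formulation of
Pospischil et al. (2008), parameterized by a per-class spike-threshold
shift ``vt`` (mV).  Gate dynamics are integrated with the exact
exponential update ``x <- xinf + (x - xinf) * exp(-dt/tau)``; to keep the
inner loops cheap, ``xinf`` and the per-step decay factor are tabulated
on a fixed voltage grid and linearly interpolated.
"""

from __future__ import annotations

import numpy as np

# Voltage grid for kinetics tables (mV)
V_MIN = -120.0
V_MAX = 60.0
DV = 0.05

# Reversal potentials (mV), shared across classes
E_NA = 50.0
E_K = -90.0
E_H = -30.0

GATE_NAMES = ("m", "h", "n", "b", "q")


def _vtrap(x: np.ndarray, y: float) -> np.ndarray:
    """x / (exp(x/y) - 1) with the removable singularity at x=0 patched."""
    out = np.empty_like(x)
    small = np.abs(x / y) < 1e-6
    out[small] = y * (1.0 - x[small] / y / 2.0)
    xs = x[~small]
    out[~small] = xs / (np.expm1(xs / y))
    return out


def na_rates(v: np.ndarray, vt: float):
    u = v - vt
    am = 0.32 * _vtrap(-(u - 13.0), 4.0)
    bm = 0.28 * _vtrap(u - 40.0, 5.0)
    ah = 0.128 * np.exp(-(u - 17.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(u - 40.0) / 5.0))
    return am, bm, ah, bh


def kdr_rates(v: np.ndarray, vt: float):
    u = v - vt
    an = 0.032 * _vtrap(-(u - 15.0), 5.0)
    bn = 0.5 * np.exp(-(u - 10.0) / 40.0)
    return an, bn


def bk_gate(v: np.ndarray):
    """Steady state and time constant of the reduced BK gate.

    The ~15 ms time constant makes this conductance accumulate over
    successive spikes, so it carries both the medium AHP (graded f-I
    onset, spike-frequency adaptation) and, through its small resting
    window current, the hyperpolarization seen when its density is
    raised.
    """
    binf = 1.0 / (1.0 + np.exp(-(v + 30.0) / 7.0))
    btau = np.full_like(v, 15.0)
    return binf, btau


def ih_gate(v: np.ndarray):
    qinf = 1.0 / (1.0 + np.exp((v + 82.0) / 7.0))
    qtau = np.full_like(v, 50.0)  # ms; slow HCN kinetics
    return qinf, qtau


def build_tables(dt: float, vt: float) -> np.ndarray:
    """Tabulate gate steady states and exponential decay factors.

    Returns an array of shape (10, nv): for each gate g in (m, h, n, b, q)
    rows (2g, 2g+1) hold ``xinf(V)`` and ``exp(-dt/tau_x(V))`` on the grid
    ``V_MIN + DV * arange(nv)``.
    """
    v = np.arange(V_MIN, V_MAX + DV / 2, DV)
    am, bm, ah, bh = na_rates(v, vt)
    an, bn = kdr_rates(v, vt)
    binf, btau = bk_gate(v)
    qinf, qtau = ih_gate(v)

    rows = []
    for a, b in ((am, bm), (ah, bh), (an, bn)):
        tau = 1.0 / (a + b)
        rows.append(a * tau)
        rows.append(np.exp(-dt / tau))
    for xinf, xtau in ((binf, btau), (qinf, qtau)):
        rows.append(xinf)
        rows.append(np.exp(-dt / xtau))
    return np.ascontiguousarray(np.vstack(rows))
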