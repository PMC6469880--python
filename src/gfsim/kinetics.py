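"""HH-type gating kinetics: rate evaluation, exponential gate updates,
and the membrane current-density function.

All gates are first-order: dx/dt = (x_inf(V) - x) / tau(V).  At a fixed
voltage the exact solution x(t) = x_inf + (x0 - x_inf) exp(-t/tau) is used as
the update rule (exponential integrator), so the gate update carries no
time-discretization error of its own.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .params import (KIN_H, KIN_M, KIN_MEXP, KIN_N, KIN_NEXP, KIN_P,
                     KineticsParams, MembraneParams)

__all__ = ["gate_rates", "advance_gates", "membrane_current", "GateState"]


@njit(cache=True)
def _rates(kp: np.ndarray, off: int, v: float):
    """(steady state, tau) of the gate whose block starts at ``off``."""
    sign = kp[off + 6]  # +1 activation, -1 inactivation
    xinf = 1.0 / (1.0 + math.exp(sign * (kp[off] - v) / kp[off + 1]))
    z = (v - kp[off + 4]) / kp[off + 5]
    tau = kp[off + 2] + kp[off + 3] * math.exp(-z * z)
    return xinf, tau


_GATE_OFFSETS = {
    ("nat", "m"): KIN_M,
    ("nat", "h"): KIN_H,
    ("nap", "p"): KIN_P,
    ("k", "n"): KIN_N,
}


def gate_rates(channel: str, gate: str, v: float,
               kinetics: KineticsParams | None = None) -> tuple[float, float]:
    """Steady state (dimensionless) and time constant (ms) at voltage ``v``.

    Parameters
    ----------
    channel : {"nat", "nap", "k"}
        Transient Na, persistent Na, or delayed-rectifier K.
    gate : {"m", "h", "p", "n"}
        Activation (m/p/n) or inactivation (h) variable of that channel.
    v : float
        Membrane potential, mV.
    """
    if not np.isfinite(v):
        raise ValueError("voltage must be finite")
    try:
        off = _GATE_OFFSETS[(channel, gate)]
    except KeyError:
        raise KeyError(f"unknown channel/gate pair {channel!r}/{gate!r}") from None
    kp = (kinetics or KineticsParams()).to_array()
    return _rates(kp, off, float(v))


class GateState:
    """Per-compartment gating variables (arrays of equal length, in [0, 1])."""

    __slots__ = ("m", "h", "p", "n")

    def __init__(self, m, h, p, n):
        self.m = np.asarray(m, dtype=np.float64)
        self.h = np.asarray(h, dtype=np.float64)
        self.p = np.asarray(p, dtype=np.float64)
        self.n = np.asarray(n, dtype=np.float64)
        for a in (self.h, self.p, self.n):
            if a.shape != self.m.shape:
                raise ValueError("gate arrays must share one shape")

    @classmethod
    def steady_state(cls, v, kinetics: KineticsParams | None = None) -> "GateState":
        """All gates at their fixed point for voltage(s) ``v``."""
        kp = (kinetics or KineticsParams()).to_array()
        v = np.atleast_1d(np.asarray(v, dtype=np.float64))
        out = []
        for off in (KIN_M, KIN_H, KIN_P, KIN_N):
            out.append(np.array([_rates(kp, off, float(vi))[0] for vi in v]))
        return cls(*out)

    def copy(self) -> "GateState":
        return GateState(self.m.copy(), self.h.copy(), self.p.copy(), self.n.copy())


def advance_gates(gates: GateState, v, dt: float,
                  kinetics: KineticsParams | None = None) -> GateState:
    """Advance all gates one step of ``dt`` ms at (fixed) voltage ``v``.

    Exact exponential update; values stay in [0, 1] for any dt > 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    kp = (kinetics or KineticsParams()).to_array()
    v = np.broadcast_to(np.asarray(v, dtype=np.float64), gates.m.shape)
    new = gates.copy()
    for arr, off in ((new.m, KIN_M), (new.h, KIN_H), (new.p, KIN_P), (new.n, KIN_N)):
        for i, vi in enumerate(v.ravel()):
            xinf, tau = _rates(kp, off, float(vi))
            arr.flat[i] = xinf + (arr.flat[i] - xinf) * math.exp(-dt / tau)
    return new


def membrane_current(v, gates: GateState, params: MembraneParams | None = None,
                     kinetics: KineticsParams | None = None):
    """Total membrane current density, mA/cm^2, positive outward.

    I = g_leak (V - E_leak) + gbar_Nat m^3 h (V - E_Na)
        + gbar_Nap p (V - E_Na) + gbar_K n^4 (V - E_K)

    Densities are mS/cm^2 and voltages mV, so mS/cm^2 * mV = uA/cm^2; the
    result is scaled to mA/cm^2.
    """
    params = params or MembraneParams()
    kin = kinetics or KineticsParams()
    v = np.asarray(v, dtype=np.float64)
    a, c = kin.nat_m_exp, kin.k_n_exp
    i_ua = (params.g_leak * (v - params.e_leak)
            + params.gbar_nat * gates.m ** a * gates.h * (v - params.e_na)
            + params.gbar_nap * gates.p * (v - params.e_na)
            + params.gbar_k * gates.n ** c * (v - params.e_k))
    return i_ua * 1e-3
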