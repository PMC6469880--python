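"""Default physiological parameters and unit conventions.

Internal unit system
--------------------
==================  =========  =============================================
quantity            unit       notes
==================  =========  =============================================
voltage             mV
time                ms
length, diameter    um
membrane area       cm^2
axial resistivity   Ohm*cm     specific (per unit cross-section)
capacitance (spec)  uF/cm^2
capacitance (comp)  pF         uF/cm^2 * cm^2 * 1e6
conductance (dens)  mS/cm^2
conductance (point) nS         gap junctions, chemical synapses, per-
                               compartment lumped channel conductances
current (point)     pA         nS * mV = pA;  pF * mV/ms = pA
current (density)   mA/cm^2
stimulus amplitude  nA         converted to pA (x1000) at injection
==================  =========  =============================================

The consistent triplet (pF, nS, pA) on the (mV, ms) timebase means no unit
constants appear inside the integrator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# unit conversion factors
UF_PER_CM2_TO_PF = 1.0e6       # uF -> pF for an area given in cm^2
MS_PER_CM2_TO_NS = 1.0e6       # mS -> nS for an area given in cm^2
NA_TO_PA = 1.0e3
UM2_TO_CM2 = 1.0e-8

#: fixed neuromuscular-junction delay added to motoneuron AP-peak latencies (ms)
NMJ_DELAY_MS = 0.35


@dataclass
class MembraneParams:
    """Channel densities (mS/cm^2) and reversal potentials (mV).

    Densities apply uniformly to every *active* section (all axons carry the
    same transient Na, persistent Na and delayed-rectifier K densities);
    passive sections carry the leak only.
    """

    gbar_nat: float = 300.0    # transient Na, mS/cm^2
    gbar_nap: float = 0.11     # persistent Na, mS/cm^2
    gbar_k: float = 10.0       # delayed-rectifier K, mS/cm^2
    g_leak: float = 0.03       # ohmic leak, mS/cm^2
    e_na: float = 65.0         # mV
    e_k: float = -74.0         # mV
    e_leak: float = -85.0      # mV

    def validate(self) -> None:
        for name in ("gbar_nat", "gbar_nap", "gbar_k", "g_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MembraneParams":
        return cls(**d)


@dataclass
class GateKinetics:
    """One first-order gate: sigmoid steady state, bell-shaped time constant.

    steady state : x_inf(V) = 1 / (1 + exp(sign * (vhalf - V) / slope))
                   with sign = +1 for activation, -1 for inactivation
    time constant: tau(V) = tau_min + tau_amp * exp(-((V - tau_vhalf)/tau_sigma)^2)
    """

    vhalf: float          # mV, half-(in)activation
    slope: float          # mV, sigmoid slope factor (> 0)
    tau_min: float        # ms, floor of the time constant
    tau_amp: float        # ms, bell amplitude above the floor
    tau_vhalf: float      # mV, bell center
    tau_sigma: float      # mV, bell width
    inactivation: bool = False


@dataclass
class KineticsParams:
    """HH-type gating scheme for the three axonal channels.

    Transient Na opens as m^3*h, persistent Na as p, delayed-rectifier K as
    n^4.  The scheme follows the convention of published *Drosophila*
    motoneuron models; the numeric defaults were calibrated (see
    ``protocols.calibrate`` and docs/methods.md) so that the default circuit
    reproduces the recorded young- and old-fly escape latencies.
    """

    nat_m: GateKinetics = field(default_factory=lambda: GateKinetics(
        vhalf=-26.60789959129344, slope=3.0281064702047313,
        tau_min=0.08329424613820105, tau_amp=0.5860541232344363,
        tau_vhalf=-35.0, tau_sigma=25.0))
    nat_h: GateKinetics = field(default_factory=lambda: GateKinetics(
        vhalf=-49.781124003681896, slope=3.001426439118955,
        tau_min=0.5265701350973422, tau_amp=2.9757165754490735,
        tau_vhalf=-52.0, tau_sigma=20.0, inactivation=True))
    nap_p: GateKinetics = field(default_factory=lambda: GateKinetics(
        vhalf=-61.65349294644173, slope=4.181425288242798,
        tau_min=1.0, tau_amp=0.0, tau_vhalf=-50.0, tau_sigma=20.0))
    k_n: GateKinetics = field(default_factory=lambda: GateKinetics(
        vhalf=-64.29208219869139, slope=8.605043182061266,
        tau_min=0.906149959480532, tau_amp=1.8,
        tau_vhalf=-50.0, tau_sigma=30.0))
    nat_m_exp: int = 3
    k_n_exp: int = 4

    def to_array(self) -> np.ndarray:
        """Pack into the flat layout consumed by the integrator kernel."""
        out = []
        for g in (self.nat_m, self.nat_h, self.nap_p, self.k_n):
            out += [g.vhalf, g.slope, g.tau_min, g.tau_amp, g.tau_vhalf,
                    g.tau_sigma, -1.0 if g.inactivation else 1.0]
        out += [float(self.nat_m_exp), float(self.k_n_exp)]
        return np.asarray(out, dtype=np.float64)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "KineticsParams":
        kw = {}
        for key in ("nat_m", "nat_h", "nap_p", "k_n"):
            if key in d:
                kw[key] = GateKinetics(**d[key])
        for key in ("nat_m_exp", "k_n_exp"):
            if key in d:
                kw[key] = int(d[key])
        return cls(**kw)


# offsets into the flat kinetics array: 7 slots per gate (m, h, p, n)
KIN_M, KIN_H, KIN_P, KIN_N = 0, 7, 14, 21
KIN_MEXP, KIN_NEXP = 28, 29
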