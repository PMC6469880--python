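"""Rectifying electrical synapses and the delayed double-exponential
chemical synapse, plus presynaptic spike detection.

The giant-fiber circuit's gap junctions are rectifying (unidirectional):
the postsynaptic compartment receives ohmic current g_gap*(V_pre - V_post)
while the presynaptic cell is completely unaffected by the postsynaptic
side.  Point conductances are expressed in nS (see docs/methods.md for the
unit reading of the published parameter table).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

Site = tuple[str, str, float]   # (cell, section, normalized position)

G_GAP_YOUNG_NS = 135.0
G_GAP_OLD_NS = 34.5


@dataclass
class ElectricalSynapseSpec:
    """One rectifying gap junction: post feels pre, pre feels nothing."""

    pre_site: Site
    post_site: Site
    g_gap: float = G_GAP_YOUNG_NS    # nS

    def __post_init__(self):
        if self.g_gap < 0:
            raise ValueError("g_gap must be non-negative")
        if self.pre_site[0] == self.post_site[0]:
            raise ValueError("electrical synapse must couple two different cells")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["type"] = "electrical"
        return d


@dataclass
class ChemicalSynapseSpec:
    """Delayed double-exponential conductance synapse.

    Triggered by an upward threshold crossing of the presynaptic voltage;
    after ``delay`` the conductance follows
    g(t) = g_peak * N * (exp(-t/tau_decay) - exp(-t/tau_rise)), with N
    normalizing the peak to exactly ``g_peak``.  Events superpose linearly.
    """

    pre_site: Site
    post_site: Site
    tau_rise: float = 0.1       # ms
    tau_decay: float = 1.0      # ms
    e_rev: float = 0.0          # mV
    delay: float = 0.15         # ms
    g_peak: float = 80.0        # nS
    spike_threshold: float = -20.0   # mV, upward crossing on the pre trace

    def __post_init__(self):
        if not 0 < self.tau_rise < self.tau_decay:
            raise ValueError("need 0 < tau_rise < tau_decay")
        if self.delay < 0 or self.g_peak < 0:
            raise ValueError("delay and g_peak must be non-negative")

    @property
    def t_peak(self) -> float:
        """Time of the conductance maximum after activation (ms)."""
        tr, td = self.tau_rise, self.tau_decay
        return tr * td / (td - tr) * math.log(td / tr)

    @property
    def norm_factor(self) -> float:
        """N such that max_t N*(exp(-t/td) - exp(-t/tr)) = 1."""
        tp = self.t_peak
        return 1.0 / (math.exp(-tp / self.tau_decay) - math.exp(-tp / self.tau_rise))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["type"] = "chemical"
        return d


def gap_current(v_pre: float, v_post: float, g_gap: float) -> tuple[float, float]:
    """Currents (pA) injected by one rectifying gap junction.

    Returns ``(i_pre, i_post)``; i_pre is always 0 (unidirectional coupling)
    and i_post = g_gap * (v_pre - v_post), positive depolarizing the
    postsynaptic compartment.
    """
    return 0.0, g_gap * (v_pre - v_post)


def chem_conductance(t_since_event, spec: ChemicalSynapseSpec):
    """Synaptic conductance (nS) at time(s) since activation (post-delay).

    Zero for negative times; peaks at exactly ``spec.g_peak`` at
    ``spec.t_peak``.
    """
    t = np.asarray(t_since_event, dtype=np.float64)
    g = spec.g_peak * spec.norm_factor * (
        np.exp(-t / spec.tau_decay) - np.exp(-t / spec.tau_rise))
    g = np.where(t >= 0.0, g, 0.0)
    return float(g) if np.isscalar(t_since_event) else g


def detect_presynaptic_spike(times, values, threshold: float) -> np.ndarray:
    """Upward threshold-crossing times of a uniformly sampled trace.

    One event per crossing, with a refractory lockout until the trace falls
    back below the threshold; crossing times are linearly interpolated
    between samples.  A trace starting at/above threshold does not fire
    until it first drops below.
    """
    times = np.asarray(times, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if times.shape != values.shape:
        raise ValueError("times and values must have the same shape")
    events = []
    above = bool(values[0] >= threshold)
    for i in range(1, len(values)):
        if not above and values[i] >= threshold:
            v0, v1 = values[i - 1], values[i]
            frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 1.0
            events.append(times[i - 1] + frac * (times[i] - times[i - 1]))
            above = True
        elif above and values[i] < threshold:
            above = False
    return np.asarray(events, dtype=np.float64)
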