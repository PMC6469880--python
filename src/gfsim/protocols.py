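"""Stimulation protocols and latency extraction.

The escape-response latency is measured as the time from stimulus onset to
the motoneuron action-potential peak, plus a fixed 0.35 ms neuromuscular-
junction delay (the muscle itself is not simulated; the delay is a constant
additive bias).  The head stimulus approximating high-amplitude brain
stimulation of the GF is a 120 nA, 0.03 ms current step at the GF proximal
end; thoracic stimulation is modeled as direct TTMn current injection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec
from .engine import SimConfig, Simulation, StimulusSpec, Trace
from .params import NMJ_DELAY_MS

HEAD_STIMULUS = StimulusSpec(site=("GF", "axon", 0.0), amplitude=120.0,
                             duration=0.03, onset=0.0)

#: AP definition: the first voltage excursion whose peak exceeds 0 mV
AP_PEAK_THRESHOLD_MV = 0.0


@dataclass
class LatencyResult:
    """Stimulus-onset-to-AP-peak time for one readout cell."""

    cell: str
    t_ap_peak: float          # ms from stimulus onset; NaN if no spike
    nmj_delay: float = NMJ_DELAY_MS
    spike_found: bool = True
    peak_v: float = float("nan")    # mV at the AP peak

    @property
    def latency_total(self) -> float:
        """t_ap_peak + NMJ delay (ms); NaN when no spike was found."""
        if not self.spike_found:
            return float("nan")
        return self.t_ap_peak + self.nmj_delay

    def to_dict(self) -> dict:
        return {"cell": self.cell, "t_ap_peak_ms": self.t_ap_peak,
                "nmj_delay_ms": self.nmj_delay,
                "latency_total_ms": self.latency_total,
                "spike_found": self.spike_found}


def _refine_peak(t: np.ndarray, v: np.ndarray, i: int) -> tuple[float, float]:
    """Quadratic (three-point) refinement of a sampled maximum."""
    if i == 0 or i == len(v) - 1:
        return float(t[i]), float(v[i])
    y0, y1, y2 = v[i - 1], v[i], v[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0.0:
        return float(t[i]), float(v[i])
    off = 0.5 * (y0 - y2) / denom
    dt = t[1] - t[0]
    return float(t[i] + off * dt), float(y1 - 0.25 * (y0 - y2) * off)


def measure_latency(trace: Trace, readout_cell: str, stimulus_onset: float = 0.0,
                    nmj_delay: float = NMJ_DELAY_MS,
                    section: str | None = None) -> LatencyResult:
    """Latency to the AP peak of the first suprathreshold excursion.

    The AP peak is the global maximum of the first contiguous excursion of
    the recorded voltage above 0 mV; sub-zero depolarizations never count
    as spikes.  The peak time is refined by quadratic interpolation of the
    three samples around the discrete maximum.  When no excursion crosses
    0 mV the result carries ``spike_found=False`` and NaN latency (scans
    must tolerate propagation failures).
    """
    v = trace[readout_cell] if section is None else \
        trace.values[:, trace.site_index(readout_cell, section)]
    above = v > AP_PEAK_THRESHOLD_MV
    if not above.any():
        return LatencyResult(readout_cell, float("nan"), nmj_delay,
                             spike_found=False)
    start = int(np.argmax(above))
    rest = np.nonzero(~above[start:])[0]
    end = start + (int(rest[0]) if rest.size else above.size - start)
    i = start + int(np.argmax(v[start:end]))
    t_peak, v_peak = _refine_peak(trace.times, v, i)
    return LatencyResult(readout_cell, t_peak - stimulus_onset, nmj_delay,
                         spike_found=True, peak_v=v_peak)


def run_head_stimulation(circuit: CircuitSpec,
                         sim_config: SimConfig | None = None,
                         stimulus: StimulusSpec = HEAD_STIMULUS,
                         ) -> dict[str, LatencyResult]:
    """Head stimulus at the GF proximal end; TTM and DLM branch latencies.

    Returns ``{"TTM": ..., "DLM": ...}`` with total latencies including the
    NMJ delay; the underlying trace is attached as ``result["trace"]`` for
    plotting/inspection (keys "TTM"/"DLM" are the muscle readouts of the
    TTMn/DLMn motoneuron AP peaks).
    """
    sim = Simulation(circuit, sim_config)
    trace = sim.run([stimulus])
    out = {
        "TTM": measure_latency(trace, "TTMn", stimulus.onset),
        "DLM": measure_latency(trace, "DLMn", stimulus.onset),
    }
    out["TTM"].cell, out["DLM"].cell = "TTM", "DLM"
    out["trace"] = trace
    return out


def run_thoracic_stimulation(circuit: CircuitSpec,
                             sim_config: SimConfig | None = None,
                             amplitude: float | None = None,
                             duration: float = 0.03,
                             ) -> LatencyResult:
    """Direct TTMn stimulation (thoracic protocol), no NMJ delay added.

    With ``amplitude=None`` the pulse amplitude is auto-escalated by
    doubling from 10 nA until the TTMn fires (first suprathreshold value);
    the amplitude used is reported in ``result.amplitude_nA``.
    """
    site = ("TTMn", "medial_dendrite", 0.0)
    cfg = sim_config or SimConfig(t_stop=3.0)
    amps = [float(amplitude)] if amplitude is not None else \
        [10.0 * 2 ** k for k in range(12)]
    res = LatencyResult("TTMn", float("nan"), nmj_delay=0.0, spike_found=False)
    sim = Simulation(circuit, cfg)
    sim.equilibrate()
    rest = sim.snapshot()
    for amp in amps:
        stim = StimulusSpec(site=site, amplitude=amp, duration=duration)
        sim.restore(rest)
        trace = sim.run([stim], record_sites=[("TTMn", "axon", 1.0)])
        res = measure_latency(trace, "TTMn", stim.onset, nmj_delay=0.0)
        if res.spike_found:
            break
    res.amplitude_nA = amp
    return res
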