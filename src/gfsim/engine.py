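"""Assembly of a circuit into flat solver arrays and implicit time stepping.

Scheme
------
Backward Euler (default dt = 0.0025 ms) on the voltage system.  Within each
cell the tree of compartments is solved exactly per step by Hines-ordered
elimination (parents precede children in the global ordering, so a single
upward elimination + downward substitution pass solves all cells at once;
cells occupy independent blocks).  Gating variables advance by their exact
exponential update at the pre-step voltage (staggered update).

Inter-cell coupling is explicit in the *presynaptic* voltage only: the
postsynaptic conductance of every gap junction and chemical synapse is
folded into the post cell's implicit diagonal, while the driving presynaptic
voltage is taken from the previous step.  This keeps each cell's matrix
tree-structured and remains stable for arbitrarily large point conductances;
the lag error is first-order in dt and checked by the convergence tests.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .cable import discretize
from .circuit import CircuitSpec
from .kinetics import _rates
from .params import (KIN_H, KIN_M, KIN_MEXP, KIN_N, KIN_NEXP, KIN_P,
                     MS_PER_CM2_TO_NS, NA_TO_PA, UF_PER_CM2_TO_PF)
from .synapses import Site

MAX_CHEM_EVENTS = 64


class NumericalInstabilityError(RuntimeError):
    """Non-finite voltage during integration; names compartment and time."""


@dataclass
class StimulusSpec:
    """A square current pulse injected into one compartment.

    The default head stimulus of the escape-response protocol is a 120 nA,
    0.03 ms pulse at the GF proximal end (see :mod:`gfsim.protocols`).
    """

    site: Site                  # (cell, section, normalized position)
    amplitude: float            # nA
    duration: float = 0.03     # ms
    onset: float = 0.0          # ms, relative to end of equilibration

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("stimulus duration must be positive")


@dataclass
class SimConfig:
    """Integration and recording settings."""

    dt: float = 0.0025           # ms, stimulus-phase step
    t_stop: float = 6.0          # ms of simulated time after equilibration
    v_init: float = -85.0        # mV, leak reversal
    equil_time: float = 200.0    # ms of pre-stimulus settling
    equil_dt: float = 0.05       # ms, settling-phase step (stable implicitly)
    record_sites: list[Site] | None = None   # default: distal axon ends

    def __post_init__(self):
        if self.dt <= 0 or self.equil_dt <= 0:
            raise ValueError("time steps must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["record_sites"] is not None:
            d["record_sites"] = [list(s) for s in d["record_sites"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if d.get("record_sites"):
            d["record_sites"] = [tuple(s) for s in d["record_sites"]]
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "SimConfig":
        """Load from a YAML or JSON file with the same field names."""
        import json

        import yaml
        text = open(path).read()
        data = json.loads(text) if str(path).endswith(".json") \
            else yaml.safe_load(text)
        return cls.from_dict(data)


class Trace:
    """Uniformly sampled voltage traces at labelled sites."""

    def __init__(self, times: np.ndarray, sites: list[Site], values: np.ndarray):
        self.times = np.asarray(times, dtype=np.float64)
        self.sites = list(sites)
        self.values = np.asarray(values, dtype=np.float64)
        if self.values.shape != (self.times.size, len(self.sites)):
            raise ValueError("trace shape mismatch")

    @staticmethod
    def label(site: Site) -> str:
        cell, sec, pos = site
        return f"{cell}.{sec}@{pos:g}"

    def site_index(self, cell: str, section: str | None = None) -> int:
        for i, (c, s, _) in enumerate(self.sites):
            if c == cell and (section is None or s == section):
                return i
        raise KeyError(f"no recorded site for cell {cell!r}")

    def __getitem__(self, cell: str) -> np.ndarray:
        """Voltage trace (mV) of the first recorded site of ``cell``."""
        return self.values[:, self.site_index(cell)]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_ms": self.times})
        for i, site in enumerate(self.sites):
            df[self.label(site)] = self.values[:, i]
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class Network:
    """A circuit flattened into per-compartment solver arrays."""

    def __init__(self, circuit: CircuitSpec):
        self.circuit = circuit
        parent, g_par = [], []
        cap, area, active = [], [], []
        self._index: dict[tuple[str, str], tuple[int, object]] = {}
        comp_meta: list[tuple[str, str, int]] = []

        for cell in circuit.cells.values():
            order = cell.section_order()
            for sname in order:
                sec = cell.sections[sname]
                comps = discretize(sec)
                offset = len(parent)
                self._index[(cell.name, sname)] = (offset, sec)
                att = cell.parent_of(sname)
                for c in comps:
                    comp_meta.append((cell.name, sname, c.index))
                    area.append(c.area)
                    cap.append(sec.cm * c.area * UF_PER_CM2_TO_PF)
                    active.append(sec.active)
                    if c.index > 0:
                        prev = comps[c.index - 1]
                        r = prev.axial_r_half_right + c.axial_r_half_left
                        parent.append(offset + c.index - 1)
                        g_par.append(1.0e3 / r)   # 1/MOhm = uS -> nS
                    elif att is None:
                        parent.append(-1)
                        g_par.append(0.0)
                    else:
                        poff, psec = self._index[(cell.name, att.parent)]
                        pidx = psec.seg_index(att.parent_pos)
                        pcomp = discretize(psec)[pidx]
                        # fraction of the parent compartment between its
                        # center and the attachment point
                        frac = att.parent_pos * psec.nseg - pidx - 0.5
                        half = (pcomp.axial_r_half_left if frac < 0
                                else pcomp.axial_r_half_right)
                        r = c.axial_r_half_left + abs(frac) * 2.0 * half
                        parent.append(poff + pidx)
                        g_par.append(1.0e3 / r)

        self.n = len(parent)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.g_par = np.asarray(g_par, dtype=np.float64)
        self.area = np.asarray(area, dtype=np.float64)          # cm^2
        self.cap = np.asarray(cap, dtype=np.float64)            # pF
        self.active = np.asarray(active, dtype=np.uint8)
        self.comp_meta = comp_meta

        mem = circuit.membrane
        act = self.active.astype(bool)
        ns = self.area * MS_PER_CM2_TO_NS
        self.g_leak = mem.g_leak * ns
        self.g_nat = np.where(act, mem.gbar_nat, 0.0) * ns
        self.g_nap = np.where(act, mem.gbar_nap, 0.0) * ns
        self.g_k = np.where(act, mem.gbar_k, 0.0) * ns
        self.kp = circuit.kinetics.to_array()

        self.gap_pre = np.asarray(
            [self.site_index(s.pre_site) for s in circuit.electrical], dtype=np.int64)
        self.gap_post = np.asarray(
            [self.site_index(s.post_site) for s in circuit.electrical], dtype=np.int64)
        self.gap_g = np.asarray(
            [s.g_gap for s in circuit.electrical], dtype=np.float64)
        self.chem = circuit.chemical
        self.chem_pre = np.asarray(
            [self.site_index(s.pre_site) for s in circuit.chemical], dtype=np.int64)
        self.chem_post = np.asarray(
            [self.site_index(s.post_site) for s in circuit.chemical], dtype=np.int64)

    def site_index(self, site: Site) -> int:
        cell, sec, pos = site
        try:
            offset, spec = self._index[(cell, sec)]
        except KeyError:
            raise KeyError(f"unknown site {site}") from None
        return offset + spec.seg_index(pos)

    def comp_label(self, i: int) -> str:
        cell, sec, idx = self.comp_meta[i]
        return f"{cell}.{sec}[{idx}]"

    def distal_axon_sites(self) -> list[Site]:
        out = []
        for cname, cell in self.circuit.cells.items():
            sname = "axon" if "axon" in cell.sections else cell.root
            out.append((cname, sname, 1.0))
        return out


@njit(cache=True)
def _advance(v, m, h, p, n, active, parent, g_par, cap,
             g_leak, g_nat, g_nap, g_k, e_leak, e_na, e_k, kp,
             dt, nsteps, t0,
             stim_idx, stim_amp, stim_on, stim_dur,
             gap_pre, gap_post, gap_g,
             chem_pre, chem_post, chem_gpeak, chem_taur, chem_taud,
             chem_erev, chem_delay, chem_thresh, chem_norm,
             chem_tact, chem_count, chem_above,
             rec_idx, rec_out, gate_range, d, b):
    N = v.size
    mexp = int(kp[KIN_MEXP])
    nexp = int(kp[KIN_NEXP])
    for s in range(nsteps):
        t_old = t0 + s * dt
        t_new = t_old + dt
        # 1. exact exponential gate update at the pre-step voltage
        for i in range(N):
            if active[i] == 0:
                continue
            vi = v[i]
            xinf, tau = _rates(kp, KIN_M, vi)
            m[i] = xinf + (m[i] - xinf) * math.exp(-dt / tau)
            xinf, tau = _rates(kp, KIN_H, vi)
            h[i] = xinf + (h[i] - xinf) * math.exp(-dt / tau)
            xinf, tau = _rates(kp, KIN_P, vi)
            p[i] = xinf + (p[i] - xinf) * math.exp(-dt / tau)
            xinf, tau = _rates(kp, KIN_N, vi)
            n[i] = xinf + (n[i] - xinf) * math.exp(-dt / tau)
            for x in (m[i], h[i], p[i], n[i]):
                if x < gate_range[0]:
                    gate_range[0] = x
                if x > gate_range[1]:
                    gate_range[1] = x
        # 2. membrane terms
        for i in range(N):
            mm = m[i]
            ma = mm
            for _ in range(mexp - 1):
                ma *= mm
            nn = n[i]
            na = nn
            for _ in range(nexp - 1):
                na *= nn
            gna = g_nat[i] * ma * h[i] + g_nap[i] * p[i]
            gk = g_k[i] * na
            d[i] = cap[i] / dt + g_leak[i] + gna + gk
            b[i] = cap[i] / dt * v[i] + g_leak[i] * e_leak + gna * e_na + gk * e_k
        # 3. stimuli (exact charge: fractional overlap of pulse and step)
        for k in range(stim_idx.size):
            lo = max(t_old, stim_on[k])
            hi = min(t_new, stim_on[k] + stim_dur[k])
            if hi > lo:
                b[stim_idx[k]] += stim_amp[k] * (hi - lo) / dt
        # 4. gap junctions: post implicit diagonal, pre explicit source
        for k in range(gap_pre.size):
            g = gap_g[k]
            d[gap_post[k]] += g
            b[gap_post[k]] += g * v[gap_pre[k]]
        # 5. chemical synapses, conductance evaluated at t_new
        for k in range(chem_pre.size):
            g = 0.0
            for e in range(chem_count[k]):
                ta = chem_tact[k, e]
                if t_new > ta:
                    te = t_new - ta
                    g += chem_gpeak[k] * chem_norm[k] * (
                        math.exp(-te / chem_taud[k]) - math.exp(-te / chem_taur[k]))
            d[chem_post[k]] += g
            b[chem_post[k]] += g * chem_erev[k]
        # remember presynaptic voltages before overwriting v
        for k in range(chem_pre.size):
            chem_tact[k, MAX_CHEM_EVENTS - 1] = v[chem_pre[k]]
        # 6. axial terms and Hines elimination (parents precede children)
        for i in range(N):
            if parent[i] >= 0:
                d[i] += g_par[i]
                d[parent[i]] += g_par[i]
        for i in range(N - 1, 0, -1):
            pi = parent[i]
            if pi >= 0:
                f = g_par[i] / d[i]
                d[pi] -= f * g_par[i]
                b[pi] += f * b[i]
        for i in range(N):
            if parent[i] < 0:
                v[i] = b[i] / d[i]
            else:
                v[i] = (b[i] + g_par[i] * v[parent[i]]) / d[i]
            if not math.isfinite(v[i]):
                return 1, i, t_new
        # 7. presynaptic spike detection (interpolated upward crossing)
        for k in range(chem_pre.size):
            vold = chem_tact[k, MAX_CHEM_EVENTS - 1]
            vnew = v[chem_pre[k]]
            if chem_above[k] == 0 and vnew >= chem_thresh[k]:
                frac = 1.0 if vnew == vold else (chem_thresh[k] - vold) / (vnew - vold)
                if chem_count[k] < MAX_CHEM_EVENTS - 1:
                    chem_tact[k, chem_count[k]] = t_old + frac * dt + chem_delay[k]
                    chem_count[k] += 1
                chem_above[k] = 1
            elif chem_above[k] == 1 and vnew < chem_thresh[k]:
                chem_above[k] = 0
        # 8. recording
        for r in range(rec_idx.size):
            rec_out[s, r] = v[rec_idx[r]]
    return 0, -1, 0.0


class Simulation:
    """Mutable simulation state over a compiled :class:`Network`.

    ``equilibrate`` settles the circuit to rest (coarse implicit steps,
    stable at any dt), then ``run`` integrates the stimulus phase at the
    fine dt with full recording; ``step`` advances manually.
    """

    def __init__(self, circuit: CircuitSpec, config: SimConfig | None = None):
        self.config = config or SimConfig()
        self.net = Network(circuit)
        n = self.net.n
        self.t = 0.0
        self.v = np.full(n, self.config.v_init, dtype=np.float64)
        kp = self.net.kp
        self.m = np.empty(n)
        self.h = np.empty(n)
        self.p = np.empty(n)
        self.ngate = np.empty(n)
        for i in range(n):
            self.m[i] = _rates(kp, KIN_M, self.v[i])[0]
            self.h[i] = _rates(kp, KIN_H, self.v[i])[0]
            self.p[i] = _rates(kp, KIN_P, self.v[i])[0]
            self.ngate[i] = _rates(kp, KIN_N, self.v[i])[0]
        nchem = len(self.net.chem)
        self._chem_tact = np.full((max(nchem, 1), MAX_CHEM_EVENTS), np.inf)
        self._chem_count = np.zeros(max(nchem, 1), dtype=np.int64)
        self._chem_above = np.zeros(max(nchem, 1), dtype=np.uint8)
        self.gate_range = np.array([1.0, 0.0])
        self._d = np.empty(n)
        self._b = np.empty(n)
        self._equilibrated = False

    def snapshot(self) -> dict:
        """Copy of the full dynamic state (voltages, gates, synapse queues)."""
        return {"t": self.t, "v": self.v.copy(), "m": self.m.copy(),
                "h": self.h.copy(), "p": self.p.copy(),
                "ngate": self.ngate.copy(),
                "chem_tact": self._chem_tact.copy(),
                "chem_count": self._chem_count.copy(),
                "chem_above": self._chem_above.copy(),
                "equilibrated": self._equilibrated}

    def restore(self, snap: dict) -> None:
        self.t = snap["t"]
        self.v[:] = snap["v"]
        self.m[:] = snap["m"]
        self.h[:] = snap["h"]
        self.p[:] = snap["p"]
        self.ngate[:] = snap["ngate"]
        self._chem_tact[:] = snap["chem_tact"]
        self._chem_count[:] = snap["chem_count"]
        self._chem_above[:] = snap["chem_above"]
        self._equilibrated = snap["equilibrated"]

    # -- low-level stepping ----------------------------------------------
    def step(self, dt: float | None = None, nsteps: int = 1,
             stimuli: list[StimulusSpec] = (),
             record_sites: list[Site] | None = None) -> np.ndarray | None:
        """Advance ``nsteps`` implicit steps of ``dt`` (default config dt).

        Returns the recorded voltage block (nsteps x nsites) when
        ``record_sites`` is given, else None.
        """
        net = self.net
        dt = self.config.dt if dt is None else float(dt)
        stim_idx = np.asarray([net.site_index(s.site) for s in stimuli], dtype=np.int64)
        stim_amp = np.asarray([s.amplitude * NA_TO_PA for s in stimuli])
        stim_on = np.asarray([s.onset for s in stimuli], dtype=np.float64)
        stim_dur = np.asarray([s.duration for s in stimuli], dtype=np.float64)
        if record_sites:
            rec_idx = np.asarray([net.site_index(s) for s in record_sites],
                                 dtype=np.int64)
        else:
            rec_idx = np.empty(0, dtype=np.int64)
        rec_out = np.empty((nsteps if rec_idx.size else 0, rec_idx.size))
        nchem = len(net.chem)
        mem = net.circuit.membrane
        status, bad, t_bad = _advance(
            self.v, self.m, self.h, self.p, self.ngate, net.active,
            net.parent, net.g_par, net.cap,
            net.g_leak, net.g_nat, net.g_nap, net.g_k,
            mem.e_leak, mem.e_na, mem.e_k, net.kp,
            dt, nsteps, self.t,
            stim_idx, stim_amp, stim_on, stim_dur,
            net.gap_pre, net.gap_post, net.gap_g,
            net.chem_pre, net.chem_post,
            np.asarray([s.g_peak for s in net.chem]),
            np.asarray([s.tau_rise for s in net.chem]),
            np.asarray([s.tau_decay for s in net.chem]),
            np.asarray([s.e_rev for s in net.chem]),
            np.asarray([s.delay for s in net.chem]),
            np.asarray([s.spike_threshold for s in net.chem]),
            np.asarray([s.norm_factor for s in net.chem]),
            self._chem_tact[:nchem] if nchem else self._chem_tact[:0],
            self._chem_count[:nchem] if nchem else self._chem_count[:0],
            self._chem_above[:nchem] if nchem else self._chem_above[:0],
            rec_idx, rec_out, self.gate_range, self._d, self._b)
        if status != 0:
            raise NumericalInstabilityError(
                f"non-finite voltage in compartment {net.comp_label(bad)} "
                f"at t = {t_bad:.4f} ms")
        self.t += nsteps * dt
        return rec_out if rec_idx.size else None

    def equilibrate(self) -> float:
        """Settle to rest; returns max |dV/dt| (mV/ms) at the end."""
        cfg = self.config
        nsteps = max(1, int(round(cfg.equil_time / cfg.equil_dt)))
        v_before = None
        self.step(dt=cfg.equil_dt, nsteps=nsteps)
        v_before = self.v.copy()
        self.step(dt=cfg.dt, nsteps=1)
        dvdt = float(np.max(np.abs(self.v - v_before)) / cfg.dt)
        self.t = 0.0
        self._equilibrated = True
        return dvdt

    def run(self, stimuli: list[StimulusSpec],
            record_sites: list[Site] | None = None) -> Trace:
        """Equilibrate (once), apply stimuli, record every fine step."""
        cfg = self.config
        if not self._equilibrated:
            self.equilibrate()
        sites = record_sites or cfg.record_sites or self.net.distal_axon_sites()
        t0 = self.t
        nsteps = int(round(cfg.t_stop / cfg.dt))
        v0 = self.v[[self.net.site_index(s) for s in sites]].copy()
        block = self.step(dt=cfg.dt, nsteps=nsteps, stimuli=list(stimuli),
                          record_sites=sites)
        times = t0 + cfg.dt * np.arange(nsteps + 1)
        values = np.vstack([v0[None, :], block])
        return Trace(times, sites, values)

    def membrane_current_density(self) -> np.ndarray:
        """Net instantaneous membrane current density (mA/cm^2) per compartment."""
        net, mem = self.net, self.net.circuit.membrane
        kin = self.net.circuit.kinetics
        a = net.area
        i_pa = (net.g_leak * (self.v - mem.e_leak)
                + net.g_nat * self.m ** kin.nat_m_exp * self.h
                * (self.v - mem.e_na)
                + net.g_nap * self.p * (self.v - mem.e_na)
                + net.g_k * self.ngate ** kin.k_n_exp * (self.v - mem.e_k))
        return i_pa * 1e-9 / a   # pA -> mA over cm^2


def run(circuit: CircuitSpec, sim_config: SimConfig | None = None,
        stimuli: list[StimulusSpec] = ()) -> Trace:
    """Equilibrate, stimulate and record a circuit in one call."""
    sim = Simulation(circuit, sim_config)
    return sim.run(list(stimuli))
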