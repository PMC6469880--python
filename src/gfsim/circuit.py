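"""The four-cell giant-fiber circuit: default construction from the
published anatomy table, parameter overrides, validation and (de)serialization.

Cells and sections
------------------
GF    : one active axon, 400 um x 8 um.
TTMn  : active axon 50 um + passive medial (60 um) and lateral (30 um)
        dendrites, all 6 um diameter.
PSI   : active axon 90 um + passive dendrite 170 um, 4.5 um diameter.
DLMn  : active tapering axon 50 um (2 -> 4 um) + passive dendrite
        100 um x 2 um.

Dendrites attach by their 0-end to the proximal (0) end of their cell's
axon.  The GF contacts the TTMn medial dendrite (12 um from its proximal
end) from its own distal end, and the PSI axon (45 um) from 360 um; the PSI
axon (76.5 um) drives the DLMn axon (12.5 um) through the chemical synapse.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import yaml

from .cable import Cell, SectionSpec, SpecificationError
from .params import KineticsParams, MembraneParams
from .synapses import (G_GAP_OLD_NS, G_GAP_YOUNG_NS, ChemicalSynapseSpec,
                       ElectricalSynapseSpec)

CELL_NAMES = ("GF", "TTMn", "PSI", "DLMn")

_EXPECTED_SECTIONS = {
    "GF": {"axon"},
    "TTMn": {"axon", "medial_dendrite", "lateral_dendrite"},
    "PSI": {"axon", "dendrite"},
    "DLMn": {"axon", "dendrite"},
}


class OverrideError(KeyError):
    """Parameter-override path did not resolve to exactly one parameter."""


@dataclass
class CircuitSpec:
    cells: dict[str, Cell] = field(default_factory=dict)
    electrical: list[ElectricalSynapseSpec] = field(default_factory=list)
    chemical: list[ChemicalSynapseSpec] = field(default_factory=list)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "cells": [c.to_dict() for c in self.cells.values()],
            "synapses": ([e.to_dict() for e in self.electrical]
                         + [c.to_dict() for c in self.chemical]),
            "membrane": self.membrane.to_dict(),
            "kinetics": self.kinetics.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitSpec":
        spec = cls()
        for cd in d["cells"]:
            cell = Cell.from_dict(cd)
            spec.cells[cell.name] = cell
        for sd in d.get("synapses", []):
            sd = dict(sd)
            kind = sd.pop("type")
            sd["pre_site"] = tuple(sd["pre_site"])
            sd["post_site"] = tuple(sd["post_site"])
            if kind == "electrical":
                spec.electrical.append(ElectricalSynapseSpec(**sd))
            elif kind == "chemical":
                spec.chemical.append(ChemicalSynapseSpec(**sd))
            else:
                raise SpecificationError(f"unknown synapse type {kind!r}")
        if "membrane" in d:
            spec.membrane = MembraneParams.from_dict(d["membrane"])
        if "kinetics" in d:
            spec.kinetics = KineticsParams.from_dict(d["kinetics"])
        return spec

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "CircuitSpec":
        return cls.from_dict(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CircuitSpec":
        return cls.from_dict(json.loads(text))

    @classmethod
    def from_file(cls, path) -> "CircuitSpec":
        text = open(path).read()
        if str(path).endswith(".json"):
            return cls.from_json(text)
        return cls.from_yaml(text)

    def copy(self) -> "CircuitSpec":
        return copy.deepcopy(self)

    @property
    def n_compartments(self) -> int:
        return sum(c.n_compartments for c in self.cells.values())


def build_default_circuit(g_gap: float = G_GAP_YOUNG_NS,
                          nseg: int = 51) -> CircuitSpec:
    """The published default circuit (young-fly gap conductance).

    ``g_gap`` (nS) applies to both electrical synapses; pass
    ``synapses.G_GAP_OLD_NS`` (34.5) for the old-fly circuit.  ``nseg``
    is configurable for convergence studies only.
    """
    spec = CircuitSpec()

    gf = Cell("GF")
    gf.add_section(SectionSpec("axon", length=400.0, diam_proximal=8.0,
                               nseg=nseg, active=True))
    spec.cells["GF"] = gf

    ttmn = Cell("TTMn")
    ttmn.add_section(SectionSpec("axon", length=50.0, diam_proximal=6.0,
                                 nseg=nseg, active=True))
    ttmn.add_section(SectionSpec("medial_dendrite", length=60.0,
                                 diam_proximal=6.0, nseg=nseg))
    ttmn.add_section(SectionSpec("lateral_dendrite", length=30.0,
                                 diam_proximal=6.0, nseg=nseg))
    ttmn.attach("medial_dendrite", "axon", 0.0)
    ttmn.attach("lateral_dendrite", "axon", 0.0)
    spec.cells["TTMn"] = ttmn

    psi = Cell("PSI")
    psi.add_section(SectionSpec("axon", length=90.0, diam_proximal=4.5,
                                nseg=nseg, active=True))
    psi.add_section(SectionSpec("dendrite", length=170.0, diam_proximal=4.5,
                                nseg=nseg))
    psi.attach("dendrite", "axon", 0.0)
    spec.cells["PSI"] = psi

    dlmn = Cell("DLMn")
    dlmn.add_section(SectionSpec("axon", length=50.0, diam_proximal=2.0,
                                 diam_distal=4.0, nseg=nseg, active=True))
    dlmn.add_section(SectionSpec("dendrite", length=100.0, diam_proximal=2.0,
                                 nseg=nseg))
    dlmn.attach("dendrite", "axon", 0.0)
    spec.cells["DLMn"] = dlmn

    spec.electrical = [
        # GF distal end -> TTMn medial dendrite, 12 um of 60 um
        ElectricalSynapseSpec(("GF", "axon", 1.0),
                              ("TTMn", "medial_dendrite", 12.0 / 60.0),
                              g_gap=g_gap),
        # GF at 360 um of 400 um -> PSI axon at 45 um of 90 um
        ElectricalSynapseSpec(("GF", "axon", 360.0 / 400.0),
                              ("PSI", "axon", 45.0 / 90.0),
                              g_gap=g_gap),
    ]
    spec.chemical = [
        # PSI axon at 76.5 um of 90 um -> DLMn axon at 12.5 um of 50 um
        ChemicalSynapseSpec(("PSI", "axon", 76.5 / 90.0),
                            ("DLMn", "axon", 12.5 / 50.0)),
    ]
    return spec


def build_old_circuit(nseg: int = 51) -> CircuitSpec:
    """Default circuit with the old-fly gap conductance (34.5 nS)."""
    return build_default_circuit(g_gap=G_GAP_OLD_NS, nseg=nseg)


# -- parameter overrides --------------------------------------------------

_MEMBRANE_FIELDS = ("gbar_nat", "gbar_nap", "gbar_k", "g_leak",
                    "e_na", "e_k", "e_leak")
_SECTION_FIELDS = ("length", "diam", "diam_proximal", "diam_distal",
                   "nseg", "ra", "cm")
_CHEM_FIELDS = ("g_peak", "delay", "tau_rise", "tau_decay", "e_rev",
                "spike_threshold", "post_section", "post_pos")


def _set_section(sec: SectionSpec, attr: str, value) -> None:
    if attr == "diam":
        sec.diam_proximal = float(value)
        sec.diam_distal = float(value)
    elif attr == "nseg":
        sec.nseg = int(value)
    else:
        setattr(sec, attr, float(value))
    sec.validate()


def apply_overrides(circuit: CircuitSpec, overrides: dict) -> CircuitSpec:
    """Return a new CircuitSpec with dotted-path parameter substitutions.

    Supported paths
    ---------------
    ``g_gap``                                   all electrical synapses, nS
    ``membrane.<field>``                        channel density / reversal
    ``kinetics.<gate>.<field>``                 e.g. kinetics.nat_m.vhalf
    ``cells.<cell>.diam``                       every section of the cell, um
    ``cells.<cell>.<section>.<field>``          length / diam / nseg / ...
    ``synapses.chemical.<field>``               g_peak, delay, taus, or the
                                                post-site (post_section,
                                                post_pos) for relocation
    The input circuit is left untouched.
    """
    new = circuit.copy()
    for path, value in overrides.items():
        parts = path.split(".")
        if path == "g_gap":
            if float(value) < 0:
                raise OverrideError("g_gap must be non-negative")
            for syn in new.electrical:
                syn.g_gap = float(value)
        elif parts[0] == "membrane" and len(parts) == 2:
            if parts[1] not in _MEMBRANE_FIELDS:
                raise OverrideError(f"unknown membrane field {parts[1]!r}")
            setattr(new.membrane, parts[1], float(value))
            new.membrane.validate()
        elif parts[0] == "kinetics" and len(parts) == 3:
            gate = getattr(new.kinetics, parts[1], None)
            if gate is None or not hasattr(gate, parts[2]):
                raise OverrideError(f"unknown kinetics path {path!r}")
            setattr(gate, parts[2], float(value))
        elif parts[0] == "cells" and len(parts) == 3 and parts[2] == "diam":
            cell = new.cells.get(parts[1])
            if cell is None:
                raise OverrideError(f"unknown cell {parts[1]!r}")
            for sec in cell.sections.values():
                _set_section(sec, "diam", value)
        elif parts[0] == "cells" and len(parts) == 4:
            cell = new.cells.get(parts[1])
            if cell is None:
                raise OverrideError(f"unknown cell {parts[1]!r}")
            sec = cell.sections.get(parts[2])
            if sec is None:
                raise OverrideError(f"unknown section {parts[1]}.{parts[2]}")
            if parts[3] not in _SECTION_FIELDS:
                raise OverrideError(f"unknown section field {parts[3]!r}")
            _set_section(sec, parts[3], value)
        elif parts[:2] == ["synapses", "chemical"] and len(parts) == 3:
            if not new.chemical:
                raise OverrideError("circuit has no chemical synapse")
            if parts[2] not in _CHEM_FIELDS:
                raise OverrideError(f"unknown chemical-synapse field {parts[2]!r}")
            for syn in new.chemical:
                if parts[2] == "post_section":
                    cell, sec, pos = syn.post_site
                    syn.post_site = (cell, str(value), pos)
                elif parts[2] == "post_pos":
                    cell, sec, pos = syn.post_site
                    syn.post_site = (cell, sec, float(value))
                else:
                    setattr(syn, parts[2], float(value))
                syn.__post_init__()
        else:
            raise OverrideError(f"unknown override path {path!r}")
    return new


# -- validation -----------------------------------------------------------

def _resolve_ok(spec: CircuitSpec, site) -> bool:
    cell, sec, pos = site
    return (cell in spec.cells and sec in spec.cells[cell].sections
            and 0.0 <= pos <= 1.0)


def validate(circuit: CircuitSpec, allow_taper_anywhere: bool = False) -> list[str]:
    """Structural invariant check; returns a list of violations (empty = ok).

    ``allow_taper_anywhere`` suppresses the default-profile rule that only
    the DLMn axon tapers (useful for exploratory geometry scans).
    """
    v: list[str] = []
    for name in CELL_NAMES:
        if name not in circuit.cells:
            v.append(f"missing cell {name!r}")
    for name, cell in circuit.cells.items():
        expected = _EXPECTED_SECTIONS.get(name)
        if expected is not None and set(cell.sections) != expected:
            v.append(f"cell {name}: sections {sorted(cell.sections)} != "
                     f"expected {sorted(expected)}")
        try:
            cell.section_order()
        except Exception as exc:
            v.append(f"cell {name}: {exc}")
        if not allow_taper_anywhere:
            for sec in cell.sections.values():
                if sec.tapering and not (name == "DLMn" and sec.name == "axon"):
                    v.append(f"cell {name}: section {sec.name} tapers "
                             "(only the DLMn axon may taper)")
    if len(circuit.electrical) != 2:
        v.append(f"expected 2 electrical synapses, found {len(circuit.electrical)}")
    if len(circuit.chemical) != 1:
        v.append(f"expected 1 chemical synapse, found {len(circuit.chemical)}")
    for syn in circuit.electrical + circuit.chemical:
        for site in (syn.pre_site, syn.post_site):
            if not _resolve_ok(circuit, site):
                v.append(f"unresolvable synapse site {site}")
    return v
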