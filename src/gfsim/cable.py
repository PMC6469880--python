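"""Section geometry, compartmentalization and intra-cell topology.

A *section* is an unbranched cylinder (possibly a linearly tapering frustum)
split into ``nseg`` iso-potential compartments, the basic computational unit.
Sections attach to each other by their 0-end to form a tree per cell; the
whole cell is later flattened into parent-pointer arrays for the implicit
(Hines-ordered) solver in :mod:`gfsim.engine`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

from .params import UM2_TO_CM2

DEFAULT_NSEG = 51
DEFAULT_RA_OHM_CM = 35.4
DEFAULT_CM_UF_CM2 = 1.0


class SpecificationError(ValueError):
    """Invalid geometry or parameters in a section/circuit specification."""


class TopologyError(ValueError):
    """Section attachment would break the per-cell tree structure."""


@dataclass
class SectionSpec:
    """Geometry and membrane class of one unbranched cylindrical section.

    ``diam_distal`` defaults to ``diam_proximal`` (constant diameter);
    a differing value gives a linear taper along the section.
    """

    name: str
    length: float                 # um
    diam_proximal: float          # um
    diam_distal: float | None = None
    nseg: int = DEFAULT_NSEG
    ra: float = DEFAULT_RA_OHM_CM     # Ohm*cm
    cm: float = DEFAULT_CM_UF_CM2     # uF/cm^2
    active: bool = False

    def __post_init__(self):
        if self.diam_distal is None:
            self.diam_distal = self.diam_proximal
        self.validate()

    def validate(self) -> None:
        if self.length <= 0:
            raise SpecificationError(f"section {self.name}: length must be > 0")
        if self.diam_proximal <= 0 or self.diam_distal <= 0:
            raise SpecificationError(f"section {self.name}: diameters must be > 0")
        if self.ra <= 0 or self.cm <= 0:
            raise SpecificationError(f"section {self.name}: Ra and Cm must be > 0")
        if self.nseg < 1 or self.nseg % 2 == 0:
            raise SpecificationError(
                f"section {self.name}: nseg must be a positive odd integer")

    @property
    def tapering(self) -> bool:
        return self.diam_distal != self.diam_proximal

    def diam_at(self, x: float) -> float:
        """Diameter (um) at normalized position x in [0, 1]."""
        return self.diam_proximal + (self.diam_distal - self.diam_proximal) * x

    def seg_index(self, x: float) -> int:
        """Index of the compartment containing normalized position x."""
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"position {x} outside [0, 1]")
        return min(self.nseg - 1, int(x * self.nseg))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SectionSpec":
        return cls(**d)


@dataclass
class Compartment:
    """One iso-potential segment of a section.

    ``axial_r_half_left``/``right`` are the axial resistances (MOhm) of the
    two half-segments flanking the center node; the conductance between two
    adjacent compartments is the series combination of the facing halves.
    """

    section: str
    index: int
    center_pos: float        # normalized [0, 1]
    length: float            # um
    diam: float              # um at the center
    area: float              # lateral membrane area, cm^2
    axial_r_half_left: float   # MOhm, proximal half
    axial_r_half_right: float  # MOhm, distal half


def _frustum_area_um2(d0: float, d1: float, h: float) -> float:
    """Lateral (slant) surface of a frustum with end diameters d0, d1, axis h."""
    slant = math.hypot(h, (d1 - d0) / 2.0)
    return math.pi * (d0 + d1) / 2.0 * slant


def _axial_r_mohm(d0: float, d1: float, h: float, ra: float) -> float:
    """Axial resistance (MOhm) of a linearly tapering piece.

    integral of 4*Ra/(pi d(x)^2) dx over the piece = 4*Ra*h/(pi d0 d1)
    (exact for a linear diameter profile).  Ra in Ohm*cm, d/h in um:
    Ohm*cm * um / um^2 = Ohm * 1e4 -> MOhm factor 1e-2.
    """
    return 4.0 * ra * h / (math.pi * d0 * d1) * 1.0e-2


def discretize(section: SectionSpec) -> list[Compartment]:
    """Split a section into ``nseg`` equal-length iso-potential compartments.

    Areas use the frustum lateral-surface formula on the linearly
    interpolated diameter profile (this reduces to pi*d*L for a constant
    diameter); half-segment axial resistances use the exact integral of the
    local cross-section resistivity.
    """
    section.validate()
    n = section.nseg
    h = section.length / n
    comps = []
    for i in range(n):
        x0, xc, x1 = i / n, (i + 0.5) / n, (i + 1) / n
        d0, dc, d1 = section.diam_at(x0), section.diam_at(xc), section.diam_at(x1)
        comps.append(Compartment(
            section=section.name,
            index=i,
            center_pos=xc,
            length=h,
            diam=dc,
            area=_frustum_area_um2(d0, d1, h) * UM2_TO_CM2,
            axial_r_half_left=_axial_r_mohm(d0, dc, h / 2.0, section.ra),
            axial_r_half_right=_axial_r_mohm(dc, d1, h / 2.0, section.ra),
        ))
    return comps


@dataclass
class Attachment:
    child: str            # child section name (attaches by its 0-end)
    parent: str           # parent section name
    parent_pos: float     # normalized position on the parent


@dataclass
class Cell:
    """A named cell: a set of sections plus their tree of attachments.

    The first section added is the root of the tree.
    """

    name: str
    sections: dict[str, SectionSpec] = field(default_factory=dict)
    attachments: list[Attachment] = field(default_factory=list)

    def add_section(self, spec: SectionSpec) -> SectionSpec:
        if spec.name in self.sections:
            raise SpecificationError(
                f"cell {self.name}: duplicate section {spec.name!r}")
        self.sections[spec.name] = spec
        return spec

    @property
    def root(self) -> str:
        return next(iter(self.sections))

    def attach(self, child: str, parent: str, parent_pos: float) -> None:
        """Attach ``child``'s 0-end to ``parent`` at normalized position.

        The per-cell section graph must stay a tree rooted at the first
        section: each non-root section is attached exactly once and cycles
        (including self-attachment) are rejected.
        """
        if child not in self.sections or parent not in self.sections:
            raise TopologyError(f"cell {self.name}: unknown section in attach")
        if child == parent:
            raise TopologyError(f"cell {self.name}: cannot attach {child!r} to itself")
        if not 0.0 <= parent_pos <= 1.0:
            raise TopologyError("parent position must be in [0, 1]")
        if any(a.child == child for a in self.attachments):
            raise TopologyError(f"cell {self.name}: {child!r} already attached")
        # walk up from the parent; meeting `child` would close a cycle
        anc = parent
        parents = {a.child: a.parent for a in self.attachments}
        while anc in parents:
            anc = parents[anc]
            if anc == child:
                raise TopologyError(
                    f"cell {self.name}: attaching {child!r} under {parent!r} "
                    "creates a cycle")
        self.attachments.append(Attachment(child, parent, parent_pos))

    def parent_of(self, section: str) -> Attachment | None:
        for a in self.attachments:
            if a.child == section:
                return a
        return None

    def section_order(self) -> list[str]:
        """Sections in root-first (parent before child) order."""
        children: dict[str, list[Attachment]] = {s: [] for s in self.sections}
        for a in self.attachments:
            children[a.parent].append(a)
        order, stack = [], [self.root]
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(a.child for a in reversed(children[s]))
        if len(order) != len(self.sections):
            orphans = set(self.sections) - set(order)
            raise TopologyError(
                f"cell {self.name}: unattached sections {sorted(orphans)}")
        return order

    @property
    def n_compartments(self) -> int:
        return sum(s.nseg for s in self.sections.values())

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sections": [s.to_dict() for s in self.sections.values()],
            "attachments": [asdict(a) for a in self.attachments],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Cell":
        cell = cls(name=d["name"])
        for s in d["sections"]:
            cell.add_section(SectionSpec.from_dict(s))
        for a in d.get("attachments", []):
            cell.attach(a["child"], a["parent"], a["parent_pos"])
        return cell
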