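"""Archetype-specific SHELXL restraints and proximity-based constraints.

Distance restraints (DFIX for bonded 1-2 pairs, DANG for angle-defining
1-3 pairs) carry targets taken from the optimized tight-binding geometry,
so the least-squares refinement keeps each archetype at its quantum-
chemically plausible shape.  Bond distances to hydrogen are shrunk by
13.5% (factor 0.865) on the way from theory to experiment, because X-ray
data see the bonding electron density rather than the proton; 1-3 targets
involving hydrogen are recomputed from the repositioned H so the bond
angles themselves are untouched by the shrink.

Atoms of different archetypes that end up closer than a proximity
threshold (default 0.5 A) cannot carry independent displacement
parameters; they receive EADP constraints (or SIMU restraints, or
additional EXYZ positional constraints, by choice of mode).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from . import chem_graph
from .archetypes import ArchetypeStructure, AtomPairMapping, OccupancyPlan
from .constants import (DEFAULT_H_SCALE, DEFAULT_PROXIMITY_THRESHOLD,
                        DEFAULT_RESTRAINT_SIGMA, DEFAULT_SIMU_SIGMA)
from .structure_io import CrystalStructure, frac_to_cart


@dataclass(frozen=True)
class Restraint:
    """A DFIX (1-2) or DANG (1-3) distance restraint."""

    kind: str  # "DFIX" | "DANG"
    target: float  # A
    sigma: float
    atoms: tuple  # ((label, residue), (label, residue))

    def __post_init__(self) -> None:
        if self.kind not in ("DFIX", "DANG"):
            raise ValueError(f"unknown restraint kind {self.kind}")
        if self.target <= 0 or not np.isfinite(self.target):
            raise ValueError(f"bad restraint target {self.target}")
        if self.sigma <= 0:
            raise ValueError("restraint sigma must be positive")


@dataclass(frozen=True)
class Constraint:
    """An EADP / EXYZ constraint or SIMU restraint over proximate atoms."""

    kind: str  # "EADP" | "EXYZ" | "SIMU"
    atoms: tuple  # ((label, residue), ...), >= 2 entries
    sigma: Optional[float] = None  # SIMU only

    def __post_init__(self) -> None:
        if self.kind not in ("EADP", "EXYZ", "SIMU"):
            raise ValueError(f"unknown constraint kind {self.kind}")
        if len(self.atoms) < 2:
            raise ValueError("constraint needs at least two atoms")
        if self.kind == "SIMU" and (self.sigma is None or self.sigma <= 0):
            raise ValueError("SIMU requires a positive sigma")


@dataclass
class RefinementPlan:
    """Everything the refinement needs beyond the atomic model itself."""

    restraints: list = field(default_factory=list)
    constraints: list = field(default_factory=list)
    occupancy_plan: Optional[OccupancyPlan] = None
    strategy: str = "restrained+EADP"  # free | restrained+EADP | restrained+SIMU

    @property
    def n_restraints(self) -> int:
        return len(self.restraints)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    def residues(self) -> list:
        return sorted({r for rest in self.restraints for _, r in rest.atoms})


# ---------------------------------------------------------------------------
# restraint generation
# ---------------------------------------------------------------------------

def scaled_positions(archetype: ArchetypeStructure,
                     graph: chem_graph.BondGraph,
                     h_scale: float = DEFAULT_H_SCALE) -> np.ndarray:
    """Cartesian geometry with every H moved along its bond to the scaled
    distance; heavy atoms untouched, bond angles preserved."""
    pos = graph.positions.copy()
    for i, el in enumerate(graph.elements):
        if el != "H":
            continue
        nb = graph.neighbors(i)
        if not nb:
            continue
        j = nb[0]
        pos[i] = pos[j] + (pos[i] - pos[j]) * h_scale
    return pos


def generate_restraints(archetype: ArchetypeStructure,
                        graph: Optional[chem_graph.BondGraph] = None,
                        sigma: float = DEFAULT_RESTRAINT_SIGMA,
                        h_scale: float = DEFAULT_H_SCALE,
                        residue: Optional[int] = None,
                        exclude: Optional[Iterable] = None) -> list:
    """All DFIX (per bond) and DANG (per 1-3 pair) restraints for one
    archetype, targets from its optimized geometry.

    ``exclude`` accepts (label, label) pairs to drop individual
    restraints when a user wants a partial set.
    """
    struct = archetype.structure
    if graph is None:
        graph = chem_graph.perceive_bonds(
            struct.elements, frac_to_cart(struct.cell, struct.frac_coords))
    res = residue if residue is not None else archetype.part
    pos = scaled_positions(archetype, graph, h_scale=h_scale)
    labels = [s.label for s in struct.sites]
    excl = {frozenset(p) for p in exclude} if exclude else set()

    out = []
    for kind, pairs in (("DFIX", chem_graph.one_two_pairs(graph)),
                        ("DANG", chem_graph.one_three_pairs(graph))):
        for i, j in pairs:
            if frozenset((labels[i], labels[j])) in excl:
                continue
            target = float(np.linalg.norm(pos[i] - pos[j]))
            out.append(Restraint(kind=kind, target=target, sigma=sigma,
                                 atoms=((labels[i], res), (labels[j], res))))
    return out


# ---------------------------------------------------------------------------
# proximity constraints
# ---------------------------------------------------------------------------

def assign_constraints(mapping: AtomPairMapping,
                       threshold: float = DEFAULT_PROXIMITY_THRESHOLD,
                       mode: str = "EADP",
                       simu_sigma: float = DEFAULT_SIMU_SIGMA,
                       residues: tuple = (1, 2)) -> list:
    """Constraints for archetype atom pairs closer than ``threshold``.

    Modes: "EADP" (default, shared ADPs), "EADP+EXYZ" (also shared
    positions), "SIMU" (similarity restraint instead of the constraint).
    The DFIX/DANG restraints already keep nearly overlapping atoms apart,
    which is why positional EXYZ constraints are off by default.
    """
    if threshold <= 0:
        raise ValueError("proximity threshold must be positive")
    if mode not in ("EADP", "EADP+EXYZ", "SIMU"):
        raise ValueError(f"unknown constraint mode {mode!r}")
    res_a, res_b = residues
    out = []
    for sa, sb, dist in mapping.pairs:
        if dist >= threshold:
            continue
        atoms = ((sa.label, res_a), (sb.label, res_b))
        if mode == "SIMU":
            out.append(Constraint(kind="SIMU", atoms=atoms, sigma=simu_sigma))
        else:
            out.append(Constraint(kind="EADP", atoms=atoms))
            if mode == "EADP+EXYZ":
                out.append(Constraint(kind="EXYZ", atoms=atoms))
    return out


# ---------------------------------------------------------------------------
# SHELXL instruction-file emission and round-trip parsing
# ---------------------------------------------------------------------------

def _qualify(atom: tuple) -> str:
    label, residue = atom
    return f"{label}_{residue}" if residue else label


def write_instruction_file(plan: RefinementPlan) -> str:
    """Emit the extra SHELXL instruction file (read via '+filename').

    Deterministic ordering: restraints grouped by residue under a RESI
    card, sorted by kind then atom labels; constraints follow, sorted.
    """
    lines = ["REM archetype-specific restraints and constraints"]
    by_res: dict = {}
    for r in plan.restraints:
        by_res.setdefault(r.atoms[0][1], []).append(r)
    for res in sorted(by_res):
        lines.append(f"RESI {res}")
        for r in sorted(by_res[res],
                        key=lambda r: (r.kind, r.atoms[0][0], r.atoms[1][0])):
            lines.append(f"{r.kind} {r.target:.4f} {r.sigma:.4f} "
                         f"{_qualify(r.atoms[0])} {_qualify(r.atoms[1])}")
    for c in sorted(plan.constraints,
                    key=lambda c: (c.kind,) + tuple(map(str, c.atoms))):
        names = " ".join(_qualify(a) for a in c.atoms)
        if c.kind == "SIMU":
            lines.append(f"SIMU {c.sigma:.4f} {names}")
        else:
            lines.append(f"{c.kind} {names}")
    if plan.occupancy_plan is not None:
        sump = plan.occupancy_plan.sump_line()
        if sump:
            lines.append(sump)
    return "\n".join(lines) + "\n"


def main_file_stub(include_name: str) -> str:
    """The line to place in the main .ins file so SHELXL reads the
    instruction file."""
    return f"+{include_name}\n"


_ATOM_RE = re.compile(r"^([A-Za-z][A-Za-z0-9']*?)(?:_(\d+))?$")


def _parse_atom(token: str) -> tuple:
    m = _ATOM_RE.match(token)
    if not m:
        raise ValueError(f"bad atom name {token!r}")
    return (m.group(1), int(m.group(2)) if m.group(2) else 0)


def parse_instruction_file(text: str) -> RefinementPlan:
    """Round-trip parser for :func:`write_instruction_file` output."""
    plan = RefinementPlan()
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.upper().startswith(("REM", "RESI", "SUMP")):
            continue
        toks = line.split()
        kind = toks[0].upper()
        if kind in ("DFIX", "DANG"):
            target, sigma = float(toks[1]), float(toks[2])
            atoms = tuple(_parse_atom(t) for t in toks[3:5])
            plan.restraints.append(Restraint(kind=kind, target=target,
                                             sigma=sigma, atoms=atoms))
        elif kind in ("EADP", "EXYZ"):
            atoms = tuple(_parse_atom(t) for t in toks[1:])
            plan.constraints.append(Constraint(kind=kind, atoms=atoms))
        elif kind == "SIMU":
            sigma = float(toks[1])
            atoms = tuple(_parse_atom(t) for t in toks[2:])
            plan.constraints.append(Constraint(kind="SIMU", atoms=atoms,
                                               sigma=sigma))
    return plan


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

def count_parameters(model: CrystalStructure,
                     plan: Optional[RefinementPlan] = None) -> int:
    """Least-squares parameter count for a model under a plan.

    Convention: 9 parameters per anisotropic atom (xyz + six Uij), 4 per
    isotropic atom (xyz + U), plus one overall scale factor and one per
    independent occupancy free variable.  Each EADP group of g atoms
    removes (g-1) x 6 ADP parameters (anisotropic members) or (g-1) x 1
    (isotropic); each EXYZ group removes (g-1) x 3 positional parameters.
    """
    aniso = {}
    for s in model.sites:
        aniso[(s.label, s.residue)] = s.is_anisotropic
    total = sum(9 if a else 4 for a in aniso.values())
    total += 1  # overall scale factor
    if plan is not None and plan.occupancy_plan is not None:
        total += plan.occupancy_plan.n_independent
    else:
        fvs = {abs(s.free_variable_ref) for s in model.sites
               if s.free_variable_ref is not None}
        total += len(fvs)
    if plan is not None:
        for c in plan.constraints:
            g = len(c.atoms)
            if c.kind == "EADP":
                per = 6 if aniso.get(c.atoms[0], False) else 1
                total -= (g - 1) * per
            elif c.kind == "EXYZ":
                total -= (g - 1) * 3
    return total
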