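"""Splitting disordered models into ordered archetype structures and back.

An *archetype* is the hypothetical ordered structure obtained by taking
all shared (PART 0) atoms plus the atoms of exactly one disorder group,
with every occupancy reset to 1.  Archetypes are optimized independently;
the optimized archetypes are then recombined into one refinable model in
which every archetype is a separate residue whose occupancy hangs on a
shared free variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .structure_io import CrystalStructure, frac_to_cart


@dataclass
class ArchetypeStructure:
    """One ordered conformer extracted from a disordered parent model."""

    structure: CrystalStructure
    part: int
    parent_indices: list  # archetype site index -> parent site index
    parent_occupancy: Optional[float] = None  # occupancy of the part's atoms

    @property
    def sites(self):
        return self.structure.sites

    @property
    def cell(self):
        return self.structure.cell


@dataclass
class AtomPairMapping:
    """Sequence-position atom correspondence between two archetypes."""

    pairs: list  # (site_a, site_b, distance_A)

    def distances(self) -> np.ndarray:
        return np.array([d for _, _, d in self.pairs])

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class OccupancyPlan:
    """Free-variable plan for the recombined model.

    For two archetypes one variable suffices (fv2 and its complement).
    For n > 2, each archetype gets its own variable and a sum-to-one
    side condition (a SHELXL SUMP instruction) ties them together.
    """

    n_archetypes: int
    fv_values: list = field(default_factory=list)  # starting values
    codes: list = field(default_factory=list)      # per-archetype fv ref

    @property
    def n_independent(self) -> int:
        return max(self.n_archetypes - 1, 0)

    def sump_line(self) -> Optional[str]:
        if self.n_archetypes <= 2:
            return None
        terms = " ".join(f"1.0 {k}" for k in range(2, self.n_archetypes + 2))
        return f"SUMP 1.0 0.01 {terms}"


def split_archetypes(model: CrystalStructure) -> list:
    """Write out the n disorder groups as n ordered archetype structures.

    Each archetype keeps the parent's site order, contains every shared
    (part 0) site exactly once plus the sites of one disorder group, and
    has all occupancies reset to 1.  An ordered model yields a single
    archetype identical to the input.
    """
    parts = model.parts()
    if not parts:
        arch = model.copy()
        for s in arch.sites:
            s.occupancy = 1.0
            s.free_variable_ref = None
            s.occupancy_multiplier = 1.0
        return [ArchetypeStructure(structure=arch, part=0,
                                   parent_indices=list(range(len(
                                       model.sites))))]
    shared_labels = {(s.label, s.residue) for s in model.sites if s.part == 0}
    out = []
    for part in parts:
        part_sites = [s for s in model.sites if s.part == part]
        if not part_sites:
            raise ValueError(f"disorder group {part} has no atoms")
        clash = {(s.label, s.residue) for s in part_sites} & shared_labels
        if clash:
            raise ValueError(
                f"labels shared between PART {part} and PART 0: "
                f"{sorted(clash)}")
        occ = float(np.mean([s.occupancy for s in part_sites]))
        sites = []
        indices = []
        for idx, s in enumerate(model.sites):
            if s.part in (0, part):
                ns = s.copy(part=0, occupancy=1.0, free_variable_ref=None,
                            occupancy_multiplier=1.0)
                sites.append(ns)
                indices.append(idx)
        arch = CrystalStructure(
            cell=model.cell, operations=list(model.operations), sites=sites,
            title=f"{model.title} archetype {part}".strip(),
            temperature=model.temperature, wavelength=model.wavelength,
            latt=model.latt, symm_cards=list(model.symm_cards))
        out.append(ArchetypeStructure(structure=arch, part=part,
                                      parent_indices=indices,
                                      parent_occupancy=occ))
    return out


def recombine(archetypes: Sequence[ArchetypeStructure],
              occupancies: Optional[Sequence[float]] = None
              ) -> tuple:
    """Merge optimized archetypes into one refinable disorder model.

    Every archetype becomes a separate residue holding the *whole*
    molecule (atoms that used to share a split site become separate
    sites), all hanging on a common occupancy free-variable plan.
    Returns (model, plan).
    """
    if len(archetypes) < 2:
        raise ValueError("recombination needs at least two archetypes")
    cell0 = archetypes[0].cell
    for a in archetypes[1:]:
        if a.cell != cell0:
            raise ValueError("archetypes have mismatched unit cells")
    n = len(archetypes)
    if occupancies is None:
        occupancies = [a.parent_occupancy for a in archetypes]
        if any(o is None for o in occupancies):
            occupancies = [1.0 / n] * n
        else:
            tot = sum(occupancies)
            occupancies = [o / tot for o in occupancies]
    if abs(sum(occupancies) - 1.0) > 1e-6:
        raise ValueError("archetype occupancies must sum to 1")

    if n == 2:
        plan = OccupancyPlan(n_archetypes=2,
                             fv_values=[float(occupancies[0])],
                             codes=[2, -2])
    else:
        plan = OccupancyPlan(n_archetypes=n,
                             fv_values=[float(o) for o in occupancies],
                             codes=list(range(2, n + 2)))

    sites = []
    for k, (arch, occ) in enumerate(zip(archetypes, occupancies)):
        residue = k + 1
        fv_ref = plan.codes[k]
        for s in arch.sites:
            fv = abs(fv_ref)
            val = plan.fv_values[fv - 2]
            eff = val if fv_ref > 0 else 1.0 - val
            sites.append(s.copy(residue=residue, part=k + 1,
                                occupancy=eff, free_variable_ref=fv_ref,
                                occupancy_multiplier=1.0))
    parent = archetypes[0].structure
    model = CrystalStructure(
        cell=cell0, operations=list(parent.operations), sites=sites,
        title=f"{parent.title} recombined".strip(),
        temperature=parent.temperature, wavelength=parent.wavelength,
        latt=parent.latt, symm_cards=list(parent.symm_cards),
        free_variables=[1.0] + list(plan.fv_values))
    return model, plan


def map_atoms(a: ArchetypeStructure, b: ArchetypeStructure) -> AtomPairMapping:
    """Pair atoms of two archetypes by sequence position.

    Distances are measured in the shared crystal Cartesian frame with no
    superposition: both archetypes live in the same fixed unit cell.
    """
    if len(a.sites) != len(b.sites):
        raise ValueError(
            f"site-count mismatch: {len(a.sites)} vs {len(b.sites)}")
    for pos, (sa, sb) in enumerate(zip(a.sites, b.sites)):
        if sa.element != sb.element:
            raise ValueError(
                f"element mismatch at sequence position {pos}: "
                f"{sa.label}({sa.element}) vs {sb.label}({sb.element})")
    ca = frac_to_cart(a.cell, a.structure.frac_coords)
    cb = frac_to_cart(b.cell, b.structure.frac_coords)
    d = np.linalg.norm(ca - cb, axis=1)
    pairs = [(sa, sb, float(di))
             for sa, sb, di in zip(a.sites, b.sites, d)]
    return AtomPairMapping(pairs=pairs)


def rmscd(mapping: AtomPairMapping) -> float:
    """Root-mean-square Cartesian displacement over a mapping (A)."""
    if len(mapping) == 0:
        raise ValueError("empty atom mapping")
    d = mapping.distances()
    return float(np.sqrt(np.mean(d ** 2)))
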