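"""Deterministic synthetic crystal structures and the end-to-end pipeline.

No experimental data ships with the package: every stage is exercised on
generated toy structures.  The workhorse is a propionamide-like molecule
(CH3CH2C(=O)NH2, 5 heavy atoms + 7 H) in a monoclinic P21/c cell whose
hydrogen atoms are disordered over two PART groups related by an
out-of-plane flip — the classic two-conformer ("up/down") hydrogen
disorder of a nearly planar molecule.  Geometry comes from idealized bond
lengths (C-C 1.52, C=O 1.23, C-N 1.33, C-H 1.09, N-H 1.01 A) with a
seeded random perturbation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import archetypes as arch_mod
from . import chem_graph, cluster_builder, energetics, restraints_constraints
from .constants import (AMBIENT_TEMPERATURE, DEFAULT_CLUSTER_CUTOFF,
                        DEFAULT_H_SCALE, DEFAULT_OPT_CYCLES,
                        DEFAULT_PROXIMITY_THRESHOLD, DEFAULT_RESTRAINT_SIGMA,
                        DEFAULT_SIMU_SIGMA)
from .structure_io import (AtomSite, CrystalStructure, UnitCell, cart_to_frac,
                           expand_operations, parse_shelx, parse_symop,
                           write_shelx, write_xyz)

TEMPLATES = ("monatomic-P1", "propionamide-P21c", "two-part-generic")


@dataclass
class FixtureSpec:
    """Recipe for a synthetic structure; the seed fully determines it."""

    template: str = "propionamide-P21c"
    disorder_mode: str = "two-part"  # none | two-part | three-part
    perturbation: float = 0.02  # A, amplitude of random coordinate noise
    seed: int = 0
    occupancy_major: float = 0.5

    def __post_init__(self) -> None:
        if self.template not in TEMPLATES:
            raise ValueError(
                f"unknown template {self.template!r}; pick from {TEMPLATES}")


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _unit(v):
    return v / np.linalg.norm(v)


def _propionamide_cartesian():
    """Idealized propionamide geometry, heavy-atom skeleton in the z=0
    plane; returns (labels, elements, positions, flip_mask) where
    flip_mask marks the hydrogens (the disordered atoms)."""
    d_cc, d_co, d_cn, d_ch, d_nh = 1.52, 1.23, 1.33, 1.09, 1.01
    deg = math.radians
    C2 = np.zeros(3)
    C3 = np.array([d_cc, 0.0, 0.0])
    C1 = C2 + d_cc * np.array([math.cos(deg(112)), math.sin(deg(112)), 0.0])
    O1 = C3 + d_co * np.array([math.cos(deg(59)), math.sin(deg(59)), 0.0])
    N1 = C3 + d_cn * np.array([math.cos(deg(-64)), math.sin(deg(-64)), 0.0])

    # amide H: trigonal around N, in plane
    to_c3 = _unit(C3 - N1)
    ang = math.atan2(to_c3[1], to_c3[0])
    H1N = N1 + d_nh * np.array([math.cos(ang + deg(120)),
                                math.sin(ang + deg(120)), 0.0])
    H2N = N1 + d_nh * np.array([math.cos(ang - deg(120)),
                                math.sin(ang - deg(120)), 0.0])

    # methylene H: out-of-plane pair on the C1/C3 bisector
    b1, b2 = _unit(C1 - C2), _unit(C3 - C2)
    w = -_unit(b1 + b2)
    half = deg(109.5) / 2.0
    z = np.array([0.0, 0.0, 1.0])
    H1B = C2 + d_ch * (w * math.cos(half) + z * math.sin(half))
    H2B = C2 + d_ch * (w * math.cos(half) - z * math.sin(half))

    # methyl H: staggered, one in plane anti to C2->C3
    a = _unit(C2 - C1)
    e1 = _unit(np.cross(np.cross(a, z), a))  # in-plane, perpendicular to a
    if np.dot(e1, C3 - C2) > 0:
        e1 = -e1  # point the in-plane H away from the chain
    e2 = np.cross(a, e1)
    th = deg(109.5)
    hs = []
    for phi in (0.0, deg(120), deg(-120)):
        r = e1 * math.cos(phi) + e2 * math.sin(phi)
        hs.append(C1 + d_ch * (a * math.cos(th) + r * math.sin(th)))
    H1A, H2A, H3A = hs

    labels = ["C1", "C2", "C3", "O1", "N1",
              "H1A", "H2A", "H3A", "H1B", "H2B", "H1N", "H2N"]
    elements = ["C", "C", "C", "O", "N"] + ["H"] * 7
    positions = np.array([C1, C2, C3, O1, N1,
                          H1A, H2A, H3A, H1B, H2B, H1N, H2N])
    flip_mask = np.array([False] * 5 + [True] * 7)
    return labels, elements, positions, flip_mask


_P21C_CELL = UnitCell(7.0, 8.0, 9.0, 90.0, 102.0, 90.0)
_P21C_SYMM = "-X, 1/2+Y, 1/2-Z"


def _heavy_adp(rng) -> np.ndarray:
    base = np.array([0.030, 0.035, 0.025, 0.002, 0.004, 0.001])
    return base + rng.uniform(-0.002, 0.002, 6)


def make_fixture(spec: FixtureSpec) -> CrystalStructure:
    """Build a synthetic :class:`CrystalStructure` from a spec.

    Templates: ``monatomic-P1`` (one argon atom, triclinic identity-only
    cell), ``propionamide-P21c`` (the disordered amide described in the
    module docstring), ``two-part-generic`` (a C-O diatomic whose oxygen
    is disordered over two or three heavy-atom positions).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.template == "monatomic-P1":
        cell = UnitCell(10.0, 10.0, 10.0, 90.0, 90.0, 90.0)
        sites = [AtomSite(label="Ar1", element="Ar",
                          frac=np.zeros(3), adp=np.array([0.05]))]
        return CrystalStructure(cell=cell, sites=sites, latt=-1,
                                title="monatomic argon fixture")
    if spec.template == "two-part-generic":
        return _make_two_part_generic(spec, rng)
    return _make_propionamide(spec, rng)


def _make_propionamide(spec: FixtureSpec, rng) -> CrystalStructure:
    labels, elements, pos, flip = _propionamide_cartesian()
    pos = pos + rng.uniform(-spec.perturbation, spec.perturbation,
                            pos.shape)
    centroid = pos.mean(axis=0)
    target = _P21C_CELL.orthogonalization_matrix @ np.array(
        [0.22, 0.15, 0.18])
    pos = pos - centroid + target

    sites = []
    occ_major = spec.occupancy_major
    fvar = [1.0]
    disordered = spec.disorder_mode != "none"
    if disordered:
        fvar.append(occ_major)
    for lab, el, p, fl in zip(labels, elements, pos, flip):
        frac = cart_to_frac(_P21C_CELL, p)
        if el == "H":
            adp = np.array([0.05])
        else:
            adp = _heavy_adp(rng)
        if disordered and fl:
            sites.append(AtomSite(label=lab, element=el, frac=frac,
                                  occupancy=occ_major, free_variable_ref=2,
                                  part=1, adp=adp))
        else:
            sites.append(AtomSite(label=lab, element=el, frac=frac,
                                  adp=adp))
    if disordered:
        # second conformer: hydrogens mirrored through the heavy-atom
        # plane (the out-of-plane flip), independently perturbed
        plane_z = float(np.mean(pos[~flip][:, 2]))
        for lab, el, p, fl in zip(labels, elements, pos, flip):
            if not fl:
                continue
            flipped = p.copy()
            flipped[2] = 2.0 * plane_z - p[2]
            flipped += rng.uniform(-spec.perturbation, spec.perturbation, 3)
            frac = cart_to_frac(_P21C_CELL, flipped)
            sites.append(AtomSite(label=lab + "'", element=el, frac=frac,
                                  occupancy=1.0 - occ_major,
                                  free_variable_ref=-2, part=2,
                                  adp=np.array([0.05])))
    symm_cards = [parse_symop(_P21C_SYMM)]
    return CrystalStructure(
        cell=_P21C_CELL, operations=expand_operations(symm_cards, 1),
        sites=sites, title="synthetic propionamide-like fixture",
        latt=1, symm_cards=symm_cards,
        wavelength=0.71073, free_variables=fvar)


def _make_two_part_generic(spec: FixtureSpec, rng) -> CrystalStructure:
    cell = UnitCell(8.0, 9.0, 10.0, 90.0, 95.0, 90.0)
    center = cell.orthogonalization_matrix @ np.array([0.25, 0.25, 0.25])
    n_parts = 3 if spec.disorder_mode == "three-part" else 2
    occs = ([spec.occupancy_major, 1.0 - spec.occupancy_major]
            if n_parts == 2 else [0.5, 0.3, 0.2])
    sites = [AtomSite(label="C1", element="C",
                      frac=cart_to_frac(cell, center),
                      adp=_heavy_adp(rng))]
    fvar = [1.0] + ([occs[0]] if n_parts == 2 else occs)
    for k in range(n_parts):
        ang = math.radians(25.0 * k)
        off = 1.40 * np.array([math.cos(ang), math.sin(ang), 0.0])
        p = center + off + rng.uniform(-spec.perturbation,
                                       spec.perturbation, 3)
        fv_ref = (2 if k == 0 else -2) if n_parts == 2 else 2 + k
        sites.append(AtomSite(
            label=f"O1{'ABC'[k]}", element="O",
            frac=cart_to_frac(cell, p), occupancy=occs[k],
            free_variable_ref=fv_ref, part=k + 1, adp=_heavy_adp(rng)))
    if spec.disorder_mode == "none":
        sites = sites[:2]
        sites[1] = sites[1].copy(part=0, occupancy=1.0,
                                 free_variable_ref=None)
        fvar = [1.0]
    return CrystalStructure(cell=cell, sites=sites,
                            title="generic split-site fixture",
                            latt=-1, free_variables=fvar)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Flat configuration for one end-to-end run."""

    structure_file: Optional[str] = None  # SHELX .ins/.res or .cif
    fixture: Optional[FixtureSpec] = None
    backend: str = "mock"  # mock | xtb
    cutoff: float = DEFAULT_CLUSTER_CUTOFF
    n_cycles: int = DEFAULT_OPT_CYCLES
    sigma: float = DEFAULT_RESTRAINT_SIGMA
    h_scale: float = DEFAULT_H_SCALE
    proximity_threshold: float = DEFAULT_PROXIMITY_THRESHOLD
    constraint_mode: str = "EADP"  # EADP | EADP+EXYZ | SIMU
    simu_sigma: float = DEFAULT_SIMU_SIGMA
    temperature: float = AMBIENT_TEMPERATURE
    barrier: Optional[float] = None  # kJ/mol, user-supplied
    out_dir: Optional[str] = None


@dataclass
class PipelineResult:
    """Artifact bundle from one pipeline run."""

    n_archetypes: int
    n_restraints: int = 0
    n_constraints: int = 0
    n_parameters_free: int = 0
    n_parameters_constrained: int = 0
    rmscd: Optional[float] = None
    delta_e_kj_mol: Optional[float] = None
    assessment: Optional[energetics.DisorderAssessment] = None
    cluster_sizes: dict = field(default_factory=dict)
    energies_hartree: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)  # name -> text
    log: list = field(default_factory=list)
    short_circuit: bool = False


def load_structure(config: PipelineConfig) -> CrystalStructure:
    if config.structure_file:
        text = Path(config.structure_file).read_text()
        if config.structure_file.lower().endswith(".cif"):
            from .structure_io import parse_cif
            return parse_cif(text)
        return parse_shelx(text)
    spec = config.fixture if config.fixture is not None else FixtureSpec()
    return make_fixture(spec)


def _make_backend(config: PipelineConfig):
    if config.backend == "mock":
        return cluster_builder.MockBackend()
    if config.backend == "xtb":
        return cluster_builder.XTBBackend()
    raise ValueError(f"unknown backend {config.backend!r}")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute split -> optimize -> restraints -> recombine -> constraints
    -> instruction files -> classification, collecting counts at each
    stage."""
    structure = load_structure(config)
    backend = _make_backend(config)
    result = PipelineResult(n_archetypes=0)
    log = result.log

    def stage(name):
        log.append(name)

    stage("split")
    archetype_list = arch_mod.split_archetypes(structure)
    result.n_archetypes = len(archetype_list)
    log.append(f"  {len(archetype_list)} archetype(s)")
    if len(archetype_list) < 2:
        result.short_circuit = True
        log.append("  1 archetype, nothing to recombine")
        return result

    stage("optimize")
    optimized = []
    for arch in archetype_list:
        opt = cluster_builder.iterate_optimization(
            arch.structure, backend, n_cycles=config.n_cycles,
            cutoff=config.cutoff)
        cluster = cluster_builder.build_cluster(arch.structure,
                                                cutoff=config.cutoff)
        result.cluster_sizes[arch.part] = len(cluster.environment)
        arch.structure.set_frac_coords(opt.frac_coords)
        result.energies_hartree[arch.part] = opt.energy
        optimized.append(arch)
        log.append(f"  archetype {arch.part}: E = {opt.energy:.6f} Eh, "
                   f"{len(cluster.environment)} neighbour molecules")

    stage("restraints")
    restraints = []
    for k, arch in enumerate(optimized):
        restraints.extend(restraints_constraints.generate_restraints(
            arch, sigma=config.sigma, h_scale=config.h_scale,
            residue=k + 1))
    result.n_restraints = len(restraints)
    log.append(f"  {len(restraints)} DFIX/DANG restraints")

    stage("recombine")
    model, occ_plan = arch_mod.recombine(optimized)
    log.append(f"  {len(model.sites)} sites in the recombined model")

    stage("constraints")
    mapping = arch_mod.map_atoms(optimized[0], optimized[1])
    result.rmscd = arch_mod.rmscd(mapping)
    constraints = restraints_constraints.assign_constraints(
        mapping, threshold=config.proximity_threshold,
        mode=config.constraint_mode, simu_sigma=config.simu_sigma)
    result.n_constraints = len(constraints)
    log.append(f"  {len(constraints)} proximity constraints "
               f"(rmscd {result.rmscd:.3f} A)")

    plan_free = restraints_constraints.RefinementPlan(
        restraints=list(restraints), constraints=[],
        occupancy_plan=occ_plan, strategy="free")
    plan = restraints_constraints.RefinementPlan(
        restraints=restraints, constraints=constraints,
        occupancy_plan=occ_plan,
        strategy="restrained+SIMU" if config.constraint_mode == "SIMU"
        else "restrained+EADP")
    result.n_parameters_free = restraints_constraints.count_parameters(
        model, plan_free)
    result.n_parameters_constrained = \
        restraints_constraints.count_parameters(model, plan)
    log.append(f"  parameters: {result.n_parameters_free} free, "
               f"{result.n_parameters_constrained} constrained")

    stage("classify")
    energies = [energetics.normalize_per_asu(result.energies_hartree[a.part],
                                             1)
                for a in optimized]
    result.delta_e_kj_mol = float(max(energies) - min(energies))
    result.assessment = energetics.classify_disorder(
        result.delta_e_kj_mol, config.barrier,
        temperature=config.temperature)
    log.append(f"  delta E = {result.delta_e_kj_mol:.3f} kJ/mol -> "
               f"{result.assessment.verdict}")

    stage("write")
    result.artifacts["recombined.ins"] = write_shelx(model)
    result.artifacts["restraints.dfx"] = \
        restraints_constraints.write_instruction_file(plan)
    result.artifacts["main_stub.ins"] = \
        restraints_constraints.main_file_stub("restraints.dfx")
    for k, arch in enumerate(optimized):
        result.artifacts[f"archetype_{arch.part}.ins"] = write_shelx(
            arch.structure)
        result.artifacts[f"archetype_{arch.part}.xyz"] = write_xyz(
            arch.structure.elements, arch.structure.cart_coords,
            comment=f"archetype {arch.part}, optimized")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, text in result.artifacts.items():
            (out / name).write_text(text)
        (out / "pipeline.log").write_text("\n".join(log) + "\n")
    return result
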