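"""Symmetry expansion of the asymmetric unit into a molecular cluster, and
the iterative fixed-environment optimization loop.

The asymmetric-unit (ASU) molecules are surrounded by whole neighbour
molecules generated by the space-group operations and lattice translations;
a neighbour molecule is included when any of its atoms lies within a cutoff
(default 3.75 A) of any ASU atom.  During optimization only the ASU atoms
are free; the environment is regenerated from the updated ASU coordinates
by symmetry after every cycle, so the crystal field follows the optimization
while the unit cell stays fixed at the experimental values.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from . import chem_graph
from .constants import (BOHR_RADIUS_ANGSTROM, DEFAULT_CLUSTER_CUTOFF,
                        DEFAULT_OPT_CYCLES)
from .structure_io import (CrystalStructure, cart_to_frac, frac_to_cart,
                           write_turbomole_coord)


class BackendError(RuntimeError):
    """Raised when the external (or mock) optimizer fails."""

    def __init__(self, message: str, cycle: Optional[int] = None):
        super().__init__(message if cycle is None
                         else f"cycle {cycle}: {message}")
        self.cycle = cycle


@dataclass(frozen=True)
class SymmetryImage:
    """One whole neighbour molecule with its symmetry provenance."""

    op_index: int
    lattice_translation: tuple  # integer 3-vector
    component_id: int
    elements: tuple
    positions: np.ndarray  # Cartesian, A

    @property
    def key(self):
        return (self.op_index, self.lattice_translation, self.component_id)


@dataclass
class Cluster:
    """Free ASU atoms plus fixed symmetry-generated environment molecules."""

    asu_elements: list
    asu_positions: np.ndarray  # Cartesian, site order preserved
    environment: list = field(default_factory=list)
    cutoff: float = DEFAULT_CLUSTER_CUTOFF
    cycle: int = 0

    @property
    def n_asu(self) -> int:
        return len(self.asu_elements)

    @property
    def n_environment_atoms(self) -> int:
        return sum(len(img.elements) for img in self.environment)

    @property
    def n_atoms(self) -> int:
        return self.n_asu + self.n_environment_atoms


@dataclass
class OptimizationResult:
    """Outcome of the repeat-cycle molecule-in-cluster optimization."""

    frac_coords: np.ndarray  # optimized ASU fractional coordinates
    energy: float  # Hartree
    backend: str
    energy_trace: list = field(default_factory=list)
    n_cycles_run: int = 0
    converged_early: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy):
            raise ValueError("optimization energy is not finite")


def unwrap_asu(structure: CrystalStructure,
               graph: Optional[chem_graph.BondGraph] = None):
    """Resolve periodic wrapping so every ASU molecule is contiguous.

    Bonds are perceived under the minimum-image convention; each connected
    component is then walked breadth-first, placing every atom at the image
    nearest its already-placed bonded neighbour.  Returns (unwrapped
    fractional coordinates, molecule components, bond graph).
    """
    frac = structure.frac_coords
    cell = structure.cell
    n = len(structure.sites)
    elements = structure.elements
    # minimum-image bond perception
    radii = np.array([chem_graph.covalent_radius(e) for e in elements])
    edges = set()
    shifts = {}
    for i in range(n):
        for j in range(i + 1, n):
            d = frac[j] - frac[i]
            shift = -np.round(d)
            cart = frac_to_cart(cell, d + shift)
            if np.linalg.norm(cart) <= radii[i] + radii[j] + \
                    chem_graph.BOND_TOLERANCE:
                edges.add((i, j))
                shifts[(i, j)] = shift
    # hydrogen degree-1 rule
    for h in [i for i, e in enumerate(elements) if e == "H"]:
        cand = [e for e in edges if h in e]
        if len(cand) > 1:
            def _len(e):
                i, j = e
                return np.linalg.norm(
                    frac_to_cart(cell, frac[j] - frac[i] + shifts[(i, j)]))
            keep = min(cand, key=_len)
            edges -= {e for e in cand if e != keep}

    unwrapped = frac.copy()
    adj = {i: [] for i in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    seen = [False] * n
    comps = []
    for seed in range(n):
        if seen[seed]:
            continue
        comp = [seed]
        seen[seed] = True
        queue = [seed]
        while queue:
            i = queue.pop(0)
            for j in adj[i]:
                if not seen[j]:
                    d = frac[j] - unwrapped[i]
                    unwrapped[j] = frac[j] - np.round(d)
                    seen[j] = True
                    comp.append(j)
                    queue.append(j)
        comps.append(sorted(comp))
    comps.sort(key=lambda c: c[0])
    components = [chem_graph.MoleculeComponent(component_id=k,
                                               atoms=frozenset(c))
                  for k, c in enumerate(comps)]
    bond_graph = chem_graph.BondGraph(
        elements=list(elements),
        positions=frac_to_cart(cell, unwrapped),
        edges=edges)
    return unwrapped, components, bond_graph


def translation_range(cell, cutoff: float, diameter: float) -> list:
    """Per-axis lattice-translation search bound covering cutoff + diameter."""
    return [int(math.ceil((cutoff + diameter) / h)) + 1
            for h in cell.heights()]


def build_cluster(structure: CrystalStructure,
                  cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                  cycle: int = 0) -> Cluster:
    """Expand the ASU into a cluster of whole neighbour molecules.

    Enumerates operator x lattice-translation images over a range wide
    enough to cover the cutoff plus the molecular diameter, keeps every
    whole molecule with any atom within ``cutoff`` of any ASU atom, and
    deduplicates geometrically identical images (atoms on special
    positions would otherwise appear twice).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    cell = structure.cell
    frac_u, components, _ = unwrap_asu(structure)
    asu_cart = frac_to_cart(cell, frac_u)
    elements = structure.elements

    diameter = 0.0
    for comp in components:
        idx = comp.sorted_atoms()
        if len(idx) > 1:
            pts = asu_cart[idx]
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            diameter = max(diameter, float(d.max()))

    na, nb, nc = translation_range(cell, cutoff, diameter)
    environment = []
    seen_geom = set()
    for op_idx, op in enumerate(structure.operations):
        base = op.apply(frac_u)
        for ta in range(-na, na + 1):
            for tb in range(-nb, nb + 1):
                for tc in range(-nc, nc + 1):
                    t = (ta, tb, tc)
                    if op_idx == 0 and t == (0, 0, 0):
                        continue  # the ASU itself
                    img_frac = base + np.array(t, dtype=float)
                    img_cart = frac_to_cart(cell, img_frac)
                    for comp in components:
                        idx = comp.sorted_atoms()
                        pts = img_cart[idx]
                        dmin = np.linalg.norm(
                            pts[:, None, :] - asu_cart[None, :, :],
                            axis=-1).min()
                        if dmin < 1e-6:
                            continue  # self-coincident (special position)
                        if dmin > cutoff:
                            continue
                        geom_key = tuple(sorted(
                            (elements[i],) + tuple(np.round(p, 4))
                            for i, p in zip(idx, pts)))
                        if geom_key in seen_geom:
                            continue
                        seen_geom.add(geom_key)
                        environment.append(SymmetryImage(
                            op_index=op_idx,
                            lattice_translation=t,
                            component_id=comp.component_id,
                            elements=tuple(elements[i] for i in idx),
                            positions=pts.copy()))
    environment.sort(key=lambda img: img.key)
    return Cluster(asu_elements=list(elements), asu_positions=asu_cart,
                   environment=environment, cutoff=cutoff, cycle=cycle)


# ---------------------------------------------------------------------------
# optimization backends
# ---------------------------------------------------------------------------

class MockBackend:
    """Deterministic stand-in optimizer for tests and dry runs.

    Returns the input geometry unchanged (optionally passed through a
    user-supplied move function) and scores the cluster with a smooth
    pairwise exp-repulsion / r^-6 attraction between ASU and environment
    atoms, so that different archetype packings get different energies.
    """

    name = "mock"

    def __init__(self, move: Optional[Callable] = None):
        self.move = move

    def __call__(self, cluster: Cluster):
        pos = cluster.asu_positions.copy()
        if self.move is not None:
            pos = np.asarray(self.move(pos), dtype=float)
        return pos, self.energy(cluster, pos)

    @staticmethod
    def energy(cluster: Cluster, asu_positions=None) -> float:
        pos = cluster.asu_positions if asu_positions is None \
            else np.asarray(asu_positions)
        env = [p for img in cluster.environment for p in img.positions]
        e = 0.0
        if env:
            env = np.asarray(env)
            d = np.linalg.norm(pos[:, None, :] - env[None, :, :], axis=-1)
            d = np.clip(d, 0.5, None)
            e = float(np.sum(np.exp(-2.0 * d) * 1e3 - d ** -6))
        # scaled so that conformer-pair energy differences land on the
        # few-kJ/mol scale typical of real archetype pairs
        return 1e-5 * e


class XTBBackend:
    """Driver for an external tight-binding optimizer executable.

    Writes the TURBOMOLE coord file with fixed-atom flags plus a control
    block freezing the environment, runs the program, and parses the final
    ASU coordinates and total energy (Hartree).  Requires the executable
    on PATH; every test path uses :class:`MockBackend` instead.
    """

    name = "xtb"

    def __init__(self, executable: str = "xtb", extra_args: tuple = (),
                 charge: int = 0):
        self.executable = executable
        self.extra_args = tuple(extra_args)
        self.charge = charge

    def __call__(self, cluster: Cluster):
        exe = shutil.which(self.executable)
        if exe is None:
            raise BackendError(
                f"optimizer executable {self.executable!r} not found on PATH")
        with tempfile.TemporaryDirectory() as tmp:
            tmpdir = Path(tmp)
            coord = tmpdir / "coord"
            coord.write_text(write_turbomole_coord(cluster))
            n_fix = cluster.n_environment_atoms
            control = (
                "$fix\n   atoms: "
                f"{cluster.n_asu + 1}-{cluster.n_asu + n_fix}\n$end\n"
                if n_fix else "")
            (tmpdir / ".xcontrol").write_text(control)
            cmd = [exe, "coord", "--opt", "--charge", str(self.charge)]
            if control:
                cmd += ["--input", ".xcontrol"]
            cmd += list(self.extra_args)
            proc = subprocess.run(cmd, cwd=tmpdir, capture_output=True,
                                  text=True)
            log = tmpdir / "xtb.log"
            log.write_text(proc.stdout + proc.stderr)
            if proc.returncode != 0:
                raise BackendError(
                    f"optimizer exited with {proc.returncode}; "
                    f"output kept at {log}")
            opt = tmpdir / "xtbopt.coord"
            if not opt.exists():
                raise BackendError(f"no optimized coordinates; see {log}")
            pos, energy = parse_turbomole_coord(opt.read_text())
            return pos[: cluster.n_asu], energy


def parse_turbomole_coord(text: str):
    """Parse a $coord block (Bohr -> A); energy from an '$energy'-style
    comment if present, else nan."""
    positions = []
    energy = math.nan
    in_coord = False
    for line in text.splitlines():
        s = line.strip()
        if s.startswith("$coord"):
            in_coord = True
            if "energy" in s:
                for tok in s.replace("=", " ").split():
                    try:
                        energy = float(tok)
                        break
                    except ValueError:
                        continue
            continue
        if s.startswith("$"):
            in_coord = False
            continue
        if in_coord and s:
            toks = s.split()
            positions.append([float(t) for t in toks[:3]])
    return (np.asarray(positions) * BOHR_RADIUS_ANGSTROM, energy)


# ---------------------------------------------------------------------------
# the repeat-cycle loop
# ---------------------------------------------------------------------------

def iterate_optimization(structure: CrystalStructure,
                         backend: Callable,
                         n_cycles: int = DEFAULT_OPT_CYCLES,
                         cutoff: float = DEFAULT_CLUSTER_CUTOFF,
                         early_stop: bool = False,
                         displacement_tol: float = 0.01) -> OptimizationResult:
    """Run repeat build-cluster / optimize cycles on an ordered structure.

    Each cycle rebuilds the environment from the current ASU coordinates,
    calls the backend with the ASU free and the environment fixed, and
    replaces the ASU coordinates with the optimized ones.  The unit cell
    is never altered.  With ``early_stop`` the loop ends once the RMS
    Cartesian displacement between successive ASU geometries falls below
    ``displacement_tol`` (A).
    """
    work = structure.copy()
    trace = []
    energy = math.nan
    converged = False
    cycles_run = 0
    for cycle in range(1, n_cycles + 1):
        cluster = build_cluster(work, cutoff=cutoff, cycle=cycle)
        prev = cluster.asu_positions.copy()
        try:
            new_pos, energy = backend(cluster)
        except BackendError:
            raise
        except Exception as exc:
            raise BackendError(str(exc), cycle=cycle)
        if not np.isfinite(energy):
            raise BackendError("backend returned non-finite energy",
                               cycle=cycle)
        new_pos = np.asarray(new_pos, dtype=float)
        if new_pos.shape != prev.shape:
            raise BackendError("backend returned wrong coordinate shape",
                               cycle=cycle)
        work.set_frac_coords(cart_to_frac(work.cell, new_pos))
        trace.append(float(energy))
        cycles_run = cycle
        rms = float(np.sqrt(np.mean(np.sum((new_pos - prev) ** 2, axis=1))))
        if early_stop and rms < displacement_tol:
            converged = True
            break
    return OptimizationResult(
        frac_coords=work.frac_coords,
        energy=float(energy),
        backend=getattr(backend, "name", backend.__class__.__name__),
        energy_trace=trace,
        n_cycles_run=cycles_run,
        converged_early=converged)
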