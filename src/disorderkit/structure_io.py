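"""Crystallographic file I/O and the fractional/Cartesian coordinate contract.

The in-memory model is :class:`CrystalStructure`: a unit cell, the fully
expanded list of space-group operations (centering and inversion included),
and an ordered list of atom sites carrying the disorder bookkeeping that
SHELX files express through PART / RESI / FVAR-coded occupancies.

Coordinates are fractional internally; Cartesian values are always derived
on demand through :func:`frac_to_cart`, so the cell is the single source of
truth for metric information.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

from .constants import BOHR_RADIUS_ANGSTROM


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class ElementError(ValueError):
    """Raised for unrecognized chemical element symbols."""


#: Elements recognized in SFAC / _atom_site_type_symbol records.
KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn U D".split()
)


def normalize_element(symbol: str) -> str:
    """Canonicalize an element symbol ('BR' -> 'Br'); raise if unknown."""
    s = symbol.strip().capitalize()
    if s not in KNOWN_ELEMENTS:
        raise ElementError(f"unknown element symbol: {symbol!r}")
    return "H" if s == "D" else s


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in Angstrom, angles in degrees.

    The cell is experimental input and is never refined or rescaled by any
    operation in this package.
    """

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("cell parameters give non-positive volume")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix M with cart = M @ frac; a along x, b in the x-y plane."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * sg)  # c * sin-term
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, v],
        ])

    def heights(self) -> np.ndarray:
        """Perpendicular interplanar spacings d(100), d(010), d(001) in A."""
        m = self.orthogonalization_matrix
        av, bv, cv = m[:, 0], m[:, 1], m[:, 2]
        vol = abs(np.dot(av, np.cross(bv, cv)))
        return np.array([
            vol / np.linalg.norm(np.cross(bv, cv)),
            vol / np.linalg.norm(np.cross(cv, av)),
            vol / np.linalg.norm(np.cross(av, bv)),
        ])


TWELFTHS = 12


@dataclass(frozen=True)
class SymmetryOperation:
    """A space-group operation: integer rotation part and exact translation.

    Translations are stored as integer twelfths reduced mod 1, which keeps
    deduplication and closure checks free of floating-point drift (all
    space-group translation components are multiples of 1/12).
    """

    rotation: tuple  # 3x3 nested tuple of ints in {-1, 0, 1}
    translation_twelfths: tuple  # 3 ints in [0, 12)

    @classmethod
    def create(cls, rotation, translation) -> "SymmetryOperation":
        rot = np.asarray(rotation, dtype=int)
        if abs(round(float(np.linalg.det(rot)))) != 1:
            raise ValueError("rotation part must have determinant +/-1")
        tw = []
        for t in translation:
            fr = Fraction(t).limit_denominator(TWELFTHS)
            num = fr.numerator * (TWELFTHS // fr.denominator)
            if TWELFTHS % fr.denominator:
                raise ValueError(f"translation {t} is not a multiple of 1/12")
            tw.append(num % TWELFTHS)
        return cls(tuple(map(tuple, rot.tolist())), tuple(tw))

    @property
    def rot(self) -> np.ndarray:
        return np.array(self.rotation, dtype=int)

    @property
    def trans(self) -> np.ndarray:
        return np.array(self.translation_twelfths, dtype=float) / TWELFTHS

    def apply(self, frac: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (vector or (N, 3) array)."""
        return np.asarray(frac) @ self.rot.T + self.trans

    def compose(self, other: "SymmetryOperation") -> "SymmetryOperation":
        """self after other, translation reduced mod 1."""
        rot = self.rot @ other.rot
        tw = self.rot @ np.array(other.translation_twelfths) + np.array(
            self.translation_twelfths)
        return SymmetryOperation(tuple(map(tuple, rot.tolist())),
                                 tuple(int(t) % TWELFTHS for t in tw))

    @property
    def is_identity(self) -> bool:
        return (self.rotation == ((1, 0, 0), (0, 1, 0), (0, 0, 1))
                and self.translation_twelfths == (0, 0, 0))

    def triplet(self) -> str:
        """Human-readable xyz triplet, e.g. '-x, y+1/2, -z+1/2'."""
        out = []
        for row, tw in zip(self.rotation, self.translation_twelfths):
            terms = []
            for coef, axis in zip(row, "xyz"):
                if coef == 1:
                    terms.append(f"+{axis}" if terms else axis)
                elif coef == -1:
                    terms.append(f"-{axis}")
            if tw:
                fr = Fraction(tw, TWELFTHS)
                terms.append(f"+{fr.numerator}/{fr.denominator}")
            out.append("".join(terms))
        return ", ".join(out)


IDENTITY_OP = SymmetryOperation(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0, 0, 0))
INVERSION_OP = SymmetryOperation(((-1, 0, 0), (0, -1, 0), (0, 0, -1)),
                                 (0, 0, 0))

#: SHELX |LATT| codes -> centering translation vectors (as twelfths).
_CENTERING = {
    1: [],                                    # P
    2: [(6, 6, 6)],                           # I
    3: [(8, 4, 4), (4, 8, 8)],                # R (obverse)
    4: [(0, 6, 6), (6, 0, 6), (6, 6, 0)],     # F
    5: [(0, 6, 6)],                           # A
    6: [(6, 0, 6)],                           # B
    7: [(6, 6, 0)],                           # C
}


@dataclass
class AtomSite:
    """One crystallographic atom site with disorder bookkeeping.

    ``part`` follows the SHELX PART convention (0 = shared between all
    disorder components); ``free_variable_ref`` links the occupancy to a
    SHELX free variable: +k means occupancy = multiplier * fv(k), -k means
    occupancy = multiplier * (1 - fv(k)), None means a fixed occupancy.
    """

    label: str
    element: str
    frac: np.ndarray
    occupancy: float = 1.0
    free_variable_ref: Optional[int] = None
    occupancy_multiplier: float = 1.0
    part: int = 0
    residue: int = 0
    adp: Optional[np.ndarray] = None  # shape (1,) iso U or (6,) Uij

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.frac = np.asarray(self.frac, dtype=float)
        if not 0.0 < self.occupancy <= 1.0 + 1e-9:
            raise ValueError(
                f"occupancy of {self.label} must be in (0, 1], "
                f"got {self.occupancy}")
        if self.adp is not None:
            self.adp = np.atleast_1d(np.asarray(self.adp, dtype=float))
            if self.adp.shape not in ((1,), (6,)):
                raise ValueError("adp must be 1 (iso) or 6 (aniso) values")

    @property
    def is_anisotropic(self) -> bool:
        return self.adp is not None and self.adp.shape == (6,)

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    def copy(self, **changes) -> "AtomSite":
        site = replace(self)
        site.frac = self.frac.copy()
        site.adp = None if self.adp is None else self.adp.copy()
        for k, v in changes.items():
            setattr(site, k, v)
        return site


@dataclass
class CrystalStructure:
    """A parsed experimental model: cell + expanded symmetry + atom sites."""

    cell: UnitCell
    operations: list = field(default_factory=lambda: [IDENTITY_OP])
    sites: list = field(default_factory=list)
    title: str = ""
    temperature: Optional[float] = None
    wavelength: Optional[float] = None
    latt: int = 1
    symm_cards: list = field(default_factory=list)  # generator ops as parsed
    free_variables: list = field(default_factory=lambda: [1.0])

    def __post_init__(self) -> None:
        n_id = sum(op.is_identity for op in self.operations)
        if n_id != 1:
            raise ValueError("identity operation must be present exactly once")
        seen = set()
        for s in self.sites:
            key = (s.label, s.residue)
            if key in seen:
                raise ValueError(f"duplicate (label, residue): {key}")
            seen.add(key)

    # -- convenience accessors ------------------------------------------
    @property
    def frac_coords(self) -> np.ndarray:
        return np.array([s.frac for s in self.sites]).reshape(-1, 3)

    @property
    def cart_coords(self) -> np.ndarray:
        return frac_to_cart(self.cell, self.frac_coords)

    @property
    def elements(self) -> list:
        return [s.element for s in self.sites]

    def set_frac_coords(self, frac: np.ndarray) -> None:
        frac = np.asarray(frac, dtype=float)
        if frac.shape != (len(self.sites), 3):
            raise ValueError("coordinate array shape mismatch")
        for site, row in zip(self.sites, frac):
            site.frac = row.copy()

    def parts(self) -> list:
        """Sorted distinct nonzero disorder-group ids."""
        return sorted({s.part for s in self.sites if s.part != 0})

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(
            cell=self.cell,
            operations=list(self.operations),
            sites=[s.copy() for s in self.sites],
            title=self.title,
            temperature=self.temperature,
            wavelength=self.wavelength,
            latt=self.latt,
            symm_cards=list(self.symm_cards),
            free_variables=list(self.free_variables),
        )


# ---------------------------------------------------------------------------
# coordinate contract
# ---------------------------------------------------------------------------

def frac_to_cart(cell: UnitCell, frac) -> np.ndarray:
    """Fractional -> Cartesian (Angstrom), a along x, b in the x-y plane."""
    return np.asarray(frac, dtype=float) @ cell.orthogonalization_matrix.T


def cart_to_frac(cell: UnitCell, cart) -> np.ndarray:
    """Cartesian (Angstrom) -> fractional; inverse of :func:`frac_to_cart`."""
    inv = np.linalg.inv(cell.orthogonalization_matrix)
    return np.asarray(cart, dtype=float) @ inv.T


# ---------------------------------------------------------------------------
# symmetry-operator parsing and expansion
# ---------------------------------------------------------------------------

def parse_symop(triplet: str) -> SymmetryOperation:
    """Parse an 'x, y, z'-style operator string (SYMM card or CIF xyz)."""
    try:
        op = gemmi.Op(triplet.strip().lower())
    except Exception as exc:
        raise FormatError(f"malformed symmetry operator {triplet!r}: {exc}")
    den = gemmi.Op.DEN
    rot = [[r // den for r in row] for row in op.rot]
    if any(r * den != rr for row, orow in zip(rot, op.rot)
           for r, rr in zip(row, orow)):
        raise FormatError(f"non-crystallographic rotation in {triplet!r}")
    trans = [Fraction(t, den) for t in op.tran]
    return SymmetryOperation.create(rot, trans)


def expand_operations(symm_ops: Sequence[SymmetryOperation],
                      latt: int) -> list:
    """Expand SYMM generators by LATT centering/inversion, SHELX convention.

    |latt| selects the centering (1=P 2=I 3=R 4=F 5=A 6=B 7=C); a positive
    latt additionally applies the inversion centre at the origin.
    """
    if abs(latt) not in _CENTERING:
        raise FormatError(f"invalid LATT code {latt}")
    base = [IDENTITY_OP]
    for op in symm_ops:
        if not any(op == b for b in base):
            base.append(op)
    if latt > 0:
        for op in list(base):
            cand = INVERSION_OP.compose(op)
            if not any(cand == b for b in base):
                base.append(cand)
    out = list(base)
    for cen in _CENTERING[abs(latt)]:
        shift = SymmetryOperation(IDENTITY_OP.rotation, cen)
        for op in base:
            cand = shift.compose(op)
            if not any(cand == b for b in out):
                out.append(cand)
    return out


# ---------------------------------------------------------------------------
# SHELX occupancy coding
# ---------------------------------------------------------------------------

def decode_sof(code: float, free_variables: Sequence[float]):
    """Decode a SHELX sof code into (occupancy, fv_ref, multiplier).

    Code c with |c| >= 5: fv = floor(|c| / 10), p = |c| - 10 fv.  fv <= 1
    means fixed at p; otherwise occupancy = p * fv(k) for positive c and
    p * (1 - fv(k)) for negative c.
    """
    if abs(code) < 5.0:
        return code, None, code
    fv = int(abs(code) // 10)
    p = abs(code) - 10.0 * fv
    if fv <= 1:
        return p, None, p
    if fv > len(free_variables):
        raise FormatError(f"sof code {code} references undefined fv {fv}")
    val = free_variables[fv - 1]
    if code > 0:
        return p * val, fv, p
    return p * (1.0 - val), -fv, p


def encode_sof(site: AtomSite) -> float:
    if site.free_variable_ref is None:
        return 10.0 + site.occupancy
    fv = abs(site.free_variable_ref)
    code = 10.0 * fv + site.occupancy_multiplier
    return code if site.free_variable_ref > 0 else -code


# ---------------------------------------------------------------------------
# SHELX ins/res reader and writer
# ---------------------------------------------------------------------------

_SHELX_COMMANDS = {
    "TITL", "CELL", "ZERR", "LATT", "SYMM", "SFAC", "DISP", "UNIT", "TEMP",
    "L.S.", "CGLS", "BOND", "LIST", "FMAP", "PLAN", "ACTA", "WGHT", "FVAR",
    "PART", "RESI", "AFIX", "HKLF", "END", "MOLE", "EQIV", "CONF", "HTAB",
    "SIZE", "REM", "MORE", "TIME", "OMIT", "SHEL", "BASF", "TWIN", "EXTI",
    "SWAT", "MERG", "SPEC", "DFIX", "DANG", "SADI", "SAME", "CHIV", "FLAT",
    "DELU", "SIMU", "RIGU", "ISOR", "XNPD", "SUMP", "EADP", "EXYZ", "ANIS",
    "STIR", "BLOC", "DAMP", "GRID", "MPLA", "RTAB", "LAUE",
}


def _join_continuations(text: str) -> list:
    lines, pending = [], ""
    for raw in text.splitlines():
        line = raw.rstrip()
        if pending:
            line = pending + " " + line.lstrip()
            pending = ""
        if line.endswith("="):
            pending = line[:-1].rstrip()
            continue
        lines.append(line)
    if pending:
        lines.append(pending)
    return lines


def parse_shelx(text: str) -> CrystalStructure:
    """Parse SHELX .ins/.res content into a :class:`CrystalStructure`.

    Handles CELL/LATT/SYMM expansion, SFAC element mapping, FVAR-coded
    occupancies and PART/RESI disorder bookkeeping.  Restraint and
    refinement instructions are ignored: they are SHELXL's business.
    """
    cell = None
    latt = 1
    symm_cards: list = []
    sfac: list = []
    fvar: list = []
    sites: list = []
    title = ""
    temperature = wavelength = None
    part = 0
    residue = 0
    in_afix_head = False

    for line in _join_continuations(text):
        stripped = line.strip()
        if not stripped:
            continue
        tokens = stripped.split()
        cmd = tokens[0].upper()
        if cmd == "TITL":
            title = stripped[4:].strip()
        elif cmd == "CELL":
            if len(tokens) < 8:
                raise FormatError(f"malformed CELL card: {stripped!r}")
            wavelength = float(tokens[1])
            a, b, c, al, be, ga = map(float, tokens[2:8])
            cell = UnitCell(a, b, c, al, be, ga)
        elif cmd == "LATT":
            latt = int(tokens[1])
        elif cmd == "SYMM":
            try:
                symm_cards.append(parse_symop(stripped[4:]))
            except FormatError as exc:
                raise FormatError(f"bad SYMM card {stripped!r}: {exc}")
        elif cmd == "SFAC":
            for tok in tokens[1:]:
                try:
                    float(tok)  # scattering-factor constants, not symbols
                    break
                except ValueError:
                    sfac.append(normalize_element(tok))
        elif cmd == "TEMP":
            temperature = 273.15 + float(tokens[1])
        elif cmd == "FVAR":
            fvar.extend(float(t) for t in tokens[1:])
        elif cmd == "PART":
            part = int(float(tokens[1]))
        elif cmd == "RESI":
            # RESI n [class] or RESI class n
            nums = [t for t in tokens[1:] if re.fullmatch(r"-?\d+", t)]
            residue = int(nums[0]) if nums else 0
        elif cmd == "AFIX":
            in_afix_head = False
        elif cmd in ("HKLF", "END"):
            break
        elif cmd in _SHELX_COMMANDS or in_afix_head:
            continue
        else:
            site = _parse_shelx_atom(tokens, sfac, fvar, part, residue)
            if site is not None:
                sites.append(site)

    if cell is None:
        raise FormatError("SHELX input has no CELL card")
    ops = expand_operations(symm_cards, latt)
    return CrystalStructure(
        cell=cell, operations=ops, sites=sites, title=title,
        temperature=temperature, wavelength=wavelength, latt=latt,
        symm_cards=symm_cards,
        free_variables=fvar if fvar else [1.0])


def _parse_shelx_atom(tokens, sfac, fvar, part, residue):
    if len(tokens) < 5:
        return None
    label = tokens[0]
    try:
        sfac_idx = int(tokens[1])
        x, y, z = (float(t) for t in tokens[2:5])
    except ValueError:
        return None
    if not 1 <= sfac_idx <= len(sfac):
        raise ElementError(
            f"atom {label}: SFAC index {sfac_idx} outside the SFAC list")
    sof_code = float(tokens[5]) if len(tokens) > 5 else 11.0
    occ, fv_ref, mult = decode_sof(sof_code, fvar if fvar else [1.0])
    adp_vals = [float(t) for t in tokens[6:12]]
    adp = None
    if len(adp_vals) >= 6:
        adp = np.array(adp_vals[:6])
    elif adp_vals:
        adp = np.array(adp_vals[:1])
    # strip SHELX "fixed" offsets from coordinates (10 added to fix)
    frac = np.array([v - 10.0 if abs(v) >= 5.0 else v for v in (x, y, z)])
    return AtomSite(label=label, element=sfac[sfac_idx - 1], frac=frac,
                    occupancy=occ, free_variable_ref=fv_ref,
                    occupancy_multiplier=mult, part=part, residue=residue,
                    adp=adp)


def write_shelx(model: CrystalStructure, title: Optional[str] = None) -> str:
    """Emit a SHELX .ins representation that round-trips through
    :func:`parse_shelx` (coordinates to 6 decimals)."""
    max_fv = max((abs(s.free_variable_ref) for s in model.sites
                  if s.free_variable_ref is not None), default=1)
    fvar = list(model.free_variables)
    if max_fv > len(fvar):
        raise ValueError(
            f"sites reference free variable {max_fv} but only "
            f"{len(fvar)} FVAR slots are defined")

    elements = []
    for s in model.sites:
        if s.element not in elements:
            elements.append(s.element)
    counts = {e: 0.0 for e in elements}
    nops = len(model.operations)
    for s in model.sites:
        counts[s.element] += s.occupancy * nops

    lines = [f"TITL {title if title is not None else model.title}".rstrip()]
    wl = model.wavelength if model.wavelength is not None else 0.71073
    c = model.cell
    lines.append(
        f"CELL {wl:.5f} {c.a:.4f} {c.b:.4f} {c.c:.4f} "
        f"{c.alpha:.3f} {c.beta:.3f} {c.gamma:.3f}")
    lines.append(f"ZERR 1 0.0001 0.0001 0.0001 0.001 0.001 0.001")
    lines.append(f"LATT {model.latt}")
    for op in model.symm_cards:
        lines.append(f"SYMM {op.triplet().upper()}")
    lines.append("SFAC " + " ".join(elements))
    lines.append("UNIT " + " ".join(f"{counts[e]:.0f}" for e in elements))
    if model.temperature is not None:
        lines.append(f"TEMP {model.temperature - 273.15:.1f}")
    lines.append("FVAR " + " ".join(f"{v:.5f}" for v in fvar))

    cur_resi = 0
    cur_part = 0
    for s in model.sites:
        if s.residue != cur_resi:
            lines.append(f"RESI {s.residue}")
            cur_resi = s.residue
        if s.part != cur_part:
            lines.append(f"PART {s.part}")
            cur_part = s.part
        sfac_idx = elements.index(s.element) + 1
        sof = encode_sof(s)
        rec = (f"{s.label:<6s} {sfac_idx} "
               f"{s.frac[0]:10.6f} {s.frac[1]:10.6f} {s.frac[2]:10.6f} "
               f"{sof:10.5f}")
        if s.adp is not None:
            rec += " " + " ".join(f"{u:.5f}" for u in s.adp)
        lines.append(rec)
    if cur_part != 0:
        lines.append("PART 0")
    lines.append("HKLF 4")
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# CIF reader
# ---------------------------------------------------------------------------

def parse_cif(text: str) -> CrystalStructure:
    """Parse core small-molecule CIF content.

    Reads the _cell, symmetry-operator, and _atom_site loops;
    _atom_site_disorder_group is mapped onto the PART id ('.' -> 0).
    Only the first data block of a multi-block file is used.
    """
    doc = gemmi.cif.read_string(text)
    if len(doc) == 0:
        raise FormatError("CIF contains no data block")
    if len(doc) > 1:
        warnings.warn("multi-block CIF: using the first block only")
    block = doc[0]

    def num(tag):
        val = block.find_value(tag)
        if val is None:
            return None
        return float(gemmi.cif.as_number(val))

    params = [num("_cell_length_a"), num("_cell_length_b"),
              num("_cell_length_c"), num("_cell_angle_alpha"),
              num("_cell_angle_beta"), num("_cell_angle_gamma")]
    if any(p is None for p in params):
        raise FormatError("CIF lacks complete _cell parameters")
    cell = UnitCell(*params)

    symm_ops = []
    for tag in ("_space_group_symop_operation_xyz",
                "_symmetry_equiv_pos_as_xyz"):
        col = block.find_loop(tag)
        vals = list(col) if col else []
        if not vals:
            v = block.find_value(tag)
            vals = [v] if v else []
        if vals:
            symm_ops = [parse_symop(gemmi.cif.as_string(v)) for v in vals]
            break
    if not symm_ops:
        raise FormatError(
            "CIF has no symmetry-operator loop; supply the operators "
            "(_space_group_symop_operation_xyz) explicitly")
    ops = [IDENTITY_OP]
    for op in symm_ops:
        if not any(op == o for o in ops):
            ops.append(op)

    tags = ["_atom_site_label", "_atom_site_type_symbol",
            "_atom_site_fract_x", "_atom_site_fract_y", "_atom_site_fract_z",
            "_atom_site_occupancy", "_atom_site_disorder_group",
            "_atom_site_U_iso_or_equiv"]
    table = block.find("_atom_site_", [t[len("_atom_site_"):] for t in tags])
    if not table:
        # retry with optional columns marked optional
        table = block.find("_atom_site_", ["label", "type_symbol",
                                          "fract_x", "fract_y", "fract_z",
                                          "?occupancy", "?disorder_group",
                                          "?U_iso_or_equiv"])
    if not table:
        raise FormatError("CIF lacks an _atom_site loop")

    sites = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        element = normalize_element(gemmi.cif.as_string(row[1]))
        frac = [gemmi.cif.as_number(row[i]) for i in (2, 3, 4)]
        occ = 1.0
        if row.has(5) and row[5] not in (".", "?"):
            occ = gemmi.cif.as_number(row[5])
        part = 0
        if row.has(6) and row[6] not in (".", "?"):
            part = int(gemmi.cif.as_number(row[6]))
        adp = None
        if row.has(7) and row[7] not in (".", "?"):
            adp = np.array([gemmi.cif.as_number(row[7])])
        sites.append(AtomSite(label=label, element=element,
                              frac=np.array(frac), occupancy=occ,
                              part=part, adp=adp))

    # anisotropic loop, keyed by label
    aniso = block.find("_atom_site_aniso_", [
        "label", "U_11", "U_22", "U_33", "U_23", "U_13", "U_12"])
    if aniso:
        by_label = {s.label: s for s in sites}
        for row in aniso:
            lab = gemmi.cif.as_string(row[0])
            if lab in by_label:
                by_label[lab].adp = np.array(
                    [gemmi.cif.as_number(row[i]) for i in range(1, 7)])

    return CrystalStructure(cell=cell, operations=ops, sites=sites,
                            title=block.name)


def write_cif(model: CrystalStructure) -> str:
    """Write a minimal core CIF (cell, expanded operators, atom sites)."""
    c = model.cell
    lines = [f"data_{model.title.replace(' ', '_') or 'disorderkit'}",
             f"_cell_length_a {c.a:.4f}",
             f"_cell_length_b {c.b:.4f}",
             f"_cell_length_c {c.c:.4f}",
             f"_cell_angle_alpha {c.alpha:.3f}",
             f"_cell_angle_beta {c.beta:.3f}",
             f"_cell_angle_gamma {c.gamma:.3f}",
             "loop_",
             "_space_group_symop_operation_xyz"]
    for op in model.operations:
        lines.append(f"  '{op.triplet().replace(' ', '')}'")
    lines += ["loop_",
              "_atom_site_label",
              "_atom_site_type_symbol",
              "_atom_site_fract_x",
              "_atom_site_fract_y",
              "_atom_site_fract_z",
              "_atom_site_occupancy",
              "_atom_site_disorder_group",
              "_atom_site_U_iso_or_equiv"]
    for s in model.sites:
        dg = "." if s.part == 0 else str(s.part)
        uiso = s.adp[0] if (s.adp is not None and s.adp.shape == (1,)) else 0.0
        lines.append(
            f"  {s.label} {s.element} {s.frac[0]:.6f} {s.frac[1]:.6f} "
            f"{s.frac[2]:.6f} {s.occupancy:.4f} {dg} {uiso:.5f}")
    aniso = [s for s in model.sites if s.is_anisotropic]
    if aniso:
        lines += ["loop_", "_atom_site_aniso_label"] + [
            f"_atom_site_aniso_U_{ij}" for ij in
            ("11", "22", "33", "23", "13", "12")]
        for s in aniso:
            lines.append("  " + s.label + " "
                         + " ".join(f"{u:.5f}" for u in s.adp))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# optimizer-facing output formats
# ---------------------------------------------------------------------------

def write_turbomole_coord(cluster) -> str:
    """Write a cluster as a TURBOMOLE '$coord' file in Bohr.

    ASU atoms come first in site order (free); environment atoms follow in
    generation order and carry the fixed-atom flag 'f'.
    """
    lines = ["$coord"]
    for pos, el in zip(cluster.asu_positions, cluster.asu_elements):
        b = np.asarray(pos) / BOHR_RADIUS_ANGSTROM
        lines.append(f"{b[0]:20.14f} {b[1]:20.14f} {b[2]:20.14f} "
                     f"{el.lower()}")
    for img in cluster.environment:
        for pos, el in zip(img.positions, img.elements):
            b = np.asarray(pos) / BOHR_RADIUS_ANGSTROM
            lines.append(f"{b[0]:20.14f} {b[1]:20.14f} {b[2]:20.14f} "
                         f"{el.lower()} f")
    lines.append("$end")
    return "\n".join(lines) + "\n"


def write_xyz(elements: Iterable[str], cart: np.ndarray,
              comment: str = "") -> str:
    """Plain XYZ (Angstrom) for visual inspection."""
    cart = np.asarray(cart, dtype=float).reshape(-1, 3)
    elements = list(elements)
    lines = [str(len(elements)), comment]
    for el, pos in zip(elements, cart):
        lines.append(f"{el:<2s} {pos[0]:12.6f} {pos[1]:12.6f} {pos[2]:12.6f}")
    return "\n".join(lines) + "\n"
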