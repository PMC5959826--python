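"""CIF 1.1 reading/writing and exact symmetry-operator arithmetic.

Only the subset of CIF needed by the pipeline is handled: cell parameters,
symmetry operator lists (both the ``_symmetry_equiv_pos_as_xyz`` and
``_space_group_symop_operation_xyz`` tag families), atom-site loops with
fractional coordinates/occupancies/disorder tags, ``_geom_bond_*`` loops and
Z.  Numeric standard uncertainties ("1.234(5)") are stripped, never
propagated: the pipeline uses point geometry only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from fractions import Fraction

import gemmi.cif
import numpy as np

from .elements import normalize_element

__all__ = [
    "CifError", "UnitCell", "SymOp", "AtomSite", "GeomBond", "CrystalEntry",
    "parse_cif", "parse_symop", "apply_symop", "fract_to_cartesian",
    "write_p1_cif", "strip_su", "parse_site_symmetry",
]


class CifError(ValueError):
    """Raised for malformed or incomplete CIF content."""


_SU_RE = re.compile(r"\(\d+\)\s*$")


def strip_su(value: str) -> float:
    """Convert a CIF number, dropping a parenthesised standard uncertainty."""
    v = value.strip()
    v = _SU_RE.sub("", v)
    try:
        return float(v)
    except ValueError as exc:
        raise CifError(f"not a CIF number: {value!r}") from exc


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise CifError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise CifError("cell angles must lie in (0, 180)")
        if np.linalg.det(self.orthogonalization_matrix()) <= 1e-9:
            raise CifError("degenerate unit cell")

    def orthogonalization_matrix(self) -> np.ndarray:
        """Fractional -> Cartesian matrix, a along x, b in the xy-plane."""
        al, be, ga = (math.radians(x) for x in (self.alpha, self.beta, self.gamma))
        cx = self.c * math.cos(be)
        cy = self.c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
        cz_sq = self.c ** 2 - cx ** 2 - cy ** 2
        if cz_sq <= 0:
            raise CifError("degenerate unit cell")
        return np.array([
            [self.a, self.b * math.cos(ga), cx],
            [0.0, self.b * math.sin(ga), cy],
            [0.0, 0.0, math.sqrt(cz_sq)],
        ])


def fract_to_cartesian(cell: UnitCell, fract) -> np.ndarray:
    """Orthogonalize fractional coordinates (Angstrom result)."""
    return cell.orthogonalization_matrix() @ np.asarray(fract, dtype=float)


_TERM_RE = re.compile(r"([+-]?)\s*([^+-]+)")


def _parse_component(expr: str) -> tuple[tuple[int, int, int], Fraction]:
    row = [0, 0, 0]
    trans = Fraction(0)
    expr = expr.strip().lower()
    if not expr:
        raise CifError("empty symmetry-operator component")
    for sign, term in _TERM_RE.findall(expr):
        s = -1 if sign == "-" else 1
        term = term.strip().replace(" ", "")
        if not term:
            raise CifError(f"malformed operator component: {expr!r}")
        axis = None
        for i, var in enumerate("xyz"):
            if var in term:
                axis = i
                coeff = term.replace(var, "") or "1"
                if coeff.startswith("*") or coeff.endswith("*"):
                    coeff = coeff.strip("*") or "1"
                try:
                    c = s * int(Fraction(coeff))
                except ValueError as exc:
                    raise CifError(f"nonlinear/malformed term: {term!r}") from exc
                if c not in (-1, 0, 1):
                    raise CifError(f"rotation entry out of range in {term!r}")
                row[axis] += c
                break
        if axis is None:
            try:
                trans += s * Fraction(term)
            except ValueError as exc:
                raise CifError(f"malformed constant term: {term!r}") from exc
    return tuple(row), trans % 1


@dataclass(frozen=True)
class SymOp:
    """A symmetry operator with exact integer rotation and rational shift."""

    rotation: tuple[tuple[int, int, int], ...]
    translation: tuple[Fraction, Fraction, Fraction]

    def __post_init__(self):
        if self.determinant not in (1, -1):
            raise CifError("symmetry operator rotation must have det +-1")
        for t in self.translation:
            if not 0 <= t < 1:
                raise CifError("translation components must lie in [0, 1)")

    @property
    def determinant(self) -> int:
        (a, b, c), (d, e, f), (g, h, i) = self.rotation
        return a * (e * i - f * h) - b * (d * i - f * g) + c * (d * h - e * g)

    def apply(self, fract, wrap: bool = False) -> np.ndarray:
        rot = np.array(self.rotation, dtype=float)
        tr = np.array([float(t) for t in self.translation])
        out = rot @ np.asarray(fract, dtype=float) + tr
        return out % 1.0 if wrap else out

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other (translation reduced mod 1)."""
        r1 = np.array(self.rotation, dtype=int)
        r2 = np.array(other.rotation, dtype=int)
        rot = r1 @ r2
        tr = tuple(
            (sum(Fraction(int(r1[i][j])) * other.translation[j] for j in range(3))
             + self.translation[i]) % 1
            for i in range(3)
        )
        return SymOp(tuple(tuple(int(x) for x in row) for row in rot), tr)

    def to_jones(self) -> str:
        parts = []
        for i in range(3):
            expr = ""
            for j, var in enumerate("xyz"):
                c = self.rotation[i][j]
                if c == 1:
                    expr += ("+" if expr else "") + var
                elif c == -1:
                    expr += "-" + var
            t = self.translation[i]
            if t:
                expr += ("+" if t > 0 and expr else "") + str(t)
            parts.append(expr or "0")
        return ",".join(parts)

    @property
    def is_identity(self) -> bool:
        return (self.rotation == ((1, 0, 0), (0, 1, 0), (0, 0, 1))
                and all(t == 0 for t in self.translation))


IDENTITY_OP = SymOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)),
                    (Fraction(0), Fraction(0), Fraction(0)))


def parse_symop(jones: str) -> SymOp:
    """Parse a Jones-faithful triplet like ``-x,y+1/2,-z``."""
    comps = jones.split(",")
    if len(comps) != 3:
        raise CifError(f"operator must have three components: {jones!r}")
    rows, trans = zip(*(_parse_component(c) for c in comps))
    return SymOp(tuple(rows), tuple(trans))


def apply_symop(op: SymOp, fract, wrap: bool = False) -> np.ndarray:
    return op.apply(fract, wrap=wrap)


@dataclass
class AtomSite:
    label: str
    element: str
    fract: np.ndarray
    occupancy: float = 1.0
    disorder_assembly: str | None = None
    disorder_group: str | None = None

    def __post_init__(self):
        self.fract = np.asarray(self.fract, dtype=float)
        if not 0 < self.occupancy <= 1 + 1e-9:
            raise CifError(f"occupancy out of (0, 1] for site {self.label!r}")


@dataclass
class GeomBond:
    label1: str
    label2: str
    distance: float | None = None
    site_symmetry_2: str = "."


@dataclass
class CrystalEntry:
    id: str
    cell: UnitCell
    symops: list[SymOp]
    sites: list[AtomSite]
    geom_bonds: list[GeomBond] = field(default_factory=list)
    z: int = 1
    space_group_name: str | None = None

    def __post_init__(self):
        if not self.symops:
            raise CifError("entry has no symmetry operators")
        if not any(op.is_identity for op in self.symops):
            raise CifError("symmetry operator list lacks the identity")
        if self.z < 1:
            raise CifError("Z must be >= 1")


def parse_site_symmetry(code: str, n_ops: int) -> tuple[int, np.ndarray]:
    """Decode an ``n_klm``-style site-symmetry code.

    Returns (0-based operator index, lattice shift).  "." and "1_555" both
    mean the identity with no shift.
    """
    code = code.strip()
    if code == ".":
        return 0, np.zeros(3)
    if "_" in code:
        n_str, klm = code.split("_", 1)
    else:
        n_str, klm = code, "555"
    try:
        n = int(n_str)
        if len(klm) != 3:
            raise ValueError
        shift = np.array([int(d) - 5 for d in klm], dtype=float)
    except ValueError as exc:
        raise CifError(f"bad site-symmetry code: {code!r}") from exc
    if not 1 <= n <= n_ops:
        raise CifError(f"operator index {n} out of range in code {code!r}")
    return n - 1, shift


_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")
_SG_NAME_TAGS = ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt",
                 "_symmetry_space_group_name_Hall")


def _block_value(block, tag):
    v = block.find_value(tag)
    if v is None:
        return None
    v = gemmi.cif.as_string(v) if v.startswith(("'", '"', ";")) else v
    return None if v in ("?", ".") else v


def parse_cif(text: str) -> list[CrystalEntry]:
    """Parse CIF text into one :class:`CrystalEntry` per data block."""
    try:
        doc = gemmi.cif.read_string(text)
    except (RuntimeError, ValueError) as exc:
        raise CifError(f"CIF parse error: {exc}") from exc
    entries = []
    for block in doc:
        entries.append(_parse_block(block))
    if not entries:
        raise CifError("no data blocks found")
    return entries


def _parse_block(block) -> CrystalEntry:
    def need(tag):
        v = _block_value(block, tag)
        if v is None:
            raise CifError(f"block {block.name!r}: missing {tag}")
        return v

    cell = UnitCell(
        strip_su(need("_cell_length_a")),
        strip_su(need("_cell_length_b")),
        strip_su(need("_cell_length_c")),
        strip_su(need("_cell_angle_alpha")),
        strip_su(need("_cell_angle_beta")),
        strip_su(need("_cell_angle_gamma")),
    )

    symops: list[SymOp] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        vals = [gemmi.cif.as_string(v) for v in col]
        if not vals:
            v = _block_value(block, tag)
            if v is not None:
                vals = [v]
        if vals:
            symops = [parse_symop(v) for v in vals]
            break
    if not symops:
        raise CifError(f"block {block.name!r}: no symmetry operators")

    z_raw = _block_value(block, "_cell_formula_units_Z")
    if z_raw is None:
        raise CifError(f"block {block.name!r}: missing _cell_formula_units_Z")
    z = int(round(strip_su(z_raw)))

    table = block.find("_atom_site_", [
        "label", "type_symbol", "fract_x", "fract_y", "fract_z",
        "?occupancy", "?disorder_assembly", "?disorder_group",
    ])
    if not table:
        raise CifError(f"block {block.name!r}: no atom-site loop")
    sites = []
    for row in table:
        label = gemmi.cif.as_string(row[0])
        try:
            element = normalize_element(gemmi.cif.as_string(row[1]))
        except ValueError as exc:
            raise CifError(f"site {label!r}: {exc}") from exc
        fract = np.array([strip_su(row[i]) for i in (2, 3, 4)])
        occ = 1.0
        if table.has_column(5):
            raw = gemmi.cif.as_string(row[5])
            if raw not in (".", "?", ""):
                occ = strip_su(raw)
        assembly = None
        if table.has_column(6):
            raw = gemmi.cif.as_string(row[6])
            assembly = None if raw in (".", "?", "") else raw
        group = None
        if table.has_column(7):
            raw = gemmi.cif.as_string(row[7])
            group = None if raw in (".", "?", "") else raw
        sites.append(AtomSite(label, element, fract, occ, assembly, group))

    bonds = []
    btab = block.find("_geom_bond_", [
        "atom_site_label_1", "atom_site_label_2", "?distance",
        "?site_symmetry_2",
    ])
    labels = {s.label for s in sites}
    for row in btab:
        l1 = gemmi.cif.as_string(row[0])
        l2 = gemmi.cif.as_string(row[1])
        if l1 not in labels or l2 not in labels:
            raise CifError(f"geom bond references unknown site: {l1!r}-{l2!r}")
        dist = None
        if btab.has_column(2):
            raw = gemmi.cif.as_string(row[2])
            if raw not in (".", "?", ""):
                dist = strip_su(raw)
        code = "."
        if btab.has_column(3):
            raw = gemmi.cif.as_string(row[3])
            if raw not in ("?", ""):
                code = raw
        bonds.append(GeomBond(l1, l2, dist, code))

    name = None
    for tag in _SG_NAME_TAGS:
        name = _block_value(block, tag)
        if name:
            break

    return CrystalEntry(block.name, cell, symops, sites, bonds, z, name)


def write_p1_cif(entry_id: str, atoms, cell: UnitCell,
                 comments: list[str] | None = None) -> str:
    """Serialize atoms (objects with label/element/fract) as a P 1 block."""
    lines = [f"data_{entry_id}"]
    for c in comments or []:
        lines.append(f"# {c}")
    lines += [
        f"_cell_length_a {cell.a:.6f}",
        f"_cell_length_b {cell.b:.6f}",
        f"_cell_length_c {cell.c:.6f}",
        f"_cell_angle_alpha {cell.alpha:.6f}",
        f"_cell_angle_beta {cell.beta:.6f}",
        f"_cell_angle_gamma {cell.gamma:.6f}",
        "_cell_formula_units_Z 1",
        "_symmetry_space_group_name_H-M 'P 1'",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
        "x,y,z",
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
    ]
    for a in atoms:
        occ = getattr(a, "occupancy", 1.0)
        lines.append(
            f"{a.label} {a.element} {a.fract[0]:.9f} {a.fract[1]:.9f} "
            f"{a.fract[2]:.9f} {occ:.4f}"
        )
    return "\n".join(lines) + "\n"
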