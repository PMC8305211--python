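"""All-atom 3D construction of CS oligosaccharides from idealized templates.

Each residue is built as a rigid template: an idealized 4C1 chair ring
(uniform ring bond lengths ~1.52 A, puckering amplitude 0.25 A) with
substituents placed in axial/equatorial slots according to the beta-D-
gluco (GlcA) or beta-D-galacto (GalNAc) configuration, hydrogens
included.  The unsaturated uronate (dUA) is modelled as a half-chair
with a C4=C5 double bond.

Residues are joined at the glycosidic bond by exact internal-coordinate
placement: the downstream residue is positioned so that the phi
(O5-C1-Ox'-Cx') and psi (C1-Ox'-Cx'-C(x-1)') dihedrals equal the mean
values of the torsion table, which by default holds the crystallographic
averages for the two CS linkage classes:

====================  ======  ======
linkage               phi     psi
====================  ======  ======
GlcA(1->3)GalNAc      -81     -129
GalNAc(1->4)GlcA      -69      131
====================  ======  ======

(degrees; half-widths 12/14 and 14/9 bound the flexibility a docking
run may explore).  Assembly is deterministic; a grid-search relaxation
of exocyclic group torsions relieves any steric clash, and an
unresolvable clash raises :class:`BuildClashError` rather than being
accepted silently.

Atom naming follows the usual carbohydrate convention: ring atoms
C1-C5/O5, exocyclic C6, hydroxyl oxygens O1-O6, carboxylate O6A/O6B,
N-acetyl N2/C7/O7/C8, and a sulfate at ring position p is named
``Sp`` with terminal oxygens ``O1Sp``, ``O2Sp``, ``O3Sp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .chemistry import CSSequence, MonosaccharideResidue, ResidueKind

__all__ = [
    "Structure3D",
    "TorsionTable",
    "LinkageTorsions",
    "DEFAULT_TORSIONS",
    "BuildClashError",
    "build_3d",
    "measure_torsion",
    "dihedral",
    "ring_pucker",
    "cremer_pople",
    "residue_template",
]

# Standard bond lengths (A) and angles (deg); generic organic values.
_B = {
    "CC": 1.52, "CO": 1.43, "CH": 1.09, "OH": 0.96, "CN": 1.47,
    "NC_amide": 1.335, "C=O": 1.23, "C-Ocarb": 1.25, "S-Oe": 1.60,
    "S-Ot": 1.45, "NH": 1.01,
}
_TET = 109.47
_GLYCOSIDIC_ANGLE = 117.0  # C1-O-Cx' bond angle at the bridging oxygen

RING_ATOMS = ("O5", "C1", "C2", "C3", "C4", "C5")


class BuildClashError(RuntimeError):
    """Raised when assembly leaves heavy atoms closer than the clash floor."""


# --------------------------------------------------------------------------
# basic vector geometry


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("zero-length vector")
    return v / n


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, _unit(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = -math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def _angle(p0, p1, p2) -> float:
    u = _unit(np.asarray(p0, float) - p1)
    v = _unit(np.asarray(p2, float) - p1)
    return math.degrees(math.acos(np.clip(np.dot(u, v), -1.0, 1.0)))


def nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d with given bond |cd|, angle b-c-d and dihedral a-b-c-d."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = math.radians(angle_deg)
    chi = math.radians(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _rotation_about_axis(p0: np.ndarray, p1: np.ndarray, angle_deg: float):
    """Return f(X) rotating points by angle about the axis through p0->p1."""
    axis = _unit(p1 - p0)
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)

    def apply(X: np.ndarray) -> np.ndarray:
        return (X - p0) @ R.T + p0

    return apply


# --------------------------------------------------------------------------
# Structure3D container


@dataclass
class Structure3D:
    """A molecule or complex: atoms, bonds and Cartesian coordinates in A.

    ``bonds`` holds ``(i, j, order)`` with order 1, 2 or the string
    ``"ar"`` (used for the delocalized S-O bonds of sulfate groups).
    ``meta`` carries builder annotations such as the glycosidic torsion
    quadruples of a built ligand.
    """

    elements: list[str]
    names: list[str]
    res_indices: list[int]
    res_codes: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int, object]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not (len(self.elements) == len(self.names) == len(self.res_indices)
                == len(self.res_codes) == len(self.coords)):
            raise ValueError("inconsistent atom array lengths")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements])

    def atom_index(self, res_index: int, name: str) -> int:
        for i, (ri, nm) in enumerate(zip(self.res_indices, self.names)):
            if ri == res_index and nm == name:
                return i
        raise KeyError(f"no atom {name!r} in residue {res_index}")

    def residue_atoms(self, res_index: int) -> list[int]:
        return [i for i, ri in enumerate(self.res_indices) if ri == res_index]

    @property
    def n_residues(self) -> int:
        return len(set(self.res_indices))

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def copy(self) -> "Structure3D":
        return Structure3D(
            list(self.elements), list(self.names), list(self.res_indices),
            list(self.res_codes), self.coords.copy(), list(self.bonds),
            dict(self.meta))


# --------------------------------------------------------------------------
# torsion table


@dataclass(frozen=True)
class LinkageTorsions:
    """Mean glycosidic dihedrals and allowed half-widths for one linkage class."""

    phi_mean: float
    psi_mean: float
    phi_halfwidth: float
    psi_halfwidth: float
    #: acceptor ring position: 3 for uronic(1->3)GalNAc, 4 for GalNAc(1->4)uronic
    acceptor_position: int

    @property
    def acceptor_oxygen(self) -> str:
        return f"O{self.acceptor_position}"

    @property
    def acceptor_carbon(self) -> str:
        return f"C{self.acceptor_position}"

    @property
    def psi_reference_carbon(self) -> str:
        return f"C{self.acceptor_position - 1}"


@dataclass(frozen=True)
class TorsionTable:
    """Per-linkage-class glycosidic torsion targets.

    Keys are ``"1->3"`` (uronic to GalNAc) and ``"1->4"`` (GalNAc to
    uronic).  Defaults are the crystallographic averages used for
    library construction.
    """

    link_1_3: LinkageTorsions = LinkageTorsions(-81.0, -129.0, 12.0, 14.0, 3)
    link_1_4: LinkageTorsions = LinkageTorsions(-69.0, 131.0, 14.0, 9.0, 4)

    def for_linkage(self, linkage: str) -> LinkageTorsions:
        if linkage in ("1->3", "(1->3)"):
            return self.link_1_3
        if linkage in ("1->4", "(1->4)"):
            return self.link_1_4
        raise KeyError(f"unknown linkage class {linkage!r}")


DEFAULT_TORSIONS = TorsionTable()


# --------------------------------------------------------------------------
# residue templates

# Puckering amplitude and ring radius chosen to give ring bonds of ~1.52 A.
_RING_Z = 0.25
_RING_R = 1.435

#: exocyclic substituent layout: carbon -> (equatorial atom, axial atom)
_SUB_LAYOUT = {
    ResidueKind.GlcA: {
        "C1": ("O1", "H1"), "C2": ("O2", "H2"), "C3": ("O3", "H3"),
        "C4": ("O4", "H4"), "C5": ("C6", "H5"),
    },
    ResidueKind.GalN: {
        "C1": ("O1", "H1"), "C2": ("N2", "H2"), "C3": ("O3", "H3"),
        "C4": ("H4", "O4"),  # galacto: axial O4
        "C5": ("C6", "H5"),
    },
    ResidueKind.dUA: {
        "C1": ("O1", "H1"), "C2": ("O2", "H2"), "C3": ("O3", "H3"),
    },
}

_ELEMENT_BY_INITIAL = {"C": "C", "O": "O", "N": "N", "H": "H", "S": "S"}


def _element_of(name: str) -> str:
    return _ELEMENT_BY_INITIAL[name[0]]


def _ring_coords(flatten_c4_c5: bool = False) -> dict[str, np.ndarray]:
    """Idealized chair (or half-chair) coordinates for O5,C1..C5."""
    coords = {}
    for j, name in enumerate(RING_ATOMS):
        ang = math.radians(60.0 * j)
        z = _RING_Z * (-1 if j % 2 == 0 else 1)
        coords[name] = np.array([_RING_R * math.cos(ang), _RING_R * math.sin(ang), z])
    if flatten_c4_c5:
        for name in ("C4", "C5"):
            coords[name] = coords[name] * np.array([1.0, 1.0, 0.0])
    return coords


def _exo_directions(p: np.ndarray, n1: np.ndarray, n2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """The two tetrahedral exocyclic unit vectors at a ring atom.

    Returns (equatorial, axial), distinguished by the |z| component in
    the template frame (the ring mean plane is z ~ 0).
    """
    u1 = _unit(n1 - p)
    u2 = _unit(n2 - p)
    bis = _unit(-(u1 + u2))
    perp = _unit(np.cross(u1, u2))
    half = math.radians(_TET / 2.0)
    d1 = bis * math.cos(half) + perp * math.sin(half)
    d2 = bis * math.cos(half) - perp * math.sin(half)
    if abs(d1[2]) >= abs(d2[2]):
        return d2, d1
    return d1, d2


class _ResBuilder:
    """Accumulates one residue's atoms/bonds during template construction."""

    def __init__(self) -> None:
        self.names: list[str] = []
        self.coords: list[np.ndarray] = []
        self.bonds: list[tuple[str, str, object]] = []

    def add(self, name: str, pos: np.ndarray, bond_to: str | None = None, order: object = 1) -> None:
        self.names.append(name)
        self.coords.append(np.asarray(pos, float))
        if bond_to is not None:
            self.bonds.append((bond_to, name, order))

    def pos(self, name: str) -> np.ndarray:
        return self.coords[self.names.index(name)]


def _attach_hydroxyl_h(b: _ResBuilder, ref: str, carbon: str, oxygen: str) -> None:
    b.add("H" + oxygen, nerf(b.pos(ref), b.pos(carbon), b.pos(oxygen), _B["OH"], 108.0, 180.0),
          bond_to=oxygen)


def _attach_sulfate(b: _ResBuilder, position: int, ref: str, carbon: str, oxygen: str) -> None:
    """Attach -OSO3 at an ester oxygen, orienting it away from the residue.

    The C-O-S torsion and the spin of the three terminal oxygens are
    chosen by a deterministic grid search maximizing the minimum
    distance to the already-placed heavy atoms, so sulfated templates
    start clash-free.
    """
    s_name = f"S{position}"
    exclude_s = {carbon, oxygen}
    heavy = np.array([
        b.coords[i] for i, nm in enumerate(b.names) if nm[0] != "H" and nm not in exclude_s
    ])

    def placement(tor: float, spin: float):
        s = nerf(b.pos(ref), b.pos(carbon), b.pos(oxygen), _B["S-Oe"], 118.0, tor)
        terms = [nerf(b.pos(carbon), b.pos(oxygen), s, _B["S-Ot"], 106.0, spin + k)
                 for k in (0.0, 120.0, 240.0)]
        group = np.vstack([s] + terms)
        d = np.linalg.norm(group[:, None, :] - heavy[None, :, :], axis=-1)
        return s, terms, float(d.min())

    best = None
    for tor in np.arange(60.0, 360.0, 15.0):
        for spin in np.arange(0.0, 120.0, 15.0):
            s, terms, score = placement(float(tor), float(spin))
            if best is None or score > best[2] + 1e-9:
                best = (s, terms, score)
    s, terms, _ = best
    b.add(s_name, s, bond_to=oxygen)
    for k, o in enumerate(terms, start=1):
        b.add(f"O{k}S{position}", o, bond_to=s_name, order="ar")


def _attach_carboxylate(b: _ResBuilder) -> None:
    # C6 carboxylate on C5 (already placed); O6A/O6B in the sp2 plane.
    o6a = nerf(b.pos("O5"), b.pos("C5"), b.pos("C6"), _B["C-Ocarb"], 117.0, 0.0)
    o6b = nerf(b.pos("O5"), b.pos("C5"), b.pos("C6"), _B["C-Ocarb"], 117.0, 180.0)
    b.add("O6A", o6a, bond_to="C6", order=2)
    b.add("O6B", o6b, bond_to="C6", order=1)


def _attach_hydroxymethyl(b: _ResBuilder, sulfated: bool) -> None:
    # C6 already placed from C5; add O6 (gt rotamer) and the two H6.
    o6 = nerf(b.pos("O5"), b.pos("C5"), b.pos("C6"), _B["CO"], _TET, 60.0)
    b.add("O6", o6, bond_to="C6")
    b.add("H61", nerf(b.pos("O5"), b.pos("C5"), b.pos("C6"), _B["CH"], _TET, 180.0), bond_to="C6")
    b.add("H62", nerf(b.pos("O5"), b.pos("C5"), b.pos("C6"), _B["CH"], _TET, 300.0), bond_to="C6")
    if sulfated:
        _attach_sulfate(b, 6, "C5", "C6", "O6")
    else:
        _attach_hydroxyl_h(b, "C5", "C6", "O6")


def _attach_n_acetyl(b: _ResBuilder) -> None:
    c7 = nerf(b.pos("C3"), b.pos("C2"), b.pos("N2"), _B["NC_amide"], 122.0, 180.0)
    b.add("C7", c7, bond_to="N2")
    b.add("HN2", nerf(b.pos("C3"), b.pos("C2"), b.pos("N2"), _B["NH"], 118.0, 0.0), bond_to="N2")
    b.add("O7", nerf(b.pos("C2"), b.pos("N2"), c7, _B["C=O"], 122.0, 0.0), bond_to="C7", order=2)
    c8 = nerf(b.pos("C2"), b.pos("N2"), c7, _B["CC"], 115.0, 180.0)
    b.add("C8", c8, bond_to="C7")
    for k, chi in enumerate((60.0, 180.0, 300.0), start=1):
        b.add(f"H8{k}", nerf(b.pos("N2"), c7, c8, _B["CH"], _TET, chi), bond_to="C8")


_TEMPLATE_CACHE: dict[MonosaccharideResidue, Structure3D] = {}


def residue_template(res: MonosaccharideResidue) -> Structure3D:
    """Build one residue in its local frame, hydrogens included.

    The template is rigid: assembly into a chain only rotates/translates
    it, so its internal geometry (ring pucker, substituent placement) is
    preserved exactly.  Only a handful of distinct residues exist, so
    templates are cached; callers receive an independent copy.
    """
    cached = _TEMPLATE_CACHE.get(res)
    if cached is not None:
        return cached.copy()
    out = _build_residue_template(res)
    _TEMPLATE_CACHE[res] = out
    return out.copy()


def _build_residue_template(res: MonosaccharideResidue) -> Structure3D:
    is_dua = res.kind is ResidueKind.dUA
    ring = _ring_coords(flatten_c4_c5=is_dua)
    b = _ResBuilder()
    prev = {"O5": "C5", "C1": "O5", "C2": "C1", "C3": "C2", "C4": "C3", "C5": "C4"}
    nxt = {"O5": "C1", "C1": "C2", "C2": "C3", "C3": "C4", "C4": "C5", "C5": "O5"}
    for j, name in enumerate(RING_ATOMS):
        b.add(name, ring[name], bond_to=None if j == 0 else RING_ATOMS[j - 1])
    b.bonds.append(("C5", "O5", 1))
    if is_dua:
        # replace the C4-C5 single bond with a double bond
        b.bonds = [(a, c, 2 if {a, c} == {"C4", "C5"} else o) for a, c, o in b.bonds]

    layout = _SUB_LAYOUT[res.kind]
    for carbon, (eq_name, ax_name) in layout.items():
        d_eq, d_ax = _exo_directions(ring[carbon], ring[prev[carbon]], ring[nxt[carbon]])
        for sub, d in ((eq_name, d_eq), (ax_name, d_ax)):
            elem = _element_of(sub)
            length = {"O": _B["CO"], "H": _B["CH"], "N": _B["CN"], "C": _B["CC"]}[elem]
            b.add(sub, ring[carbon] + d * length, bond_to=carbon)

    if is_dua:
        # sp2 centres of the 4,5-unsaturation: in-plane substituents
        for carbon, sub, length in (("C4", "H4", _B["CH"]), ("C5", "C6", _B["CC"])):
            u1 = _unit(ring[prev[carbon]] - ring[carbon])
            u2 = _unit(ring[nxt[carbon]] - ring[carbon])
            d = _unit(-(u1 + u2))
            b.add(sub, ring[carbon] + d * length, bond_to=carbon)

    # anomeric hydroxyl (replaced by the glycosidic bond on linkage)
    _attach_hydroxyl_h(b, "O5", "C1", "O1")

    # position-2 substituent
    if res.kind is ResidueKind.GalN:
        _attach_n_acetyl(b)
    elif "O2" in res.sulfation:
        _attach_sulfate(b, 2, "C1", "C2", "O2")
    else:
        _attach_hydroxyl_h(b, "C1", "C2", "O2")

    # position 3
    _attach_hydroxyl_h(b, "C2", "C3", "O3")

    # position 4
    if not is_dua:
        if "O4" in res.sulfation:
            _attach_sulfate(b, 4, "C3", "C4", "O4")
        else:
            _attach_hydroxyl_h(b, "C3", "C4", "O4")

    # position 6
    if res.kind.is_uronic:
        _attach_carboxylate(b)
    else:
        _attach_hydroxymethyl(b, sulfated="O6" in res.sulfation)

    name_to_idx = {n: i for i, n in enumerate(b.names)}
    bonds = [(name_to_idx[x], name_to_idx[y], o) for x, y, o in b.bonds]
    code = res.code()
    return Structure3D(
        elements=[_element_of(n) for n in b.names],
        names=list(b.names),
        res_indices=[0] * len(b.names),
        res_codes=[code] * len(b.names),
        coords=np.array(b.coords),
        bonds=bonds,
    )


# --------------------------------------------------------------------------
# assembly


def _superpose_triplet(X_src: np.ndarray, X_dst: np.ndarray):
    """Exact rigid map taking three source points onto three congruent targets."""
    from scipy.spatial.transform import Rotation

    c_src = X_src.mean(axis=0)
    c_dst = X_dst.mean(axis=0)
    rot, _ = Rotation.align_vectors(X_dst - c_dst, X_src - c_src)

    def apply(P: np.ndarray) -> np.ndarray:
        return rot.apply(P - c_src) + c_dst

    return apply


def _clash_pairs(s: Structure3D, floor: float = 2.0) -> list[tuple[int, int, float]]:
    """Non-bonded heavy-atom pairs closer than the clash floor."""
    heavy = np.flatnonzero(s.heavy_mask())
    X = s.coords[heavy]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    ii, jj = np.triu_indices(len(heavy), k=1)
    close = d[ii, jj] < floor
    bonded = {(min(a, b), max(a, b)) for a, b, _ in s.bonds}
    out = []
    for a, c in zip(ii[close], jj[close]):
        i, j = int(heavy[a]), int(heavy[c])
        if (min(i, j), max(i, j)) not in bonded:
            out.append((i, j, float(d[a, c])))
    return out


def _rotatable_groups(s: Structure3D) -> list[tuple[int, int, list[int]]]:
    """Exocyclic groups that may be spun to relieve clashes.

    Each entry is (axis_atom_0, axis_atom_1, moving atom indices).
    """
    groups = []
    for ri in sorted(set(s.res_indices)):
        idx = {s.names[i]: i for i in s.residue_atoms(ri)}
        for pos in (2, 4, 6):
            sname = f"S{pos}"
            if sname in idx:
                carbon = idx.get(f"C{pos}")
                oxy = idx.get(f"O{pos}")
                terms = [idx[f"O{k}S{pos}"] for k in (1, 2, 3)]
                groups.append((carbon, oxy, [idx[sname]] + terms))
                # spin of the terminal oxygens about the ester O-S bond
                groups.append((oxy, idx[sname], terms))
        if "C7" in idx:  # N-acetyl about the C2-N2 bond
            moving = [idx[n] for n in ("C7", "O7", "C8", "H81", "H82", "H83", "HN2") if n in idx]
            groups.append((idx["C2"], idx["N2"], moving))
        if "O6" in idx and "C6" in idx:  # hydroxymethyl about C5-C6
            moving = [idx[n] for n in idx if n in ("O6", "H61", "H62", "HO6", "S6", "O1S6", "O2S6", "O3S6")]
            groups.append((idx["C5"], idx["C6"], moving))
    return groups


def _min_nonbonded_distance(s: Structure3D) -> float:
    heavy = np.flatnonzero(s.heavy_mask())
    pos_of = {int(i): k for k, i in enumerate(heavy)}
    X = s.coords[heavy]
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    d[np.tril_indices_from(d)] = np.inf
    for a, b, _ in s.bonds:
        if a in pos_of and b in pos_of:
            i, j = sorted((pos_of[a], pos_of[b]))
            d[i, j] = np.inf
    return float(d.min())


def _relieve_clashes(s: Structure3D, floor: float = 2.0, step: float = 30.0, passes: int = 3) -> None:
    """Greedy grid search over exocyclic torsions until no heavy clash remains."""
    if not _clash_pairs(s, floor):
        return
    groups = _rotatable_groups(s)
    for _ in range(passes):
        for a0, a1, moving in groups:
            if a0 is None or a1 is None or not moving:
                continue
            best_angle = 0.0
            best_score = _min_nonbonded_distance(s)
            base = s.coords[moving].copy()
            for ang in np.arange(step, 360.0, step):
                rot = _rotation_about_axis(s.coords[a0], s.coords[a1], float(ang))
                s.coords[moving] = rot(base)
                score = _min_nonbonded_distance(s)
                if score > best_score + 1e-9:
                    best_score = score
                    best_angle = float(ang)
            rot = _rotation_about_axis(s.coords[a0], s.coords[a1], best_angle)
            s.coords[moving] = rot(base)
        if not _clash_pairs(s, floor):
            return
    remaining = _clash_pairs(s, floor)
    if remaining:
        worst = min(remaining, key=lambda p: p[2])
        raise BuildClashError(
            f"unresolvable clash: atoms {worst[0]} and {worst[1]} at {worst[2]:.2f} A")


def build_3d(seq: CSSequence, torsions: TorsionTable = DEFAULT_TORSIONS) -> Structure3D:
    """Build all-atom coordinates for a sequence at the table's mean torsions.

    The output carries ``meta["linkages"]``: for each glycosidic bond a
    dict with the phi/psi atom-index quadruples, the linkage class, and
    the indices of the downstream atoms (used by the docking engine to
    flex the linkage within its allowed window).  Deterministic: a given
    sequence always yields bit-identical coordinates.
    """
    templates = [residue_template(r) for r in seq.residues]

    placed: list[dict] = []  # per residue: {"t": Structure3D, "drop": set of names}
    placed.append({"t": templates[0].copy(), "drop": set()})
    linkage_meta = []

    for i in range(1, len(seq.residues)):
        donor_res = seq.residues[i - 1]
        link = "1->3" if donor_res.kind.is_uronic else "1->4"
        lt = torsions.for_linkage(link)
        donor = placed[i - 1]["t"]
        di = {donor.names[k]: k for k in range(donor.n_atoms)}
        o5 = donor.coords[di["O5"]]
        c1 = donor.coords[di["C1"]]
        o1 = donor.coords[di["O1"]]

        t = templates[i].copy()
        ti = {t.names[k]: k for k in range(t.n_atoms)}
        og_name = lt.acceptor_oxygen
        cg_name = lt.acceptor_carbon
        cr_name = lt.psi_reference_carbon
        og_l, cg_l, cr_l = (t.coords[ti[n]] for n in (og_name, cg_name, cr_name))

        # target glycosidic-oxygen position: along the donor's anomeric O1
        # direction, so the O5-C1-O bond angle is inherited from the template
        og_t = c1 + np.linalg.norm(o1 - c1) * _unit(o1 - c1)
        cg_t = nerf(o5, c1, og_t, float(np.linalg.norm(cg_l - og_l)),
                    _GLYCOSIDIC_ANGLE, lt.phi_mean)
        cr_t = nerf(c1, og_t, cg_t, float(np.linalg.norm(cr_l - cg_l)),
                    _angle(og_l, cg_l, cr_l), lt.psi_mean)

        xform = _superpose_triplet(np.array([og_l, cg_l, cr_l]),
                                   np.array([og_t, cg_t, cr_t]))
        t.coords = xform(t.coords)

        placed[i - 1]["drop"].update({"O1", "HO1"})
        placed.append({"t": t, "drop": {"H" + og_name}})
        linkage_meta.append({
            "linkage": link,
            "donor_res": i - 1,
            "acceptor_res": i,
            "phi_atoms": ("O5", "C1", og_name, cg_name),
            "psi_atoms": ("C1", og_name, cg_name, cr_name),
        })

    # concatenate, applying deletions
    elements, names, res_indices, res_codes, coords, bonds = [], [], [], [], [], []
    keep_index: list[dict[str, int]] = []
    offset = 0
    for ri, entry in enumerate(placed):
        t, drop = entry["t"], entry["drop"]
        local_map = {}
        for k in range(t.n_atoms):
            if t.names[k] in drop:
                continue
            local_map[t.names[k]] = offset
            elements.append(t.elements[k])
            names.append(t.names[k])
            res_indices.append(ri)
            res_codes.append(t.res_codes[k])
            coords.append(t.coords[k])
            offset += 1
        for a, b_, o in t.bonds:
            na, nb = t.names[a], t.names[b_]
            if na in drop or nb in drop:
                continue
            bonds.append((local_map[na], local_map[nb], o))
        keep_index.append(local_map)

    s = Structure3D(elements, names, res_indices, res_codes, np.array(coords), bonds)

    # glycosidic bonds + index-resolved torsion metadata
    resolved = []
    for lm in linkage_meta:
        d, a = lm["donor_res"], lm["acceptor_res"]
        c1_i = keep_index[d]["C1"]
        og_i = keep_index[a][lm["phi_atoms"][2]]
        s.bonds.append((c1_i, og_i, 1))
        phi_idx = (keep_index[d]["O5"], c1_i, og_i, keep_index[a][lm["phi_atoms"][3]])
        psi_idx = (c1_i, og_i, keep_index[a][lm["psi_atoms"][2]], keep_index[a][lm["psi_atoms"][3]])
        downstream = [k for k in range(s.n_atoms) if s.res_indices[k] > d]
        lt = torsions.for_linkage(lm["linkage"])
        resolved.append({
            "linkage": lm["linkage"],
            "phi_atoms": phi_idx,
            "psi_atoms": psi_idx,
            "phi_mean": lt.phi_mean,
            "psi_mean": lt.psi_mean,
            "phi_halfwidth": lt.phi_halfwidth,
            "psi_halfwidth": lt.psi_halfwidth,
            "downstream": downstream,
        })
    s.meta["linkages"] = resolved
    s.meta["sequence_name"] = seq.name

    _relieve_clashes(s)
    return s


# --------------------------------------------------------------------------
# measurement


def _resolve_atom(s: Structure3D, ref) -> int:
    if isinstance(ref, (int, np.integer)):
        return int(ref)
    res_index, name = ref
    return s.atom_index(res_index, name)


def measure_torsion(s: Structure3D, quad) -> float:
    """Signed dihedral (degrees) over four atoms given by index or (res, name)."""
    idx = [_resolve_atom(s, r) for r in quad]
    if len(set(idx)) != 4:
        raise ValueError("torsion requires four distinct atoms")
    return dihedral(*(s.coords[i] for i in idx))


def cremer_pople(ring_coords: np.ndarray) -> tuple[float, float, float]:
    """Cremer-Pople puckering (Q, theta, phi2) for a six-membered ring.

    ``ring_coords`` must be ordered O5, C1, C2, C3, C4, C5 (the standard
    pyranose convention).  Q in A; theta, phi2 in degrees.
    """
    X = np.asarray(ring_coords, float)
    if X.shape != (6, 3):
        raise ValueError("expected six ring atoms")
    X = X - X.mean(axis=0)
    j = np.arange(6)
    R1 = (X * np.sin(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    R2 = (X * np.cos(2 * np.pi * j / 6)[:, None]).sum(axis=0)
    n = _unit(np.cross(R1, R2))
    z = X @ n
    q2c = math.sqrt(1 / 3) * float((z * np.cos(4 * np.pi * j / 6)).sum())
    q2s = -math.sqrt(1 / 3) * float((z * np.sin(4 * np.pi * j / 6)).sum())
    q3 = math.sqrt(1 / 6) * float((z * (-1.0) ** j).sum())
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)
    if Q < 1e-9:
        return 0.0, float("nan"), 0.0
    theta = math.degrees(math.acos(np.clip(q3 / Q, -1, 1)))
    phi2 = math.degrees(math.atan2(q2s, q2c)) % 360.0
    return Q, theta, phi2


def ring_pucker(s: Structure3D, res_index: int) -> tuple[float, float, float, str]:
    """Puckering parameters and conformer label for one residue's ring.

    Label "4C1" for theta <= 30 deg, "1C4" for theta >= 150 deg,
    "planar" for near-zero total puckering amplitude, "other" otherwise.
    """
    try:
        idx = [s.atom_index(res_index, n) for n in RING_ATOMS]
    except KeyError as e:
        raise ValueError(f"residue {res_index} lacks a six-membered ring") from e
    Q, theta, phi2 = cremer_pople(s.coords[idx])
    if Q < 0.15:
        label = "planar"
    elif theta <= 30.0:
        label = "4C1"
    elif theta >= 150.0:
        label = "1C4"
    else:
        label = "other"
    return Q, theta, phi2, label


def end_to_end_heavy_distance(s: Structure3D) -> float:
    """Distance between the anomeric C1 of the first and last residues."""
    rids = sorted(set(s.res_indices))
    a = s.atom_index(rids[0], "C1")
    b = s.atom_index(rids[-1], "C1")
    return float(np.linalg.norm(s.coords[a] - s.coords[b]))
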