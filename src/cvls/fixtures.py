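"""Deterministic synthetic fixtures for tests, demos and benchmarks.

Nothing here is derived from an experimental structure: the toy pocket
is a synthetic stand-in for a GAG-binding protein surface (a shell of
donor-bearing "residues" around a central cavity), and the planted
trajectories realize H-bond and water-bridge events with known, exact
occupancies by construction.  Reference tables of published screen
outcomes (sequence names, pose-consistency RMSDs, sulfate counts,
docking scores, glycosidic torsions) ship as TSV transcriptions for
filter and nomenclature tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Structure3D, build_3d
from .chemistry import parse_name
from .md import Trajectory, write_trajectory

__all__ = [
    "ToyPocket",
    "PlantedTrajectorySpec",
    "make_toy_pocket",
    "make_planted_trajectory",
    "make_ligand_trajectory",
    "load_reference_tables",
]


# --------------------------------------------------------------------------
# toy receptor pocket


@dataclass
class ToyPocket:
    """A synthetic mini-receptor: donor residues on a hemispherical shell.

    The cavity center (the planted ligand position) is the origin; the
    metadata records it together with the shell radius and the donor
    residue ids, so tests can assert pose containment.
    """

    receptor: Structure3D
    center: np.ndarray
    radius: float
    donor_residues: tuple[int, ...]
    seed: int


def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """n deterministic, roughly uniform unit vectors with z <= 0."""
    pts = []
    golden = math.pi * (3.0 - math.sqrt(5.0))
    for k in range(n):
        z = -(k + 0.5) / n          # in (-1, 0)
        r = math.sqrt(max(0.0, 1.0 - z * z))
        th = golden * k
        pts.append((r * math.cos(th), r * math.sin(th), z))
    return np.array(pts)


def make_toy_pocket(seed: int = 1, n_basic: int = 8, radius: float = 8.0,
                    out_path=None) -> ToyPocket:
    """Generate the synthetic pocket; regeneration with one seed is identical.

    Donor residues (ammonium-like N with three H pointing into the
    cavity, a carbon anchor behind) alternate with acceptor residues
    (carboxylate-like O pairs) on a hemispherical shell of the given
    radius; the cavity at the center is empty.
    """
    rng = np.random.default_rng(seed)
    n_acceptor = max(2, n_basic // 2)
    dirs = _fibonacci_hemisphere(n_basic + n_acceptor)
    jitter = rng.normal(scale=0.15, size=dirs.shape)
    dirs = np.array([d / np.linalg.norm(d) for d in dirs + jitter])

    elements, names, res_indices, res_codes, coords, bonds = [], [], [], [], [], []

    def add_atom(element, name, rid, rcode, xyz):
        elements.append(element)
        names.append(name)
        res_indices.append(rid)
        res_codes.append(rcode)
        coords.append(np.asarray(xyz, float))
        return len(names) - 1

    donor_ids = []
    rid = 0
    for k, d in enumerate(dirs):
        rid += 1
        outward = d
        inward = -d
        # local tangent frame for spreading hydrogens
        t1 = np.cross(outward, [0.0, 0.0, 1.0])
        if np.linalg.norm(t1) < 1e-6:
            t1 = np.cross(outward, [1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(outward, t1)
        if k < n_basic:
            donor_ids.append(rid)
            cb = add_atom("C", "CB", rid, "LYS", outward * (radius + 1.45))
            nz = add_atom("N", "NZ", rid, "LYS", outward * radius)
            bonds.append((cb, nz, 1))
            for m in range(3):
                ang = 2.0 * math.pi * m / 3.0
                hdir = inward * math.cos(0.35) + (t1 * math.cos(ang) + t2 * math.sin(ang)) * math.sin(0.35)
                h = add_atom("H", f"HZ{m + 1}", rid, "LYS", outward * radius + hdir * 1.01)
                bonds.append((nz, h, 1))
        else:
            cg = add_atom("C", "CG", rid, "ASP", outward * (radius + 1.3))
            od1 = add_atom("O", "OD1", rid, "ASP", outward * radius + t1 * 1.1)
            od2 = add_atom("O", "OD2", rid, "ASP", outward * radius - t1 * 1.1)
            bonds.append((cg, od1, "ar"))
            bonds.append((cg, od2, "ar"))

    receptor = Structure3D(elements, names, res_indices, res_codes,
                           np.array(coords), bonds)
    receptor.meta["planted_center"] = [0.0, 0.0, 0.0]
    receptor.meta["radius"] = radius
    receptor.meta["donor_residues"] = donor_ids
    receptor.meta["seed"] = seed
    pocket = ToyPocket(receptor, np.zeros(3), radius, tuple(donor_ids), seed)
    if out_path is not None:
        from .structio import write_structure
        write_structure(receptor, out_path, fmt="pdb")
    return pocket


def make_hbond_cage(ligand: Structure3D, max_sites: int = 12) -> tuple[Structure3D, np.ndarray]:
    """A receptor cage whose docking optimum is the ligand's build pose.

    For each ligand acceptor oxygen a donor group (C-N-H, aimed at the
    acceptor at ideal H-bond geometry) is placed radially outward; for
    each ligand hydroxyl an acceptor oxygen is placed along the O-H
    direction.  The global score optimum is therefore the ligand exactly
    at its input coordinates, which are returned as the planted pose.
    """
    from .engine import _type_polar

    polar = _type_polar(ligand)
    heavy = ligand.coords[ligand.heavy_mask()]
    ctr = heavy.mean(axis=0)
    elements, names, resi, resc, coords, bonds = [], [], [], [], [], []
    rid = 0

    def radial(a: np.ndarray) -> np.ndarray:
        d = a - ctr
        n = np.linalg.norm(d)
        return d / n if n > 1e-6 else np.array([1.0, 0.0, 0.0])

    def clear(points: list[np.ndarray], anchor: np.ndarray) -> bool:
        """Probe atoms must not bump the ligand (other than its anchor site)
        or previously placed cage atoms."""
        for p in points:
            dl = np.linalg.norm(heavy - p, axis=1)
            dl = dl[np.linalg.norm(heavy - anchor, axis=1) > 1e-6]
            if dl.size and dl.min() < 2.7:
                return False
            if coords and np.linalg.norm(np.array(coords) - p, axis=1).min() < 2.5:
                return False
        return True

    n_placed = 0
    for i in [j for j in polar.acceptors if ligand.elements[j] == "O"]:
        if n_placed >= max_sites:
            break
        a = ligand.coords[i]
        d = radial(a)
        n_pos = a + d * 2.9
        c_pos = n_pos + d * 1.45
        if not clear([n_pos, c_pos], a):
            continue
        rid += 1
        n_placed += 1
        ci = len(names)
        elements += ["C", "N", "H"]
        names += ["CB", "NZ", "HZ1"]
        resi += [rid] * 3
        resc += ["LYS"] * 3
        coords += [c_pos, n_pos, n_pos - d * 1.01]
        bonds += [(ci, ci + 1, 1), (ci + 1, ci + 2, 1)]
    n_placed = 0
    for dh, h in polar.donors:
        if n_placed >= max_sites:
            break
        o = ligand.coords[dh]
        hd = ligand.coords[h] - o
        hd /= np.linalg.norm(hd)
        o_pos = o + hd * 2.9
        c_pos = o + hd * (2.9 + 1.3)
        if not clear([o_pos, c_pos], o):
            continue
        rid += 1
        n_placed += 1
        oi = len(names)
        elements += ["O", "C"]
        names += ["OD1", "CG"]
        resi += [rid] * 2
        resc += ["ASP"] * 2
        coords += [o_pos, c_pos]
        bonds += [(oi, oi + 1, "ar")]

    receptor = Structure3D(elements, names, resi, resc, np.array(coords), bonds)
    receptor.meta["planted_center"] = ctr.tolist()
    return receptor, ligand.coords.copy()


# --------------------------------------------------------------------------
# planted trajectories


@dataclass(frozen=True)
class PlantedTrajectorySpec:
    """Recipe for a trajectory with exactly known occupancies.

    ``direct_fractions[k]`` is the occupancy planted for the k-th
    protein-donor/ligand-acceptor pair; ``bridge_fractions[k]`` for the
    k-th water bridge.  Every fraction times ``n_frames`` must be an
    integer — the construction realizes the fractions exactly.  With
    ``jitter`` > 0, a small seeded positional noise is added that keeps
    every planted geometry within (or outside) the criteria.
    """

    n_frames: int = 10
    direct_fractions: tuple[float, ...] = (0.7,)
    bridge_fractions: tuple[float, ...] = ()
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        for f in (*self.direct_fractions, *self.bridge_fractions):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must be in [0, 1]")
            if abs(f * self.n_frames - round(f * self.n_frames)) > 1e-9:
                raise ValueError("fraction x n_frames must be an integer")


_BOUND_D = 2.8     # planted heavy-heavy distance (qualifies at <= 3.0)
_UNBOUND_D = 8.0   # displaced distance (never qualifies)


def make_planted_trajectory(spec: PlantedTrajectorySpec, out_path=None) -> Trajectory:
    """Construct the trajectory; occupancies equal the planted fractions.

    Layout: pair k lives at x-offset 25k A so pairs cannot cross-talk.
    Direct pair: a serine-like donor (OG-HG, resid 10+k, resname PRD)
    and a ligand acceptor oxygen (resid 100+k, resname LIG).  Bridge k:
    a protein acceptor (resid 200+k, PRB), a water (O-H1-H2, resid
    300+k, HOH) and a ligand acceptor (resid 400+k, LIG).
    """
    rng = np.random.default_rng(spec.seed)
    names, elements, res_indices, res_names = [], [], [], []
    base = []  # per atom: (anchor xyz, role)

    def add(name, element, rid, rname, xyz):
        names.append(name)
        elements.append(element)
        res_indices.append(rid)
        res_names.append(rname)
        base.append(np.asarray(xyz, float))
        return len(names) - 1

    movers = []  # (atom indices, bound_offset, unbound_offset, schedule)

    def schedule(fraction: float) -> np.ndarray:
        k = round(fraction * spec.n_frames)
        return np.array([f < k for f in range(spec.n_frames)])

    for k, frac in enumerate(spec.direct_fractions):
        org = np.array([25.0 * k, 0.0, 0.0])
        og = add("OG", "O", 10 + k, "PRD", org)
        add("HG", "H", 10 + k, "PRD", org + [0.96, 0.0, 0.0])
        # acceptor on the +x axis: D-H-A angle exactly 180 when bound
        acc = add("O1", "O", 100 + k, "LIG", org + [_BOUND_D, 0.0, 0.0])
        movers.append(([acc], np.zeros(3), np.array([_UNBOUND_D - _BOUND_D, 0.0, 3.0]),
                       schedule(frac)))

    for k, frac in enumerate(spec.bridge_fractions):
        org = np.array([25.0 * k, 40.0, 0.0])
        add("O", "O", 200 + k, "PRB", org)  # protein acceptor
        wo = org + [_BOUND_D, 0.0, 0.0]
        w = add("OW", "O", 300 + k, "HOH", wo)
        add("HW1", "H", 300 + k, "HOH", wo + [-0.96, 0.0, 0.0])   # toward protein O
        add("HW2", "H", 300 + k, "HOH", wo + [0.96, 0.0, 0.0])    # toward ligand O
        lig = add("O1", "O", 400 + k, "LIG", wo + [_BOUND_D, 0.0, 0.0])
        movers.append(([w, w + 1, w + 2], np.zeros(3),
                       np.array([0.0, _UNBOUND_D, 0.0]), schedule(frac)))
        del lig

    X = np.tile(np.array(base), (spec.n_frames, 1, 1))
    for atoms, on_off, off_off, sched in movers:
        for f in range(spec.n_frames):
            X[f, atoms] += on_off if sched[f] else off_off
    if spec.jitter > 0.0:
        X = X + rng.normal(scale=spec.jitter, size=X.shape)

    traj = Trajectory(names, elements, res_indices, res_names, X)
    if out_path is not None:
        write_trajectory(traj, out_path)
    return traj


def make_ligand_trajectory(sequence_name: str, n_frames: int = 5,
                           drift_per_frame: float = 0.5, jitter: float = 0.0,
                           seed: int = 0, out_path=None) -> Trajectory:
    """A semi-rigid built oligosaccharide drifting through space.

    Useful for end-to-end-distance and RMSD-series tests: with zero
    jitter the ligand moves as a rigid body, so its EED series is
    constant and its unfitted RMSD grows linearly with the drift.
    """
    s = build_3d(parse_name(sequence_name))
    rng = np.random.default_rng(seed)
    frames = []
    for f in range(n_frames):
        X = s.coords + np.array([drift_per_frame * f, 0.0, 0.0])
        if jitter > 0.0:
            X = X + rng.normal(scale=jitter, size=X.shape)
        frames.append(X)
    traj = Trajectory(list(s.names), list(s.elements),
                      [r + 1 for r in s.res_indices],
                      ["CSL"] * s.n_atoms, np.array(frames))
    if out_path is not None:
        write_trajectory(traj, out_path)
    return traj


# --------------------------------------------------------------------------
# reference tables


def load_reference_tables() -> dict[str, pd.DataFrame]:
    """Published screen outcomes and torsion averages, as packaged TSVs.

    Keys: ``disaccharides`` (the CS02 hits), ``tetrasaccharides``,
    ``hexasaccharides`` (per-site hits with consistency RMSD, sulfate
    count and docking score) and ``torsions`` (per-linkage phi/psi).
    The docking scores are reference data from a proprietary scorer and
    are used only as filter-test inputs, never as expected outputs of
    this package's surrogate scorer.
    """
    out = {}
    pkg = resources.files("cvls.data")
    for key, fname in (
        ("disaccharides", "cs02_hits.tsv"),
        ("tetrasaccharides", "cs04_hits.tsv"),
        ("hexasaccharides", "cs06_hits.tsv"),
        ("torsions", "linkage_torsions.tsv"),
    ):
        with resources.as_file(pkg / fname) as p:
            out[key] = pd.read_csv(p, sep="\t")
    return out
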