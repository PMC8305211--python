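"""Trajectory post-processing: RMSD series, end-to-end distance, H-bond
and water-bridge occupancies.

Occupancy analysis follows the CPPTRAJ-style geometric criterion: a
donor--acceptor pair forms a hydrogen bond in a frame when the
heavy-atom distance is at most 3.0 A and the donor-H-acceptor angle is
at least 135 degrees.  Occupancy is the fraction of frames in which a
pair (aggregated per protein residue) forms at least one qualifying
bond.  A water bridge exists in a frame when one and the same water
molecule forms qualifying H-bonds (in either donor/acceptor role) to a
protein residue and to the ligand simultaneously.

Trajectories are multi-model PDB files read through MDAnalysis; frames
share one topology.  Hydrogens must be present — there is no
heavy-atom-only approximation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "HBondCriteria",
    "read_trajectory",
    "write_trajectory",
    "rmsd_series",
    "end_to_end_distance",
    "hbond_occupancy",
    "water_bridge_occupancy",
]


@dataclass
class Trajectory:
    """Frames of one topology: per-atom metadata plus (n_frames, n_atoms, 3)."""

    names: list[str]
    elements: list[str]
    res_indices: list[int]
    res_names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.coords.shape[1] != len(self.names):
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select_resnames(self, resnames: Iterable[str]) -> np.ndarray:
        wanted = set(resnames)
        return np.array([i for i, rn in enumerate(self.res_names) if rn in wanted], dtype=int)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric hydrogen-bond criteria (heavy-atom distance, D-H-A angle)."""

    distance_cutoff: float = 3.0
    angle_cutoff: float = 135.0

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0:
            raise ValueError("distance cutoff must be positive")
        if not (0.0 < self.angle_cutoff <= 180.0):
            raise ValueError("angle cutoff must be in (0, 180]")


# --------------------------------------------------------------------------
# I/O


def read_trajectory(path) -> Trajectory:
    """Read a (multi-model) PDB trajectory.

    Models must share an atom count; MDAnalysis enforces the shared
    topology and we surface its failure as a ValueError.
    """
    import warnings

    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
            coords = np.array([u.atoms.positions.copy() for _ in u.trajectory], dtype=float)
    except Exception as e:  # inconsistent models, malformed file
        raise ValueError(f"could not read trajectory {path}: {e}") from e
    names = [a.name for a in u.atoms]
    try:
        elements = [str(e).capitalize() for e in u.atoms.elements]
    except Exception:
        from .structio import _guess_element
        elements = [_guess_element(n) for n in names]
    res_indices = [int(a.resid) for a in u.atoms]
    res_names = [a.resname for a in u.atoms]
    return Trajectory(names, elements, res_indices, res_names, coords)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    lines = []
    for f in range(traj.n_frames):
        lines.append(f"MODEL     {f + 1:4d}")
        for i in range(traj.n_atoms):
            name = traj.names[i]
            pdb_name = name if len(name) >= 4 else f" {name:<3s}"
            x, y, z = traj.coords[f, i]
            lines.append(
                f"ATOM  {i + 1:5d} {pdb_name:<4s}{traj.res_names[i]:>4s} "
                f"A{traj.res_indices[i]:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{traj.elements[i]:>2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# geometry series


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rotation R and centroids aligning P onto Q (least squares)."""
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, cp, cq


def rmsd_series(traj: Trajectory, selection: Sequence[int],
                reference_frame: int = 0,
                fit_selection: Sequence[int] | None = None) -> np.ndarray:
    """Per-frame RMSD of a selection against a reference frame.

    With ``fit_selection`` each frame is first least-squares superposed
    onto the reference using those atoms (e.g. fit on protein, report
    the ligand).  Without it, raw coordinate deviations are reported.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size == 0:
        raise ValueError("empty selection")
    ref = traj.coords[reference_frame]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        X = traj.coords[f]
        if fit_selection is not None:
            fit = np.asarray(fit_selection, dtype=int)
            R, cp, cq = _kabsch(X[fit], ref[fit])
            X = (X - cp) @ R.T + cq
        diff = X[sel] - ref[sel]
        out[f] = math.sqrt(float(np.mean(np.sum(diff * diff, axis=-1))))
    return out


def end_to_end_distance(traj: Trajectory, ligand_selection: Sequence[int],
                        terminal_rule: str = "anomeric") -> np.ndarray:
    """Per-frame end-to-end distance of an oligosaccharide ligand.

    ``terminal_rule="anomeric"`` (default) measures between the anomeric
    C1 atoms of the first and last ligand residues; ``"centroid"`` uses
    the heavy-atom centroids of the terminal residues instead.  Which
    atoms bound the distance is a convention of this package — pick the
    rule that matches the analysis you are comparing to.
    """
    sel = np.asarray(ligand_selection, dtype=int)
    resids = sorted({traj.res_indices[i] for i in sel})
    if len(resids) < 2:
        raise ValueError("ligand must span at least two residues")
    first, last = resids[0], resids[-1]
    if terminal_rule == "anomeric":
        try:
            a = next(i for i in sel if traj.res_indices[i] == first and traj.names[i] == "C1")
            b = next(i for i in sel if traj.res_indices[i] == last and traj.names[i] == "C1")
        except StopIteration as e:
            raise ValueError("terminal residues lack C1 atoms; "
                             "use terminal_rule='centroid'") from e
        return np.linalg.norm(traj.coords[:, a, :] - traj.coords[:, b, :], axis=-1)
    if terminal_rule == "centroid":
        ia = [i for i in sel if traj.res_indices[i] == first and traj.elements[i] != "H"]
        ib = [i for i in sel if traj.res_indices[i] == last and traj.elements[i] != "H"]
        ca = traj.coords[:, ia, :].mean(axis=1)
        cb = traj.coords[:, ib, :].mean(axis=1)
        return np.linalg.norm(ca - cb, axis=-1)
    raise ValueError(f"unknown terminal rule {terminal_rule!r}")


# --------------------------------------------------------------------------
# hydrogen bonds


def _attached_h(traj: Trajectory, frame: int = 0) -> dict[int, list[int]]:
    """heavy atom -> bonded hydrogens, inferred from frame geometry (<1.25 A)."""
    h_idx = [i for i, e in enumerate(traj.elements) if e == "H"]
    heavy = np.array([i for i, e in enumerate(traj.elements) if e != "H"], dtype=int)
    out: dict[int, list[int]] = {}
    if not h_idx or heavy.size == 0:
        return out
    X = traj.coords[frame]
    d = np.linalg.norm(X[h_idx][:, None, :] - X[heavy][None, :, :], axis=-1)
    for k, h in enumerate(h_idx):
        j = int(np.argmin(d[k]))
        if d[k, j] < 1.25:
            out.setdefault(int(heavy[j]), []).append(h)
    return out


def _polar_atoms(traj: Trajectory, atoms: Sequence[int], h_of: dict[int, list[int]]):
    donors = []
    acceptors = []
    for i in atoms:
        e = traj.elements[i]
        if e in ("N", "O"):
            hs = h_of.get(i, [])
            for h in hs:
                donors.append((i, h))
            if e == "O" or not hs:
                acceptors.append(i)
    return donors, acceptors


def _qualifies(X: np.ndarray, donor: tuple[int, int], acceptor: int,
               criteria: HBondCriteria) -> bool:
    d_heavy, h = donor
    if acceptor == d_heavy:
        return False
    dist = float(np.linalg.norm(X[d_heavy] - X[acceptor]))
    if dist > criteria.distance_cutoff:
        return False
    u = X[d_heavy] - X[h]
    v = X[acceptor] - X[h]
    c = float(np.dot(u, v) / max(np.linalg.norm(u) * np.linalg.norm(v), 1e-12))
    ang = math.degrees(math.acos(max(-1.0, min(1.0, c))))
    return ang >= criteria.angle_cutoff


def _occupancy_frame_pairs(traj: Trajectory, atoms_a: Sequence[int], atoms_b: Sequence[int],
                           criteria: HBondCriteria):
    """Yield, per frame, the set of (residue_a, residue_b) with >= 1 H-bond."""
    h_of = _attached_h(traj)
    don_a, acc_a = _polar_atoms(traj, atoms_a, h_of)
    don_b, acc_b = _polar_atoms(traj, atoms_b, h_of)
    for f in range(traj.n_frames):
        X = traj.coords[f]
        pairs = set()
        for donor in don_a:
            for acceptor in acc_b:
                if _qualifies(X, donor, acceptor, criteria):
                    pairs.add((traj.res_indices[donor[0]], traj.res_indices[acceptor]))
        for donor in don_b:
            for acceptor in acc_a:
                if _qualifies(X, donor, acceptor, criteria):
                    pairs.add((traj.res_indices[acceptor], traj.res_indices[donor[0]]))
        yield pairs


def hbond_occupancy(traj: Trajectory, atoms_a: Sequence[int], atoms_b: Sequence[int],
                    criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Direct H-bond occupancy per (residue of side A, residue of side B).

    A frame counts for a residue pair when at least one qualifying bond
    exists between them in either donor/acceptor direction.  Returns a
    table with columns residue_a, residue_b, occupancy, n_frames; all
    occupancies are multiples of 1/n_frames.
    """
    counts: dict[tuple[int, int], int] = {}
    for pairs in _occupancy_frame_pairs(traj, atoms_a, atoms_b, criteria):
        for key in pairs:
            counts[key] = counts.get(key, 0) + 1
    rows = [
        {"residue_a": a, "residue_b": b, "occupancy": c / traj.n_frames,
         "n_frames": traj.n_frames}
        for (a, b), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["residue_a", "residue_b", "occupancy", "n_frames"])


def water_bridge_occupancy(traj: Trajectory, protein_atoms: Sequence[int],
                           ligand_atoms: Sequence[int], water_resname: str = "HOH",
                           criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Water-mediated H-bond occupancy per protein residue.

    A frame counts for a protein residue when a single water molecule
    simultaneously forms a qualifying H-bond (in either role) to that
    residue and to any ligand atom.
    """
    h_of = _attached_h(traj)
    waters: dict[int, list[int]] = {}
    for i, rn in enumerate(traj.res_names):
        if rn == water_resname:
            waters.setdefault(traj.res_indices[i], []).append(i)
    protein_atoms = [i for i in protein_atoms if traj.res_names[i] != water_resname]

    don_p, acc_p = _polar_atoms(traj, protein_atoms, h_of)
    don_l, acc_l = _polar_atoms(traj, ligand_atoms, h_of)

    counts: dict[int, int] = {}
    for f in range(traj.n_frames):
        X = traj.coords[f]
        hit_residues = set()
        for wid, watoms in waters.items():
            don_w, acc_w = _polar_atoms(traj, watoms, h_of)

            bonded_prot = set()
            for donor in don_w:
                for acceptor in acc_p:
                    if _qualifies(X, donor, acceptor, criteria):
                        bonded_prot.add(traj.res_indices[acceptor])
            for donor in don_p:
                for acceptor in acc_w:
                    if _qualifies(X, donor, acceptor, criteria):
                        bonded_prot.add(traj.res_indices[donor[0]])
            if not bonded_prot:
                continue

            bonded_lig = False
            for donor in don_w:
                if any(_qualifies(X, donor, acc, criteria) for acc in acc_l):
                    bonded_lig = True
                    break
            if not bonded_lig:
                for donor in don_l:
                    if any(_qualifies(X, donor, acc, criteria) for acc in acc_w):
                        bonded_lig = True
                        break
            if bonded_lig:
                hit_residues.update(bonded_prot)
        for rid in hit_residues:
            counts[rid] = counts.get(rid, 0) + 1

    rows = [
        {"protein_residue": rid, "occupancy": c / traj.n_frames, "n_frames": traj.n_frames}
        for rid, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["protein_residue", "occupancy", "n_frames"])
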