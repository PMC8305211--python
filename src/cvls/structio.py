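"""Reading and writing small-molecule / receptor structures.

Three formats are supported for built ligands: PDB (HETATM records with
CONECT connectivity), Tripos MOL2 and SDF v2000.  The MOL2 writer uses
the carbohydrate-docking dialect in which sulfate sulfur is typed
``S.o2``, sulfate and carboxylate oxygens ``O.co2``, and the S-O bonds
are written as ``ar`` (delocalized); this is what downstream docking
tools expect for fully deprotonated sulfates.

Receptor structures are read from standard PDB files: residue indices
carry the author residue numbers, residue codes the PDB residue names,
and chain identifiers are kept in ``meta["chains"]``.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .geometry import Structure3D

__all__ = ["write_structure", "read_structure"]

#: PDB residue names for the three monosaccharide families.
_PDB_RESNAMES = {"Z": "BDP", "V": "NGA", "u": "DUA"}

_ELEMENTS = {"C", "N", "O", "S", "H", "P"}


def _pdb_resname(res_code: str) -> str:
    return _PDB_RESNAMES.get(res_code[:1], res_code[:3].upper() or "UNK")


def _guess_element(name: str, resname: str = "") -> str:
    name = name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    for cand in (name[:1].upper(),):
        if cand in _ELEMENTS:
            return cand
    return name[0].upper()


# --------------------------------------------------------------------------
# PDB


def _write_pdb(s: Structure3D, path: Path) -> None:
    lines = []
    chains = s.meta.get("chains")
    for i in range(s.n_atoms):
        name = s.names[i]
        pdb_name = name if len(name) >= 4 else f" {name:<3s}"
        chain = chains[i] if chains else "A"
        x, y, z = s.coords[i]
        lines.append(
            f"HETATM{i + 1:5d} {pdb_name:<4s}{_pdb_resname(s.res_codes[i]):>4s} "
            f"{chain}{s.res_indices[i] + 1:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{s.elements[i]:>2s}"
        )
    conect: dict[int, list[int]] = {}
    for a, b, _ in s.bonds:
        conect.setdefault(a, []).append(b)
        conect.setdefault(b, []).append(a)
    for a in sorted(conect):
        partners = sorted(conect[a])
        for k in range(0, len(partners), 4):
            chunk = partners[k:k + 4]
            lines.append("CONECT" + f"{a + 1:5d}" + "".join(f"{p + 1:5d}" for p in chunk))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


def _read_pdb(path: Path) -> Structure3D:
    elements, names, res_indices, res_codes, coords, chains = [], [], [], [], [], []
    serial_to_index: dict[int, int] = {}
    bonds: list[tuple[int, int, object]] = []
    for line in path.read_text().splitlines():
        rec = line[:6]
        if rec in ("ATOM  ", "HETATM"):
            serial = int(line[6:11])
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21]
            resseq = int(line[22:26])
            x, y, z = float(line[30:38]), float(line[38:46]), float(line[46:54])
            elem = line[76:78].strip() if len(line) >= 78 else ""
            elements.append(elem.capitalize() if elem else _guess_element(name, resname))
            names.append(name)
            res_indices.append(resseq)
            res_codes.append(resname)
            chains.append(chain)
            coords.append((x, y, z))
            serial_to_index[serial] = len(names) - 1
        elif rec == "CONECT":
            fields = [line[i:i + 5] for i in range(6, min(len(line), 31), 5)]
            serials = [int(f) for f in fields if f.strip()]
            if len(serials) >= 2:
                a = serial_to_index.get(serials[0])
                for sb in serials[1:]:
                    b = serial_to_index.get(sb)
                    if a is not None and b is not None and a < b:
                        bonds.append((a, b, 1))
        elif rec in ("ENDMDL",):
            break  # single-model contract here; trajectories use cvls.md
    if not names:
        raise ValueError(f"no atoms found in {path}")
    s = Structure3D(elements, names, res_indices, res_codes, np.array(coords), bonds)
    s.meta["chains"] = chains
    return s


# --------------------------------------------------------------------------
# MOL2


def _sybyl_type(s: Structure3D, i: int) -> str:
    elem = s.elements[i]
    name = s.names[i]
    if elem == "S":
        return "S.o2"
    if elem == "O":
        if any(o == "ar" for a, b, o in s.bonds if i in (a, b)):
            return "O.co2"  # sulfate oxygens (delocalized S-O)
        if name in ("O6A", "O6B"):
            return "O.co2"  # carboxylate
        if any(o == 2 for a, b, o in s.bonds if i in (a, b)):
            return "O.2"
        return "O.3"
    if elem == "N":
        return "N.am"
    if elem == "C":
        if any(o == 2 for a, b, o in s.bonds if i in (a, b)) or name in ("C6A", "C7"):
            return "C.2"
        if name == "C6" and any(
                s.names[b if a == i else a] in ("O6A", "O6B") for a, b, _ in s.bonds if i in (a, b)):
            return "C.2"
        return "C.3"
    return elem


def _write_mol2(s: Structure3D, path: Path) -> None:
    lines = ["@<TRIPOS>MOLECULE", s.meta.get("sequence_name", "ligand"),
             f"{s.n_atoms} {len(s.bonds)} {s.n_residues} 0 0", "SMALL", "USER_CHARGES", ""]
    lines.append("@<TRIPOS>ATOM")
    for i in range(s.n_atoms):
        x, y, z = s.coords[i]
        lines.append(
            f"{i + 1:7d} {s.names[i]:<8s}{x:10.4f}{y:10.4f}{z:10.4f} "
            f"{_sybyl_type(s, i):<8s}{s.res_indices[i] + 1:4d} {s.res_codes[i]:<8s}{0.0:8.4f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, (a, b, o) in enumerate(s.bonds, start=1):
        btype = {1: "1", 2: "2", "ar": "ar"}.get(o, "1")
        lines.append(f"{k:6d} {a + 1:5d} {b + 1:5d} {btype:>4s}")
    path.write_text("\n".join(lines) + "\n")


def _read_mol2(path: Path) -> Structure3D:
    section = None
    elements, names, res_indices, res_codes, coords = [], [], [], [], []
    bonds: list[tuple[int, int, object]] = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if line.startswith("@<TRIPOS>"):
            section = line[9:]
            continue
        if not line:
            continue
        if section == "ATOM":
            f = line.split()
            names.append(f[1])
            coords.append((float(f[2]), float(f[3]), float(f[4])))
            elements.append(f[5].split(".")[0].capitalize())
            res_indices.append(int(f[6]) - 1 if len(f) > 6 else 0)
            res_codes.append(f[7] if len(f) > 7 else "LIG")
        elif section == "BOND":
            f = line.split()
            order: object = "ar" if f[3] == "ar" else int(f[3]) if f[3].isdigit() else 1
            bonds.append((int(f[1]) - 1, int(f[2]) - 1, order))
    if not names:
        raise ValueError(f"no atoms found in {path}")
    return Structure3D(elements, names, res_indices, res_codes, np.array(coords), bonds)


# --------------------------------------------------------------------------
# SDF (v2000) — elements, coordinates and bonds; atom names are not a part
# of this format and are regenerated as element+serial on read.


def _write_sdf(s: Structure3D, path: Path) -> None:
    lines = [s.meta.get("sequence_name", "ligand"), "  cvls", ""]
    lines.append(f"{s.n_atoms:3d}{len(s.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for i in range(s.n_atoms):
        x, y, z = s.coords[i]
        lines.append(f"{x:10.4f}{y:10.4f}{z:10.4f} {s.elements[i]:<3s} 0  0  0  0  0  0  0  0  0  0  0  0")
    for a, b, o in s.bonds:
        code = {1: 1, 2: 2, "ar": 4}.get(o, 1)
        lines.append(f"{a + 1:3d}{b + 1:3d}{code:3d}  0")
    lines.append("M  END")
    lines.append("$$$$")
    path.write_text("\n".join(lines) + "\n")


def _read_sdf(path: Path) -> Structure3D:
    lines = path.read_text().splitlines()
    counts = lines[3]
    n_atoms = int(counts[0:3])
    n_bonds = int(counts[3:6])
    elements, coords = [], []
    for i in range(n_atoms):
        f = lines[4 + i]
        coords.append((float(f[0:10]), float(f[10:20]), float(f[20:30])))
        elements.append(f[31:34].strip().capitalize())
    bonds: list[tuple[int, int, object]] = []
    for i in range(n_bonds):
        f = lines[4 + n_atoms + i]
        a, b, code = int(f[0:3]) - 1, int(f[3:6]) - 1, int(f[6:9])
        bonds.append((a, b, {1: 1, 2: 2, 4: "ar"}.get(code, 1)))
    names = [f"{e}{i + 1}" for i, e in enumerate(elements)]
    return Structure3D(elements, names, [0] * n_atoms, ["LIG"] * n_atoms,
                       np.array(coords), bonds)


# --------------------------------------------------------------------------


_WRITERS = {".pdb": _write_pdb, ".mol2": _write_mol2, ".sdf": _write_sdf, ".mol": _write_sdf}
_READERS = {".pdb": _read_pdb, ".mol2": _read_mol2, ".sdf": _read_sdf, ".mol": _read_sdf}


def write_structure(s: Structure3D, path, fmt: str | None = None) -> None:
    """Write a structure; the format is taken from ``fmt`` or the extension."""
    path = Path(path)
    ext = f".{fmt.lower()}" if fmt else path.suffix.lower()
    writer = _WRITERS.get(ext)
    if writer is None:
        raise ValueError(f"unknown structure format {ext!r}")
    writer(s, path)


def read_structure(path, fmt: str | None = None) -> Structure3D:
    """Read a structure from PDB, MOL2 or SDF."""
    path = Path(path)
    ext = f".{fmt.lower()}" if fmt else path.suffix.lower()
    reader = _READERS.get(ext)
    if reader is None:
        raise ValueError(f"unknown structure format {ext!r}")
    return reader(path)
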