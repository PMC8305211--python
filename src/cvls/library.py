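"""Combinatorial enumeration of the CS oligosaccharide libraries.

A library is defined by its chain length (2, 4 or 6 residues, named CS02,
CS04 and CS06) and by the residue at the non-reducing end (dUA, GlcA or
GalNAc), giving three families per length.  Within a family every uronic
position varies over {unsulfated, 2-O-sulfated} and every GalNAc position
over {unsulfated, 4S, 6S, 4S6S}, so a family of length L contains
8^(L/2) sequences and a full length-L library 3 x 8^(L/2): 24
disaccharides, 192 tetrasaccharides and 1536 hexasaccharides — 1752
sequences in total.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .chemistry import (
    GALN_SULFATION_VARIANTS,
    URONIC_SULFATION_VARIANTS,
    CSSequence,
    MonosaccharideResidue,
    NRELibrary,
    ResidueKind,
    galNAc,
)

__all__ = ["LibrarySpec", "enumerate_library", "full_library", "LIBRARY_LENGTHS"]

LIBRARY_LENGTHS = (2, 4, 6)


@dataclass(frozen=True)
class LibrarySpec:
    """One library family: chain length plus non-reducing-end identity."""

    length: int
    nre_library: NRELibrary

    def __post_init__(self) -> None:
        if self.length not in LIBRARY_LENGTHS:
            raise ValueError(f"unsupported length {self.length}; expected one of {LIBRARY_LENGTHS}")
        object.__setattr__(self, "nre_library", NRELibrary(self.nre_library))

    @property
    def expected_size(self) -> int:
        return 8 ** (self.length // 2)


def _position_kinds(spec: LibrarySpec) -> list[ResidueKind]:
    """Residue kind at each chain position, NRE first."""
    first = spec.nre_library.nre_kind
    kinds = []
    for i in range(spec.length):
        if i == 0:
            kinds.append(first)
        elif first is ResidueKind.GalN:
            kinds.append(ResidueKind.GalN if i % 2 == 0 else ResidueKind.GlcA)
        else:
            # dUA only ever appears at position 1; internal uronics are GlcA
            kinds.append(ResidueKind.GlcA if i % 2 == 0 else ResidueKind.GalN)
    return kinds


def enumerate_library(spec: LibrarySpec) -> list[CSSequence]:
    """All sequences of one family, duplicate-free, sorted by name.

    Enumeration is a cartesian product over per-position sulfation
    variants, then sorted lexicographically by sequence code so that two
    calls always return the same order (screens cut the library at a
    score quantile, so a stable order matters for reproducibility).
    """
    kinds = _position_kinds(spec)
    per_position = [
        GALN_SULFATION_VARIANTS if k is ResidueKind.GalN else URONIC_SULFATION_VARIANTS
        for k in kinds
    ]
    sequences = []
    for combo in itertools.product(*per_position):
        residues = tuple(
            galNAc(s) if k is ResidueKind.GalN else MonosaccharideResidue(k, s)
            for k, s in zip(kinds, combo)
        )
        sequences.append(CSSequence(residues))
    sequences.sort(key=lambda s: s.name)
    assert len({s.name for s in sequences}) == len(sequences) == spec.expected_size
    return sequences


def full_library(length: int) -> list[CSSequence]:
    """Union of the three NRE families at one length, ordered by (family, name)."""
    out: list[CSSequence] = []
    for nre in NRELibrary:
        out.extend(enumerate_library(LibrarySpec(length, nre)))
    return out
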