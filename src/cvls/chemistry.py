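"""Chondroitin sulfate residue chemistry, building blocks, and nomenclature.

Chondroitin sulfate (CS) chains alternate a uronic acid (glucuronic acid,
GlcA, or at the non-reducing end of lyase digests the 4,5-unsaturated
uronate dUA) with N-acetylgalactosamine (GalNAc).  Sulfation is variable:
the uronic 2-O position may carry a sulfate, GalNAc may carry 4-O and/or
6-O sulfates.  This module models residues and sequences, enumerates the
24 disaccharide building blocks from which the combinatorial libraries
are assembled, and implements the compact GLYCAM-style sequence code used
throughout this package:

* base letter: ``Z`` = GlcA, ``uA`` = dUA, ``V`` = GalN
* ring pucker: ``b`` for the 4C1 chair (omitted for dUA, whose
  unsaturated ring is not a chair)
* ``C`` marks the N-acetyl group (always present on GalN here)
* digits ``2``, ``4``, ``6`` mark O-sulfates at those ring positions
* trailing ``B`` marks the beta anomeric configuration

so that e.g. ``Zb2B–VbC46B`` is the 2-O-sulfated GlcA linked to
4,6-di-O-sulfated GalNAc.  Residue codes are joined with an en dash
(a plain hyphen is accepted on input).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

__all__ = [
    "ResidueKind",
    "NRELibrary",
    "MonosaccharideResidue",
    "DisaccharideBlock",
    "CSSequence",
    "enumerate_building_blocks",
    "sequence_name",
    "parse_name",
    "count_sulfates",
    "formal_charge",
    "library_to_tsv",
    "EN_DASH",
]

EN_DASH = "–"

#: Valid O-sulfation positions per residue kind.
_ALLOWED_SULFATION = {
    "GlcA": ({"O2"},),
    "dUA": ({"O2"},),
    "GalN": ({"O4"}, {"O6"}, {"O4", "O6"}),
}

#: GalNAc sulfation variants in canonical (enumeration) order.
GALN_SULFATION_VARIANTS = (frozenset(), frozenset({"O4"}), frozenset({"O6"}), frozenset({"O4", "O6"}))
#: Uronic sulfation variants in canonical order.
URONIC_SULFATION_VARIANTS = (frozenset(), frozenset({"O2"}))


class ResidueKind(str, Enum):
    GlcA = "GlcA"
    dUA = "dUA"
    GalN = "GalN"

    @property
    def is_uronic(self) -> bool:
        return self in (ResidueKind.GlcA, ResidueKind.dUA)


class NRELibrary(str, Enum):
    """The three library families, distinguished by the non-reducing-end residue."""

    dUA_NRE = "dUA_NRE"
    GlcA_NRE = "GlcA_NRE"
    GalN_NRE = "GalN_NRE"

    @property
    def nre_kind(self) -> ResidueKind:
        return {
            NRELibrary.dUA_NRE: ResidueKind.dUA,
            NRELibrary.GlcA_NRE: ResidueKind.GlcA,
            NRELibrary.GalN_NRE: ResidueKind.GalN,
        }[self]


@dataclass(frozen=True)
class MonosaccharideResidue:
    """One pyranose residue with its substitution state.

    ``ring_pucker`` is a conformer label: "4C1" for the chair adopted by
    GlcA and GalNAc, "planar-d45" for the flattened unsaturated uronate.
    """

    kind: ResidueKind
    sulfation: frozenset[str] = frozenset()
    n_acetyl: bool = False
    ring_pucker: str = "4C1"
    anomeric_config: str = "beta"

    def __post_init__(self) -> None:
        kind = ResidueKind(self.kind)
        object.__setattr__(self, "kind", kind)
        object.__setattr__(self, "sulfation", frozenset(self.sulfation))
        if kind is ResidueKind.dUA and self.ring_pucker == "4C1":
            object.__setattr__(self, "ring_pucker", "planar-d45")
        self.validate()

    def validate(self) -> None:
        if self.anomeric_config != "beta":
            raise ValueError(f"only beta anomers are supported, got {self.anomeric_config!r}")
        if self.kind is ResidueKind.GalN:
            if not self.n_acetyl:
                raise ValueError("GalN residues must be N-acetylated in this library")
            if not self.sulfation <= {"O4", "O6"}:
                raise ValueError(f"illegal GalNAc sulfation {set(self.sulfation)}")
        else:
            if self.n_acetyl:
                raise ValueError("uronic residues cannot carry an N-acetyl group")
            if not self.sulfation <= {"O2"}:
                raise ValueError(f"illegal {self.kind.value} sulfation {set(self.sulfation)}")

    @property
    def n_sulfates(self) -> int:
        return len(self.sulfation)

    def code(self) -> str:
        """The per-residue token of the sequence code (e.g. ``VbC46B``)."""
        if self.kind is ResidueKind.GlcA:
            base, pucker = "Z", "b"
        elif self.kind is ResidueKind.dUA:
            base, pucker = "uA", ""  # the unsaturated ring prints no pucker letter
        else:
            base, pucker = "V", "b"
        digits = "".join(sorted(p[1] for p in self.sulfation))
        return base + pucker + ("C" if self.n_acetyl else "") + digits + "B"


def glcA(sulfated: bool = False) -> MonosaccharideResidue:
    return MonosaccharideResidue(ResidueKind.GlcA, frozenset({"O2"}) if sulfated else frozenset())


def dUA(sulfated: bool = False) -> MonosaccharideResidue:
    return MonosaccharideResidue(ResidueKind.dUA, frozenset({"O2"}) if sulfated else frozenset())


def galNAc(sulfation: Iterable[str] = ()) -> MonosaccharideResidue:
    return MonosaccharideResidue(ResidueKind.GalN, frozenset(sulfation), n_acetyl=True)


@dataclass(frozen=True)
class DisaccharideBlock:
    """An ordered residue pair, the unit of combinatorial assembly.

    Three series exist: dUA-GalN and GlcA-GalN (uronic 1->3 GalNAc linkage)
    and GalN-GlcA (GalNAc 1->4 uronic linkage); eight sulfation variants
    each, 24 blocks in total.
    """

    series: str
    nre_residue: MonosaccharideResidue
    re_residue: MonosaccharideResidue

    def __post_init__(self) -> None:
        if self.series not in ("dUA-GalN", "GlcA-GalN", "GalN-GlcA"):
            raise ValueError(f"unknown series {self.series!r}")
        expect_nre, expect_re = self.series.split("-")
        if self.nre_residue.kind.value != expect_nre:
            raise ValueError("NRE residue kind inconsistent with series")
        if self.re_residue.kind.value != expect_re:
            raise ValueError("RE residue kind inconsistent with series")

    @property
    def linkage(self) -> str:
        """(1->3) for uronic->GalNAc blocks, (1->4) for GalNAc->uronic."""
        return "(1->3)" if self.nre_residue.kind.is_uronic else "(1->4)"

    @property
    def name(self) -> str:
        return self.nre_residue.code() + EN_DASH + self.re_residue.code()


def enumerate_building_blocks() -> list[DisaccharideBlock]:
    """All 24 disaccharide building blocks, in canonical order.

    Each of the three series contributes 8 blocks: the uronic partner's
    2-O-sulfation is binary, and the GalNAc partner spans the four
    {none, 4S, 6S, 4S6S} variants (2 x 4 = 8 per series).
    """
    blocks: list[DisaccharideBlock] = []
    for u_sulf in URONIC_SULFATION_VARIANTS:
        for g_sulf in GALN_SULFATION_VARIANTS:
            blocks.append(DisaccharideBlock(
                "dUA-GalN",
                MonosaccharideResidue(ResidueKind.dUA, u_sulf),
                galNAc(g_sulf)))
    for u_sulf in URONIC_SULFATION_VARIANTS:
        for g_sulf in GALN_SULFATION_VARIANTS:
            blocks.append(DisaccharideBlock(
                "GlcA-GalN",
                MonosaccharideResidue(ResidueKind.GlcA, u_sulf),
                galNAc(g_sulf)))
    for g_sulf in GALN_SULFATION_VARIANTS:
        for u_sulf in URONIC_SULFATION_VARIANTS:
            blocks.append(DisaccharideBlock(
                "GalN-GlcA",
                galNAc(g_sulf),
                MonosaccharideResidue(ResidueKind.GlcA, u_sulf)))
    assert len({b.name for b in blocks}) == len(blocks) == 24
    return blocks


@dataclass(frozen=True)
class CSSequence:
    """An oligosaccharide written non-reducing end (NRE) first.

    Residues strictly alternate uronic / GalNAc; the unsaturated uronate
    dUA can only occur at position 1 (it is the signature the bacterial
    lyase leaves at the non-reducing terminus).
    """

    residues: tuple[MonosaccharideResidue, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", tuple(self.residues))
        self.validate()

    def validate(self) -> None:
        n = len(self.residues)
        if n < 2 or n % 2:
            raise ValueError(f"sequence length must be a positive even number, got {n}")
        first_is_uronic = self.residues[0].kind.is_uronic
        for i, res in enumerate(self.residues):
            expect_uronic = first_is_uronic ^ (i % 2 == 1)
            if res.kind.is_uronic != expect_uronic:
                raise ValueError(f"residue {i + 1} breaks the uronic/GalNAc alternation")
            if res.kind is ResidueKind.dUA and i != 0:
                raise ValueError("dUA is only allowed at the non-reducing end")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def nre_library(self) -> NRELibrary:
        return {
            ResidueKind.dUA: NRELibrary.dUA_NRE,
            ResidueKind.GlcA: NRELibrary.GlcA_NRE,
            ResidueKind.GalN: NRELibrary.GalN_NRE,
        }[self.residues[0].kind]

    @property
    def name(self) -> str:
        return sequence_name(self)

    @property
    def n_sulfates(self) -> int:
        return sum(r.n_sulfates for r in self.residues)

    @property
    def linkages(self) -> tuple[str, ...]:
        """Linkage type between residue i and i+1: '(1->3)' or '(1->4)'."""
        return tuple("(1->3)" if r.kind.is_uronic else "(1->4)" for r in self.residues[:-1])


def sequence_name(seq: CSSequence, ascii_safe: bool = False) -> str:
    """The sequence code, residues NRE->RE joined by an en dash.

    With ``ascii_safe`` a plain hyphen is used instead.
    """
    dash = "-" if ascii_safe else EN_DASH
    return dash.join(r.code() for r in seq.residues)


_RESIDUE_CODE = re.compile(r"^(uA|Z|V)(b?)(C?)(2|4|6|46)?B$")


def _parse_residue_code(token: str) -> MonosaccharideResidue:
    m = _RESIDUE_CODE.match(token)
    if m is None:
        raise ValueError(f"malformed residue code {token!r}")
    base, pucker, acetyl, digits = m.groups()
    digits = digits or ""
    sulfation = frozenset({"O" + d for d in digits})
    if base == "uA":
        if pucker:
            raise ValueError(f"dUA code {token!r} must not carry a pucker letter")
        if acetyl:
            raise ValueError(f"uronic code {token!r} cannot be N-acetylated")
        return MonosaccharideResidue(ResidueKind.dUA, sulfation)
    if not pucker:
        raise ValueError(f"residue code {token!r} is missing the ring pucker letter 'b'")
    if base == "Z":
        if acetyl:
            raise ValueError(f"uronic code {token!r} cannot be N-acetylated")
        if not sulfation <= {"O2"}:
            raise ValueError(f"illegal GlcA sulfation in {token!r}")
        return MonosaccharideResidue(ResidueKind.GlcA, sulfation)
    # base == "V"
    if not acetyl:
        raise ValueError(f"GalN code {token!r} must carry the N-acetyl letter 'C'")
    if not sulfation <= {"O4", "O6"}:
        raise ValueError(f"illegal GalNAc sulfation in {token!r}")
    return MonosaccharideResidue(ResidueKind.GalN, sulfation, n_acetyl=True)


def parse_name(name: str) -> CSSequence:
    """Parse a sequence code back into a :class:`CSSequence`.

    Both the en dash and the ASCII hyphen are accepted as residue
    separators.  Raises :class:`ValueError` on unknown tokens, an odd
    residue count, or a dUA residue away from the non-reducing end.
    """
    tokens = [t for t in re.split(r"[-–—]", name.strip()) if t]
    if not tokens:
        raise ValueError("empty sequence name")
    residues = tuple(_parse_residue_code(t) for t in tokens)
    return CSSequence(residues)


def count_sulfates(seq_or_name: CSSequence | str) -> int:
    """Total number of O-sulfate substituents in a sequence or its name."""
    seq = parse_name(seq_or_name) if isinstance(seq_or_name, str) else seq_or_name
    return seq.n_sulfates


def formal_charge(seq_or_name: CSSequence | str) -> int:
    """Net formal charge with carboxylates and sulfates fully deprotonated.

    Each uronic residue contributes one carboxylate (-1) and each sulfate
    ester one further -1.
    """
    seq = parse_name(seq_or_name) if isinstance(seq_or_name, str) else seq_or_name
    n_uronic = sum(1 for r in seq.residues if r.kind.is_uronic)
    return -(n_uronic + seq.n_sulfates)


def library_to_tsv(sequences: Sequence[CSSequence], path, ascii_safe: bool = False) -> None:
    """Write a library as TSV: name, length, nre_library, n_sulfates, formal_charge."""
    import pandas as pd

    df = pd.DataFrame({
        "name": [sequence_name(s, ascii_safe=ascii_safe) for s in sequences],
        "length": [len(s) for s in sequences],
        "nre_library": [s.nre_library.value for s in sequences],
        "n_sulfates": [s.n_sulfates for s in sequences],
        "formal_charge": [formal_charge(s) for s in sequences],
    })
    df.to_csv(path, sep="\t", index=False)
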