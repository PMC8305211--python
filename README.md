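# cvls — combinatorial virtual library screening of chondroitin sulfate

Chondroitin sulfate (CS) is a glycosaminoglycan built from alternating
glucuronic acid (GlcA) and N-acetylgalactosamine (GalNAc) residues with
variable O-sulfation (GlcA 2-O; GalNAc 4-O and/or 6-O). Which of the many
possible sulfation sequences a given protein surface prefers is hard to
probe experimentally, because defined CS oligosaccharides are nearly
impossible to synthesize. `cvls` implements the computational alternative:
enumerate *every* possible CS oligosaccharide, dock each one against a
protein site, and keep the sequences that bind both strongly and
*consistently*.

The package provides, for researchers working on protein–GAG recognition:

- **Sequence space.** All 24 disaccharide building blocks and the complete
  combinatorial libraries: 24 disaccharides (CS02), 192 tetrasaccharides
  (CS04) and 1536 hexasaccharides (CS06) — 1752 sequences across three
  families distinguished by the non-reducing-end residue (ΔUA, GlcA or
  GalNAc). Sequences carry compact GLYCAM-style codes such as
  `Zb2B–VbC46B` (2-O-sulfo-GlcA → 4,6-di-O-sulfo-GalNAc) with a
  round-tripping parser, sulfate counting and formal-charge accounting.
- **3D construction.** All-atom coordinates from idealized ⁴C₁ pyranose
  templates joined at the crystallographic average glycosidic torsions
  (φ/ψ = −81/−129° for GlcA(1→3)GalNAc, −69/131° for GalNAc(1→4)GlcA),
  with Cremer–Pople pucker validation, deterministic output, and PDB /
  Tripos MOL2 (S.o2 / O.co2 sulfate typing) / SDF writers.
- **The dual-filter screen.** A self-contained genetic-algorithm pose
  sampler over rigid-body placement plus restrained glycosidic flexibility,
  scored by a GOLDScore-shaped objective `total = HB_EXT + 1.375·VDW_EXT`
  (a documented surrogate — the shape and decomposition of the published
  fitness, not its numeric values). Three independent docking experiments
  per sequence; the pooled top-6 poses' spread (consistency RMSD) marks a
  sequence **selective** when ≤ 2.5 Å. Libraries of ≥ 500 members are first
  pre-screened and only the top 2 % advance to triplicate refinement.
- **Trajectory analytics.** Multi-model-PDB trajectories: RMSD series,
  oligosaccharide end-to-end distance, direct hydrogen-bond occupancy and
  water-bridge occupancy under the 3.0 Å / 135° criteria.

## Worked example

```python
from cvls import (full_library, parse_name, count_sulfates, formal_charge,
                  build_3d, measure_torsion, ring_pucker)

lib = full_library(6)
print(len(lib))                                   # 1536
seq = parse_name("ZbB–VbC46B–Zb2B–VbC4B–Zb2B–VbC46B")
print(count_sulfates(seq), formal_charge(seq))    # 7 -10

s = build_3d(parse_name("ZbB–VbCB"))
phi = measure_torsion(s, s.meta["linkages"][0]["phi_atoms"])
print(round(phi, 1))                              # -81.0
print(ring_pucker(s, 0)[3])                       # 4C1
```

A miniature screen on the synthetic toy pocket (a shell of donor residues
standing in for a protein site — no downloads needed):

```python
from cvls import GAParams, define_binding_site, two_step_screen, full_library
from cvls.fixtures import make_toy_pocket

pocket = make_toy_pocket(seed=1)
site = define_binding_site(pocket.receptor,
                           sorted(set(pocket.receptor.res_indices)), radius=8.0)
result = two_step_screen(full_library(2), site, GAParams(seed=11))
print(result.table[["name", "best_total", "consistency_rmsd", "selective"]].head(3))
```

```
          name  best_total  consistency_rmsd  selective
0  Zb2B–VbC46B   52.848192          8.250291      False
1  uA2B–VbC46B   48.962389          9.428266      False
2   uA2B–VbC4B   48.621962          7.009382      False
```

The spread of ~10 Å across replicates says the symmetric toy pocket binds
these disaccharides in many equivalent orientations — none are selective,
which is exactly what the consistency filter is designed to flag.

To screen a real receptor, prepare a protonated PDB (e.g. TGF-β2, PDB id
1TFG — fetch it manually) and use the shipped BS1/BS2 residue presets:

```
cvls screen --library lib.tsv --receptor tgfb2.pdb --site BS1 --seed 7 --out hits.tsv
```

The CLI also offers `build-library`, `build-3d`, `analyze-traj` and
`fixtures`; `--paper-scale` restores the exhaustive GA settings
(100 runs × 100,000 iterations).

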