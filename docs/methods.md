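# Methods

## Sequence model and nomenclature

A CS oligosaccharide is an alternating chain of uronic acid and
N-acetylgalactosamine residues, written non-reducing end (NRE) first.
Three residue kinds exist: GlcA (β-D-glucopyranuronic acid), GalNAc
(2-acetamido-2-deoxy-β-D-galactopyranose) and ΔUA, the 4,5-unsaturated
uronate that chondroitin lyases leave at the NRE of digestion products —
hence ΔUA is legal only at position 1. Sulfation is restricted to the
positions observed in CS: the uronic 2-O (binary) and the GalNAc 4-O/6-O
(four combinations). N-sulfation, 3-O-sulfation and α anomers never occur
in this chemistry and are rejected by the type system.

The residue code is `base + pucker + substituents + anomer`: `Z`/`uA`/`V`
for GlcA/ΔUA/GalN, `b` for the ⁴C₁ chair (omitted for ΔUA, whose
unsaturated ring is not a chair), `C` for N-acetyl, digits `2`/`4`/`6`
for O-sulfates, `B` for β. Residue codes are joined by an en dash; a
plain hyphen is accepted on input and available on output
(`ascii_safe=True`). The parser is the exact inverse of the writer and
round-trips every library member.

One published disaccharide row pairs the name `uAB–VbCB` (which encodes
zero sulfates) with a printed count of one. The parser trusts the name;
that row is excluded from name→count consistency tests.

Formal charge is −(uronic residues + sulfates): carboxylates and
sulfates are treated as fully deprotonated, the physiological state this
chemistry is screened in.

## Combinatorial libraries

A library family is (length, NRE kind). Within a family each uronic
position contributes 2 sulfation variants and each GalNAc position 4, so
a family of L residues has 8^(L/2) members and the full length-L library
3·8^(L/2): 24 (CS02), 192 (CS04), 1536 (CS06), 1752 overall. The
composition of the 24 disaccharide building blocks follows the same
2 × 4 (or mirrored 4 × 2) pattern per series — the unique choice that
reproduces both the printed library sizes and every published hit name.
Enumeration output is sorted by (family, sequence code); the published
protocol specifies no order, and a fixed order makes score-quantile cuts
reproducible.

## 3D construction

Each residue is a rigid template: an idealized chair ring (uniform ring
bonds ≈ 1.52 Å, puckering amplitude 0.25 Å, giving Cremer–Pople θ ≈ 0°
for the ⁴C₁ label) with substituents placed in the axial/equatorial
slots of the β-D-gluco or β-D-galacto configuration, standard bond
lengths (C–C 1.53, C–O 1.43, S–O ester 1.60 Å) and tetrahedral angles.
Template chirality was validated against reference stereo-SMILES by
InChI equality. Hydrogens are generated everywhere (the H-bond scorer
and the occupancy analytics require them). Sulfate orientation within a
template is chosen by a deterministic grid search maximizing clearance
from the rest of the residue, so sulfated templates start clash-free.

ΔUA is modelled as a half-chair with a C4=C5 double bond and no O4; its
geometry is approximate and no test asserts its pucker class (the source
data only constrain GlcA/GalNAc to ⁴C₁).

Chains are assembled by exact internal-coordinate placement: the
downstream residue is positioned so that φ (O5–C1–Ox′–Cx′) and ψ
(C1–Ox′–Cx′–C(x−1)′) equal the torsion-table means — by default the
crystallographic averages −81/−129° for GlcA(1→3)GalNAc and −69/131° for
GalNAc(1→4)GlcA, with half-widths 12/14° and 14/9° bounding the
flexibility docking may explore. The glycosidic C1–O–C angle is set to
117°. Realized torsions are exact to numerical precision; the ±2°
test tolerance covers any future relaxation step. Dihedrals follow the
standard IUPAC sign convention (cross-checked against RDKit). A
consistency observation worth recording: at the printed torsion means
the chains assemble clash-free only with the correct D-sugar chirality
and sign convention — with either mirrored, rings collide.

After assembly a greedy grid search over exocyclic torsions (sulfates,
N-acetyl, hydroxymethyl, sulfate spin) relieves any remaining heavy-atom
contact below 2.0 Å; an unresolvable clash raises an error rather than
being silently accepted. All 1536 hexasaccharides build clash-free in a
few seconds; built CS06 end-to-end distances fall at 23.8–24.6 Å,
within the 20–35 Å window expected for a ⁴C₁ chain at these torsions.
Construction is fully deterministic (bit-identical coordinates).

Force-field minimization (Tripos/Gasteiger–Hückel) is out of scope; the
torsion-exact single conformer is the contract.

## File formats

PDB (HETATM + CONECT), Tripos MOL2 and SDF v2000 writers/readers are
minimal and symmetric. The MOL2 dialect types sulfate sulfur `S.o2`,
sulfate/carboxylate oxygens `O.co2`, and writes delocalized S–O bonds as
`ar`, matching what carbohydrate-docking pipelines expect for fully
deprotonated sulfates. Biopython (PDB) and RDKit (SDF) act as
third-party conformance oracles in the tests. SDF carries no atom
names; names are regenerated on read. Trajectories (multi-model PDB) are
read through MDAnalysis.

## The dual-filter screen

The screen uses two surrogates: a docking score for in-silico affinity
and pose-consistency for in-silico specificity.

**Scorer.** `total = HB_EXT + 1.375·VDW_EXT`. HB_EXT sums, over
intermolecular donor–H···acceptor triples, a block function that is
maximal (4.0) at ideal geometry and ramps linearly to zero over
heavy-atom distance 2.5→3.5 Å and D–H–A angle 180→120°. VDW_EXT is a
pairwise 4–8 dispersion term (ε = 0.15, r₀ = 3.8 Å) with per-pair
repulsion clamped at −5; polar–polar pairs use r₀ = 2.8 Å so that
hydrogen-bond contact distances are not penalized (the analogue of
GOLD's exclusion of H-bonded pairs from its external vdW sum). The
scorer reproduces the published fitness's *shape* and its exact
HB/VDW decomposition identity; its numbers are not comparable to any
proprietary implementation, and published score columns ship only as
reference fixtures for filter tests.

**Pose sampler.** A steady-state elitist GA over a genotype of
translation (confined to the site sphere), rotation quaternion and
per-linkage φ/ψ offsets clipped to the torsion-table half-widths
("inter-glycosidic bonds constrained within the normal range"). One
iteration = one genetic operation: tournament parent selection, uniform
crossover, Gaussian mutation (σ = 0.75 Å translation, 0.25 rad rotation,
3° torsion), replace-worst acceptance. A run pre-terminates when the
top-2 poses agree within 2.5 Å RMSD — checked only after half the
iteration budget, because random initial poses in a ~8 Å sphere can
satisfy the criterion by chance before any optimization has happened.
Seeds: replicate r uses `seed + r`; run k within a replicate draws its
generator from the pair (replicate seed, k), so every experiment is
independently reproducible.

Defaults are desk-scale (population 20, 2000 iterations, 10 runs,
3 replicates); `GAParams.paper_scale` restores the exhaustive published
settings (100 / 100,000 / 100).

**Consistency and the filter.** Pose RMSD is heavy-atom, identity
mapping, *no superposition* — both poses live in the receptor frame, so
rigid displacement is dissimilarity. The consistency spread of the
pooled top-6 poses (top-2 × 3 replicates) is the maximum pairwise RMSD,
the strictest reading of "the top six poses within the threshold";
mean and mean-to-medoid aggregations are available. Selectivity is
inclusive at the threshold (≤ 2.5 Å — published hit tables list passing
rows at exactly 2.5). Libraries under 500 members go straight to
triplicate docking; larger ones are pre-screened with a single run per
sequence and the top 2 % advance, with ceiling rounding
(⌈0.02·1536⌉ = 31) and ties at the cut broken by name.

**Binding sites.** A site is the unweighted heavy-atom centroid of a
residue list plus a 12–16 Å radius. Residue presets for the TGF-β2
structure 1TFG ship with the package (BS1: 25, 26, 31, 34, 37, 94, 97;
BS2: 58, 60, 110); the receptor itself must be fetched and prepared by
the user, and the presets validated against that file's numbering. The
Cardin–Weintraub scan (XBBXBX, XBBBXXBX; B ∈ {K,R}, optionally H)
reports all overlapping matches — on TGF-β2 it finds none, which is why
sites are defined from residue lists rather than motifs.

## Trajectory analytics

Direct H-bond: heavy-atom donor–acceptor distance ≤ 3.0 Å AND D–H–A
angle ≥ 135° (CPPTRAJ-style convention). Occupancy is the fraction of
frames in which a (residue, residue) pair has at least one qualifying
bond; values are exact multiples of 1/n_frames, invariant to frame
order, and monotone non-increasing under criteria tightening (property
tested). A water bridge requires one single water simultaneously
H-bonded (either role) to the protein residue and to the ligand.
Hydrogens are mandatory; attachment is inferred from frame-0 geometry
(H within 1.25 Å of its heavy atom) when no bond list is present.

RMSD series optionally least-squares-superpose each frame on a fit
selection (Kabsch) before measuring a report selection — fit on protein,
report ligand is the usual pattern. End-to-end distance defaults to the
anomeric C1 atoms of the terminal residues; which atoms bound the EED is
a convention of this package (the source analyses never state theirs),
and a ring-centroid rule is provided as the alternative.

## Synthetic fixtures — what they do and do not show

The toy pocket is a hemispherical shell of ammonium-like donors and
carboxylate-like acceptors around an empty cavity: a deterministic,
seed-reproducible stand-in for a GAG-binding surface. It supports
reproducibility, containment and baseline tests, but it is nearly
symmetric — many poses score alike, so screens on it correctly find *no*
selective sequences. The H-bond cage places donors/acceptors
complementary to a built ligand's own polar atoms (clearance-filtered),
making the build pose the known global optimum; the GA recovers it to
within 2 Å centroid distance at desk-scale settings. Planted
trajectories realize occupancies exactly by construction (qualifying
frames at 2.8 Å/180°, displaced frames at 8 Å), so analytics tests are
exact rather than tolerance-based. None of these fixtures emulate real
protein flexibility, solvation or the electrostatics of a true binding
site: passing them validates the machinery, not biological predictions.

## Known limitations

- The scorer is a surrogate: rankings on real receptors will differ from
  any specific docking engine's.
- Receptor is rigid; protonation/preparation is the user's
  responsibility.
- ΔUA geometry is approximate (no dedicated half-chair parametrization).
- Free-energy estimation (MM-GBSA/SRED) and MD simulation itself are
  deliberately out of scope; the analytics operate on externally
  produced trajectories.
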