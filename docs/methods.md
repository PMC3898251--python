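# Methods

## Geometric model

The scan treats a candidate disulfide as a rigid-geometry kinematics problem.
Only backbone atoms (N, Cα, C) enter the prediction: Cβ is always rebuilt with
ideal tetrahedral geometry (d(Cα–Cβ) = 1.53 Å; ∠N–Cα–Cβ = ∠C–Cα–Cβ = 110.5°;
improper torsion N→Cα→C→Cβ positive, i.e. L-amino-acid chirality). Rebuilding
rather than reusing the file's Cβ makes glycine, alanine mutants and
incomplete residues uniform and keeps the blind-validation protocol honest
(the native side chain is never consulted); `ScanConfig(use_file_cb=True)`
restores file Cβ for users who want it. The file's Cβ *is* used for B-factor
averaging, since mobility is a property of the deposited model.

Sγ is placed from (N, Cα, Cβ) with d(Cβ–Sγ) = 1.81 Å and ∠Cα–Cβ–Sγ = 114.6°
as a function of χ1 alone. All ideal covalent values live in `IdealParams`
and are configuration, not constants; the defaults follow standard cystine
stereochemistry. Torsions use the standard atan2 sign convention (positive =
clockwise rotation of the far bond looking down the axis); this fixes the
meaning of χ3 handedness ("chirality") throughout.

## Pose search

For every unordered residue pair with sequence separation ≥ 2 (inter-chain
pairs always allowed), pairs whose rebuilt Cβ–Cβ distance falls outside
3.0–5.5 Å are rejected outright — outside that band no unstrained bridge
geometry exists. The remaining pairs are searched over a χ1 × χ1′ grid
(default 5°). A pose is accepted when

- |d(Sγ,Sγ′) − 2.04 Å| ≤ 0.2 Å,
- χ3 lies within ±10° of −87° or +97°, and
- both ∠Cβ–Sγ–Sγ′ are within 10° of 104.9°.

The grid defaults are deliberately generous around native geometry and every
one of them is a `ScanConfig` field (and a CLI flag); users tightening or
loosening stringency change only configuration.

With refinement on (default), grid cells whose S–S deviation is within a
chord-length margin of the tolerance — the margin is the maximum distance a
sulfur can travel when χ1 moves by half a grid step, ≈0.14 Å at 5° — are
explored on a 1° sub-lattice, and the winning pose is polished by coordinate
descent on the S–S deviation down to steps below 0.01°. This construction
makes the candidate set a superset of an exhaustive 1° grid search wherever a
valid pose exists, so the coarse scan accepts exactly the pairs a 1°
brute-force scan accepts (a property the test suite checks directly). The
polished pose replaces the lattice winner only when it does not materially
change the energy (±0.02 kcal/mol), so reported scores stay comparable to the
brute-force reference; its purpose is geometric accuracy (sub-0.01° χ1) when
the true optimum falls between lattice points, e.g. after coordinates are
rounded to PDB precision.

Among valid poses the one with the lowest total energy is kept; ties break by
distance of χ3 from the nearest window center, then by the lower χ1. The
choice of coarse-grid + sub-lattice + descent over a closed-form circle–circle
intersection is deliberate: it is simple, robust to all the angular gates,
and checkable against a brute-force oracle.

## Energy score

E(χ1, χ1′, χ3, θ, θ′) = a3[1 − cos(k3(χ3 + φ3))] + a1[1 + cos 3χ1] +
a1[1 + cos 3χ1′] + k_θ(θ − θ0)² + k_θ(θ′ − θ0)², angles in degrees.

Defaults: a3 = 4.0 kcal/mol, k3 = 1.957, φ3 = 87°, a1 = 1.4 kcal/mol,
k_θ = 0.015 kcal/mol/deg², θ0 = 104.9°. The χ3 term has period 360/1.957 ≈
183.96°, so its two minima per turn sit at −87° and +96.96° — the peaks of
the χ3 distribution in native disulfides. The χ1 term is the standard
threefold rotamer potential with zeros at the staggered positions (±60°,
180°); the θ terms are harmonic strain on the Cβ–Sγ–Sγ′ angles. The χ1 and θ
constants were chosen so that minima sit at canonical rotamer/geometry values
and near-native geometries score below the ~2.2 kcal/mol guideline that
brackets 90% of native bridges; they are exposed in `EnergyParams` for
recalibration. No χ2 term is included — χ2 does not constrain whether the
sulfurs can meet, only where the remainder of the side chain points — and the
score is a relative geometry-conformity measure, not a ΔΔG.

## ΣB mobility metric and colorimetric scale

Per-residue mobility is the arithmetic mean B-factor over the present atoms
among {N, Cα, C, O, Cβ} (glycine: backbone only). The carbonyl O is included
in "backbone"; excluding it changes means by well under typical inter-residue
differences, but the choice is recorded here because conventions differ. A
pair's ΣB is the sum of its two residue means. For display, residue means are
normalized to 512 discrete steps between the structure's minimum and maximum:
index = round((b − b_min)/(b_max − b_min)·511), rounding half-up, indices
0–255 blue and 256–511 red (so an exact midpoint is the first red step; the
tie rule is a convention, flagged here). Because B-factor scales vary between
structures with refinement protocol and resolution, the scale is always
relative to the structure at hand.

## Survey / blind validation

Native bridges are the union of SSBOND-declared pairs and cysteine pairs
whose file Sγ–Sγ distance is < 2.5 Å, deduplicated. Validation hides side
chains (the scan never reads them), then reports: recovery (native pair
present among predictions), chirality agreement (sign of predicted vs native
χ3), R² of the ordinary least-squares fit of predicted on native χ3 over the
chirality-correct subset (an intercept is fitted, not forced through the
origin), and the median distance between modelled and file sulfurs, pooling
both sulfurs of each recovered bridge (the pairing of modelled to native
sulfur is by residue; pooling is used because a single per-bridge convention
would hide the per-atom error). Energy statistics (mean, 90th percentile,
0.25 kcal/mol histogram) are computed on the *native* geometry of each bridge
(file χ1, χ1′, χ3, θ, θ′). `select_survey_set` applies the two mechanical
survey criteria — at least one native bridge, resolution ≤ 2.0 Å — and leaves
sequence-redundancy filtering to a user-supplied non-redundant list, because
identity clustering is outside this package's scope.

## Synthetic fixtures

`build_ideal_bridge` inverts the kinematics: the disulfide core is laid down
in a canonical frame (Sγ at the origin, Sγ′ at 2.04 Å on x) so the requested
χ1, χ1′, χ3, the S–S length and both 104.9° Cβ–Sγ–Sγ′ angles hold exactly,
then backbones are grown outward and three extended-conformation (φ = −140°,
ψ = 135°) alanine stubs are attached on each side of both cysteines so that
Cβ reconstruction and ΣB averaging see realistic neighbours. χ2 of each
cysteine defaults to −60° (it does not affect any scanned quantity).
Optional i.i.d. Gaussian coordinate noise (seeded) degrades the geometry
controllably; B-factor plans are `constant` (10 Ų) or `gradient` (5→50 Ų
along the chain) to exercise ranking and the colour scale.

What the fixtures emulate — and what they do not: they provide exact planted
geometric ground truth, so recovery/chirality/R²/sulfur-displacement have
known right answers; they are not physically realistic proteins (no packing,
no clash field, arbitrary relative placement of the two chain segments). A
perfect score on them demonstrates the correctness of the kinematics, search
and bookkeeping, not predictive performance on crystal structures. At wide,
non-default χ3 windows the alanine stubs of the two segments can themselves
admit strained candidate poses; these score far above the native-like energy
range and do not affect the validation statistics, which are keyed to the
planted pair.

The survey generator draws χ3 uniformly from [−92°, −82°] ∪ [+92°, +102°]
(the two native peaks ± 5°) and each χ1 from the staggered rotamers, σ = 0,
with per-structure seeds derived from the master seed.

## Numerical choices and degenerate inputs

- Angles are degrees everywhere; torsions are mapped to (−180°, 180°].
- Collinear or coincident points raise `DegenerateGeometryError`; residues
  missing backbone atoms are skipped with a warning, never crash the scan.
- Alternate locations: the highest-occupancy conformer wins, ties go to the
  alphabetically first altloc; HETATM is skipped except MSE (read as MET);
  hydrogens are ignored.
- A flat B-factor profile maps every residue to colour index 0 (blue).
- R² is clamped to [0, 1]; a degenerate regression (fewer than two points or
  zero spread in native χ3) returns 1.0 only on exact agreement.
- Problem sizes in the test-suite/acceptance runs: 50 planted bridges for the
  blind-validation statistics, 8 structures for the brute-force oracle
  cross-check, 0.01° grids for locating energy minima. These sizes make the
  statistics exact for the synthetic ground truth while keeping a full run in
  tens of seconds on one CPU.

## Known limitations

- No clash detection against surrounding side chains, no multi-bridge joint
  optimization, and no loop-length or ΔΔG stability model: the outputs are a
  geometric feasibility score and a mobility ranking.
- The energy's χ1/θ constants are this package's calibration (only the χ3
  term has a published closed form); all constants are user-adjustable.
- mmCIF is not parsed; use PDB format.
- `fetch_pdb` needs network once per entry (then serves a disk cache); every
  other feature, including the whole test suite, is offline.
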