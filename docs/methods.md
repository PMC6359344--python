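# Methods

## The scoring model

PeptoGrid is a knowledge-based rescoring function for peptide docking poses.
Its premise: when a closed library of related peptides is docked into one
binding site, the spatial distribution of atom types across the whole pose
ensemble approximates the site's preferences, and individual poses can be
re-ranked by how well they conform to that distribution.

The pipeline is:

1. **Typing.** Every ligand atom gets a Tripos SYBYL type. Because the
   ligand universe is restricted to peptides of the 20 standard amino acids,
   typing is an exact lookup in a curated (residue, atom name) template
   table rather than general chemical perception; the table was validated
   against bond-perception typing (OpenBabel) on real 3D structures, and the
   test suite repeats that cross-check. Protonation follows standard
   physiological-pH preparation: charged termini (`N.4`, `O.co2` on both
   carboxylate oxygens), charged Asp/Glu/Lys/Arg side chains, neutral His.
   The type alphabet is fixed and ordered (`C.3, C.2, C.ar, C.cat, N.am,
   N.4, N.pl3, N.ar, O.2, O.3, O.co2, S.3, H`); `C.cat` is included because
   arginine's guanidinium carbon requires it. The table ships as JSON and
   can be overridden wholesale (e.g. for a different radii set).

2. **Accumulation.** A vertex lattice covers the docking box: per axis
   `floor(edge/step) + 1` vertices starting at `center − edges/2`, step
   0.1 Å by default. For each atom, all lattice vertices inside its van der
   Waals sphere (closed ball, `|v − x| ≤ r`) increment the occurrence
   counter of the atom's type. Bondi element radii are the default
   (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å).

3. **Scoring.** A pose's raw score is the mean over its atoms of the
   occurrence-map value of the atom's type at the *nearest* lattice vertex
   (rounding of fractional lattice coordinates, half-to-even on exact
   ties). Raw scores are divided by the run maximum, so final scores lie in
   [0, 1] and the best pose scores exactly 1.

A single vertex lattice serves both accumulation and lookup; no distinction
between cell centers and vertices is made anywhere.

## Design choices where the design was open

- **"Frequency" is raw counts.** The final score is normalized by the run
  maximum, so any global positive rescaling of the grid leaves every
  normalized score and rank unchanged (asserted as a property test). A
  `per_pose_fraction` weighting is exposed for interpretability (values
  become per-pose occupancy fractions) but is equivalent for ranking.
- **Out-of-box atoms** contribute nothing to grids (clipping preserves
  additivity of grids over pose-set concatenation) and score 0 while
  remaining in the denominator N — a pose drifting out of the site is
  penalized, not truncated. Fully-outside atoms are tallied in a
  diagnostics counter.
- **Normalization is per run**, not per sequence: one score distribution
  per screening run.
- **Rank ties** are broken by better (lower) native docking energy when
  available, then pose id, for reproducible output files.
- **Hydrogens** are typed (`H`) and included in grids by default, with an
  exclusion switch; docking outputs typically carry polar hydrogens only.
- **Peptide ranking for evaluation** uses each peptide's best-ranked pose
  (a mean-over-poses switch exists in the CLI workflow via the ranked CSV).
- **Grid storage** is dense float32 per type, allocated lazily for types
  that actually occur, processed one type at a time; HDF5 persistence is
  chunked and gzip-compressed, one dataset per type, box metadata in
  attributes. float32 is exact for occurrence counts below 2²⁴. A 30 Å box
  at 0.1 Å step is 301³ ≈ 2.7×10⁷ vertices, ~104 MB per occurring type.

## Numerical choices

- The sphere-membership test is a closed ball with a 1e-12 relative
  tolerance on r², and the candidate bounding box is padded by 1e-9 lattice
  steps, so vertices lying *exactly* on the sphere (atom centered on a
  vertex with a radius that is a multiple of the step) are not lost to
  floating-point rounding. For atoms in general position the tolerance is
  far below coordinate precision and never changes the set.
- Box shape computation adds 1e-9 before flooring, absorbing binary
  representation error in `edge/step` (30/0.1 is not exact in floats).
- Nearest-vertex rounding uses `np.rint` (half-to-even); with a 0.1 Å step,
  exact half-step coordinates are measure-zero in real data.
- Degenerate inputs: an all-zero score set normalizes to all zeros, keeps
  input order, and warns; empty pose sets, untyped atoms, and under-populated
  bootstrap intervals raise immediately with the offending item named.

## Library curation and evaluation

Activity filtering keeps peptides with a single consistent IC50 inside
[1, 1000] μM (bounds inclusive). "Multiple diverse values" is
operationalized as max/min ratio above a 2× tolerance; consistent repeats
collapse to their median. The combinatorial accounting utility reports
`20^k` (8000 tripeptides, 160 000 tetrapeptides).

The stratified bootstrap divides 1–1000 μM into five 200-μM intervals
([1, 200], (200, 400], ... (800, 1000]), draws five peptides per interval
uniformly *without* replacement per replicate, computes Spearman's rho
(average-rank ties; scipy) between the method's ranking and the IC50s of
the 25 drawn peptides, and repeats 1000 times. Rank 1 is the best score and
low IC50 is most potent, so a potency-tracking ranking yields positive rho.
Fixed seed ⇒ bit-identical replicate lists. Note that a *fixed* ranking
independent of the IC50s still has a nonzero sample correlation with them;
the null calibration therefore redraws an independent ranking per replicate,
which is the distribution the symmetry check addresses.

## What the synthetic generator emulates — and what it does not

`synth` produces pose ensembles with planted structure: a fraction of poses
concentrated at designated "binding sites" with Gaussian positional jitter,
the rest uniform decoys, every pose carrying an independent uniform random
rotation. Peptide geometry is an idealized rigid extended chain (generic
1.5 Å heavy-atom bonds, deterministic zig-zag side-chain placement, correct
PDB atom names, no hydrogens); scoring depends only on positions, names and
types, so chemically plausible rigid templates suffice. Ground-truth site
labels accompany the pose set but never enter the fixture files.

What it does **not** emulate: real docking energetics, receptor sterics,
conformational flexibility, correlated pose clusters from a sampling
algorithm, or realistic score–activity relationships. Passing the planted-
site recovery test shows the pipeline concentrates score mass where the
ensemble concentrates atoms — the mechanism the method relies on — not that
any particular experimental correlation will be achieved on real targets,
which depends on the docking program's sampling quality.

## Problem sizes

The test suite and acceptance script run on scaled-down study conditions —
boxes of 10–20 Å at 0.2–0.5 Å steps and ensembles of 40–200 poses — chosen
so the full pipeline (including brute-force oracle comparisons over every
lattice vertex) completes in seconds. The scoring and ranking mathematics
are invariant to these sizes; the memory notes above cover production-scale
grids (0.1 Å step, 30 Å box, thousands of poses).

## Known limitations

- Rescoring is only meaningful within a closed pose ensemble large enough
  to estimate the site's type distributions; a handful of poses yields a
  self-confirming grid.
- Template typing covers standard L-amino-acid peptides only: no modified
  residues, capped termini, or non-peptidic ligands.
- Nearest-vertex lookup (no trilinear interpolation) is faithful to the
  0.1 Å-step design; at much coarser steps the lookup discretization error
  grows.
- The evaluation protocol requires at least five peptides with measured
  IC50s in *every* 200-μM interval.
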