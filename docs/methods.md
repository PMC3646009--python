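# Methods

This note records the models implemented in `srpatch`, the assumptions and
defaults behind them, and what the synthetic-data generator does and does
not emulate.

## Structural data model

Structures are chains of residues with heavy atoms only; HETATM records,
waters and hydrogens are dropped on read. Alternate locations are resolved
to the highest-occupancy conformer, ties going to altloc letter 'A' —
deterministic and conventional. Two numbering schemes coexist: a 0-based
contiguous `seq_index` per chain drives every computation, while author
numbering (plus insertion codes) is preserved for reporting, since
published per-residue results use author numbering. Residues lacking a Cα
are excluded from contact and patch analyses with a logged warning rather
than an error. Multi-chain files are analysed per chain; SR models are
single-chain.

## Solvent accessibility and burial

SASA uses Shrake–Rupley quadrature with a deterministic Fibonacci-spiral
point set (default 960 points, probe 1.4 Å), so no random seed is involved.
Before quadrature the coordinates are expressed in a frame intrinsic to the
structure (principal axes with sign fixing on the third moment), which
makes areas invariant under rigid motion of the input at the cost of exact
occlusion monotonicity across *different* structures; with the
`canonicalize=False` switch the lab frame is kept and adding an atom can
never increase another atom's area.

Radii: carbons 1.87 Å aliphatic / 1.70 Å sp² (carbonyl, carboxyl/amide and
aromatic ring carbons), N 1.55, O 1.52, S 1.80 Å. In the package's coarse
representation (backbone + Cβ only) the Cβ pseudo-atom instead carries a
residue-specific effective radius, the radius of a sphere with the mean
side-chain volume of that residue type — a coarse-grained treatment in the
spirit of single-point-per-side-chain SASA methods. The representation is
auto-detected per structure.

Relative accessibility divides a residue's in-protein area by its area in
an extended (φ = −139°, ψ = +135°) isolated Ala-Xxx-Ala tripeptide built by
the same chain builder and measured by the same engine with the same
representation — numerator and denominator are mutually consistent, which
matters more than matching any particular published reference table.
Residues at or below 20% relative accessibility are buried, above 20%
exposed; the boundary value itself is classified buried because the
defining rule states strict inequalities on both sides and a convention had
to be chosen. Absolute areas from coarse-grained engines differ between
implementations; the buried/exposed classification is the contract, not
the raw Å² values.

## Secondary structure

A compact Kabsch–Sander implementation: amide hydrogens are reconstructed
1 Å from N parallel to the preceding C=O bond (inputs are heavy-atom;
proline and chain-initial residues cannot donate); hydrogen bonds use the
electrostatic energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
kcal/mol with a bond below −0.5 kcal/mol and sub-0.5 Å distances clamped;
n-turns (i→i+3, 4, 5) combine into minimal helices (two consecutive
n-turns) with precedence H > G > I; strand detection is minimal — ladders
of at least two consecutive H-bonded bridges — because SR structures are
helical and sheet accuracy is not a contract here. Helical content counts
H + G + I: SR linkers are known to populate π-helix, so π counts as helix.
Whether published helicity percentages include G and I is generally
unstated; the convention here is recorded and configurable in spirit (the
label vector is returned, so any recount is one line).

## Conservation patches (pbs)

Grades are consumed as input (1..9, 9 most conserved); conserved means
grade ≥ 7. The Cα contact relation is Contact(i,j) = 1 iff |i−j| > 1 and
d(i,j) ≤ 10 Å — the boundary is inclusive (the defining formula), with a
strict-inequality mode available since prose descriptions of the same rule
sometimes read "less than". Sequence neighbours never count as contacts
even when spatially adjacent; consequently a centre's own ±1 neighbours
cannot support it. A conserved exposed residue is a centre when strictly
more than five of its contacts are conserved and exposed themselves —
neighbour qualification requires both properties, the stricter and explicit
of the two published phrasings. Per-repeat counts use centres only (not
cluster members), and flagged regions are maximal runs of adjacent repeats
each holding more than five centres. All thresholds (0.20, 7, 5, 10 Å) are
parameters defaulting to these published values.

## Model quality

The helicity gate reads "within 10% of the 82% template average" as
*relative*: refine below 0.9 × 0.82 = 73.8%. This is the unique reading
consistent with the published outlier set — repeat models at 73% helicity
are reported as diverging, which an absolute ten-point threshold (72%)
would not flag. The absolute reading remains selectable. Z-score bands
partition the line at −5.3 (centre of the canonical-template score
distribution) and −3 (centre of the distribution of non-repeat three-helix
-bundle decoy models): ≤ −5.3 very reliable, ≥ −3 less reliable, reliable
between. "Centre" is the arithmetic mean by default, with a histogram-mode
option (bin width 0.5) since such distributions are usually read off plots.
This module never computes a knowledge-based potential; Z-scores are
inputs.

## Essential dynamics

Ensembles are Cα-only, mass-unweighted. Frames are superposed by Kabsch
(SVD, proper rotation enforced) onto an iteratively refined mean structure,
two passes. RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩. PCA eigendecomposes the 3N×3N
covariance; eigenvalues are clipped at zero and rank deficiency is logged,
not fatal. Subspace overlap between two ensembles is the average square
projection of the first k = 10 eigenvectors of one set onto the first k of
the other: 1 for identical subspaces, ~k/3N for unrelated ones, invariant
to ordering/rotation within each subspace. Motion correlations are
normalized displacement covariances; pairs with |C| above 0.8 are reported
with their signs (anti-correlated pairs count). Porcupine export writes
the mean structure and a copy displaced by scale × eigenvector as two
MODELs, so the per-atom difference vectors are the quills.

Note an unavoidable subtlety: least-squares superposition absorbs whatever
rigid-body component a motion carries. A hinge swing of one segment is
mostly a rigid rotation of that segment, so the PCA eigenvector matches
the *internal* component of the planted hinge field, and RMSF profiles
reflect displacement relative to the best-fit frame (the smaller moiety
appears to move). Tests and analyses therefore compare against
rigid-projected ("internal") modes.

## Synthetic generator: the stated world

`build_bundle` produces an idealized SR-like fold: three ideal α-helices
(φ = −57°, ψ = −47°, Engh–Huber-style bonds and angles, trans peptides)
packed antiparallel on a triangular arrangement at a stated axis separation
(default 10 Å, helix lengths 16/18/16, loops 4/4 — a compact bundle that
keeps test runtimes low while preserving the fold's topology). Loops are
grown by internal-coordinate extension with their dihedrals solved by least
squares to land on the next rigidly placed helix, with up to ten seeded
jittered restarts and fresh helix spins on failure; a purely extended loop
cannot connect antiparallel helices at a fixed separation, which is why
closure is solved rather than prescribed. Carbonyl oxygens are rebuilt
against the actual next amide across junctions. Side chains are a single
Cβ (ideal tetrahedral placement, L-configuration; none for Gly) — see the
SASA section for how the reference areas stay consistent. Consecutive Cα
distances stay at 3.80 Å and non-bonded Cα pairs are checked against
< 3 Å clashes.

`plant_conservation` assigns grades from {7,8,9} to exposed residues within
a radius (default 10 Å) of an exposed centre and background grades 1..6
elsewhere. Because sequence neighbours never count as contacts, a planted
ball can contain seven residues yet no residue with six qualifying
contacts; the generator therefore widens the ball in 1 Å steps (up to
20 Å) until some planted residue would satisfy the centre criterion at the
10 Å detection radius. This guarantee is constructive, logged, and
switchable off.

`build_ensemble` synthesizes frames as reference + Σ_m amplitude_m ·
sin(2π(m+1)t/T + φ_m) · mode_m + isotropic Gaussian noise. Each mode runs
at its own harmonic: harmonics are orthogonal over a full period, keeping
planted modes statistically independent (equal-frequency sinusoids with
random phases correlate by cos Δφ, which would make multi-mode recovery
impossible in principle); per-mode variance is amplitude²/2 regardless of
harmonic. Phases and noise derive from the seed; every generator is
deterministic under a fixed seed.

What the generator does **not** emulate: real side-chain packing and
rotamers, sequence-dependent loop conformations, solvent structure,
anharmonic and multi-basin dynamics, and the length (~106 residues) and
irregularities of real SR units. A green test on synthetic data therefore
establishes that the *operations* implement their definitions and recover
planted ground truth — not that any particular biological repeat has a
binding site or a specific flexibility.

## Numerical choices

- Quadrature: 960 spiral points ≈ 1% worst-case area error on smooth
  spheres; errors shrink roughly monotonically with point doubling.
- Loop closure accepts a maximum atom-position residual of 0.3 Å at the
  junction (about a quarter of a bond length), then rebuilds carbonyls.
- Kabsch rejects < 3 atoms and collinear sets (second singular value
  < 1e−12); reflections are corrected to proper rotations.
- Canonical JSON reports round floats to 1e−6 and sort keys, making
  repeated runs byte-identical.
- Exact-boundary conventions: relative SASA exactly 0.20 → buried;
  contact distance exactly 10 Å → contact; helicity exactly at the gate
  threshold → pass; Z exactly at a cut → the outer class (very_reliable /
  less_reliable).

## Known limitations

- The template-average helicity reference (0.82) is embodied as a default,
  and `template_average_helicity` recomputes it from template coordinates;
  the experimental template structures themselves are not redistributable
  with the package and must be supplied (e.g. under `data/templates/`) to
  reproduce the number.
- Secondary-structure assignment is not full DSSP (no bend/chirality
  classes, minimal strands); agreement is validated against an independent
  Cα-geometry assigner on ideal structures, not on sheets.
- Coarse Cβ SASA is not comparable in absolute terms to all-atom engines;
  only the burial classification is portable.
- Multi-repeat synthetic rods place units side by side without modelling
  the covalent linker; they exercise per-repeat bookkeeping, not linker
  mechanics (hinge ensembles cover that separately).
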