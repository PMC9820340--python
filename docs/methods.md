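# Methods

xenbkit analyses why a flavin-dependent reductase (the motivating case is
xenobiotic reductase B, XenB, which transfers a hydride from FMN N5 to bound
nitroaromatics) processes some chemically similar substrates and not others.
It combines four largely independent calculations — ligand reactivity from
frontier orbital energies, hydride acceptor–donor (HAD) distance statistics
over trajectories, density-based pose clustering with contact mapping, and
promolecular non-covalent-interaction (NCI) grids — plus a synthetic-data
generator that stands in for molecular-dynamics and quantum-chemistry runs.

## Global reactivity descriptors

Inputs are per-compound frontier orbital eigenvalues (eV). Within the
Koopmans approximation, I = −ε_HOMO and A = −ε_LUMO, and the descriptors are

- gap = ε_LUMO − ε_HOMO,
- electronegativity χ = (I + A)/2,
- global hardness η = (I − A)/2,
- electrophilicity ω = χ²/(2η),
- electrodonating power ω⁻ = (3I + A)²/(16(I − A)),
- electroaccepting power ω⁺ = (I + 3A)²/(16(I − A)),
- net electrophilicity Δω± = ω⁺ + ω⁻.

ω⁻ − ω⁺ = χ and 2ηω = χ² hold identically and are asserted as properties.
All descriptors are homogeneous of degree one in the orbital energies.

Two display modes are provided because published tables differ in how they
shorten values: `truncate` (toward zero) and `round_half_even`. The packaged
seven-compound table of nitroaromatic orbital energies agrees cell-by-cell
with its published one-decimal form under truncation for the unambiguous
cells; a few published cells (e.g. the TNT Δω± column) were evidently
computed from unrounded energies and cannot be reproduced from the rounded
orbital columns, so they are documented rather than targeted. For the same
reason the fixture carries the published gap column separately
(`gap_printed`): differencing the rounded orbital energies does not
reproduce it for every compound, and the energy-gap ordering
(TNB > NBZ > {DN6, DN4} > TNT > {4AD, 2AD} at a 0.05 eV tie tolerance) is
defined on that column. Display truncation first absorbs binary-float
representation noise at 1e-9 so that a value that is exactly 5.9 in decimal
arithmetic never truncates to 5.8.

## Superposition, RMSD, and HAD distances

Rigid superposition is the Kabsch algorithm via 3×3 SVD with the
determinant correction that excludes reflections; it is cross-checked in the
tests against an exhaustive Euler-angle grid search and against an
independent library implementation. RMSD is available raw (fixed
correspondence) or fitted (Kabsch-minimized); raw RMSD is a metric and the
fitted value can never exceed it.

The HAD distance is the per-frame Euclidean distance from the cofactor
donor atom (FMN N5) to one named acceptor atom of the ligand (a nitro
nitrogen or ring carbon). Distances are summarized as normalized histograms
(default bin width 0.1 Å, covering the observed range) — histograms, not
kernel density estimates, so every probability mass is exactly
reconstructable.

No quantitative stability criterion is standard, so the package makes its
own explicit: a complex is *stable* when the fraction of frames with HAD
distance ≤ cutoff reaches a required occupancy. Defaults: cutoff 6.0 Å,
occupancy 0.8. Both are reported with every classification so the call is
always auditable.

## Pose clustering

Entry (i, j) of the pairwise ligand-RMSD matrix superposes frame j onto
frame i by a protein *fit* selection and then takes the ligand heavy-atom
RMSD **without re-fitting the ligand** — the quantity measured is the pose
relative to the binding site, which is what distinguishes binding modes.
Hydrogens are rejected from the ligand selection outright. The matrix is
exactly symmetric for a unique optimal fit; both orientations are computed
and averaged as a numerical guard.

Clustering is classic DBSCAN on the precomputed matrix with the defaults
ε = 1.5 Å and min_points = 5, where neighbor counts include the point
itself (stated explicitly because implementations differ). Clusters are
connected components of core points under ε-adjacency; border points join
the cluster of their lowest-labeled core neighbor, which makes the
order-dependence of textbook DBSCAN explicit and deterministic. Labels are
assigned by each component's smallest frame index, so relabeling is the only
freedom under frame reordering. Each cluster's representative is its medoid
(minimal summed RMSD to the other members, ties to the lowest frame id) —
the standard deterministic choice when only a distance matrix is available.

Contact residues are all residues (excluding the ligand's own) with any
atom — hydrogens included — within a cutoff (default 3.0 Å) of any ligand
atom, sorted by residue id.

## Promolecular NCI grids

The electron density is promolecular: a sum of spherical free-atom
densities ρ_atom(r) = Σᵢ cᵢ exp(−r/ζᵢ) (atomic units). The shipped
parameter set is an occupation-normalized exponential-shell model built
from Clementi–Raimondi screened exponents: a shell of occupation n and
exponent ζ contributes (nζ³/π)·e^(−2ζr), which is the exact 1s-shell
density and integrates to n electrons for every shell. Parameters are plain
data (H, C, N, O, P, S) and can be replaced wholesale by any positive
exponential fit.

Density, gradient, and Hessian are accumulated analytically per exponential
term — no finite differences anywhere in the production path; the
finite-difference comparison lives only in the tests and the acceptance
script, where it is the oracle. The reduced density gradient is

    s = |∇ρ| / (2 (3π²)^(1/3) ρ^(4/3)),

and λ₂ is the middle eigenvalue (ascending order) of the 3×3 density
Hessian. Points with s < s_max (default 0.5) are weak-interaction
candidates and are partitioned by sign(λ₂)ρ against ±t (default t = 0.01
a.u.): attractive below −t, van der Waals within ±t, repulsive above +t.
The thresholds follow common NCI practice and are exposed as parameters.
Interfacial analysis restricts the grid to the ligand bounding box padded
by a margin (default 3 Å, the same shell used for contact residues) while
summing the density over every atom of the complex. Grid geometry is
Angstrom in memory; cube files are written in Bohr (the format's
convention) with conversion localized to the writer. Default spacing is
0.15 Å. Heavy-atom-only structures are accepted with a warning, since
trajectory frames often lack hydrogens.

## Electrostatic potential maps and ring currents

The ESP is evaluated at monopole level, V(r) = Σ q_a/|r − R_a| (a.u.), from
user-supplied partial charges (a RESP fit, in the motivating workflow);
grids that touch a nucleus are rejected rather than regularized. Extrema
are searched on a van-der-Waals-scaled shell band (Bondi-style radii,
default scales 1.2–2.0): outside every atom's inner scaled radius, within
some atom's outer scaled radius. This is a deliberately coarse stand-in for
density-based potential maps — adequate for the qualitative statement that
minima localize on nitro oxygens, not for quantitative surface potentials.

Ring current strengths (nA/T) arrive as integrated diatropic (≥ 0) and
paratropic (≤ 0) components per ring; the package adds them and classifies:
aromatic if net > z, antiaromatic if net < −z, else non-aromatic, with
z = 1.0 nA/T by default and strict inequalities at the boundaries. Display
rounds half away from zero at one decimal so the benzene reference
(17.60 − 4.95 = 12.65 → 12.7) reports in its published form.

## Synthetic data generator

The generator emulates what a long (200 ns, 50 frames/ns) bound-complex
simulation hands to the analysis stages, at test scale:

- a fixed pocket scaffold: an FMN-like residue with donor atom N5 defining
  the z = 0 plane, three pocket residues placed ~2.8 Å from the ligand
  (so the 3 Å contact shell finds exactly those three), and one distant
  residue that must never register;
- a rigid planar TNT-like ligand (16 heavy atoms + 5 H; ring C1–C6, methyl
  C7, nitro groups N2/N4/N6 with their oxygens) stacked ~3.3 Å above the
  cofactor plane, so the standard selection expressions (FMN N5, nitro
  nitrogens, ring carbons, "not element H") all resolve;
- per frame, a pose mode drawn by weight, a rigid displacement plus
  isotropic Gaussian noise, then a slide along the donor→acceptor axis so
  the realized HAD distance equals a N(mean, sd) draw *relative to that
  mode's own donor–acceptor geometry*. The relative formulation matters:
  sliding every mode to one absolute distance would drag displaced modes
  back toward the donor and destroy planted cluster structure, while the
  single-mode default still realizes exactly N(mean, sd), giving the
  distributional tests closed-form expectations (sample mean within
  3σ/√n of the recipe mean);
- optionally an escape event: from a given frame on, the slide is dropped
  and the ligand drifts away at a constant rate — the unstable counterpart.

Defaults are 500 frames at 0.02 ns intervals with HAD mean 3.5 Å and sd
0.2 Å; `full_scale_recipe()` provides the full 10,000-frame version of the
same process. Poses are sampled independently per frame, not propagated:
there is no force field, no solvent, no autocorrelation. Passing tests
therefore demonstrate that the analysis operations recover planted
structure exactly as specified — they do not demonstrate robustness to
force-field artifacts, slow conformational drift, or correlated noise in
real trajectories. All draws come from one `numpy` generator seeded per
recipe; identical recipes give bitwise-identical trajectories.

## Numerical choices and degenerate inputs

- Coordinates are Å everywhere in memory; NCI/ESP fields are atomic units;
  unit conversion happens only at cube I/O and field evaluation.
- A degenerate HOMO/LUMO gap raises (ω-type descriptors divide by η);
  inverted levels are rejected at parse time with an explanatory message.
- Histogram edges start at the series minimum with fixed-width bins; a
  constant series yields a single full-mass bin.
- Grid nodes exactly on a nucleus: rejected for ESP; for promolecular
  fields the radius is clamped at 1e-12 Bohr, which leaves ρ finite and the
  gradient zero by symmetry.
- Medoid and DBSCAN ties break toward the lowest frame id / label, never
  toward insertion order.
- Selection grammar is conjunctions of five predicates only (resname,
  resid, name, element, not element); anything else is a syntax error that
  echoes the expression.

## Problem sizes used in the checked runs

The test suite and the acceptance script run the NCI oracles on a ~6 Å box
at 0.15 Å spacing (≈ 69k points), DBSCAN reference comparisons on 100
random instances of up to 200 points, pose recovery on 40 frames per
planted mode, HAD statistics at n = 500 frames, and the superposition
guarantees on 1,000 random pairs. These sizes were chosen so each property
is measured well inside its stated tolerance; the generator scales to the
full 10,000-frame preset unchanged.

## Known limitations

- Promolecular densities are qualitative: exponential shells have no
  shell-structure shoulder, so absolute ρ values near heavy nuclei are
  rough; NCI topology (saddles, low-s regions) is what the model is for.
- Monopole ESP cannot reproduce density-based potential maps; it supports
  sign/location statements only.
- No bond perception, no mmCIF/binary trajectory formats, no altloc
  handling; trajectories must share one topology in file order.
- DBSCAN is O(n²) on the precomputed matrix, and the pairwise RMSD matrix
  itself is the cost driver for long trajectories; subsample frames before
  clustering very long runs.
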