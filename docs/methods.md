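# Methods

`peas` produces candidate gas-phase conformer ensembles of singly charged
small-molecule adducts for ion-mobility mass spectrometry (IM-MS) structure
assignment. The pipeline runs five stages with no user intervention between
them: charge-site enumeration and ranking, torsional conformer generation,
CCS-focused filtering, normal-walk similarity reduction, and
Boltzmann-weighted evaluation. This note records the models, parameters and
numerical choices behind each stage, and what the built-in surrogates do and
do not emulate.

## Charge models and two-tier ranking

A neutral input (SMILES or XYZ) is turned into candidate **protomers**
([M+H]+) or **deprotomers** ([M−H]−). Titratability is valence-based: for
protonation, any N with fewer than 4 connections or O with fewer than 3 (a
lone pair is available); for deprotonation, any N or O bearing at least one
hydrogen. Valence-saturated nitrogens (e.g. nitro N) are thereby excluded.
The added proton is placed at a standard bond length (N–H 1.01 Å, O–H
0.96 Å) along the least-crowded direction — the direction, among 64
Fibonacci-sphere candidates plus the anti-bonding direction, that maximizes
the minimum distance of the new H to every existing atom. Deprotonation
removes the lowest-index H on the site. All other atoms are untouched, so
sibling models share geometry except at the charge site.

Ranking is two-tier through the `SiteScorer` contract: a primary scorer
orders all models, a secondary scorer re-scores (and may re-geometrize) the
top-k, and the secondary ordering **supersedes** the primary one within that
group. This mirrors the common pattern of a cheap learned ranker refined by
a physics-based or ML potential. Both tiers default to the built-in
surrogate: a fixed site-affinity table (amine N 225 > imine N 218 >
carbonyl O 197 > hydroxyl/ether O 190 on the protonation side; carboxyl-type
O–H 338 < generic O–H 347 < N–H 366 on the acidity side, kcal/mol scale)
plus the clash score of the geometry. The table reproduces coarse gas-phase
basicity/acidity orderings well enough to exercise the machinery; it is
explicitly a surrogate and **its scores are not chemical energies**. Scorer
failures drop the affected model with a warning rather than aborting.

Gas-phase mole fractions per charge state are Boltzmann weights
x_i = exp(−ΔE_i/RT)/Σ exp(−ΔE_j/RT) with R = 1.98720425864×10⁻³
kcal mol⁻¹ K⁻¹ and T defaulting to 298.15 K (a conventional choice; ions in
a drift tube are near ambient temperature).

## Conformer generation and diversity filtering

The built-in generator drives every rotatable bond over a uniform torsion
grid (default 120°, i.e. 3 settings per bond) and enumerates all
combinations, rotating the smaller fragment about each bond (Rodrigues
rotation; axis endpoints never move, so sequential application is
well-defined). A **rotatable bond** is an acyclic single bond between two
non-terminal heavy atoms, each with at least one further heavy neighbor;
amide C–N bonds count (the simplest consistent rule — the stricter
convention that excludes amides would lower the count and hence the
normal-walk step number for peptide-like systems). When the grid exceeds
`num_of_conf` (default 1000), a seeded uniform subsample of torsion
combinations is taken.

Energies come from a purely repulsive clash score,
E = Σ_nonbonded k·max(0, 0.8·(r_vdw,i + r_vdw,j) − d_ij)² with
k = 100 kcal mol⁻¹ Å⁻² and Bondi radii; 1-2 and 1-3 pairs are excluded. The
score has no torsional, electrostatic or dispersion terms — it only orders
clashed against open geometries, which is all the downstream filters need
deterministically. Real generators and energy models plug in through the
`ConformerGenerator` contract.

The diversity filter drops conformers above `min_energy + energy_window`
(default 50 kcal/mol), then scans the rest greedily in ascending energy
(tie → input index), rejecting anything within `rmsd_cutoff` (default
0.5 Å, superposed RMSD) of an already-kept member, stopping at
`num_of_conf`. The global minimum-energy conformer is therefore always
kept. The 0.5 Å / 50 kcal/mol defaults follow the published defaults of
widely used torsion-driving generators; both are configurable.

## CCS prediction and focusing

The built-in predictor is the **projection approximation (PA)**: the CCS is
estimated as the orientation-averaged projected area of the union of
atom-centered disks with radii r_vdw + r_probe, r_probe = 1.55 Å for N₂
buffer gas. Areas are computed by rejection sampling (default 4096 points
per orientation over the disks' bounding box) averaged over 64 seeded
uniform random orientations (quaternion sampling), giving ≈1% Monte-Carlo
standard error on small molecules; the standard error across orientations
is exposed as metadata. Every `predict` call reuses the predictor's seed,
so predictions are a pure function of geometry and filtering is idempotent.
PA systematically underestimates the CCS of concave ions relative to
trajectory-method values, and the built-in is charge-blind; trained
predictors plug in through the `CCSPredictor` contract, which also carries
an `accuracy` attribute (fractional 1-σ relative error, default 0.03).

The focus filter keeps conformers with |CCS_pred − CCS_ref| ≤ w·CCS_ref.
The window fraction w defaults to the predictor's accuracy — a predictor
you trust to 3% cannot meaningfully exclude conformers closer than 3% to
the reference. The exact functional form tying window width to model
accuracy is an open design point; the symmetric relative window is this
package's choice. An empty focus result is a warning plus a structured
advisory (regenerate with `num_of_conf ≫ 1000`), never a crash, so users
can backtrack.

## Normal-walk reduction

Focus ensembles larger than 50 members are thinned before quantum-chemical
refinement. Every member's RMSD to a reference — the lowest-energy
conformer (tie → lowest index; first conformer when energies are absent) —
is computed by SVD/Kabsch superposition over all atoms (members share a
full atom ordering; a heavy-atom option exists). The mean, population
standard deviation, minimum and maximum of the non-reference RMSDs define
the distribution the walk traverses in

    steps = max(1, 20 × ROT)

moves from the trailing tail (minimum RMSD) to the leading tail (maximum),
so flexible molecules keep proportionally more structures. The default
(`variant="binned"`) partitions [min, max] into `steps` equal-width
intervals and keeps exactly the lowest-energy member of each occupied
interval (tie → lowest index); everything else at a walk position falls
below that position's similarity score and is removed. A quantile variant
(`variant="quantile"`) places the interval edges at quantiles of the fitted
normal N(mean, sd), concentrating walk positions where the RMSD density is
highest. The reference always survives, output preserves input order, the
survivor count is bounded by steps + 1, and the reduction is deterministic
and idempotent. A degenerate distribution (min = max, e.g. an ensemble of
identical geometries) keeps the reference plus the overall lowest-energy
member — one conformer when those coincide — with a warning.

The 20-steps-per-rotatable-bond factor is a sampling heuristic; the floor
of one step keeps rigid molecules (ROT = 0) well-defined.

## Evaluation

Per rank, the surviving conformers' predicted CCS values are Boltzmann
averaged with weights from their energies (whatever energy model produced
them — the clash score by default; the weighting code is
energy-source-agnostic), and the weighted CCS is compared with the
reference: error % = 100·|CCS_w − CCS_ref|/CCS_ref, **viable** iff
≤ 3.0% (boundary inclusive), the community threshold for agreement between
calculated and drift-tube CCS. As T → ∞ the weighted CCS tends to the
arithmetic mean, as T → 0⁺ to the minimum-energy conformer's CCS; both
limits are verified numerically in the tests. Evaluation is skipped when no
reference is supplied.

Outputs land in `Completed_Job/<name>/`: one `opt_Rank[n]_<site>.xyz` per
charge model, `Conformer/opt_Rank[n]_ensemble/` and
`Conformer/opt_Rank[n]_focus/` per rank, a `results_sum.log` with stable
field order and fixed numeric formats (fixed seed ⇒ byte-identical runs),
and a zip of the focus folders plus the log (fixed timestamps, so the
archive is also reproducible).

## Synthetic ensembles

`synth_ensemble` builds test ensembles by adding i.i.d. Gaussian noise
(given sd) to a base geometry, then applying a seeded random rigid rotation
and translation per member, with clash-score energies. It emulates an
ensemble of near-degenerate conformers scattered around one basin — the
regime the RMSD-based filters operate in — but not genuine torsional
multi-basin structure, anharmonic distortions, or energy–geometry
correlation. Tests passing on it demonstrate the correctness of the
filtering/reduction logic, not predictive accuracy on real conformer
ensembles.

## Numerical choices and limitations

- Kabsch superposition uses the SVD determinant sign correction, so
  reflections are never counted as matches; RMSD of identical sets is zero
  to ~1e−15 (floating-point).
- XYZ I/O is the strict 2-header-line dialect, coordinates written with 6
  decimals; the comment line carries `name energy=E` metadata. XYZ input
  gets distance-based bond perception (covalent radii + 0.45 Å tolerance),
  which assigns all orders as single — rotatable-bond counts from XYZ input
  can therefore differ from SMILES input for conjugated systems.
- Formal charge is restricted to {−1, 0, +1}; multiply charged and metal
  adducts are out of scope, as are stereochemistry/tautomer enumeration,
  ring-conformation sampling, force-field minimization, and
  trajectory-method CCS.
- Pipeline test and example runs use `num_of_conf = 50` on glycine-sized
  molecules — small torsion spaces make larger targets moot there; 1000
  remains the shipped default for real use.
- Determinism: every stochastic stage (embedding, grid subsampling,
  Monte-Carlo orientations, synthetic fixtures) draws from a seed derived
  from the run seed; equal seeds give byte-identical output trees.
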