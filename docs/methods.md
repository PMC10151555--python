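# Methods

This note documents the models, formulas, numerical choices and design
decisions behind `argqsar`, and what the synthetic benchmarks do and do
not demonstrate about real data.

## Structure preparation

Input structures (SDF/MOL/SMILES) are reduced to their largest covalent
fragment (salt counter-ions are discarded, the common QSAR curation
choice), given explicit hydrogens, and — when no 3D conformer is
supplied — embedded with seeded ETKDG distance geometry followed by
MMFF94 relaxation. Descriptors computed from embedded conformers
therefore depend mildly on the embedding seed; fixed-coordinate inputs
are used as-is and give exactly reproducible values. Per-record parse
failures are collected and reported, never silently dropped; an input
with zero valid records is a hard error.

Atom typing:

* **ring membership** — smallest set of smallest rings (SSSR);
  `ring-nitrogen`/`ring-carbon` are the element-restricted ring flags.
  A toolkit-free fallback (leaf pruning to find cycle atoms) serves
  hand-built molecules in tests.
* **donor** — N or O bearing at least one bonded hydrogen (the
  conventional hydrogen-bond-donor definition).
* **sp2 oxygen** — oxygen participating in a double bond (carbonyl,
  nitro, sulfonyl-type oxygens).
* **partial charges** — Gasteiger–Marsili iterative partial
  equalization; the model is the configurable default because it is
  the de facto standard of the molecular-graphics ecosystem this kind
  of descriptor pipeline grew out of. A **lipophilic hydrogen** is any
  hydrogen with |q| ≤ 0.200 e (inclusive).

## Surface areas

MSA (molecular / van der Waals surface) and SASA (solvent-accessible
surface) are both computed with an in-package Shrake–Rupley algorithm:
quasi-uniform golden-spiral test points on each probe-inflated atomic
sphere (Bondi radii; probe 1.4 Å for SASA, probe 0 for MSA), with a
point counted as buried when strictly inside a neighbouring sphere.
Points lying exactly on a coincident neighbour's surface are assigned
to the lower-indexed atom, so perfectly overlapping spheres contribute
one surface rather than two or zero — a deterministic tie-break for the
degenerate case. 960 points per atom keep the single-sphere error well
under 1%; doubling the count moves molecular areas by < 1%.

The `rsa` descriptor is the ratio MSA/SASA. Absolute areas depend on
the radius set, probe and point density, which the original descriptor
software does not publish; only the ratio arithmetic is anchored
(460.1/677.8 = 0.6788).

## Descriptors

"Frequency of occurrence" descriptors are read as the number of
**unordered qualifying atom pairs** (one atom from the source category,
one from the target category) at an **exact** shortest-bond-path
distance; each pair counts once even when the categories overlap. A
per-target-atom alternative is available behind `counting_mode`.
Distances are computed on the full molecular graph including hydrogens
(`fHringC2B` requires explicit H). Disconnected atom pairs are at
infinite distance and never match.

`fsp2OC9B` carries the published exclusion clause, implemented as: a
carbon is not counted for a given sp2 oxygen if it also lies exactly
nine bonds from **any other** oxygen atom; the rule is switchable
(`apply_exclusion=False`). Ring carbons are eligible "carbon" targets
in `fringCC3B` (benzene scores 3, its para pairs); the definition says
"carbon atom", not "non-ring carbon".

`com_lipohyd_3A` counts lipophilic hydrogens within 3.0 Å (Euclidean)
of the all-atom mass-weighted centre of mass; it is rigid-motion
invariant because the centre of mass moves with the molecule.

## Objective feature selection

`ofs_prune` removes, in order: constant columns; near-constant columns
(≥ 95% identical values by default — "near-constant" is not quantified
in the QSAR literature consistently, this is common practice); then
iteratively the worst-correlated pair above |r| > 0.90, dropping the
member less correlated with activity (or the later column when no
activity is attached). The procedure is deterministic and idempotent.

## Model and selection

Models are ordinary least squares with intercept (numpy
QR/least-squares); rank-deficient designs raise with the collinear
columns named via pivoted QR. The published equation is frozen as a
constant with its printed coefficients and ± values; those
uncertainties are stored verbatim and not recomputed (their definition
is not published), while textbook (XᵀX)⁻¹s² standard errors are
available behind `compute_se=True`.

**Q²LOO fitness** uses the hat-matrix identity (LOO residual =
e_i/(1−h_ii)); property tests pin it to explicit n-refit enumeration at
1e-10. **QUIK**: K(M) = Σ|λ_j/Σλ − 1/p| / (2(p−1)/p) over the
eigenvalues of the correlation matrix; a subset passes when
K_xy − K_xx ≥ ΔK (default 0.05). During evolution infeasible subsets
retain their Q² minus a constant penalty of 1000 instead of −∞, so
selection pressure still points toward feasibility; the reported
winners are re-checked and must pass QUIK outright.

GA internals (this package's own reproducible choices, since the
original selection software does not publish its operators): tournament
selection of size 2, uniform crossover on index sets (children keep the
parents' intersection and fill up randomly from the symmetric
difference), point mutation swapping one descriptor, elitism 2,
population 100 × 200 generations by default. Fitness values are
memoized per subset. Identical seeds reproduce identical results
bit-for-bit.

## Validation statistics

With n training compounds, p descriptors, residual sum RSS and total
sum TSS:

* R² = 1 − RSS/TSS; R²adj = 1 − (1−R²)(n−1)/(n−p−1);
  RMSE = √(RSS/n); s = √(RSS/(n−p−1)); F = (R²/p)/((1−R²)/(n−p−1));
  Friedman LOF = (RSS/n)/(1 − (p+1+d·p)/n)² with smoothing d = 0.5
  (configurable; published LOF values are not comparable because d is
  never stated).
* Q²LOO = 1 − PRESS/TSS from hat-shortcut LOO residuals; RMSEcv, MAEcv
  and CCCcv come from the same LOO predictions.
* Q²LMO: random left-out groups (30% out, 1,000 repeats by default),
  per-repeat Q² = 1 − PRESS/TSS with TSS about the training-fold mean,
  averaged. Random groups (not contiguous blocks) are used.
* Y-scrambling permutes the response, refits and records R², Q²LOO and
  RMSE per iteration (2,000 by default). Because the design is fixed,
  all iterations share one orthogonal basis and one hat diagonal, so
  the whole battery is a single matrix product — effectively free.
* External set: Q²F1 (training-mean reference), Q²F2 (external-mean
  reference; never exceeds Q²F1), Q²F3 (per-observation training
  variance), Lin's CCC, and the through-origin diagnostics
  k = Σyŷ/Σŷ², k′ = Σyŷ/Σy², R²o and R′²o from through-origin fits in
  both orientations, r²m = r²(1 − √(r² − R²o)) averaged over both
  orientations with their absolute difference as Δr²m. The regression
  angle is arctan(slope of predicted-on-observed OLS) − 45°.
  Zero-variance prediction or observation blocks set the through-origin
  R² terms to 0 rather than dividing by zero.
* Lin's CCC uses population (1/n) moments and is symmetric in its
  arguments.

`external_stats` takes the full training response vector (not just its
mean): Q²F3 needs TSS_train/n_train, which the mean alone cannot
provide.

## Applicability domain

Leverage of a (query) descriptor vector x is h = x̃(X̃ᵀX̃)⁻¹x̃ᵀ with an
intercept column; training leverages sum to p+1 and lie in [1/n, 1].
The warning threshold is h* = 3(p+1)/n_train — 0.1409 for n = 149,
p = 6. A compound is in-domain when h ≤ h* and, when residuals are
available, |standardized residual| ≤ 3 (the conventional Williams-plot
band). Screening hits are annotated against the training descriptor
block; entries failing descriptor computation are counted and listed,
never dropped from the accounting.

## Synthetic data

`make_regression_dataset` draws a correlated multivariate-normal
descriptor pool (pairwise correlation 0.2 by default, mimicking the
mild intercorrelation of a pruned descriptor pool), plants a linear
signal on named columns and adds Gaussian noise. When no noise level is
given it is calibrated so the population R² — Var(Xβ)/(Var(Xβ)+σ²) —
equals the target (0.9 by default, matching the fit quality the
workflow is designed to detect). The canonical benchmark is n = 150,
43 pool columns, 3 informative.

`make_molecules` assembles valence-legal SMILES from chain, ring,
fused-ring and pyridine scaffold templates with polar/apolar
substituents, then embeds and charges them; the generated sets span all
atom categories the descriptors test. `make_library` writes
deterministic `.smi` files and can append a planted positive control —
a compact branched alkane (2,2,4,4,6,6-hexamethylheptane) whose
computed descriptors (high rsa, many lipophilic hydrogens near the
centre of mass, zero ring-carbon counts) predict pIC50 ≈ 10 under the
published equation across embedding seeds.

What the synthetic benchmarks show: the selection/validation machinery
recovers planted truth at realistic signal-to-noise, the statistics
match their defining formulas, and the screening pipeline ranks and
flags correctly. What they do not show: that the six descriptors
capture real arginase pharmacology, or that the pipeline reproduces the
descriptor values of the original 149-compound dataset — those
structures are not machine-readable here, and the original surface
algorithm, radius set and charge model are unpublished, so absolute
MSA/SASA (and hence rsa) values may differ from the original software's
by a few percent.

## Known limitations and recorded inconsistencies

* Conformer-dependent descriptors (rsa, com_lipohyd_3A) vary slightly
  with the embedding seed for SMILES inputs.
* The printed training statistics of the published model cannot be
  re-derived exactly without the original 119/30 split labels; the
  package verifies the arithmetic identities that are derivable
  (adjusted R² from printed R², h* from n and p, the intercept
  prediction, the rsa ratio).
* Some published constants are internally inconsistent (an s and F pair
  that do not follow from the printed RSS/n/p under textbook formulas;
  one molecule's rsa arithmetic; a ΔK printed without a decimal point).
  The package uses the textbook formulas throughout and does not anchor
  tests to those values.
* Acceptance-scale runs use the n = 150 benchmark and 10-seed GA
  repeats — sizes chosen so the whole battery completes in seconds
  while leaving the planted-recovery test statistically meaningful.
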