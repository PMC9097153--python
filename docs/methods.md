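# Methods

This note records the models implemented in `endstate`, the defaults and
why they were chosen, what the synthetic fixtures do and do not emulate,
and the numerical choices a maintainer would want to know about.

## End-state decomposition

All energies are kcal/mol, lengths Å, times ps. The per-frame binding free
energy is the sum of four terms evaluated on the complex, receptor, and
ligand views of one snapshot (single-trajectory bookkeeping, so bonded
terms are identical in all three states and are never computed):

* **Gas phase.** ΔE_ele and ΔE_vdW are receptor↔ligand cross sums with no
  cutoff (end-state post-processing convention; the systems handled here
  are small). The Coulomb constant is 332.0637 kcal·Å·mol⁻¹·e⁻²; LJ
  combination is Lorentz–Berthelot (arithmetic rmin/2, geometric ε). The
  interior dielectric ε_int divides the Coulomb cross term only; the same
  ε-scaled ΔE_int series feeds the interaction-entropy estimator. The
  scaling E_ele(ε) = E_ele(1)/ε is exact by construction and is asserted
  as such in the tests.
* **Polar solvation.** The GB flavor is the Still functional form,
  f_GB = √(r² + R_iR_j·e^(−r²/4R_iR_j)), with the i=j self-terms included,
  so the single-atom limit is the exact Born formula. Effective radii come
  either from the intrinsic radii unchanged or from an HCT-style pairwise
  descreening integral with neighbor-radius scale 0.8 and zero radius
  offset — the zero offset keeps the isolated-atom limit exact. This is
  deliberately *not* a reproduction of any Amber GB parameterization
  (GB-Neck2 etc.); users should not expect Amber-identical numbers, only
  the same protocol structure. GB exposes no interior-dielectric knob
  (interior effects are approximated through the Born radii); only the PB
  solver and the gas-phase Coulomb term do.
* **Salt.** In GB, an exponential Debye factor e^(−κf)/ε_w on the solvent
  term; in PB, κ² applied outside the solute plus a 2.0 Å ion-exclusion
  layer. κ is computed from first principles for a 1:1 electrolyte
  (κ² = 8π·k_coul·N_A·I/(ε_w·k_B·T·10²⁷)); at 150 mM/298 K the Debye
  length is 7.85 Å. Default ionic strength 0.150 M.
* **PB solver.** Finite-difference linearized PB on a uniform grid:
  harmonic face dielectrics assigned from the two-dielectric sphere map,
  trilinear charge spreading, Dirichlet boundary from a Debye–Hückel
  monopole (or zero), red-black SOR with the optimal-ω estimate and a
  10⁻⁶ relative-residual tolerance. The reaction field subtracts a
  same-grid homogeneous-dielectric solve, so the grid Coulomb self-energy
  cancels exactly. On the Born ion the relative error is ~8% at 0.8 Å,
  ~5% at 0.5 Å, and ~1.5% at 0.25 Å spacing.
* **Nonpolar.** γ·SASA + b per species with γ = 0.00542 kcal mol⁻¹ Å⁻²
  and b = 0.92 kcal mol⁻¹ (both configurable). SASA is Shrake–Rupley on a
  fixed golden-section spiral of 960 points (probe 1.4 Å), deterministic
  by construction; the isolated-sphere discretization error at 960 points
  is far below 1%. Because each species carries its own offset b, the
  binding difference for non-interacting parts is exactly −b — a
  bookkeeping identity the tests audit.

## Solute entropy

* **Interaction entropy.** −TΔS = (1/β)·ln⟨e^(β(ΔE_int−⟨ΔE_int⟩))⟩
  evaluated with log-sum-exp; non-negative by Jensen's inequality, zero
  for a constant series, and βσ²/2 in the i.i.d. Gaussian limit (σ = 2
  kcal/mol at 298 K gives ≈ 3.38 kcal/mol). The estimate is computed once
  on the series pooled over all replicas — no per-replica SD — so replica
  error bars elsewhere exclude this term. The estimator's exponential
  average converges slowly for wide distributions; the error branch
  recommends raising ε_int, which narrows ΔE_int.
* **Truncated NMA.** Residues with any atom within r_keep (default 16 Å)
  of the partner are retained; those whose minimum distance falls in
  [r_freeze_inner, r_keep] (default 12–16 Å) are frozen through both
  minimization and the frequency calculation, as are the n closest whole
  waters (defaults 1000 for the complex, 500 for free species) and the
  caps. Distances use the any-atom convention on a user-designated
  reference frame. A chain break is closed by a single frozen pseudo-atom
  taking its per-frame coordinates from the first atom of the first
  deleted residue (acetyl on the N-terminal side of a break, amide on the
  C-terminal side); since the toy systems carry no real chemistry, a
  heavier cap model would be fiction. Belly minimization (L-BFGS-B over
  flexible coordinates only) runs to an RMS gradient ≤ 10⁻⁶
  kcal·mol⁻¹·Å⁻¹ — the convergence criterion is interpreted as an RMS
  *gradient* because those are its units — with frozen coordinates
  bit-identical by construction. The Hessian is a central finite
  difference of the analytic gradient (step 10⁻⁴ Å), symmetrized by
  averaging and mass-weighted; entropies use the quantum harmonic
  oscillator formula S/R = x/(eˣ−1) − ln(1−e⁻ˣ), x = ħω/k_BT. Modes with
  |eigenvalue| < 10⁻⁶ (mass-weighted units) are discarded and counted
  rather than assuming six rigid-body modes — belly systems do not have
  them exactly. Frames are taken every 100 ps of each replica's retained
  span (750 frames at the full 25 × 3 ns schedule); per-frame failures
  are skipped and logged, with a hard error above 20%.

## Ensemble statistics

Per-variant ΔG is the mean of per-replica means; its SD uses the n−1
denominator over replicas (NaN, flagged, for one replica). ΔΔG is taken
against a designated reference variant. Metrics: Pearson on raw values,
Spearman as Pearson on average ranks (ties averaged), MAD as the mean
|residual| about the OLS line of calculated vs experimental ΔΔG. Outliers
are |standardized OLS residual| > 2 by default, with metrics reported with
and without them; collinear data (residual SD at floating-point noise)
flags nothing. The bootstrap resamples *replicas* (not frames) with
replacement, independently per variant including the reference, recomputes
ΔΔG and both correlations per resample, and reports percentile CIs per
replica count; degenerate resamples (zero ΔΔG variance) are skipped and
counted. Default 10⁶ resamples; the tests and the acceptance script run
10⁴, which widens the CI-of-the-CI by ~10× √(n) but leaves the qualitative
replica-sufficiency picture unchanged. Fixed seeds make the sweep
bit-reproducible.

## Hydrogen bonds and explicit waters

H-bonds use donor–acceptor distance < 3 Å (strict) and donor–H–acceptor
angle within 180 ± 45° (inclusive); donor chemistry is an explicit
donor→hydrogen map, never inferred. A water bridges two groups when it
forms at least one qualifying H-bond with each, either polarity, in the
same frame; only single-water bridges count. Explicit-water augmentation
ranks waters by the minimum distance from their oxygen to any O/N atom of
the user-specified binding-site residues (ties to the lower index),
re-selected every frame — the only choice that keeps the retained waters
near the site throughout the ensemble — and appends them to the receptor
and complex (never the ligand) for every energy term, so a water's
internal terms cancel in the binding difference. With X = 0 the pipeline
is bit-identical to the water-free path.

## Synthetic fixtures

The generators emulate the study conditions at desk scale: two facing bead
chains with interface contacts near the LJ minimum (gap 3.8 Å at the
default rmin/2 = 1.9 Å), alternating ±0.3 e charges, a polar
(backbone-N-like) first atom per residue, optional 3-site waters near the
interface, and Gaussian coordinate jitter (per-replica substreams of one
global seed) standing in for thermal sampling. Schedule metadata follows
the 25 × 4 ns / discard 1 ns / 10 ps convention; smaller test runs derive
their stride from the requested frame count. Variants scale the ligand
charges by factors in [0.6, 1.4], so the true ΔΔG ordering is computable
exactly on the unjittered reference frame — that is the recovery target
for the end-to-end test. What the fixtures do *not* emulate: real protein
geometry, rotamers and mutations, anisotropic or correlated fluctuations,
conformational transitions between replicas, and force-field realism.
Passing tests therefore demonstrate correctness of the machinery and
internal consistency of the protocol, not predictive accuracy on real
complexes.

## Problem sizes and defaults

Test and acceptance runs use toy complexes of ~10–30 atoms, ensembles of
25 replicas × 10 frames for the ranking recovery (jitter 0.08 Å), 10⁵
samples for the interaction-entropy Gaussian limit, 10⁴ bootstrap
resamples, and the Born-ion PB solve at 0.25 Å spacing — sizes chosen so
the whole suite completes in a couple of minutes while every check retains
its discriminating power. Library defaults remain at the full protocol
values (300 frames/replica, 10⁶ resamples, 16/12 Å shells, 1000/500
waters).

## Known limitations

* The GB parameterization is generic (Still + HCT-style radii); no
  attempt is made to match any specific published radii set, so absolute
  ΔG_pol values differ from Amber's.
* The PB solver is linearized, uses sphere-union (accessible-surface-free)
  dielectric boundaries without smoothing, and is not intended for
  production electrostatics — it exists as a transparent reference
  implementation with a closed-form oracle.
* Trunc-NMA caps are single pseudo-atoms, adequate for the harmonic toy
  potentials the fixtures provide but not for chemical realism.
* Whether the "indi" convention rescales the PB reference state
  identically to Amber's internals is not asserted; the convention here
  (ε_int divides the gas-phase Coulomb cross term and enters the PB
  dielectric map) is documented behavior, not a compatibility claim.
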