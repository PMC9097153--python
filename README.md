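# endstate

Ensemble end-state (MMPB/GBSA-style) **relative binding free-energy
ranking** for protein–protein complexes.

Absolute binding free energies from end-state methods are notoriously
unreliable, but *relative* affinities (ΔΔG between sequence variants of one
complex) can rank-order binders well when the calculation averages over an
ensemble of many short, independent MD replicas. `endstate` implements that
protocol as a reusable library and CLI: per-snapshot energy decomposition
with a configurable interior dielectric, implicit-solvent polar and
nonpolar terms, two solute-entropy corrections, replica aggregation,
rank-correlation assessment, and a bootstrap analysis of how many replicas
the ranking actually needs. MD itself is out of scope — the package
post-processes snapshots (multi-model PDB trajectories), and ships a
synthetic-fixtures module that generates toy complexes and jittered
ensembles so every stage is testable without external data.

## Model

For each snapshot of the complex trajectory (single-trajectory approach:
receptor and ligand coordinates are subsets of the complex frame, so bonded
terms cancel identically):

```
ΔG_bind = ΔE_int + ΔG_pol + ΔG_npol − TΔS
ΔE_int  = ΔE_ele + ΔE_vdW          (receptor↔ligand cross terms only)
ΔG_npol = γ·ΔSASA                   with γ = 0.00542 kcal mol⁻¹ Å⁻², b = 0.92 kcal mol⁻¹
```

* **ΔE_ele** — Coulomb cross term divided by the interior dielectric ε_int
  (the "indi" convention; default 6).
* **ΔG_pol** — Still-form generalized Born with HCT-style pairwise
  descreening radii and Debye salt screening (150 mM default), or a
  finite-difference linearized Poisson–Boltzmann solver.
* **ΔG_npol** — linear SASA model via a deterministic Shrake–Rupley
  implementation (γ·SASA + b per species).
* **−TΔS** — either the interaction entropy,
  (1/β)·ln⟨exp(β(ΔE_int − ⟨ΔE_int⟩))⟩ over all pooled frames, or a
  truncated normal-mode analysis (binding-site region kept, a 12–16 Å
  buffer and a water shell frozen "belly"-style, chain breaks capped).

Per-variant ΔG is the mean over replica means (default schedule: 25
replicas × 4 ns, last 3 ns sampled every 10 ps → 300 frames/replica, 7500
frames/complex); uncertainty is the SD over replicas. Variants are ranked
against experiment by Pearson r, Spearman ρ and the mean absolute deviation
from the OLS line; outliers are flagged by standardized regression
residuals; replica sufficiency is probed by resampling replicas with
replacement (percentile CIs of r_s/r_p versus replica count).

## Worked example

```python
from endstate import ToySpec, make_toy_complex, make_ensemble, interaction_entropy
from endstate.pipeline import PipelineConfig, ensemble_binding_matrix
from endstate.ensemble_stats import aggregate_variant

topo, frame = make_toy_complex(ToySpec(seed=7))
ens = make_ensemble(topo, frame, n_replicas=5, n_frames=20, jitter_sd=0.08, seed=0)
matrix, series = ensemble_binding_matrix(ens, PipelineConfig(eps_int=6.0))
mean, per_rep, sd = aggregate_variant(matrix)
ie = interaction_entropy(series)
print(f"dG_bind = {mean:.3f} +/- {sd:.3f} kcal/mol over {matrix.values.shape[0]} replicas")
print(f"-TdS (interaction entropy) = {ie.minus_T_delta_S:.3f} kcal/mol")
```

prints

```
dG_bind = -3.898 +/- 0.026 kcal/mol over 5 replicas
-TdS (interaction entropy) = 0.002 kcal/mol
```

The toy complex binds by about −3.9 kcal/mol (dominated by the LJ contact
and the nonpolar offset); the ±0.026 is the SD over the 5 replica means,
and the interaction-entropy penalty is tiny because the coordinate jitter
produces only ~0.05 kcal/mol fluctuations in ΔE_int.

The same flow is available from the shell:

```bash
endstate --seed 3 fixtures --preset 1g4-shaped --out-dir fx
endstate --eps-int 6 energy --pdb fx/complex.pdb --params fx/params.csv --out energies.csv
endstate entropy --method ie --energies energies.csv
```

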