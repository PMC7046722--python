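# trajscope

Trajectory analysis for protein conformational dynamics, built around the
question the TREM2 ectodomain literature keeps asking: *what does a missense
variant do to a fold's stability, collective motions, and interaction
network?*  The package implements the full desk-side analysis chain that
follows a molecular-dynamics run — structural-stability metrics, correlated
motions, free-energy landscapes, hydrogen-bond and residue-interaction
networks, secondary-structure content — plus the multi-predictor
pathogenicity consensus used to triage the variants in the first place.
Because production MD trajectories are rarely distributable, every stage is
exercisable on synthetic trajectories with planted, analytically known
structure, so each claim the pipeline makes is testable.

## What it computes

For a trajectory (multi-model PDB or DCD + PDB topology, coordinates in Å):

- **RMSD / Rg / SASA series, RMSF profiles.** RMSD after optimal Kabsch
  superposition; radius of gyration (mass-weighted by default); solvent
  accessible surface area by Shrake–Rupley point sampling on a
  deterministic Fibonacci sphere (default 960 points, 1.4 Å probe); RMSF
  about the iteratively converged mean structure.
- **Dynamic cross-correlation matrix (DCCM).** For selected atoms *i*, *j*
  with displacements *d* from their time-mean positions,

      c_ij = ⟨d_i · d_j⟩ / sqrt(⟨d_i²⟩ ⟨d_j²⟩),     c_ij ∈ [−1, 1].

- **Essential-dynamics PCA.** Eigendecomposition of the 3n×3n positional
  covariance; trace (Å²), variance fractions, projections, per-residue
  mode loadings and ±2σ mode-extreme conformers.
- **Free-energy landscape.** 2-D Boltzmann inversion over two collective
  variables (default Rg vs RMSD),

      G_i = −k_B T ln(N_i / N_max),   k_B = 0.0019872041 kcal/(mol·K),

  with empty bins flagged and set to an artificial barrier of
  (max occupied G) + k_B·T; basin detection by steepest descent over the
  occupied 8-neighborhood, plus representative-conformer extraction.
- **H-bonds and residue interaction networks.** Geometric H-bond criterion
  (D–A ≤ 3.0 Å, ≤ 20° off linear, both configurable); per-pair occupancy
  percentages; typed contacts (van der Waals, salt bridge ≤ 4.0 Å, π-π
  centroid ≤ 6.5 Å, disulfide ≤ 2.5 Å); occupancy-weighted residue graphs
  over ≤ 1000 snapshots, exported as GraphML and edge-list CSV.
- **Secondary structure.** Kabsch–Sander backbone H-bond energies
  (E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol, bond iff
  E < −0.5) driving a 3-class helix/strand/coil assignment with per-frame
  timelines and content percentages.
- **Variant consensus.** Eight per-tool deleteriousness cutoffs — SIFT
  (= 0), PolyPhen-2 (> 0.9), PROVEAN (< −2.5), I-Mutant (< −0.5), FATHMM
  (|score| > 3.0), MutPred (> 0.75), CADD (> 20), Condel (> 0.8) — applied
  to a variant × tool score table, with deleterious-count ranking.
  Predictor scores are consumed as input; no external service is queried.

The `trajscope.synthetic` module generates the study systems: ideal-geometry
helix/extended/hairpin backbones, Gaussian ensembles with planted
residue–residue correlation blocks, two-state trajectories with planted
basin populations, and an H-bond toy bonded in a prescribed fraction of
frames.  All generators are pure functions of spec + seed.

## Worked example

```python
import trajscope as ts

ref = ts.make_toy_protein(30, "helix", author_offset=20)
spec = ts.EnsembleSpec(
    reference=ref, sigma=0.5,
    correlation_blocks=[([1, 2, 3, 4, 5], [6, 7, 8, 9, 10], 0.8)],
    n_frames=4000, seed=1)
traj = ts.make_gaussian_ensemble(spec)

ca = ts.select_atoms(ref, "name CA")
d = ts.dccm(traj, ca, superpose=False)
print(f"self-correlation {d.matrix[0, 0]:.1f}, "
      f"planted block mean {d.matrix[0:5, 5:10].mean():+.3f}")

p = ts.pca_covariance(traj, ca, superpose=False)
print(f"trace {p.trace:.2f} A^2, PC1 fraction "
      f"{p.variance_fractions[0]:.3f}")
```

prints

```
self-correlation 1.0, planted block mean +0.800
trace 22.34 A^2, PC1 fraction 0.094
```

— the diagonal is exactly 1 by construction, the planted correlation of
0.8 is recovered to sampling precision, and the trace sits at the
isotropic expectation 3·30·0.5² = 22.5 Å², with the correlated block
concentrating ~9% of that variance in the leading mode.

The `analysis/` directory holds the numbered study drivers
(`01_build_systems.py` … `07_variant_consensus.py`): baseline-vs-variant
stability metrics, DCCM/PCA recovery, the 70/30 free-energy landscape,
interaction networks, secondary-structure content, and the consensus
ranking.  Each writes its tables under `results/` and prints what it found.
The same stages are drivable from a config file via the CLI:

```bash
trajscope run --config run.yaml        # full pipeline
trajscope simulate --spec spec.yaml --out traj.pdb
trajscope consensus --scores scores.csv
trajscope compare results/a/report.json results/b/report.json
```

Selection grammar: clauses joined by `and` — `name CA`, `backbone`
(N, CA, C, O), `resid 37:47` (author numbering), `index 17:27` (sequence
numbering), `chain A`.

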