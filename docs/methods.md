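# Methods

This note documents the models, numerical choices and deliberate
simplifications behind trajscope, and what its synthetic-data tests do and
do not demonstrate about real molecular-dynamics output.

## Coordinates, numbering, selections

Coordinates are held in ångströms throughout; free energies in kcal/mol.
Residues carry a dual numbering: a 1-based sequence index contiguous within
each chain, and the author (PDB `resSeq`) number, related by a per-chain
constant offset that is validated at construction.  All user-facing labels
(profiles, network nodes, DCCM axes) use author numbering; the TREM2
ectodomain convention of a +20 offset between the two (mature residues
starting at 21) is the motivating case.  The selection language is a
conjunction of clauses (`name`, `backbone` = N/CA/C/O, `resid` in author
numbers, `index` in sequence numbers, `chain`); selections are
deterministic and order-preserving, so downstream outputs are reproducible.

PDB I/O is fixed-column; element symbols come from columns 77–78 with a
documented name-based fallback (a left-padded name like ` CA ` is a carbon;
a name starting in column 13 whose first two letters form a known symbol,
like `FE`, is that element).  Waters and hetero groups are excluded by
default.  Van der Waals radii are the Bondi set; unknown elements fall back
to 1.70 Å with a logged warning.  Trajectories are multi-model PDB (parsed
here) or CHARMM/X-PLOR-style DCD in Å (read via MDAnalysis's low-level DCD
reader).

## Superposition and the `superpose` switch

Rigid superposition is Kabsch via SVD with determinant-sign correction, so
the rotation is always proper and a mirror image retains its residual.  The
RMSD is evaluated from the actual residuals rather than the singular-value
identity: the identity loses roughly half the available digits to
cancellation near exact fits, and the contract here is ≤1e-10 Å error under
planted rigid motions.  The reference for RMSF, DCCM and PCA is the
iteratively converged mean structure (superpose onto the running mean until
it moves < 1e-10 Å RMS; equilibrium-like ensembles converge in 2–3 passes),
which also makes these statistics independent of frame order.

Fitting each frame onto the mean by least squares *absorbs* fluctuation:
for n selected atoms with iid noise, about 6/(3n) of the variance (the six
rigid degrees of freedom), and substantially more when a planted collective
mode is spatially localized, because the fitted rotation partially tracks
it (a lever effect).  Measured on a 60-residue system, a planted
inter-block correlation of 0.8 attenuates to ≈0.61 under fitting.  The
synthetic generators emit frames in a fixed laboratory frame with no
rigid-body motion, so refitting them is pure distortion; `dccm`,
`pca_covariance`, `rmsf_profile` and `project_onto_pcs` therefore accept
`superpose=False` for ensembles already sharing a frame.  The default
remains `True`, which is the correct setting for real MD output where the
molecule tumbles.  Recovery tests use `superpose=False`; the
rotation-invariance tests use `superpose=True`.

## Structural metrics

- **RMSD**: weighted least-squares minimum per frame against a reference
  conformation of the selection (default backbone).
- **RMSF**: sqrt of the time-averaged squared displacement about the mean,
  per selected atom (default Cα), reported against author residue numbers.
- **Rg**: mass-weighted by default (unweighted available).
- **SASA** (Shrake–Rupley): each atom's sphere of radius (vdW + probe) is
  sampled at `n_points` positions from a deterministic golden-spiral
  (Fibonacci) point set — not random points — so results are
  bit-reproducible; a point is accessible iff outside every neighbour's
  expanded sphere.  Defaults: probe 1.4 Å, 960 points (error vs the
  analytic isolated-sphere area < 1%, and total areas agree with an
  independent implementation to ≈0.1% on a small helix).  The inner loop
  runs through a numba kernel with nearest-first neighbour ordering and
  early exit; a pure-numpy path computes identical values when numba is
  unavailable.  Per-residue SASA is the sum over the residue's atoms.

## Correlated motions

The cross-correlation entry is the time-averaged vector dot product of
displacements, normalized by sqrt(⟨d_i²⟩⟨d_j²⟩) — full 3-D displacement
vectors, not per-axis correlations, which is what bounds the entries in
[−1, 1] and fixes the diagonal at exactly 1.  Zero-variance atoms have no
defined correlation; their entries are NaN and flagged in a missing mask
rather than silently zeroed.  A deliberately naive double-loop evaluator is
kept in the code base as an independent oracle; the vectorized path matches
it to 1e-12 on small instances.

PCA eigendecomposes the 3n×3n covariance of the superposed, mean-centred
selection.  Eigenvalues are clipped at zero and sorted descending; each
eigenvector's largest-magnitude component is made positive, a sign
convention that makes outputs stable across LAPACK builds.  The trace
equals the summed per-coordinate variance (checked to 1e-8 relative) and is
reported in Å², the convention in which trajectory studies quote total
flexibility.  Mode profiles report the per-residue norm of the eigenvector;
mode extremes displace the mean by ±s·sqrt(λ) (default s = 2).

## Free-energy landscape

G_i = −k_B T ln(N_i/N_max) over a 2-D histogram of two collective-variable
series, k_B = 0.0019872041 kcal/(mol·K), default T = 300 K, default grid
50×50 spanning the observed range padded by half a bin so no frame sits on
an edge.  The most populated bin is exactly 0 and occupied-bin free
energies decrease strictly with count.  Empty bins have no defined G; they
are flagged and assigned (max occupied G) + k_B·T — an explicit, finite
artificial barrier chosen so surfaces stay plottable and basin growth
cannot leak through unsampled space.  Basins are local minima over the
occupied 8-neighborhood grown by steepest-descent assignment; exact ties
descend toward the smaller (i, j) index, so a perfectly flat surface yields
one basin.  No smoothing is applied before minima detection (smoothing is
off by default and not used in the tests: it changes basin counts).  The
representative conformer of a basin is the frame in the minimum bin closest
to the bin centre after scaling each axis by its bin width; ties take the
lowest frame index.

For a two-state system with populations p₁/p₂ the basin gap should be
−k_B T ln(p₂/p₁); with Bernoulli state assignment the estimate inherits a
binomial error, and the acceptance test propagates that through the log to
a 3-SE band at 10,000 frames (0.505 kcal/mol expected for 70/30 at 300 K).

## Hydrogen bonds, contacts, networks

The H-bond criterion is geometric: donor–acceptor (N/O to N/O) distance
≤ 3.0 Å and, when the donor's hydrogen is present, deviation of the
D–H···A angle from linearity ≤ 20°.  Both thresholds are configurable, and
hydrogen-free topologies fall back to distance-only with a logged warning
— published occupancies depend strongly on these choices, which is why the
pipeline logs every defaulted criterion.  Note that the ideal-geometry
helix generator places N···O at 3.09 Å, so demonstrations on it use a 3.3 Å
cutoff explicitly.  Occupancy is the percentage of examined frames with at
least one bond between a residue pair (donor→acceptor direction kept).

Typed contacts follow common residue-interaction-network defaults: vdW at
heavy-atom distance ≤ r_i + r_j + 0.5 Å between sequence-non-adjacent
residues, salt bridges at opposite-charge N/O pairs ≤ 4.0 Å
(Arg/Lys/His⁺ vs Asp/Glu), π-π at aromatic ring centroids ≤ 6.5 Å
(Phe/Tyr/Trp six-ring/His), disulfides at SG–SG ≤ 2.5 Å.  The ensemble
network keeps every residue as a node, evaluates bonds and contacts on at
most 1000 evenly strided snapshots (echoing the common 1000-snapshot
protocol), and keeps an edge type iff its occupancy reaches the threshold
(default 10%), weighted by that occupancy.  Criteria are recorded in the
graph metadata and survive GraphML export.

## Secondary structure

Backbone H-bonds are scored with the Kabsch–Sander electrostatic model
(0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN); bond iff E < −0.5
kcal/mol; pairs closer than 0.5 Å are treated as bonded, as in the original
formulation).  Missing amide hydrogens are constructed 1.0 Å from N,
anti-parallel to the preceding carbonyl C=O; prolines and chain-start
residues have no donor.  Assignment is a deliberate 3-class reduction of
the 8-class scheme: H where two consecutive i→i+4 turns overlap (3₁₀/π
turns folded in only when flanked by an i→i+4 bond), E for residues in
parallel or antiparallel bridge patterns (|i−j| ≥ 3), C otherwise, helix
winning on overlap.  Chains under 5 residues are all-coil.  The 3-class
scheme is sufficient for helix/strand/coil content reasoning; it does not
reproduce any proprietary assigner's bend/turn classes, so only content
percentages — not per-residue agreement with such tools — are meaningful.

## Variant consensus

Cutoffs are tool-native: SIFT = 0 (implemented as ≤ 1e-9, since the tool
prints 0.00 at fully intolerant positions), PolyPhen-2 > 0.9, PROVEAN
< −2.5, I-Mutant ΔΔG < −0.5 (destabilizing), FATHMM two-tailed |score| > 3,
MutPred > 0.75, CADD > 20, Condel > 0.8.  Missing scores are excluded from
both the count and the denominator.  Ranking is by deleterious count
descending with alphabetical tie-break, and is monotone under any single
threshold relaxation.  Scores are user input; the package never queries the
predictors, and the bundled demonstration table is synthetic.

## Synthetic generators: what they emulate, and what they don't

- `make_toy_protein` builds ideal-geometry backbones by natural-extension
  (NeRF) placement: helix φ/ψ = −57°/−47°, extended −120°/120°, hairpin
  strands −139°/135° joined by a fixed 4-residue chain-reversal turn whose
  dihedrals were tuned once, by direct search over turn angles, until the
  flanking strands register their Kabsch–Sander bonds (the "ideal hairpin"
  is defined by that registration).  Standard bond lengths/angles; amide H
  constructed as above.
- `make_gaussian_ensemble` plants residue–residue correlations via a block
  correlation matrix (cross-set ρ, intra-set |ρ| — the minimal completion
  that keeps the matrix positive semi-definite) factored by Cholesky and
  applied identically and independently per axis.  Planted ρ is the exact
  expectation of the DCCM entry.
- `make_two_state_trajectory` mixes two conformers with Gaussian jitter;
  the deterministic schedule visits state A in exactly round(p_A·n) evenly
  interleaved frames (Bresenham interleaving), enabling exact-count
  assertions; Bernoulli mode gives the binomial statistics the FEL ΔG test
  needs.  Two-state tests deform part of the chain rather than rigidly
  shifting the whole molecule — a rigid shift is invisible after
  superposition.
- `make_hbond_toy` is a minimal donor/acceptor system at 2.9 Å (linear)
  when bonded and 5.0 Å otherwise, with the same schedule/Bernoulli modes.

All generators are pure functions of spec + seed (bit-reproducible), and
none emulates force-field physics: fluctuations are stationary and
Gaussian, states are exchangeable in time, and there is no kinetics.
Passing recovery tests therefore demonstrates the *estimators* are correct
and unbiased under known ground truth — not that real MD output is
stationary, harmonic, or two-state.  Real trajectories add rigid-body
tumbling (hence `superpose=True` by default), anharmonicity, and time
correlation that widens all sampling errors relative to the iid formulas
used in the tests.

## Problem sizes and determinism

The test suite and analysis drivers run on systems of 10–60 residues with
10²–10⁴ frames, sizes at which every planted quantity's sampling error is
far inside its tolerance band (e.g. DCCM SE ≈ (1−ρ²)/√n ≈ 0.005 at 5000
frames against a ±0.05 band).  The pipeline is fully deterministic: a
config plus seed fixes every output byte, CSV/JSON writers use fixed
formats and sorted keys, report paths are stored relative to the output
directory, and the config digest excludes the output directory so the same
run is recognizable wherever it lands.

## Known limitations

- No mmCIF, bond-topology perception, or protonation logic; element and
  donor/acceptor classification is template- and name-based.
- The SASA point construction converges as n_points^(−1/2) or better but is
  not an analytic (Lee–Richards) method.
- DCCM is the standard equal-time vector correlation; no time-lagged or
  mutual-information variants.
- FEL assumes unbiased sampling (no reweighting) and 2-D collective
  variables only; basin depths are relative to the artificial barrier, not
  to kinetic transition states.
- π-cation and water-mediated interactions are not typed; H-bonds are
  detected geometrically, not energetically, in the network module.
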