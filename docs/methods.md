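# Methods

This note documents the models, default parameters, numerical choices,
and known limitations of `pepcat`, and states precisely what the
synthetic-data generator does and does not emulate.

## Building blocks and peptide assembly

A building block is a residue SMILES carrying two attachment dummies:
`[*:1]` on the backbone amine nitrogen and `[*:2]` on the backbone
carbonyl carbon (`[*:1]N[C@@H](C)C(=O)[*:2]` is L-alanine). Explicit
attachment points were chosen over backbone template matching because
noncanonical residues in this catalyst family — piperidine-2-carboxylic
acid, α-methyl-proline, 4-substituted prolines — break any template
that assumes a primary α-amine.

Assembly joins residues N→C by consuming one `[*:2]`/`[*:1]` dummy pair
per amide bond (the graph-level equivalent of losing one water per
condensation). The N-terminus is a free amine; the C-terminal cap
defaults to a primary amide (`-NH2`), because the catalysts this
package targets are predominantly peptide amides, with a free acid
(`-OH`) available per spec. Stereocenters annotated in the residue
SMILES are preserved through assembly and re-perceived afterwards.

Enumeration fixes position 1 (default: D-proline, the conserved
N-terminal residue of this catalyst family) and takes the ordered
Cartesian square of the pool at positions 2–3, sorted lexicographically
by (position-2 id, position-3 id) so library indices are reproducible.
A 174-residue pool yields exactly 30,276 members.

## Conformer ensembles

- Generation: ETKDGv3 distance-geometry embedding (`n_embed` = 200 by
  default, fixed seed, up to 3 retries with randomized initial
  coordinates) followed by MMFF94 minimization, with a UFF fallback for
  molecules outside MMFF atom-type coverage. Energies are stored
  relative to the ensemble minimum, in kcal/mol.
- Pruning: conformers above `energy_window` (default 5 kcal/mol) over
  the minimum are dropped; the rest are deduplicated greedily in order
  of increasing energy at `rmsd_threshold` (default 0.5 Å). The RMSD is
  a fixed-correspondence Kabsch best fit over **heavy atoms only**:
  hydrogen labels are permuted by methyl/amine rotations, and including
  them makes geometrically identical conformers look distinct. Input
  ordering of the surviving conformers is preserved, so a no-op prune
  is the identity. The minimum-energy conformer is always retained.
- Alignment: each conformer is rigidly superposed (proper rotations
  only; the Kabsch determinant correction forbids reflections) so that
  a core motif best fits a shared reference geometry. The default core
  is the N-terminal proline ring plus its backbone carbonyl carbon;
  when a peptide contains several prolines, the match with the
  lexicographically smallest atom-index tuple is used — assembly orders
  atoms N→C, so this is the N-terminal residue. The reference geometry
  is taken from the lowest-energy conformer of the first ensemble
  processed and must be persisted and reused for the rest of a library.
- Averaging over retained conformers is uniform. Boltzmann weighting
  would privilege the force-field energy ranking, which is the least
  trustworthy part of the pipeline; uniform weighting is also the
  convention under which the steric-occupancy descriptor was
  introduced.

## Grid descriptors

The grid is rectangular with spacing 1.0 Å and a 3.0 Å margin beyond
the bounding box of all aligned calibration ensembles (both
configurable). van der Waals radii are the Bondi set.

- ASO(g) is the fraction of conformers in which at least one atomic
  vdW sphere covers grid point g — bounded in [0, 1], binary for a
  single conformer.
- AEIF(g) is the conformer average of the partial charge of the
  *nearest covering atom* (zero where uncovered). Partial charges are
  Gasteiger–Marsili by default and swappable. This nearest-covering-atom
  form is one admissible realization of an electronic indicator field;
  the package treats the specific functional form as a configuration
  point, not a commitment.

Feature assembly stacks `concat(ASO, AEIF)` per catalyst and
standardizes columns (zero-variance columns get unit scale so the
transform stays invertible; they are removed in reduction). Reduction
drops columns with variance ≤ 1e-12, then greedily drops the later
member of any pair with |Pearson r| ≥ 0.95 (index-order scan, so the
result is deterministic), then projects onto the first 20 principal
components. On the synthetic 40-residue pool this captures ≈ 83% of the
variance, comparable to the ≈ 87% quoted for real amino-acid pools at
this component count.

## Training-set design

K-means (k-means++ initialization, 25 restarts, tolerance 1e-6, fixed
seed) is scanned over a k-range. Distortion is the mean squared
Euclidean distance of points to their assigned centroid. Because
restarts alone do not guarantee a monotone elbow curve, each k also
warm-starts from the previous k's best centroids plus the currently
worst-fit point; Lloyd iteration from that initialization can only
reduce distortion, so the reported curve is non-increasing by
construction.

The number of clusters is a user decision informed by the scan — the
elbow is read qualitatively, and chemical redundancy among exemplars is
judged by the user. Exemplars are the members nearest their centroid
(ties broken by lowest id, with distances compared at 1e-12
resolution). Manual additions are kept disjoint from algorithmic
exemplars and flagged separately. The UTS is the combinatorial library
over the pooled exemplars: 10 + 3 residues → 169 peptides.

Distribution diagnostics use population-moment (uncorrected) skewness
and excess kurtosis (normal = 0; a symmetric two-point sample gives
exactly 0 and −2), plus a Kolmogorov–Smirnov test against a normal with
the sample's mean and SD.

## Selectivity modeling

Free-energy transforms use R = 1.987×10⁻³ kcal·mol⁻¹·K⁻¹ and default
T = 293.15 K (the screening temperature of the trial reactions;
per-record override supported). ee is a signed fraction strictly inside
(−1, 1) — the sign encodes which enantiomer predominates — and maps to
ΔΔG = RT·ln((1+ee)/(1−ee)); the inverse is a scaled tanh, exact to
1e-12 round trip. dr maps to RT·ln(syn/anti).

PLS regression (no internal rescaling; inputs are already
standardized) is fitted per task — enantio- and diastereoselectivity
separately. The component count, when not given, is selected by
leave-catalyst-group-out cross-validation over 1–10 components on MAE.
Reaction identity is one-hot encoded so one model spans several trial
reactions; per-reaction models are available by filtering records.
Validation is catalyst-out: all records of a held-out catalyst leave
the training set together, pinned labels (e.g. the best performer) are
always held out, and `evaluate` refuses models whose training scope
intersects the test catalysts.

## Optimization campaigns

Each round fits the configured model families under 5-fold CV and keeps
every (family, fold) fit as an ensemble member alongside a full-data
fit per family. Point predictions are the mean over family full fits;
**prediction certainty is the population SD of all member predictions**
(kcal/mol; 0 = unanimous). This is one documented realization of a
prediction-confidence score, swappable behind
`optimizer.prediction_certainty`.

Families: PLS (≤ 5 components), RBF kernel ridge (α = 0.1,
γ = 1/n_features), random forest (100 trees), and a single-hidden-layer
network (min(64, 2·n_features) units). The network is trained with
L-BFGS rather than stochastic gradient with early stopping: at the
hundreds-of-rows scale this package targets, L-BFGS converges tightly
and deterministically, which the determinism contracts require.

Selection is greedy (sort by |predicted ΔΔG|) or certainty-filtered
(drop candidates above a certainty quantile, then sort). Measured
catalysts are always excluded, so no catalyst is ever selected twice.
The default three-round schedule mirrors the published campaign shape:
a greedy neural-network round followed by two certainty-filtered rounds
with simpler families at the 50th-percentile cutoff; batch size
defaults to 5 (the per-round batch is not stated in the source study).

Two properties of this design deserve emphasis, because the benchmark
experiments are built around them:

- A *heterogeneous* ensemble (PLS + RBF kernel ridge + forest)
  disagrees most strongly at the extremes of feature space — kernel
  predictions decay toward the data mean, forests saturate at the
  training range, linear models extrapolate without bound. On a
  latent-linear landscape whose optimum *is* the feature-space extreme,
  an aggressive cross-family certainty filter therefore systematically
  excludes the optimum. The planted-optimum recovery experiment
  consequently uses a homogeneous PLS ensemble (certainty = SD over CV
  folds, quantile 0.9), which prunes only genuinely unstable
  predictions; it recovers the planted optimum in ≥ 90% of replicates
  at 5% noise.
- That same cross-family disagreement is exactly the right signal when
  the landscape *bends* outside the sampled region. The
  greedy-vs-certainty benchmark trains both arms on an identical
  in-distribution set, uses the identical heterogeneous zoo, and varies
  only the selection rule; the certainty-filtered arm's median
  |predicted − realized| error is about half the greedy arm's,
  reproducing qualitatively the round-1 → round-2 improvement seen when
  prediction confidence enters the selection criterion.

## Synthetic data

`make_toy_building_blocks` produces chemically valid residues with
systematically varied side chains (a linear carbon chain of increasing
length capped by one of ten terminal groups: alkyl, hydroxyl, amino,
fluoro, chloro, bromo, thiol, carboxyl, amide, phenyl) and
seed-determined L/D stereo labels; the first residue is glycine-like.
The grammar supports pools beyond the 174 needed for full-scale
enumeration, and every residue assembles into valid tripeptides.

`simulate_selectivity` draws ΔΔG = w·x + ε over reduced descriptor
coordinates (ε Gaussian), converts to ee through the inverse energy
transform, and caps ee at ±0.999 to keep the log-ratio finite. The
planted-optimum option relocates the member with the largest |w·x| to a
configured maximum, which keeps the optimum *learnable* by
latent-linear models (an arbitrary member with a boosted outcome would
be statistically invisible to any feature-based model). With weights
of norm ≈ 1 over standardized 20-dimensional features the simulated
UTS screen is near-normal (|skew| ≲ 0.3 across seeds), matching the
shape observed for real mechanism-agnostic screens.

`make_trial_dataset` emulates the 50 × 4 trial screen: conversions from
a 25/50/25 mixture (< 10%, 10–90%, > 90%), ee uniform on [0.10, 0.98],
dr syn fraction uniform on [0.58, 0.98]. Conversion is simulated
independently of selectivity and is not modeled downstream.

What the generator does **not** emulate: real descriptor–selectivity
couplings (the latent-linear landscape is an assumption, not chemistry),
conformational-flexibility pathologies of long side chains,
reaction-mechanism changes between trial reactions, or synthesis
failures. Passing tests therefore demonstrate correctness of the
workflow's statistics and algorithms on data obeying the workflow's own
assumptions — not predictive accuracy for laboratory campaigns.

## Problem sizes and numerics

The test and acceptance experiments run at desk scale by design:
40-residue descriptor pools (n_embed = 15), 169-member training sets,
400-member campaign libraries, 20–25 replicate Monte-Carlo experiments.
Degenerate inputs are handled by contract: pruning never empties an
ensemble; standardization gives zero-variance columns unit scale;
k-scans guarantee monotone distortion; splits with zero holdouts are
legal; a batch size of zero makes campaign rounds no-ops; all ties
(exemplar distance, candidate ranking) break lexicographically by id.

## Known limitations

- The electronic field's functional form (nearest-covering-atom
  Gasteiger charge) is one of several plausible realizations; absolute
  AEIF values should not be compared across charge models.
- Force-field conformer energetics are rough; the energy window is a
  recall device, not a thermodynamic statement.
- The certainty score conflates model-family disagreement with fold
  instability; applications that need calibrated uncertainty should
  substitute a dedicated estimator behind the same interface.
- Library-scale descriptor calculation (30,276 tripeptides × hundreds
  of conformers) is compute-bound and intended for batch execution via
  the CLI; the in-repo experiments substitute synthetic reduced
  features at that scale.
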