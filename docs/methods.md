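# Methods

## Problem and approach

A monoclonal antibody (mAb) with a linear cognate epitope is assayed
against a combinatorial peptide microarray: ~10⁵ near-random peptides of
5–11 residues built from a 16-letter amino-acid alphabet
(`ADEFGHKLNPQRSVWY`), each measured at four antibody concentrations
(0.125, 0.5, 2 and 8 nM, a 4× ladder) in quadruplicate on a 16-bit
fluorescence scanner. Because mAbs are highly sequence-specific, almost
all probes sit at the instrument background (~850 counts, log₁₀ ≈ 2.93)
and the informative high-binding tail is tiny. The package trains a
fully connected network on these sequence→binding pairs and evaluates it
by asking whether the cognate epitope — which is *excluded* from
training — outranks large libraries of random sequences of the same
length, whether single-residue substitution scans recover position-wise
residue importance, and whether tiling a protein antigen localizes the
epitope.

## Data pipeline

1. **Replicate averaging.** Each peptide×concentration cell is the
   arithmetic mean of the log₁₀ replicate counts. No outlier removal.
   Exact duplicate sequences (control/cognate probes occur in multiple
   copies on real arrays) are collapsed by averaging their log values;
   the collapse is recorded in provenance.
2. **Saturation correction.** A cell is saturated when its averaged
   log₁₀ value reaches log₁₀ 65,536 = 4.816 within 10⁻⁹ (replicate
   averaging can leave fully saturated cells infinitesimally below the
   cap). Scanning concentrations in ascending order, a saturated cell is
   replaced by the next-lower concentration's value plus log₁₀ of the
   concentration ratio (log₁₀ 4 = 0.602), justified by the observed
   linearity of on-array binding with concentration; corrections cascade
   upward and may exceed the cap. A saturated cell at the lowest
   concentration cannot be corrected and is flagged with a warning.
   Correction runs on the *averaged* table: the substitution rule is
   stated on binding values, and averaging first keeps the rule
   single-pass per peptide.
3. **Length filter** to 5–11 residues, then **cognate exclusion**
   (exact match) before any training.

## Sequence encoding

Peptides are framed as `(` + peptide + `)` + `X`-padding to width 13
(11-mer maximum plus termini marks). With register shifting the frame is
placed at each of 6 offsets inside an 18-wide window. One-hot encoding
uses 19 tokens (16 amino acids + `X(` + `)`), flattened position-major:
247 features unshifted, 342 shifted. Token order is frozen so weight
files reproduce.

## Dataset transformations (the ablation ladder)

* **Weighting.** Peptides are binned on their saturation-corrected 8 nM
  log₁₀ value (bin width 0.2, bins anchored at 0). Any bin under 300
  members is grown toward 300 by seeded uniform copying of members, no
  pair exceeding 100 copies (so a 2-member bin stops at 200).
  Multiplicities are carried as per-example loss weights — identical in
  expectation to materialized copies, and composing cheaply with
  shifting; a literal-copies oracle backs this in tests.
* **Shifting.** Each (possibly weighted) training pair expands to its 6
  register frames, all sharing the target values. At prediction time
  every query is likewise submitted in 6 frames and the highest
  predicted value per concentration is kept. Frame-max is taken
  independently per concentration (a single-argmax-frame alternative is
  conceivable; the per-concentration choice is symmetric across queries
  so it cannot bias ranking).
* **Composition subtraction.** Ordinary least squares of log₁₀ binding
  on the 16-element residue-count vector (16 coefficients + intercept),
  fitted independently per concentration on the training peptides only.
  The network is trained on residuals; predictions add the composition
  part back so outputs stay on the total log₁₀-binding scale (ranking on
  residuals is available as a switch). A pooled-across-concentration fit
  is also available; per-concentration is the default since the four
  concentration columns have visibly different dynamic range.

The ladder is cumulative: baseline → +weighting → +shifting →
+composition, the order used everywhere.

## Network and training

2 hidden layers × 250 ReLU units, 4 linear outputs (one per
concentration), trained jointly with Adam (learning rate 10⁻³, minibatch
128, MSE, weighted by multiplicity). The regressor is implemented
directly in numpy: the model is small enough that single-thread BLAS
trains it in seconds-to-minutes, and the implementation gives exact
seeded reproducibility (initialization and minibatch order from one
generator) plus per-example loss weights. Targets are centered on their
weighted column means before training (the offset is stored in the model
and added back at prediction); this removes the ~2.9-log background
pedestal from the optimization and speeds convergence substantially.
Defaults: 30 epochs in `ModelConfig`; the desk presets (below) use 8.
No dropout or weight decay — the training set is large relative to the
~150k parameters and the evaluation is rank-based.

Ensembles train n models differing only in seed; the ensemble prediction
is the exact mean of member predictions. Serialization round-trips
bit-exactly (`.npz` weights + JSON metadata including token order and
the composition model).

## Ranking statistic

The cognate and N random sequences of the same length (i.i.d. uniform
over the 16 letters) are predicted with the ensemble; each concentration
column is ranked descending (rank 1 = strongest); each sequence takes
its best rank across concentrations; best-rank ties are then re-ranked
into unique final ranks. Tie-break: sort by the full ascending-sorted
per-concentration rank vector, then by a fixed blake2b sequence hash.
Rank-based keys keep the final order invariant under any strictly
monotone transform of predictions, including per-concentration offsets —
a value-based tie-break would not be. Percent rank = 100·rank/(N+1).

Error statistics follow a grid of n_models × n_random_sets × n_repeats
(default 12 × 2 × 5) with fresh seeds per repeat, reporting mean ± SEM
over per-set final ranks.

## Synthetic landscapes

The generator is the ground-truth oracle for every downstream claim.
Affinity of a peptide is the best ungapped identity alignment of a
planted motif (partial overlaps allowed; per-position match energies in
log₁₀ units) plus a residue-composition term. Expected counts are
`baseline + gain·c·10^affinity`; replicates multiply by `10^ε`,
ε ~ N(0, σ) with σ = 0.02 log units, rounded and clipped to [1, 65,536].
This reproduces the background level, the log-scale replicate noise, the
linear concentration scaling and the detector ceiling of the real assay.
It does **not** model spot morphology, spatial artifacts, inter-array
normalization, similarity-graded (non-identity) motif matching, or
mimotopes; passing tests therefore demonstrate the pipeline's mechanics
and its sample-efficiency behavior, not performance on any real
antibody.

Two frozen presets define the study conditions:

* **abundant-signal** (motif `PLEEVLN`, energies 0.6/position, gain 1):
  partial matches of 3+ residues already clear background, full matches
  saturate at 8 nM; with 200 spiked motif variants (0–3 mutations,
  random flanks) the library carries hundreds of above-background
  probes. This is the easy regime (plentiful graded signal).
* **scarce-signal** (motif `SDLWKLL`, energies 0.8/position, gain 0.02):
  only 5+ matched positions are detectable; 12 spiked variants (1–2
  mutations) plus a handful of lucky random probes are the entire
  signal. Spiked probes always carry at least one left-flank residue, so
  the motif never occupies the cognate's own register — position-specific
  (baseline) models cannot transfer, and register-shift augmentation is
  what bridges the gap. This mirrors the regime where real scarce-signal
  antibodies fail at baseline and recover with shifting.

Spiking motif-bearing probes emulates the cognate-variant probes
deliberately synthesized on real arrays; an unspiked uniform library at
desk scale would contain almost no high-binding tail at all.

## Problem sizes

Desk presets: 20,000 peptides, 3-model ensembles, 8 training epochs,
50,000 random comparison sequences. These sizes were fixed once from
throughput measurements of the numpy network so that the entire
simulation-to-ranking pipeline runs on one CPU in minutes; the
full-scale settings of the method (10⁵ peptides, 12 models, 10⁶ randoms,
repeat grids) remain available through `ModelConfig`/`RankConfig`.

The shuffled-label control deserves a note: after permuting targets, the
cognate's percent rank is a single draw from an approximately uniform
null, so the median over n repeats has standard error ≈ 50/√n percentage
points. Five repeats (SE ≈ 22) cannot distinguish 50% from 25%; the
control therefore uses 101 cheap repeats (SE ≈ 5) — each training 2
epochs on a 5,000-row subsample, which is a valid null draw because fit
quality is irrelevant once labels are shuffled.

## Numerical choices and degenerate inputs

* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; repeat seeds are derived by fixed prime
  strides.
* OLS uses `numpy.linalg.lstsq`; rank-deficient composition designs fall
  back to the minimum-norm solution with a warning.
* Zero counts cannot occur (counts clipped to ≥1), so log₁₀ is always
  finite.
* Empty weighting input yields an empty multiplicity vector; a bin
  target is `min(max(n, 300), 100·n)`.
* Non-finite training loss aborts with diagnostics rather than
  returning a silently broken model.
* Sequences containing `I`, `T`, `M` or `C` must pass through the
  PAM250-derived map I→V, T→S, M→L, C→S before prediction; prediction
  raises on foreign letters rather than mapping silently.

## Known limitations

* The real study's headline numbers require its deposited arrays and a
  12-model ensemble over 10⁶ randoms; this package reproduces the
  method and its qualitative behavior at desk scale on synthetic
  landscapes with known truth.
* Identity-only motif matching means the generator cannot produce
  mimotopes; substitution-scan fidelity is measured against the
  generator's own mutant effects.
* The unpublished training hyperparameters of the original work were
  fixed here as stated above; rank-based acceptance is deliberately
  insensitive to the exact choices.
* Repeat-grid conventions differ between sources (10 repetitions vs a
  12 × 2 × 5 grid); the grid is implemented and the discrepancy noted
  here.
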