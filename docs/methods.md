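# Methods

## Problem and coordinates

A protease substrate is a protein with one or more experimentally verified
cleavage sites. Sites are identified by the 1-based index of the P1 residue
(the residue immediately N-terminal to the scissile bond). A window `Pa–Pb'`
around a P1 at position *p* covers sequence positions *p−a+1 … p+b* and has
fixed length *L = a + b*; windows that overrun a terminus are padded with a
reserved gap symbol `-` so that feature vectors keep a fixed length and
near-terminal sites (e.g. signal-peptidase cleavages) are not discarded. The
default modelling window is P4–P2' (*L* = 6); feature selection uses the
extended P8–P8' window (*L* = 16).

## Window extraction and class balance

One positive window per annotated P1. Negative candidates are all other
positions 1 … len−1 of every substrate; negatives are drawn uniformly at
random without replacement from the global pool (not per substrate),
downsampled to ⌊3 × positives⌋ by default. Sampling is seeded and happens
once per run, not per cross-validation fold; the windows are then split by
substrate. If the pool is smaller than the request, all candidates are used
and a warning is logged — warnings never pass silently.

## Encoding

**BEAA.** Each window residue maps to a 20-dimensional one-hot vector
(orthonormal encoding); the gap symbol and unknown residue X encode as all
zeros. Block length *L* × 20.

**Bi-profile Bayesian profiles.** For a channel with alphabet *A* (amino
acids, {H,E,C}, {e,b} or {*,.}), two per-position frequency tables are
fitted, one on positive and one on negative training windows, with Laplace
pseudocount *c* (default 1):

    f(s at i | class) = (count + c) / (n_observed(i, class) + c·|A|)

`n_observed(i, class)` counts windows whose symbol at position *i* is in the
alphabet; terminal padding is excluded, which keeps every row a proper
distribution even at positions where some windows are padded (when no
padding is present this is exactly division by the class size). A window
then contributes, per position, the pair (positive-profile value,
negative-profile value) of its observed symbol — all positive halves before
all negative halves — giving *L* × 2 values per channel. A padded position
encodes to the unseen-symbol frequency `c / (n_class + c·|A|)`.

Two design points were genuinely open and are decided as follows. The BPB
values are raw class-conditional frequencies, not posterior probabilities
p(class | symbol): frequencies need no class prior, keep the *L* × 2 layout
exact, and the downstream kernel machine can form any monotone combination
it needs. Structural channels use the argmax state as the symbol; predictor
probabilities are retained in the annotation objects but not encoded, which
keeps the 28 *L* identity exact. Block order is fixed: BEAA, BPBAA, BPBSS,
BPBSA, BPBDISO.

**Schemes.** A scheme names an ordered subset of blocks; `ALL` uses all
five, with vector length 28 *L* (168 at *L* = 6, 448 at *L* = 16). Feature
descriptors are labelled `<block>:<subsite>:<symbol-or-half>`, and group
into 16 per-position BEAA groups plus 4 channel-level BPB groups for the
extended window.

## Structural annotation

Three per-residue channels accompany each substrate: 3-state secondary
structure with per-state probabilities, 2-state solvent accessibility and
2-state native disorder. Readers accept the common predictor output
dialects (vertical index/residue/state/probability lines for secondary
structure and disorder; a flat e/b string for accessibility), cross-check
residues against the sequence, and apply documented repair policies: if the
state letter disagrees with the probability argmax the letter wins (with a
warning); a missing disorder probability column is imputed 0.9/0.1 by
state; mixed-case accessibility strings are normalised.

The built-in heuristic annotator is a deterministic physico-chemical
stand-in: sliding-window Kyte–Doolittle hydropathy calls buried/exposed,
smoothed Chou–Fasman-style propensities with a coil baseline call H/E/C,
and hydrophilicity plus local low complexity call disorder. It satisfies
the annotation invariants and makes scanning possible with no external
predictor, but it carries **no accuracy claim**; synthetic data bypasses it
by emitting ground-truth states directly.

## Scoring model

An RBF-kernel support vector regression is trained on targets +1 (cleaved)
and −1 (non-cleaved). SVR output is unbounded, so the package reports the
raw score plus a rank-percentile against the training scores; no
probability calibration is attempted. Hyper-parameters are chosen by seeded
internal stratified 5-fold cross-validation maximising AUC over a grid —
default C ∈ {0.1, 1, 10, 100} × γ ∈ {0.001, 0.01, 0.1, 1}, ε = 0.1; a
documented fast grid C ∈ {1, 10, 100} × γ ∈ {0.01, 0.1} is used in routine
runs and the acceptance experiments. Ties break deterministically toward
smaller C, then smaller γ. Features are already in [0, 1], so no
standardisation is applied. Degenerate folds (a class absent) trigger
seeded re-shuffles up to a bounded retry count.

## Threshold calibration

For a specificity level *s*, the threshold is the smallest value whose
empirical specificity on validation negatives is ≥ *s*: sort the negative
scores descending and take the (⌊(1−s)·n⌋+1)-th largest; decisions are
`score > threshold`. At *s* = 1.0 the threshold is the maximum negative
score. Thresholds are forced monotone across levels by a running maximum.
Calibration resolution is limited by the negative count (a level *s* needs
at least 1/(1−s) negatives; a warning is emitted below that). By default
thresholds are calibrated on the training scores; `recalibrate()` replaces
them from held-out validation scores, which is what the calibration
experiments do.

## Feature selection

Mean-decrease-Gini importances come from a seeded random forest (default
500 trees; 200 in the repeated-seed experiments). Z-scores use the
population standard deviation, so they have mean 0 and standard deviation 1
by construction; all-equal importances are a hard error (no
discrimination). Selection keeps features with Z strictly greater than the
threshold (default 1.0; ties at the threshold are excluded). Selection
defaults to running inside each training fold during cross-validation,
which is leakage-safe; a single global selection is available through the
model API for exploratory use.

## Evaluation

Cross-validation folds partition substrates, never windows, so windows from
one substrate never straddle train and test. Pooled (micro-averaged)
metrics over the concatenated fold predictions are primary; per-fold and
macro averages are also reported. Self-consistency (train = test) is
reported as an upper bound on attainable fit. Independent tests verify
substrate-id disjointness and fail on overlap. Metric conventions for empty
denominators: MCC = 0 when any marginal is zero; F = 0 when precision +
recall is zero; each rate is 0 when its own denominator is zero. AUC is
computed by the midrank (Mann–Whitney) statistic with midrank tie handling;
a test invariant pins its equality with trapezoidal integration of the
empirical ROC to ≤ 1e-12.

## Scanning

Every position 1 … len−1 of a query is a candidate P1; no residue
pre-filter is applied (the model itself encodes the specificity). Output
per site: rank, raw score, rank-percentile, the P4–P4' context rendered
`XXXX|XXXX` with `-` padding, and pass flags at each calibrated level.
Fragment reports cut after every passing P1; lengths partition the query
and masses use average (not monoisotopic) residue masses plus one water.

## Synthetic data

The generator emulates a curated substrate collection: substrate lengths
uniform on 100–200 residues; sites per substrate 1 + Poisson(0.6), i.e.
mean ≈ 1.6, matching the ratio of cleavage sites to substrates in curated
collections; background residues uniform over the 20 amino acids (a
natural-abundance option exists). True sites implant residues drawn from
per-subsite distributions over P8–P8'; presets encode a caspase-3-like
D/E/V/D|G-S motif (P1 Asp is a point mass, consistent with the
near-universal P1 Asp of caspase substrates), a granzyme-B-like V/-/-/D|-
motif, and a motif-free null. Structural states are generated, not
predicted: background coil/helix/strand ≈ 0.50/0.33/0.17, exposure 0.5,
disorder 0.3; within P6–P6' of a true site the states are re-drawn with
coil 0.78, exposed 0.86 and disordered 0.72 — mid-range of the coil
(72–84 %), exposure (80–92 %) and disorder (66–78 %) occupancies observed
at real cleavage sites. Sites are spaced ≥ 16 residues apart so implanted
motifs never overlap; substrate length is resampled (bounded retries) when
a draw cannot accommodate the requested sites.

What passing on synthetic data does and does not show: it demonstrates that
the pipeline recovers a planted position-specific signal of realistic
strength, that calibration and ranking behave as specified, and that the
null condition returns to chance. It does not demonstrate accuracy on real
substrates — real specificity is weaker and correlated with homology,
structural context comes from imperfect predictors rather than ground
truth, and exosite-dependent proteases (e.g. matrix metallopeptidases,
thrombin) are poorly captured by active-site window features at all.
Redundancy reduction (greedy longest-first clustering at 70 % pairwise
global-alignment identity, an approximation of external clustering tools)
is therefore off by default for synthetic data, which is non-redundant by
construction.

## Problem sizes and determinism

Routine experiments use 200 substrates (≈ 320 positive and 960 negative
windows) for motif recovery, 100–150 substrates for calibration with a 9:1
negative ratio (≈ 2000–3000 calibration negatives), 60 + 30 substrates per
seed for the null control, and 100 substrates per seed for the
selection-enrichment experiments — sizes at which every result above is
stable across seeds. All randomness (generation, sampling, folds, forests,
grid CV) flows from explicit integer seeds; identical seeds reproduce
identical outputs byte-for-byte in the generator and bit-for-bit in
scores.

## Known limitations

- The heuristic annotator is a placeholder for real structure predictors.
- Redundancy reduction is greedy and O(n²) pairwise alignments; for large
  curated sets an external clustering tool is preferable.
- SVR scores are not probabilities; threshold calibration is empirical and
  bounded by the validation negative count.
- Multiple proteases are modelled independently (one model per protease);
  no shared representation across families.
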