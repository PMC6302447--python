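# Methods

## Problem setting

Bacterial sRNA prediction is cast as binary sequence classification.
Positives are experimentally supported sRNA sequences; negatives
("pseudo-sRNAs") are fragments extracted at the same coordinates from a
residue-shuffled genome, which preserves genome-wide mono-nucleotide
composition and fragment lengths while destroying all genuine sequence
signal. `build_benchmark` implements this recipe: coordinates are 1-based
and inclusive on both ends (the NCBI convention of bacterial annotation
tables), minus-strand intervals return the reverse complement, exact
duplicate positives are removed before negatives are sized, and a 1:r class
ratio uses r independent whole-genome shuffles re-extracted at the retained
coordinates, so |neg| = r·|pos| exactly. Shuffling is a seeded uniform
permutation; every stochastic operation takes an explicit seed.

Ambiguity codes (N, R, …) are rejected at parse time rather than skipped:
the encoders' window arithmetic assumes a strict 4-letter alphabet, and
silently dropping residues would shift every k-mer window. The redundancy
criterion behind "removing redundant sRNAs" in curated sets is rarely
stated; `deduplicate` removes exact residue-string duplicates (stable,
first occurrence kept) and is the hook to replace with similarity-based
deduplication if needed.

## Feature encoders

Seventeen encoders map a sequence of length L to a fixed-dimension vector.
Counts are normalized to frequencies by the window count (raw counts behind
`normalize=False`); k-mer order is lexicographic with A < C < G < T, and
the canonical RevcKmer representative is the lexicographic minimum of a
k-mer and its reverse complement. Both conventions are arbitrary but fixed
and documented; nothing downstream depends on the order, only on its
stability.

* **Spectrum** (F1–F5, k = 1..5): frequency of each of the 4^k contiguous
  k-mers; entries sum to 1.
* **Mismatch** (F6–F8, k = 3..5): entry t counts windows within Hamming
  distance ≤ m of t (exact matches included), normalized by L−k+1. The
  default m = 1 follows the usual rule of thumb m < k/3 for k = 3..5.
  Counting enumerates each window's Hamming ball (C(k,j)·3^j neighbors for
  j ≤ m mismatches) rather than scanning all 4^k candidates per window,
  which keeps k = 5 cheap.
* **RevcKmer** (F9–F13, k = 1..5): frequencies over canonical classes;
  dimension 4^k/2 for odd k and (4^k + 4^{k/2})/2 for even k (the extra
  term counts self-complementary k-mers). The profile is invariant under
  reverse complementation of the input by construction.
* **Pseudo nucleotide composition** (F14–F17): di- or tri-nucleotide
  frequencies f_v plus λ correlation factors, with weight w balancing the
  two blocks. Parallel-correlation (PC) variants use
  θ_j = (1/(M−j)) Σ_i Θ(O_i, O_{i+j}) with Θ the mean squared difference of
  standardized property values over all properties, giving dimension
  base + λ and components that sum exactly to 1. Series-correlation (SC)
  variants keep one product-moment factor τ_{j,u} per (lag, property)
  ordered lag-outer/property-inner, giving dimension base + N_p·λ; τ can be
  negative, so only PC vectors carry the sum-to-one identity. The defaults
  λ = 9 (PCPseDNC), 15 (SCPseDNC), 1 (PCPseTNC), 1 (SCPseTNC) come from
  cross-validated grid search on curated sRNA benchmarks;
  `grid_search_lambda` re-runs that selection on any dataset. λ is bounded by L−2 (di) or L−3 (tri) for the shortest
  sequence — with the 45 nt minimum typical of curated sRNA sets, all
  defaults are valid. The weight w is not fixed by the protocol; the
  default 0.05 is the customary pseudo-composition setting and is
  configurable per spec.

Property tables are standardized once at load (z-score across the 16 or 64
oligonucleotides, population variance), so every column has mean 0 and
variance 1; constant columns are rejected. The packaged default tables are
**synthetic**: frozen fixed-seed values with the standard shape (6
dinucleotide properties, 12 trinucleotide properties). The synthetic
defaults reproduce the dimensions, the standardization contract and every
encoder identity, but not any particular published index values. Users supply
their own TSV (an `oligo` column plus one column per property) to use real
indices; all results in this repository are invariant to that substitution
except the numeric values of the correlation factors themselves.

The four merged group vectors used by the neural ensemble concatenate each
family in F-index order: SP = 1364, MP = 1344, RCK = 692, PNC = 272
dimensions under the defaults.

## Base predictors

One classifier per feature, consumed by the ensembles only through its
positive-class probability. The default engine is a random forest with 200
trees (probability = fraction of trees voting positive); RBF-kernel SVM and
one-hidden-layer MLP engines are interchangeable. SVM margins are mapped to
probabilities by Platt-style sigmoid calibration, since the margin is not a
probability. Scale-sensitive engines (SVM, MLP) are wrapped with per-column
standardization fitted on training data. All non-stated hyperparameters
remain library defaults and are recorded in the training manifest together
with the seed and a training-data hash.

## WAEM: GA-optimized weighted averaging

The ensemble score is F(x) = Σ w_i f_i(x) on the simplex (Σw = 1, w ≥ 0).
Weight search is a genetic algorithm:

* **Encoding/repair**: chromosomes are real vectors of length N, repaired
  after every operator by clipping at zero and renormalizing to sum 1.
* **Initialization**: the N simplex corners plus Dirichlet(1) draws. Corner
  seeding guarantees the best single predictor is representable, so the
  optimized ensemble can never score below it on the fitness set.
* **Operators**: fitness-proportional selection; arithmetic (convex)
  crossover, which preserves the simplex; single-gene Gaussian mutation
  (σ = 0.15). Crossover and mutation probabilities adapt per chromosome,
  interpolating linearly between configured bounds by the chromosome's
  fitness relative to the population mean and maximum — fitter chromosomes
  are disturbed less. One elite chromosome survives unchanged, making the
  best fitness non-decreasing by construction (and testable as such).
* **Fitness**: AUC of the weighted ensemble on the training data. By
  default the base-predictor probabilities entering the fitness are
  computed *out-of-fold* (3-fold cross-fitting within the training set,
  `fitness_mode="oof"`). This is a deliberate deviation from the literal
  protocol (probabilities from the final predictors on their own training
  data, available as `fitness_mode="fit"`): with memorizing engines such as
  random forests, every feature's refit training AUC is ≈ 1.0, the fitness
  landscape is flat, ties are broken arbitrarily, and the returned weights
  carry no information about which features generalize — measured on the
  planted synthetic benchmark, held-out WAEM AUC rises from 0.87 (fit) to
  1.00 (oof) while the best base predictor sits at ~1.00. Out-of-fold
  fitness restores the ranking the weighted average is meant to exploit.
* **Defaults**: population 100, 200 generations, matching the benchmark
  protocol; the scaled-down study below uses 20 × 30, which already
  saturates on these problem sizes.

## NNEM: two-stage neural stacking

Stage 1 fits four one-hidden-layer MLPs (rectifier activation, cross-entropy
loss with L2 penalty; hidden 700, L2 = 0.3 by default) on the SP/MP/RCK/PNC
group vectors, each standardized per column on the training folds. The L2
term matters because the group vectors (up to 1364 dims) are longer than
typical benchmark datasets. Stage 2 fits a one-hidden-layer MLP (10 nodes,
cross entropy) on the 4-vector of stage-1 positive-class outputs; its input
dimension is always exactly 4 and a missing group fails loudly. Both stages
use scikit-learn's MLPClassifier. By default stage-2 inputs are stage-1
outputs on the same training set (the literal two-step recipe);
`stacking="oof"` substitutes out-of-fold stage-1 outputs, which is the
standard guard against optimistic meta-features and is recommended off the
benchmark protocol.

## Evaluation

Stratified 5-fold cross-validation repeated (20 runs by default) with folds
re-shuffled per run on the fixed dataset; the alternative of regenerating
negatives each run is not used, so run-to-run variance reflects fold
assignment only. Per-run performance is the mean over folds; the overall
figure is the mean over runs. All fitting — base predictors, GA weights,
NNEM stacking — happens strictly on the training folds; a guard asserts
train/test disjointness and coverage every fold. Feature encodings are
computed once over the whole dataset and sliced per fold: encoders are
per-sequence deterministic transforms with no fitted state, so this is
leakage-free (property standardization uses fixed alphabet-wide constants,
not data statistics).

AUC is computed from the Mann–Whitney rank statistic with average ranks, so
ties count one half; it is checked against a brute-force all-pairs oracle in
the tests. SN/SP/ACC are computed at threshold 0.5 (the protocol does not
fix a threshold; AUC is the primary metric precisely because it needs
none). Zero-denominator rates are reported as NaN with an explicit
`undefined` marker, never as 0. The paired t-test on per-run AUCs is
two-sided; zero-variance differences are flagged degenerate (p = 1 for
identical samples, NaN otherwise) instead of dividing by zero.

Two baseline configurations mirror earlier sRNA predictors for comparison:
RBF-SVM on concatenated mono- + di-nucleotide composition (= 1- and
2-spectrum), and SVM on tri-nucleotide composition (= 3-spectrum).

## Synthetic benchmark

The generator emulates the structure the method assumes, not sRNA biology
(no promoters, terminators or secondary structure):

* **Lengths** log-uniform on [45, 500] nt — right-skewed like curated sRNA
  length distributions, whose exact shape is not recoverable; the bounds
  and distribution are parameters.
* **Positives** from a (k−1)-th-order Markov chain whose per-context
  emissions are tilted away from the background composition. The tilt is
  solved by bisection so that the mean per-position KL divergence from
  background equals the requested `effect_size` (nats), making "weak" and
  "strong" signal statements reproducible. The default 0.25 nats is a
  strong, cleanly recoverable bias; 0 removes all class signal.
* **Negatives**: each negative is a seeded shuffle of a fresh background
  sequence matched in length to its paired positive — preserving the
  source's mono-nucleotide composition exactly (the pseudo-sRNA contract)
  while keeping negatives statistically independent of the positives.
  Shuffling the positives themselves was rejected: paired siblings share
  per-sequence composition quirks across CV folds and bias the
  no-signal control below 0.5 (measured AUC ≈ 0.36 instead of ≈ 0.5).
* **Correlation-lag mode**: positives copy the residue `lag` positions
  upstream with probability `copy_prob`, planting dependence at exactly
  that lag and none below it — pseudo-composition features see the signal
  only once λ reaches the planted lag, which is what the λ-grid recovery
  test exercises.

Passing tests on this generator demonstrate signal recovery, calibration
and the ensemble contracts; they do not certify performance on real
genomes, where class signal is weaker, structured and confounded with
composition.

## Problem sizes and numerical choices

The acceptance study is a scaled-down mirror of the benchmark protocol,
chosen as the smallest sizes at which the contracts are non-trivial:
n = 200+200 sequences, one run of 5-fold CV, GA population 20 × 30
generations, NNEM stage-1 hidden size 50. At these sizes the planted-signal
conclusions (matched spectrum ≥ 0.95 AUC; ensembles within 0.02 of the best
base predictor; permuted-label control in [0.4, 0.6]) are stable across
seeds. Exact-identity checks use 1e-12 tolerances (pure floating-point
arithmetic), normalization and standardization 1e-9. Simplex repair maps
the all-zero chromosome to the uniform vector. Encoders reject sequences
shorter than their window (or λ bound) with the offending length in the
message.

## Known limitations

* The shipped property tables are synthetic stand-ins (see above); absolute
  pseudo-composition values are not comparable to implementations using
  published index sets, although dimensions, identities and invariances are.
* GA fitness, even out-of-fold, is still optimized on training folds;
  weights can overfit small fitness sets. An external validation split is
  the caller's responsibility.
* `fitness_mode="fit"` and `stacking="fit"` reproduce the literal benchmark
  recipe but are optimistic by construction; the defaults deviate where
  measurement showed the literal recipe breaks (WAEM weight selection), and
  keep the literal behavior where it does not (NNEM stacking).
* Multi-record genomes are handled per record; there is no coordinate
  liftover or download tooling.
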