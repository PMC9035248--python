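# Methods

This note records what the package computes, the conventions adopted
where more than one reasonable definition exists, and what the synthetic
corpora do and do not establish about behaviour on real protein data.

## The SNARER descriptor panel

The panel is 24 per-residue scales: 17 AAindex accessions (helix
propensity and positional helix frequencies, solvation and partition
energies, accessible surface area, charge and charge-transfer
parameters, bulkiness, side-chain interaction) and the seven Fauchère
amino-acid parameter sets (steric parameter, polarizability, volume,
isoelectric point, helix probability, sheet probability,
hydrophobicity). The values are vendored in
`src/snare_profiler/data/snarer_panel.tsv`, one row per scale with its
source accession, so the transcription is auditable against the public
AAindex release; loading validates 24 entries × 20 finite values and
fails loudly on any gap rather than imputing.

A sequence is encoded as the arithmetic mean of each scale over its
residues. The mean is the standard way to turn a per-residue AAindex
scale into a global descriptor: it is length-invariant, order-invariant
(encoding a sequence and its reversal give identical vectors — a tested
invariant) and keeps each feature in the units of its scale. Panel
order fixes feature order; users can supply their own panel in the same
TSV format.

## Feature classes

**GAAC.** Frequencies of five physicochemical groups — positive (K, R,
H), negative (D, E), aromatic (F, Y, W), aliphatic (A, G, I, L, M, V),
uncharged (C, N, P, Q, S, T) — in that fixed order. The five features
sum to 1.

**CKSAAP.** For each spacing k = 0..k_max (default 5) and each of the
400 ordered residue pairs in row-major alphabet order, the count of
positions i with seq[i] = a and seq[i+k+1] = b. Counts are divided by
the number of k-spaced windows, L − k − 1, so features are comparable
across sequence lengths; raw-count mode is available
(`normalize=False`). A sequence too short for a spacing contributes an
all-zero block. Total length 400·(k_max + 1) = 2400 at the default.

**CTDT.** For each three-class property partition, the sequence is
mapped to its class string and the frequencies of unordered adjacent
class changes {1,2}, {1,3}, {2,3} are computed over the L − 1 adjacent
pairs. The default partition list is the seven classic CTD properties
(hydrophobicity, normalized van der Waals volume, polarity,
polarizability, charge, secondary structure, solvent accessibility),
giving 21 features. These groupings are the widely used Dubchak-style
tables; they are a convention, not a biological necessity, and the
partition list is a parameter so users can match whatever extraction
tool they need to reproduce.

**188D.** 20 residue frequencies plus, for each of 8 properties (the
seven above plus surface tension), 21 features: 3 class compositions, 3
transitions (as in CTDT) and 15 distribution features. The
distribution convention: for each class, the 1-based position of its
ceil(p·n_c)-th occurrence (p = first occurrence, 25%, 50%, 75%, 100%;
n_c = class count) divided by L, and 0 for an absent class. Percentile
conventions differ between published implementations; the ceiling rule
was chosen because it is exact on small n and agrees with the common
tools at the quartile points.

**.ext classes.** A base feature vector concatenated with the 24
SNARER features, order preserved (GAAC.ext = 29, CTDT.ext = 45,
CKSAAP.ext = 2424, 188D.ext = 212 features).

Sequences are sanitized before encoding: uppercased, and non-canonical
symbols (X, B, Z, U, O, and anything else outside the 20-letter
alphabet) dropped by default (`policy="reject"` raises instead). All
denominators use the cleaned length, so a dropped symbol never distorts
a frequency.

## Redundancy reduction

Greedy incremental clustering with the semantics of CD-HIT: sort by
decreasing length (ties keep input order); each sequence joins the
*first* cluster whose representative it matches at identity ≥ the
threshold, else founds a new cluster. Identity is exact
global-alignment identity — identical columns divided by alignment
length, under match +1 / mismatch 0 / linear gap −1 (configurable) —
computed with Biopython's pairwise aligner rather than CD-HIT's word
filters: at the corpus sizes this package targets (hundreds to a few
thousand sequences) the exact computation is affordable and has no
heuristic failure modes. Note that low thresholds such as the default
0.25 are below the range where short-word heuristics are reliable,
which is a further reason to align exactly. Reduction is applied per
class before dataset assembly.

## Balancing

Random oversampling (duplicate minority rows with replacement until
class counts match; duplicates carry `#dupN` provenance ids) and random
subsampling (drop a uniform random majority subset), both seeded. No
synthetic-minority interpolation. During cross-validation, balancing
is applied to the training part of each fold only, never to validation
folds — balancing before splitting leaks duplicated rows across the
train/validation boundary and inflates every metric. A global
"balance the whole matrix first" mode exists (`apply_sampling`) for
reproducing workflows defined that way; results from it should be read
with that caveat.

## Evaluation

**Classifiers.** Random forest (100 trees), k-nearest-neighbours
(k = 1, Euclidean distance) and AdaBoost (10 iterations), as
scikit-learn adapters. The Weka-style AdaBoost weight threshold
(default 100) is recorded in `ClassifierSpec` for configuration
fidelity but has no scikit-learn counterpart; with the default
threshold Weka's behaviour is unaffected anyway (it only truncates the
lightest-weighted training instances below the 100th percentile).

**Split plans.** Seeded, class-stratified k-fold (presets k = 10..100
step 10) and hold-out (presets 20%..80% validation). Stratification is
used because at k near the record count an unstratified fold can end up
single-class, which leaves SN or SP undefined; it changes nothing at
small k on balanced data. Folds with a single-class *training* part
are skipped and recorded.

**Normalization.** Optional per-fold min-max scaling, fitted on the
training part and applied to the validation part. Default on for KNN
(distance-based, scale-sensitive — mirroring the distance normalization
most workbenches apply) and off for the tree-based learners, which are
scale-invariant. Constant features get span 1 to avoid division by
zero.

**Metrics.** ACC, SN, SP and MCC from the confusion counts with the
SNARE class positive everywhere. MCC returns 0 when any marginal sum
is zero (the coefficient is undefined there; 0 is the no-information
convention). ROC-AUC is computed by midrank concordance (the
Mann–Whitney statistic; ties count ½), which is identical to the
trapezoidal area under the ROC curve — the test suite checks that
equality against an independent implementation on small instances.
AUPRC is the area under the precision–recall step curve evaluated at
each distinct score threshold (equivalently, average precision).
Undefined metrics (zero denominators, single-class validation folds)
are reported as NaN, and means are taken over the defined folds with
the defined count disclosed — silently dropping them would bias
aggregate tables exactly where imbalance makes them interesting.

**Aggregation.** The default report is the mean of per-fold metrics;
the pooled-confusion alternative (sum counts over folds, then compute)
is always reported alongside, since the two differ when folds vary in
size or difficulty.

**Determinism.** Every stochastic step (corpus generation, fold
assignment, balancing draws, forest/boosting seeds) flows from explicit
seeds; fold-level seeds are derived as
`(seed·100003 + fold·7919 + 1) mod (2³¹−1)`. Identical inputs and
seeds give byte-identical reports, and the pipeline writes a sha256
manifest so reruns can be compared file-by-file.

## Synthetic corpora

The generator draws i.i.d. sequences over the 20-letter alphabet with
lengths uniform on [60, 200] (the scale of SNARE-motif-bearing
proteins) and uniform base composition by default. The class signal
adds a total probability mass δ (default 0.15) to a chosen residue set
(default {Q, R}, echoing the conserved glutamine/arginine zero layer of
SNARE bundles), split equally, with the remaining residues scaled down
to renormalize; δ = 0 gives a null corpus with both classes identically
distributed. The default design is 64 + 64 records, matching a small
balanced two-class study; an imbalanced variant at a chosen
negative:positive ratio (≈2.9 for the unbalanced design the balancing
filters are aimed at) exercises oversampling and subsampling. A motif
mode plants a fixed substring in positives instead, producing a signal
that pair-composition features can see even when single-residue
composition is matched.

What the generator does **not** emulate: residue autocorrelation,
domain structure, coiled-coil periodicity, homology between sequences,
and database-level biases (taxon composition, annotation errors).
Passing calibration tests on these corpora therefore establishes that
the harness is leak-free and recovers a known composition signal — it
does not establish any particular accuracy on real SNARE data, which
depends on the dataset snapshot used.

## Problem sizes in the checks

The calibration checks use corpora of 60–200 sequences and 10-fold
cross-validation: null corpora (δ = 0, 30 + 30 records) over 20 seeds
must give mean accuracy in [0.40, 0.60], and an injected signal at
δ = 0.15 with 100 + 100 records must beat a permuted-label baseline by
at least 0.25 accuracy. These sizes keep the full suite fast while
leaving both checks far from their thresholds (observed: null ≈ 0.52,
margin ≈ 0.4–0.5 across seeds).

## Known limitations

- The vendored AAindex transcriptions are auditable via their recorded
  accessions but the package does not parse AAindex flat files itself;
  custom panels must use the documented TSV format.
- CTD group tables and the 188D property list vary between published
  extraction tools; results are only comparable across tools when the
  same partitions are configured.
- `pairwise_identity` is O(len(a)·len(b)) per pair and the greedy
  clustering is quadratic in cluster count; very large corpora (tens of
  thousands of sequences) would need a heuristic pre-filter, which is
  out of scope.
- AdaBoost's scikit-learn implementation (SAMME) is not numerically
  identical to Weka's; only the algorithmic parameters are mirrored.
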