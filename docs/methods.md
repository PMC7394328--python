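# Methods

## Problem and data model

The package identifies lysine acylation substrate sites (the motivating
modification is glutarylation) from local sequence context. The unit of
analysis is a *window*: a `2n+1`-mer peptide centred on a candidate lysine,
positions indexed `−n..+n` with 0 the lysine itself. Windows overrunning a
protein terminus are padded with `X`; non-standard residue codes (B, Z, U,
O, J) are mapped to `X` on read so public proteome FASTA files pass
through. The default half-width is `n = 10` (21-mers), the window length
that window-sweep experiments on curated glutarylation data selected; the
`sweep` facilities cover 11–25-mers.

Coordinates are 1-based in all user-facing files ("Lys-59" style); window
offsets are signed internally. Negatives default to every non-annotated
lysine in the annotated proteins (the standard construction when only
positives are curated); an `annotated` mode restricts to explicitly
labelled negatives. Whether negatives should be drawn from a wider protein
universe is genuinely open; drawing them from the annotated proteins keeps
the compositional background matched, and the switch is exposed.

## Redundancy reduction

Because all windows are equal-length and centre-aligned, percent identity
is a column-match fraction (X matches only X) and an exact greedy
single-pass clustering (first representative with identity ≥ cutoff wins,
input order decides) reproduces identity-threshold filtering without any
external clustering tool or word-size heuristics; at a few thousand
21-mers the all-vs-all scan is exact and fast. Default cutoff 0.40.
Cross-class exact duplicates keep the positive copy (an unannotated
identical negative is most plausibly an unverified positive). Negatives
are then subsampled (seeded, uniform) to `round(ratio × positives)`,
default ratio 2.

## Feature encodings

All encoders live on the 21-symbol alphabet `ACDEFGHIKLMNPQRSTVWY` + `X`
in fixed order, and produce vectors on the probability simplex:

* **AAC** (dim 21): letter counts divided by the window length `2n+1`. A
  displayed-equation variant normalising by native residues only exists in
  the literature; dividing by the full window keeps padded and unpadded
  windows on one simplex, and the native-only denominator is available via
  a flag for sensitivity checks.
* **AAPC** (dim 441 = 21²): ordered adjacent pairs over the `2n` slots,
  divided by `2n` (the standard dipeptide-composition reading).
* **CKSAAP(k)** (dim 441 per k ∈ {1,2,3}): ordered pairs separated by
  exactly k arbitrary residues ("GxA" at k=1: the x denotes the skipped
  position, not the letter X), divided by the `2n−k` slots. Each spacing is
  a separate vector by default (matching how the spacings are usually
  benchmarked separately); concatenation is provided.

`X` is a full symbol at either end of a pair, so terminal padding is
represented rather than discarded.

## Positional interdependence

For window positions i ≠ j the dependence statistic is Pearson's
chi-square on the co-occurrence table:

    χ²(X_i, X_j) = Σ_mn (Y_mn − E_mn)² / E_mn,   E_mn = Y_mc · Y_rn / Y

at residue level (21×21, the dependency-graph view over all flanking
pairs; the centre position is excluded as constant) and at the level of
five biochemical groups (5×5) for the decomposition. Cells with zero
expected count are skipped, not smoothed — this keeps the statistic
exactly the textbook formula on sparse tables and equals dropping empty
rows/columns. Windows with `X` at either position are excluded from the
grouped table and their count reported. A printed variant of the grouped
expected-count formula that subtracts rather than multiplies the marginals
circulates in the literature; it is dimensionally inconsistent and the
product form is used throughout.

Per-position class differences (two-sample logo statistics) use a pooled
two-proportion z-test per (position, residue), two-sided, with Fisher's
exact test as a small-count alternative; no multiple-testing correction is
applied, matching the per-position `P < 0.01` convention of two-sample
logos. Pairs absent from both classes are skipped.

## Maximal dependence decomposition

The 20 amino acids are partitioned into polar {S,T,N,Q,C,G}, acidic {D,E},
basic {K,R,H}, hydrophobic {A,V,L,I,M,P} and aromatic {F,W,Y}; only the
basic membership is fixed by the motif literature, the rest are
conventional and replaceable via a JSON scheme file.

At each node the grouped χ² is computed for every flanking pair. The node
is split when the maximum exceeds the threshold (default 34.3, the value
conventionally quoted for P = 0.01 at 16 degrees of freedom — the exact
0.01 critical value is 32.0 and 34.3 corresponds to α ≈ 0.005; the printed
convention is kept and configurable). The split position i* maximises the
total *significant* dependence Σ_j χ²(A_i, A_j) restricted to pairs that
individually clear the threshold. Summing all pairs — the textbook
phrasing — turns out to be numerically unusable here: with 20 flanking
positions the unrestricted sum is dominated by its noise floor (19
independent pairs contribute χ² with mean ≈ 19·16 = 304 and sd ≈ 25,
whereas one genuinely significant pair adds only ~40–80), so the selected
position would be close to random whenever a single pair carries the
signal. Restricting to significant pairs makes the argmax concentrate on
the truly dependent positions; the same masking picks the split group g*
(the
binary "residue at i* in group g" indicator against the remaining
positions, 2×5 tables), falling back to the unmasked sum when no indicator
pair clears the threshold alone. Ties break deterministically: smaller
|position|, upstream before downstream, then scheme group order.

The yes-branch takes windows whose residue at i* is in g* (X goes to the
no-branch); recursion stops when a node is smaller than the maximum
cluster size (default 100), no pair is significant, or a child would fall
below the minimum leaf size (default 20, a guard against degenerate
one-sequence leaves; the smallest subgroup reported for real glutarylation
data had 55 members). Leaves are labelled `Glutar1..M` in pre-order,
yes-branch first. The procedure is deterministic.

Two properties of the method worth stating plainly:

* Under positional independence the maximum of ~190 pairwise χ² statistics
  exceeds 34.3 with probability ≈ 0.6, so spurious splits of large
  unstructured nodes are expected behaviour of the method at this
  threshold, not a defect; the minimum-leaf-size guard limits their damage.
* A mixture of subpopulations each carrying a *single* planted
  position-group motif produces exactly one dependent pair at the root.
  After the first split that signal is spent — conditioning on the split
  group removes the only mixture dependence, and both children are
  position-independent — so no dependence-driven rule can recover the
  second subpopulation as a split. Recovering several subgroups requires
  multi-position motif families (as real substrate data exhibits). The
  synthetic benchmarks below are designed accordingly.

## Classifiers

One RBF-kernel SVM per leaf, on AAC features by default (the encoding that
benchmarks best for this task), features min-max scaled to [0,1] per
dimension with the scaling stored in the model. (C, γ) are chosen by
exhaustive grid search over log₂ grids (C: 2⁻⁵..2¹⁵ step 2²; γ:
2⁻¹⁵..2³ step 2²) maximising stratified k-fold CV accuracy (MCC objective
switchable); ties prefer smaller C then smaller γ; a reduced 4×4 grid is
provided for quick experiments and used in the test suite.

Each leaf trains on its member positives plus negatives allocated as a
seeded random partition of the negative pool, `round(2 × leaf positives)`
per leaf. Routing negatives down the tree is also implemented
(`method='routed'`) but is not the default: with composition features,
negatives that satisfy a leaf's split predicates are compositionally
matched to that leaf's positives, which empirically erases the subgroup
signal and collapses the subgroup models to the majority class — and the
per-leaf negative counts reported for real data are exact proportional
≈2:1 shares of the whole pool, consistent with random allocation.

The integrated model stacks the M subgroup classifiers: each window's
meta-vector is the M subgroup positive-class probabilities (Platt
scaling), and a meta RBF-SVM (same grid search) maps it to the final
probability (decision threshold 0.5). Meta-training vectors are computed
*out-of-fold* — a window in a subgroup model's training set is scored by a
refit on the other folds — so the meta-classifier never sees optimistic
in-sample probabilities; in-sample stacking is available but leaks.
Reported counts of "five" stacked models in the motivating work coexist
with six displayed subgroups; the number of leaves M is whatever the
decomposition yields.

All randomness (fold assignment, Platt calibration, negative allocation)
derives from explicit seeds; two runs with equal inputs and seed produce
byte-identical predictions.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/N and
MCC = (TP·TN − FN·FP)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)). Cross-validation
pools the per-fold predictions into a single confusion matrix (each window
scored exactly once) rather than averaging per-fold metrics. Folds are
stratified by class by default (plain random assignment is switchable);
ROC/AUC by threshold sweep with tied scores grouped and trapezoidal
integration. Report formatting: percentages to one decimal, MCC to two.
An empty actual class is an error; an empty *predicted* class yields
MCC = 0 with an explicit flag. Sweeps re-run pooled CV per window length
(by trimming wider windows), per fold count, and per encoding.

## Synthetic data

Negatives are i.i.d. draws from a background profile over the 20 standard
residues (uniform by default; a "glutaryl-like" preset enriches K/R by
×1.8 and depletes N/H/M/F/P to ×0.6, echoing reported compositional
tendencies) with the centre forced to K. Positives belong to
subpopulations; each subpopulation plants one or more (position, residue
group) motifs carried with probability *penetrance* (the planted residue
is resampled uniformly from the group). Full-length proteins can be
synthesised around the windows, with a configurable fraction placed flush
against a terminus so that X-padding paths are exercised end-to-end.

What passing tests on this generator show: correctness of the statistics,
the decomposition and the training pipeline under known ground truth.
What they do not show: performance on real proteomes — the generator has
no homology between windows, no domain structure, and no positional
correlations beyond the planted mixture.

Benchmark presets (also the problem sizes used by the test suite and the
acceptance script, chosen to finish on a single CPU):

* `two-motif`: 200 + 200 single-position subpopulations (basic@−8,
  acidic@+4, penetrance 0.9) + 100 background positives, 1000 negatives.
  The canonical motif-recovery condition; by the mixture argument above
  its first split is recoverable and its second is not.
* `stacked-benchmark`: curated-dataset scale (430 positives / 860
  negatives) with an upstream basic family (−10, −8, −6) of 170, a
  downstream acidic family (+3, +4) of 170, and 90 background positives,
  penetrance 0.9. Calibrated so a pooled AAC SVM lands in the CV-MCC
  ≈ 0.1–0.2 regime reported for real data and both pooled and stacked
  models learn non-degenerately; single-position subpopulations at this
  class imbalance leave both models at the majority class, which makes
  model comparisons vacuous.
* `one-motif` / `null`: homogeneous and unstructured controls.

Type-I calibration of the grouped χ² uses 3-mer windows (one flanking
pair) with 500 windows per replicate, putting the smallest expected cell
at ≈ 5 where the asymptotic χ² approximation is conventionally adequate.

## Known limitations

* The 34.3 threshold with ~190 tested pairs implies frequent spurious
  splits on unstructured data (see above); interpret small leaves with
  single odd split rules sceptically.
* Stacking at these problem sizes is not reliably better than the pooled
  model on the synthetic benchmark: subgroup structure expressible in
  composition space is largely within reach of a pooled RBF-SVM, while
  stacking pays a data-splitting cost. The comparison machinery reports
  whatever the data support.
* Grid-search accuracy as an objective under 1:2 imbalance can prefer
  majority-class solutions when the signal is weak; the MCC objective is
  available.
* Identity clustering is window-level only; full-protein homology is out
  of scope.
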