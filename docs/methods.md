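# Methods

This note records the model, its assumptions, the parameter choices that
matter, and the numerical conventions the package commits to. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The threshold model and its AUROC

The per-transcript classifier is deliberately primitive: one direction and
one cut-point. The direction is fixed by comparing class means — the class
with the greater mean log₂(FPKM+1) is predicted when expression is at or
above the threshold (the rule is inclusive, `x >= t`). Candidate thresholds
are the sorted unique observed values; scanning midpoints adds nothing under
an inclusive rule because any cut between two observed values classifies
identically to the upper value.

"AUROC" for such a fixed-threshold rule is defined as
(sensitivity + specificity)/2 — the **point AUROC** — which is exactly the
trapezoidal area under the three-point ROC through (0,0), (FPR, TPR), (1,1).
This is the only reading under which a per-threshold AUROC is a non-constant
function being maximized: the full-curve AUROC of a score does not depend on
any threshold. The full-curve rank AUROC remains available in `evaluate` and
is used for score-producing models.

Numerical conventions, chosen for determinism:

- ties in the maximal point AUROC resolve to the smallest maximizing
  threshold (this slightly favors sensitivity for positive-high features);
- equal class means default the direction to positive-high and set a
  `degenerate` flag; constant transcripts get point AUROC 0.5 and the flag;
- the optimum can never fall below 0.5 because the extreme cut that calls
  every sample the higher-mean class is always available.

Two invariances are property-tested: exchanging the class labels flips the
direction and preserves the point AUROC (defined when the means differ), and
any increasing transform that preserves the class-mean ordering preserves
the point AUROC and maps the threshold through the transform. The ordering
caveat is real: a nonlinear monotone map can reorder the class *means* and
thereby flip the direction choice; affine maps never do.

## Preprocessing chain

Fixed order: log₂(FPKM+1) → variance filter → Z-score. Variance and σ use
the n−1 (sample) denominator, so the variance cutoffs — 0.25 for the
early/late task, 0.02 for tumor/normal — are interpretable as sample
variances of log₂ expression. Z-scoring always uses training-partition μ, σ;
applying a model to new data replays the stored statistics, never the
target's own. Zero-variance transcripts are flagged at fit time and rejected
only if Z-scoring is actually attempted on them, so they can be filtered
upstream without ceremony.

The stratified split uses the original four-stage label (not the merged
early/late class) as the stratum key and assigns exactly
floor(train_fraction · n) samples per stratum to training. With the cohort's
stage composition (281/52/112/55 tumors, 58 normals) and an 80:20 ratio this
yields 265 early / 133 late / 46 normal training samples; a rounding rule
would give 267. Transcript version suffixes (`ENSTxxxx.N`) are stripped for
cross-cohort matching, with original IDs retained in outputs.

## Feature selection

**FCBF.** Continuous expression is first discretized by recursive
entropy-minimizing binary splits accepted under the Fayyad–Irani MDL
criterion (cuts at midpoints between adjacent distinct values); features
that collapse to a single bin carry no class information (SU 0) and are
never selected. Features are ranked by symmetrical uncertainty with the
class, SU = 2·I(X;Y)/(H(X)+H(Y)) with base-2 entropies, and a feature is
pruned when an already-kept feature predominates it (feature–feature SU at
or above its class SU). The default SU threshold is 0: keep everything
relevant, prune only redundancy. The implementation is tested against an
independent transcription of the published FCBF pseudocode.

**ANOVA-F** is the classical one-way F statistic (top-k, descending); with
two classes it equals the squared pooled t statistic, which the tests check
numerically.

**L1 margin selection** minimizes a squared-hinge loss plus
`penalty_strength`·‖w‖₁ on Z-scored features and keeps features with
|w| > 1e-8, ordered by |w|. Because the penalty producing a given panel size
is data-dependent, `l1_panel_size_search` bisects the penalty to hit a
requested size. The solver's internal shuffling is explicitly seeded; panel
size is empirically non-increasing in the penalty on the fixture data.

**Stochastic subset search** replaces a wrapper search with an external
optimizer by a generic seeded genetic algorithm over feature bit-masks
(uniform crossover of an elite half plus bit-flip mutation, population 12,
mutation rate 0.1), with fitness = pooled 10-fold cross-validated MCC of an
RBF margin classifier on the masked features. It shares the encoding (binary
mask over a pool of at most 100 features) and objective with the wrapper it
stands in for, and is reproducible from its seed.

## Classification and calibration

The classifier is an RBF-kernel SVC tuned by stratified k-fold grid search
over γ ∈ {10⁻³, 10⁻², 10⁻¹, 1, 10} and integer C ∈ [1, 10] (log-spaced γ
spanning the stated interval; accuracy is the tuning metric; ties resolve to
the smallest C, then smallest γ). Probability scores come from a Platt
sigmoid — p = 1/(1+exp(a·d+b)) with smoothed targets — fitted on
*out-of-fold* decision values within the training set, so scores are not
optimistic about the training fit. Any monotone calibration preserves the
semantics of score-threshold tables, which is all the operating-point
analysis needs.

A trained model freezes panel, normalization statistics, support vectors,
dual coefficients, kernel parameters, calibration, classes and decision
threshold into a plain-text archive (TSV + JSON). The RBF decision function
is recomputed from the stored vectors at load time and is verified in tests
to match the fitted estimator to machine precision; floats round-trip
through text exactly (`%.17g` out, round-trip parsing in). The default
decision threshold is 0.5; `choose_decision_threshold` instead selects the
candidate score minimizing |recall − specificity|, breaking ties by maximum
accuracy then smallest threshold — the "balanced operating point" used when
presenting results at a single cut-off. Multiclass discrimination
(normal/early/late) is one-vs-rest: one calibrated scorer per class, argmax
prediction, per-class score vectors exposed for per-class ROC.

Inputs at prediction time may be raw FPKM or log₂; the model applies its own
stored chain. Samples whose Z-scored features exceed |z| > 6 anywhere are
flagged out-of-distribution rather than rejected.

## Metric suite

Sensitivity, specificity, accuracy are reported in percent; precision,
recall, MCC, F1 and AUROC as fractions. MCC uses the standard four-factor
denominator with the convention MCC = 0 when any marginal vanishes.
Undefined ratios (zero denominators) are reported as undefined-with-reason,
never as NaN. F1 is emitted in four variants (per-class, macro, weighted,
micro); for a complete binary confusion the micro variant equals accuracy,
which is how the printed binary "F1 score" column of the source tables
behaves in most rows — the table-parity column therefore shows micro-F1
while the other variants are always available.

Full-curve AUROC is computed two ways — trapezoid over the ROC vertices and
the normalized Mann–Whitney statistic with ties counted ½ — and the
implementations assert agreement to 1e-12 on every call. The bootstrap CI is
a stratified percentile interval (resampling within each class, default
2,000 replicates, seeded).

The PPV/NPV operating table uses a dual rule at cut-off t: positive (early)
call when score ≥ t, negative (late) call when score ≤ 1−t, samples in
between abstain. This is the only reading under which published positive and
negative call counts at a single cut-off need not partition the sample set.
The complementary cut is rounded to 12 decimals so that 1−0.9 is 0.1
exactly. Empty call sets report 0.00 with a flag.

## Synthetic cohorts

`generate_dataset` emulates a GDC-style FPKM cohort: per transcript a
lognormal baseline (log₂ level ~ Normal(3, 2)), per sample
value = 2^(level + class shift + Normal(0, noise_sd)) − 1 clipped at 0, and
structural zeros (dropout, default 5%) applied last. Defaults mirror the
study conditions: 333 early / 167 late / 58 normal samples (raw stages
apportioned 281:52 within early and 112:55 within late so stratified splits
behave as in real data), 2,000 transcripts as a desk-scale stand-in for the
60,483-feature matrices, and 36 planted markers with an early↔late shift of
1.5 within-class standard deviations plus a stronger (2.5 sd) tumor↔normal
shift, signs alternating. Effects are additive in log₂, i.e. multiplicative
fold changes in FPKM.

What the generator does **not** emulate: gene–gene correlation structure,
batch effects, library-size artifacts, or real annotation. Passing tests
therefore demonstrate that the machinery recovers planted signal under
realistic marginal distributions — not that any particular transcript panel
generalizes to real tumors.

One deliberate consequence of clipping at zero: a planted marker whose
baseline is low loses part of its configured effect (values pile up at 0),
so recovery of planted markers is high but not guaranteed to be total. The
acceptance suite quantifies this: averaged over 20 seeds, at least 90% of
the 36 planted markers must appear in the ranking's top 100.

`generate_external_cohort` reproduces the cross-platform validation setting:
it keeps a configurable fraction of features (never less than half of the
planted set), applies a monotone per-feature distortion (scale ~ U(0.8,1.2),
offset ~ U(−1,1) on the log₂ level), and draws fresh samples — by default
17 early / 3 late, the size of the real external series. Because accuracy on
20 samples moves in steps of 0.05, the harmonization acceptance check
(internal vs external accuracy within 0.1) uses a 67/33 external cohort
matching the internal validation class ratio; the 17/3 default is exercised
structurally.

## Known limitations

- The threshold model's monotone-transform invariance is conditional on the
  class-mean ordering surviving the transform (see above).
- Quantile normalization onto a reference with tied values (its dropout
  zeros) can merge distinct target values; the map is always weakly
  monotone, but per-feature Spearman correlation with the pre-normalization
  values is exactly 1 only for tie-free features.
- Per-fold metric reports under leave-one-out are omitted (singleton test
  folds make most ratios undefined); only the pooled confusion is reported.
- The wrapper-style subset search is a generic stochastic optimizer; it
  makes no claim of numeric parity with any specific published optimizer,
  and the package does not attempt bit-parity with WEKA's classifier
  implementations — alternative classifier families plug in behind the same
  train/predict/persist surface.
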