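# Methods

## Junction quantification

Junctions are internally 1-based inclusive intron intervals; BED input
(0-based half-open) and GTF exons (introns derived between consecutive
exons per transcript, deduplicated) are normalised on read. This matches
CIGAR walking on SAM's 1-based coordinates: an `N` operation of length L
starting after reference position p spans the intron [p+1, p+L].

A read increments a junction's count iff (i) its CIGAR contains at least
one `N`, (ii) some gap equals the intron exactly, and (iii) its aligned
blocks touch the exonic flank window (default 150 bp) on both sides of the
junction. "Spanning 150 bp upstream and downstream" is interpreted as
*overlap* (≥ 1 bp in each window): requiring full containment would make a
single 150 bp read uncountable, which contradicts a 150 bp paired-end
design. Both interpretations are implemented (`span_mode`), with flank
length configurable. Deletions (`D`) do not split an aligned block;
insertions and clips consume no reference. Secondary and supplementary
alignments are ignored; alignments to chromosomes absent from the
annotation are counted as warnings, not errors. Each mate of a pair counts
independently, and a read with two gaps can support two junctions.

CPM uses, per sample, the number of distinct annotation-matched
junction-supporting primary reads as denominator (self-contained and
robust to differences outside annotated junctions), with total primary
reads as an option. log₂CPM uses pseudocount 1 so that zero CPM maps to
exactly 0, keeping "completely absent" finite; note that at this
convention the screen's 0.2–0.5 thresholds correspond to sub-CPM
expression.

## Candidate screen

A (threshold, control-fraction) pair admits a junction when the fraction
of control samples (asymptomatic + benign, training split) with value
strictly below the threshold (ties count as *not below*) reaches the
required fraction, and at least `min_case_count` (default 1) cancer
samples are clearly expressed. "Clearly expressed" defaults to
value ≥ threshold + margin (margin 1.0 log₂CPM); a Tukey-fence outlier
rule (above controls' Q3 + 1.5·IQR) is available. The candidate set is the
union over the 4 × 6 grid ({0.2, 0.3, 0.4, 0.5} × {0.70 … 0.95}), with the
admitting pairs recorded. Admission is monotone: raising the fraction
never adds candidates; raising the threshold never removes them.

Validation regresses reversed ΔCq (per-marker maximum minus value, so
higher = more expression) on scaled log₂CPM (marker minus ACTB) by
ordinary least squares over samples with genuinely measured qPCR signal
(censored and undetected cells are excluded — the sentinel value carries
no quantitative information). For simple regression R² equals the squared
sample correlation. A marker undetected in every control sample passes
regardless of R²; otherwise R² ≥ 0.4 with at least 3 paired points is
required.

## ΔCq preprocessing

Undetected replicates are assigned 41 cycles before duplicate averaging
(averaging precedes censoring by default; a flag reverses the order). A
cell with one missing replicate uses the other; a cell missing both
replicates is an error, distinguishing assay dropout from
no-amplification. Non-specific cutoffs default to the maximum Cq observed
among *detected* benign training reactions per marker — any signal weaker
than every benign signal is deemed non-specific — with a percentile
alternative; markers never detected in benign receive the vacuous cutoff
41 − 1e-6 so that real detections are never censored. Censoring is
strictly "exceeding" (a value equal to the cutoff passes) and idempotent.
ΔCq subtracts the sample's ACTB Cq; an undetected or censored reference
invalidates the sample (error), and reference Cq outside a plausibility
window (default 17.25–20.88, the range consistent with reliable qPCR
efficiency) raises a warning only.

## Scoring classifier

Panel variables are the five individual markers (FMO2_a, CD177_a, TCN2_a,
NPRL3_a, GCKR_a) and one composite summing the ΔCq of the IL1R2/DEFA
family (IL1R2_a, IL1R2_b, DEFA1_a, DEFA1B_a, DEFA3_a) with divisor 5. The
partition is fully configurable, and markers that fail validation are
dropped from it.

Cutoff calibration: with target specificity s and n benign training
values, at most ⌊n(1−s)⌋ benign values may sit at or below the cutoff; at
s = 0.99 and n ≤ 100 that is none, so the benign minimum q is the
boundary. The cutoff is the midpoint between q and the largest cancer
value strictly below q, or q − δ (δ = 0.5 ΔCq) when no cancer value lies
below; a cancer value tied with q counts as benign-side. This guarantees
training specificity ≥ s by construction. Variables constant across
training are dropped with a warning.

Weights are the training ROC AUC of each variable's x values
(Mann–Whitney pair counting, ties ½) — equivalent to the AUC of −ΔCq,
since AUC is invariant under monotone transforms with positive divisor.

Scoring: x = (cutoff − observed)/divisor, F = tanh(x) for x ≥ 0 and x/10
for x < 0 (continuous at 0, bounded above by 1, gently linear below).
Zero-replacement: if any F > 0 the negatives become 0; the Total Score is
Σ F·w / |M_s| over the contributing set M_s = {F ≠ 0}, or 0 when M_s is
empty. A score of 0 arises exactly when no variable exceeds its cutoff, so
the boundary is assigned to non-cancer (configurable).

Two structural properties are worth stating precisely. The call is
equivalent to "any variable strictly below its cutoff" whenever all
weights are positive, and increasing expression can never flip a cancer
call to non-cancer. The raw Total Score, however, is **not** monotone in
ΔCq: when a variable's F crosses from negative (zeroed) to weakly
positive, it joins M_s and can dilute the weighted mean. The tests assert
the true properties (per-variable F monotone, call monotone), not score
monotonicity.

## Evaluation

Ovarian cancer is the positive class; borderline ovarian tumors are
excluded from every 2×2 and reported as a side count of positive calls.
Four reports are produced: training (13 OC vs 16 benign, n = 29), test
(4 OC vs 21 benign, n = 25, 2 BOT aside), the 34 asymptomatic controls
(specificity only — they never enter model fitting), and the pooled total
(17 OC vs 71 controls, n = 88). AUC is pair-counting Mann–Whitney. The
AUC confidence interval uses the Wilson score interval with n = number of
evaluated samples. Wilson's method is defined for binomial proportions and
this use on an AUC is a diagnostic-field convention, not an orthodox
variance treatment; it is implemented because it is the package's target
convention, and it exactly reproduces closed-form checks at (0.938, 29) →
(0.790, 0.984) and (0.933, 88) → (0.861, 0.969). No (p, n) pair near the
test-set configuration reproduces an interval of (0.746, 0.976) under this
formula, so test-set intervals from this convention should be read with
that caveat. Empty-class metrics are reported as undefined, never 0.

## Synthetic data generator

The generator emulates the statistical skeleton the algorithm consumes,
not platelet biology. Cohort: 90 samples (13/16/32 OC/Benign/AC training,
4/21/2 OC/Benign/BOT test, 2 further AC completing the 34-control
validation set); controls come from a single institution, mirroring the
collection pattern.

Counts: background junctions (default 500) share one negative-binomial
model across groups with per-junction mean CPM log-uniform on [2, 500] and
dispersion 10 — constitutively expressed junctions. Planted markers
(default: the ten panel names) are zero in controls apart from a leak rate
of 0.05 at trace level (~0.5 log₂CPM); an OC sample expresses each marker
with probability 0.75 at level `marker_effect` × exp(N(0, 0.3)) log₂CPM
(default effect 5), so effect 0 silences the markers entirely — the null
configuration. BOT samples draw OC-like expression with probability 0.5.
The reference junction sits at ~13.3 log₂CPM everywhere. Counts are
Poisson around the level-implied rate; the recorded library size is the
nominal genome-wide junction-read total (mean 2×10⁶), since the simulated
junctions stand for a small subset of a real annotation — normalising
against their own column sum would inflate every CPM.

One deliberate consequence of the moderate background expression: at
realistic library sizes a single read already exceeds ~0.5 log₂CPM, so
ultra-rare null junctions would be admitted by any thresholded screen
through count granularity alone (which is why qPCR validation exists).
The generator's null junctions are therefore expressed well above the
screen thresholds, making "no identically-distributed junction is
admitted" a meaningful, testable property.

qPCR: latent Cq = Cq_ACTB + 9 − 1.0 · (log₂CPM_marker − log₂CPM_ACTB) +
N(0, 0.8), two replicates each with N(0, 0.15) technical noise, undetected
above 40 cycles; ACTB per sample from N(19, 0.6) (within the plausible
17.25–20.88 window; ~5 % of samples fall just outside and exercise the
plausibility warning). With these defaults the expressed-marker
sequencing–qPCR R² concentrates in ≈ 0.75–0.98 and stays inside the
plausible (0.4, 1.0) band in well over 90 % of runs, while absent markers
drop out — the regimes the validation rule distinguishes. The generator
does not simulate institutional batch effects, transcriptome-wide
splicing, fragment-level read pairing, or amplification-efficiency
curves; passing tests demonstrate algorithmic correctness under the
assumed model, not clinical performance.

Everything is a pure function of (config, seed): two runs with the same
seed are identical across metadata, counts, alignments and Cq tables.

## Numerical choices and problem sizes

Floating-point ties: screen thresholds use strict `<` for "below";
censoring uses strict `>` for "exceeding"; classification assigns 0 to
non-cancer. The vacuous-cutoff ε is 1e-6 cycles. The Wilson z for 95 % is
the normal quantile 1.959964. Tests and the acceptance script run the
default cohort (90 samples, ~510 junctions) over up to 50 seeds and
SAM fixtures of a few dozen junctions — sizes chosen so the full suite
completes in about a minute while every property is exercised at the
study's own cohort dimensions.

## Known limitations

Out-of-sample specificity is not guaranteed at 99 %: the cutoff
construction controls *training* specificity only, and with 16 benign
training samples the benign minimum is a noisy boundary; on synthetic
validation controls the realised specificity is typically ~85–95 %. The
composite variable's midpoint cutoff can sit far below the benign minimum
when expressing cancer samples are strong, widening the positive region
for samples with unusually high reference Cq. Fragment-level counting
(counting a read pair once) is available only as a convention flag; no
duplicate marking or base-quality filtering is performed beyond
primary-alignment selection.
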