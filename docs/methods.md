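# Methods

## Design and contrasts

The pipeline analyzes a pooled four-group TMT design: NoSNI (uninjured),
NoSCS (injured, untreated), DTMP and LRSCS (injured, treated). Pooling
leaves a single reporter channel per group, so there are no biological
replicates at the group level; inference rests on peptide-level replication
(proteomic path) and duplicate technical runs (phospho path). Three
contrasts are computed throughout: pain = NoSCS/NoSNI, DTMP = DTMP/NoSCS,
LR = LRSCS/NoSCS.

## Normalization

Peptide log2 intensities are median-centered per group onto the grand
median, defined as the median of the four per-group medians (unweighted by
group size). This is robust, preserves within-group rank order, and is
idempotent. Because every peptide delta is a difference of two channels,
any constant per-group offset in the raw data — and hence the choice of
common target — cancels in all three contrasts; the unweighted definition is
preferred because it leaves the output exactly invariant when a single
channel is globally shifted. Phospho intensities are not re-normalized:
ratios are formed within runs, which removes run-level scale.

## Quantification

*Proteins.* For each contrast, per-peptide deltas are
log2(numerator) − log2(denominator) over uniquely assigned peptides measured
in both channels. The fold change is the mean delta; significance is a
two-tailed one-sample *t*-test of the deltas against 0 with
df = n_peptides − 1. Proteins with one usable peptide are quantified but
flagged untestable (no p-value); so are proteins whose delta sample standard
deviation is below 1e−9 on the log2 scale — deltas constant to
double-precision rounding carry no usable variance, and treating them as
"infinitely significant" would be an artifact of floating-point noise. No
multiple-testing correction is applied: the decision rules are defined at
per-test α = 0.05, which is a scientific caveat of the rule set itself, not
of the implementation.

*Phospho-isoforms.* Per-run linear ratios are paired by run id; the fold
change is the mean of per-run log2 ratios. Each group's CV is the n−1
standard deviation of its linear intensities across runs divided by their
mean (conventional even at n = 2), and the ratio CV is
√(CV_num² + CV_den²). CVs are reported but not used as a classification
filter by default.

## Classification rules

Phospho (threshold-gated): affected ⇔ |r_pain − 1| ≥ threshold
(default 0.10), evaluated with a 1e−12 relative tolerance so the "at least"
boundary is inclusive under binary floating point (|0.90 − 1| is
0.0999…98). Back-regulated by treatment T ⇔ affected ∧ |r_T − 1| ≥
threshold ∧ sign(r_T − 1) = −sign(r_pain − 1): the magnitude is measured
against NoSCS and the direction is toward NoSNI. A same-direction change
meeting the magnitude gate is *further modulated*. By default a reversal
may overshoot past uninjured levels (`overshoot_allowed = true`); when
disabled, a reversal whose net level vs. NoSNI (r_pain·r_T) crosses the
threshold on the far side is vetoed.

Protein (significance-gated): affected ⇔ p_pain < α; back-regulated ⇔
affected ∧ p_T < α ∧ opposite fold-change sign. Significance rather than
the 10% rule gates the protein path because peptide replication supports a
test there, while duplicates on the phospho path do not. An undefined pain
p-value makes a record unclassifiable (counted in totals, never affected);
an undefined treatment p-value simply never reaches significance.

Aggregation reports n_total, n_affected, n_backreg per treatment, with
percentages of affected over total and of back-regulated over affected.
Percentages are rounded half-up: one decimal at the overall level, nearest
integer in per-category tables, matching the conventions of the printed
tables this pipeline reproduces.

## Categories and overlaps

Annotations map proteins to subsets of {structural, adhesion, junction,
signaling}; isoforms inherit their parent protein's categories. Rollups
count an entity once per category it belongs to, so category totals may sum
to more than the number of distinct entities. Overlap counts use exact set
arithmetic over three circles — structural, adhesion/junction (the two
categories pooled), signaling — returning circle sizes, pairwise
intersections and the common (triple) intersection.

## Synthetic generator

The generator emulates the study conditions: four pooled channels, 4–10
peptides per protein (uniform, seeded), duplicate technical runs, and
multiplicative log-normal noise (intensity = mean × 2^ε,
ε ~ Normal(0, noise_sd)) — the standard noise model for spectral
intensities. Each entity receives a planted class: unaffected, or up/down
with any combination of DTMP/LR reversal. Planted linear ratios sit a
multiplicative margin beyond the decision boundary: up-regulation at
1.10·(1+m), down-regulation at 0.90/(1+m), so both lie log2(1+m) beyond
their boundary on the log2 scale. The default margin is 0.25 (planted
changes ≈ ±37%), consistent with the tens-to-hundreds-of-percent phospho
changes typical of this kind of injury model data; reported intensity-noise
magnitudes are not available for the emulated study, so the default
noise_sd = 0.05 (log2) is a generator choice, not an estimate.

On the proteomic path, planted effects are common log2 shifts across a
protein's peptides, sized by the classical power formula
δ = (t_{1−α/2,k−1} + t_{1−β,k−1})·noise_sd·√2/√k·(1+margin) with β = 1e−6
and floored at log2(1.10·(1+margin)), so detection of every planted effect
is essentially certain. Contrasts with *no* planted effect copy the
reference channel's peptide intensities verbatim: their deltas are
identically zero, the t-test is undefined, and the null is deterministically
non-significant. This is what makes planted proteomic compositions exactly
recoverable — with independently noisy nulls, ~α of null contrasts would be
falsely significant. It is also the generator's main departure from real
data, where null contrasts carry noise and per-test false positives are
unavoidable; exact-recovery results therefore validate the decision rules
and counting conventions, not the error rates of significance testing on
real measurements. Phospho generation keeps independent noise on every
channel; its recovery is exact only at noise_sd = 0.

Truth labels are assigned to entities in a fixed class order, so the same
spec plants the same truth under every seed; the seed drives only noise,
abundances, peptide counts and site strings. Truth is written as a sidecar
`truth.tsv` next to the generated tables; real runs simply lack the sidecar.

*Resolution limit.* With duplicate runs the mean log2 ratio has standard
deviation equal to noise_sd, while a planted ratio sits log2(1+m) beyond
the boundary. Faithful recovery of the affected fraction therefore needs
log2(1+m) ≳ 2.5·noise_sd; e.g. at noise_sd = 0.05, a margin of 0.05
(distance 0.070) leaves ≈ 8% of planted affected isoforms below the
boundary, while the default margin 0.25 (distance 0.32) makes
misclassification negligible. The noisy-recovery tests are run where the
margin exceeds this resolution (noise 0.05 with margin 0.25, and noise 0.02
with margin 0.05).

The annotation generator realizes exact circle sizes and intersections by
inclusion–exclusion and rejects infeasible specifications. The shipped
benchmark overlap fixture uses circle sizes 48/112/102 with pairwise
intersections 7/15/69 and triple intersection 4; the proteomic benchmark
realizes the reported reversal percentages (83%/67%) as 83 and 67 of 100
affected proteins out of 186, since only the percentages are on record.

## Reporting

Protein heatmap cells are tri-state: sign(log2FC) where p < α, else 0 (an
exact zero fold change has no direction). Phospho heatmaps carry percent
changes for each protein's most pain-affected isoform (ties broken
lexicographically by isoform id). Rows are ordered alphabetically; columns
are fixed as pain, DTMP, LR. The canonical artifacts are numeric TSVs;
rendering images is out of scope. `summary.json` echoes the configuration
and seed alongside all totals.

## Problem sizes and determinism

The shipped benchmarks span 69–883 entities; the full test suite and the
benchmark script run in seconds on one CPU. Every random quantity flows
through a single integer seed per dataset (numpy `default_rng`); identical
spec + seed reproduces byte-identical tables and outputs.

## Known limitations

The generator does not simulate missing values, batch effects, isobaric
interference, peptide-spectrum matching or protein inference from shared
peptides. Classification applies no FDR control (by design of the rule
set). The pooled design means all inference is conditional on the single
pool per group; nothing here estimates biological between-animal variance.
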