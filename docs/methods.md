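# Methods

This note documents the models, parameter choices and numerical decisions
behind `srleseq`, and what the synthetic-data experiments do and do not
demonstrate.

## The screen model

A reporter library member is an insert cloned between constant flanks in the
carrier transcript's 3′ UTR. Sequencing a fraction yields reads of the form
`flank5 + insert + flank3` (possibly reverse-complemented, possibly junk).
A read is **valid** if it contains the two constant 10-nt anchors exactly
(the last 10 nt of the 5′ flank, the first 10 nt of the 3′ flank); the
insert is the substring strictly between the first 5′-anchor occurrence and
the first subsequent 3′-anchor occurrence, searched forward first and then
on the reverse complement, once. Anchor matching is exact by default:
"contains the flanking region" is read conservatively, which keeps
extraction a pure, deterministic function of the read; a Hamming-tolerance
flag (`max_mismatches`) exists for noisier chemistry. Inserts containing N
or with out-of-range length are invalid — they cannot be assigned to a
library bin. The default 6-mer library flanks are synthetic stand-ins;
their anchors were chosen with no internal or cross-junction periodicity,
so first-occurrence extraction is unambiguous for every possible insert.

## Synthetic data generator

The generator is the package's study-condition bench, not a sequencing
simulator. Its fractionation model: element *i* has relative abundance
*a_i* (log-normal, σ = 0.5) and a true enrichment *e_i* (log2). Expected
reads in a fraction of depth *D* are proportional to *a_i*·2^(+e_i/2)
(nuclear) or *a_i*·2^(−e_i/2) (cytoplasmic), normalized within the
fraction — the tilt is split symmetrically so whole-cell composition is
class-independent, and the expected nuclear:cytoplasmic CPM log-ratio
equals *e_i* up to a small compositional offset (CPMs are relative; with
sparse planting the offset is ≪ 0.1 and the tests account for it exactly).
Replicate counts are negative-binomial with variance μ + αμ²; α = 0
degenerates to Poisson.

Default dispersion is **α = 0.02** (extra CV ≈ 14% between biological
replicates), chosen a priori as a realistic overdispersion for a
transfected amplicon screen with well-controlled fractionation; procedures
whose calibration is assessed at a stated dispersion (the null calibration
at α = 0.1, the knockdown recovery at α = 0.05) use those values.

Reads are emitted already trimmed: constant Q40 qualities, no adapters, no
sequencing errors (quality trimming is a pass-through hook). Junk reads
(anchor-free) and reverse-complemented reads are optional fractions;
defaults 0. Fragment libraries sample uniform starts and uniform lengths
in [30, 100] nt — the detected-fragment range; the amplified range
(75–150) is configurable where needed. What passing tests therefore show
is that the *statistics* recover planted truth under NB noise; they say
nothing about alignment artifacts, PCR bias, or error-containing reads,
which the screen's real upstream tools handle.

## Enrichment testing

Per element, nuclear vs cytoplasmic counts across replicates are tested
with a negative-binomial Wald test:

1. **Size factors**: median-of-ratios against the geometric-mean
   pseudo-reference, elements with any zero excluded from the reference
   (depth-proportional fallback if none qualify).
2. **Dispersion**: per-element method of moments on normalized counts
   (pooled within-fraction variance minus the counting variance, over the
   squared mean), floored at 10⁻⁸, then **moderated** toward the
   library-wide mean dispersion with prior weight 20 df against the
   residual 4 df. The moderation is essential: with triplicates the raw
   per-element moment estimate is so noisy that the normal-reference Wald
   test rejects ~12% at nominal 5%; pulling toward the central value
   restores ~5.5% (the null-calibration test asserts the [0.03, 0.07]
   band). No trend fitting, shrinkage priors, or outlier handling beyond
   this — exact numerical agreement with full empirical-Bayes pipelines is
   a non-goal; calibration is validated behavioural instead.
3. **Wald statistic**: log2 fold change of normalized means (pseudocount
   0.5) over a delta-method SE from the NB variance model; two-sided
   normal p; BH adjustment over all elements as one family.

The NRS itself is computed from CPMs with pseudocount 0.5 and is the
quantity thresholded at ±0.58; the test supplies the p-value. The
classification threshold uses the **raw** p-value by default, matching the
stated rule; `use_adjusted_p` switches to BH-adjusted. Replicate
aggregation for NRS is mean CPM per fraction.

## Tracks, regions, peaks

All intervals are 0-based half-open. Fragment mapping is exact substring
search (forward, then reverse complement); synthetic references are
error-free so alignment tolerance is out of scope. Multimapped fragments
keep their first occurrence, flagged. Coverage is per-position fragment
count; the NRS track is the per-position mean NRS of covering fragments,
with a coverage mask. Enriched regions are maximal runs of |NRS| ≥ 0.58
with coverage ≥ 10, runs separated by ≤ 10 nt merged, minimum length 20 —
permissive defaults standing in for a by-eye retrieval step, all exposed
in configuration.

Transcript profiles: `raw[i]` is the table score of the window starting at
i (windows with non-ACGT characters score 0 and are flagged); `averaged[p]`
is the mean of the ≤ 6 windows covering p — edge positions average only
the windows that exist, so no scores are invented. Peaks are called on the
averaged vector at ±0.5 (inclusive), minimum length 6, merge gap 3; a merge
never spans a position passing the opposite-sign threshold, so peaks of
opposite classes cannot overlap. Raw-vector calling is available by flag.
Peak-calling morphology parameters are this package's choices; the source
method states only the ±0.5 cutoffs.

## Localization classifier

Transcripts are labeled nuclear (cytoplasmic) when their per-context
log2 fraction ratio is ≥ +1 (≤ −1) in **every** expression context
(default 12; FPKM pseudocount 0.1); anything else is excluded.

The classifier consumes a per-position scalar track — raw or averaged NRS,
optionally from a value-permuted table (the randomized control) — or plain
6-mer identities (the sequence-only baseline). Encoding lifts each scalar
to an m-dimensional token via a learned linear map (an embedding table for
the baseline), adds fixed sinusoidal positional encodings, prepends a
learned CLS token, and masks padding. The network is a pre-norm
transformer: 2 layers, 4 heads, feed-forward width 2m, classification head
on the final CLS representation. It is implemented directly in numpy with
hand-derived gradients (validated against finite differences in the test
suite) and Adam; float32 by default, float64 available for gradient
checking. The encoding scheme and depth are this package's design — the
source method specifies only the n×m matrix, the CLS token and "a
multilayer Transformer".

Study conditions for the ordering experiment: 100 transcripts per class of
100–200 nt, 10 planted class-specific 6-mers each, the ±1-effect truth
table, m = 32, batch 16, learning rate 10⁻³, 6 epochs (test loss rises
beyond that on these data), stratified 80/20 split, accuracies averaged
over 3 generator seeds. These sizes are desk-scale by design; the
qualitative claim tested is the *ordering* — NRS-guided modes beat the
randomized and baseline controls by ≥ 0.1 accuracy — not any absolute
accuracy on real transcriptomes.

## Knockdown shifts

Within each condition, nuclear and cytoplasmic samples are paired by
replicate index and per-replicate log2 CPM ratios computed (pseudocount
0.5). Δlog2FC is the difference of condition means, tested by a two-sample
equal-variance Student t on the per-replicate ratios (Welch by flag; the
pairing unit is this package's decision — the source states only "Student
t test"). Shift classes use strict inequalities: to-nuclear iff
Δ > 0.58 and p < 0.05, to-cytoplasm iff Δ < −0.58 and p < 0.05. Volcano
output is tabular (point list plus binned density grid); no figure is
rendered.

## Numerical notes and limitations

- All randomness flows through `numpy.random.default_rng` seeds; every
  generator and training run is bit-reproducible under a fixed seed.
- CPM columns sum to 10⁶ by construction; zero-depth samples are an error.
- The Fisher tests in the base-composition contrast pool positions within
  each set, treating bases as independent draws — adequate for 6-mer sets,
  not a motif model.
- The binomial-oracle equivalence (Wald p monotone with an exact binomial
  test on Poisson data) holds at α → 0 and equal depths; it is a ranking
  check, not a p-value identity.
- Known limitations: no PCR or sequencing-error model, no paired-end or
  spliced handling, exact-match mapping only, and classifier experiments
  at desk scale as described above.
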