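# srleseq

Analysis pipeline for **sequence-based RNA subcellular localization element
screens**: massively parallel reporter experiments in which short sequence
elements are cloned into the 3′ UTR of a carrier transcript, the transfected
cells are fractionated into nucleus and cytoplasm, and the elements are
amplicon-sequenced from each fraction. The package takes the screen from raw
fraction FASTQ files to scored elements, per-nucleotide score tracks,
transcript-level peaks, a localization classifier, and knockdown shift
analysis. A first-class synthetic-data generator produces every input with
known ground truth, so each stage is testable end to end.

It is written for computational biologists analysing such screens (the
saturating 6-mer library design and the random-fragment tiling design are
both supported) and for anyone who wants a transparent, dependency-light
re-implementation of the statistics involved.

## The score and the tests

For an element *e* with mean counts-per-million CPM<sub>nuc</sub> and
CPM<sub>cyt</sub> across replicate fractions, the **nuclear retention score** is

    NRS(e) = log2( (CPM_nuc + c) / (CPM_cyt + c) ),   c = 0.5 CPM

Positive NRS means the element retains the reporter in the nucleus; negative
means it promotes export. Significance comes from a negative-binomial Wald
test across replicates (median-of-ratios size factors, moment-based
dispersions moderated toward the library-wide value, delta-method standard
errors, Benjamini–Hochberg adjustment). Elements are called
nuclear-enriched at **NRS ≥ 0.58 and p < 0.05** and cytoplasm-enriched at
**NRS ≤ −0.58 and p < 0.05** (0.58 = log2 1.5, truncated).

Downstream, the 4,096-entry 6-mer NRS table is slid along transcripts
(6-nt window, 1-nt step) to produce raw and per-nucleotide averaged
profiles; peaks are maximal averaged-NRS runs at ±0.5; a small
attention-based classifier (CLS-token pooling, implemented in numpy)
predicts nuclear vs cytoplasmic transcripts from those profiles; and
knockdown shifts are tested per gene as Δlog2FC between knockdown and
control nuclear:cytoplasmic ratios with a Student t-test (|Δ| > 0.58,
p < 0.05).

## Worked example

Simulate a small 6-mer screen (40 nuclear + 20 cytoplasmic planted elements
at effect 1.0, triplicate fractions at 10^6 reads each), extract inserts by
their constant 10-bp anchors, and score:

```sh
srle simulate --preset 6mer --seed 1 --out-dir sim \
    --depth 1000000 --n-nuclear 40 --n-cyto 20 --effect 1.0
srle extract --out counts.tsv --whitelist-6mers \
    $(for f in sim/sample_*.fastq; do n=$(basename $f .fastq); \
       echo --fastq ${n#sample_}=$f; done)
srle score counts.tsv scores.tsv
```

The extract step prints a coverage summary and the score step the call counts:

```
{"n_elements": 4096, "median_coverage": 1280.0, "fraction_above": 1.0, "threshold": 10.0}
{"nuclear": 44, "cytoplasmic": 22}
```

All 4,096 6-mers are detected (median 1,280 reads per element; every element
above the 10-read floor), and the caller reports 44 nuclear and 22
cytoplasmic elements — the 60 planted ones plus a handful of borderline
false calls at this modest depth. `scores.tsv` holds one row per element
with its CPMs, NRS, Wald statistic, raw and adjusted p-values and class:

```
element  cpm_nuclear  cpm_cytoplasmic  nrs      ...  enrichment_class
AAAAAA   249.65       267.98           -0.102   ...  neutral
```

Other stages follow the same pattern: `srle fragments` maps a scored
fragment library back to its reference and writes coverage/NRS bedGraph
tracks plus enriched-region BED; `srle peaks` calls NRS peaks on transcript
FASTA; `srle train` / `srle evaluate` fit and assess the localization
classifier; `srle shift` runs the knockdown shift test.

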