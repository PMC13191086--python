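"""Synthetic inputs with known ground truth.

Every input the pipeline consumes can be generated here: the saturating
6-mer insert library, amplicon FASTQ reads per fraction sample, a
random-fragment library tiling a reference, transcript sets with planted
localization 6-mers, and knockdown/control fraction count matrices.

The fractionation model: each element has a relative library abundance and a
true nuclear:cytoplasmic log2 enrichment ``e``.  Its expected read share is
tilted by ``2^(+e/2)`` in the nuclear fraction and ``2^(-e/2)`` in the
cytoplasmic fraction, so the expected CPM log-ratio equals ``e`` while the
marginal (whole-cell) abundance is class-independent.  Replicate counts are
negative-binomial with variance ``mu + alpha*mu^2``; ``alpha = 0`` degenerates
to Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CYTOPLASMIC, NUCLEAR, CountTable, FractionSample
from .library import ALPHABET, LibrarySpec, all_kmers, revcomp

#: Default per-element negative-binomial dispersion for replicate counts.
#: Chosen as a realistic biological-replicate overdispersion for a saturating
#: amplicon screen (extra CV ~14%); see the methods note.
DEFAULT_DISPERSION = 0.02

_CLASSES = (NUCLEAR, CYTOPLASMIC, "neutral")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one library element."""

    element: str
    base_abundance: float
    log2_enrichment: float
    class_true: str

    def __post_init__(self) -> None:
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")
        if self.class_true not in _CLASSES:
            raise ValueError(f"class_true must be one of {_CLASSES}")


def truth_to_frame(truth: list[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element": [t.element for t in truth],
            "base_abundance": [t.base_abundance for t in truth],
            "log2_enrichment": [t.log2_enrichment for t in truth],
            "class_true": [t.class_true for t in truth],
        }
    )


def truth_from_frame(df: pd.DataFrame) -> list[SimTruth]:
    return [
        SimTruth(r.element, float(r.base_abundance), float(r.log2_enrichment), r.class_true)
        for r in df.itertuples(index=False)
    ]


def write_truth_tsv(truth: list[SimTruth], path: str | Path) -> None:
    # %.17g keeps the round trip lossless for float64
    truth_to_frame(truth).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_truth_tsv(path: str | Path) -> list[SimTruth]:
    return truth_from_frame(pd.read_csv(path, sep="\t", float_precision="round_trip"))


# ---------------------------------------------------------------------------
# 6-mer library truth
# ---------------------------------------------------------------------------

def simulate_6mer_truth(
    n_nuclear: int,
    n_cyto: int,
    effect_log2: float = 1.0,
    seed: int = 0,
    abundance_sigma: float = 0.5,
) -> list[SimTruth]:
    """Plant nuclear/cytoplasmic enrichment on a random subset of all 4,096 6-mers.

    ``n_nuclear`` elements get ``+effect_log2``, ``n_cyto`` get ``-effect_log2``,
    the rest are neutral.  Base abundances are log-normal (sigma in log space).
    Deterministic under ``seed``.
    """
    kmers = all_kmers(6)
    if n_nuclear < 0 or n_cyto < 0 or n_nuclear + n_cyto > len(kmers):
        raise ValueError(f"need n_nuclear + n_cyto <= {len(kmers)}, both non-negative")
    if effect_log2 <= 0:
        raise ValueError("effect_log2 must be positive")
    rng = np.random.default_rng(seed)
    abundance = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(kmers))
    planted = rng.choice(len(kmers), size=n_nuclear + n_cyto, replace=False)
    effect = np.zeros(len(kmers))
    effect[planted[:n_nuclear]] = effect_log2
    effect[planted[n_nuclear:]] = -effect_log2
    classes = np.where(effect > 0, NUCLEAR, np.where(effect < 0, CYTOPLASMIC, "neutral"))
    return [
        SimTruth(k, float(a), float(e), str(c))
        for k, a, e, c in zip(kmers, abundance, effect, classes)
    ]


# ---------------------------------------------------------------------------
# Fraction counts and amplicon reads
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, variance mu + dispersion*mu^2); Poisson when dispersion == 0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mu)
    n = 1.0 / dispersion
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def fraction_means(truth: list[SimTruth], depth: int, fraction: str) -> np.ndarray:
    """Expected read counts per element in one fraction at the given depth."""
    ab = np.array([t.base_abundance for t in truth])
    eff = np.array([t.log2_enrichment for t in truth])
    sign = +0.5 if fraction == NUCLEAR else -0.5
    tilted = ab * np.exp2(sign * eff)
    return depth * tilted / tilted.sum()


def simulate_fraction_counts(
    truth: list[SimTruth],
    samples: list[FractionSample],
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
) -> CountTable:
    """Draw the per-sample NB count matrix implied by the truth table."""
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = np.random.default_rng(seed)
    cols = []
    for s in samples:
        if s.depth is None:
            raise ValueError(f"sample {s.name} has no depth")
        cols.append(_nb_draw(rng, fraction_means(truth, s.depth, s.fraction), dispersion))
    return CountTable(
        elements=[t.element for t in truth],
        samples=samples,
        counts=np.column_stack(cols).astype(np.int64),
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=length))


def simulate_fraction_reads(
    truth: list[SimTruth],
    spec: LibrarySpec,
    samples: list[FractionSample],
    dispersion: float = DEFAULT_DISPERSION,
    read_len: int | None = None,
    rc_fraction: float = 0.0,
    junk_fraction: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = ".",
    prefix: str = "sample",
) -> dict[str, Path]:
    """Emit one FASTQ per sample plus a truth TSV.

    Each valid read is ``flank5 + insert + flank3``, optionally padded with
    random sequence up to ``read_len`` (``None`` emits full amplicons).  A
    fraction ``rc_fraction`` of reads is reverse-complemented and a fraction
    ``junk_fraction`` is replaced by anchor-free random sequence.  Reads are
    emitted already quality-trimmed, with constant Phred quality 'I' (Q40).
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    if not 0 <= rc_fraction <= 0.5:
        raise ValueError("rc_fraction must be in [0, 0.5]")
    if not 0 <= junk_fraction < 1:
        raise ValueError("junk_fraction must be in [0, 1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = simulate_fraction_counts(truth, samples, dispersion=dispersion, seed=seed)
    rng = np.random.default_rng(np.random.default_rng(seed).integers(2**31))

    amplicon_min = len(spec.flank5) + spec.insert_len_min + len(spec.flank3)
    if read_len is not None and read_len < len(spec.flank5) + spec.insert_len_max + len(spec.flank3):
        raise ValueError("read_len shorter than the longest amplicon; use read_len=None")

    paths: dict[str, Path] = {}
    for j, sample in enumerate(samples):
        path = out_dir / f"{prefix}_{sample.name}.fastq"
        paths[sample.name] = path
        col = counts.counts[:, j]
        total = int(col.sum())
        # junk reads are added on top of the element counts; a Poisson draw at
        # rate total*f/(1-f) makes the expected junk share of emitted reads f
        n_junk = (
            rng.poisson(total * junk_fraction / (1.0 - junk_fraction))
            if junk_fraction > 0
            else 0
        )
        with open(path, "w") as fh:
            rid = 0
            chunk: list[str] = []
            for element, k in zip(counts.elements, col):
                if k == 0:
                    continue
                core = spec.flank5 + element + spec.flank3
                n_rc = rng.binomial(k, rc_fraction) if rc_fraction > 0 else 0
                for variant, m in ((core, int(k) - n_rc), (revcomp(core), n_rc)):
                    for _ in range(m):
                        seq = variant
                        if read_len is not None and len(seq) < read_len:
                            seq = seq + _random_seq(rng, read_len - len(seq))
                        qual = "I" * len(seq)
                        chunk.append(f"@r{rid}\n{seq}\n+\n{qual}\n")
                        rid += 1
                        if len(chunk) >= 100_000:
                            fh.writelines(chunk)
                            chunk = []
            junk_len = read_len if read_len is not None else amplicon_min
            for _ in range(n_junk):
                seq = _junk_read(rng, junk_len, spec)
                chunk.append(f"@j{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
                rid += 1
            fh.writelines(chunk)
    truth_path = out_dir / f"{prefix}_truth.tsv"
    write_truth_tsv(truth, truth_path)
    paths["truth"] = truth_path
    return paths


def _junk_read(rng: np.random.Generator, length: int, spec: LibrarySpec) -> str:
    """Random read guaranteed to carry neither anchor in either orientation."""
    bad = (spec.anchor5, spec.anchor3, revcomp(spec.anchor5), revcomp(spec.anchor3))
    for _ in range(100):
        seq = _random_seq(rng, length)
        if not any(b in seq for b in bad):
            return seq
    raise RuntimeError("could not generate an anchor-free junk read")  # pragma: no cover


# ---------------------------------------------------------------------------
# Random-fragment library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentTruth:
    """A simulated library fragment with its true reference coordinates."""

    element: str
    start: int
    end: int
    truth: SimTruth


def simulate_fragment_library(
    reference: str,
    n_fragments: int,
    len_min: int = 30,
    len_max: int = 100,
    nuclear_regions: list[tuple[int, int]] | None = None,
    effect_log2: float = 2.0,
    seed: int = 0,
) -> list[FragmentTruth]:
    """Sample fragments uniformly along a reference sequence.

    Fragment starts are uniform over valid positions and lengths uniform in
    ``[len_min, len_max]``.  A fragment overlapping any ``nuclear_region``
    (0-based half-open) by at least 50% of its own length is planted with
    ``+effect_log2``; all others are neutral.  Distinct fragments covering
    identical coordinates share one truth row (elements are keyed by sequence
    downstream, so duplicated sequences are collapsed by the caller).
    """
    if len_min < 20 or len_min > len_max:
        raise ValueError("need 20 <= len_min <= len_max")
    L = len(reference)
    if L < len_max:
        raise ValueError("reference shorter than len_max")
    nuclear_regions = nuclear_regions or []
    for a, b in nuclear_regions:
        if not 0 <= a < b <= L:
            raise ValueError(f"region ({a}, {b}) outside reference [0, {L})")
    rng = np.random.default_rng(seed)
    lengths = rng.integers(len_min, len_max + 1, size=n_fragments)
    starts = rng.integers(0, L - lengths + 1)
    out: list[FragmentTruth] = []
    for s, ln in zip(starts, lengths):
        s, e = int(s), int(s + ln)
        ov = sum(max(0, min(e, rb) - max(s, ra)) for ra, rb in nuclear_regions)
        enriched = ov >= 0.5 * ln
        seq = reference[s:e]
        truth = SimTruth(
            element=seq,
            base_abundance=1.0,
            log2_enrichment=effect_log2 if enriched else 0.0,
            class_true=NUCLEAR if enriched else "neutral",
        )
        out.append(FragmentTruth(seq, s, e, truth))
    return out


def fragment_truth_table(fragments: list[FragmentTruth]) -> list[SimTruth]:
    """Collapse fragments with identical sequence into one truth row each.

    Base abundance accumulates multiplicity; enrichment is taken from the
    first occurrence (identical sequences at different loci are rare on
    random references).
    """
    seen: dict[str, SimTruth] = {}
    mult: dict[str, int] = {}
    for f in fragments:
        if f.element in seen:
            mult[f.element] += 1
        else:
            seen[f.element] = f.truth
            mult[f.element] = 1
    return [
        SimTruth(t.element, t.base_abundance * mult[e], t.log2_enrichment, t.class_true)
        for e, t in seen.items()
    ]


def random_reference(length: int, seed: int = 0) -> str:
    """Uniform-random ACGT reference sequence."""
    return _random_seq(np.random.default_rng(seed), length)


# ---------------------------------------------------------------------------
# Transcripts with planted localization elements
# ---------------------------------------------------------------------------

def simulate_transcripts(
    n_per_class: int,
    len_min: int,
    len_max: int,
    planted_nuc_6mers: list[str],
    planted_cyto_6mers: list[str],
    copies_per_transcript: int = 10,
    seed: int = 0,
    out_fasta: str | Path | None = None,
    out_labels: str | Path | None = None,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Random-background transcripts carrying planted class-specific 6-mers.

    Returns ``(records, labels)`` where records are ``(transcript_id,
    sequence)`` and labels a DataFrame with columns transcript_id, label.
    Nuclear-labeled transcripts receive ``copies_per_transcript`` occurrences
    of randomly chosen nuclear 6-mers at random non-overlapping positions;
    symmetric for cytoplasmic.  Optionally writes FASTA and a label TSV.
    """
    if set(planted_nuc_6mers) & set(planted_cyto_6mers):
        raise ValueError("planted 6-mer lists must be disjoint between classes")
    if len_min < 6 or len_min > len_max:
        raise ValueError("need 6 <= len_min <= len_max")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    labels: list[str] = []
    for label, planted in ((NUCLEAR, planted_nuc_6mers), (CYTOPLASMIC, planted_cyto_6mers)):
        for i in range(n_per_class):
            L = int(rng.integers(len_min, len_max + 1))
            seq = list(_random_seq(rng, L))
            if copies_per_transcript > 0 and planted:
                taken: list[tuple[int, int]] = []
                placed = 0
                attempts = 0
                while placed < copies_per_transcript and attempts < 200 * copies_per_transcript:
                    attempts += 1
                    pos = int(rng.integers(0, L - 6 + 1))
                    if any(pos < e and pos + 6 > s for s, e in taken):
                        continue
                    kmer = planted[int(rng.integers(len(planted)))]
                    seq[pos:pos + 6] = list(kmer)
                    taken.append((pos, pos + 6))
                    placed += 1
            records.append((f"{label[:3]}_{i:04d}", "".join(seq)))
            labels.append(label)
    label_df = pd.DataFrame({"transcript_id": [r[0] for r in records], "label": labels})
    if out_fasta is not None:
        with open(out_fasta, "w") as fh:
            for tid, seq in records:
                fh.write(f">{tid}\n{seq}\n")
    if out_labels is not None:
        label_df.to_csv(out_labels, sep="\t", index=False)
    return records, label_df


# ---------------------------------------------------------------------------
# Knockdown / control fraction counts
# ---------------------------------------------------------------------------

def simulate_kd_counts(
    n_genes: int,
    n_shift_nuc: int,
    n_shift_cyto: int,
    delta_log2: float = 2.0,
    replicates: int = 3,
    dispersion: float = 0.05,
    depth: int = 2_000_000,
    seed: int = 0,
    ratio_sigma: float = 0.7,
) -> tuple[CountTable, CountTable, pd.DataFrame]:
    """Control and knockdown fraction count tables with planted localization shifts.

    Each gene's control nuclear:cytoplasmic log2 ratio is drawn from a
    centered normal (sd ``ratio_sigma``); in the knockdown the ratio is
    shifted by ``+delta_log2`` for shift-to-nuclear genes and ``-delta_log2``
    for shift-to-cytoplasm genes.  Counts are negative-binomial.
    Returns ``(control, knockdown, truth)``.
    """
    if n_shift_nuc + n_shift_cyto > n_genes:
        raise ValueError("shifted gene counts exceed n_genes")
    if replicates < 2:
        raise ValueError("need >= 2 replicates for the t-test")
    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    base = rng.lognormal(0.0, 1.0, size=n_genes)
    ctrl_ratio = rng.normal(0.0, ratio_sigma, size=n_genes)
    shift = np.zeros(n_genes)
    planted = rng.choice(n_genes, size=n_shift_nuc + n_shift_cyto, replace=False)
    shift[planted[:n_shift_nuc]] = delta_log2
    shift[planted[n_shift_nuc:]] = -delta_log2
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "delta_true": shift,
            "shift_class_true": np.where(
                shift > 0, "to_nuclear", np.where(shift < 0, "to_cytoplasm", "none")
            ),
        }
    )

    def _table(condition: str, ratio: np.ndarray, sub_seed: int) -> CountTable:
        sub = np.random.default_rng(sub_seed)
        samples, cols = [], []
        for fraction, sign in ((NUCLEAR, +0.5), (CYTOPLASMIC, -0.5)):
            tilt = base * np.exp2(sign * ratio)
            mean = depth * tilt / tilt.sum()
            for rep in range(1, replicates + 1):
                samples.append(
                    FractionSample(fraction, rep, depth=depth, condition=condition)
                )
                cols.append(_nb_draw(sub, mean, dispersion))
        return CountTable(genes, samples, np.column_stack(cols).astype(np.int64))

    seeds = np.random.default_rng(seed).integers(2**31, size=2)
    ctrl = _table("ctrl", ctrl_ratio, int(seeds[0]))
    kd = _table("kd", ctrl_ratio + shift, int(seeds[1]))
    return ctrl, kd, truth
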