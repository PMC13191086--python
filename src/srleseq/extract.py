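"""Valid-read identification and insert extraction.

A read is valid if it contains the library's constant 10-bp anchors; the
insert is the substring strictly between the first occurrence of the 5'
anchor and the first subsequent occurrence of the 3' anchor.  Forward
orientation is tried first, then the reverse complement of the read, once.
Matching is exact by default (a mismatch-tolerance flag exists).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .counts import CountTable, FractionSample
from .library import ANCHOR_LEN, LibrarySpec, revcomp


def _find_approx(hay: str, needle: str, start: int, max_mismatches: int) -> int:
    """First index >= start where needle matches hay with <= max_mismatches."""
    n, m = len(hay), len(needle)
    for i in range(start, n - m + 1):
        mis = 0
        for a, b in zip(hay[i:i + m], needle):
            if a != b:
                mis += 1
                if mis > max_mismatches:
                    break
        else:
            return i
    return -1


def extract_insert(read: str, spec: LibrarySpec, max_mismatches: int = 0) -> str | None:
    """Extract the insert from a read, or ``None`` if the read is invalid.

    Pure function of ``(read, spec)``; inserts containing N or with length
    outside the library's bounds are invalid.
    """
    a5, a3 = spec.anchor5, spec.anchor3
    for seq in (read, revcomp(read)):
        if max_mismatches == 0:
            i = seq.find(a5)
            if i < 0:
                continue
            j = seq.find(a3, i + ANCHOR_LEN)
        else:
            i = _find_approx(seq, a5, 0, max_mismatches)
            if i < 0:
                continue
            j = _find_approx(seq, a3, i + ANCHOR_LEN, max_mismatches)
        if j < 0:
            continue
        insert = seq[i + ANCHOR_LEN:j]
        if spec.insert_len_min <= len(insert) <= spec.insert_len_max and "N" not in insert:
            return insert
    return None


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _iter_fastq(path: Path) -> Iterable[tuple[str, str]]:
    n = 0
    with _open_maybe_gzip(path) as fh:
        try:
            for title, seq, _qual in FastqGeneralIterator(fh):
                n += 1
                yield title, seq
        except ValueError as exc:
            raise ValueError(
                f"malformed FASTQ record in {path} at record index {n}: {exc}"
            ) from exc


def count_reads(
    fastq_by_sample: dict[FractionSample, list[str | Path]] | dict[FractionSample, str | Path],
    spec: LibrarySpec,
    restrict_to: Iterable[str] | None = None,
    max_mismatches: int = 0,
) -> CountTable:
    """Build the raw element-by-sample count table from per-sample FASTQ files.

    With ``restrict_to`` set, only whitelisted elements become rows; valid
    reads whose insert is not whitelisted are dropped and tallied (reported
    via the returned table's ``dropped_reads`` attribute).  Row order is
    lexicographic, so the result is independent of read order.
    """
    if not fastq_by_sample:
        raise ValueError("need at least one sample")
    samples = list(fastq_by_sample)
    whitelist = None if restrict_to is None else set(restrict_to)
    tallies: list[dict[str, int]] = []
    invalid = np.zeros(len(samples), dtype=np.int64)
    dropped = np.zeros(len(samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        paths = fastq_by_sample[sample]
        if isinstance(paths, (str, Path)):
            paths = [paths]
        tally: dict[str, int] = {}
        for path in paths:
            for _title, seq in _iter_fastq(Path(path)):
                insert = extract_insert(seq, spec, max_mismatches=max_mismatches)
                if insert is None:
                    invalid[j] += 1
                elif whitelist is not None and insert not in whitelist:
                    dropped[j] += 1
                else:
                    tally[insert] = tally.get(insert, 0) + 1
        tallies.append(tally)
    if whitelist is not None:
        elements = sorted(whitelist)
    else:
        elements = sorted(set().union(*[t.keys() for t in tallies])) if tallies else []
    counts = np.zeros((len(elements), len(samples)), dtype=np.int64)
    for j, tally in enumerate(tallies):
        for i, e in enumerate(elements):
            counts[i, j] = tally.get(e, 0)
    table = CountTable(elements=elements, samples=samples, counts=counts, invalid_reads=invalid)
    table.dropped_reads = dropped  # whitelist misses, kept separate from invalids
    return table


def coverage_summary(table: CountTable, threshold: int = 10) -> dict[str, float]:
    """Per-element total-count summary: median fold-coverage and detection fraction.

    ``fraction_above`` counts elements whose summed count across samples is
    strictly greater than ``threshold``.
    """
    if len(table.elements) == 0:
        raise ValueError("empty count table")
    totals = table.counts.sum(axis=1)
    return {
        "n_elements": int(len(totals)),
        "median_coverage": float(np.median(totals)),
        "fraction_above": float(np.mean(totals > threshold)),
        "threshold": float(threshold),
    }
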