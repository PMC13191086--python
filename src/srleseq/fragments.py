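"""The random-fragment screen arm: map extracted fragments back to a
reference, build coverage and per-base NRS tracks, retrieve enriched regions,
and summarize fragment lengths.

Synthetic references are error-free, so mapping is exact substring search on
the forward strand and then on the reverse complement; mismatch-tolerant
alignment is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CYTOPLASMIC, NUCLEAR
from .intervals import threshold_runs
from .library import revcomp


@dataclass(frozen=True)
class MappedFragment:
    element: str
    ref_id: str
    start: int
    end: int
    strand: str
    multimapped: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("need 0 <= start < end")
        if self.end - self.start != len(self.element):
            raise ValueError("interval length must equal element length")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")


def _count_occurrences(hay: str, needle: str, limit: int = 2) -> int:
    n, i = 0, hay.find(needle)
    while i >= 0 and n < limit:
        n += 1
        i = hay.find(needle, i + 1)
    return n


def map_fragments(
    elements: list[str], ref_id: str, reference: str
) -> tuple[list[MappedFragment], int]:
    """Exact/reverse-complement substring mapping of fragments to a reference.

    Forward strand is searched first; a unique hit maps the fragment, multiple
    hits keep the first occurrence with ``multimapped=True``; fragments absent
    from both strands are excluded and tallied.  Returns (mapped, n_unmapped).
    """
    if not reference:
        raise ValueError("empty reference")
    mapped: list[MappedFragment] = []
    unmapped = 0
    for el in elements:
        hit = None
        for strand, query in (("+", el), ("-", revcomp(el))):
            i = reference.find(query)
            if i >= 0:
                multi = _count_occurrences(reference, query) > 1
                hit = MappedFragment(el, ref_id, i, i + len(el), strand, multi)
                break
        if hit is None:
            unmapped += 1
        else:
            mapped.append(hit)
    return mapped, unmapped


def coverage_track(mapped: list[MappedFragment], ref_len: int) -> np.ndarray:
    """Per-position count of overlapping mapped fragments (integer vector)."""
    track = np.zeros(ref_len, dtype=np.int64)
    for f in mapped:
        track[f.start:f.end] += 1
    return track


def covered_fraction(track: np.ndarray, depth_threshold: float = 10) -> float:
    """Fraction of positions covered strictly deeper than the threshold."""
    track = np.asarray(track)
    return float(np.mean(track > depth_threshold))


def nrs_track(
    mapped: list[MappedFragment],
    nrs_by_element: dict[str, float],
    ref_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-position mean NRS of covering fragments.

    Returns ``(values, covered_mask)``; uncovered positions carry 0 and
    ``covered_mask`` False.  Fragments missing from ``nrs_by_element`` are
    skipped.
    """
    total = np.zeros(ref_len)
    n = np.zeros(ref_len, dtype=np.int64)
    for f in mapped:
        score = nrs_by_element.get(f.element)
        if score is None:
            continue
        total[f.start:f.end] += score
        n[f.start:f.end] += 1
    mask = n > 0
    values = np.zeros(ref_len)
    values[mask] = total[mask] / n[mask]
    return values, mask


@dataclass(frozen=True)
class Region:
    ref_id: str
    start: int
    end: int
    mean_nrs: float
    klass: str


def enriched_regions(
    nrs_values: np.ndarray,
    coverage: np.ndarray,
    ref_id: str = "ref",
    nrs_cut: float = 0.58,
    min_cov: int = 10,
    min_len: int = 20,
    max_gap: int = 10,
) -> list[Region]:
    """Maximal well-covered runs above +nrs_cut (nuclear) or below -nrs_cut
    (cytoplasmic), with gap merging and a minimum length."""
    nrs_values = np.asarray(nrs_values, dtype=float)
    coverage = np.asarray(coverage)
    out: list[Region] = []
    covered = coverage >= min_cov
    for klass, passing, forbid in (
        (NUCLEAR, (nrs_values >= nrs_cut) & covered, (nrs_values <= -nrs_cut) & covered),
        (CYTOPLASMIC, (nrs_values <= -nrs_cut) & covered, (nrs_values >= nrs_cut) & covered),
    ):
        for s, e in threshold_runs(passing, min_len=min_len, max_gap=max_gap, forbid=forbid):
            out.append(Region(ref_id, s, e, float(nrs_values[s:e].mean()), klass))
    return sorted(out, key=lambda r: (r.start, r.end))


def length_distribution(elements: list[str]) -> dict:
    """Summary of fragment lengths: min/max/median plus a unit-bin histogram."""
    lengths = np.array([len(e) for e in elements])
    if lengths.size == 0:
        raise ValueError("no elements")
    lo, hi = int(lengths.min()), int(lengths.max())
    edges = np.arange(lo, hi + 2)
    hist, _ = np.histogram(lengths, bins=edges)
    return {
        "min": lo,
        "max": hi,
        "median": float(np.median(lengths)),
        "bin_left_edges": edges[:-1],
        "counts": hist,
    }


# ---------------------------------------------------------------------------
# Track / interval serialization
# ---------------------------------------------------------------------------

def write_bedgraph(path: str | Path, ref_id: str, values: np.ndarray) -> None:
    """bedGraph with maximal constant-value runs; zero runs are kept so the
    file round-trips to an identical vector."""
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        if values.size == 0:
            return
        change = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [values.size]))
        for s, e in zip(starts, ends):
            fh.write(f"{ref_id}\t{s}\t{e}\t{values[s]:.10g}\n")


def read_bedgraph(path: str | Path, ref_len: int) -> np.ndarray:
    values = np.zeros(ref_len)
    with open(path) as fh:
        for line in fh:
            _ref, s, e, v = line.rstrip("\n").split("\t")
            values[int(s):int(e)] = float(v)
    return values


def write_regions_bed(path: str | Path, regions: list[Region], nrs_scale: float = 2.0) -> None:
    """BED6: name carries the class, score is |mean NRS| mapped to [0, 1000]
    saturating at ``nrs_scale``."""
    with open(path, "w") as fh:
        for r in regions:
            score = int(round(min(abs(r.mean_nrs) / nrs_scale, 1.0) * 1000))
            fh.write(f"{r.ref_id}\t{r.start}\t{r.end}\t{r.klass}\t{score}\t.\n")
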