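"""Per-transcript NRS profiles, randomized controls, peak calling, metagene.

The 4,096-entry 6-mer NRS table is assigned along a transcript with a 6-nt
sliding window at 1-nt steps ("raw", window-start indexed, length L-5).  The
per-nucleotide "averaged" profile (length L) is the mean of all windows
covering each position: interior positions average 6 windows, positions
within 5 nt of either end average only the windows that exist.  Peaks are
maximal averaged-NRS runs at +/-0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CYTOPLASMIC, NUCLEAR
from .intervals import threshold_runs

K = 6


@dataclass
class TranscriptNRSProfile:
    transcript_id: str
    sequence: str
    raw: np.ndarray        # length L - 5, score of window starting at i
    averaged: np.ndarray   # length L, mean over covering windows
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]  # windows free of non-ACGT

    def __post_init__(self) -> None:
        L = len(self.sequence)
        if len(self.raw) != L - K + 1 or len(self.averaged) != L:
            raise ValueError("profile vector lengths inconsistent with sequence")
        if self.valid is None:
            self.valid = np.ones(L - K + 1, dtype=bool)


def load_nrs_table(path) -> dict[str, float]:
    """Read an (element, nrs) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return dict(zip(df["element"], df["nrs"].astype(float)))


def assign_nrs(
    transcript_id: str, sequence: str, nrs_table: dict[str, float]
) -> TranscriptNRSProfile:
    """Slide the 6-mer NRS table along a transcript.

    Windows containing non-ACGT characters score 0 (neutral) and are flagged
    in the profile's ``valid`` mask.  Raises on sequences shorter than 6 nt
    or on a table missing an encountered ACGT 6-mer.
    """
    L = len(sequence)
    if L < K:
        raise ValueError(f"sequence shorter than {K} nt")
    sequence = sequence.upper()
    n_win = L - K + 1
    raw = np.zeros(n_win)
    valid = np.ones(n_win, dtype=bool)
    for i in range(n_win):
        kmer = sequence[i:i + K]
        score = nrs_table.get(kmer)
        if score is None:
            if set(kmer) <= {"A", "C", "G", "T"}:
                raise KeyError(f"NRS table missing 6-mer {kmer!r}")
            valid[i] = False
        else:
            raw[i] = score
    # averaged[p] = mean of raw[j] over windows j covering p (j <= p <= j+5)
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    pos = np.arange(L)
    lo = np.maximum(pos - K + 1, 0)
    hi = np.minimum(pos, n_win - 1)
    averaged = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return TranscriptNRSProfile(transcript_id, sequence, raw, averaged, valid)


def randomize_nrs(nrs_table: dict[str, float], seed: int = 0) -> dict[str, float]:
    """Permute NRS values among 6-mers; the value multiset is preserved."""
    keys = sorted(nrs_table)
    values = np.array([nrs_table[k] for k in keys])
    perm = np.random.default_rng(seed).permutation(len(keys))
    return {k: float(values[p]) for k, p in zip(keys, perm)}


@dataclass(frozen=True)
class Peak:
    transcript_id: str
    start: int
    end: int
    mean_nrs: float
    klass: str


def call_peaks(
    profile: TranscriptNRSProfile,
    nrs_cut: float = 0.5,
    min_len: int = K,
    max_gap: int = 3,
    on: str = "averaged",
) -> list[Peak]:
    """Maximal runs of averaged NRS >= nrs_cut (nuclear) / <= -nrs_cut
    (cytoplasmic); same-class runs separated by <= max_gap are merged, and
    merged runs shorter than min_len are dropped.  ``on='raw'`` calls on the
    window-start vector instead."""
    values = profile.averaged if on == "averaged" else profile.raw
    peaks: list[Peak] = []
    for klass, passing, forbid in (
        (NUCLEAR, values >= nrs_cut, values <= -nrs_cut),
        (CYTOPLASMIC, values <= -nrs_cut, values >= nrs_cut),
    ):
        for s, e in threshold_runs(passing, min_len=min_len, max_gap=max_gap, forbid=forbid):
            peaks.append(Peak(profile.transcript_id, s, e, float(values[s:e].mean()), klass))
    return sorted(peaks, key=lambda p: (p.start, p.end))


def metagene(
    profiles: dict[str, TranscriptNRSProfile],
    peaks: list[Peak],
    half_window: int = 50,
) -> pd.DataFrame:
    """Mean averaged-NRS around peak midpoints, one curve per peak class.

    Offsets run -half_window..+half_window from each peak's midpoint;
    positions falling outside the transcript are skipped.  Returns a
    DataFrame indexed by offset with one column per class present.
    """
    if not peaks:
        raise ValueError("no peaks")
    offsets = np.arange(-half_window, half_window + 1)
    curves: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for pk in peaks:
        prof = profiles[pk.transcript_id]
        center = (pk.start + pk.end) // 2
        pos = center + offsets
        ok = (pos >= 0) & (pos < len(prof.averaged))
        acc = curves.setdefault(pk.klass, np.zeros(offsets.size))
        cnt = counts.setdefault(pk.klass, np.zeros(offsets.size))
        acc[ok] += prof.averaged[pos[ok]]
        cnt[ok] += 1
    data = {}
    for klass, acc in curves.items():
        with np.errstate(invalid="ignore"):
            data[klass] = np.where(counts[klass] > 0, acc / counts[klass], np.nan)
    return pd.DataFrame(data, index=pd.Index(offsets, name="offset"))


def peak_origin_summary(peaks: list[Peak], biotype_map: dict[str, str]) -> pd.DataFrame:
    """Counts of peaks per (class, biotype), e.g. protein-coding vs noncoding."""
    rows = [
        {"klass": p.klass, "biotype": biotype_map.get(p.transcript_id, "unknown")}
        for p in peaks
    ]
    if not rows:
        return pd.DataFrame(columns=["klass", "biotype", "n"])
    df = pd.DataFrame(rows).value_counts().reset_index(name="n")
    return df.sort_values(["klass", "biotype"]).reset_index(drop=True)


def write_peak_fasta(path, peaks: list[Peak], sequences: dict[str, str]) -> None:
    """Peak subsequences as FASTA, ready for external motif discovery."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            seq = sequences[p.transcript_id][p.start:p.end]
            fh.write(f">{p.transcript_id}:{p.start}-{p.end}|{p.klass}|peak{i}\n{seq}\n")


def write_peaks_bed(path, peaks: list[Peak], nrs_scale: float = 2.0) -> None:
    """BED6 with the class in the name field, transcript coordinates."""
    with open(path, "w") as fh:
        for p in peaks:
            score = int(round(min(abs(p.mean_nrs) / nrs_scale, 1.0) * 1000))
            fh.write(f"{p.transcript_id}\t{p.start}\t{p.end}\t{p.klass}\t{score}\t.\n")
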