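"""Sliding-window NRS assignment, randomized controls, peaks and metagene."""

import numpy as np
import pandas as pd
import pytest

from srleseq import all_kmers, assign_nrs, call_peaks, metagene, randomize_nrs
from srleseq.profiles import TranscriptNRSProfile, load_nrs_table, peak_origin_summary


@pytest.fixture(scope="module")
def zero_table():
    return {k: 0.0 for k in all_kmers(6)}


@pytest.fixture(scope="module")
def random_table():
    rng = np.random.default_rng(7)
    return {k: float(v) for k, v in zip(all_kmers(6), rng.normal(0, 0.5, 4096))}


def brute_force_averaged(raw: np.ndarray, L: int) -> np.ndarray:
    """Independent oracle: per position, average raw scores of all covering windows."""
    out = np.zeros(L)
    for p in range(L):
        scores = [raw[j] for j in range(len(raw)) if j <= p <= j + 5]
        out[p] = np.mean(scores)
    return out


class TestAssignNrs:
    def test_raw_length_is_L_minus_5(self, zero_table):
        prof = assign_nrs("t", "ACGTACGTAC", zero_table)
        assert len(prof.raw) == 5 and len(prof.averaged) == 10

    def test_zero_table_gives_zero_vectors(self, zero_table):
        prof = assign_nrs("t", "ACGT" * 10, zero_table)
        assert not prof.raw.any() and not prof.averaged.any()

    def test_raw_window_scores_match_table(self, random_table):
        seq = "ACGTACGTACGTAC"
        prof = assign_nrs("t", seq, random_table)
        for i in range(len(seq) - 5):
            assert prof.raw[i] == random_table[seq[i:i + 6]]

    def test_averaged_equals_brute_force(self, random_table, rng):
        """Moving-average oracle over random sequences up to 30 nt."""
        for _ in range(200):
            L = int(rng.integers(6, 31))
            seq = "".join(rng.choice(list("ACGT"), L))
            prof = assign_nrs("t", seq, random_table)
            np.testing.assert_allclose(prof.averaged, brute_force_averaged(prof.raw, L),
                                       atol=1e-12)

    def test_interior_positions_average_six_windows(self, random_table):
        seq = "ACGTACGTACGTACGTACGT"
        prof = assign_nrs("t", seq, random_table)
        for p in range(5, len(seq) - 5):
            assert prof.averaged[p] == pytest.approx(np.mean(prof.raw[p - 5:p + 1]))

    def test_non_acgt_window_scores_zero_and_flagged(self, random_table):
        seq = "ACGTACNACGTACGT"
        prof = assign_nrs("t", seq, random_table)
        for i in range(len(seq) - 5):
            if "N" in seq[i:i + 6]:
                assert prof.raw[i] == 0.0 and not prof.valid[i]
            else:
                assert prof.valid[i]

    def test_short_sequence_rejected(self, zero_table):
        with pytest.raises(ValueError):
            assign_nrs("t", "ACGTA", zero_table)

    def test_missing_kmer_rejected(self):
        with pytest.raises(KeyError):
            assign_nrs("t", "ACGTACGTAC", {"AAAAAA": 1.0})


class TestRandomize:
    def test_multiset_preserved(self, random_table):
        permuted = randomize_nrs(random_table, seed=1)
        assert sorted(permuted.values()) == sorted(random_table.values())
        assert set(permuted) == set(random_table)

    def test_deterministic_under_seed(self, random_table):
        assert randomize_nrs(random_table, seed=5) == randomize_nrs(random_table, seed=5)

    def test_decorrelates_values(self, random_table):
        keys = sorted(random_table)
        orig = np.array([random_table[k] for k in keys])
        rs = [
            np.corrcoef(orig, [randomize_nrs(random_table, seed=s)[k] for k in keys])[0, 1]
            for s in range(5)
        ]
        assert max(abs(r) for r in rs) < 0.06


def _profile_from_vector(values: np.ndarray) -> TranscriptNRSProfile:
    """Build a profile whose averaged vector is exactly `values`."""
    L = len(values)
    raw = np.zeros(max(L - 5, 1))
    return TranscriptNRSProfile("t", "A" * L, raw, np.asarray(values, dtype=float))


def brute_force_peaks(values, cut, min_len, max_gap):
    """Exhaustive run enumeration for a given class sign."""
    out = []
    for sign in (+1, -1):
        passing = values >= cut if sign > 0 else values <= -cut
        forbid = values <= -cut if sign > 0 else values >= cut
        runs = []
        i = 0
        n = len(values)
        while i < n:
            if passing[i]:
                j = i
                while j < n and passing[j]:
                    j += 1
                if runs and i - runs[-1][1] <= max_gap and not any(
                    forbid[runs[-1][1]:i]
                ):
                    runs[-1][1] = j
                else:
                    runs.append([i, j])
                i = j
            else:
                i += 1
        out.extend(
            ("nuclear" if sign > 0 else "cytoplasmic", s, e)
            for s, e in runs if e - s >= min_len
        )
    return sorted(out, key=lambda t: (t[1], t[2]))


class TestCallPeaks:
    def test_constant_above_cut_single_peak(self):
        prof = _profile_from_vector(np.full(30, 0.6))
        peaks = call_peaks(prof, nrs_cut=0.5, min_len=6, max_gap=3)
        assert len(peaks) == 1
        assert (peaks[0].start, peaks[0].end, peaks[0].klass) == (0, 30, "nuclear")

    def test_threshold_inclusive_at_cut(self):
        assert call_peaks(_profile_from_vector(np.full(30, 0.49)), nrs_cut=0.5) == []
        peaks = call_peaks(_profile_from_vector(np.full(30, 0.5)), nrs_cut=0.5)
        assert len(peaks) == 1

    def test_dip_merging(self):
        v = np.full(30, 0.8)
        v[12:14] = 0.1
        peaks = call_peaks(_profile_from_vector(v), nrs_cut=0.5, min_len=6, max_gap=3)
        assert [(p.start, p.end) for p in peaks] == [(0, 30)]

    def test_matches_exhaustive_enumeration(self, rng):
        """Oracle equivalence on random vectors of length <= 30."""
        for _ in range(300):
            n = int(rng.integers(6, 31))
            v = rng.normal(0, 0.7, n)
            min_len = int(rng.integers(1, 7))
            max_gap = int(rng.integers(0, 5))
            prof = _profile_from_vector(v)
            got = [(p.klass, p.start, p.end)
                   for p in call_peaks(prof, 0.5, min_len, max_gap)]
            assert got == brute_force_peaks(v, 0.5, min_len, max_gap)

    def test_flanking_subthreshold_sequence_shifts_coordinates_only(self):
        core = np.array([0.8] * 10)
        pad = np.zeros(7)
        p1 = call_peaks(_profile_from_vector(core), 0.5, 6, 0)
        p2 = call_peaks(_profile_from_vector(np.concatenate([pad, core, pad])), 0.5, 6, 0)
        assert len(p1) == len(p2) == 1
        assert (p2[0].start, p2[0].end) == (p1[0].start + 7, p1[0].end + 7)

    def test_mean_nrs_sign_matches_class(self, rng):
        v = rng.normal(0, 1.0, 50)
        for p in call_peaks(_profile_from_vector(v), 0.5, 1, 0):
            assert (p.mean_nrs > 0) == (p.klass == "nuclear")


class TestMetagene:
    def test_constant_profile_flat_curve(self):
        prof = _profile_from_vector(np.full(101, 0.7))
        peaks = call_peaks(prof, 0.5, 6, 0)
        curve = metagene({"t": prof}, peaks, half_window=20)
        np.testing.assert_allclose(curve["nuclear"], 0.7)

    def test_symmetric_profile_symmetric_curve(self):
        x = np.arange(101)
        v = 1.0 * np.exp(-((x - 50) ** 2) / 200.0)
        prof = _profile_from_vector(v)
        peaks = call_peaks(prof, 0.5, 6, 0)
        curve = metagene({"t": prof}, peaks, half_window=15)["nuclear"].to_numpy()
        np.testing.assert_allclose(curve, curve[::-1], atol=1e-9)

    def test_out_of_transcript_offsets_skipped(self):
        prof = _profile_from_vector(np.full(20, 0.9))
        peaks = call_peaks(prof, 0.5, 6, 0)
        curve = metagene({"t": prof}, peaks, half_window=30)
        assert curve["nuclear"].isna().sum() > 0

    def test_empty_peaks_rejected(self):
        with pytest.raises(ValueError):
            metagene({}, [], 10)

    def test_planted_element_metagene_center_exceeds_flanks(self, rng):
        """Transcripts carrying a tandem repeat of a nuclear 6-mer produce a
        nuclear metagene whose center clearly exceeds its flanks."""
        kmer = "GACGGG"
        table = {k: 0.0 for k in __import__("srleseq").all_kmers(6)}
        # a tandem repeat exposes every cyclic rotation as a window
        double = kmer * 2
        for off in range(6):
            table[double[off:off + 6]] = 1.0
        profiles, peaks = {}, []
        for i in range(20):
            bg = "".join(rng.choice(list("ACGT"), 200))
            pos = int(rng.integers(40, 140))
            seq = bg[:pos] + kmer * 3 + bg[pos + 18:]
            prof = assign_nrs(f"t{i}", seq, table)
            profiles[f"t{i}"] = prof
            peaks.extend(call_peaks(prof, nrs_cut=0.5, min_len=6, max_gap=3))
        assert peaks, "tandem planting must produce peaks"
        curve = metagene(profiles, peaks, half_window=30)["nuclear"]
        center = curve.loc[0]
        flanks = curve.loc[[-30, -29, -28, 28, 29, 30]].mean()
        assert center - flanks >= 0.2


class TestPeakOrigin:
    def test_counts_match_brute_force(self, rng):
        from srleseq.profiles import Peak
        biotypes = {f"t{i}": ("coding" if i % 3 else "noncoding") for i in range(30)}
        peaks = [
            Peak(f"t{int(rng.integers(0, 30))}", 0, 10, 0.8,
                 "nuclear" if rng.random() < 0.5 else "cytoplasmic")
            for _ in range(100)
        ]
        df = peak_origin_summary(peaks, biotypes)
        for _, row in df.iterrows():
            expected = sum(
                1 for p in peaks
                if p.klass == row["klass"] and biotypes[p.transcript_id] == row["biotype"]
            )
            assert row["n"] == expected

    def test_empty_peaks_zero_table(self):
        df = peak_origin_summary([], {})
        assert df.empty


class TestNrsTableIo:
    def test_load_round_trip(self, tmp_path, random_table):
        df = pd.DataFrame({"element": list(random_table), "nrs": list(random_table.values())})
        p = tmp_path / "nrs.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.17g")
        assert load_nrs_table(p) == random_table
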