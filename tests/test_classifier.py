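"""Labeling rules, encoding, the attention model's gradients, and metrics."""

import numpy as np
import pandas as pd
import pytest

from srleseq import all_kmers
from srleseq.classifier import (
    EncoderConfig,
    LocalizationLabelRule,
    TrainConfig,
    build_dataset,
    encode,
    evaluate,
    label_transcripts,
    load_model,
    pr_curve_points,
    roc_curve_points,
    save_model,
    stratified_split,
    train,
)
from srleseq.nn import TinyTransformer
from srleseq.profiles import assign_nrs
from srleseq.simulate import simulate_transcripts


class TestLabelTranscripts:
    def _matrices(self, lfc_rows, n_contexts=12):
        """Build FPKM matrices whose log2 ratios equal the given rows exactly
        (cytoplasmic side fixed at 10, nuclear = 10 * 2^lfc, pseudocount 0)."""
        genes = [f"g{i}" for i in range(len(lfc_rows))]
        cols = [f"c{j}" for j in range(n_contexts)]
        cyt = pd.DataFrame(10.0, index=genes, columns=cols)
        nuc = cyt * np.exp2(np.asarray(lfc_rows))
        return nuc, cyt

    def test_inclusive_boundary_in_all_contexts(self):
        nuc, cyt = self._matrices([[1.0] * 12])
        rule = LocalizationLabelRule(pseudocount=0.0)
        assert label_transcripts(nuc, cyt, rule).iloc[0] == "nuclear"

    def test_one_discordant_context_excludes(self):
        nuc, cyt = self._matrices([[2.0] * 11 + [-2.0]])
        rule = LocalizationLabelRule(pseudocount=0.0)
        assert label_transcripts(nuc, cyt, rule).iloc[0] == "excluded"

    def test_cytoplasmic_side(self):
        nuc, cyt = self._matrices([[-1.5] * 12])
        rule = LocalizationLabelRule(pseudocount=0.0)
        assert label_transcripts(nuc, cyt, rule).iloc[0] == "cytoplasmic"

    def test_all_zero_expression_excluded(self):
        genes, cols = ["g0"], [f"c{j}" for j in range(12)]
        z = pd.DataFrame(0.0, index=genes, columns=cols)
        assert label_transcripts(z, z, LocalizationLabelRule()).iloc[0] == "excluded"

    def test_misaligned_matrices_rejected(self):
        nuc, cyt = self._matrices([[1.0] * 12, [0.0] * 12])
        with pytest.raises(ValueError):
            label_transcripts(nuc, cyt.iloc[::-1], LocalizationLabelRule())


@pytest.fixture(scope="module")
def table():
    rng = np.random.default_rng(3)
    return {k: float(v) for k, v in zip(all_kmers(6), rng.normal(0, 0.5, 4096))}


class TestEncoding:
    def test_feature_matrix_shape_with_cls(self, table):
        prof = assign_nrs("t", "ACGT" * 10, table)
        cfg = EncoderConfig(m=16, max_len=64, mode="nrs_raw")
        F = encode(prof, cfg, seed=0)
        assert F.shape == (len(prof.raw) + 1, 16)

    def test_padding_gives_equal_shapes_different_masks(self, table):
        recs = [("a", "ACGT" * 10), ("b", "ACGT" * 15)]
        labels = pd.DataFrame({"transcript_id": ["a", "b"],
                               "label": ["nuclear", "cytoplasmic"]})
        cfg = EncoderConfig(m=16, max_len=64, mode="nrs_raw")
        ds = build_dataset(recs, labels, table, cfg)
        assert ds["x"].shape == (2, 64)
        assert ds["mask"][0].sum() == 35 and ds["mask"][1].sum() == 55

    def test_baseline_mode_uses_integer_kmer_ids(self, table):
        recs = [("a", "AAAAAACC")]
        labels = pd.DataFrame({"transcript_id": ["a"], "label": ["nuclear"]})
        cfg = EncoderConfig(m=16, max_len=16, mode="baseline_kmer")
        ds = build_dataset(recs, labels, table, cfg)
        assert ds["x"].dtype == np.int64
        assert ds["x"][0, 0] == 0          # AAAAAA
        assert ds["x"][0, 1] == 1          # AAAAAC
        assert ds["x"][0, 2] == 4 + 1      # AAAACC

    def test_rand_mode_uses_permuted_table(self, table):
        recs = [("a", "ACGT" * 10)]
        labels = pd.DataFrame({"transcript_id": ["a"], "label": ["nuclear"]})
        nrs = build_dataset(recs, labels, table, EncoderConfig(m=16, max_len=64, mode="nrs_raw"))
        rnd1 = build_dataset(recs, labels, table,
                             EncoderConfig(m=16, max_len=64, mode="rand_raw"), rand_seed=1)
        rnd1b = build_dataset(recs, labels, table,
                              EncoderConfig(m=16, max_len=64, mode="rand_raw"), rand_seed=1)
        assert not np.allclose(nrs["x"], rnd1["x"])
        np.testing.assert_array_equal(rnd1["x"], rnd1b["x"])


class TestGradients:
    @pytest.mark.parametrize("vocab", [None, 32])
    def test_backprop_matches_finite_differences(self, vocab, rng):
        model = TinyTransformer(m=8, n_layers=2, n_heads=2, max_len=6, vocab=vocab,
                                seed=1, dtype=np.float64)
        B, n = 2, 5
        x = rng.integers(0, 32, (B, n)) if vocab else rng.normal(size=(B, n))
        mask = np.ones((B, n), bool)
        mask[0, 3:] = False
        y = np.array([0, 1])
        _loss, grads = model.loss_and_grads(x, mask, y)
        checked = 0
        for k, g in grads.items():
            P = model.params[k]
            flat_idx = rng.choice(P.size, size=min(P.size, 4), replace=False)
            for fi in flat_idx:
                idx = np.unravel_index(fi, P.shape)
                eps = 1e-6
                orig = P[idx]
                P[idx] = orig + eps
                lp, _ = model.loss_and_grads(x, mask, y)
                P[idx] = orig - eps
                lm, _ = model.loss_and_grads(x, mask, y)
                P[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) <= 1e-4 * max(1.0, abs(num)), k
                checked += 1
        assert checked > 50

    def test_padded_positions_do_not_affect_logits(self, rng):
        model = TinyTransformer(m=8, n_layers=1, n_heads=2, max_len=8, seed=0,
                                dtype=np.float64)
        x1 = rng.normal(size=(1, 8))
        mask = np.zeros((1, 8), bool)
        mask[0, :4] = True
        x2 = x1.copy()
        x2[0, 4:] = 99.0  # padded content must be irrelevant
        np.testing.assert_allclose(model.forward(x1, mask), model.forward(x2, mask))


class TestTraining:
    def test_stratified_split_preserves_class_balance(self, rng):
        y = np.array([0] * 60 + [1] * 40)
        tr, te = stratified_split(y, 0.8, seed=2)
        assert len(tr) == 80 and len(te) == 20
        assert (y[tr] == 1).sum() == 32 and (y[te] == 1).sum() == 8
        assert not set(tr) & set(te)

    def test_single_class_rejected(self):
        ds = {"x": np.zeros((10, 4)), "mask": np.ones((10, 4), bool),
              "y": np.zeros(10, dtype=int)}
        with pytest.raises(ValueError):
            train(ds, EncoderConfig(m=8, max_len=4, mode="nrs_raw"))

    def test_shuffled_labels_accuracy_near_chance(self):
        rng = np.random.default_rng(0)
        table = {k: float(v) for k, v in zip(all_kmers(6), rng.normal(0, 0.5, 4096))}
        recs, labels = simulate_transcripts(40, 60, 90, ["GGGGGG"], ["TTTTTT"],
                                            copies_per_transcript=0, seed=1)
        cfg = EncoderConfig(m=16, max_len=85, mode="nrs_raw")
        ds = build_dataset(recs, labels, table, cfg)
        model, hist = train(ds, cfg, TrainConfig(epochs=3, seed=0))
        te = hist.attrs["test_idx"]
        ev = evaluate(model, ds["x"][te], ds["mask"][te], ds["y"][te])
        assert 0.2 <= ev["accuracy"] <= 0.8  # no planted signal

    def test_training_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        table = {k: float(v) for k, v in zip(all_kmers(6), rng.normal(0, 0.5, 4096))}
        recs, labels = simulate_transcripts(10, 60, 80, ["GGGGGG"], ["TTTTTT"], 3, seed=2)
        cfg = EncoderConfig(m=16, max_len=75, mode="nrs_raw")
        ds = build_dataset(recs, labels, table, cfg)
        h1 = train(ds, cfg, TrainConfig(epochs=2, seed=5))[1]
        h2 = train(ds, cfg, TrainConfig(epochs=2, seed=5))[1]
        pd.testing.assert_frame_equal(h1, h2)


class TestMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.2, 0.8, 0.9])
        _f, _t, auroc = roc_curve_points(s, y)
        assert auroc == 1.0

    def test_auroc_equals_pairwise_concordance(self, rng):
        """Oracle: AUROC is the probability a positive outranks a negative,
        ties counting half."""
        for _ in range(20):
            n = int(rng.integers(6, 15))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse grid to exercise ties
            _f, _t, auroc = roc_curve_points(s, y)
            pos, neg = s[y == 1], s[y == 0]
            wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            assert auroc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-9)

    def test_random_scores_auroc_near_half(self, rng):
        y = rng.integers(0, 2, 2000)
        s = rng.random(2000)
        _f, _t, auroc = roc_curve_points(s, y)
        assert 0.45 <= auroc <= 0.55

    def test_pr_curve_perfect(self):
        y = np.array([0, 1, 1])
        s = np.array([0.1, 0.8, 0.9])
        _r, _p, auprc = pr_curve_points(s, y)
        assert auprc == pytest.approx(1.0)

    def test_roc_against_reference_implementation(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 300)
        s = rng.normal(size=300)
        _f, _t, auroc = roc_curve_points(s, y)
        assert auroc == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = TinyTransformer(m=8, n_layers=1, n_heads=2, max_len=10, seed=3)
        cfg = EncoderConfig(m=8, max_len=10, mode="nrs_avg")
        p = tmp_path / "model.ckpt"
        save_model(p, model, cfg)
        back, cfg2 = load_model(p)
        assert cfg2 == cfg
        x = rng.normal(size=(2, 10))
        mask = np.ones((2, 10), bool)
        np.testing.assert_allclose(model.forward(x, mask), back.forward(x, mask),
                                   rtol=1e-6)
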