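"""NRS-guided RNA localization classification.

Transcripts are labeled nuclear or cytoplasmic from fraction expression
(consistent log2 fold change across all contexts), encoded as per-position
NRS tracks (raw sliding-window or per-nucleotide averaged; optionally with a
value-permuted NRS table as a randomized control) or as plain 6-mer ids
(sequence-only baseline), and classified by a small attention model whose
CLS representation feeds the class head.  Epoch accuracy/loss curves, ROC
and PR summaries are reported.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counts import CYTOPLASMIC, NUCLEAR
from .nn import TinyTransformer, sinusoidal_pe  # noqa: F401  (sinusoidal_pe re-exported)
from .profiles import K, TranscriptNRSProfile, assign_nrs, randomize_nrs

MODES = ("nrs_raw", "nrs_avg", "rand_raw", "rand_avg", "baseline_kmer")

_KMER_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class LocalizationLabelRule:
    """Conjunctive fold-change rule across expression contexts."""

    lfc_cut: float = 1.0
    n_contexts: int = 12
    pseudocount: float = 0.1

    def __post_init__(self) -> None:
        if self.lfc_cut <= 0:
            raise ValueError("lfc_cut must be positive")


@dataclass(frozen=True)
class EncoderConfig:
    m: int = 256
    max_len: int = 512
    mode: str = "nrs_raw"

    def __post_init__(self) -> None:
        if self.m < 8:
            raise ValueError("embedding width m must be >= 8")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


@dataclass(frozen=True)
class TrainConfig:
    train_frac: float = 0.8
    epochs: int = 6
    seed: int = 0
    batch_size: int = 16
    learning_rate: float = 1e-3
    n_layers: int = 2
    n_heads: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")


def label_transcripts(
    fpkm_nuc: pd.DataFrame,
    fpkm_cyt: pd.DataFrame,
    rule: LocalizationLabelRule = LocalizationLabelRule(),
) -> pd.Series:
    """Label genes nuclear/cytoplasmic/excluded from per-context expression.

    Nuclear requires log2((nuc+eps)/(cyt+eps)) >= lfc_cut in *every* context
    (inclusive bound); cytoplasmic symmetric at <= -lfc_cut; anything else,
    including genes with conflicting contexts, is excluded.
    """
    if not fpkm_nuc.index.equals(fpkm_cyt.index) or not fpkm_nuc.columns.equals(fpkm_cyt.columns):
        raise ValueError("FPKM matrices must be aligned on genes and contexts")
    if fpkm_nuc.shape[1] != rule.n_contexts:
        raise ValueError(
            f"expected {rule.n_contexts} contexts, got {fpkm_nuc.shape[1]}"
        )
    eps = rule.pseudocount
    lfc = np.log2((fpkm_nuc + eps) / (fpkm_cyt + eps))
    nuclear = (lfc >= rule.lfc_cut).all(axis=1)
    cyto = (lfc <= -rule.lfc_cut).all(axis=1)
    out = pd.Series("excluded", index=fpkm_nuc.index, name="label")
    out[nuclear] = NUCLEAR
    out[cyto] = CYTOPLASMIC
    return out


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _kmer_ids(sequence: str) -> np.ndarray:
    ids = np.zeros(len(sequence) - K + 1, dtype=np.int64)
    for i in range(len(ids)):
        v = 0
        for ch in sequence[i:i + K]:
            v = v * 4 + _KMER_BASE.get(ch, 0)
        ids[i] = v
    return ids


def profile_track(profile: TranscriptNRSProfile, mode: str) -> np.ndarray:
    """The scalar (or id) sequence a mode feeds to the model."""
    if mode in ("nrs_raw", "rand_raw"):
        return profile.raw
    if mode in ("nrs_avg", "rand_avg"):
        return profile.averaged
    if mode == "baseline_kmer":
        return _kmer_ids(profile.sequence)
    raise ValueError(f"unknown mode {mode!r}")


def build_dataset(
    records: list[tuple[str, str]],
    labels: pd.DataFrame,
    nrs_table: dict[str, float],
    cfg: EncoderConfig,
    rand_seed: int = 0,
) -> dict:
    """Assign (possibly randomized) NRS along transcripts and pad to max_len.

    Returns dict with keys x (B, max_len), mask, y (0=cytoplasmic, 1=nuclear),
    transcript_ids.
    """
    table = nrs_table
    if cfg.mode.startswith("rand"):
        table = randomize_nrs(nrs_table, seed=rand_seed)
    label_by_id = dict(zip(labels["transcript_id"], labels["label"]))
    is_int = cfg.mode == "baseline_kmer"
    xs, masks, ys, ids = [], [], [], []
    for tid, seq in records:
        lab = label_by_id.get(tid)
        if lab not in (NUCLEAR, CYTOPLASMIC):
            continue
        profile = assign_nrs(tid, seq, table)
        track = profile_track(profile, cfg.mode)
        if len(track) > cfg.max_len:
            raise ValueError(f"transcript {tid} longer than max_len {cfg.max_len}")
        pad = cfg.max_len - len(track)
        xs.append(np.concatenate([track, np.zeros(pad, dtype=track.dtype)]))
        masks.append(np.concatenate([np.ones(len(track), bool), np.zeros(pad, bool)]))
        ys.append(1 if lab == NUCLEAR else 0)
        ids.append(tid)
    if not xs:
        raise ValueError("no labeled transcripts")
    x = np.stack(xs).astype(np.int64 if is_int else float)
    return {
        "x": x,
        "mask": np.stack(masks),
        "y": np.array(ys, dtype=np.int64),
        "transcript_ids": ids,
    }


def encode(profile: TranscriptNRSProfile, cfg: EncoderConfig, model: TinyTransformer | None = None,
           seed: int = 0) -> np.ndarray:
    """The (n+1) x m feature matrix a model sees for one transcript: CLS row,
    then the learned lift (or embedding) of the track plus positional
    encoding.  Uses the given model's parameters, or a freshly initialized
    model under ``seed``."""
    track = profile_track(profile, cfg.mode)
    if model is None:
        model = _new_model(cfg, TrainConfig(seed=seed))
    x = track[None, :]
    tok = model._embed(x.astype(np.int64 if cfg.mode == "baseline_kmer" else float))
    tok = tok + model.pe[:tok.shape[1]]
    return np.concatenate([model.params["cls"][None, :], tok[0]], axis=0)


# ---------------------------------------------------------------------------
# Training / evaluation
# ---------------------------------------------------------------------------

def _new_model(cfg: EncoderConfig, tcfg: TrainConfig) -> TinyTransformer:
    return TinyTransformer(
        m=cfg.m,
        n_layers=tcfg.n_layers,
        n_heads=tcfg.n_heads,
        max_len=cfg.max_len,
        vocab=4**K if cfg.mode == "baseline_kmer" else None,
        seed=tcfg.seed,
    )


def stratified_split(y: np.ndarray, train_frac: float, seed: int):
    """Deterministic per-class split; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        k = int(round(train_frac * idx.size))
        train.append(idx[:k])
        test.append(idx[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def train(
    dataset: dict,
    enc_cfg: EncoderConfig,
    cfg: TrainConfig = TrainConfig(),
) -> tuple[TinyTransformer, pd.DataFrame]:
    """Train the classifier with a stratified split and record epoch curves.

    Returns (model, history); history has per-epoch train/test accuracy and
    loss.  The test-set indices are stored as ``history.attrs['test_idx']``.
    """
    x, mask, y = dataset["x"], dataset["mask"], dataset["y"]
    if np.unique(y).size < 2:
        raise ValueError("need both classes present")
    tr, te = stratified_split(y, cfg.train_frac, cfg.seed)
    if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
        raise ValueError("both classes must appear in train and test splits")
    model = _new_model(enc_cfg, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = tr[rng.permutation(tr.size)]
        for i in range(0, order.size, cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            _loss, grads = model.loss_and_grads(x[b], mask[b], y[b])
            model.adam_step(grads, lr=cfg.learning_rate)
        p_tr = model.predict_proba(x[tr], mask[tr])
        p_te = model.predict_proba(x[te], mask[te])
        rows.append(
            {
                "epoch": epoch,
                "train_accuracy": float(np.mean(p_tr.argmax(1) == y[tr])),
                "test_accuracy": float(np.mean(p_te.argmax(1) == y[te])),
                "train_loss": float(-np.mean(np.log(p_tr[np.arange(tr.size), y[tr]] + 1e-12))),
                "test_loss": float(-np.mean(np.log(p_te[np.arange(te.size), y[te]] + 1e-12))),
            }
        )
    history = pd.DataFrame(rows)
    history.attrs["train_idx"] = tr
    history.attrs["test_idx"] = te
    return model, history


def roc_curve_points(scores: np.ndarray, labels: np.ndarray):
    """ROC by threshold sweep over the positive-class score; trapezoidal AUROC."""
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    labels = np.asarray(labels)[order]
    sorted_scores = scores[order]
    P = labels.sum()
    N = len(labels) - P
    if P == 0 or N == 0:
        raise ValueError("need both classes to draw a ROC curve")
    # tied scores move together: emit one point per distinct threshold
    last_of_group = np.flatnonzero(np.diff(sorted_scores) != 0)
    cut = np.concatenate([last_of_group, [len(labels) - 1]])
    tps = np.cumsum(labels)[cut]
    fps = np.cumsum(1 - labels)[cut]
    tpr = np.concatenate(([0.0], tps / P))
    fpr = np.concatenate(([0.0], fps / N))
    auroc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auroc


def pr_curve_points(scores: np.ndarray, labels: np.ndarray):
    """Precision-recall sweep; area by trapezoid over recall."""
    order = np.argsort(-scores, kind="stable")
    labels = np.asarray(labels)[order]
    P = labels.sum()
    if P == 0:
        raise ValueError("no positive labels")
    tps = np.cumsum(labels)
    precision = tps / np.arange(1, len(labels) + 1)
    recall = tps / P
    recall = np.concatenate(([0.0], recall))
    precision = np.concatenate(([1.0], precision))
    auprc = float(np.trapezoid(precision, recall))
    return recall, precision, auprc


def evaluate(model: TinyTransformer, x, mask, y) -> dict:
    """Accuracy, ROC (fpr/tpr/AUROC) and PR (recall/precision/AUPRC) on a set."""
    p = model.predict_proba(x, mask)
    scores = p[:, 1]
    fpr, tpr, auroc = roc_curve_points(scores, y)
    recall, precision, auprc = pr_curve_points(scores, y)
    return {
        "accuracy": float(np.mean(p.argmax(1) == y)),
        "scores": scores,
        "fpr": fpr,
        "tpr": tpr,
        "auroc": auroc,
        "recall": recall,
        "precision": precision,
        "auprc": auprc,
    }


def save_metrics(path: str | Path, history: pd.DataFrame, metrics: dict,
                 enc_cfg: EncoderConfig, cfg: TrainConfig) -> None:
    payload = {
        "encoder": asdict(enc_cfg),
        "training": asdict(cfg),
        "epochs": history.to_dict(orient="records"),
        "accuracy": metrics["accuracy"],
        "auroc": metrics["auroc"],
        "auprc": metrics["auprc"],
        "roc": {"fpr": metrics["fpr"].tolist(), "tpr": metrics["tpr"].tolist()},
        "pr": {"recall": metrics["recall"].tolist(),
               "precision": metrics["precision"].tolist()},
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def save_model(path: str | Path, model: TinyTransformer, enc_cfg: EncoderConfig) -> None:
    """Self-describing checkpoint: JSON header line + flattened parameters."""
    meta = {
        "format": "srleseq-tiny-transformer",
        "version": 1,
        "m": model.m,
        "n_layers": model.n_layers,
        "n_heads": model.n_heads,
        "max_len": model.max_len,
        "vocab": model.vocab,
        "encoder": asdict(enc_cfg),
        "shapes": {k: list(v.shape) for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        fh.write(json.dumps(meta) + "\n")
        for k in sorted(model.params):
            flat = " ".join(repr(float(v)) for v in model.params[k].ravel())
            fh.write(f"{k}\t{flat}\n")


def load_model(path: str | Path) -> tuple[TinyTransformer, EncoderConfig]:
    with open(path) as fh:
        meta = json.loads(fh.readline())
        model = TinyTransformer(
            m=meta["m"], n_layers=meta["n_layers"], n_heads=meta["n_heads"],
            max_len=meta["max_len"], vocab=meta["vocab"],
        )
        for line in fh:
            k, flat = line.rstrip("\n").split("\t")
            shape = tuple(meta["shapes"][k])
            model.params[k] = np.array([float(t) for t in flat.split()]).reshape(shape)
    enc = EncoderConfig(**meta["encoder"])
    return model, enc
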