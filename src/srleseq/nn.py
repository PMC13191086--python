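"""A small self-attention classifier in plain numpy.

Architecture: per-position scalar scores (or 6-mer ids) are lifted to an
m-dimensional token by a learned linear map (or embedding), summed with a
fixed sinusoidal positional encoding; a learned CLS token is prepended; the
sequence passes through a pre-norm transformer stack (multi-head
self-attention + two-layer feed-forward, residual connections); the final
CLS representation is layer-normalized and mapped to two class logits.

All gradients are derived by hand and validated against finite differences
in the test suite.  float64 throughout; training is deterministic under the
constructor seed.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-5
_NEG = -1e9


def sinusoidal_pe(n: int, m: int) -> np.ndarray:
    """Fixed sin/cos positional encoding, shape (n, m)."""
    pos = np.arange(n)[:, None]
    i = np.arange(m // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / m)
    pe = np.zeros((n, m))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def _layernorm_fwd(x, g, b):
    mu = x.mean(-1, keepdims=True)
    xc = x - mu
    var = (xc**2).mean(-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = xc * inv
    return g * xhat + b, (xhat, inv, g)


def _layernorm_bwd(dy, cache):
    xhat, inv, g = cache
    m = xhat.shape[-1]
    dg = (dy * xhat).sum(tuple(range(dy.ndim - 1)))
    db = dy.sum(tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(-1, keepdims=True))
    return dx, dg, db


def _softmax(z):
    z = z - z.max(-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(-1, keepdims=True)


class TinyTransformer:
    """Two-class sequence classifier over scalar tracks or k-mer ids."""

    def __init__(
        self,
        m: int = 32,
        n_layers: int = 2,
        n_heads: int = 4,
        ff_mult: int = 2,
        max_len: int = 512,
        vocab: int | None = None,
        seed: int = 0,
        dtype=np.float32,
    ):
        if m % n_heads:
            raise ValueError("m must be divisible by n_heads")
        self.m, self.n_layers, self.n_heads = m, n_layers, n_heads
        self.dh = m // n_heads
        self.vocab = vocab
        self.max_len = max_len
        self.dtype = np.dtype(dtype)
        self.pe = sinusoidal_pe(max_len, m).astype(self.dtype)
        rng = np.random.default_rng(seed)
        sd = 0.02
        P: dict[str, np.ndarray] = {}
        if vocab is None:
            P["lift_w"] = rng.normal(0, 1.0, size=m)   # scalar -> m
            P["lift_b"] = np.zeros(m)
        else:
            P["emb"] = rng.normal(0, sd, size=(vocab, m))
        P["cls"] = rng.normal(0, sd, size=m)
        h = ff_mult * m
        for l in range(n_layers):
            for nm in ("q", "k", "v", "o"):
                P[f"W{nm}{l}"] = rng.normal(0, sd, size=(m, m))
                P[f"b{nm}{l}"] = np.zeros(m)
            P[f"ln1g{l}"], P[f"ln1b{l}"] = np.ones(m), np.zeros(m)
            P[f"ln2g{l}"], P[f"ln2b{l}"] = np.ones(m), np.zeros(m)
            P[f"W1{l}"] = rng.normal(0, sd, size=(m, h))
            P[f"b1{l}"] = np.zeros(h)
            P[f"W2{l}"] = rng.normal(0, sd, size=(h, m))
            P[f"b2{l}"] = np.zeros(m)
        P["lnfg"], P["lnfb"] = np.ones(m), np.zeros(m)
        P["Whead"] = rng.normal(0, sd, size=(m, 2))
        P["bhead"] = np.zeros(2)
        self.params = {k: v.astype(self.dtype) for k, v in P.items()}
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward -------------------------------------------------------

    def _embed(self, x: np.ndarray) -> np.ndarray:
        P = self.params
        if self.vocab is None:
            return x.astype(self.dtype)[..., None] * P["lift_w"] + P["lift_b"]
        return P["emb"][x]

    def forward(self, x: np.ndarray, mask: np.ndarray, cache: bool = False):
        """Logits (B, 2) from inputs (B, n) with validity mask (B, n)."""
        P, H, dh = self.params, self.n_heads, self.dh
        B, n = x.shape
        if n > self.max_len:
            raise ValueError(f"sequence length {n} exceeds max_len {self.max_len}")
        tok = self._embed(x) + self.pe[:n]
        tok = tok * mask[..., None]          # padded positions carry no signal
        h0 = np.concatenate([np.broadcast_to(P["cls"], (B, 1, self.m)), tok], axis=1)
        full_mask = np.concatenate([np.ones((B, 1), bool), mask.astype(bool)], axis=1)
        zero, neg = self.dtype.type(0.0), self.dtype.type(_NEG)
        bias = np.where(full_mask[:, None, None, :], zero, neg)  # (B,1,1,n+1)

        caches = []
        hcur = h0
        for l in range(self.n_layers):
            ln1, c_ln1 = _layernorm_fwd(hcur, P[f"ln1g{l}"], P[f"ln1b{l}"])
            Q = ln1 @ P[f"Wq{l}"] + P[f"bq{l}"]
            Km = ln1 @ P[f"Wk{l}"] + P[f"bk{l}"]
            V = ln1 @ P[f"Wv{l}"] + P[f"bv{l}"]
            n1 = hcur.shape[1]

            def _split(z):
                return z.reshape(B, n1, H, dh).transpose(0, 2, 1, 3)

            Qh, Kh, Vh = _split(Q), _split(Km), _split(V)
            logits = Qh @ Kh.transpose(0, 1, 3, 2) / np.sqrt(dh) + bias
            A = _softmax(logits)
            Oh = A @ Vh
            O = Oh.transpose(0, 2, 1, 3).reshape(B, n1, self.m)
            attn_out = O @ P[f"Wo{l}"] + P[f"bo{l}"]
            h1 = hcur + attn_out
            ln2, c_ln2 = _layernorm_fwd(h1, P[f"ln2g{l}"], P[f"ln2b{l}"])
            z1 = ln2 @ P[f"W1{l}"] + P[f"b1{l}"]
            r1 = np.maximum(z1, 0.0)
            ff = r1 @ P[f"W2{l}"] + P[f"b2{l}"]
            hnext = h1 + ff
            caches.append((c_ln1, ln1, Qh, Kh, Vh, A, O, c_ln2, ln2, z1, r1, h1))
            hcur = hnext
        lnf, c_lnf = _layernorm_fwd(hcur[:, 0, :], P["lnfg"], P["lnfb"])
        out = lnf @ P["Whead"] + P["bhead"]
        if cache:
            self._cache = (x, mask, bias, h0, caches, hcur, c_lnf, lnf)
        return out

    # -- loss and backward ---------------------------------------------

    def loss_and_grads(self, x, mask, y):
        """Mean cross-entropy over the batch plus the full gradient dict."""
        P, H, dh = self.params, self.n_heads, self.dh
        B = x.shape[0]
        logits = self.forward(x, mask, cache=True)
        probs = _softmax(logits)
        loss = -np.mean(np.log(probs[np.arange(B), y] + 1e-12))

        grads = {k: np.zeros_like(v) for k, v in P.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B

        x_in, mask_in, bias, h0, caches, hfinal, c_lnf, lnf = self._cache
        grads["Whead"] = lnf.T @ dlogits
        grads["bhead"] = dlogits.sum(0)
        dlnf = dlogits @ P["Whead"].T
        dcls_row, dg, db = _layernorm_bwd(dlnf, c_lnf)
        grads["lnfg"], grads["lnfb"] = dg, db
        dh_cur = np.zeros_like(hfinal)
        dh_cur[:, 0, :] = dcls_row

        for l in reversed(range(self.n_layers)):
            c_ln1, ln1, Qh, Kh, Vh, A, O, c_ln2, ln2, z1, r1, h1 = caches[l]
            n1 = ln1.shape[1]
            # FFN branch
            dff = dh_cur
            grads[f"W2{l}"] += r1.reshape(-1, r1.shape[-1]).T @ dff.reshape(-1, self.m)
            grads[f"b2{l}"] += dff.sum((0, 1))
            dr1 = dff @ P[f"W2{l}"].T
            dz1 = dr1 * (z1 > 0)
            grads[f"W1{l}"] += ln2.reshape(-1, self.m).T @ dz1.reshape(-1, dz1.shape[-1])
            grads[f"b1{l}"] += dz1.sum((0, 1))
            dln2 = dz1 @ P[f"W1{l}"].T
            dh1_ln, dg, db = _layernorm_bwd(dln2, c_ln2)
            grads[f"ln2g{l}"], grads[f"ln2b{l}"] = dg, db
            dh1 = dh_cur + dh1_ln
            # attention branch
            dattn_out = dh1
            grads[f"Wo{l}"] += O.reshape(-1, self.m).T @ dattn_out.reshape(-1, self.m)
            grads[f"bo{l}"] += dattn_out.sum((0, 1))
            dO = dattn_out @ P[f"Wo{l}"].T
            dOh = dO.reshape(B, n1, H, dh).transpose(0, 2, 1, 3)
            dA = dOh @ Vh.transpose(0, 1, 3, 2)
            dVh = A.transpose(0, 1, 3, 2) @ dOh
            dlogits_att = A * (dA - (dA * A).sum(-1, keepdims=True))
            dQh = dlogits_att @ Kh / np.sqrt(dh)
            dKh = dlogits_att.transpose(0, 1, 3, 2) @ Qh / np.sqrt(dh)

            def _merge(z):
                return z.transpose(0, 2, 1, 3).reshape(B, n1, self.m)

            dQ, dK, dV = _merge(dQh), _merge(dKh), _merge(dVh)
            dln1 = np.zeros_like(ln1)
            for dZ, nm in ((dQ, "q"), (dK, "k"), (dV, "v")):
                grads[f"W{nm}{l}"] += ln1.reshape(-1, self.m).T @ dZ.reshape(-1, self.m)
                grads[f"b{nm}{l}"] += dZ.sum((0, 1))
                dln1 += dZ @ P[f"W{nm}{l}"].T
            dh_ln1, dg, db = _layernorm_bwd(dln1, c_ln1)
            grads[f"ln1g{l}"], grads[f"ln1b{l}"] = dg, db
            dh_cur = dh1 + dh_ln1

        # input embedding
        dtok = dh_cur[:, 1:, :] * mask_in[..., None]
        grads["cls"] = dh_cur[:, 0, :].sum(0)
        if self.vocab is None:
            grads["lift_w"] = (dtok * x_in[..., None]).sum((0, 1))
            grads["lift_b"] = dtok.sum((0, 1))
        else:
            np.add.at(grads["emb"], x_in, dtok)
        return loss, grads

    # -- optimizer -----------------------------------------------------

    def adam_step(self, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, g in grads.items():
            self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g**2
            mhat = self._adam_m[k] / (1 - beta1**t)
            vhat = self._adam_v[k] / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- inference -----------------------------------------------------

    def predict_proba(self, x, mask, batch: int = 64) -> np.ndarray:
        """Class probabilities (B, 2), computed in mini-batches."""
        out = []
        for i in range(0, x.shape[0], batch):
            out.append(_softmax(self.forward(x[i:i + batch], mask[i:i + batch])))
        return np.concatenate(out)
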