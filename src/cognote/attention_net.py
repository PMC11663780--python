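"""Attention-based neural text classifier (embedding → 1-D convolution →
bidirectional LSTM → additive attention pooling → sigmoid).

A compact, CPU-friendly NumPy implementation with explicit backpropagation.
The sizes are deliberately small (32-d embeddings, 64 conv channels, 32
hidden units per direction) — enough capacity for section-level keyword
signal without GPU training.  All computation is vectorised over the batch;
padded positions are handled with a masked state carry, so a section's
score and attention trace are independent of how it is batched.

The per-token attention weights (softmax over valid positions, summing to 1)
are the interpretation channel: tokens whose within-section weight exceeds
the section mean by two standard deviations are the network's "keywords".
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .corpus import ConfigurationError, Corpus, NoteSection, tokenize

__all__ = ["AttentionNetConfig", "AttentionNetClassifier", "train_attention_net"]

PAD, UNK = 0, 1


@dataclass(frozen=True)
class AttentionNetConfig:
    embed_dim: int = 32
    conv_channels: int = 64
    kernel_size: int = 3
    hidden_size: int = 32
    max_len: int = 512  # token truncation
    vocab_cap: int = 20000
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 0.01

    def validate(self) -> None:
        for name in ("embed_dim", "conv_channels", "hidden_size", "max_len", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.kernel_size % 2 != 1:
            raise ConfigurationError("kernel_size must be odd (same-padding convolution)")


def _build_vocab(corpus: Corpus, cap: int) -> dict[str, int]:
    counts: Counter[str] = Counter()
    for s in corpus.sections:
        counts.update(tokenize(s.text))
    if len(counts) + 2 > cap:
        raise ConfigurationError(
            f"vocabulary of {len(counts)} tokens exceeds the configured cap {cap - 2}"
        )
    vocab = {"<pad>": PAD, "<unk>": UNK}
    for tok, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        vocab[tok] = len(vocab)
    return vocab


def _encode(texts: list[str], vocab: dict[str, int], max_len: int) -> list[np.ndarray]:
    out = []
    for text in texts:
        ids = [vocab.get(t, UNK) for t in tokenize(text)[:max_len]]
        out.append(np.asarray(ids if ids else [UNK], dtype=np.int64))
    return out


def _pad_batch(seqs: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    T = max(len(s) for s in seqs)
    ids = np.zeros((len(seqs), T), dtype=np.int64)
    mask = np.zeros((len(seqs), T), dtype=np.float64)
    for i, s in enumerate(seqs):
        ids[i, : len(s)] = s
        mask[i, : len(s)] = 1.0
    return ids, mask


def _init_params(cfg: AttentionNetConfig, vocab_size: int, rng: np.random.Generator) -> dict:
    def u(shape, scale):
        return rng.uniform(-scale, scale, size=shape)

    d, c, h, k = cfg.embed_dim, cfg.conv_channels, cfg.hidden_size, cfg.kernel_size
    params = {
        "E": u((vocab_size, d), 0.1),
        "Wc": u((k, d, c), np.sqrt(1.0 / (k * d))),
        "bc": np.zeros(c),
        "va": u((2 * h,), np.sqrt(1.0 / (2 * h))),
        "Wa": u((2 * h, 2 * h), np.sqrt(1.0 / (2 * h))),
        "ba": np.zeros(2 * h),
        "wo": u((2 * h,), np.sqrt(1.0 / (2 * h))),
        "bo": np.zeros(1),
    }
    for direction in ("f", "b"):
        params[f"Wx_{direction}"] = u((c, 4 * h), np.sqrt(1.0 / c))
        Wh = u((h, 4 * h), np.sqrt(1.0 / h))
        params[f"Wh_{direction}"] = Wh
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias
        params[f"b_{direction}"] = b
    params["E"][PAD] = 0.0
    return params


def _lstm_forward(X, mask, Wx, Wh, b, h_size, reverse=False):
    """Masked-carry LSTM; returns outputs (B,T,H) and per-step caches."""
    B, T, _ = X.shape
    H = h_size
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    outputs = np.zeros((B, T, H))
    caches = []
    steps = range(T - 1, -1, -1) if reverse else range(T)
    for t in steps:
        m = mask[:, t : t + 1]
        x = X[:, t, :]
        z = x @ Wx + h @ Wh + b
        i = expit(z[:, :H])
        f = expit(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = expit(z[:, 3 * H :])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        h_prev, c_prev = h, c
        h = m * h_new + (1 - m) * h_prev
        c = m * c_new + (1 - m) * c_prev
        outputs[:, t, :] = h
        caches.append((t, x, h_prev, c_prev, i, f, g, o, c_new, tc, m))
    return outputs, caches


def _lstm_backward(dOut, caches, Wx, Wh, h_size, X_shape):
    """Backprop through the masked-carry LSTM; dOut is (B,T,H)."""
    B, T, _ = X_shape
    H = h_size
    dX = np.zeros(X_shape)
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(4 * H)
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t, x, h_prev, c_prev, i, f, g, o, c_new, tc, m in reversed(caches):
        dh = dh + dOut[:, t, :]
        dh_new = m * dh
        dh_prev = (1 - m) * dh
        dc_new = m * dc
        dc_prev = (1 - m) * dc
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1 - tc**2)
        df = dc_new * c_prev
        dc_prev = dc_prev + dc_new * f
        di = dc_new * g
        dg = dc_new * i
        dz = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
            axis=1,
        )
        dWx += x.T @ dz
        dWh += h_prev.T @ dz
        db += dz.sum(axis=0)
        dX[:, t, :] += dz @ Wx.T
        dh = dh_prev + dz @ Wh.T
        dc = dc_prev
    return dX, dWx, dWh, db


def _forward(params, cfg, ids, mask, want_cache=False):
    """Full forward pass; returns probabilities, attention, and a cache."""
    k, H = cfg.kernel_size, cfg.hidden_size
    B, T = ids.shape
    X = params["E"][ids] * mask[:, :, None]
    # Same-padded 1-D convolution along the token axis.
    pre = np.broadcast_to(params["bc"], (B, T, cfg.conv_channels)).copy()
    half = k // 2
    for j in range(k):
        off = j - half
        lo, hi = max(0, -off), min(T, T - off)
        pre[:, lo:hi, :] += X[:, lo + off : hi + off, :] @ params["Wc"][j]
    relu_mask = (pre > 0).astype(np.float64)
    H1 = pre * relu_mask * mask[:, :, None]

    out_f, cache_f = _lstm_forward(H1, mask, params["Wx_f"], params["Wh_f"], params["b_f"], H)
    out_b, cache_b = _lstm_forward(
        H1, mask, params["Wx_b"], params["Wh_b"], params["b_b"], H, reverse=True
    )
    Hcat = np.concatenate([out_f, out_b], axis=2)  # (B,T,2H)

    u = np.tanh(Hcat @ params["Wa"] + params["ba"])
    scores = u @ params["va"]
    scores = np.where(mask > 0, scores, -1e30)
    scores = scores - scores.max(axis=1, keepdims=True)
    exps = np.exp(scores) * mask
    alpha = exps / exps.sum(axis=1, keepdims=True)
    context = (alpha[:, :, None] * Hcat).sum(axis=1)
    logits = context @ params["wo"] + params["bo"][0]
    probs = expit(logits)
    cache = None
    if want_cache:
        cache = dict(
            X=X, pre=pre, relu_mask=relu_mask, H1=H1, cache_f=cache_f, cache_b=cache_b,
            Hcat=Hcat, u=u, alpha=alpha, context=context, ids=ids, mask=mask,
        )
    return probs, alpha, cache


def _backward(params, cfg, cache, probs, y):
    """Gradients of mean binary cross-entropy w.r.t. all parameters."""
    B, T = cache["ids"].shape
    k, H = cfg.kernel_size, cfg.hidden_size
    mask, alpha, Hcat, u = cache["mask"], cache["alpha"], cache["Hcat"], cache["u"]
    grads = {}

    dlogits = (probs - y) / B
    grads["wo"] = cache["context"].T @ dlogits
    grads["bo"] = np.array([dlogits.sum()])
    dcontext = dlogits[:, None] * params["wo"][None, :]

    dalpha = np.einsum("bd,btd->bt", dcontext, Hcat)
    dHcat = alpha[:, :, None] * dcontext[:, None, :]
    dscores = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
    du = dscores[:, :, None] * params["va"][None, None, :]
    grads["va"] = np.einsum("bt,btd->d", dscores, u)
    da = du * (1 - u**2)
    grads["Wa"] = np.einsum("btd,bte->de", Hcat, da)
    grads["ba"] = da.sum(axis=(0, 1))
    dHcat = dHcat + da @ params["Wa"].T

    dH1 = np.zeros_like(cache["H1"])
    dOut_f, dOut_b = dHcat[:, :, :H], dHcat[:, :, H:]
    dX_f, dWx_f, dWh_f, db_f = _lstm_backward(
        dOut_f, cache["cache_f"], params["Wx_f"], params["Wh_f"], H, cache["H1"].shape
    )
    dX_b, dWx_b, dWh_b, db_b = _lstm_backward(
        dOut_b, cache["cache_b"], params["Wx_b"], params["Wh_b"], H, cache["H1"].shape
    )
    grads["Wx_f"], grads["Wh_f"], grads["b_f"] = dWx_f, dWh_f, db_f
    grads["Wx_b"], grads["Wh_b"], grads["b_b"] = dWx_b, dWh_b, db_b
    dH1 = dX_f + dX_b

    dpre = dH1 * cache["relu_mask"] * mask[:, :, None]
    grads["bc"] = dpre.sum(axis=(0, 1))
    grads["Wc"] = np.zeros_like(params["Wc"])
    dX = np.zeros_like(cache["X"])
    half = k // 2
    for j in range(k):
        off = j - half
        lo, hi = max(0, -off), min(T, T - off)
        grads["Wc"][j] = np.einsum(
            "btd,btc->dc", cache["X"][:, lo + off : hi + off, :], dpre[:, lo:hi, :]
        )
        dX[:, lo + off : hi + off, :] += dpre[:, lo:hi, :] @ params["Wc"][j].T
    dX *= mask[:, :, None]
    dE = np.zeros_like(params["E"])
    np.add.at(dE, cache["ids"].ravel(), dX.reshape(-1, cfg.embed_dim))
    dE[PAD] = 0.0
    grads["E"] = dE
    return grads


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, g in grads.items():
            self.m[key] = b1 * self.m[key] + (1 - b1) * g
            self.v[key] = b2 * self.v[key] + (1 - b2) * g**2
            mhat = self.m[key] / (1 - b1**self.t)
            vhat = self.v[key] / (1 - b2**self.t)
            params[key] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class AttentionNetClassifier:
    """A trained attention network exposing scores and attention traces."""

    config: AttentionNetConfig
    vocab: dict[str, int]
    params: dict
    seed: int
    history: list[float] = field(default_factory=list)

    def _forward_texts(self, texts: list[str], batch_size: int = 256):
        seqs = _encode(texts, self.vocab, self.config.max_len)
        probs = np.zeros(len(texts))
        for start in range(0, len(texts), batch_size):
            chunk = seqs[start : start + batch_size]
            ids, mask = _pad_batch(chunk)
            p, _, _ = _forward(self.params, self.config, ids, mask)
            probs[start : start + len(chunk)] = p
        return probs

    def predict_score(self, corpus: Corpus) -> np.ndarray:
        return self._forward_texts([s.text for s in corpus.sections])

    def attention_trace(self, section: NoteSection) -> tuple[list[str], np.ndarray]:
        """Tokens of one section with their attention weights (sum to 1)."""
        tokens = tokenize(section.text)[: self.config.max_len]
        if not tokens:
            tokens = ["<unk>"]
        ids, mask = _pad_batch(_encode([section.text], self.vocab, self.config.max_len))
        _, alpha, _ = _forward(self.params, self.config, ids, mask)
        return tokens, alpha[0, : len(tokens)]


def train_attention_net(
    corpus: Corpus,
    config: AttentionNetConfig | None = None,
    seed: int = 0,
) -> AttentionNetClassifier:
    """Train the attention network with Adam on mini-batches.

    Mini-batches are built over a seeded shuffle each epoch and padded to the
    batch maximum; the run is fully deterministic given (corpus, config, seed).
    """
    cfg = config or AttentionNetConfig()
    cfg.validate()
    y_all = np.asarray(corpus.labels, dtype=np.float64)
    if len(np.unique(y_all)) < 2:
        raise ValueError("training corpus must contain both classes")
    vocab = _build_vocab(corpus, cfg.vocab_cap)
    seqs = _encode([s.text for s in corpus.sections], vocab, cfg.max_len)
    rng = np.random.default_rng(seed)
    params = _init_params(cfg, len(vocab), rng)
    opt = _Adam(params, cfg.learning_rate)

    n = len(seqs)
    history = []
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            ids, mask = _pad_batch([seqs[i] for i in idx])
            y = y_all[idx]
            probs, _, cache = _forward(params, cfg, ids, mask, want_cache=True)
            p = np.clip(probs, 1e-9, 1 - 1e-9)
            epoch_loss += float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).sum())
            grads = _backward(params, cfg, cache, probs, y)
            opt.step(params, grads)
        history.append(epoch_loss / n)
    return AttentionNetClassifier(config=cfg, vocab=vocab, params=params, seed=seed, history=history)
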