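"""Straight-through-estimator training of the binarized network, in NumPy.

Latent real-valued weights are kept in [-1, 1]; every forward pass binarizes
them at > 0 (so a latent sign change flips the deployed bit) and binarizes
activations the same way.  Gradients pass straight through each binarization
inside a window around its threshold (the standard STE recipe), max-pool
routes gradients to the maximal entries, and batch norm is trained with
batch statistics while running statistics are tracked for inference and for
threshold folding.  Optimization is Adam under a cosine learning-rate decay
from 1e-3 to 1e-4, cross-entropy loss, and early stopping on validation
loss with a 10-epoch patience.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, DEFAULT_CONFIG
from .model import BNParams, ModelWeights
from .preprocess import Beat, beat_to_image, rr_code

logger = logging.getLogger(__name__)

__all__ = ["TrainSettings", "prepare_dataset", "train"]


@dataclass(frozen=True)
class TrainSettings:
    max_epochs: int = 30
    batch_size: int = 128
    lr_start: float = 1e-3
    lr_end: float = 1e-4
    patience: int = 10
    bn_momentum: float = 0.9
    bn_eps: float = 1e-4


def prepare_dataset(beats: list, cfg: ModelConfig = DEFAULT_CONFIG):
    """Beats -> (images (N,M,M), rr bit codes (N,rr_bits), labels (N,)).

    The RR ratio is normalized by the median rr_prev of each beat's record.
    """
    from .metrics import CLASS_ORDER

    med: dict[str, float] = {}
    for b in beats:
        med.setdefault(b.record_id, []).append(b.rr_prev)
    med = {rid: float(np.median(v)) for rid, v in med.items()}
    X = np.stack([beat_to_image(b, cfg.M) for b in beats]).astype(np.float32)
    R = np.stack([rr_code(b.rr_prev, med[b.record_id], cfg.rr_bits)
                  for b in beats]).astype(np.float32)
    y = np.array([CLASS_ORDER.index(b.label) for b in beats], dtype=np.int64)
    return X, R, y


# ---------------------------------------------------------------------------
# internals

def _binw(latent):
    return (latent > 0).astype(np.float32)


def _bn_forward(x, gamma, beta, eps, axes):
    mean = x.mean(axis=axes)
    var = x.var(axis=axes)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean) * inv
    return gamma * xhat + beta, (xhat, inv, mean, var)


def _bn_backward(gy, cache, gamma, axes, n):
    xhat, inv, _, _ = cache
    g_gamma = (gy * xhat).sum(axis=axes)
    g_beta = gy.sum(axis=axes)
    gx = (gamma * inv / n) * (n * gy - g_beta - xhat * g_gamma)
    return gx, g_gamma, g_beta


class _Adam:
    def __init__(self, params, lr):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.lr = lr

    def step(self, params, grads):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


@dataclass
class _State:
    """Latent parameters plus BN statistics."""

    p: dict = field(default_factory=dict)       # trainable tensors
    run_mean: dict = field(default_factory=dict)
    run_var: dict = field(default_factory=dict)

    def snapshot(self):
        return ({k: v.copy() for k, v in self.p.items()},
                {k: v.copy() for k, v in self.run_mean.items()},
                {k: v.copy() for k, v in self.run_var.items()})

    def restore(self, snap):
        p, rm, rv = snap
        self.p = {k: v.copy() for k, v in p.items()}
        self.run_mean = {k: v.copy() for k, v in rm.items()}
        self.run_var = {k: v.copy() for k, v in rv.items()}


def _init_state(cfg: ModelConfig, rng: np.random.Generator) -> _State:
    st = _State()
    u = lambda *s: rng.uniform(-0.5, 0.5, s).astype(np.float32)
    st.p = {
        "conv1": u(cfg.K, cfg.KO, cfg.KO),
        "dw": u(cfg.K, cfg.KD, cfg.KD),
        "pw": u(cfg.KP, cfg.K),
        "fc1": u(cfg.fc1_in, cfg.F1),
        "fc2": u(cfg.F1, cfg.C),
        "g_dsc": np.ones(cfg.KP, np.float32), "b_dsc": np.zeros(cfg.KP, np.float32),
        "g_fc1": np.ones(cfg.F1, np.float32), "b_fc1": np.zeros(cfg.F1, np.float32),
        "g_fc2": np.ones(cfg.C, np.float32), "b_fc2": np.zeros(cfg.C, np.float32),
    }
    for k, n in (("dsc", cfg.KP), ("fc1", cfg.F1), ("fc2", cfg.C)):
        st.run_mean[k] = np.zeros(n, np.float32)
        st.run_var[k] = np.ones(n, np.float32)
    return st


def _forward(X, R, st, cfg, settings, train_mode):
    """Shared forward pass; returns logits-path values and a cache for backprop."""
    p = st.p
    eps = settings.bn_eps
    wc, wdw, wpw = _binw(p["conv1"]), _binw(p["dw"]), _binw(p["pw"])
    wf1, wf2 = _binw(p["fc1"]), _binw(p["fc2"])

    win1 = np.lib.stride_tricks.sliding_window_view(X, (cfg.KO, cfg.KO), axis=(1, 2))
    pre1 = np.einsum("nxyab,kab->nxyk", win1, wc, optimize=True)
    a1 = (pre1 > 0).astype(np.float32)

    n, s, _, K = a1.shape
    a1r = a1.reshape(n, s // cfg.SP, cfg.P, s // cfg.SP, cfg.P, K)
    pooled = a1r.max(axis=(2, 4))

    win2 = np.lib.stride_tricks.sliding_window_view(
        pooled, (cfg.KD, cfg.KD), axis=(1, 2))
    pre_dw = np.einsum("nxykab,kab->nxyk", win2, wdw, optimize=True)
    pre_pw = np.einsum("nxyk,pk->nxyp", pre_dw, wpw, optimize=True)

    def bn(name, x, axes):
        if train_mode:
            y, cache = _bn_forward(x, p[f"g_{name}"], p[f"b_{name}"], eps, axes)
            m = settings.bn_momentum
            st.run_mean[name] = m * st.run_mean[name] + (1 - m) * cache[2]
            st.run_var[name] = m * st.run_var[name] + (1 - m) * cache[3]
            return y, cache
        inv = 1.0 / np.sqrt(st.run_var[name] + eps)
        xhat = (x - st.run_mean[name]) * inv
        return p[f"g_{name}"] * xhat + p[f"b_{name}"], (xhat, inv, None, None)

    y_dsc, c_dsc = bn("dsc", pre_pw, (0, 1, 2))
    a2 = (y_dsc > 0).astype(np.float32)
    z = np.concatenate([a2.reshape(n, -1), R], axis=1)
    pre_f1 = z @ wf1
    y_f1, c_f1 = bn("fc1", pre_f1, (0,))
    a3 = (y_f1 > 0).astype(np.float32)
    pre_f2 = a3 @ wf2
    y_f2, c_f2 = bn("fc2", pre_f2, (0,))

    cache = dict(win1=win1, pre1=pre1, a1=a1, a1r=a1r, pooled=pooled,
                 win2=win2, pre_dw=pre_dw, y_dsc=y_dsc, c_dsc=c_dsc, a2=a2,
                 z=z, c_f1=c_f1, y_f1=y_f1, a3=a3, c_f2=c_f2,
                 wc=wc, wdw=wdw, wpw=wpw, wf1=wf1, wf2=wf2)
    return y_f2, cache


def _loss_and_grad(y_f2, y, cfg):
    n = y_f2.shape[0]
    shift = y_f2 - y_f2.max(axis=1, keepdims=True)
    logp = shift - np.log(np.exp(shift).sum(axis=1, keepdims=True))
    loss = -logp[np.arange(n), y].mean()
    probs = np.exp(logp)
    g = probs
    g[np.arange(n), y] -= 1.0
    return loss, g / n


def _backward(g_y2, cache, st, cfg, settings):
    p = st.p
    n = g_y2.shape[0]
    grads = {}

    g_pre_f2, grads["g_fc2"], grads["b_fc2"] = _bn_backward(
        g_y2, cache["c_f2"], p["g_fc2"], (0,), n)
    grads["fc2"] = cache["a3"].T @ g_pre_f2
    g_a3 = g_pre_f2 @ cache["wf2"].T

    g_y1 = g_a3 * (np.abs(cache["y_f1"]) <= 1.0)
    g_pre_f1, grads["g_fc1"], grads["b_fc1"] = _bn_backward(
        g_y1, cache["c_f1"], p["g_fc1"], (0,), n)
    grads["fc1"] = cache["z"].T @ g_pre_f1
    g_z = g_pre_f1 @ cache["wf1"].T

    md = cfg.MD
    g_a2 = g_z[:, : md * md * cfg.KP].reshape(n, md, md, cfg.KP)
    g_ydsc = g_a2 * (np.abs(cache["y_dsc"]) <= 1.0)
    n_dsc = n * md * md
    g_pre_pw, grads["g_dsc"], grads["b_dsc"] = _bn_backward(
        g_ydsc, cache["c_dsc"], p["g_dsc"], (0, 1, 2), n_dsc)

    grads["pw"] = np.einsum("nxyp,nxyk->pk", g_pre_pw, cache["pre_dw"],
                            optimize=True)
    g_pre_dw = np.einsum("nxyp,pk->nxyk", g_pre_pw, cache["wpw"], optimize=True)
    grads["dw"] = np.einsum("nxyk,nxykab->kab", g_pre_dw, cache["win2"],
                            optimize=True)

    g_pooled = np.zeros_like(cache["pooled"])
    wdw = cache["wdw"]
    for a in range(cfg.KD):
        for b in range(cfg.KD):
            g_pooled[:, a : a + md, b : b + md, :] += g_pre_dw * wdw[:, a, b]

    a1r, pooled = cache["a1r"], cache["pooled"]
    is_max = (a1r == pooled[:, :, None, :, None, :])
    share = is_max / is_max.sum(axis=(2, 4), keepdims=True)
    g_a1 = (g_pooled[:, :, None, :, None, :] * share).reshape(cache["a1"].shape)

    g_pre1 = g_a1 * (cache["pre1"] <= 2.0)
    grads["conv1"] = np.einsum("nxyk,nxyab->kab", g_pre1, cache["win1"],
                               optimize=True)
    return grads


def _weights_from_state(st: _State, cfg: ModelConfig,
                        settings: TrainSettings) -> ModelWeights:
    p = st.p

    def bn(name):
        return BNParams(gamma=p[f"g_{name}"].astype(np.float64),
                        beta=p[f"b_{name}"].astype(np.float64),
                        mu=st.run_mean[name].astype(np.float64),
                        sigma=np.sqrt(st.run_var[name]).astype(np.float64),
                        eps=settings.bn_eps)

    return ModelWeights(
        conv1=_binw(p["conv1"]).astype(np.uint8),
        dw=_binw(p["dw"]).astype(np.uint8),
        pw=_binw(p["pw"]).astype(np.uint8),
        bn_dsc=bn("dsc"),
        fc1=_binw(p["fc1"]).astype(np.uint8),
        bn_fc1=bn("fc1"),
        fc2=_binw(p["fc2"]).astype(np.uint8),
        bn_fc2=bn("fc2"),
        config=cfg,
    )


def train(train_set, val_set, cfg: ModelConfig = DEFAULT_CONFIG, seed: int = 0,
          settings: TrainSettings = TrainSettings()):
    """Train on Beat lists (or prepared (X, R, y) triples).

    Returns (ModelWeights, log) where log is a list of per-epoch dicts with
    train/val loss and accuracy.  Raises RuntimeError on divergence.
    """
    cfg.validate()
    if isinstance(train_set, tuple):
        Xt, Rt, yt = train_set
        Xv, Rv, yv = val_set
    else:
        train_set, val_set = list(train_set), list(val_set)
        if not train_set or not val_set:
            raise ValueError("training and validation sets must be non-empty")
        Xt, Rt, yt = prepare_dataset(train_set, cfg)
        Xv, Rv, yv = prepare_dataset(val_set, cfg)
    if len(yt) == 0 or len(yv) == 0:
        raise ValueError("training and validation sets must be non-empty")

    rng = np.random.default_rng(seed)
    st = _init_state(cfg, rng)
    opt = _Adam(st.p, settings.lr_start)
    n = len(yt)
    best = (np.inf, None, -1)
    log = []

    for epoch in range(settings.max_epochs):
        # cosine decay between the start and end learning rates
        frac = epoch / max(settings.max_epochs - 1, 1)
        opt.lr = settings.lr_end + 0.5 * (settings.lr_start - settings.lr_end) * (
            1 + np.cos(np.pi * frac))

        order = rng.permutation(n)
        tr_loss, tr_hits = 0.0, 0
        for start in range(0, n, settings.batch_size):
            idx = order[start : start + settings.batch_size]
            y_f2, cache = _forward(Xt[idx], Rt[idx], st, cfg, settings, True)
            loss, g = _loss_and_grad(y_f2, yt[idx], cfg)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (loss={loss}) at epoch {epoch}")
            grads = _backward(g, cache, st, cfg, settings)
            opt.step(st.p, grads)
            for k in ("conv1", "dw", "pw", "fc1", "fc2"):
                np.clip(st.p[k], -1.0, 1.0, out=st.p[k])
            tr_loss += loss * len(idx)
            tr_hits += int((y_f2.argmax(axis=1) == yt[idx]).sum())

        yv_f2, _ = _forward(Xv, Rv, st, cfg, settings, False)
        val_loss, _ = _loss_and_grad(yv_f2, yv, cfg)
        val_acc = float((yv_f2.argmax(axis=1) == yv).mean())
        entry = {"epoch": epoch, "lr": float(opt.lr),
                 "train_loss": float(tr_loss / n), "train_acc": tr_hits / n,
                 "val_loss": float(val_loss), "val_acc": val_acc}
        log.append(entry)
        logger.info("epoch %(epoch)d: train_loss=%(train_loss).4f "
                    "val_loss=%(val_loss).4f val_acc=%(val_acc).3f", entry)

        if val_loss < best[0] - 1e-6:
            best = (float(val_loss), st.snapshot(), epoch)
        elif epoch - best[2] >= settings.patience:
            log[-1]["early_stopped"] = True
            break

    if best[1] is not None:
        st.restore(best[1])
    return _weights_from_state(st, cfg, settings), log
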