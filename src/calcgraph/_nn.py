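"""Minimal neural-network kernels on autograd.

Everything trainable in this package (patch verifier, patch feature
extractor, spatial embedding, edge-conditioned graph convolution, classifier
head) is expressed as pure functions of a parameter pytree (nested dicts of
numpy arrays) so that ``autograd`` can differentiate end to end.  Kernels are
hand-vectorized: convolution via shifted-slice im2col, graph message passing
via a segment-sum primitive with a gather adjoint.
"""

from __future__ import annotations

import numpy as _np
import autograd.numpy as np
from autograd import value_and_grad
from autograd.extend import defvjp, primitive
from autograd.misc.flatten import flatten

__all__ = [
    "segment_sum",
    "conv2d",
    "maxpool2",
    "dense",
    "relu",
    "sigmoid",
    "glorot",
    "AdamState",
    "adam_step",
    "flatten",
    "verifier_init",
    "verifier_forward",
    "extractor_init",
    "extractor_forward",
]


# ---------------------------------------------------------------------------
# primitives


@primitive
def segment_sum(data, segment_ids, num_segments):
    """Sum rows of ``data`` into ``num_segments`` buckets given by ``segment_ids``."""
    out = _np.zeros((num_segments,) + data.shape[1:], dtype=data.dtype)
    _np.add.at(out, segment_ids, data)
    return out


defvjp(segment_sum, lambda ans, data, ids, n: lambda g: g[ids])


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    # clip keeps exp finite; sigmoid saturates far before +-30 anyway
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def dense(x, w, b):
    return np.dot(x, w) + b


def _pad_same(x, kh, kw):
    """Zero-pad NCHW input for 'same' convolution (odd kernels)."""
    b, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    zh = np.zeros((b, c, ph, w))
    x = np.concatenate([zh, x, zh], axis=2)
    zw = np.zeros((b, c, h + 2 * ph, pw))
    return np.concatenate([zw, x, zw], axis=3)


def conv2d(x, w, b, same=True):
    """2-D convolution, NCHW input, OIHW kernel, stride 1.

    Implemented as a stack of shifted slices contracted with einsum so that
    autograd can trace it; adequate for the small patch sizes used here.
    """
    o, i, kh, kw = w.shape
    if same:
        x = _pad_same(x, kh, kw)
    bsz, c, h, ww = x.shape
    ho, wo = h - kh + 1, ww - kw + 1
    cols = []
    for di in range(kh):
        for dj in range(kw):
            cols.append(x[:, :, di : di + ho, dj : dj + wo])
    col = np.stack(cols, axis=2)  # (B, C, kh*kw, Ho, Wo)
    out = np.einsum("bckhw,ock->bohw", col, np.reshape(w, (o, i, kh * kw)))
    return out + np.reshape(b, (1, o, 1, 1))


def maxpool2(x):
    """2x2 max pool, stride 2; trailing odd row/column is dropped."""
    b, c, h, w = x.shape
    h2, w2 = (h // 2) * 2, (w // 2) * 2
    x = x[:, :, :h2, :w2]
    a = np.maximum(x[:, :, 0::2, 0::2], x[:, :, 1::2, 0::2])
    return np.maximum(np.maximum(a, x[:, :, 0::2, 1::2]), x[:, :, 1::2, 1::2])


def glorot(rng, *shape):
    fan_in = int(_np.prod(shape[1:])) if len(shape) > 1 else shape[0]
    fan_out = shape[0]
    scale = _np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=shape)


# ---------------------------------------------------------------------------
# Adam


class AdamState:
    """Adam moment buffers over a flat parameter vector."""

    def __init__(self, n, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = _np.zeros(n)
        self.v = _np.zeros(n)
        self.t = 0
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps


def adam_step(state, flat_params, flat_grad, lr=None):
    state.t += 1
    lr = state.lr if lr is None else lr
    state.m = state.beta1 * state.m + (1 - state.beta1) * flat_grad
    state.v = state.beta2 * state.v + (1 - state.beta2) * flat_grad**2
    mhat = state.m / (1 - state.beta1**state.t)
    vhat = state.v / (1 - state.beta2**state.t)
    return flat_params - lr * mhat / (_np.sqrt(vhat) + state.eps)


def minimize_adam(loss_fn, params, batches, epochs, lr, lr_decay=0.5,
                  decay_every=30, callback=None, patience=None):
    """Run Adam over ``epochs`` sweeps of ``batches`` (a callable epoch->list).

    With ``patience`` set, training stops early once the epoch loss has not
    improved for that many consecutive epochs.  Returns (params, history)
    where history is the per-epoch mean loss.
    """
    flat, unflatten = flatten(params)
    state = AdamState(flat.size, lr=lr)
    vag = value_and_grad(lambda p, batch: loss_fn(p, batch))
    history = []
    best, stale = _np.inf, 0
    for epoch in range(epochs):
        cur_lr = lr * (lr_decay ** (epoch // decay_every))
        losses = []
        for batch in batches(epoch):
            value, g = vag(unflatten(flat), batch)
            gflat, _ = flatten(g)
            flat = adam_step(state, flat, gflat, lr=cur_lr)
            losses.append(value)
        history.append(float(_np.mean(losses)))
        if callback is not None:
            callback(epoch, history[-1])
        if patience is not None:
            if history[-1] < best - 1e-6:
                best, stale = history[-1], 0
            else:
                stale += 1
                if stale >= patience:
                    break
    return unflatten(flat), history


# ---------------------------------------------------------------------------
# patch verifier: 4 conv layers + global average pool + 2 dense layers


def verifier_init(rng, channels=(8, 16, 16, 32), hidden=16):
    params = {"conv": [], "fc": []}
    cin = 1
    for c in channels:
        params["conv"].append({"w": glorot(rng, c, cin, 3, 3), "b": _np.zeros(c)})
        cin = c
    params["fc"].append({"w": glorot(rng, hidden, cin).T, "b": _np.zeros(hidden)})
    params["fc"].append({"w": glorot(rng, 1, hidden).T, "b": _np.zeros(1)})
    return params


def verifier_forward(params, patches):
    """Patches (B, D, D) -> logits (B,). Pools after the 2nd and 4th conv."""
    x = np.reshape(patches, (patches.shape[0], 1) + patches.shape[1:])
    for i, layer in enumerate(params["conv"]):
        x = relu(conv2d(x, layer["w"], layer["b"]))
        if i in (1, 3):
            x = maxpool2(x)
    x = np.mean(x, axis=(2, 3))  # global average pool
    x = relu(dense(x, params["fc"][0]["w"], params["fc"][0]["b"]))
    return dense(x, params["fc"][1]["w"], params["fc"][1]["b"])[:, 0]


# ---------------------------------------------------------------------------
# patch feature extractor: six conv layers with two residual skips,
# global average pool at the tap layer


def extractor_init(rng, out_dim=64, width=16):
    chans = [width, width, width, 2 * width, 2 * width, out_dim]
    params = {"conv": []}
    cin = 1
    for c in chans:
        params["conv"].append({"w": glorot(rng, c, cin, 3, 3), "b": _np.zeros(c)})
        cin = c
    return params


def extractor_forward(params, patches, tap_layer=6):
    """Patches (B, D, D) -> features (B, out_dim of tap layer).

    Residual skips join layers 1->3 and 4->5 (equal widths); features are the
    global-average-pooled maps of ``tap_layer`` (1-based).
    """
    x = np.reshape(patches, (patches.shape[0], 1) + patches.shape[1:])
    taps = []
    c = params["conv"]
    h1 = relu(conv2d(x, c[0]["w"], c[0]["b"]))
    taps.append(h1)
    h2 = relu(conv2d(h1, c[1]["w"], c[1]["b"]))
    taps.append(h2)
    h3 = relu(conv2d(h2, c[2]["w"], c[2]["b"]) + h1)
    taps.append(h3)
    h3 = maxpool2(h3)
    h4 = relu(conv2d(h3, c[3]["w"], c[3]["b"]))
    taps.append(h4)
    h5 = relu(conv2d(h4, c[4]["w"], c[4]["b"]) + h4)
    taps.append(h5)
    h6 = relu(conv2d(h5, c[5]["w"], c[5]["b"]))
    taps.append(h6)
    return np.mean(taps[tap_layer - 1], axis=(2, 3))
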