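"""Multilevel guided self-aware attention bottleneck.

Two complementary attention components act on the bottleneck feature map
``F ∈ R^{c×h×w}`` (flattened to ``c×n`` with ``n = h·w``):

* **TSAC** — channel-level transformer self-attention.  After adding a
  learned position encoding, channel-mixing projections produce Q, K, V;
  the contextual attention map ``CAM = softmax(Q·Kᵀ/√d_k)`` is ``c×c`` with
  rows summing to 1, and the output is ``CAM·V``.  Optionally several heads
  split the channels, each attends separately, and a final linear embedding
  mixes the concatenation.

* **GCAC** — position-level attention.  Two 1×1 convolutions compress the
  map to ``c₁ = max(1, c₀/8)`` channels giving V and W; the position
  attention map ``L_{i,j} = softmax_i(V_i·W_j)`` is ``n×n`` with columns
  summing to 1, and output position j aggregates ``Σ_i L_{i,j}·U_{:,i}``
  over the full-channel map U.  (The aggregation runs over U so the output
  keeps c₀ channels; aggregating W would collapse to a constant because L's
  columns are normalized.)

* **Fusion** — ``out = α₁·TSAC + α₂·GCAC + F`` with learnable scalars α
  initialized to 0, so the module is exactly the identity at initialization.

The functional ops accept plain arrays or autodiff tensors; the modules
wrap them with learned parameters for use inside the network.
"""

from __future__ import annotations

import math

import numpy as np

from .engine import Tensor, as_tensor, concat, softmax
from .nn import DTYPE, Conv2d, Module

__all__ = ["position_encode", "tsac_project", "tsac_attend", "gcac_project",
           "gcac_attention", "gcac_aggregate", "mgam_fuse",
           "TSAC", "GCAC", "MGAM", "ALPHA_GRID"]

# fixed (alpha1, alpha2) combinations probed when tuning the fusion weights
ALPHA_GRID = ((1.0, 0.0), (0.75, 0.25), (0.0, 1.0), (0.5, 0.5), (0.25, 0.75))


def position_encode(fm, embedding):
    """Add a learned position encoding, elementwise; shapes must match."""
    fm, embedding = as_tensor(fm), as_tensor(embedding)
    if fm.shape[-3:] != embedding.shape[-3:]:
        raise ValueError(f"position embedding {embedding.shape} does not match "
                         f"feature map {fm.shape}")
    return fm + embedding


def tsac_project(fm, w_q, w_k, w_v):
    """Flatten (…,c,h,w) to (…,c,n) and apply channel-mixing projections."""
    fm = as_tensor(fm)
    c, h, w = fm.shape[-3:]
    flat = fm.reshape(fm.shape[:-3] + (c, h * w))
    w_q, w_k, w_v = as_tensor(w_q), as_tensor(w_k), as_tensor(w_v)
    if w_q.shape[-1] != c:
        raise ValueError(f"projection shape {w_q.shape} incompatible with c={c}")
    return w_q @ flat, w_k @ flat, w_v @ flat


def tsac_attend(q, k, v, d_k: float, out_shape=None):
    """Scaled dot-product channel attention: row-softmax(Q·Kᵀ/√d_k)·V."""
    if d_k <= 0:
        raise ValueError("d_k must be > 0")
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    cam = softmax((q @ k.T) * (1.0 / math.sqrt(d_k)), axis=-1)
    out = cam @ v
    if out_shape is not None:
        out = out.reshape(out.shape[:-2] + tuple(out_shape))
    return out, cam


def gcac_project(fm, conv_v: "Conv2d", conv_w: "Conv2d"):
    """Reshape the c0-channel map to U and compress with two 1x1 convs to
    c1-channel V and W, all flattened over positions."""
    fm = as_tensor(fm)
    squeeze = fm.ndim == 3
    x = fm.reshape((1,) + fm.shape) if squeeze else fm
    n_, c0, h, w = x.shape
    u = x.reshape((n_, c0, h * w))
    v = conv_v(x).reshape((n_, conv_v.weight.shape[0], h * w))
    wm = conv_w(x).reshape((n_, conv_w.weight.shape[0], h * w))
    if squeeze:
        u, v, wm = u[0], v[0], wm[0]
    return u, v, wm


def gcac_attention(v, w):
    """Position attention L_{i,j} = softmax over i of <V_i, W_j>;
    V_i/W_j are the per-position feature columns.  Columns of L sum to 1."""
    v, w = as_tensor(v), as_tensor(w)
    logits = v.T @ w                      # (…, n, n): [i, j] = V_i · W_j
    return softmax(logits, axis=-2)


def gcac_aggregate(l_map, u, out_shape=None):
    """Output position j = Σ_i L_{i,j} · U_{:,i}, i.e. U @ L."""
    l_map, u = as_tensor(l_map), as_tensor(u)
    out = u @ l_map
    if out_shape is not None:
        out = out.reshape(out.shape[:-2] + tuple(out_shape))
    return out


def mgam_fuse(enc, tsac_out, gcac_out, a1, a2):
    """Learnable fusion a1·TSAC + a2·GCAC + encoder feature."""
    enc, tsac_out, gcac_out = as_tensor(enc), as_tensor(tsac_out), as_tensor(gcac_out)
    if not (enc.shape == tsac_out.shape == gcac_out.shape):
        raise ValueError("fused maps must share a shape")
    return as_tensor(a1) * tsac_out + as_tensor(a2) * gcac_out + enc


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class TSAC(Module):
    """Channel self-attention with shared learned position encoding."""

    def __init__(self, channels: int, spatial: tuple[int, int],
                 rng: np.random.Generator, n_heads: int = 1):
        if channels % n_heads:
            raise ValueError(f"channels {channels} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.channels = channels
        h, w = spatial
        scale = 1.0 / math.sqrt(channels)
        init = lambda: Tensor((rng.standard_normal((channels, channels)) * scale
                               ).astype(DTYPE), requires_grad=True)
        self.w_q, self.w_k, self.w_v = init(), init(), init()
        self.w_out = init()
        self.pos = Tensor(np.zeros((channels, h, w), dtype=DTYPE), requires_grad=True)

    def forward(self, x):
        x = position_encode(x, self.pos)
        q, k, v = tsac_project(x, self.w_q, self.w_k, self.w_v)
        ch = self.channels // self.n_heads
        d_k = ch
        outs = []
        for i in range(self.n_heads):
            sl = slice(i * ch, (i + 1) * ch)
            idx = (..., sl, slice(None))
            out, _ = tsac_attend(q[idx], k[idx], v[idx], d_k)
            outs.append(out)
        out = outs[0] if self.n_heads == 1 else concat(outs, axis=-2)
        out = self.w_out @ out
        return out.reshape(x.shape)


class GCAC(Module):
    """Position attention aggregating global context into local features."""

    def __init__(self, channels: int, rng: np.random.Generator):
        c1 = max(1, channels // 8)
        self.conv_v = Conv2d(channels, c1, 1, rng)
        self.conv_w = Conv2d(channels, c1, 1, rng)

    def forward(self, x):
        u, v, w = gcac_project(x, self.conv_v, self.conv_w)
        l_map = gcac_attention(v, w)
        return gcac_aggregate(l_map, u, out_shape=None).reshape(x.shape)


class MGAM(Module):
    """Attention bottleneck: identity at init (fusion scalars start at 0)."""

    def __init__(self, channels: int, spatial: tuple[int, int],
                 rng: np.random.Generator, n_heads: int = 1):
        self.tsac = TSAC(channels, spatial, rng, n_heads)
        self.gcac = GCAC(channels, rng)
        self.a1 = Tensor(np.zeros((), dtype=DTYPE), requires_grad=True)
        self.a2 = Tensor(np.zeros((), dtype=DTYPE), requires_grad=True)

    def set_fusion_weights(self, a1: float, a2: float) -> None:
        """Pin the fusion scalars (used by the alpha-grid experiment mode)."""
        self.a1.data = np.asarray(a1, dtype=DTYPE).reshape(())
        self.a2.data = np.asarray(a2, dtype=DTYPE).reshape(())

    def forward(self, x):
        return mgam_fuse(x, self.tsac(x), self.gcac(x), self.a1, self.a2)
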