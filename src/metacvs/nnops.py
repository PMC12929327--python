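"""Neural-network layers in functional style.

Parameters live in a flat ``dict[str, Tensor]`` keyed by dotted names; every
layer is a pure function of (params, inputs).  The flat dict is what makes
bi-level training straightforward: an adapted parameter set is just another
dict, and the network can be re-evaluated at any parameter point, including
points that are themselves differentiable graph nodes.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

Params = dict[str, Tensor]

LN_EPS = 1e-6


def trunc_normal(rng: np.random.Generator, shape, sd: float = 0.02) -> np.ndarray:
    """Normal(0, sd) clipped at two standard deviations."""
    return np.clip(rng.normal(0.0, sd, size=shape), -2 * sd, 2 * sd)


# ---------------------------------------------------------------------------
# linear / layernorm / mlp
# ---------------------------------------------------------------------------

def init_linear(params: Params, name: str, din: int, dout: int,
                rng: np.random.Generator) -> None:
    params[f"{name}.w"] = ad.parameter(trunc_normal(rng, (din, dout)), f"{name}.w")
    params[f"{name}.b"] = ad.parameter(np.zeros(dout), f"{name}.b")


def linear(params: Params, name: str, x: Tensor) -> Tensor:
    return ad.matmul(x, params[f"{name}.w"]) + params[f"{name}.b"]


def init_layernorm(params: Params, name: str, dim: int) -> None:
    params[f"{name}.g"] = ad.parameter(np.ones(dim), f"{name}.g")
    params[f"{name}.b"] = ad.parameter(np.zeros(dim), f"{name}.b")


def layernorm(params: Params, name: str, x: Tensor) -> Tensor:
    mu = ad.tmean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = ad.tmean(xc * xc, axis=-1, keepdims=True)
    xn = xc * ad.power(var + LN_EPS, -0.5)
    return xn * params[f"{name}.g"] + params[f"{name}.b"]


def init_mlp(params: Params, name: str, dim: int, hidden: int,
             rng: np.random.Generator) -> None:
    init_linear(params, f"{name}.fc1", dim, hidden, rng)
    init_linear(params, f"{name}.fc2", hidden, dim, rng)


def mlp(params: Params, name: str, x: Tensor) -> Tensor:
    return linear(params, f"{name}.fc2", ad.gelu(linear(params, f"{name}.fc1", x)))


# ---------------------------------------------------------------------------
# multi-head self-attention over the trailing (S, D) axes
# ---------------------------------------------------------------------------

def init_attention(params: Params, name: str, dim: int,
                   rng: np.random.Generator) -> None:
    init_linear(params, f"{name}.qkv", dim, 3 * dim, rng)
    init_linear(params, f"{name}.proj", dim, dim, rng)


def attention(params: Params, name: str, x: Tensor, n_heads: int,
              return_weights: bool = False):
    """Self-attention on a (..., S, D) tensor; leading axes are batch-like."""
    *lead, S, D = x.shape
    dh = D // n_heads
    qkv = linear(params, f"{name}.qkv", x)          # (..., S, 3D)
    qkv = ad.reshape(qkv, (*lead, S, 3, n_heads, dh))
    nl = len(lead)
    # -> (3, ..., heads, S, dh)
    perm = (nl + 1, *range(nl), nl + 2, nl, nl + 3)
    qkv = ad.transpose(qkv, perm)
    q, k, v = qkv[0], qkv[1], qkv[2]
    scores = ad.matmul(q, _swap(k)) * (1.0 / np.sqrt(dh))
    w = ad.softmax(scores, axis=-1)                 # (..., heads, S, S)
    out = ad.matmul(w, v)                           # (..., heads, S, dh)
    # -> (..., S, heads, dh) -> (..., S, D)
    perm_back = (*range(nl), nl + 1, nl, nl + 2)
    out = ad.reshape(ad.transpose(out, perm_back), (*lead, S, D))
    out = linear(params, f"{name}.proj", out)
    if return_weights:
        return out, w
    return out


def _swap(t: Tensor) -> Tensor:
    axes = list(range(t.ndim))
    axes[-1], axes[-2] = axes[-2], axes[-1]
    return ad.transpose(t, axes)


# ---------------------------------------------------------------------------
# convolution (via im2col) and bilinear upsampling
# ---------------------------------------------------------------------------

def init_conv(params: Params, name: str, cin: int, cout: int, k: int,
              rng: np.random.Generator) -> None:
    fan_in = cin * k * k
    sd = float(np.sqrt(2.0 / fan_in))
    w = np.clip(rng.normal(0.0, sd, size=(fan_in, cout)), -2 * sd, 2 * sd)
    params[f"{name}.w"] = ad.parameter(w, f"{name}.w")
    params[f"{name}.b"] = ad.parameter(np.zeros(cout), f"{name}.b")


def conv2d(params: Params, name: str, x: Tensor, k: int, stride: int = 1,
           pad: int = 0) -> Tensor:
    """x: (B, C, H, W) -> (B, Cout, OH, OW)."""
    B, C, H, W = x.shape
    xp = ad.pad2d(x, pad)
    cols = ad.im2col(xp, k, k, stride, stride)      # (B, OH*OW, C*k*k)
    y = ad.matmul(cols, params[f"{name}.w"]) + params[f"{name}.b"]
    oh = (H + 2 * pad - k) // stride + 1
    ow = (W + 2 * pad - k) // stride + 1
    cout = params[f"{name}.w"].shape[1]
    return ad.transpose(ad.reshape(y, (B, oh, ow, cout)), (0, 3, 1, 2))


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(h: int) -> np.ndarray:
    """(2h, h) bilinear interpolation matrix (half-pixel-centre convention)."""
    m = _UPSAMPLE_CACHE.get(h)
    if m is None:
        m = np.zeros((2 * h, h))
        for i in range(2 * h):
            src = (i + 0.5) / 2.0 - 0.5
            i0 = int(np.floor(src))
            w1 = src - i0
            i0c = min(max(i0, 0), h - 1)
            i1c = min(max(i0 + 1, 0), h - 1)
            m[i, i0c] += 1.0 - w1
            m[i, i1c] += w1
        _UPSAMPLE_CACHE[h] = m
    return m


def upsample2x(x: Tensor) -> Tensor:
    """Bilinear 2x upsampling of a (B, C, H, W) tensor."""
    B, C, H, W = x.shape
    mh = ad.astensor(_upsample_matrix(H))
    mw = ad.astensor(_upsample_matrix(W))
    y = ad.matmul(mh, x)                  # (B, C, 2H, W)
    return ad.matmul(y, ad.transpose(mw, (1, 0)))   # (B, C, 2H, 2W)


def upsample2x_nearest(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    y = ad.reshape(x, (B, C, H, 1, W, 1))
    ones = ad.astensor(np.ones((1, 1, 1, 2, 1, 2)))
    return ad.reshape(y * ones, (B, C, 2 * H, 2 * W))
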