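"""Video and last-frame encoders.

Two encoders share the "backbone" parameter group:

* a divided space-time attention transformer over the whole clip, yielding
  a clip-level class token for milestone classification.  Each block applies
  temporal attention (same spatial patch across frames), then spatial
  attention (patches within a frame, with the class token broadcast to every
  frame and averaged back), then an MLP, all pre-normalized with residuals.
  At T = 1 the temporal sub-attention is skipped (there is no temporal axis),
  which makes the block coincide with joint space-time attention.
* a hybrid CNN-transformer encoder over the last frame of the clip: a
  three-stage stride-2 convolutional stem whose intermediate features become
  decoder skip connections, followed by a transformer unit on a 1/16-scale
  token grid with a learned auxiliary class token prepended.

Parameter names are dotted and prefix-partitioned: ``backbone.*`` and
``auxenc.*`` belong to the shared group, ``auxtok.*`` (the auxiliary class
token) to the segmentation-specific group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nnops as nn
from .autodiff import Tensor
from .exceptions import ConfigError
from .nnops import Params


@dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters (defaults: the full-scale profile)."""

    frame_length: int = 6
    input_size: int = 224
    patch_size: int = 16
    embed_dim: int = 768
    n_layers: int = 12
    n_heads: int = 12
    mlp_ratio: float = 4.0
    # auxiliary (last-frame) encoder
    stem_channels: tuple[int, int, int] = (16, 32, 64)
    aux_embed_dim: int = 256
    aux_layers: int = 2
    aux_heads: int = 4
    # heads
    n_classes: int = 8              # mask labels incl. background
    cls_hidden: int | None = None   # None -> embed_dim // 2
    decoder_channels: int = 64
    upsample_mode: str = "bilinear"  # or "nearest"

    def __post_init__(self):
        if self.input_size % self.patch_size:
            raise ConfigError("input_size must be divisible by patch_size")
        if self.embed_dim % self.n_heads:
            raise ConfigError("embed_dim must be divisible by n_heads")
        if self.aux_embed_dim % self.aux_heads:
            raise ConfigError("aux_embed_dim must be divisible by aux_heads")
        if self.input_size % 16:
            raise ConfigError("input_size must be divisible by 16 (4 halvings)")
        if self.frame_length < 1:
            raise ConfigError("frame_length must be >= 1")

    @property
    def n_patches(self) -> int:
        return (self.input_size // self.patch_size) ** 2

    @property
    def token_count(self) -> int:
        """Patch tokens over the clip plus the class token."""
        return self.frame_length * self.n_patches + 1

    @property
    def bottleneck_grid(self) -> int:
        return self.input_size // 16

    @property
    def hidden_width(self) -> int:
        return self.cls_hidden if self.cls_hidden is not None else self.embed_dim // 2


def tiny_config(**over) -> NetConfig:
    """A desk-scale profile for tests and gradient checks."""
    base = dict(frame_length=2, input_size=16, patch_size=8, embed_dim=8,
                n_layers=1, n_heads=2, mlp_ratio=2.0, stem_channels=(4, 6, 8),
                aux_embed_dim=8, aux_layers=1, aux_heads=2, n_classes=3,
                decoder_channels=8)
    base.update(over)
    return NetConfig(**base)


@dataclass
class AuxEncoderOutput:
    """Multi-scale skip features, bottleneck tokens and the auxiliary token."""

    skips: list[Tensor]             # 1/2, 1/4, 1/8 resolution, CNN stem order
    grid_tokens: Tensor             # (B, G*G, D_aux)
    cls_token: Tensor               # (B, D_aux)
    grid: int


# ---------------------------------------------------------------------------
# initialisation
# ---------------------------------------------------------------------------

def init_video_encoder(params: Params, cfg: NetConfig,
                       rng: np.random.Generator) -> None:
    d = cfg.embed_dim
    patch_dim = 3 * cfg.patch_size ** 2
    nn.init_linear(params, "backbone.patch", patch_dim, d, rng)
    params["backbone.pos_spatial"] = ad.parameter(
        nn.trunc_normal(rng, (1, 1, cfg.n_patches, d)), "backbone.pos_spatial")
    params["backbone.pos_temporal"] = ad.parameter(
        nn.trunc_normal(rng, (1, cfg.frame_length, 1, d)), "backbone.pos_temporal")
    params["backbone.cls"] = ad.parameter(
        nn.trunc_normal(rng, (1, 1, d)), "backbone.cls")
    hidden = int(d * cfg.mlp_ratio)
    for i in range(cfg.n_layers):
        p = f"backbone.blk{i}"
        nn.init_layernorm(params, f"{p}.ln_t", d)
        nn.init_attention(params, f"{p}.attn_t", d, rng)
        nn.init_layernorm(params, f"{p}.ln_s", d)
        nn.init_attention(params, f"{p}.attn_s", d, rng)
        nn.init_layernorm(params, f"{p}.ln_m", d)
        nn.init_mlp(params, f"{p}.mlp", d, hidden, rng)
    nn.init_layernorm(params, "backbone.ln_f", d)


def init_aux_encoder(params: Params, cfg: NetConfig,
                     rng: np.random.Generator) -> None:
    c1, c2, c3 = cfg.stem_channels
    da = cfg.aux_embed_dim
    nn.init_conv(params, "auxenc.stem1", 3, c1, 3, rng)
    nn.init_conv(params, "auxenc.stem2", c1, c2, 3, rng)
    nn.init_conv(params, "auxenc.stem3", c2, c3, 3, rng)
    nn.init_conv(params, "auxenc.patch", c3, da, 2, rng)
    g2 = cfg.bottleneck_grid ** 2
    params["auxenc.pos"] = ad.parameter(
        nn.trunc_normal(rng, (1, g2 + 1, da)), "auxenc.pos")
    hidden = int(da * cfg.mlp_ratio)
    for i in range(cfg.aux_layers):
        p = f"auxenc.blk{i}"
        nn.init_layernorm(params, f"{p}.ln_a", da)
        nn.init_attention(params, f"{p}.attn", da, rng)
        nn.init_layernorm(params, f"{p}.ln_m", da)
        nn.init_mlp(params, f"{p}.mlp", da, hidden, rng)
    nn.init_layernorm(params, "auxenc.ln_f", da)
    # the auxiliary class token belongs to the segmentation-specific group
    params["auxtok.cls"] = ad.parameter(
        nn.trunc_normal(rng, (1, 1, da)), "auxtok.cls")


# ---------------------------------------------------------------------------
# forward passes
# ---------------------------------------------------------------------------

def _check_frames(cfg: NetConfig, shape, clip: bool) -> None:
    want = ((cfg.frame_length, cfg.input_size, cfg.input_size, 3) if clip
            else (cfg.input_size, cfg.input_size, 3))
    if tuple(shape[1:]) != want:
        raise ConfigError(f"input shaped {tuple(shape)}, expected (B, {want})")


def encode_clip(params: Params, cfg: NetConfig, frames) -> Tensor:
    """Class token (B, D) of a (B, T, H, W, 3) clip batch in [0, 1]."""
    frames = ad.astensor(frames)
    _check_frames(cfg, frames.shape, clip=True)
    B, T = frames.shape[0], cfg.frame_length
    p, d, nh = cfg.patch_size, cfg.embed_dim, cfg.n_heads
    x = ad.transpose(frames, (0, 1, 4, 2, 3))               # (B,T,3,H,W)
    x = ad.reshape(x, (B * T, 3, cfg.input_size, cfg.input_size))
    cols = ad.im2col(x, p, p, p, p)                         # (B*T, N, 3*p*p)
    tok = nn.linear(params, "backbone.patch", cols)
    tok = ad.reshape(tok, (B, T, cfg.n_patches, d))
    tok = tok + params["backbone.pos_spatial"] + params["backbone.pos_temporal"]
    cls = params["backbone.cls"] + ad.astensor(np.zeros((B, 1, 1)))

    for i in range(cfg.n_layers):
        pfx = f"backbone.blk{i}"
        if T > 1:
            zt = nn.layernorm(params, f"{pfx}.ln_t", tok)
            zt = ad.transpose(zt, (0, 2, 1, 3))             # (B,N,T,D)
            at = nn.attention(params, f"{pfx}.attn_t", zt, nh)
            tok = tok + ad.transpose(at, (0, 2, 1, 3))
        cls4 = ad.reshape(cls, (B, 1, 1, d)) + ad.astensor(np.zeros((1, T, 1, 1)))
        seq = ad.concat([cls4, tok], axis=2)                # (B,T,N+1,D)
        zs = nn.layernorm(params, f"{pfx}.ln_s", seq)
        as_ = nn.attention(params, f"{pfx}.attn_s", zs, nh)
        tok = tok + as_[:, :, 1:, :]
        cls = cls + ad.tmean(as_[:, :, 0:1, :], axis=1)     # average over frames
        tok = tok + nn.mlp(params, f"{pfx}.mlp",
                           nn.layernorm(params, f"{pfx}.ln_m", tok))
        cls = cls + nn.mlp(params, f"{pfx}.mlp",
                           nn.layernorm(params, f"{pfx}.ln_m", cls))

    out = nn.layernorm(params, "backbone.ln_f", cls)
    return ad.reshape(out, (B, d))


def encode_last_frame(params: Params, cfg: NetConfig, frame) -> AuxEncoderOutput:
    """Hybrid CNN-transformer encoding of a (B, H, W, 3) frame batch."""
    frame = ad.astensor(frame)
    _check_frames(cfg, frame.shape, clip=False)
    B = frame.shape[0]
    x = ad.transpose(frame, (0, 3, 1, 2))                   # (B,3,H,W)
    s1 = ad.relu(nn.conv2d(params, "auxenc.stem1", x, 3, stride=2, pad=1))
    s2 = ad.relu(nn.conv2d(params, "auxenc.stem2", s1, 3, stride=2, pad=1))
    s3 = ad.relu(nn.conv2d(params, "auxenc.stem3", s2, 3, stride=2, pad=1))
    emb = nn.conv2d(params, "auxenc.patch", s3, 2, stride=2)  # (B,Da,G,G)
    g, da = cfg.bottleneck_grid, cfg.aux_embed_dim
    tokens = ad.transpose(ad.reshape(emb, (B, da, g * g)), (0, 2, 1))
    cls = params["auxtok.cls"] + ad.astensor(np.zeros((B, 1, 1)))
    seq = ad.concat([cls, tokens], axis=1) + params["auxenc.pos"]
    for i in range(cfg.aux_layers):
        pfx = f"auxenc.blk{i}"
        seq = seq + nn.attention(params, f"{pfx}.attn",
                                 nn.layernorm(params, f"{pfx}.ln_a", seq),
                                 cfg.aux_heads)
        seq = seq + nn.mlp(params, f"{pfx}.mlp",
                           nn.layernorm(params, f"{pfx}.ln_m", seq))
    seq = nn.layernorm(params, "auxenc.ln_f", seq)
    return AuxEncoderOutput(skips=[s1, s2, s3], grid_tokens=seq[:, 1:, :],
                            cls_token=ad.reshape(seq[:, 0:1, :], (B, da)), grid=g)
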