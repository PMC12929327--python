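"""Task heads: milestone classification MLP and cascaded segmentation decoder.

The classifier concatenates the clip-level class token with the auxiliary
class token and maps it through a one-hidden-layer MLP to three logits, one
per milestone criterion.  The decoder reshapes the bottleneck token grid to
a feature map and restores full input resolution by stacked (2x upsample,
3x3 convolution, ReLU) blocks, concatenating the matching-scale CNN skip
feature before each convolution, with a final 1x1 projection to class
logits.  Parameter prefixes: ``head.*`` (classification), ``decoder.*``
(segmentation).
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nnops as nn
from .autodiff import Tensor
from .backbone import AuxEncoderOutput, NetConfig
from .exceptions import ConfigError
from .nnops import Params


def init_cls_head(params: Params, cfg: NetConfig, rng: np.random.Generator) -> None:
    din = cfg.embed_dim + cfg.aux_embed_dim
    nn.init_linear(params, "head.fc1", din, cfg.hidden_width, rng)
    nn.init_linear(params, "head.fc2", cfg.hidden_width, 3, rng)


def classify(params: Params, cfg: NetConfig, primary_token: Tensor,
             aux_token: Tensor) -> Tensor:
    """Three criterion logits (B, 3) from the concatenated class tokens."""
    if primary_token.shape[-1] != cfg.embed_dim:
        raise ConfigError(
            f"primary token dim {primary_token.shape[-1]} != {cfg.embed_dim}")
    if aux_token.shape[-1] != cfg.aux_embed_dim:
        raise ConfigError(
            f"aux token dim {aux_token.shape[-1]} != {cfg.aux_embed_dim}")
    z = ad.concat([primary_token, aux_token], axis=-1)
    h = ad.gelu(nn.linear(params, "head.fc1", z))
    return nn.linear(params, "head.fc2", h)


def init_decoder(params: Params, cfg: NetConfig, rng: np.random.Generator) -> None:
    c1, c2, c3 = cfg.stem_channels
    dc = cfg.decoder_channels
    ins = [cfg.aux_embed_dim + c3, dc + c2, dc + c1, dc]
    for i, cin in enumerate(ins):
        nn.init_conv(params, f"decoder.block{i}.conv", cin, dc, 3, rng)
    nn.init_conv(params, "decoder.out", dc, cfg.n_classes, 1, rng)


def decode_mask(params: Params, cfg: NetConfig, aux: AuxEncoderOutput) -> Tensor:
    """Per-pixel class logits (B, H, W, K) at full input resolution."""
    B = aux.grid_tokens.shape[0]
    g, da = aux.grid, cfg.aux_embed_dim
    if aux.grid_tokens.shape[1] != g * g:
        raise ConfigError("bottleneck token count does not match the grid")
    up = nn.upsample2x if cfg.upsample_mode == "bilinear" else nn.upsample2x_nearest
    x = ad.reshape(ad.transpose(aux.grid_tokens, (0, 2, 1)), (B, da, g, g))
    skips = [aux.skips[2], aux.skips[1], aux.skips[0], None]
    for i, skip in enumerate(skips):
        x = up(x)
        if skip is not None:
            if skip.shape[2] != x.shape[2]:
                raise ConfigError(
                    f"decoder stage {i}: skip at {skip.shape[2]} px does not "
                    f"match upsampled {x.shape[2]} px")
            x = ad.concat([x, skip], axis=1)
        x = ad.relu(nn.conv2d(params, f"decoder.block{i}.conv", x, 3, pad=1))
    logits = nn.conv2d(params, "decoder.out", x, 1)          # (B,K,H,W)
    return ad.transpose(logits, (0, 2, 3, 1))


def predict_mask(logits) -> np.ndarray:
    """Per-pixel argmax label map; exact ties go to the lowest class index."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    if not np.isfinite(arr).all():
        raise ValueError("non-finite segmentation logits")
    return np.argmax(arr, axis=-1).astype(np.int64)
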