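"""Whole-model assembly: initialisation, forward pass, parameter partition,
checkpoint serialisation."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .backbone import (AuxEncoderOutput, NetConfig, encode_clip,
                       encode_last_frame, init_aux_encoder, init_video_encoder)
from .exceptions import ConfigError
from .heads import classify, decode_mask, init_cls_head, init_decoder
from .nnops import Params

#: parameter-group membership by name prefix
_GROUP_PREFIXES = {
    "backbone.": "B", "auxenc.": "B",   # shared trunk
    "head.": "Pri",                     # classification head
    "decoder.": "Aux", "auxtok.": "Aux",  # segmentation decoder + aux token
}


def group_of(name: str) -> str:
    for pfx, grp in _GROUP_PREFIXES.items():
        if name.startswith(pfx):
            return grp
    raise ConfigError(f"parameter {name!r} belongs to no group")


def init_model(cfg: NetConfig, seed: int) -> Params:
    """All trainable weights, reproducibly initialised from the seed."""
    rng = np.random.default_rng(seed)
    params: Params = {}
    init_video_encoder(params, cfg, rng)
    init_aux_encoder(params, cfg, rng)
    init_cls_head(params, cfg, rng)
    init_decoder(params, cfg, rng)
    for name in params:
        group_of(name)  # every weight must be assigned to exactly one group
    return params


def forward(params: Params, cfg: NetConfig, frames,
            need_seg: bool = False):
    """Criterion logits and (optionally) segmentation logits for a clip batch.

    ``frames``: (B, T, H, W, 3) array in [0, 1].  The auxiliary branch always
    runs (its class token feeds the classifier); the decoder only runs when
    ``need_seg`` is set.
    """
    frames = ad.astensor(frames)
    cls = encode_clip(params, cfg, frames)
    last = frames[:, -1]
    aux = encode_last_frame(params, cfg, last)
    logits = classify(params, cfg, cls, aux.cls_token)
    seg = decode_mask(params, cfg, aux) if need_seg else None
    return logits, seg


def n_parameters(params: Params) -> int:
    return sum(int(p.size) for p in params.values())


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: Path, params: Params, cfg: NetConfig,
                    extra: dict | None = None) -> None:
    """Single-file checkpoint embedding the parameter-partition table."""
    meta = {
        "config": asdict(cfg),
        "partition": {name: group_of(name) for name in params},
        "extra": extra or {},
    }
    arrays = {f"param/{k}": v.data for k, v in params.items()}
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: Path) -> tuple[Params, NetConfig, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg_d = meta["config"]
        cfg_d["stem_channels"] = tuple(cfg_d["stem_channels"])
        cfg = NetConfig(**cfg_d)
        params: Params = {}
        for key in z.files:
            if key.startswith("param/"):
                name = key[len("param/"):]
                params[name] = ad.parameter(z[key], name)
    return params, cfg, meta.get("extra", {})
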