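"""YAML run configuration: strict schema, defaults, and frozen copies.

A run config has nested blocks ``synthetic``, ``model``, ``loss``, ``meta``
and ``eval``; unknown keys anywhere are rejected.  The resolved config can
be written back next to run outputs so every run is reproducible from its
frozen copy plus the seed.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .backbone import NetConfig
from .dataset_io import AnatomyOntology, MT_CVS_ONTOLOGY, REDUCED_ONTOLOGY, TOY_ONTOLOGY
from .exceptions import ConfigError
from .losses import LossWeights
from .meta import MetaConfig
from .synthetic import SceneConfig

_ONTOLOGIES = {"toy": TOY_ONTOLOGY, "mt_cvs": MT_CVS_ONTOLOGY,
               "reduced": REDUCED_ONTOLOGY}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticBlock(_Strict):
    image_size: tuple[int, int] = (32, 32)
    n_procedures: int = 50
    frames_per_procedure: int = 10
    dual_label_fraction: float = 0.2
    drift_px_per_frame: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0
    event_prob: float = 0.9
    gap_event_prob: float = 0.7
    distractor_prob: float = 0.0

    def to_scene_config(self) -> SceneConfig:
        return SceneConfig(image_size=tuple(self.image_size),
                           n_procedures=self.n_procedures,
                           frames_per_procedure=self.frames_per_procedure,
                           dual_label_fraction=self.dual_label_fraction,
                           drift_px_per_frame=self.drift_px_per_frame,
                           noise_sd=self.noise_sd, seed=self.seed,
                           event_prob=self.event_prob,
                           gap_event_prob=self.gap_event_prob,
                           distractor_prob=self.distractor_prob)


class ModelBlock(_Strict):
    frame_length: int = 4
    input_size: int = 32
    patch_size: int = 8
    embed_dim: int = 32
    n_layers: int = 1
    n_heads: int = 4
    mlp_ratio: float = 2.0
    stem_channels: tuple[int, int, int] = (8, 16, 32)
    aux_embed_dim: int = 32
    aux_layers: int = 1
    aux_heads: int = 4
    n_classes: int = 4
    cls_hidden: int | None = None
    decoder_channels: int = 24
    upsample_mode: str = "bilinear"

    def to_net_config(self) -> NetConfig:
        return NetConfig(**self.model_dump())


class LossBlock(_Strict):
    w_pri: float = 0.9
    w_aux: float = 0.1
    focal_gamma: float = 2.0

    def to_loss_weights(self) -> LossWeights:
        return LossWeights(**self.model_dump())


class MetaBlock(_Strict):
    alpha_l: float = 0.1
    alpha_g: float = 1e-3
    m: int = 10
    n: int = 6
    inner_steps: int = 1
    gradient_mode: str = "first_order"
    epochs: int = 25
    seed: int = 0
    optimizer: str = "adam"
    weight_decay: float = 0.0
    augment: bool = True
    lr_schedule: str = "cosine"
    clip_norm: float | None = 5.0
    eval_every: int | None = 200
    outer_base: str = "theta_tilde"
    checkpoint_every: int | None = None


class EvalBlock(_Strict):
    threshold: float = 0.5
    achievement_mode: str = "all"
    ontology: str = "toy"

    def to_ontology(self) -> AnatomyOntology:
        if self.ontology not in _ONTOLOGIES:
            raise ConfigError(
                f"unknown ontology {self.ontology!r}; options: {sorted(_ONTOLOGIES)}")
        return _ONTOLOGIES[self.ontology]


class RunConfig(_Strict):
    synthetic: SyntheticBlock = SyntheticBlock()
    model: ModelBlock = ModelBlock()
    loss: LossBlock = LossBlock()
    meta: MetaBlock = MetaBlock()
    eval: EvalBlock = EvalBlock()
    precision: str = "float32"      # working dtype for training/inference

    def apply_precision(self) -> None:
        import numpy as np

        from . import autodiff as ad
        if self.precision not in ("float32", "float64"):
            raise ConfigError(f"unknown precision {self.precision!r}")
        ad.set_default_dtype(getattr(np, self.precision))

    def to_meta_config(self) -> MetaConfig:
        return MetaConfig(loss_weights=self.loss.to_loss_weights(),
                          **self.meta.model_dump())


def load_config(path: Path | None = None,
                overrides: list[str] | None = None) -> RunConfig:
    """Load a YAML config (defaults when None) and apply dot-path overrides
    like ``meta.alpha_l=0.2``."""
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
    for ov in overrides or []:
        if "=" not in ov:
            raise ConfigError(f"override {ov!r} must look like key.path=value")
        keypath, raw = ov.split("=", 1)
        node = data
        keys = keypath.split(".")
        for k in keys[:-1]:
            node = node.setdefault(k, {})
            if not isinstance(node, dict):
                raise ConfigError(f"override {ov!r} descends into a non-mapping")
        node[keys[-1]] = yaml.safe_load(raw)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def freeze_config(cfg: RunConfig, path: Path) -> None:
    """Write the fully resolved config next to run outputs (round-trips)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.model_dump(), fh, sort_keys=True)
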