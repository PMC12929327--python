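"""Model/Results interface over the training machinery.

``MetaAuxiliaryModel`` is constructed from clip data (or a manifest) plus an
architecture config; ``fit`` runs either meta-auxiliary training or the
single-level joint baseline and returns a ``MetaAuxiliaryResults`` carrying
the fitted parameters, loss traces, prediction and evaluation methods and a
``summary()`` table.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from . import autodiff as ad
from .backbone import NetConfig
from .dataset_io import (AnatomyOntology, LabeledFrameClip, SplitAssignment,
                         TOY_ONTOLOGY, filter_by_split, load_manifest,
                         make_clips, split_by_procedure)
from .evaluation import EvalReport, build_report
from .exceptions import ConfigError
from .heads import predict_mask
from .meta import MetaConfig, ParamPartition, TrainState, train, train_joint_baseline
from .network import forward, load_checkpoint, n_parameters


class MetaAuxiliaryModel:
    """Dual-task milestone classifier with an auxiliary segmentation branch.

    Parameters
    ----------
    train_clips, val_clips : lists of LabeledFrameClip
        Training pool (mixed dual-labeled and primary-only) and an optional
        held-out pool used only for reporting.
    net_config : NetConfig
        Architecture profile; its ``n_classes`` must cover the ontology.
    ontology : AnatomyOntology
        Mask label semantics, used by evaluation.
    """

    def __init__(self, train_clips: list[LabeledFrameClip],
                 val_clips: list[LabeledFrameClip] | None = None,
                 net_config: NetConfig | None = None,
                 ontology: AnatomyOntology = TOY_ONTOLOGY):
        self.net_config = net_config or NetConfig()
        if self.net_config.n_classes < ontology.n_labels:
            raise ConfigError(
                f"model has {self.net_config.n_classes} mask classes but the "
                f"ontology needs {ontology.n_labels}")
        self.train_clips = train_clips
        self.val_clips = val_clips or []
        self.ontology = ontology

    @classmethod
    def from_manifest(cls, manifest_path: Path, ontology: AnatomyOntology,
                      net_config: NetConfig, split_seed: int = 0,
                      assignment: SplitAssignment | None = None,
                      pad_mode: str = "skip") -> "MetaAuxiliaryModel":
        """Build train/val pools from an on-disk dataset, splitting by
        procedure (7:1:2)."""
        records = load_manifest(manifest_path, ontology)
        if assignment is None:
            assignment = split_by_procedure(records, split_seed)
        clips = make_clips(records, net_config.frame_length,
                           image_size=net_config.input_size, pad_mode=pad_mode)
        model = cls(filter_by_split(clips, assignment, "train"),
                    filter_by_split(clips, assignment, "val"),
                    net_config, ontology)
        model.assignment = assignment
        model.all_clips = clips
        return model

    def fit(self, meta_config: MetaConfig | None = None, method: str = "meta",
            steps: int | None = None, out_dir: Path | None = None,
            log_hook=None) -> "MetaAuxiliaryResults":
        """Train and return a results object.

        ``method="meta"`` runs bi-level meta-auxiliary training;
        ``method="joint"`` the single-level dual-task baseline on
        dual-labeled clips only.
        """
        cfg = meta_config or MetaConfig()
        val = self.val_clips if cfg.eval_every else None
        if method == "meta":
            state = train(self.train_clips, self.net_config, cfg, steps=steps,
                          out_dir=out_dir, log_hook=log_hook, val_clips=val)
        elif method == "joint":
            state = train_joint_baseline(self.train_clips, self.net_config,
                                         cfg, steps=steps, out_dir=out_dir,
                                         log_hook=log_hook, val_clips=val)
        else:
            raise ConfigError(f"unknown method {method!r}")
        return MetaAuxiliaryResults(self, state, method)


class MetaAuxiliaryResults:
    """Fitted parameters plus prediction, evaluation and reporting."""

    def __init__(self, model: MetaAuxiliaryModel, state: TrainState,
                 method: str = "meta"):
        self.model = model
        self.state = state
        self.method = method

    # -- accessors ----------------------------------------------------
    @property
    def params(self):
        return self.state.params

    @property
    def partition(self) -> ParamPartition:
        return ParamPartition(self.state.params)

    @property
    def history(self) -> list[dict]:
        return self.state.history

    def loss_trace(self, key: str = "L_Pri_outer") -> np.ndarray:
        return np.array([h[key] for h in self.history])

    # -- inference ----------------------------------------------------
    def predict(self, clips: list[LabeledFrameClip], batch_size: int = 16,
                need_seg: bool = False):
        """Criterion probabilities (N, 3) and, if asked, predicted label maps."""
        probs, masks = [], []
        with ad.no_grad():
            for i in range(0, len(clips), batch_size):
                chunk = clips[i:i + batch_size]
                frames = np.stack([c.frames for c in chunk])
                logits, seg = forward(self.params, self.model.net_config,
                                      frames, need_seg=need_seg)
                probs.append(1.0 / (1.0 + np.exp(-logits.data)))
                if need_seg:
                    masks.extend(predict_mask(seg))
        return np.concatenate(probs), masks

    def evaluate(self, clips: list[LabeledFrameClip] | None = None,
                 threshold: float = 0.5, mode: str = "all") -> EvalReport:
        """Full report on a clip list (default: the model's validation pool).

        Segmentation metrics are computed on the clips that carry masks;
        classification metrics on all clips.
        """
        clips = clips if clips is not None else self.model.val_clips
        probs, _ = self.predict(clips)
        labels = np.array([c.criteria for c in clips])
        dual = [c for c in clips if c.is_dual]
        pred_maps, true_maps = [], []
        if dual:
            _, pred_maps = self.predict(dual, need_seg=True)
            true_maps = [c.mask for c in dual]
        return build_report(probs, labels, pred_maps, true_maps,
                            self.model.ontology, threshold, mode)

    # -- reporting / persistence --------------------------------------
    def summary(self, report: EvalReport | None = None) -> str:
        cfg, mcfg = self.model.net_config, self.state.meta_cfg
        counts = self.partition.counts()
        lines = [
            "Meta-auxiliary dual-task model",
            "=" * 46,
            f"method:            {self.method}",
            f"frame length T:    {cfg.frame_length}   input: {cfg.input_size}px"
            f"   patch: {cfg.patch_size}px",
            f"embed dim:         {cfg.embed_dim} ({cfg.n_layers} layers, "
            f"{cfg.n_heads} heads)",
            f"parameters:        {n_parameters(self.params)} "
            f"(shared {counts['B']}, primary {counts['Pri']}, aux {counts['Aux']})",
            f"steps trained:     {self.state.step}",
            f"alpha_l / alpha_g: {mcfg.alpha_l} / {mcfg.alpha_g}"
            f"   m:n = {mcfg.m}:{mcfg.n}   mode: {mcfg.gradient_mode}",
        ]
        if self.history:
            lines.append(f"final L_Pri:       {self.history[-1]['L_Pri_outer']:.4f}")
        if report is not None:
            lines += [
                "-" * 46,
                f"criterion accuracy: C1 {report.acc_c1:.3f}  "
                f"C2 {report.acc_c2:.3f}  C3 {report.acc_c3:.3f}",
                f"achievement:        P {report.precision:.3f}  "
                f"R {report.recall:.3f}  F1 {report.f1:.3f}",
                f"segmentation:       mIOU {report.miou:.3f}  "
                f"Dice {report.dice:.3f}",
            ]
        return "\n".join(lines)

    def save(self, path: Path) -> None:
        self.state.save(path)

    @classmethod
    def from_checkpoint(cls, path: Path, train_clips=None, val_clips=None,
                        ontology: AnatomyOntology = TOY_ONTOLOGY
                        ) -> "MetaAuxiliaryResults":
        params, net_cfg, extra = load_checkpoint(path)
        model = MetaAuxiliaryModel(train_clips or [], val_clips, net_cfg, ontology)
        state = TrainState(params, net_cfg, MetaConfig(),
                           step=extra.get("step", 0),
                           history=extra.get("history", []))
        return cls(model, state)
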