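"""Synthetic toy "procedures" with pixel-exact masks and geometry-derived labels.

Each procedure is a short 1 fps sequence of a drifting scene built from
anatomy-like shapes on a textured background:

* ``organA`` — a large disk (liver analogue),
* ``organB`` — a medium disk (gallbladder analogue), possibly overlapping
  organA, drawn on top of it,
* ``ductC`` — thin capsule-shaped structures, some attached to organB's
  boundary, optionally one detached distractor elsewhere.

The three milestone criteria are structural analogues of the clinical ones
and are *recomputed from the rasterized mask of every frame*:

* C1 (separation): the minimum pixel distance between organA and organB
  exceeds a clearance threshold.
* C2 (exposure): the fraction of organB's boundary lying within a contact
  tolerance of organA is below a maximum-contact threshold.
* C3 (counting): exactly two ductC connected components touch organB.

Because labels are derived from the emitted mask, segmentation is genuinely
informative for classification — the structural premise of the auxiliary
design.  Scenes are sampled per procedure in crisp regimes (well separated /
lightly touching / deeply overlapping; 1–3 attached ducts), drift rigidly
between frames, and may undergo at most discrete mid-procedure regime
events, so borderline label flips are rare by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .dataset_io import TOY_ONTOLOGY, AnatomyOntology, FrameRecord
from .exceptions import ConfigError

# label values in the toy ontology
BG, ORGAN_A, ORGAN_B, DUCT_C = 0, 1, 2, 3


@dataclass(frozen=True)
class SceneConfig:
    """Generator configuration; defaults are the package's study conditions."""

    image_size: tuple[int, int] = (32, 32)
    ontology: AnatomyOntology = TOY_ONTOLOGY
    n_procedures: int = 50
    frames_per_procedure: int = 10
    #: fraction of frames carrying a mask (the clinical dataset the method
    #: targets has roughly one mask per five milestone labels)
    dual_label_fraction: float = 0.2
    drift_px_per_frame: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0
    #: probability of one discrete duct attach/detach event per procedure
    event_prob: float = 0.9
    #: probability of one discrete separation-regime switch per procedure
    gap_event_prob: float = 0.7
    #: probability of a detached duct-like distractor floating beside organA
    distractor_prob: float = 0.0
    # criteria thresholds (pixels; tuned to the default 32 px scenes)
    c1_clearance_px: float = 2.1
    c2_contact_tol_px: float = 2.0
    c2_max_contact_frac: float = 0.40
    c3_touch_tol_px: float = 1.6

    def __post_init__(self):
        if not (0.0 < self.dual_label_fraction <= 1.0):
            raise ConfigError(
                f"dual_label_fraction must be in (0, 1], got {self.dual_label_fraction}")
        if not (0.0 <= self.noise_sd <= 0.5):
            raise ConfigError(f"noise_sd must be in [0, 0.5], got {self.noise_sd}")
        if self.n_procedures < 1 or self.frames_per_procedure < 1:
            raise ConfigError("need at least one procedure and one frame")
        total = self.n_procedures * self.frames_per_procedure
        if round(self.dual_label_fraction * total) < 1:
            raise ConfigError("dual_label_fraction too small: no masked frame")


@dataclass
class Duct:
    """Thin capsule: segment p0-p1 with a stroke width."""

    p0: np.ndarray
    p1: np.ndarray
    width: float


@dataclass
class SceneState:
    """Full geometry of one frame; criteria derive from it deterministically."""

    organ_a_center: np.ndarray
    organ_a_radius: float
    organ_b_center: np.ndarray
    organ_b_radius: float
    ducts: list[Duct]
    criteria: tuple[bool, bool, bool] | None = None


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize(state: SceneState, image_size: tuple[int, int]) -> np.ndarray:
    """Indexed label map; later shapes overwrite earlier (ducts on top)."""
    h, w = image_size
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=np.int64)
    ca, cb = state.organ_a_center, state.organ_b_center
    mask[(rr - ca[0]) ** 2 + (cc - ca[1]) ** 2 <= state.organ_a_radius ** 2] = ORGAN_A
    mask[(rr - cb[0]) ** 2 + (cc - cb[1]) ** 2 <= state.organ_b_radius ** 2] = ORGAN_B
    pts = np.stack([rr, cc], axis=-1).astype(float)
    for d in state.ducts:
        mask[_segment_distance(pts, d.p0, d.p1) <= d.width / 2.0] = DUCT_C
    return mask


def _segment_distance(pts: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> np.ndarray:
    seg = p1 - p0
    L2 = float(seg @ seg)
    if L2 == 0.0:
        return np.linalg.norm(pts - p0, axis=-1)
    t = np.clip(((pts - p0) @ seg) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * seg
    return np.linalg.norm(pts - proj, axis=-1)


# ---------------------------------------------------------------------------
# criteria
# ---------------------------------------------------------------------------

def criteria_from_mask(mask: np.ndarray, cfg: SceneConfig) -> tuple[bool, bool, bool]:
    """The three milestone predicates evaluated on a label map."""
    a = mask == ORGAN_A
    b = mask == ORGAN_B
    ducts = mask == DUCT_C
    if not a.any() or not b.any():
        return (False, False, False)
    # distance from every pixel to the nearest organA pixel
    dist_a = ndimage.distance_transform_edt(~a)
    c1 = bool(dist_a[b].min() > cfg.c1_clearance_px)
    # organB boundary: organB pixels 4-adjacent to a non-organB pixel
    eroded = ndimage.binary_erosion(b, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]), border_value=0)
    boundary = b & ~eroded
    contact = float((dist_a[boundary] <= cfg.c2_contact_tol_px).mean())
    c2 = bool(contact < cfg.c2_max_contact_frac)
    # connected ductC components touching organB
    dist_b = ndimage.distance_transform_edt(~b)
    labels, n_comp = ndimage.label(ducts, structure=np.ones((3, 3), dtype=int))
    touching = sum(
        1 for k in range(1, n_comp + 1)
        if dist_b[labels == k].min() <= cfg.c3_touch_tol_px)
    c3 = touching == 2
    return (c1, c2, c3)


def derive_criteria(state: SceneState, cfg: SceneConfig) -> tuple[bool, bool, bool]:
    """Criteria of a scene: pure function of geometry via its rasterization."""
    return criteria_from_mask(rasterize(state, cfg.image_size), cfg)


# ---------------------------------------------------------------------------
# procedure scripting
# ---------------------------------------------------------------------------

@dataclass
class _Geometry:
    """Per-procedure base geometry in assembly coordinates (organA at origin)."""

    r_a: float
    r_b: float
    gap: float                      # organA-organB boundary gap (negative: overlap)
    scale: float                    # image scale factor (min dimension / 32)
    axis_angle: float               # direction organA -> organB
    duct_angles: list[float]        # attach angles relative to B->A axis
    duct_len: float
    duct_width: float
    attached: list[bool]
    has_detached: bool
    detached_offset: np.ndarray     # relative to organA centre


def _build_state(g: _Geometry, origin: np.ndarray) -> SceneState:
    ca = origin
    u = np.array([np.sin(g.axis_angle), np.cos(g.axis_angle)])
    cb = ca + (g.r_a + g.r_b + g.gap) * u
    ducts: list[Duct] = []
    for ang, att in zip(g.duct_angles, g.attached):
        if not att:
            continue
        # radial capsule rooted at organB's boundary (roots stay disjoint)
        theta = g.axis_angle + np.pi + ang      # direction B -> outward
        v = np.array([np.sin(theta), np.cos(theta)])
        p0 = cb + (g.r_b + 0.2) * v
        p1 = cb + (g.r_b + 0.2 + g.duct_len) * v
        ducts.append(Duct(p0, p1, g.duct_width))
    if g.has_detached:
        # a detached duct-like distractor lies alongside organA
        base = ca + g.detached_offset
        half = 0.5 * g.duct_len * u
        ducts.append(Duct(base - half, base + half, g.duct_width))
    return SceneState(ca, g.r_a, cb, g.r_b, ducts)


_SEP_REGIMES = ("separated", "light", "heavy")


_MAX_SEP_GAP = 4.0


def _sample_gap(regime: str, r_b: float, rng: np.random.Generator) -> float:
    if regime == "separated":
        return float(rng.uniform(3.0, _MAX_SEP_GAP))
    if regime == "light":
        return float(rng.uniform(0.15, 0.7))
    return float(-rng.uniform(1.0, 1.3) * r_b)


def _sample_geometry(cfg: SceneConfig, rng: np.random.Generator) -> _Geometry:
    s = min(cfg.image_size)
    if s < 28:
        raise ConfigError(f"image_size {cfg.image_size} too small for the scenes")
    scale = s / 32.0
    for _ in range(64):
        r_a = rng.uniform(4.8, 5.6) * scale
        r_b = rng.uniform(2.8, 3.4) * scale
        regime = rng.choice(_SEP_REGIMES, p=[0.4, 0.3, 0.3])
        gap = _sample_gap(regime, r_b / scale, rng) * scale
        k_touch = int(rng.choice([1, 2], p=[0.5, 0.5]))
        duct_len = 3.4 * scale
        duct_width = max(2.0, 2.0 * scale)
        # attach angles away from the organA side, mutually separated
        angles = _spread_angles(k_touch, rng)
        has_detached = bool(rng.random() < cfg.distractor_prob)
        axis_angle = rng.uniform(0, 2 * np.pi)
        # distractor beside organA, perpendicular to the organA->organB axis
        det_r = r_a + rng.uniform(1.8, 2.6) * scale
        side = 1.0 if rng.random() < 0.5 else -1.0
        perp = np.array([np.sin(axis_angle + side * np.pi / 2),
                         np.cos(axis_angle + side * np.pi / 2)])
        detached_offset = det_r * perp
        g = _Geometry(r_a, r_b, gap, scale, axis_angle, angles, duct_len,
                      duct_width, [True] * k_touch, has_detached, detached_offset)
        if _fits(g, cfg.image_size) and _detached_clear(g):
            return g
    raise ConfigError("could not fit a scene into the configured image size")


def _spread_angles(k: int, rng: np.random.Generator) -> list[float]:
    """k angles at least 0.9 rad off the B->A axis and >= 1.2 rad apart."""
    for _ in range(200):
        raw = sorted(rng.uniform(0.9, 2 * np.pi - 0.9, size=k))
        gaps = np.diff(raw + [raw[0] + 2 * np.pi]) if k > 1 else [2 * np.pi]
        if min(gaps) >= 1.2:
            return [float(a) for a in raw]
    return [0.9 + i * (2 * np.pi - 1.8) / max(k, 1) for i in range(k)]


def _worst_case_states(g: _Geometry) -> list[SceneState]:
    """Assembly at the origin under every regime, everything rendered."""
    states = []
    for gap in (_MAX_SEP_GAP * g.scale, 0.7 * g.scale, -1.3 * g.r_b):
        gg = replace(g, gap=gap, has_detached=True)
        states.append(_build_state(gg, np.zeros(2)))
    return states


def _extents(g: _Geometry) -> tuple[float, float, float, float]:
    """Bounding box (rmin, rmax, cmin, cmax) relative to the assembly origin."""
    lo = np.full(2, np.inf)
    hi = np.full(2, -np.inf)
    for st in _worst_case_states(g):
        pts = [st.organ_a_center - st.organ_a_radius,
               st.organ_a_center + st.organ_a_radius,
               st.organ_b_center - st.organ_b_radius,
               st.organ_b_center + st.organ_b_radius]
        for d in st.ducts:
            pts += [d.p0 - d.width / 2, d.p0 + d.width / 2,
                    d.p1 - d.width / 2, d.p1 + d.width / 2]
        arr = np.stack(pts)
        lo = np.minimum(lo, arr.min(axis=0))
        hi = np.maximum(hi, arr.max(axis=0))
    return float(lo[0]), float(hi[0]), float(lo[1]), float(hi[1])


def _fits(g: _Geometry, image_size: tuple[int, int]) -> bool:
    rmin, rmax, cmin, cmax = _extents(g)
    h, w = image_size
    return (rmax - rmin) <= h - 2.5 and (cmax - cmin) <= w - 2.5


def _detached_clear(g: _Geometry) -> bool:
    """Detached duct must never count as touching organB, in any regime."""
    for gap in (_MAX_SEP_GAP * g.scale, 0.7 * g.scale, -1.3 * g.r_b):
        gg = replace(g, gap=gap, attached=[False] * len(g.attached),
                     has_detached=True)
        st = _build_state(gg, np.zeros(2))
        cb, rb = st.organ_b_center, st.organ_b_radius
        for d in st.ducts:
            dmin = min(np.linalg.norm(d.p0 - cb), np.linalg.norm(d.p1 - cb))
            # coarse segment-to-circle clearance check
            mid = 0.5 * (d.p0 + d.p1)
            dmin = min(dmin, float(np.linalg.norm(mid - cb)))
            if dmin - rb - d.width / 2 < 4.0:
                return False
    return True


def procedure_states(cfg: SceneConfig, proc_idx: int) -> list[SceneState]:
    """Scripted scene states of one procedure (rigid drift + discrete events)."""
    rng = np.random.default_rng([cfg.seed, proc_idx])
    g = _sample_geometry(cfg, rng)
    s = min(cfg.image_size)
    h, w = cfg.image_size
    rmin, rmax, cmin, cmax = _extents(g)
    lo = np.array([-rmin + 0.75, -cmin + 0.75])
    hi = np.array([h - 1 - rmax - 0.75, w - 1 - cmax - 0.75])
    hi = np.maximum(lo, hi)
    pos = np.clip(rng.uniform(lo, hi + 1e-9, size=2), lo, hi)
    ang = rng.uniform(0, 2 * np.pi)
    vel = cfg.drift_px_per_frame * np.array([np.sin(ang), np.cos(ang)])

    n = cfg.frames_per_procedure
    duct_event = gap_event = -1
    if n >= 6 and rng.random() < cfg.event_prob:
        duct_event = int(rng.integers(2, n - 2))
    if n >= 6 and rng.random() < cfg.gap_event_prob:
        gap_event = int(rng.integers(2, n - 2))
    regime = _current_regime(g)
    states: list[SceneState] = []
    for t in range(n):
        if t == duct_event:
            g = _toggle_duct(g, rng)
        if t == gap_event:
            new_regime = rng.choice([r for r in _SEP_REGIMES if r != regime])
            g = replace(g, gap=_sample_gap(str(new_regime), g.r_b, rng) * (s / 32.0))
            regime = str(new_regime)
        st = _build_state(g, pos.copy())
        st.criteria = derive_criteria(st, cfg)
        states.append(st)
        pos = pos + vel
        for k in range(2):
            if pos[k] < lo[k]:
                pos[k] = 2 * lo[k] - pos[k]
                vel[k] = -vel[k]
            if pos[k] > hi[k] and hi[k] > lo[k]:
                pos[k] = 2 * hi[k] - pos[k]
                vel[k] = -vel[k]
        pos = np.clip(pos, lo, np.maximum(lo, hi))
    return states


def _current_regime(g: _Geometry) -> str:
    if g.gap >= 2.5:
        return "separated"
    if g.gap >= -0.5 * g.r_b:
        return "light"
    return "heavy"


def _toggle_duct(g: _Geometry, rng: np.random.Generator) -> _Geometry:
    att = list(g.attached)
    if all(att) and len(att) < 2 and rng.random() < 0.5:
        att.append(True)
        return replace(g, attached=att,
                       duct_angles=g.duct_angles + _spread_angles(1, rng))
    idx = [i for i, a in enumerate(att) if a]
    if idx:
        att[idx[int(rng.integers(len(idx)))]] = False
    return replace(g, attached=att)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BASE_COLORS = {
    ORGAN_A: np.array([0.55, 0.25, 0.25]),
    ORGAN_B: np.array([0.30, 0.55, 0.30]),
    DUCT_C: np.array([0.80, 0.75, 0.30]),
}


def _background_texture(shape, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency texture so intensities are not constant."""
    h, w = shape
    coarse = rng.uniform(0.05, 0.28, size=(4, 4, 3))
    img = np.asarray(Image.fromarray(
        (coarse * 255).astype(np.uint8)).resize((w, h), Image.BILINEAR))
    return img.astype(np.float64) / 255.0


def render_frame(mask: np.ndarray, texture: np.ndarray,
                 colors: dict[int, np.ndarray], noise_sd: float,
                 rng: np.random.Generator) -> np.ndarray:
    img = texture.copy()
    for label, col in colors.items():
        img[mask == label] = col
    img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------

def generate_dataset(cfg: SceneConfig, out_dir: Path) -> list[FrameRecord]:
    """Write images, indexed-PNG masks and the CSV manifest; return records.

    Exactly round(dual_label_fraction x total frames) frames carry masks,
    chosen deterministically from the seed.  Identical configs produce
    byte-identical output.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)

    total = cfg.n_procedures * cfg.frames_per_procedure
    sel_rng = np.random.default_rng([cfg.seed, 999983])
    n_dual = int(round(cfg.dual_label_fraction * total))
    dual_idx = set(sel_rng.choice(total, size=n_dual, replace=False).tolist())

    rows = []
    records: list[FrameRecord] = []
    flat = 0
    for p in range(cfg.n_procedures):
        pid = f"proc{p:03d}"
        prng = np.random.default_rng([cfg.seed, p, 7])
        texture = _background_texture(cfg.image_size, prng)
        colors = _BASE_COLORS
        for t, state in enumerate(procedure_states(cfg, p)):
            mask = rasterize(state, cfg.image_size)
            img = render_frame(mask, texture, colors, cfg.noise_sd, prng)
            img_rel = f"images/{pid}_t{t:03d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / img_rel)
            mask_rel = ""
            mask_path = None
            if flat in dual_idx:
                mask_rel = f"masks/{pid}_t{t:03d}.png"
                Image.fromarray(mask.astype(np.uint8), mode="L").save(out_dir / mask_rel)
                mask_path = out_dir / mask_rel
            c1, c2, c3 = state.criteria
            rows.append({"procedure_id": pid, "timestamp_s": t, "image": img_rel,
                         "mask": mask_rel, "c1": int(c1), "c2": int(c2), "c3": int(c3)})
            records.append(FrameRecord(pid, t, out_dir / img_rel, mask_path,
                                       (c1, c2, c3)))
            flat += 1
    pd.DataFrame(rows, columns=["procedure_id", "timestamp_s", "image", "mask",
                                "c1", "c2", "c3"]).to_csv(
        out_dir / "manifest.csv", index=False)
    return records
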