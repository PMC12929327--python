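"""On-disk dataset schema, manifest parsing, splitting and batch assembly.

A dataset is a directory of RGB frame images sampled at 1 fps, optional
indexed-PNG anatomy masks for a subset of frames ("dual-labeled" frames),
and a flat CSV manifest with one row per frame:

    procedure_id,timestamp_s,image,mask,c1,c2,c3

``mask`` may be empty (frame carries only the milestone labels); ``c1..c3``
are the three binary milestone criteria for that frame.  Paths are relative
to the manifest's directory.  Splitting is by procedure so that no procedure
contributes frames to more than one of train/val/test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .exceptions import ConfigError, DataError

MANIFEST_COLUMNS = ["procedure_id", "timestamp_s", "image", "mask", "c1", "c2", "c3"]

SPLIT_FRACTIONS = {"train": 0.7, "val": 0.1, "test": 0.2}
SPLIT_ORDER = ["train", "val", "test"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnatomyOntology:
    """Ordered anatomy classes; pixel value 0 is always background."""

    class_names: tuple[str, ...]
    background_index: int = 0

    def __post_init__(self):
        if len(set(self.class_names)) != len(self.class_names):
            raise ConfigError("ontology class names must be unique")
        if self.background_index != 0:
            raise ConfigError("background index must be 0")

    @property
    def n_labels(self) -> int:
        """Number of mask label values, background included."""
        return len(self.class_names) + 1

    def label_name(self, idx: int) -> str:
        return "background" if idx == 0 else self.class_names[idx - 1]


#: full ontology of the clinical dataset: 4 major + 3 peripheral anatomies
MT_CVS_ONTOLOGY = AnatomyOntology((
    "liver", "gallbladder", "cystic_duct", "cystic_artery",
    "common_hepatic_duct", "stomach", "colon"))

#: reduced 3-class ontology used for cross-dataset benchmarking
REDUCED_ONTOLOGY = AnatomyOntology(("gallbladder", "cystic_artery", "cystic_duct"))

#: toy ontology emitted by the synthetic generator
TOY_ONTOLOGY = AnatomyOntology(("organA", "organB", "ductC"))


@dataclass(frozen=True)
class FrameRecord:
    procedure_id: str
    timestamp_s: int
    image_path: Path
    mask_path: Path | None
    criteria: tuple[bool, bool, bool]

    def __post_init__(self):
        if self.timestamp_s < 0:
            raise DataError(f"negative timestamp {self.timestamp_s}")
        if len(self.criteria) != 3:
            raise DataError("criteria must be a triple")


@dataclass
class LabeledFrameClip:
    """T consecutive 1 fps frames ending at an anchor frame.

    ``frames`` is (T, H, W, 3) in [0, 1]; ``criteria`` and the optional
    ``mask`` (H, W integer label map) belong to the anchor (last) frame.
    """

    frames: np.ndarray
    criteria: tuple[bool, bool, bool]
    mask: np.ndarray | None
    procedure_id: str
    timestamp_s: int

    @property
    def is_dual(self) -> bool:
        return self.mask is not None


@dataclass
class SplitAssignment:
    mapping: dict[str, str]
    split_seed: int

    def procedures(self, split: str) -> list[str]:
        return sorted(p for p, s in self.mapping.items() if s == split)

    def save(self, path: Path) -> None:
        rows = sorted(self.mapping.items())
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("procedure_id,split\n")
            for pid, split in rows:
                fh.write(f"{pid},{split}\n")

    @classmethod
    def load(cls, path: Path, split_seed: int = -1) -> "SplitAssignment":
        df = pd.read_csv(path, dtype=str)
        return cls(dict(zip(df["procedure_id"], df["split"])), split_seed)


@dataclass
class MixedBatch:
    """m dual-labeled + n primary-only clips, the unit of meta-training."""

    dual_samples: list[LabeledFrameClip]
    primary_only_samples: list[LabeledFrameClip]

    def __post_init__(self):
        if any(not c.is_dual for c in self.dual_samples):
            raise DataError("dual sample without a mask")
        if any(c.is_dual for c in self.primary_only_samples):
            raise DataError("primary-only sample carries a mask")

    @property
    def m(self) -> int:
        return len(self.dual_samples)

    @property
    def n(self) -> int:
        return len(self.primary_only_samples)

    @property
    def all_samples(self) -> list[LabeledFrameClip]:
        return self.dual_samples + self.primary_only_samples


# ---------------------------------------------------------------------------
# image I/O
# ---------------------------------------------------------------------------

def load_image(path: Path, size: int | None = None) -> np.ndarray:
    """RGB image as (H, W, 3) float in [0, 1]; plain bilinear resize if asked."""
    img = Image.open(path).convert("RGB")
    if size is not None and img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    return np.asarray(img, dtype=np.float64) / 255.0


def load_mask(path: Path, size: int | None = None) -> np.ndarray:
    img = Image.open(path)
    if img.mode not in ("P", "L", "I"):
        img = img.convert("L")
    if size is not None and img.size != (size, size):
        img = img.resize((size, size), Image.NEAREST)
    return np.asarray(img, dtype=np.int64)


def save_mask(mask: np.ndarray, path: Path) -> None:
    Image.fromarray(mask.astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_manifest(manifest_path: Path, ontology: AnatomyOntology,
                  validate_masks: bool = True) -> list[FrameRecord]:
    """Parse a CSV manifest into frame records, validating referenced files.

    Masks are scanned for label values outside the ontology (a mask pixel
    value must be < ontology.n_labels); missing files are fatal.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path, dtype={"procedure_id": str, "mask": str})
    if list(df.columns) != MANIFEST_COLUMNS:
        raise DataError(
            f"manifest columns must be {MANIFEST_COLUMNS}, got {list(df.columns)}")
    root = manifest_path.parent
    records: list[FrameRecord] = []
    seen: set[tuple[str, int]] = set()
    for i, row in df.iterrows():
        image_path = root / str(row["image"])
        if not image_path.exists():
            raise DataError(f"manifest row {i}: missing image file {image_path}")
        mask_cell = row["mask"]
        mask_path = None
        if isinstance(mask_cell, str) and mask_cell.strip():
            mask_path = root / mask_cell.strip()
            if not mask_path.exists():
                raise DataError(f"manifest row {i}: missing mask file {mask_path}")
            if validate_masks:
                vals = np.unique(load_mask(mask_path))
                bad = vals[vals >= ontology.n_labels]
                if bad.size:
                    raise DataError(
                        f"manifest row {i}: mask {mask_path} contains label value "
                        f"{int(bad[0])} outside ontology "
                        f"(valid 0..{ontology.n_labels - 1})")
        crit = tuple(bool(int(row[c])) for c in ("c1", "c2", "c3"))
        key = (str(row["procedure_id"]), int(row["timestamp_s"]))
        if key in seen:
            raise DataError(f"manifest row {i}: duplicate timestamp {key}")
        seen.add(key)
        records.append(FrameRecord(str(row["procedure_id"]), int(row["timestamp_s"]),
                                   image_path, mask_path, crit))
    return records


def clip_anchor_indices(records: list[FrameRecord], frame_length: int,
                        pad_mode: str = "skip") -> list[list[int]]:
    """Index lists (into ``records``) of the frames of each valid clip.

    An anchor is valid when frame_length consecutive 1 fps timestamps ending
    at it exist within the same procedure ("skip" mode).  In "repeat_first"
    mode every frame anchors a clip and missing history repeats the earliest
    available contiguous frame.
    """
    if frame_length < 1:
        raise ConfigError(f"frame_length must be >= 1, got {frame_length}")
    if pad_mode not in ("skip", "repeat_first"):
        raise ConfigError(f"unknown pad_mode {pad_mode!r}")
    by_key: dict[tuple[str, int], int] = {
        (r.procedure_id, r.timestamp_s): i for i, r in enumerate(records)}
    out: list[list[int]] = []
    for i, rec in enumerate(records):
        idxs: list[int] = []
        ok = True
        for dt in range(frame_length - 1, -1, -1):
            key = (rec.procedure_id, rec.timestamp_s - dt)
            j = by_key.get(key)
            if j is None:
                ok = False
                break
            idxs.append(j)
        if ok:
            out.append(idxs)
        elif pad_mode == "repeat_first":
            # walk back while contiguous, then repeat the earliest frame
            hist = [i]
            t = rec.timestamp_s
            while len(hist) < frame_length:
                j = by_key.get((rec.procedure_id, t - 1))
                if j is None:
                    break
                hist.append(j)
                t -= 1
            hist = hist[::-1]
            pad = [hist[0]] * (frame_length - len(hist))
            out.append(pad + hist)
    return out


def make_clips(records: list[FrameRecord], frame_length: int,
               image_size: int | None = None,
               pad_mode: str = "skip") -> list[LabeledFrameClip]:
    """Assemble clips with a full contiguous 1 fps history per anchor."""
    index_lists = clip_anchor_indices(records, frame_length, pad_mode)
    cache: dict[Path, np.ndarray] = {}

    def image(rec: FrameRecord) -> np.ndarray:
        arr = cache.get(rec.image_path)
        if arr is None:
            arr = load_image(rec.image_path, image_size)
            cache[rec.image_path] = arr
        return arr

    clips: list[LabeledFrameClip] = []
    for idxs in index_lists:
        anchor = records[idxs[-1]]
        frames = np.stack([image(records[j]) for j in idxs])
        mask = (load_mask(anchor.mask_path, image_size)
                if anchor.mask_path is not None else None)
        clips.append(LabeledFrameClip(frames, anchor.criteria, mask,
                                      anchor.procedure_id, anchor.timestamp_s))
    return clips


def largest_remainder_counts(n: int, fractions: list[float]) -> list[int]:
    """Apportion n items to fractions by the largest-remainder rule."""
    quotas = [n * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_by_procedure(records: list[FrameRecord] | list[str],
                       seed: int) -> SplitAssignment:
    """Deterministic 7:1:2 procedure-level split (largest-remainder rounding).

    Accepts frame records or bare procedure ids; the assignment is a pure
    function of the procedure-id set and the seed.
    """
    if records and isinstance(records[0], FrameRecord):
        pids = sorted({r.procedure_id for r in records})
    else:
        pids = sorted(set(records))  # type: ignore[arg-type]
    if not pids:
        raise DataError("no procedures to split")
    if len(pids) < 10:
        warnings.warn(
            f"only {len(pids)} procedures; 7:1:2 proportions are coarse below 10",
            stacklevel=2)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pids))
    shuffled = [pids[i] for i in perm]
    counts = largest_remainder_counts(
        len(pids), [SPLIT_FRACTIONS[s] for s in SPLIT_ORDER])
    mapping: dict[str, str] = {}
    pos = 0
    for split, c in zip(SPLIT_ORDER, counts):
        for pid in shuffled[pos:pos + c]:
            mapping[pid] = split
        pos += c
    return SplitAssignment(mapping, seed)


def filter_by_split(clips: list[LabeledFrameClip], assignment: SplitAssignment,
                    split: str) -> list[LabeledFrameClip]:
    return [c for c in clips if assignment.mapping.get(c.procedure_id) == split]


def sample_mixed_batch(clips: list[LabeledFrameClip], m: int, n: int,
                       rng: np.random.Generator) -> MixedBatch:
    """Draw m dual-labeled and n primary-only clips without replacement."""
    dual = [c for c in clips if c.is_dual]
    prim = [c for c in clips if not c.is_dual]
    if len(dual) < m:
        raise DataError(
            f"need {m} dual-labeled clips but only {len(dual)} available; "
            f"lower m or raise the dual-label fraction")
    if len(prim) < n:
        raise DataError(
            f"need {n} primary-only clips but only {len(prim)} available; lower n")
    di = rng.choice(len(dual), size=m, replace=False)
    pi = rng.choice(len(prim), size=n, replace=False) if n else np.array([], int)
    return MixedBatch([dual[i] for i in di], [prim[int(i)] for i in pi])
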