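"""Clip dataset handling: directory scanning, first-clip-per-polyp
filtering, temporal windowing, loading/resizing, consistent per-window
augmentation and cross-validation folds.

Expected layout (SUN-SEG-style, frames pre-extracted to images)::

    root/
      attributes.csv            # clip_id, [case_id,] attributes ("FM;SO")
      <clip_id>/frames/*.png    # RGB frames, sorted by filename
      <clip_id>/masks/*.png     # binary masks, 1:1 with frames

If the CSV has no ``case_id`` column the polyp case is taken as the part
of the clip id before the last underscore.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .metrics import ATTRIBUTE_IDS

__all__ = [
    "ClipRecord",
    "WindowIndex",
    "scan_dataset",
    "first_clip_per_polyp",
    "make_windows",
    "load_window",
    "augment_window",
    "make_folds",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

logger = logging.getLogger(__name__)

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
IMAGENET_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)

_IMG_EXTS = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class ClipRecord:
    """One annotated video clip."""

    clip_id: str
    polyp_case_id: str
    frame_paths: tuple[Path, ...]
    mask_paths: tuple[Path, ...]
    attributes: frozenset[str] = frozenset()

    def __len__(self):
        return len(self.frame_paths)


@dataclass(frozen=True)
class WindowIndex:
    """A run of ``length`` consecutive frames of one clip."""

    clip_id: str
    start: int
    length: int


def _parse_attributes(raw: str) -> frozenset[str]:
    attrs = frozenset(a.strip() for a in str(raw).split(";") if a.strip())
    bad = attrs - ATTRIBUTE_IDS
    if bad:
        raise ValueError(f"unknown attribute ids: {sorted(bad)}")
    return attrs


def scan_dataset(root) -> list[ClipRecord]:
    """Scan a dataset tree into ClipRecords, sorted by clip id.

    Every frame must have a mask with the same filename stem; a frame
    without one is a hard error.  Clips with no frames are skipped with a
    warning.
    """
    root = Path(root)
    table_path = root / "attributes.csv"
    attrs: dict[str, frozenset] = {}
    cases: dict[str, str] = {}
    if table_path.exists():
        table = pd.read_csv(table_path, dtype=str).fillna("")
        for _, row in table.iterrows():
            cid = row["clip_id"]
            attrs[cid] = _parse_attributes(row.get("attributes", ""))
            if "case_id" in table.columns and row["case_id"]:
                cases[cid] = row["case_id"]
    records = []
    for clip_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        cid = clip_dir.name
        frame_dir, mask_dir = clip_dir / "frames", clip_dir / "masks"
        frames = sorted(
            p for p in frame_dir.iterdir() if p.suffix.lower() in _IMG_EXTS
        ) if frame_dir.is_dir() else []
        if not frames:
            warnings.warn(f"clip {cid} has no frames; skipped", stacklevel=2)
            continue
        masks = []
        for fp in frames:
            candidates = [mask_dir / (fp.stem + ext) for ext in (".png", fp.suffix)]
            mp = next((c for c in candidates if c.exists()), None)
            if mp is None:
                raise FileNotFoundError(
                    f"frame {fp} has no matching mask in {mask_dir}"
                )
            masks.append(mp)
        case = cases.get(cid, cid.rsplit("_", 1)[0])
        records.append(ClipRecord(
            clip_id=cid,
            polyp_case_id=case,
            frame_paths=tuple(frames),
            mask_paths=tuple(masks),
            attributes=attrs.get(cid, frozenset()),
        ))
    return records


def first_clip_per_polyp(records) -> list[ClipRecord]:
    """Keep only the lexicographically first clip of each polyp case."""
    best: dict[str, ClipRecord] = {}
    for rec in records:
        cur = best.get(rec.polyp_case_id)
        if cur is None or rec.clip_id < cur.clip_id:
            best[rec.polyp_case_id] = rec
    return sorted(best.values(), key=lambda r: r.clip_id)


def make_windows(record: ClipRecord, length: int = 5,
                 stride: int | None = None) -> list[WindowIndex]:
    """Consecutive-frame windows covering every frame of the clip.

    Windows start every ``stride`` frames (default: ``length``, i.e.
    non-overlapping chunks); if the tail is not covered a final window
    anchored at the clip end is appended.  Clips shorter than ``length``
    yield no windows (with a warning).
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    stride = stride or length
    n = len(record)
    if n < length:
        warnings.warn(
            f"clip {record.clip_id} has {n} frames < window {length}; skipped",
            stacklevel=2,
        )
        return []
    starts = list(range(0, n - length + 1, stride))
    if starts[-1] + length < n:
        starts.append(n - length)
    return [WindowIndex(record.clip_id, s, length) for s in starts]


def _load_rgb(path, size):
    try:
        with Image.open(path) as img:
            img = img.convert("RGB").resize(
                (size[1], size[0]), Image.Resampling.BILINEAR
            )
            return np.asarray(img, dtype=np.float32) / 255.0
    except OSError as exc:
        raise OSError(f"unreadable image {path}: {exc}") from exc


def _load_mask(path, size):
    try:
        with Image.open(path) as img:
            img = img.convert("L").resize(
                (size[1], size[0]), Image.Resampling.NEAREST
            )
            return np.asarray(img, dtype=np.float32) / 255.0 > 0.5
    except OSError as exc:
        raise OSError(f"unreadable mask {path}: {exc}") from exc


def load_window(record: ClipRecord, window: WindowIndex,
                size=(256, 256), normalize: str = "unit"):
    """Load one window: frames (F, 3, H, W float32) + masks (F, H, W bool).

    Frames are resized bilinearly and scaled to [0, 1] (``normalize="unit"``)
    or standardized with the ImageNet channel statistics
    (``normalize="imagenet"``, the pretrained-backbone convention); masks
    are resized nearest-neighbour and binarized at 0.5.
    """
    sl = slice(window.start, window.start + window.length)
    frames = np.stack([_load_rgb(p, size) for p in record.frame_paths[sl]])
    masks = np.stack([_load_mask(p, size) for p in record.mask_paths[sl]])
    if normalize == "imagenet":
        frames = (frames - IMAGENET_MEAN) / IMAGENET_STD
    elif normalize != "unit":
        raise ValueError(f"unknown normalization {normalize!r}")
    return frames.transpose(0, 3, 1, 2).copy(), masks


@dataclass(frozen=True)
class AugmentParams:
    """One random draw of the geometric augmentation."""

    angle_deg: float
    hflip: bool
    vflip: bool
    crop_scale: float


def draw_augment_params(rng, max_angle: float = 20.0,
                        crop_range=(0.8, 1.0)) -> AugmentParams:
    return AugmentParams(
        angle_deg=float(rng.uniform(-max_angle, max_angle)),
        hflip=bool(rng.random() < 0.5),
        vflip=bool(rng.random() < 0.5),
        crop_scale=float(rng.uniform(*crop_range)),
    )


def _apply_geometric(img, params: AugmentParams, order: int):
    from skimage.transform import resize, rotate

    out = rotate(img, params.angle_deg, order=order, preserve_range=True,
                 mode="constant", cval=0.0)
    if params.hflip:
        out = out[:, ::-1]
    if params.vflip:
        out = out[::-1]
    if params.crop_scale < 1.0:
        h, w = out.shape[:2]
        ch, cw = round(h * params.crop_scale), round(w * params.crop_scale)
        top, left = (h - ch) // 2, (w - cw) // 2
        out = out[top:top + ch, left:left + cw]
        out = resize(out, (h, w), order=order, preserve_range=True,
                     anti_aliasing=False)
    return np.ascontiguousarray(out)


def augment_window(frames, masks, seed: int,
                   max_angle: float = 20.0, crop_range=(0.8, 1.0)):
    """Apply one random (rotation, h-flip, v-flip, centre-crop) draw
    identically to all frames and masks of a window.

    Frames are (F, 3, H, W) and interpolated bilinearly; masks are
    (F, H, W) boolean and transformed nearest-neighbour.  Deterministic
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    params = draw_augment_params(rng, max_angle, crop_range)
    out_frames = np.stack([
        _apply_geometric(f.transpose(1, 2, 0), params, order=1).transpose(2, 0, 1)
        for f in frames
    ]).astype(np.float32)
    out_masks = np.stack([
        _apply_geometric(m.astype(np.float32), params, order=0) > 0.5
        for m in masks
    ])
    return out_frames, out_masks


def make_folds(records, k: int = 5, seed: int = 0):
    """Deterministic clip-level k-fold partition.

    Returns k (train_records, val_records) pairs; validation sets are
    disjoint and cover all clips.
    """
    records = sorted(records, key=lambda r: r.clip_id)
    if k > len(records):
        raise ValueError(f"cannot make {k} folds from {len(records)} clips")
    order = np.random.default_rng(seed).permutation(len(records))
    folds = []
    val_groups = np.array_split(order, k)
    for group in val_groups:
        val_ids = {records[i].clip_id for i in group}
        train = [r for r in records if r.clip_id not in val_ids]
        val = [r for r in records if r.clip_id in val_ids]
        folds.append((train, val))
    return folds
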