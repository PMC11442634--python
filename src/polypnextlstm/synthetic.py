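"""Synthetic colonoscopy-like clips: a deformable bright "polyp" blob
moving over a textured mucosa-like background, with ground-truth masks and
automatically derived visual-attribute labels.

The generator exists so the full pipeline (data loading, windowing,
augmentation, training, evaluation, attribute stratification) can be
exercised without the SUN-SEG download.  Blobs are rasterized ellipses
with a soft-edged brightness bump; backgrounds are smoothed pink-tinted
noise.  Clips are deterministic functions of their spec's seed.

The four numerically defined visual attributes are implemented as
checkable rules over the mask sequence:

* ``FM`` (fast motion): mean Euclidean centroid displacement between
  consecutive frames > 20 px.
* ``SO`` (small object): mean object/image area ratio < 0.05.
* ``LO`` (large object): mean bounding-box/image area ratio > 0.15.
* ``SV`` (scale variation): min over frame pairs of (smaller bbox area /
  larger bbox area) < 0.5.

The qualitative attributes OCC (occlusion), GH (ghosting) and OV (out of
view) are tagged from the generator's own construction flags, not detected
from pixels; SI/IB/HO are outside the generator's scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SynthClipSpec",
    "render_clip",
    "label_attributes",
    "make_benchmark_suite",
    "FM_CENTROID_PX",
    "SO_AREA_RATIO",
    "LO_BBOX_RATIO",
    "SV_BBOX_RATIO",
]

# Numeric attribute thresholds (SUN-SEG visual-attribute definitions).
FM_CENTROID_PX = 20.0
SO_AREA_RATIO = 0.05
LO_BBOX_RATIO = 0.15
SV_BBOX_RATIO = 0.5


@dataclass
class SynthClipSpec:
    """Parameters of one synthetic clip."""

    n_frames: int = 5
    image_size: tuple[int, int] = (256, 256)  # (H, W)
    centers: np.ndarray | None = None  # (n_frames, 2) as (row, col)
    axes: np.ndarray | None = None  # (n_frames, 2) semi-axes (a, b) px
    angles: np.ndarray | None = None  # (n_frames,) rad
    occlusion_band: tuple[int, int] | None = None  # column range zeroed
    ghost_shift: int = 0  # px shift of a colour fringe at the boundary
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if self.centers is None:
            self.centers = np.tile([h / 2, w / 2], (self.n_frames, 1)).astype(float)
        if self.axes is None:
            self.axes = np.tile([h / 6, w / 8], (self.n_frames, 1)).astype(float)
        if self.angles is None:
            self.angles = np.zeros(self.n_frames)
        self.centers = np.asarray(self.centers, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if len(self.centers) != self.n_frames:
            raise ValueError("trajectory length must equal n_frames")
        if (self.axes <= 0).any():
            raise ValueError("ellipse semi-axes must be positive")

    def construction_attributes(self) -> set[str]:
        """Attribute tags implied by the generator's own flags."""
        tags = set()
        if self.occlusion_band is not None:
            tags.add("OCC")
        if self.ghost_shift:
            tags.add("GH")
        h, w = self.image_size
        for (cy, cx), (a, b), ang in zip(self.centers, self.axes, self.angles):
            r = max(a, b)
            if cy - r < 0 or cx - r < 0 or cy + r > h or cx + r > w:
                tags.add("OV")
                break
        return tags


def _ellipse_field(h, w, center, axes, angle):
    """Signed ellipse field: <= 1 inside the ellipse."""
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dy, dx = yy - center[0], xx - center[1]
    c, s = np.cos(angle), np.sin(angle)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / axes[1]) ** 2 + (v / axes[0]) ** 2


def render_clip(spec: SynthClipSpec):
    """Render frames (n, H, W, 3 uint8) and masks (n, H, W bool)."""
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    base = gaussian_filter(rng.standard_normal((h, w)), sigma=8)
    base = (base - base.min()) / (np.ptp(base) + 1e-12)
    # mucosa-like pink background, static across the clip
    bg = np.stack([0.55 + 0.25 * base, 0.25 + 0.20 * base, 0.25 + 0.15 * base],
                  axis=-1)
    frames, masks = [], []
    for t in range(spec.n_frames):
        field = _ellipse_field(h, w, spec.centers[t], spec.axes[t],
                               spec.angles[t])
        mask = field <= 1.0
        # soft-edged brightness bump on all channels (reddish highlight)
        bump = np.clip(1.0 - field, 0.0, 1.0) ** 0.5
        img = bg + bump[..., None] * np.array([0.35, 0.25, 0.20])
        if spec.ghost_shift:
            fringe = np.roll(bump, spec.ghost_shift, axis=1) - bump
            img[..., 0] += 0.15 * np.clip(fringe, 0, 1)
        if spec.occlusion_band is not None:
            lo, hi = spec.occlusion_band
            img[:, lo:hi] = 0.0
            mask[:, lo:hi] = False
        frames.append((np.clip(img, 0, 1) * 255).astype(np.uint8))
        masks.append(mask)
    return np.stack(frames), np.stack(masks)


def _bbox_area(mask) -> float:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    return float((rows[-1] - rows[0] + 1) * (cols[-1] - cols[0] + 1))


def label_attributes(masks) -> set[str]:
    """Numeric visual-attribute labels {FM, SO, LO, SV} of a mask sequence.

    Frames with an empty mask are excluded from the means; a fully empty
    sequence is an error.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    nonempty = [m for m in masks if m.any()]
    if not nonempty:
        raise ValueError("attribute labelling requires at least one "
                         "non-empty mask")
    h, w = nonempty[0].shape
    img_area = float(h * w)
    labels: set[str] = set()

    centroids = [np.argwhere(m).mean(axis=0) for m in nonempty]
    if len(centroids) > 1:
        steps = [
            float(np.linalg.norm(a - b))
            for a, b in zip(centroids[:-1], centroids[1:])
        ]
        if np.mean(steps) > FM_CENTROID_PX:
            labels.add("FM")

    if np.mean([m.sum() / img_area for m in nonempty]) < SO_AREA_RATIO:
        labels.add("SO")

    bareas = [_bbox_area(m) for m in nonempty]
    if np.mean([a / img_area for a in bareas]) > LO_BBOX_RATIO:
        labels.add("LO")

    if len(bareas) > 1:
        ratios = [
            min(a, b) / max(a, b)
            for i, a in enumerate(bareas)
            for b in bareas[i + 1:]
        ]
        if min(ratios) < SV_BBOX_RATIO:
            labels.add("SV")
    return labels


def _default_specs(n_clips, size, n_frames, rng):
    """Clip specs cycling through the attribute phenomena."""
    h, w = size
    specs = []
    for i in range(n_clips):
        kind = i % 6
        seed = int(rng.integers(2**31 - 1))
        if kind == 0:  # fast motion: 25 px zig-zag, stays in canvas
            centers = np.tile([h / 2, w / 2], (n_frames, 1))
            centers[:, 1] += np.where(np.arange(n_frames) % 2, 12.5, -12.5)
            spec = SynthClipSpec(n_frames, size, centers=centers,
                                 axes=np.tile([h / 7, w / 9], (n_frames, 1)),
                                 seed=seed)
        elif kind == 1:  # small object
            r = np.sqrt(0.01 * h * w / np.pi)
            spec = SynthClipSpec(n_frames, size,
                                 axes=np.tile([r, r], (n_frames, 1)),
                                 seed=seed)
        elif kind == 2:  # large object
            spec = SynthClipSpec(n_frames, size,
                                 axes=np.tile([h / 3.5, w / 3.5],
                                              (n_frames, 1)),
                                 seed=seed)
        elif kind == 3:  # scale variation: bbox area quadruples
            grow = np.linspace(1.0, 2.0, n_frames)
            axes = np.stack([h / 10 * grow, w / 10 * grow], axis=1)
            spec = SynthClipSpec(n_frames, size, axes=axes, seed=seed)
        elif kind == 4:  # occlusion band
            spec = SynthClipSpec(n_frames, size,
                                 occlusion_band=(w // 2 - w // 16,
                                                 w // 2 + w // 16),
                                 seed=seed)
        else:  # ghosting artifact + slow drift
            centers = np.tile([h / 2, w / 2], (n_frames, 1)) + \
                np.arange(n_frames)[:, None] * [2.0, 3.0]
            spec = SynthClipSpec(n_frames, size, centers=centers,
                                 ghost_shift=4, seed=seed)
        specs.append(spec)
    return specs


def make_benchmark_suite(root, n_clips: int = 6, seed: int = 0,
                         image_size=(256, 256), n_frames: int = 10,
                         clips_per_case: int = 1):
    """Write a loader-compatible dataset tree of synthetic clips.

    Layout: ``root/<clip_id>/frames/*.png``, ``root/<clip_id>/masks/*.png``
    and ``root/attributes.csv`` with columns clip_id, case_id, attributes
    (semicolon-separated).  ``clips_per_case > 1`` assigns consecutive
    clips to the same polyp case (exercising first-clip-per-polyp
    filtering).  Returns the list of written clip ids.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    specs = _default_specs(n_clips, image_size, n_frames, rng)
    rows, clip_ids = [], []
    for i, spec in enumerate(specs):
        case = f"case{i // clips_per_case:03d}"
        clip_id = f"{case}_clip{i % clips_per_case + 1}"
        frames, masks = render_clip(spec)
        fdir, mdir = root / clip_id / "frames", root / clip_id / "masks"
        fdir.mkdir(parents=True, exist_ok=True)
        mdir.mkdir(parents=True, exist_ok=True)
        for t in range(spec.n_frames):
            Image.fromarray(frames[t]).save(fdir / f"{t:04d}.png")
            Image.fromarray((masks[t] * np.uint8(255))).save(
                mdir / f"{t:04d}.png"
            )
        attrs = label_attributes(masks) | spec.construction_attributes()
        rows.append((clip_id, case, ";".join(sorted(attrs))))
        clip_ids.append(clip_id)
    with open(root / "attributes.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["clip_id", "case_id", "attributes"])
        writer.writerows(rows)
    return clip_ids
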