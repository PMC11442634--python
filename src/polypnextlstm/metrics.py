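"""Training objective and evaluation metrics.

Training uses the sum of a soft Dice loss and pixelwise binary
cross-entropy.  Evaluation reports Dice, IoU, 95th-percentile Hausdorff
distance (HD95, in pixels at evaluation resolution) and recall, per clip
and aggregated, with Dice additionally stratified by the clip-level
visual-attribute labels.

Conventions (all documented in the methods note):

* Dice-loss smoothing constant ``smooth = 1.0``; the Dice and BCE terms
  are weighted equally.
* Masks are obtained from sigmoid probabilities at threshold 0.5.
* Both-empty mask pairs score Dice = IoU = 1 and HD95 = 0; recall of an
  empty ground truth is 1.  If exactly one mask of an HD95 pair is empty
  the image diagonal is returned as a finite sentinel.
* A mask pixel is a boundary pixel if any 4-neighbour is background or it
  touches the image edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .nn import Tensor

__all__ = [
    "ATTRIBUTE_IDS",
    "dice_loss",
    "bce_loss",
    "dice_bce_loss",
    "dice_bce_loss_t",
    "dice_score",
    "iou_score",
    "hd95",
    "recall_score",
    "boundary_pixels",
    "frame_metrics",
    "aggregate_by_attribute",
    "MetricReport",
]

#: SUN-SEG visual-attribute identifiers.
ATTRIBUTE_IDS = frozenset(
    {"SI", "IB", "HO", "GH", "FM", "SO", "LO", "OCC", "OV", "SV"}
)

_EPS = 1e-7


def _check_pair(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


# ---------------------------------------------------------------------------
# loss


def _check_probs(probs, target):
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if probs.shape != target.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {target.shape}")
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return probs, target


def dice_loss(probs, target, smooth: float = 1.0) -> float:
    """Soft Dice loss, computed per frame (last two axes) and averaged.

    ``1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s)``; the smoothing
    constant ``s`` cancels for an exact binary prediction, so a perfect
    prediction scores exactly 0.
    """
    probs, target = _check_probs(probs, target)
    flat_p = probs.reshape(-1, probs.shape[-2] * probs.shape[-1])
    flat_t = target.reshape(flat_p.shape)
    inter = (flat_p * flat_t).sum(axis=1)
    denom = flat_p.sum(axis=1) + flat_t.sum(axis=1)
    return float(np.mean(1.0 - (2.0 * inter + smooth) / (denom + smooth)))


def bce_loss(probs, target) -> float:
    """Mean pixelwise binary cross-entropy (probabilities clipped for
    numerical stability)."""
    probs, target = _check_probs(probs, target)
    p = np.clip(probs, _EPS, 1.0 - _EPS)
    return float(
        -np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    )


def dice_bce_loss(probs, target, smooth: float = 1.0) -> float:
    """Training objective: equally weighted Dice loss + BCE on
    probability maps (numpy, evaluation-side)."""
    return dice_loss(probs, target, smooth) + bce_loss(probs, target)


def dice_bce_loss_t(logits: Tensor, target: Tensor,
                    smooth: float = 1.0) -> Tensor:
    """Differentiable Dice + BCE on logits (autodiff Tensor path).

    Mirrors :func:`dice_bce_loss` with the per-frame Dice averaging done
    over the flattened batch*frame axis.
    """
    probs = logits.sigmoid().clip(_EPS, 1.0 - _EPS)
    shape = probs.shape
    n_frames = int(np.prod(shape[:-2]))
    p = probs.reshape(n_frames, shape[-2] * shape[-1])
    t = target.reshape(n_frames, shape[-2] * shape[-1])
    dice_terms = []
    for i in range(n_frames):
        pi = p.narrow(0, i, 1)
        ti = t.narrow(0, i, 1)
        inter = (pi * ti).sum()
        dice_terms.append(
            1.0 - (2.0 * inter + smooth) / (pi.sum() + ti.sum() + smooth)
        )
    dice_term = dice_terms[0]
    for d in dice_terms[1:]:
        dice_term = dice_term + d
    dice_term = dice_term / n_frames
    bce = -(t * p.log() + (1.0 - t) * (1.0 - p).log()).mean()
    return dice_term + bce


# ---------------------------------------------------------------------------
# overlap metrics


def dice_score(pred, gt) -> float:
    """2|P&G| / (|P|+|G|); both-empty pairs score 1."""
    pred, gt = _check_pair(pred, gt)
    p, g = pred.sum(), gt.sum()
    if p + g == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / (p + g))


def iou_score(pred, gt) -> float:
    """|P&G| / |P|G|; both-empty pairs score 1."""
    pred, gt = _check_pair(pred, gt)
    union = np.logical_or(pred, gt).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pred, gt).sum() / union)


def recall_score(pred, gt) -> float:
    """TP / (TP + FN); an empty ground truth scores 1 by convention."""
    pred, gt = _check_pair(pred, gt)
    positives = gt.sum()
    if positives == 0:
        return 1.0
    return float(np.logical_and(pred, gt).sum() / positives)


# ---------------------------------------------------------------------------
# HD95


def boundary_pixels(mask) -> np.ndarray:
    """(k, 2) row/col coordinates of boundary pixels.

    A foreground pixel is boundary if any 4-neighbour is background or it
    lies on the image edge.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.empty((0, 2), dtype=np.int64)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] &
        padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    return np.argwhere(mask & ~interior)


def hd95(pred, gt) -> float:
    """95th-percentile (linear interpolation) symmetric Hausdorff distance
    between the boundary point sets, in pixels."""
    pred, gt = _check_pair(pred, gt)
    bp, bg = boundary_pixels(pred), boundary_pixels(gt)
    if len(bp) == 0 and len(bg) == 0:
        return 0.0
    if len(bp) == 0 or len(bg) == 0:
        return float(np.hypot(*pred.shape))  # finite sentinel: image diagonal
    d_pg = cKDTree(bg).query(bp)[0]
    d_gp = cKDTree(bp).query(bg)[0]
    return float(max(np.percentile(d_pg, 95), np.percentile(d_gp, 95)))


def frame_metrics(pred, gt) -> dict:
    """All four metrics for one predicted/ground-truth mask pair."""
    return {
        "dice": dice_score(pred, gt),
        "iou": iou_score(pred, gt),
        "hd95": hd95(pred, gt),
        "recall": recall_score(pred, gt),
    }


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class MetricReport:
    """Per-clip, aggregate and attribute-stratified evaluation results."""

    per_clip: dict[str, dict[str, float]]
    aggregate: dict[str, float] = field(init=False)
    by_attribute: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        keys = ("dice", "iou", "hd95", "recall")
        if self.per_clip:
            self.aggregate = {
                k: float(np.mean([v[k] for v in self.per_clip.values()]))
                for k in keys
            }
        else:
            self.aggregate = {}

    def to_frame(self):
        """Per-clip rows as a pandas DataFrame (clip_id, dice, iou, hd95,
        recall)."""
        import pandas as pd

        rows = [
            {"clip_id": cid, **scores}
            for cid, scores in sorted(self.per_clip.items())
        ]
        return pd.DataFrame(
            rows, columns=["clip_id", "dice", "iou", "hd95", "recall"]
        )


def aggregate_by_attribute(per_clip_scores: dict[str, float],
                           clip_attributes: dict[str, set]) -> dict[str, float]:
    """Unweighted mean of a clip-level score over the clips carrying each
    attribute; a clip contributes to every attribute it is labelled with.
    Attributes with no clips are absent from the result."""
    missing = set(per_clip_scores) - set(clip_attributes)
    if missing:
        raise ValueError(f"clips without attribute entry: {sorted(missing)}")
    sums: dict[str, list] = {}
    for cid, score in per_clip_scores.items():
        attrs = set(clip_attributes[cid])
        bad = attrs - ATTRIBUTE_IDS
        if bad:
            raise ValueError(f"unknown attribute ids for {cid}: {sorted(bad)}")
        for a in attrs:
            sums.setdefault(a, []).append(score)
    return {a: float(np.mean(v)) for a, v in sorted(sums.items())}
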