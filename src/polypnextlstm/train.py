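"""Seeded training loop and evaluation runner.

Training follows the published recipe: Adam at an initial learning rate
of 1e-4 (no schedule), Dice + BCE supervision on all F output frames of
each window (many-to-many), 5-fold cross-validation at clip level, batches
of B windows of F consecutive frames whose batch and frame axes are
flattened inside the encoder/decoder.  The checkpoint with the best
validation Dice is kept per fold.  All randomness (fold split, window
shuffling, augmentation) derives from the config seed, so same-seed runs
are bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .arch import ModelConfig, PolypNextLSTM, build_model, save_checkpoint
from .data import (
    ClipRecord,
    WindowIndex,
    augment_window,
    load_window,
    make_folds,
    make_windows,
)
from .metrics import (
    MetricReport,
    aggregate_by_attribute,
    dice_bce_loss_t,
    frame_metrics,
)
from .nn import Adam, Tensor

__all__ = ["TrainConfig", "TrainState", "train", "evaluate", "predict_clip",
           "verify_params"]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyper-parameters (defaults are the published recipe)."""

    lr: float = 1e-4
    epochs: int = 100
    batch: int = 8
    frames: int = 5
    folds: int = 5
    seed: int = 0
    augment: bool = True
    pretrained: bool = False
    image_size: tuple[int, int] = (256, 256)
    normalize: str = "unit"
    stride: int | None = None  # window stride; default = frames (chunks)
    max_steps: int | None = None  # optional cap for desk-scale runs
    device: str = "cpu"
    out_dir: str = "runs"

    @property
    def effective_batch(self) -> int:
        """Flattened encoder/decoder batch (B*F; 40 at defaults)."""
        return self.batch * self.frames


class TrainState:
    """Model + optimizer with a single-step interface on window arrays."""

    def __init__(self, model: PolypNextLSTM, lr: float = 1e-4):
        self.model = model
        self.opt = Adam(model.parameters(), lr=lr)

    def step(self, x: np.ndarray, y: np.ndarray) -> float:
        """One Adam step on a B x F x 3 x H x W batch; returns the loss."""
        self.model.train()
        logits = self.model(Tensor(np.ascontiguousarray(x, dtype=np.float32)))
        target = Tensor(np.asarray(y, dtype=np.float32).reshape(logits.shape))
        loss = dice_bce_loss_t(logits, target)
        self.model.zero_grad()
        loss.backward()
        self.opt.step()
        return float(loss.data)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities (B, F, H, W) without building the tape."""
        self.model.eval()
        logits = self.model(Tensor(np.ascontiguousarray(x, dtype=np.float32)))
        b, f = logits.shape[:2]
        return 1.0 / (1.0 + np.exp(-logits.data[:, :, 0]))


def _window_seed(base: int, fold: int, epoch: int, index: int) -> int:
    mix = np.random.SeedSequence([base, fold, epoch, index])
    return int(mix.generate_state(1)[0] % (2**31 - 1))


def train(cfg: TrainConfig, records: list[ClipRecord]):
    """Cross-validated training; returns per-fold result dicts.

    Writes ``fold<k>_best.npz`` checkpoints plus a ``train_log.jsonl``
    of per-epoch loss and validation Dice under ``cfg.out_dir``.
    """
    if not records:
        raise ValueError("empty dataset")
    if cfg.folds > len(records):
        raise ValueError(
            f"fold count {cfg.folds} exceeds clip count {len(records)}"
        )
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "train_log.jsonl"
    results = []
    folds = (
        make_folds(records, cfg.folds, cfg.seed)
        if cfg.folds > 1 else [(records, records)]
    )
    with open(log_path, "w") as log_fh:
        for fold_idx, (train_recs, val_recs) in enumerate(folds):
            model_cfg = ModelConfig(seed=cfg.seed,
                                    pretrained_backbone=cfg.pretrained)
            state = TrainState(build_model(model_cfg), lr=cfg.lr)
            windows = [
                (rec, win)
                for rec in train_recs
                for win in make_windows(rec, cfg.frames, cfg.stride)
            ]
            if not windows:
                raise ValueError("no usable training windows "
                                 f"(clips shorter than {cfg.frames} frames?)")
            best = {"val_dice": -1.0, "epoch": -1}
            ckpt_path = out_dir / f"fold{fold_idx}_best.npz"
            n_steps = 0
            for epoch in range(cfg.epochs):
                rng = np.random.default_rng(
                    _window_seed(cfg.seed, fold_idx, epoch, 0)
                )
                order = rng.permutation(len(windows))
                losses = []
                t0 = time.time()
                for bstart in range(0, len(order), cfg.batch):
                    idxs = order[bstart:bstart + cfg.batch]
                    xs, ys = [], []
                    for j, wi in enumerate(idxs):
                        rec, win = windows[wi]
                        frames, masks = load_window(
                            rec, win, cfg.image_size, cfg.normalize
                        )
                        if cfg.augment:
                            frames, masks = augment_window(
                                frames, masks,
                                _window_seed(cfg.seed, fold_idx, epoch,
                                             int(wi) + 1),
                            )
                        xs.append(frames)
                        ys.append(masks[:, None])
                    losses.append(state.step(np.stack(xs), np.stack(ys)))
                    n_steps += 1
                    if cfg.max_steps and n_steps >= cfg.max_steps:
                        break
                report = evaluate(state, val_recs, cfg)
                val_dice = report.aggregate["dice"]
                entry = {
                    "fold": fold_idx, "epoch": epoch,
                    "loss": float(np.mean(losses)), "val_dice": val_dice,
                    "seconds": round(time.time() - t0, 2),
                }
                log_fh.write(json.dumps(entry) + "\n")
                log_fh.flush()
                logger.info("fold %d epoch %d loss %.4f val_dice %.4f",
                            fold_idx, epoch, entry["loss"], val_dice)
                if val_dice > best["val_dice"]:
                    best = {"val_dice": val_dice, "epoch": epoch}
                    save_checkpoint(ckpt_path, state.model, model_cfg,
                                    extra={"train_config": asdict(cfg),
                                           **best})
                if cfg.max_steps and n_steps >= cfg.max_steps:
                    break
            results.append({"fold": fold_idx, "checkpoint": str(ckpt_path),
                            **best})
    return results


def predict_clip(state: TrainState, record: ClipRecord,
                 cfg: TrainConfig) -> np.ndarray:
    """Per-frame sigmoid probabilities for a whole clip.

    Sliding windows of F frames cover the clip; frames covered by more
    than one window (the end-anchored remainder) average their
    probabilities.
    """
    windows = make_windows(record, cfg.frames, cfg.stride)
    if not windows:
        raise ValueError(
            f"clip {record.clip_id} shorter than window {cfg.frames}"
        )
    h, w = cfg.image_size
    acc = np.zeros((len(record), h, w))
    hits = np.zeros(len(record))
    for win in windows:
        frames, _ = load_window(record, win, cfg.image_size, cfg.normalize)
        probs = state.predict_proba(frames[None])[0]
        acc[win.start:win.start + win.length] += probs
        hits[win.start:win.start + win.length] += 1
    return acc / hits[:, None, None]


def evaluate(state: TrainState, records: list[ClipRecord],
             cfg: TrainConfig, threshold: float = 0.5) -> MetricReport:
    """Clip-level metrics (mean of per-frame Dice/IoU/HD95/recall) with
    attribute-stratified Dice."""
    per_clip = {}
    for rec in records:
        probs = predict_clip(state, rec, cfg)
        scores = []
        for t in range(len(rec)):
            _, gt = load_window(rec, WindowIndex(rec.clip_id, t, 1),
                                cfg.image_size, cfg.normalize)
            scores.append(frame_metrics(probs[t] > threshold, gt[0]))
        per_clip[rec.clip_id] = {
            k: float(np.mean([s[k] for s in scores])) for k in scores[0]
        }
    report = MetricReport(per_clip=per_clip)
    labelled = {r.clip_id: set(r.attributes) for r in records}
    if any(labelled.values()):
        report.by_attribute = aggregate_by_attribute(
            {cid: v["dice"] for cid, v in per_clip.items()}, labelled
        )
    return report


def verify_params() -> dict:
    """Build the three networks and compare rounded parameter counts with
    the published figures (12.35M reduced, 27.82M unpruned, 21.95M full)."""
    from .arch import (
        ReducedConvNeXt,
        UnprunedConvNeXt,
        count_parameters,
        round_millions,
    )

    cfg = ModelConfig()
    checks = {
        "reduced_backbone": (ReducedConvNeXt(cfg), 12.35),
        "unpruned_backbone": (UnprunedConvNeXt(cfg), 27.82),
        "full_model": (PolypNextLSTM(cfg), 21.95),
    }
    report = {}
    for name, (module, expected) in checks.items():
        count = count_parameters(module)
        got = round_millions(count)
        report[name] = {
            "parameters": count,
            "millions": got,
            "expected_millions": expected,
            "match": got == expected,
        }
    report["all_match"] = all(v["match"] for v in report.values()
                              if isinstance(v, dict))
    return report
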