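"""Evaluation metrics and end-to-end reports.

Dice overlap for segmentation, confusion matrix / accuracy for bladder
detection, and signed percentage volume errors, aggregated into a single
:class:`EvalReport` over a dataset manifest plus a repeated-measurement
protocol on freshly rendered phantoms (each nominal volume is imaged and
measured several times, mirroring repeated free-hand acquisitions).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import phantom_sim
from .exceptions import DataError, InvalidArgumentError
from .measure import auto_measure
from .net_arch import postprocess, preprocess


def dice_coefficient(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty."""
    a = np.asarray(pred_mask, bool)
    b = np.asarray(gt_mask, bool)
    if a.shape != b.shape:
        raise InvalidArgumentError("mask shapes differ")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def classification_report(pred_labels, true_labels):
    """(2x2 confusion matrix with rows = true class, accuracy)."""
    pred = np.asarray(pred_labels, int)
    true = np.asarray(true_labels, int)
    if pred.shape != true.shape:
        raise InvalidArgumentError("label vectors differ in length")
    if pred.size and (np.min([pred.min(), true.min()]) < 0
                      or np.max([pred.max(), true.max()]) > 1):
        raise InvalidArgumentError("labels must be 0 (no bladder) or 1 (bladder)")
    confusion = np.zeros((2, 2), int)
    for t, p in zip(true, pred):
        confusion[t, p] += 1
    accuracy = float(np.trace(confusion) / confusion.sum()) if confusion.sum() else 0.0
    return confusion, accuracy


def volume_error_pct(measured: float, nominal: float) -> float:
    """Signed percent error 100 * (measured - nominal) / nominal."""
    if not nominal > 0:
        raise InvalidArgumentError("nominal volume must be positive")
    return 100.0 * (measured - nominal) / nominal


@dataclass
class EvalReport:
    dice_mean: float
    dice_std: float
    confusion: np.ndarray
    accuracy: float
    volume_errors_pct: dict[float, list[float]]
    n_samples: int

    def volume_error_summary(self) -> dict[float, float]:
        """Mean |error| percent per nominal volume."""
        return {v: float(np.mean(np.abs(e))) for v, e in self.volume_errors_pct.items()}

    def to_json(self, path=None) -> str:
        payload = {
            "dice_mean": self.dice_mean,
            "dice_std": self.dice_std,
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "volume_errors_pct": {str(k): v for k, v in self.volume_errors_pct.items()},
            "n_samples": self.n_samples,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def confusion_to_csv(self, path) -> None:
        pd.DataFrame(
            self.confusion,
            index=["true_no_bladder", "true_bladder"],
            columns=["pred_no_bladder", "pred_bladder"],
        ).to_csv(path)


def _plane_records(row, root):
    present = str(row.has_bladder) in ("True", "1")
    for ipath, mpath in ((row.path_sagittal, row.mask_sagittal),
                         (row.path_transverse, row.mask_transverse)):
        img = iio.imread(Path(root) / ipath)
        mask = iio.imread(Path(root) / mpath) > 127
        yield img, mask, present


def evaluate_run(
    manifest,
    model=None,
    shape_label: str = "unknown",
    n_repeats: int = 5,
    seed: int = 0,
    root: str | Path = ".",
    volumes: tuple[float, ...] = (50.0, 150.0, 300.0),
    coefficient: float | None = None,
    cfg: phantom_sim.ImagingConfig | None = None,
    split: str = "val",
    measurement_eccentricity: tuple[float, float] = (1.0, 1.0),
) -> EvalReport:
    """Aggregate Dice, classification and repeated volume measurements.

    ``model=None`` runs the ground-truth oracle (predictions = labels),
    which isolates the geometric measurement chain from learning.  Volume
    errors are measured on ``n_repeats`` freshly rendered phantoms per
    nominal volume (spherical by default, matching the measurement-phantom
    protocol), with the same gating and geometry as ``auto_measure``.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, keep_default_na=False)
    if len(manifest) == 0:
        raise DataError("empty manifest")
    part = manifest[manifest["split"] == split] if split else manifest
    if len(part) == 0:
        raise DataError(f"manifest has no rows in split {split!r}")

    dices, preds, trues = [], [], []
    for row in part.itertuples():
        for img, mask, present in _plane_records(row, root):
            if model is None:
                pred_label, pred_mask = int(present), mask
            else:
                size = model.config.input_size
                seg, clf = model.predict(preprocess(img, size))
                pred_label = int(np.argmax(clf))
                pred_mask = postprocess(seg, img.shape)
            preds.append(pred_label)
            trues.append(int(present))
            if present:
                dices.append(dice_coefficient(pred_mask, mask))
    confusion, accuracy = classification_report(preds, trues)

    rng = np.random.default_rng(seed)
    cfg = cfg or phantom_sim.ImagingConfig()
    errors: dict[float, list[float]] = {v: [] for v in volumes}
    for vol in volumes:
        for _ in range(n_repeats):
            draw = dataclasses.replace(cfg, seed=int(rng.integers(2**31)))
            phantom = phantom_sim.sample_phantom(
                vol, eccentricity_range=measurement_eccentricity,
                rng_seed=int(rng.integers(2**31)), max_tilt=0.0,
            )
            sample = phantom_sim.render_biplane(phantom, draw)
            est = auto_measure(sample, model=model, shape_label=shape_label,
                               coefficient=coefficient)
            if est.volume is not None:
                errors[vol].append(volume_error_pct(est.volume, vol))
    return EvalReport(
        dice_mean=float(np.mean(dices)) if dices else 1.0,
        dice_std=float(np.std(dices)) if dices else 0.0,
        confusion=confusion,
        accuracy=accuracy,
        volume_errors_pct=errors,
        n_samples=len(preds),
    )
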