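"""Reproducible desk-scale end-to-end study on synthetic phantoms.

Renders a seeded biplane dataset (bladder-positive and bladder-free
samples), runs the staged training + 8-bit quantization pipeline, and then
measures seeded spherical phantoms of 50 / 150 / 300 mL with the spherical
shape coefficient (c = 0.52), once through the trained quantized model and
once with ground-truth masks injected — the latter isolates the geometric
measurement chain from segmentation quality.

Problem sizes (128 positive + 128 negative biplane pairs, i.e. 256
positive and 256 negative plane images; stage 1 trained at 96 px for 14
epochs; deployment and quantization at the native 192 px input) are the
package's standard reduced-scale protocol; they are deliberately small
enough to run on a single CPU in a few minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import phantom_sim as ps
from .measure import auto_measure
from .metrics_eval import dice_coefficient, volume_error_pct
from .train_quant import arrays_from_samples, train_and_quantize


@dataclass
class StudyResult:
    parameter_count: int
    dice_float: float
    dice_int8: float
    classification_accuracy: float
    volume_errors_model_pct: dict[float, list[float]]
    volume_errors_oracle_pct: dict[float, list[float]]
    n_undetected: int
    n_phantoms: int
    n_val_images: int

    @property
    def dice_drop(self) -> float:
        return self.dice_float - self.dice_int8

    def _flat(self, errors) -> np.ndarray:
        return np.concatenate([np.asarray(v) for v in errors.values()])

    @property
    def median_abs_error_model_pct(self) -> float:
        return float(np.median(np.abs(self._flat(self.volume_errors_model_pct))))

    @property
    def median_abs_error_oracle_pct(self) -> float:
        return float(np.median(np.abs(self._flat(self.volume_errors_oracle_pct))))


def run_synthetic_study(
    seed: int = 0,
    n_pos: int = 128,
    n_neg: int = 128,
    train_frac: float = 0.8,
    train_size: int = 96,
    deploy_size: int = 192,
    seg_epochs: int = 14,
    clf_epochs: int = 60,
    volumes: tuple[float, ...] = (50.0, 150.0, 300.0),
    n_repeats: int = 10,
    coefficient: float = 0.52,
    cfg: ps.ImagingConfig | None = None,
) -> StudyResult:
    """Run the full simulate/train/quantize/measure experiment."""
    cfg = cfg or ps.ImagingConfig()
    ss = np.random.SeedSequence(seed)
    data_seed, train_seed, meas_seed = (int(s % 2**31) for s in ss.generate_state(3))

    rng = np.random.default_rng(data_seed)
    samples, splits = [], []
    n_pos_train = int(round(n_pos * train_frac))
    n_neg_train = int(round(n_neg * train_frac))
    for i in range(n_pos):
        samples.append(ps.generate_sample(rng.uniform(50, 300), cfg, rng))
        splits.append("train" if i < n_pos_train else "val")
    for i in range(n_neg):
        samples.append(ps.generate_negative(cfg, rng))
        splits.append("train" if i < n_neg_train else "val")

    data_train = arrays_from_samples(samples, splits, train_size)
    data_deploy = (data_train if deploy_size == train_size
                   else arrays_from_samples(samples, splits, deploy_size))
    model, qmodel, _ = train_and_quantize(
        data_train, data_deploy, seed=train_seed,
        seg_epochs=seg_epochs, clf_epochs=clf_epochs)

    # segmentation parity and detection accuracy on the validation split
    xv, mv, _ = data_deploy.subset("val", positives_only=True)
    dice_f, dice_q = [], []
    for i in range(len(xv)):
        dice_f.append(dice_coefficient(np.argmax(model.predict(xv[i])[0], -1) > 0, mv[i] > 0))
        dice_q.append(dice_coefficient(np.argmax(qmodel.predict(xv[i])[0], -1) > 0, mv[i] > 0))
    xa, _, ya = data_deploy.subset("val")
    correct = sum(int(np.argmax(qmodel.predict(xa[i])[1]) == ya[i]) for i in range(len(xa)))

    # repeated measurements of spherical phantoms, trained model vs oracle
    mrng = np.random.default_rng(meas_seed)
    errs_model: dict[float, list[float]] = {v: [] for v in volumes}
    errs_oracle: dict[float, list[float]] = {v: [] for v in volumes}
    undetected = 0
    for vol in volumes:
        for _ in range(n_repeats):
            phantom = ps.sample_phantom(vol, (1.0, 1.0),
                                        rng_seed=int(mrng.integers(2**31)), max_tilt=0.0)
            draw = dataclasses.replace(cfg, seed=int(mrng.integers(2**31)))
            sample = ps.render_biplane(phantom, draw)
            oracle = auto_measure(sample, model=None, coefficient=coefficient)
            errs_oracle[vol].append(volume_error_pct(oracle.volume, vol))
            est = auto_measure(sample, model=qmodel, coefficient=coefficient)
            if est.volume is None:
                undetected += 1
            else:
                errs_model[vol].append(volume_error_pct(est.volume, vol))

    return StudyResult(
        parameter_count=model.count_parameters(),
        dice_float=float(np.mean(dice_f)),
        dice_int8=float(np.mean(dice_q)),
        classification_accuracy=correct / max(len(xa), 1),
        volume_errors_model_pct=errs_model,
        volume_errors_oracle_pct=errs_oracle,
        n_undetected=undetected,
        n_phantoms=len(volumes) * n_repeats,
        n_val_images=len(xa),
    )
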