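"""Staged training, combo loss, augmentation, QAT and 8-bit quantization.

The two heads are trained in three stages: (1) the segmentation path plus
the shared backbone are trained (classification path frozen); (2) the
classification path alone is trained with the backbone and segmentation
path frozen, so stage 2 cannot disturb the segmentation weights; (3) the
two weight sets are merged into a single model — backbone + segmentation
from stage 1, classification from stage 2.  Because the paths only share
the (frozen-in-stage-2) backbone, the merged model reproduces each stage's
head output bit for bit.

Training minimizes the combo loss ``alpha * CE + (1 - alpha) * (1 - soft
Dice)`` for segmentation and plain cross-entropy for classification, with
Adam, reduce-on-plateau learning-rate scheduling, early stopping, random
intensity-shift / left-right-flip augmentation, and optional
quantization-aware training (weights rounded to the signed 8-bit grid in
the forward pass, straight-through gradients).  Masks exist only for
bladder-positive images, so the segmentation stage consumes positives
only; the classification stage sees positives and negatives.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import DataError, GraphMismatchError, InvalidArgumentError
from .net_arch import MultitaskModel, ModelConfig, build_model, preprocess
from .nn import Adam
from .nn.layers import BatchNorm, Conv2D, Dense, DepthwiseConv2D, Identity
from .nn.quant import (
    QuantSpec,
    activation_range,
    fake_quantize_affine,
    fake_quantize_symmetric,
    quantize_weights,
)

SEG_GROUPS = ("backbone", "seg")
CLF_GROUPS = ("clf",)
_EPS = 1e-7


@dataclass
class TrainConfig:
    alpha: float = 0.5
    learning_rate: float = 1e-3
    lr_factor: float = 0.5
    lr_patience: int = 5
    patience: int = 20
    batch_size: int = 8
    max_epochs: int = 100
    seed: int = 0
    qat_enabled: bool = True
    intensity_shift_range: float = 10.0
    lr_flip_prob: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise InvalidArgumentError("alpha must lie in [0, 1]")
        if self.patience < 1:
            raise InvalidArgumentError("patience must be >= 1")


# ----------------------------------------------------------------------- loss

def soft_dice(pred_fg: np.ndarray, gt: np.ndarray) -> float:
    """2 sum(p y) / (sum p + sum y); 1.0 when both masses vanish."""
    denom = float(pred_fg.sum() + gt.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * (pred_fg * gt).sum() / denom)


def combo_loss(pred: np.ndarray, gt: np.ndarray, alpha: float = 0.5) -> float:
    loss, _ = combo_loss_with_grad(pred, gt, alpha)
    return loss


def combo_loss_with_grad(pred, gt, alpha=0.5):
    """Loss and its gradient w.r.t. the per-pixel class probabilities."""
    pred = np.asarray(pred, np.float64)
    gt = np.asarray(gt)
    if pred.size == 0 or gt.size == 0:
        raise InvalidArgumentError("empty tensors")
    if pred.shape[:-1] != gt.shape or pred.shape[-1] != 2:
        raise InvalidArgumentError("pred must be gt.shape + (2,)")
    if not 0.0 <= alpha <= 1.0:
        raise InvalidArgumentError("alpha must lie in [0, 1]")
    y = (gt > 0).astype(np.float64)
    p = np.clip(pred, _EPS, 1.0)
    npix = y.size
    ce = float(-(y * np.log(p[..., 1]) + (1 - y) * np.log(p[..., 0])).sum() / npix)
    p1 = pred[..., 1]
    s = float(p1.sum() + y.sum())
    if s == 0:
        dice, py = 1.0, 0.0
    else:
        py = float((p1 * y).sum())
        dice = 2.0 * py / s
    loss = alpha * ce + (1 - alpha) * (1.0 - dice)

    grad = np.zeros_like(pred)
    grad[..., 1] = -alpha * y / p[..., 1] / npix
    grad[..., 0] = -alpha * (1 - y) / p[..., 0] / npix
    if s > 0:
        grad[..., 1] += (1 - alpha) * (2.0 * py / s**2 - 2.0 * y / s)
    return float(loss), grad.astype(np.float32)


def cross_entropy_with_grad(pred, labels):
    """Mean CE over (N, 2) class probabilities and integer labels."""
    pred = np.asarray(pred, np.float64)
    labels = np.asarray(labels, int)
    n = len(labels)
    p = np.clip(pred, _EPS, 1.0)
    picked = p[np.arange(n), labels]
    loss = float(-np.log(picked).mean())
    grad = np.zeros_like(pred)
    grad[np.arange(n), labels] = -1.0 / picked / n
    return loss, grad.astype(np.float32)


# --------------------------------------------------------------- augmentation

def augment(image, mask, rng=None, intensity_shift_range=10.0, lr_flip_prob=0.5,
            shift=None, flip=None):
    """Random intensity shift and left-right flip, applied jointly to mask.

    ``shift`` / ``flip`` override the random draws (for deterministic use).
    Intensity shifts are expressed in 8-bit counts; float images in [0, 1]
    are shifted by ``shift / 255``.
    """
    rng = rng or np.random.default_rng(0)
    if shift is None:
        shift = rng.uniform(-intensity_shift_range, intensity_shift_range)
    if flip is None:
        flip = bool(rng.random() < lr_flip_prob)
    img = np.asarray(image)
    if img.dtype == np.uint8:
        img = np.clip(img.astype(np.int16) + round(shift), 0, 255).astype(np.uint8)
    else:
        img = np.clip(img + np.float32(shift / 255.0), 0.0, 1.0).astype(np.float32)
    out_mask = mask
    if flip:
        img = img[:, ::-1].copy()
        out_mask = mask[:, ::-1].copy() if mask is not None else None
    return img, out_mask


# -------------------------------------------------------------------- dataset

@dataclass
class TrainData:
    """Per-plane training arrays at model resolution.

    images are float32 in [0, 1]; masks are {0,1} uint8 (all-zero rows for
    negatives); labels are 1 = bladder present.
    """

    images: np.ndarray
    masks: np.ndarray
    labels: np.ndarray
    split: np.ndarray

    def subset(self, split=None, positives_only=False):
        sel = np.ones(len(self.labels), bool)
        if split is not None:
            sel &= self.split == split
        if positives_only:
            sel &= self.labels == 1
        return self.images[sel], self.masks[sel], self.labels[sel]


def arrays_from_samples(samples, splits, input_size: int) -> TrainData:
    """Flatten biplane samples into independent per-plane records."""
    from skimage.transform import resize

    imgs, masks, labels, spl = [], [], [], []
    for sample, split in zip(samples, splits):
        for img, mask, present in (
            (sample.sagittal_image, sample.sagittal_mask, sample.has_bladder[0]),
            (sample.transverse_image, sample.transverse_mask, sample.has_bladder[1]),
        ):
            imgs.append(preprocess(img, input_size))
            m = resize(mask.astype(np.uint8), (input_size, input_size), order=0,
                       mode="edge", anti_aliasing=False, preserve_range=True)
            masks.append(m.astype(np.uint8))
            labels.append(int(present))
            spl.append(split)
    return TrainData(np.stack(imgs), np.stack(masks), np.asarray(labels), np.asarray(spl))


def load_training_arrays(manifest, root, input_size: int) -> TrainData:
    """Read a dataset manifest (CSV path or DataFrame) into training arrays."""
    from skimage.transform import resize

    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, keep_default_na=False)
    required = {"path_sagittal", "path_transverse", "mask_sagittal",
                "mask_transverse", "split", "has_bladder"}
    if not required.issubset(manifest.columns):
        raise DataError(f"manifest missing columns {sorted(required - set(manifest.columns))}")
    root = Path(root)
    imgs, masks, labels, spl = [], [], [], []
    for row in manifest.itertuples():
        present = str(row.has_bladder) in ("True", "1")
        for ipath, mpath in ((row.path_sagittal, row.mask_sagittal),
                             (row.path_transverse, row.mask_transverse)):
            img = iio.imread(root / ipath)
            imgs.append(preprocess(img, input_size))
            mask = iio.imread(root / mpath) > 127
            m = resize(mask.astype(np.uint8), (input_size, input_size), order=0,
                       mode="edge", anti_aliasing=False, preserve_range=True)
            masks.append(m.astype(np.uint8))
            labels.append(int(present))
            spl.append(row.split)
    return TrainData(np.stack(imgs), np.stack(masks), np.asarray(labels), np.asarray(spl))


# ------------------------------------------------------------ staged training

def frozen_checksum(network, frozen_groups) -> dict[str, float]:
    """Bit-level audit value per frozen parameter tensor."""
    return {key: float(np.float64(val).sum()) + float(np.abs(val).sum())
            for key, _, _, val in network.parameters(set(frozen_groups))}


def _epoch_pass(model, opt, xs, masks, labels, cfg, rng, path, training):
    """One pass over the data; updates weights when ``training``."""
    n = len(xs)
    order = rng.permutation(n) if training else np.arange(n)
    total, correct, dices = 0.0, 0, []
    for start in range(0, n, cfg.batch_size):
        idx = order[start:start + cfg.batch_size]
        xb = xs[idx]
        mb = masks[idx]
        yb = labels[idx]
        if training:
            aug_x, aug_m = [], []
            for i in range(len(idx)):
                ai, am = augment(xb[i], mb[i], rng,
                                 cfg.intensity_shift_range, cfg.lr_flip_prob)
                aug_x.append(ai)
                aug_m.append(am)
            xb, mb = np.stack(aug_x), np.stack(aug_m)
        # The classification stage trains only the head on a frozen backbone:
        # run the graph in inference mode so batch-norm uses its stage-1
        # running statistics — the exact features seen at deployment — and
        # the frozen path's state (including those statistics) stays intact.
        out = model.forward(xb, training=training and path == "segmentation")
        if path == "segmentation":
            loss, grad = combo_loss_with_grad(out["seg"], mb, cfg.alpha)
            head_grads = {"seg": grad}
            pred = np.argmax(out["seg"], -1)
            for i in range(len(idx)):
                inter = float((pred[i] * mb[i]).sum())
                denom = float(pred[i].sum() + mb[i].sum())
                dices.append(1.0 if denom == 0 else 2 * inter / denom)
        else:
            loss, grad = cross_entropy_with_grad(out["clf"], yb)
            head_grads = {"clf": grad}
            correct += int((np.argmax(out["clf"], -1) == yb).sum())
        total += loss * len(idx)
        if training:
            opt.zero_grad()
            model.network.backward(head_grads, trainable_groups=opt.groups)
            opt.step()
    metric = float(np.mean(dices)) if path == "segmentation" else correct / max(n, 1)
    return total / max(n, 1), metric


def _extract_head_features(model, xs, batch=16):
    feats = []
    for i in range(0, len(xs), batch):
        model.forward(xs[i:i + batch], training=False)
        feats.append(model.network.activations()["clf_flatten"].copy())
    return np.concatenate(feats) if feats else np.zeros((0, 0), np.float32)


def _train_head_cached(model, data, cfg: TrainConfig):
    """Classification stage with augmentation off: the frozen backbone's
    pooled features are computed once and the dense head is trained on the
    cache, which is orders of magnitude cheaper than re-running the
    encoder every epoch."""
    x_tr, _, y_tr = data.subset("train")
    x_va, _, y_va = data.subset("val")
    f_tr = _extract_head_features(model, x_tr)
    f_va = _extract_head_features(model, x_va)
    dense = model.network.by_name["clf_dense"].layer
    smax = model.network.by_name["clf_softmax"].layer
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.network, groups={"clf"}, lr=cfg.learning_rate)

    def run(feats, labels, training):
        n, total, correct = len(labels), 0.0, 0
        order = rng.permutation(n) if training else np.arange(n)
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            probs = smax.forward(dense.forward(feats[idx]))
            loss, grad = cross_entropy_with_grad(probs, labels[idx])
            total += loss * len(idx)
            correct += int((np.argmax(probs, -1) == labels[idx]).sum())
            if training:
                opt.zero_grad()
                dense.backward(smax.backward(grad))
                opt.step()
        return total / max(n, 1), correct / max(n, 1)

    history, best, best_state, bad, lr_bad = [], np.inf, None, 0, 0
    for epoch in range(1, cfg.max_epochs + 1):
        tr_loss, tr_acc = run(f_tr, y_tr, True)
        va_loss, va_acc = run(f_va, y_va, False)
        history.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss,
                        "train_acc": tr_acc, "val_acc": va_acc, "lr": opt.lr})
        if va_loss < best - 1e-9:
            best, bad, lr_bad = va_loss, 0, 0
            best_state = model.network.state_dict()
        else:
            bad += 1
            lr_bad += 1
            if lr_bad >= cfg.lr_patience:
                opt.lr *= cfg.lr_factor
                lr_bad = 0
            if bad >= cfg.patience:
                break
    return history, best_state


def train_stage(model: MultitaskModel, trainable_path: str, data: TrainData,
                cfg: TrainConfig | None = None):
    """Train one path; returns (state_dict, history DataFrame).

    ``trainable_path`` is ``"segmentation"`` (updates backbone + segmentation
    path, on positives only) or ``"classification"`` (updates the
    classification head only, on positives and negatives).
    """
    cfg = cfg or TrainConfig()
    if trainable_path == "segmentation":
        groups, positives_only = set(SEG_GROUPS), True
    elif trainable_path == "classification":
        groups, positives_only = set(CLF_GROUPS), False
    else:
        raise InvalidArgumentError("trainable_path must be segmentation|classification")

    x_tr, m_tr, y_tr = data.subset("train", positives_only)
    x_va, m_va, y_va = data.subset("val", positives_only)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise DataError(f"manifest lacks {trainable_path} samples in train/val splits")
    if trainable_path == "segmentation" and m_tr.max() == 0:
        raise DataError("segmentation stage requires non-empty masks")

    frozen = {n.group for n in model.network.nodes} - groups
    audit_before = frozen_checksum(model.network, frozen)
    model.network.set_qat(cfg.qat_enabled)
    rng = np.random.default_rng(cfg.seed)

    if (trainable_path == "classification"
            and cfg.intensity_shift_range == 0 and cfg.lr_flip_prob == 0):
        history, best_state = _train_head_cached(model, data, cfg)
    else:
        opt = Adam(model.network, groups=groups, lr=cfg.learning_rate)
        met = "dice" if trainable_path == "segmentation" else "acc"
        history = []
        best, best_state = np.inf, None
        bad, lr_bad = 0, 0
        for epoch in range(1, cfg.max_epochs + 1):
            tr_loss, tr_metric = _epoch_pass(model, opt, x_tr, m_tr, y_tr, cfg, rng,
                                             trainable_path, training=True)
            va_loss, va_metric = _epoch_pass(model, opt, x_va, m_va, y_va, cfg, rng,
                                             trainable_path, training=False)
            history.append({"epoch": epoch, "train_loss": tr_loss, "val_loss": va_loss,
                            f"train_{met}": tr_metric, f"val_{met}": va_metric,
                            "lr": opt.lr})
            if va_loss < best - 1e-9:
                best, bad, lr_bad = va_loss, 0, 0
                best_state = model.network.state_dict()
            else:
                bad += 1
                lr_bad += 1
                if lr_bad >= cfg.lr_patience:
                    opt.lr *= cfg.lr_factor
                    lr_bad = 0
                if bad >= cfg.patience:
                    break
    if best_state is not None:
        model.network.load_state_dict(best_state)
    model.network.set_qat(False)

    audit_after = frozen_checksum(model.network, frozen)
    if audit_before != audit_after:
        raise GraphMismatchError("frozen parameters changed during training")
    return model.network.state_dict(), pd.DataFrame(history)


def merge_paths(stage1_weights: dict, stage2_weights: dict) -> dict:
    """Backbone + segmentation weights from stage 1, classification from stage 2."""
    if set(stage1_weights) != set(stage2_weights):
        raise GraphMismatchError("weight sets come from different graphs")
    merged = {}
    for key, val in stage1_weights.items():
        src = stage2_weights if key.startswith("clf_") else stage1_weights
        merged[key] = src[key].copy()
    return merged


def train_full(model: MultitaskModel, data: TrainData, cfg: TrainConfig | None = None):
    """Stages 1-3: segmentation, classification, merge. Returns histories."""
    cfg = cfg or TrainConfig()
    w1, h1 = train_stage(model, "segmentation", data, cfg)
    w2, h2 = train_stage(model, "classification", data, cfg)
    model.network.load_state_dict(merge_paths(w1, w2))
    return {"segmentation": h1, "classification": h2}


def train_and_quantize(
    data_train: TrainData,
    data_deploy: TrainData | None = None,
    seed: int = 0,
    seg_epochs: int = 14,
    finetune_epochs: int = 4,
    clf_epochs: int = 60,
    batch_size: int = 16,
    alpha: float = 0.5,
    qat_enabled: bool = True,
    calibration_size: int = 16,
):
    """Reference staged pipeline with progressive resizing: stage 1 at the
    (reduced) training resolution, then a short segmentation fine-tune,
    the classification head (cached features) and quantization at the
    deployment resolution.

    ``data_train`` holds images at the resolution used for the bulk of
    segmentation training; ``data_deploy`` holds the same samples at the
    deployment resolution (defaults to ``data_train``).  Every layer is
    convolutional or globally pooled, so the weights transfer across input
    sizes unchanged; the fine-tune sharpens the mask boundary on the finer
    logit grid.  Returns (float model, quantized model, histories dict).
    """
    import dataclasses as _dc

    from .net_arch import resize_model

    train_size = data_train.images.shape[1]
    data_deploy = data_deploy if data_deploy is not None else data_train
    deploy_size = data_deploy.images.shape[1]

    model = build_model(ModelConfig(input_size=train_size, seed=seed))
    cfg_seg = TrainConfig(max_epochs=seg_epochs, batch_size=batch_size,
                          seed=seed, alpha=alpha, qat_enabled=qat_enabled)
    w1, h_seg = train_stage(model, "segmentation", data_train, cfg_seg)

    if deploy_size != train_size:
        deploy = resize_model(model, deploy_size)
        if finetune_epochs > 0:
            cfg_ft = _dc.replace(cfg_seg, max_epochs=finetune_epochs,
                                 learning_rate=3e-4, seed=seed + 2)
            w1, h_ft = train_stage(deploy, "segmentation", data_deploy, cfg_ft)
            h_seg = pd.concat([h_seg, h_ft], ignore_index=True)
    else:
        deploy = model
    cfg_clf = TrainConfig(max_epochs=clf_epochs, learning_rate=1e-2,
                          batch_size=max(batch_size, 32), seed=seed + 1,
                          qat_enabled=qat_enabled,
                          intensity_shift_range=0.0, lr_flip_prob=0.0)
    w2, h_clf = train_stage(deploy, "classification", data_deploy, cfg_clf)
    deploy.network.load_state_dict(merge_paths(w1, w2))
    calib = data_deploy.images[:calibration_size][..., None]
    qmodel = quantize_model(deploy, calib)
    return deploy, qmodel, {"segmentation": h_seg, "classification": h_clf}


# ----------------------------------------------------------------- quantization

def fake_quantize(tensor: np.ndarray, spec: QuantSpec | None = None,
                  scale: float | None = None) -> np.ndarray:
    """Round to the symmetric signed 8-bit grid and de-quantize (QAT forward)."""
    spec = spec or QuantSpec()
    if spec.bit_width != 8:
        raise InvalidArgumentError("only 8-bit quantization is supported")
    return fake_quantize_symmetric(np.asarray(tensor, np.float32), scale)


def _fold_batchnorm(network) -> None:
    """Fold conv -> BN pairs into biased convolutions (in place)."""
    consumers: dict[str, list] = {}
    for node in network.nodes:
        for i in node.inputs:
            consumers.setdefault(i, []).append(node)
    for node in network.nodes:
        lay = node.layer
        if not isinstance(lay, BatchNorm):
            continue
        (src_name,) = node.inputs
        src = network.by_name[src_name]
        conv = src.layer
        if not isinstance(conv, (Conv2D, DepthwiseConv2D)):
            continue
        if len(consumers.get(src_name, [])) != 1:
            continue
        scale = lay.params["gamma"] / np.sqrt(lay.running_var + lay.eps)
        shift = lay.params["beta"] - scale * lay.running_mean
        w = conv.params["w"]
        conv.params["w"] = (w * scale).astype(np.float32)  # broadcast over out-ch
        bias = conv.params.get("b", np.zeros_like(shift))
        conv.params["b"] = (bias * scale + shift).astype(np.float32)
        conv.use_bias = True
        node.layer = Identity()


class QuantizedModel:
    """8-bit fixed-point model: int8 weights, affine-quantized activations.

    Inference is simulated in float arithmetic on the exact de-quantized
    values, so outputs are bit-deterministic for a given input.
    """

    def __init__(self, network, config, weight_codes, weight_scales, act_ranges,
                 spec: QuantSpec | None = None):
        self.network = network
        self.config = config
        self.weight_codes = weight_codes
        self.weight_scales = weight_scales
        self.act_ranges = act_ranges
        self.spec = spec or QuantSpec()

    @classmethod
    def from_float(cls, model: MultitaskModel, calibration: np.ndarray,
                   spec: QuantSpec | None = None) -> "QuantizedModel":
        net = copy.deepcopy(model.network)
        _fold_batchnorm(net)
        weight_codes: dict[str, np.ndarray] = {}
        weight_scales: dict[str, float] = {}
        for key, layer, pname, val in net.parameters():
            if pname == "w" and isinstance(layer, (Conv2D, DepthwiseConv2D, Dense)):
                codes, scale = quantize_weights(val)
                layer.params["w"] = codes.astype(np.float32) * np.float32(scale)
                weight_codes[key] = codes
                weight_scales[key] = scale
        x = np.asarray(calibration, np.float32)
        if x.ndim == 3:
            x = x[..., None]
        if len(x) == 0:
            raise InvalidArgumentError("calibration set must be non-empty")
        net.forward(x)
        acts = net.activations()
        act_ranges = {name: activation_range(acts[name])
                      for name in acts if name != "input"}
        return cls(net, model.config, weight_codes, weight_scales, act_ranges, spec)

    @classmethod
    def from_file(cls, path) -> "QuantizedModel":
        from .net_arch import ModelConfig, build_model
        from .nn.layers import BatchNorm

        with np.load(path) as data:
            store = dict(data)
        size = int(store.pop("__input_size__"))
        model = build_model(ModelConfig(input_size=size))
        net = model.network
        for node in net.nodes:  # structural fold only; stored weights follow
            if isinstance(node.layer, BatchNorm):
                node.layer = Identity()
        codes = {k[6:]: v for k, v in store.items() if k.startswith("code::")}
        scales = {k[7:]: float(v) for k, v in store.items() if k.startswith("scale::")}
        biases = {k[6:]: v for k, v in store.items() if k.startswith("bias::")}
        ranges = {k[7:]: (float(v[0]), float(v[1]))
                  for k, v in store.items() if k.startswith("range::")}
        for key, c in codes.items():
            node_name = key.rsplit("/", 1)[0]
            layer = net.by_name[node_name].layer
            layer.params["w"] = c.astype(np.float32) * np.float32(scales[key])
        for node_name, b in biases.items():
            layer = net.by_name[node_name].layer
            layer.params["b"] = b.astype(np.float32)
            layer.use_bias = True
        return cls(net, model.config, codes, scales, ranges)

    def forward(self, images: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(images, np.float32)
        if x.ndim == 3:
            x = x[..., None]
        acts = {"input": fake_quantize_affine(x, 0.0, 1.0)}
        for node in self.network.nodes:
            y = node.layer.forward(*[acts[i] for i in node.inputs])
            lo, hi = self.act_ranges[node.name]
            acts[node.name] = fake_quantize_affine(y, lo, hi)
        return {head: acts[name] for head, name in self.network.outputs.items()}

    def predict(self, image: np.ndarray):
        out = self.forward(image[None])
        return out["seg"][0], out["clf"][0]

    # -- export ----------------------------------------------------------
    def save(self, path) -> None:
        meta = {f"scale::{k}": v for k, v in self.weight_scales.items()}
        ranges = {f"range::{k}": np.asarray(v) for k, v in self.act_ranges.items()}
        biases = {f"bias::{k.rsplit('/', 1)[0]}": lay.params["b"]
                  for k, lay, pn, _ in self.network.parameters()
                  if pn == "b"}
        np.savez(path,
                 __input_size__=self.config.input_size,
                 **{f"code::{k}": v for k, v in self.weight_codes.items()},
                 **{k: np.float64(v) for k, v in meta.items()},
                 **ranges, **biases)


def quantize_model(model: MultitaskModel, calibration: np.ndarray,
                   spec: QuantSpec | None = None) -> QuantizedModel:
    """Fold normalization, fix scales from calibration, emit the int8 model."""
    return QuantizedModel.from_float(model, calibration, spec)
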