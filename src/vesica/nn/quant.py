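"""8-bit fixed-point quantization primitives.

Weights use per-tensor *symmetric* quantization (signed codes in
[-127, 127], zero exactly representable); activations use per-tensor
*affine* quantization (unsigned codes in [0, 255] with a zero point).
``fake_quantize_*`` round to the integer grid and immediately de-quantize,
which is the forward operation used during quantization-aware training;
gradients are passed straight through by the callers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class QuantSpec:
    """How the network is quantized for 8-bit fixed-point deployment."""

    bit_width: int = 8
    weight_scheme: str = "per-tensor-symmetric"
    activation_scheme: str = "per-tensor-affine"
    calibration_size: int = 16


def weight_scale(w: np.ndarray) -> float:
    """Symmetric per-tensor scale mapping max|w| onto code 127."""
    m = float(np.max(np.abs(w))) if w.size else 0.0
    if m == 0.0:
        return 1.0
    return m / 127.0


def quantize_weights(w: np.ndarray, scale: float | None = None):
    """Return (int8 codes, scale) for a weight tensor."""
    if scale is None:
        scale = weight_scale(w)
    codes = np.clip(np.round(w / scale), -127, 127).astype(np.int8)
    return codes, scale


def fake_quantize_symmetric(w: np.ndarray, scale: float | None = None) -> np.ndarray:
    codes, scale = quantize_weights(w, scale)
    return (codes.astype(np.float32) * np.float32(scale)).astype(np.float32)


def activation_range(samples: np.ndarray) -> tuple[float, float]:
    """Calibrated (min, max) for an activation tensor, always spanning 0."""
    lo = min(float(samples.min()), 0.0)
    hi = max(float(samples.max()), 0.0)
    if hi == lo:
        warnings.warn("degenerate activation range; falling back to scale 1")
        return 0.0, 255.0
    return lo, hi


def affine_params(lo: float, hi: float) -> tuple[float, int]:
    scale = (hi - lo) / 255.0
    zp = int(np.clip(round(-lo / scale), 0, 255))
    return scale, zp


def fake_quantize_affine(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    scale, zp = affine_params(lo, hi)
    q = np.clip(np.round(x / scale) + zp, 0, 255)
    return ((q - zp) * np.float32(scale)).astype(np.float32)
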