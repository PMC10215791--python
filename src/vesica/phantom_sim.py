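"""Synthetic B-mode biplane bladder phantom simulator.

Generates pairs of sagittal/transverse grayscale images with exact
geometric ground truth, emulating scans of tissue-mimicking bladder
phantoms.  The bladder is an ellipsoid with known semi-axes, pose and
volume; the surrounding medium is rendered as fully developed speckle
(exponentially distributed intensity — the squared magnitude of a
circular complex Gaussian scatter sum), log-compressed to 8 bits, and the
bladder interior is anechoic.  Simulation starts at the scan-converted
image: beamforming, demodulation and envelope detection are not modelled.

Coordinate conventions
----------------------
Physical frame: x = lateral position in the sagittal plane (mm),
y = lateral position in the transverse plane (mm), z = depth (mm,
increasing downward from the probe face).  Image row ``r`` maps to depth
``(r + 0.5) * spacing`` and column ``c`` to lateral
``(c + 0.5 - W/2) * spacing``.  Both planes cut the phantom through its
centre; optional per-plane cut offsets emulate free-hand probe placement.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError, OutOfViewError

#: factor applied to the mean background intensity inside the bladder lumen
ANECHOIC_FACTOR = 0.03
#: log-compression gain (dimensionless); chosen so speckle spans most of uint8
LOG_COMPRESSION_K = 50.0


@dataclass(frozen=True)
class Phantom3D:
    """Ellipsoidal bladder ground truth.

    semi_axes are (a, b, c) in mm along the body axes; rotation is an
    intrinsic x-y-z Euler triple in radians; center is (x, y, z) in mm in
    the physical frame above.  ``true_volume`` (mm^3) is derived.
    """

    semi_axes: tuple[float, float, float]
    center: tuple[float, float, float] = (0.0, 0.0, 60.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_volume: float = None  # type: ignore[assignment]

    def __post_init__(self):
        a, b, c = self.semi_axes
        if not (a > 0 and b > 0 and c > 0):
            raise InvalidArgumentError("all semi-axes must be positive")
        vol = 4.0 / 3.0 * np.pi * a * b * c
        if self.true_volume is None:
            object.__setattr__(self, "true_volume", vol)
        elif abs(self.true_volume - vol) > 1e-9 * vol:
            raise InvalidArgumentError("true_volume inconsistent with semi-axes")

    @property
    def volume_mL(self) -> float:
        return self.true_volume / 1000.0

    def rotation_matrix(self) -> np.ndarray:
        rx, ry, rz = self.rotation
        cx, sx = np.cos(rx), np.sin(rx)
        cy, sy = np.cos(ry), np.sin(ry)
        cz, sz = np.cos(rz), np.sin(rz)
        Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return Rz @ Ry @ Rx

    def half_extents(self) -> np.ndarray:
        """Support half-widths along the physical x, y, z axes (mm)."""
        R = self.rotation_matrix()
        return np.sqrt(((R * np.asarray(self.semi_axes)) ** 2).sum(axis=1))


@dataclass(frozen=True)
class ImagingConfig:
    """Rendering parameters of the simulated scanner.

    ``depth_setting`` (mm of imaged depth) overrides ``pixel_spacing`` when
    set: spacing = depth_setting / grid_height, emulating the depth knob.
    ``sector_angle`` enables a cosmetic sector crop when not None (masks are
    never cropped); the default view is rectilinear because large-volume
    cross-sections do not fit a 70-degree sector at this grid size.
    """

    grid_height: int = 330
    grid_width: int = 570
    pixel_spacing: float = 0.35
    sector_angle: float | None = None
    gain_offset: float = 0.0
    depth_setting: float | None = None
    speckle_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_height <= 0 or self.grid_width <= 0:
            raise InvalidArgumentError("grid dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise InvalidArgumentError("pixel_spacing must be positive")

    @property
    def spacing(self) -> float:
        if self.depth_setting is not None:
            return self.depth_setting / self.grid_height
        return self.pixel_spacing


@dataclass
class BiplaneSample:
    """A sagittal + transverse image pair with masks and metadata."""

    sagittal_image: np.ndarray
    transverse_image: np.ndarray
    sagittal_mask: np.ndarray
    transverse_mask: np.ndarray
    has_bladder: tuple[bool, bool]
    spacing: float
    phantom: Phantom3D | None = None

    def __post_init__(self):
        if self.sagittal_image.shape != self.sagittal_mask.shape:
            raise InvalidArgumentError("sagittal image/mask shape mismatch")
        if self.transverse_image.shape != self.transverse_mask.shape:
            raise InvalidArgumentError("transverse image/mask shape mismatch")
        for present, mask in zip(self.has_bladder, (self.sagittal_mask, self.transverse_mask)):
            if not present and mask.any():
                raise InvalidArgumentError("has_bladder false but mask non-empty")


# --------------------------------------------------------------------- sampling

def sample_phantom(
    target_volume_mL: float,
    eccentricity_range: tuple[float, float] = (0.7, 1.0),
    rng_seed: int = 0,
    center: tuple[float, float, float] | None = None,
    max_tilt: float = 0.25,
) -> Phantom3D:
    """Draw an ellipsoid of exactly the requested volume.

    The two minor/major semi-axis ratios are drawn uniformly from
    ``eccentricity_range`` and the leading semi-axis solved from
    V = (4/3) pi a b c, so the target volume is met to machine precision.
    """
    if not target_volume_mL > 0:
        raise InvalidArgumentError("target_volume_mL must be positive")
    lo, hi = eccentricity_range
    if not (0 < lo <= hi <= 1):
        raise InvalidArgumentError("eccentricity_range must lie in (0, 1]")
    rng = np.random.default_rng(rng_seed)
    r1 = rng.uniform(lo, hi)
    r2 = rng.uniform(lo, hi)
    vol_mm3 = target_volume_mL * 1000.0
    a = (3.0 * vol_mm3 / (4.0 * np.pi * r1 * r2)) ** (1.0 / 3.0)
    rotation = tuple(rng.uniform(-max_tilt, max_tilt, 3)) if max_tilt > 0 else (0.0, 0.0, 0.0)
    if center is None:
        center = (0.0, 0.0, 60.0)
    return Phantom3D(semi_axes=(a, a * r1, a * r2), center=center, rotation=rotation)


# -------------------------------------------------------------------- rendering

def _plane_grid(cfg: ImagingConfig):
    s = cfg.spacing
    z = (np.arange(cfg.grid_height) + 0.5) * s
    u = (np.arange(cfg.grid_width) + 0.5 - cfg.grid_width / 2.0) * s
    return np.meshgrid(u, z)  # (lateral, depth), each (H, W)


def _section_mask(phantom: Phantom3D, cfg: ImagingConfig, plane: str, cut_offset: float):
    """Exact rasterized interior of the ellipsoid's planar cross-section."""
    U, Z = _plane_grid(cfg)
    cx, cy, cz = phantom.center
    if plane == "sagittal":
        P = np.stack([U, np.full_like(U, cy + cut_offset), Z], axis=-1)
    else:
        P = np.stack([np.full_like(U, cx + cut_offset), U, Z], axis=-1)
    Q = (P - np.array([cx, cy, cz])) @ phantom.rotation_matrix()
    Q /= np.asarray(phantom.semi_axes)
    return (Q**2).sum(-1) <= 1.0


def _sector_mask(cfg: ImagingConfig) -> np.ndarray | None:
    if cfg.sector_angle is None:
        return None
    U, Z = _plane_grid(cfg)
    half = np.deg2rad(cfg.sector_angle / 2.0)
    return np.abs(U) <= np.tan(half) * Z


def _log_compress(intensity: np.ndarray, gain_offset: float) -> np.ndarray:
    k = LOG_COMPRESSION_K
    y = 255.0 * np.log1p(k * intensity) / np.log1p(k * 4.0) + gain_offset
    return np.clip(np.round(y), 0, 255).astype(np.uint8)


def _speckle(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Mixture of a uniform mean level and exponential speckle intensity."""
    if scale == 0:
        return np.ones(shape)
    return (1.0 - scale) + scale * rng.exponential(1.0, shape)


def _render_plane(mask, cfg, rng, posterior_enhancement=False):
    intensity = _speckle(rng, mask.shape, cfg.speckle_scale)
    if mask.any():
        intensity = np.where(mask, intensity * ANECHOIC_FACTOR, intensity)
        if posterior_enhancement:
            cols = mask.any(axis=0)
            last = np.where(mask, np.arange(mask.shape[0])[:, None], -1).max(axis=0)
            boost = (np.arange(mask.shape[0])[:, None] > last[None, :]) & cols[None, :]
            intensity = np.where(boost, intensity * 1.6, intensity)
    img = _log_compress(intensity, cfg.gain_offset)
    sector = _sector_mask(cfg)
    if sector is not None:
        img = np.where(sector, img, 0).astype(np.uint8)
    return img


def check_in_view(phantom: Phantom3D, cfg: ImagingConfig) -> None:
    """Raise :class:`OutOfViewError` naming the first violating axis."""
    hx, hy, hz = phantom.half_extents()
    cx, cy, cz = phantom.center
    s = cfg.spacing
    half_w = cfg.grid_width / 2.0 * s
    depth = cfg.grid_height * s
    if abs(cx) + hx > half_w:
        raise OutOfViewError("phantom exceeds the lateral field of view on the x axis")
    if abs(cy) + hy > half_w:
        raise OutOfViewError("phantom exceeds the lateral field of view on the y axis")
    if cz - hz < 0 or cz + hz > depth:
        raise OutOfViewError("phantom exceeds the imaged depth on the z axis")
    sector = _sector_mask(cfg)
    if sector is not None:
        half = np.deg2rad(cfg.sector_angle / 2.0)
        z_top = cz - hz
        if max(abs(cx) + hx, abs(cy) + hy) > np.tan(half) * z_top:
            raise OutOfViewError("phantom exceeds the sector on the lateral axes")


def render_biplane(
    phantom: Phantom3D,
    cfg: ImagingConfig,
    plane_offsets: tuple[float, float] = (0.0, 0.0),
    posterior_enhancement: bool = False,
) -> BiplaneSample:
    """Render the central sagittal (x-z) and transverse (y-z) sections."""
    check_in_view(phantom, cfg)
    rng = np.random.default_rng(cfg.seed)
    sag_mask = _section_mask(phantom, cfg, "sagittal", plane_offsets[0])
    trn_mask = _section_mask(phantom, cfg, "transverse", plane_offsets[1])
    sag_img = _render_plane(sag_mask, cfg, rng, posterior_enhancement)
    trn_img = _render_plane(trn_mask, cfg, rng, posterior_enhancement)
    return BiplaneSample(
        sagittal_image=sag_img,
        transverse_image=trn_img,
        sagittal_mask=sag_mask,
        transverse_mask=trn_mask,
        has_bladder=(bool(sag_mask.any()), bool(trn_mask.any())),
        spacing=cfg.spacing,
        phantom=phantom,
    )


def render_negative(cfg: ImagingConfig) -> BiplaneSample:
    """A bladder-free speckle pair (both masks all-zero)."""
    rng = np.random.default_rng(cfg.seed)
    zero = np.zeros((cfg.grid_height, cfg.grid_width), bool)
    sag = _render_plane(zero, cfg, rng)
    trn = _render_plane(zero, cfg, rng)
    return BiplaneSample(sag, trn, zero, zero.copy(), (False, False), cfg.spacing, None)


# ---------------------------------------------------------------- dataset build

def _place_phantom(volume_mL, rng, cfg: ImagingConfig) -> Phantom3D:
    """Sample a phantom and a random in-view centre (free-hand ROI placement)."""
    base = sample_phantom(volume_mL, rng_seed=int(rng.integers(2**31)))
    hx, hy, hz = base.half_extents()
    s = cfg.spacing
    margin = 2.0 * s
    half_w = cfg.grid_width / 2.0 * s
    depth = cfg.grid_height * s
    def span(h, lim):
        room = lim - h - margin
        return rng.uniform(-room, room) if room > 0 else 0.0
    lo_z, hi_z = hz + margin, depth - hz - margin
    cz = rng.uniform(lo_z, hi_z) if hi_z > lo_z else depth / 2.0
    center = (span(hx, half_w), span(hy, half_w), cz)
    return dataclasses.replace(base, center=center, true_volume=None)


def generate_sample(
    volume_mL: float,
    cfg: ImagingConfig,
    rng: np.random.Generator,
    plane_offset_frac: float = 0.2,
) -> BiplaneSample:
    """One randomized positive sample: volume, pose, position, gain, depth."""
    draw_cfg = dataclasses.replace(
        cfg,
        gain_offset=cfg.gain_offset + rng.uniform(-15, 15),
        seed=int(rng.integers(2**31)),
    )
    phantom = _place_phantom(volume_mL, rng, draw_cfg)
    hx, hy, _ = phantom.half_extents()
    offsets = (
        rng.uniform(-plane_offset_frac, plane_offset_frac) * hy,
        rng.uniform(-plane_offset_frac, plane_offset_frac) * hx,
    )
    return render_biplane(phantom, draw_cfg, plane_offsets=offsets)


def generate_negative(cfg: ImagingConfig, rng: np.random.Generator) -> BiplaneSample:
    draw_cfg = dataclasses.replace(
        cfg,
        gain_offset=cfg.gain_offset + rng.uniform(-15, 15),
        seed=int(rng.integers(2**31)),
    )
    return render_negative(draw_cfg)


MANIFEST_COLUMNS = [
    "path_sagittal",
    "path_transverse",
    "mask_sagittal",
    "mask_transverse",
    "split",
    "has_bladder",
    "true_volume_mL",
    "spacing_mm",
]


def make_dataset(
    n_pos_train: int,
    n_pos_val: int,
    n_neg_train: int,
    n_neg_val: int,
    volume_range: tuple[float, float] = (50.0, 300.0),
    master_seed: int = 0,
    out_dir: str | Path = "data",
    cfg: ImagingConfig | None = None,
    write_images: bool = True,
) -> pd.DataFrame:
    """Write a seeded synthetic dataset and return its manifest.

    Each manifest row is one biplane sample (a sagittal/transverse pair plus
    masks).  ``write_images=False`` produces the manifest bookkeeping only,
    useful for split accounting at full acquisition-scale counts.
    """
    for n in (n_pos_train, n_pos_val, n_neg_train, n_neg_val):
        if n < 0:
            raise InvalidArgumentError("counts must be non-negative")
    cfg = cfg or ImagingConfig()
    out = Path(out_dir)
    if write_images:
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(master_seed)
    rows = []

    def emit(split, positive, idx):
        stem = f"{split}_{'pos' if positive else 'neg'}_{idx:05d}"
        if positive:
            vol = rng.uniform(*volume_range)
            sample = generate_sample(vol, cfg, rng) if write_images else None
            true_vol = round(vol, 4)
        else:
            sample = generate_negative(cfg, rng) if write_images else None
            true_vol = ""
        paths = {
            "path_sagittal": f"images/{stem}_sag.png",
            "path_transverse": f"images/{stem}_trn.png",
            "mask_sagittal": f"masks/{stem}_sag.png",
            "mask_transverse": f"masks/{stem}_trn.png",
        }
        if sample is not None:
            iio.imwrite(out / paths["path_sagittal"], sample.sagittal_image)
            iio.imwrite(out / paths["path_transverse"], sample.transverse_image)
            iio.imwrite(out / paths["mask_sagittal"], sample.sagittal_mask.astype(np.uint8) * 255)
            iio.imwrite(out / paths["mask_transverse"], sample.transverse_mask.astype(np.uint8) * 255)
            spacing = sample.spacing
        else:
            spacing = cfg.spacing
        rows.append(
            {**paths, "split": split, "has_bladder": positive,
             "true_volume_mL": true_vol, "spacing_mm": round(spacing, 6)}
        )

    for i in range(n_pos_train):
        emit("train", True, i)
    for i in range(n_pos_val):
        emit("val", True, i)
    for i in range(n_neg_train):
        emit("train", False, i)
    for i in range(n_neg_val):
        emit("val", False, i)

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
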