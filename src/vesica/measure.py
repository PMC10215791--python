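"""Biplane axis detection and shape-coefficient volume estimation.

Given bladder masks on the two orthogonal planes, the bladder *depth* is
the longer of the two chords cut by the diagonals of the minimum-area
rotated bounding box on the sagittal mask; *height* and *width* are the
maximum per-column and per-row pixel extents of the transverse mask.  The
volume is then

    volume = c * depth * height * width        (axes in cm, volume in mL)

with the shape coefficient ``c`` looked up from an empirical table
(0.52 sphere ... 0.89 cuboid, 0.72 for an unknown shape).  When a trained
model is supplied, its classification head gates the measurement: if
either plane is judged bladder-free the segmentation is considered
invalid and no volume is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import label as cc_label

from .exceptions import DegenerateRegionError, InvalidArgumentError, NoRegionError
from .net_arch import postprocess, preprocess
from .phantom_sim import BiplaneSample

#: empirical shape-label -> coefficient table (dimensionless, in (0, 1])
SHAPE_COEFFICIENTS = {
    "unknown": 0.72,
    "triangular prism": 0.66,
    "cylinder": 0.81,
    "cuboid": 0.89,
    "spherical": 0.52,
}


@dataclass(frozen=True)
class AxisMeasurements:
    depth: float  # mm, sagittal plane
    height: float  # mm, transverse plane
    width: float  # mm, transverse plane
    spacing: float  # mm / pixel of the source masks

    def __post_init__(self):
        if not (self.depth > 0 and self.height > 0 and self.width > 0):
            raise InvalidArgumentError("axis measurements must be positive")


@dataclass(frozen=True)
class VolumeEstimate:
    volume: float | None  # mL; None when detection failed on either plane
    coefficient: float
    shape_label: str
    axes: AxisMeasurements | None
    detected: tuple[bool, bool]  # (sagittal, transverse)


# ------------------------------------------------------------------ regions

def largest_region(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        return np.zeros_like(mask)
    lab, n = cc_label(mask, connectivity=2, return_num=True)
    if n == 1:
        return mask.copy()
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def _corner_cloud(mask: np.ndarray) -> np.ndarray:
    """(x, y) corners of the foreground pixels' unit squares (boundary only)."""
    from scipy.ndimage import binary_erosion

    boundary = mask & ~binary_erosion(mask)
    rr, cc = np.nonzero(boundary)
    if len(rr) == 0:
        raise NoRegionError("mask has no foreground region")
    pts = np.stack([cc.astype(float), rr.astype(float)], axis=1)
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    return (pts[:, None, :] + offs[None]).reshape(-1, 2)


def min_area_bbox(mask: np.ndarray, axis_aligned: bool = False) -> np.ndarray:
    """Minimum-area enclosing rectangle of the foreground, as 4 (x, y) corners.

    Corners are ordered clockwise on screen (y grows downward) starting at
    the topmost corner (leftmost on ties).  ``axis_aligned=True`` returns
    the plain bounding box instead.
    """
    mask = np.asarray(mask, bool)
    pts = _corner_cloud(mask)
    if axis_aligned:
        (x0, y0), (x1, y1) = pts.min(0), pts.max(0)
        corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        return _order_corners(corners)
    if len(np.unique(pts, axis=0)) <= 2:
        raise NoRegionError("region degenerate: fewer than three distinct corners")
    hull = pts[ConvexHull(pts).vertices]
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    best = None
    for ang in angles:
        rot = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
        proj = hull @ rot.T
        lo, hi = proj.min(0), proj.max(0)
        area = np.prod(hi - lo)
        if best is None or area < best[0]:
            best = (area, ang, lo, hi)
    _, ang, lo, hi = best
    rect = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    inv = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    return _order_corners(rect @ inv.T)


def _order_corners(corners: np.ndarray) -> np.ndarray:
    """Clockwise on screen, starting from the topmost(-leftmost) corner."""
    ctr = corners.mean(0)
    # screen clockwise == increasing atan2 with y pointing down
    ang = np.arctan2(corners[:, 1] - ctr[1], corners[:, 0] - ctr[0])
    corners = corners[np.argsort(ang)]
    start = np.lexsort((corners[:, 0], corners[:, 1]))[0]
    return np.roll(corners, -start, axis=0)


# ------------------------------------------------------------------- chords

def _chord_along(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> float:
    """Length (px) between the outermost mask intersections of segment p0-p1."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(length * 4), 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = p0[None] + ts[:, None] * (p1 - p0)[None]
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, mask.shape[0] - 1)
    inside = mask[rows, cols]
    idx = np.nonzero(inside)[0]
    if len(idx) < 2:
        raise DegenerateRegionError("diagonal intersects the region in fewer than 2 pixels")
    return float(np.hypot(*(pts[idx[-1]] - pts[idx[0]])))


def depth_from_sagittal(mask: np.ndarray, spacing: float,
                        axis_aligned: bool = False) -> float:
    """Depth (mm): the greater diagonal chord of the min-area box.

    Both diagonals of the rotated bounding box are rasterized; each chord
    runs between its first and last intersection with the region (the
    outermost pair, robust to re-entrant contours).  Ties go to the
    diagonal leaving the top(-left) corner.
    """
    mask = largest_region(mask)
    if not mask.any():
        raise NoRegionError("empty mask")
    c = min_area_bbox(mask, axis_aligned=axis_aligned)
    chord_a = _chord_along(mask, c[0], c[2])
    chord_b = _chord_along(mask, c[1], c[3])
    return max(chord_a, chord_b) * spacing if chord_b > chord_a else chord_a * spacing


def height_width_from_transverse(mask: np.ndarray, spacing: float,
                                 mode: str = "extent") -> tuple[float, float]:
    """(height, width) in mm from per-column / per-row extents.

    ``mode="extent"`` (default) takes the maximum first-to-last foreground
    span over all columns (height) and rows (width); ``mode="center_chord"``
    instead measures the vertical/horizontal chords through the bounding-box
    centre.
    """
    mask = largest_region(np.asarray(mask, bool))
    if not mask.any():
        raise NoRegionError("empty mask")
    if mode == "center_chord":
        c = min_area_bbox(mask, axis_aligned=True)
        ctr = c.mean(0)
        h = _chord_along(mask, np.array([ctr[0], 0.0]),
                         np.array([ctr[0], mask.shape[0] - 1.0]))
        w = _chord_along(mask, np.array([0.0, ctr[1]]),
                         np.array([mask.shape[1] - 1.0, ctr[1]]))
        return h * spacing, w * spacing

    def max_extent(m):
        any_col = m.any(axis=0)
        first = m.argmax(axis=0)
        last = m.shape[0] - 1 - m[::-1].argmax(axis=0)
        return int((last - first + 1)[any_col].max())

    height = max_extent(mask)
    width = max_extent(mask.T)
    return height * spacing, width * spacing


# -------------------------------------------------------------------- volume

def estimate_volume(axes: AxisMeasurements, shape_label: str = "unknown",
                    coefficient: float | None = None,
                    detected: tuple[bool, bool] = (True, True)) -> VolumeEstimate:
    """Apply the shape-coefficient formula; axes in mm, volume in mL."""
    if coefficient is None:
        key = shape_label.strip().lower().replace("_", " ")
        if key not in SHAPE_COEFFICIENTS:
            raise InvalidArgumentError(
                f"unknown shape label {shape_label!r}; valid labels: "
                f"{sorted(SHAPE_COEFFICIENTS)}"
            )
        coefficient = SHAPE_COEFFICIENTS[key]
    vol = coefficient * (axes.depth / 10.0) * (axes.height / 10.0) * (axes.width / 10.0)
    return VolumeEstimate(vol, coefficient, shape_label, axes, detected)


def measure_masks(sag_mask: np.ndarray, trn_mask: np.ndarray, spacing: float,
                  shape_label: str = "unknown", coefficient: float | None = None,
                  axis_aligned: bool = False) -> VolumeEstimate:
    """Full geometric measurement from a pair of binary masks."""
    sag = largest_region(sag_mask)
    trn = largest_region(trn_mask)
    depth = depth_from_sagittal(sag, spacing, axis_aligned=axis_aligned)
    height, width = height_width_from_transverse(trn, spacing)
    axes = AxisMeasurements(depth, height, width, spacing)
    return estimate_volume(axes, shape_label, coefficient)


def auto_measure(sample: BiplaneSample, model=None, shape_label: str = "unknown",
                 coefficient: float | None = None, spacing: float | None = None,
                 axis_aligned: bool = False) -> VolumeEstimate:
    """End-to-end measurement of a biplane sample.

    ``model`` may be a trained (float or quantized) multitask model exposing
    ``predict``; with ``model=None`` the sample's ground-truth masks and
    labels are injected instead (the geometry-only oracle route).  No
    volume is emitted unless *both* planes are classified bladder-positive.
    """
    spacing = sample.spacing if spacing is None else spacing
    if model is None:
        det_sag, det_trn = sample.has_bladder
        sag_mask, trn_mask = sample.sagittal_mask, sample.transverse_mask
    else:
        size = model.config.input_size
        seg_s, clf_s = model.predict(preprocess(sample.sagittal_image, size))
        seg_t, clf_t = model.predict(preprocess(sample.transverse_image, size))
        det_sag = bool(np.argmax(clf_s) == 1)
        det_trn = bool(np.argmax(clf_t) == 1)
        sag_mask = postprocess(seg_s, sample.sagittal_image.shape)
        trn_mask = postprocess(seg_t, sample.transverse_image.shape)
    if coefficient is None:
        key = shape_label.strip().lower().replace("_", " ")
        if key not in SHAPE_COEFFICIENTS:
            raise InvalidArgumentError(
                f"unknown shape label {shape_label!r}; valid labels: "
                f"{sorted(SHAPE_COEFFICIENTS)}"
            )
        coeff = SHAPE_COEFFICIENTS[key]
    else:
        coeff = coefficient
    if not (det_sag and det_trn):
        return VolumeEstimate(None, coeff, shape_label, None, (det_sag, det_trn))
    try:
        est = measure_masks(sag_mask, trn_mask, spacing, shape_label, coeff,
                            axis_aligned=axis_aligned)
    except (NoRegionError, DegenerateRegionError) as err:
        plane = "sagittal" if not largest_region(sag_mask).any() else "transverse"
        raise type(err)(f"{err} (plane: {plane})") from err
    return VolumeEstimate(est.volume, coeff, shape_label, est.axes, (det_sag, det_trn))
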