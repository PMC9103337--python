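"""Geometric camera calibration from a circular-slot grid.

The calibration target is an aluminium plate machined with a regular grid
of circular slots (4 mm diameter, 10 mm center-to-center pitch by
default), imaged in the egg position.  The slots appear as dark blobs on
the bright plate; sub-pixel centers are recovered by intensity-weighted
centroiding, and the millimetre-per-pixel scale follows from the mean
adjacent center-to-center distance along the two grid axes.

Distortion is modelled, optionally, by a single first-order radial term
about the image center: r_distorted = r * (1 + k1 * r^2).  With a 50 mm
lens at ~40 cm working distance the residual distortion is small, so the
default pipeline is scale-only (k1 = 0); the model is there to be
estimated and applied when the optics warrant it.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import minimize_scalar
from skimage.filters import threshold_otsu

from .errors import DetectionError, GeometryError, ParameterError

__all__ = [
    "GridSpec",
    "CalibrationResult",
    "detect_grid_centers",
    "estimate_scale",
    "estimate_k1",
    "correct_distortion",
    "distort_points",
    "undistort_points",
]


@dataclass
class GridSpec:
    """Geometry of the circular-slot calibration target."""

    pitch_mm: float = 10.0
    slot_diameter_mm: float = 4.0
    rows: int | None = None
    cols: int | None = None

    def __post_init__(self) -> None:
        if not self.pitch_mm > self.slot_diameter_mm > 0:
            raise ParameterError("require pitch_mm > slot_diameter_mm > 0")


@dataclass
class CalibrationResult:
    """Scale estimate with the residual of the detected centers to a regular grid."""

    scale_mm_per_px: float
    rms_residual_px: float
    n_slots_used: int
    radial_k1: float | None = None

    def __post_init__(self) -> None:
        if not self.scale_mm_per_px > 0:
            raise ParameterError("scale_mm_per_px must be > 0")
        if self.rms_residual_px < 0 or self.n_slots_used < 2:
            raise ParameterError("invalid calibration result")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationResult":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def detect_grid_centers(image: np.ndarray, min_blob_px: int = 4) -> np.ndarray:
    """Sub-pixel slot centers, ordered row-major by grid position.

    Otsu binarization -> connected components -> intensity-weighted
    centroids.  The slot polarity (dark on bright plate, or the reverse)
    is taken as the minority class.  Returns an (n, 2) array of
    (row, col) centers.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise DetectionError("grid image must be 2-D")
    if np.ptp(img) == 0:
        raise DetectionError("uniform image: no slots detectable")
    thr = threshold_otsu(img)
    dark = img < thr
    mask = dark if 0 < dark.mean() <= 0.5 else ~dark
    labels, n = ndi.label(mask)
    if n == 0:
        raise DetectionError("no blobs found")
    background = np.median(img[~mask]) if (~mask).any() else img.max()
    slots_dark = np.median(img[mask]) < background
    contrast = np.clip(background - img if slots_dark else img - background, 0.0, None)
    centers = []
    for idx in range(1, n + 1):
        blob = labels == idx
        if blob.sum() < min_blob_px:
            continue
        # include the feathered edge ring so sub-pixel centroids are unbiased
        support = ndi.binary_dilation(blob, iterations=2)
        w = contrast * support
        total = w.sum()
        if total <= 0:
            continue
        rr, cc = np.nonzero(support)
        centers.append((float((w[rr, cc] * rr).sum() / total),
                        float((w[rr, cc] * cc).sum() / total)))
    if len(centers) < 2:
        raise DetectionError(f"only {len(centers)} usable blobs detected (need >= 2)")
    return _order_row_major(np.asarray(centers))


def _principal_axes(centers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two dominant grid directions, from nearest-neighbor vectors.

    A regular square grid is an *isotropic* point cloud, so PCA axes are
    degenerate; nearest-neighbor directions folded modulo 90 degrees give
    the grid rotation robustly instead.  Returns unit axes (u, v) with u
    within 45 degrees of the column direction.
    """
    import math

    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    vecs = centers[nn] - centers
    alpha = np.arctan2(vecs[:, 0], vecs[:, 1])  # angle from the column axis
    phi = float(np.angle(np.sum(np.exp(4j * alpha))) / 4.0)
    u = np.array([math.sin(phi), math.cos(phi)])
    v = np.array([math.cos(phi), -math.sin(phi)])
    if v[0] < 0:
        v = -v
    return u, v


def _nearest_neighbor_distance(centers: np.ndarray) -> float:
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def _grid_indices(centers: np.ndarray) -> np.ndarray:
    """Integer (i, j) grid coordinates for each center."""
    u, v = _principal_axes(centers)
    pu = centers @ u
    pv = centers @ v
    step = _nearest_neighbor_distance(centers)
    if not np.isfinite(step) or step <= 0:
        raise GeometryError("degenerate center configuration")
    gi = np.round((pv - pv.min()) / step).astype(int)
    gj = np.round((pu - pu.min()) / step).astype(int)
    return np.column_stack([gi, gj])

def _order_row_major(centers: np.ndarray) -> np.ndarray:
    if len(centers) == 2:
        order = np.lexsort((centers[:, 1], centers[:, 0]))
        return centers[order]
    ij = _grid_indices(centers)
    order = np.lexsort((ij[:, 1], ij[:, 0]))
    return centers[order]


def _regular_grid_residual(centers: np.ndarray) -> float:
    """RMS distance of centers to the best-fit affine regular grid."""
    if len(centers) < 4:
        return 0.0
    ij = _grid_indices(centers)
    basis = np.column_stack([ij, np.ones(len(centers))])
    sol, *_ = np.linalg.lstsq(basis, centers, rcond=None)
    resid = centers - basis @ sol
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def estimate_scale(centers: np.ndarray, spec: GridSpec | None = None) -> CalibrationResult:
    """mm-per-pixel scale from the mean adjacent center-to-center distance.

    Adjacent means nearest neighbors along the grid axes (no diagonals):
    pairs whose separation is within 25% of the median nearest-neighbor
    distance.  Deterministic; invariant to image gain/offset because it
    only consumes coordinates.
    """
    spec = spec or GridSpec()
    centers = np.asarray(centers, dtype=np.float64)
    if centers.ndim != 2 or centers.shape[1] != 2 or len(centers) < 2:
        raise DetectionError("need an (n >= 2, 2) array of centers")
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    iu = np.triu_indices(len(centers), k=1)
    pair_d = d[iu]
    if pair_d.max() < 1e-9:
        raise GeometryError("all centers coincident")
    np.fill_diagonal(d, np.inf)
    d_nn = np.median(d.min(axis=1))
    if d_nn < 1e-9:
        raise GeometryError("coincident centers in the grid")
    adjacent = pair_d[(pair_d > 1e-9) & (pair_d <= 1.25 * d_nn)]
    if adjacent.size == 0:
        raise GeometryError("no adjacent center pairs found")
    mean_pitch_px = float(adjacent.mean())
    scale = spec.pitch_mm / mean_pitch_px
    rms = _regular_grid_residual(centers)
    return CalibrationResult(
        scale_mm_per_px=scale, rms_residual_px=rms, n_slots_used=len(centers)
    )


# ---------------------------------------------------------------------------
# first-order radial distortion
# ---------------------------------------------------------------------------

def _image_center(shape: tuple[int, int]) -> np.ndarray:
    return np.array([(shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0])


def distort_points(points: np.ndarray, k1: float, center: np.ndarray) -> np.ndarray:
    """Apply r -> r (1 + k1 r^2) about ``center`` to (row, col) points."""
    p = np.asarray(points, dtype=np.float64) - center
    r2 = np.sum(p**2, axis=-1, keepdims=True)
    return center + p * (1.0 + k1 * r2)


def undistort_points(
    points: np.ndarray, k1: float, center: np.ndarray, iterations: int = 8
) -> np.ndarray:
    """Invert the radial model by fixed-point iteration (k1 r^2 << 1)."""
    p_d = np.asarray(points, dtype=np.float64) - center
    p_u = p_d.copy()
    for _ in range(iterations):
        r2 = np.sum(p_u**2, axis=-1, keepdims=True)
        p_u = p_d / (1.0 + k1 * r2)
    return center + p_u


def estimate_k1(
    centers: np.ndarray,
    image_shape: tuple[int, int],
    bounds: tuple[float, float] = (-1e-6, 1e-6),
) -> float:
    """Radial coefficient k1 (px^-2) minimizing the regular-grid residual.

    Detected (distorted) centers are undistorted with a trial k1 and
    compared to the best-fit affine grid; on an undistorted grid the
    minimum sits at k1 = 0.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if len(centers) < 6:
        raise DetectionError("need >= 6 centers to estimate distortion")
    c0 = _image_center(image_shape)

    def cost(k1: float) -> float:
        return _regular_grid_residual(undistort_points(centers, k1, c0))

    res = minimize_scalar(cost, bounds=bounds, method="bounded",
                          options={"xatol": 1e-13})
    return float(res.x)


def correct_distortion(image: np.ndarray, result: CalibrationResult) -> np.ndarray:
    """Resample the image onto undistorted coordinates.

    Identity (bit-exact copy) when ``radial_k1`` is null or zero.  Output
    pixel (r, c) samples the input at the distorted position of (r, c)
    with bilinear interpolation.
    """
    img = np.asarray(image, dtype=np.float64)
    k1 = result.radial_k1
    if not k1:
        return img.copy()
    c0 = _image_center(img.shape)
    rr, cc = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]), indexing="ij")
    pts = np.stack([rr.ravel(), cc.ravel()], axis=1)
    src = distort_points(pts, k1, c0)
    out = ndi.map_coordinates(img, [src[:, 0], src[:, 1]], order=1, mode="nearest")
    return out.reshape(img.shape)
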