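"""Air-chamber sizing from a raw PT frame and a PPT phase image.

The measurement exploits the complementary strengths of the two images:
the egg outline is sharp in a raw cooling frame but the chamber edge is
blurred, while the phase image renders the chamber edge crisply but
blurs the shell.  The hybrid procedure is therefore:

1. segment the egg from the background in the raw frame (Otsu, largest
   connected component, holes filled);
2. segment the air-chamber projection inside the egg in the phase image;
3. crop the phase image to the egg's bounding rectangle and zero the
   background -> the *hybrid image*, a dark, homogeneous field around the
   bright chamber projection;
4. for several rows crossing the chamber, smooth the brightness profile
   with a smoothing spline and locate the perimeter points P1 (left of
   the chamber center) and P2 (right) where the profile crosses the
   threshold w_th = b_max / 3, one third of the row's maximum smoothed
   brightness — a heuristic fraction that generalizes across eggs
   because it is relative, not absolute;
5. fit an ellipse (direct least-squares conic fit) to the >= 5 collected
   points; its semi-axes a (minor) and b (major), converted to mm by the
   calibration scale, give the projected area A_b = pi*a*b and the
   single-view volume proxy A_b^(3/2).

The lateral view yields the chamber height c: per row, the external
profile is the last positive-brightness column (the shell), the internal
profile the last upward w_th-crossing before it; c averages the
difference over the dull-pole rows (those whose external column is
within 10% of the egg length of the global maximum).

Freshness grading applies the EU marketing thresholds: air-chamber
height at most 6 mm for marketable eggs, at most 4 mm within 9 days of
laying for "extra fresh".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from scipy.interpolate import make_smoothing_spline
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel

from .calibration import CalibrationResult
from .errors import (
    FitError,
    GeometryError,
    InsufficientPointsError,
    OviThermError,
    ParameterError,
    SegmentationError,
    UngradableError,
)

__all__ = [
    "Flag",
    "Grade",
    "EggMask",
    "HybridImage",
    "RowProfile",
    "BoundaryPoint",
    "EllipseFit",
    "AirChamberMeasurement",
    "segment_egg",
    "segment_air_chamber",
    "make_hybrid_image",
    "find_boundary_points",
    "fit_ellipse",
    "quality_flags",
    "measure_front",
    "measure_lateral",
    "grade_freshness",
]

logger = logging.getLogger("ovitherm.sizing")

#: fraction of the row maximum used as the perimeter threshold (w_th = b_max / 3)
THRESHOLD_FRACTION = 1.0 / 3.0

#: EU regulatory limits on the air-chamber height
MARKETABLE_MAX_HEIGHT_MM = 6.0
EXTRA_FRESH_MAX_HEIGHT_MM = 4.0
EXTRA_FRESH_MAX_DAYS = 9


class Flag(str, Enum):
    """Advisory quality flags; flagged measurements are emitted, not dropped."""

    NEAR_PERIMETER = "near_perimeter"
    HOLES = "holes"
    LATERAL_INVISIBLE = "lateral_invisible"
    FIT_FAILED = "fit_failed"


class Grade(str, Enum):
    EXTRA_FRESH = "extra_fresh"
    MARKETABLE = "marketable"
    NOT_MARKETABLE = "not_marketable"


@dataclass
class EggMask:
    """Single connected egg region with its tight half-open bounding rectangle."""

    mask: np.ndarray
    bounding_rect: tuple[int, int, int, int]  # (row_min, col_min, row_max, col_max)

    @classmethod
    def from_mask(cls, mask: np.ndarray) -> "EggMask":
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        if rows.size == 0:
            raise GeometryError("empty egg mask")
        rect = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        return cls(mask=mask.astype(bool), bounding_rect=rect)


@dataclass
class HybridImage:
    """Phase-derived brightness cropped to the egg bounding rectangle.

    Background (outside the egg mask) is exactly 0; within the egg the
    phase is affinely shifted so its minimum maps to 0.
    """

    values: np.ndarray
    origin: tuple[int, int]


@dataclass
class RowProfile:
    """One row's raw and spline-smoothed brightness profile."""

    row_index: int
    raw: np.ndarray
    smoothed: np.ndarray
    center_col: float

    @property
    def b_max(self) -> float:
        return float(self.smoothed.max())

    @property
    def w_th(self) -> float:
        return self.b_max * THRESHOLD_FRACTION


@dataclass
class BoundaryPoint:
    """A chamber-perimeter point (P1 left of the center, P2 right of it)."""

    kind: str  # "P1" | "P2"
    position: tuple[float, float]  # (row, col); col is sub-pixel
    brightness: float


@dataclass
class EllipseFit:
    center: tuple[float, float]  # (row, col)
    semi_axis_a_px: float  # minor
    semi_axis_b_px: float  # major
    rotation_deg: float
    rms_residual_px: float
    n_points: int

    def __post_init__(self) -> None:
        if not 0 < self.semi_axis_a_px <= self.semi_axis_b_px:
            raise FitError("require 0 < a <= b")
        if self.n_points < 5:
            raise InsufficientPointsError("an ellipse fit needs >= 5 points")


@dataclass
class AirChamberMeasurement:
    """Final measurement: semi-axes, height, area, volume proxy, flags.

    ``A_b_mm2 = pi * a_mm * b_mm`` and ``V_proxy_mm3 = A_b_mm2^(3/2)``
    whenever the inputs are present; fields are None when the pipeline
    could not produce them (see ``flags``).
    """

    a_mm: float | None = None
    b_mm: float | None = None
    c_mm: float | None = None
    A_b_mm2: float | None = None
    V_proxy_mm3: float | None = None
    flags: set[Flag] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.a_mm is not None and self.b_mm is not None and self.A_b_mm2 is None:
            self.A_b_mm2 = math.pi * self.a_mm * self.b_mm
        if self.A_b_mm2 is not None and self.V_proxy_mm3 is None:
            self.V_proxy_mm3 = self.A_b_mm2**1.5

    @property
    def valid(self) -> bool:
        return Flag.FIT_FAILED not in self.flags


def _values(image) -> np.ndarray:
    """Accept a bare array or a PhaseImage-like object with ``.values``."""
    return np.asarray(getattr(image, "values", image), dtype=np.float64)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def segment_egg(raw_frame: np.ndarray, min_area: int = 500) -> EggMask:
    """Separate the egg (bright foreground) from the background.

    Otsu binarization, keep the largest connected component, fill holes.
    Raises :class:`SegmentationError` when no component reaches
    ``min_area`` pixels.
    """
    img = _values(raw_frame)
    if img.ndim != 2:
        raise SegmentationError("raw frame must be 2-D")
    if np.ptp(img) == 0:
        raise SegmentationError("uniform frame: no foreground")
    thr = threshold_otsu(img)
    fg = img > thr
    labels, n = ndi.label(fg)
    if n == 0:
        raise SegmentationError("no foreground component")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_area:
        raise SegmentationError(
            f"largest component has {int(sizes[largest - 1])} px < min_area={min_area}"
        )
    mask = ndi.binary_fill_holes(labels == largest)
    return EggMask.from_mask(mask)


def _otsu_separation(values: np.ndarray, thr: float) -> float:
    """Between-class variance fraction of an Otsu split (0..1)."""
    total = values.var()
    if total <= 0:
        return 0.0
    lo = values[values <= thr]
    hi = values[values > thr]
    if lo.size == 0 or hi.size == 0:
        return 0.0
    p = hi.size / values.size
    return float((1 - p) * p * (hi.mean() - lo.mean()) ** 2 / total)


def segment_air_chamber(
    phase_image,
    egg: EggMask,
    threshold: str | float = "otsu",
    min_separation: float = 0.75,
) -> np.ndarray:
    """Segment the air-chamber projection inside the egg in the phase image.

    Binarization restricted to within-egg phase values: Otsu by default,
    or a fixed phase threshold (degrees).  The largest above-threshold
    component is kept.  Returns a boolean mask (full image size), which
    is empty — not an exception — when no contrast is found: with Otsu,
    a split whose between-class variance fraction is below
    ``min_separation`` is treated as "no chamber" (an Otsu split of pure
    noise explains ~0.64 of the variance, a genuine chamber > 0.9).
    """
    ph = _values(phase_image)
    if ph.shape != egg.mask.shape:
        raise GeometryError("phase image and egg mask dimensions differ")
    inside = egg.mask
    vals = ph[inside]
    finite = vals[np.isfinite(vals)]
    empty = np.zeros_like(inside, dtype=bool)
    if finite.size < 2 or np.ptp(finite) == 0:
        return empty
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ParameterError(f"unknown threshold method {threshold!r}")
        thr = threshold_otsu(finite)
        if _otsu_separation(finite, thr) < min_separation:
            logger.info("chamber segmentation: no significant phase contrast")
            return empty
    else:
        thr = float(threshold)
    fg = inside & np.greater(np.nan_to_num(ph, nan=-np.inf), thr)
    labels, n = ndi.label(fg)
    if n == 0:
        return empty
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def make_hybrid_image(raw_frame, phase_image, egg: EggMask) -> HybridImage:
    """Crop the phase image to the egg bounding rect and zero the background.

    Within the egg, phase is affinely shifted so the minimum within-egg
    value maps to brightness 0 (undefined NaN phases also map to 0).
    ``raw_frame`` participates only through ``egg`` (segmented from it);
    it is accepted here so the call mirrors the processing chain.
    """
    del raw_frame  # the raw image enters via the egg mask
    ph = _values(phase_image)
    if ph.shape != egg.mask.shape:
        raise GeometryError("phase image and egg mask dimensions differ")
    r0, c0, r1, c1 = egg.bounding_rect
    if r1 <= r0 or c1 <= c0:
        raise GeometryError("degenerate bounding rectangle")
    crop = ph[r0:r1, c0:c1]
    inside = egg.mask[r0:r1, c0:c1]
    vals = np.zeros(crop.shape, dtype=np.float64)
    finite_inside = inside & np.isfinite(crop)
    if finite_inside.any():
        mn = crop[finite_inside].min()
        vals[finite_inside] = crop[finite_inside] - mn
    return HybridImage(values=vals, origin=(r0, c0))


# ---------------------------------------------------------------------------
# row profiles and perimeter points
# ---------------------------------------------------------------------------

def _smooth_profile(y: np.ndarray) -> np.ndarray:
    """Cubic smoothing spline of a row profile.

    The penalty is chosen (by bisection on log-lambda) so the residual
    RMS matches a robust noise estimate from second differences
    (MAD-based); on a noise-free profile this degenerates to
    near-interpolation.  A penalized spline is a *linear* smoother, so a
    symmetric profile stays symmetric to floating-point precision.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if n < 4:
        return y.copy()
    d2 = np.diff(y, 2)
    sigma = 1.4826 * np.median(np.abs(d2 - np.median(d2))) / math.sqrt(6.0)
    if sigma <= 0:
        return y.copy()
    x = np.arange(n, dtype=np.float64)

    def rms(lam: float) -> float:
        sm = make_smoothing_spline(x, y, lam=lam)(x)
        return math.sqrt(float(np.mean((sm - y) ** 2)))

    lo, hi = -12.0, 12.0  # log10 lambda bracket
    if rms(10.0**lo) >= sigma:
        return make_smoothing_spline(x, y, lam=10.0**lo)(x)
    if rms(10.0**hi) <= sigma:
        return make_smoothing_spline(x, y, lam=10.0**hi)(x)
    for _ in range(40):
        mid = (lo + hi) / 2.0
        if rms(10.0**mid) < sigma:
            lo = mid
        else:
            hi = mid
    return make_smoothing_spline(x, y, lam=10.0 ** ((lo + hi) / 2.0))(x)


def _upward_crossing_left(
    sm: np.ndarray, w_th: float, stop: int, raw: np.ndarray | None = None
) -> float | None:
    """Sub-pixel column of the last upward w_th-crossing at or before ``stop``.

    The crossing *bracket* is found on the smoothed profile (robust to
    noise); the sub-pixel *position* interpolates the raw samples of the
    bracket when they still bracket the threshold — the raw samples
    carry the sharp edge that global smoothing widens — and falls back
    to the smoothed samples otherwise.
    """
    hi = min(stop, sm.size - 2)
    for j in range(hi, -1, -1):
        if sm[j] < w_th <= sm[j + 1]:
            lo_v, hi_v = sm[j], sm[j + 1]
            if raw is not None and raw[j] < w_th <= raw[j + 1]:
                lo_v, hi_v = raw[j], raw[j + 1]
            return j + (w_th - lo_v) / (hi_v - lo_v)
    return None


def _downward_crossing_right(
    sm: np.ndarray, w_th: float, start: int, raw: np.ndarray | None = None
) -> float | None:
    """Sub-pixel column of the first downward w_th-crossing at or after ``start``."""
    lo = max(start, 1)
    for j in range(lo, sm.size):
        if sm[j] < w_th <= sm[j - 1]:
            hi_v, lo_v = sm[j - 1], sm[j]
            if raw is not None and raw[j] < w_th <= raw[j - 1]:
                hi_v, lo_v = raw[j - 1], raw[j]
            return (j - 1) + (hi_v - w_th) / (hi_v - lo_v)
    return None


def find_boundary_points(
    hybrid: HybridImage,
    chamber_center: tuple[float, float],
    rows: list[int],
) -> list[BoundaryPoint]:
    """Perimeter points P1/P2 on the requested rows of the hybrid image.

    Per row: spline-smooth the profile, set w_th = b_max / 3, then locate
    P1 as the last sub-threshold position scanning from column 0 up to
    the chamber-center column, and P2 symmetrically from the center to
    the row end.  Sub-pixel positions come from linear interpolation of
    the threshold crossing (on the raw samples of the detected bracket,
    which carry the sharp edge; see ``_upward_crossing_left``).  A side
    with no crossing contributes no point (logged).
    """
    center_col = float(chamber_center[1])
    points: list[BoundaryPoint] = []
    for r in rows:
        raw = hybrid.values[int(r)]
        sm = _smooth_profile(raw)
        b_max = float(sm.max())
        if b_max <= 0:
            logger.info("row %d: empty profile, skipped", r)
            continue
        w_th = b_max * THRESHOLD_FRACTION
        profile = RowProfile(row_index=int(r), raw=raw, smoothed=sm, center_col=center_col)
        ic = int(math.floor(center_col))
        p1 = _upward_crossing_left(sm, w_th, ic, raw=raw)
        p2 = _downward_crossing_right(sm, w_th, max(ic, 0) + 1, raw=raw)
        logger.debug(
            "row %d: b_max=%.3f w_th=%.3f P1=%s P2=%s", r, b_max, w_th, p1, p2
        )
        if p1 is not None:
            points.append(BoundaryPoint("P1", (float(r), float(p1)), profile.w_th))
        else:
            logger.info("row %d: no w_th crossing left of center, P1 omitted", r)
        if p2 is not None:
            points.append(BoundaryPoint("P2", (float(r), float(p2)), profile.w_th))
        else:
            logger.info("row %d: no w_th crossing right of center, P2 omitted", r)
    return points


# ---------------------------------------------------------------------------
# ellipse fit
# ---------------------------------------------------------------------------

def fit_ellipse(points) -> EllipseFit:
    """Direct least-squares conic fit constrained to an ellipse.

    ``points`` may be BoundaryPoints or an (n, 2) array of (row, col)
    positions.  Requires >= 5 points (the minimum determining an
    ellipse).  Returns semi-axes with a = minor, b = major; rotation is
    fitted, not constrained.
    """
    if len(points) and isinstance(points[0], BoundaryPoint):
        pos = np.array([p.position for p in points], dtype=np.float64)
    else:
        pos = np.asarray(points, dtype=np.float64)
    if pos.ndim != 2 or pos.shape[1] != 2:
        raise ParameterError("points must be (n, 2) (row, col)")
    if len(pos) < 5:
        raise InsufficientPointsError(
            f"{len(pos)} points; the minimum number of points to fit an ellipse is 5"
        )
    xy = pos[:, ::-1]  # EllipseModel works in (x, y) = (col, row)
    model = EllipseModel.from_estimate(xy)
    if not model:
        raise FitError(f"conic fit failed: {model}")
    xc, yc = (float(v) for v in model.center)
    ax, ay = (float(v) for v in model.axis_lengths)
    theta = float(model.theta)
    if not all(np.isfinite([xc, yc, ax, ay, theta])) or ax <= 0 or ay <= 0:
        raise FitError("fit did not produce a valid ellipse")
    if ax <= ay:
        a, b = ax, ay
        rot = theta + math.pi / 2.0
    else:
        a, b = ay, ax
        rot = theta
    rot_deg = math.degrees((rot + math.pi / 2.0) % math.pi - math.pi / 2.0)
    residuals = model.residuals(xy)
    rms = float(np.sqrt(np.mean(residuals**2)))
    logger.debug("ellipse fit: a=%.3f b=%.3f rms=%.4f n=%d", a, b, rms, len(pos))
    return EllipseFit(
        center=(yc, xc),
        semi_axis_a_px=a,
        semi_axis_b_px=b,
        rotation_deg=rot_deg,
        rms_residual_px=rms,
        n_points=len(pos),
    )


# ---------------------------------------------------------------------------
# quality flags and full-view measurements
# ---------------------------------------------------------------------------

def quality_flags(
    chamber_mask: np.ndarray,
    egg: EggMask,
    d_min: float = 3.0,
    hole_frac: float = 0.02,
) -> set[Flag]:
    """Advisory flags for the two documented error modes.

    ``near_perimeter``: the chamber approaches the egg boundary to within
    ``d_min`` px, where the brightness transition degrades.  ``holes``:
    the chamber mask's filled area exceeds its raw area by more than
    ``hole_frac`` (internal cavities from shell defects).
    """
    if chamber_mask.shape != egg.mask.shape:
        raise GeometryError("masks must share dimensions")
    flags: set[Flag] = set()
    if not chamber_mask.any():
        return flags
    filled = ndi.binary_fill_holes(chamber_mask)
    raw_area = int(chamber_mask.sum())
    if filled.sum() > raw_area * (1.0 + hole_frac):
        flags.add(Flag.HOLES)
    dist_inside = ndi.distance_transform_edt(egg.mask)
    if float(dist_inside[chamber_mask].min()) < d_min:
        flags.add(Flag.NEAR_PERIMETER)
    return flags


def _chamber_rows(ch_crop: np.ndarray, n_rows: int, row_span: float) -> list[int]:
    rows = np.flatnonzero(ch_crop.any(axis=1))
    r_lo, r_hi = int(rows[0]), int(rows[-1])
    margin = (1.0 - row_span) / 2.0 * (r_hi - r_lo)
    picks = np.linspace(r_lo + margin, r_hi - margin, n_rows)
    return sorted(set(int(round(p)) for p in picks))


def measure_front(
    raw_frame,
    phase_image,
    calib: CalibrationResult,
    n_rows: int = 9,
    row_span: float = 0.8,
    min_area: int = 500,
    threshold: str | float = "otsu",
    d_min: float = 3.0,
    hole_frac: float = 0.02,
) -> AirChamberMeasurement:
    """Front-view pipeline: semi-axes, area and volume proxy in mm units.

    Runs segmentation -> hybrid image -> boundary points on ``n_rows``
    evenly spaced rows over the central ``row_span`` of the chamber ->
    ellipse fit -> unit conversion.  Any stage failure returns a
    measurement with the ``fit_failed`` flag and null geometry instead of
    raising, so batch processing continues.
    """
    scale = calib.scale_mm_per_px
    flags: set[Flag] = set()
    try:
        egg = segment_egg(raw_frame, min_area=min_area)
        ph = _values(phase_image)
        chamber = segment_air_chamber(ph, egg, threshold=threshold)
        if not chamber.any():
            logger.warning("front view: empty chamber mask")
            return AirChamberMeasurement(flags={Flag.FIT_FAILED})
        flags |= quality_flags(chamber, egg, d_min=d_min, hole_frac=hole_frac)
        hybrid = make_hybrid_image(raw_frame, ph, egg)
        r0, c0, r1, c1 = egg.bounding_rect
        ch_crop = chamber[r0:r1, c0:c1]
        rows = _chamber_rows(ch_crop, n_rows=n_rows, row_span=row_span)
        com = ndi.center_of_mass(ch_crop)
        points = find_boundary_points(hybrid, com, rows)
        fit = fit_ellipse(points)
        a_mm = fit.semi_axis_a_px * scale
        b_mm = fit.semi_axis_b_px * scale
        logger.info(
            "front view: a=%.2f mm b=%.2f mm (%d points, rms %.3f px) flags=%s",
            a_mm, b_mm, fit.n_points, fit.rms_residual_px, sorted(f.value for f in flags),
        )
        return AirChamberMeasurement(a_mm=a_mm, b_mm=b_mm, flags=flags)
    except OviThermError as exc:
        logger.warning("front view measurement failed: %s", exc)
        return AirChamberMeasurement(flags=flags | {Flag.FIT_FAILED})


def measure_lateral(
    raw_frame,
    phase_image,
    calib: CalibrationResult,
    dull_pole_band: float = 0.10,
    min_area: int = 500,
    threshold: str | float = "otsu",
    min_visible_px: float = 1.0,
) -> tuple[float | None, set[Flag]]:
    """Lateral-view chamber height c (mm) from external/internal profiles.

    Expects the package's lateral orientation: long axis horizontal, dull
    pole at the maximum-column side.  Per row of the dull-pole region
    (external column within ``dull_pole_band`` of the egg length from the
    global maximum), height = external column (last positive brightness)
    minus internal column (last upward w_th crossing).  When the two
    profiles are indistinguishable (difference < ``min_visible_px`` px,
    or missing, on more than half of the region rows) the chamber is
    declared invisible and c is None.
    """
    scale = calib.scale_mm_per_px
    try:
        egg = segment_egg(raw_frame, min_area=min_area)
        ph = _values(phase_image)
        chamber = segment_air_chamber(ph, egg, threshold=threshold)
        if not chamber.any():
            logger.info("lateral view: no chamber phase contrast")
            return None, {Flag.LATERAL_INVISIBLE}
        hybrid = make_hybrid_image(raw_frame, ph, egg)
        r0, c0, r1, c1 = egg.bounding_rect
        inside = egg.mask[r0:r1, c0:c1]
        egg_length = c1 - c0
        height, width = hybrid.values.shape
        externals = np.full(height, -1, dtype=int)
        for r in range(height):
            cols = np.flatnonzero(inside[r])
            if cols.size:
                externals[r] = int(cols[-1])
        max_ext = externals.max()
        region = np.flatnonzero(externals >= max_ext - dull_pole_band * egg_length)
        gaps: list[float | None] = []
        for r in region:
            ext = externals[r]
            if ext < 4:
                gaps.append(None)
                continue
            raw_row = hybrid.values[r, : ext + 1]
            sm = _smooth_profile(raw_row)
            b_max = float(sm.max())
            if b_max <= 0:
                gaps.append(None)
                continue
            w_th = b_max * THRESHOLD_FRACTION
            internal = _upward_crossing_left(sm, w_th, ext - 1, raw=raw_row)
            gaps.append(None if internal is None else float(ext) - internal)
        n_invisible = sum(1 for g in gaps if g is None or g < min_visible_px)
        if not gaps or n_invisible > 0.5 * len(gaps):
            logger.info(
                "lateral view: chamber indistinguishable on %d/%d dull-pole rows",
                n_invisible, len(gaps),
            )
            return None, {Flag.LATERAL_INVISIBLE}
        valid = [g for g in gaps if g is not None and g >= min_visible_px]
        c_px = float(np.mean(valid))
        c_mm = c_px * scale
        logger.info(
            "lateral view: c=%.2f mm over %d dull-pole rows", c_mm, len(valid)
        )
        return c_mm, set()
    except OviThermError as exc:
        logger.warning("lateral view measurement failed: %s", exc)
        return None, {Flag.FIT_FAILED}


def grade_freshness(c_mm: float | None, days_since_laying: int) -> Grade:
    """EU marketing grade from air-chamber height and age.

    "Extra fresh" requires height <= 4 mm within 9 days of laying;
    marketable eggs must not exceed 6 mm (boundary inclusive).
    """
    if c_mm is None or (isinstance(c_mm, float) and math.isnan(c_mm)):
        raise UngradableError("no chamber-height measurement to grade")
    if c_mm < 0 or days_since_laying < 0:
        raise ParameterError("height and age must be non-negative")
    if c_mm <= EXTRA_FRESH_MAX_HEIGHT_MM and days_since_laying <= EXTRA_FRESH_MAX_DAYS:
        return Grade.EXTRA_FRESH
    if c_mm <= MARKETABLE_MAX_HEIGHT_MM:
        return Grade.MARKETABLE
    return Grade.NOT_MARKETABLE
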