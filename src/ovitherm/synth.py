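"""Synthetic thermogram, calibration-grid and cohort generators.

Every downstream module is exercised against phantoms with exact ground
truth, so nothing here depends on recorded data.  The forward model is a
sum of exponential cooling decays, not a heat-diffusion solve: after the
flash frame, pixel brightness is

    ambient + egg * A * exp(-t / tau_egg)
            + chamber * dA * exp(-t / tau_air)
            + reflections (fast-decaying Gaussian spots)
            + N(0, noise_sd)

with t measured from the flash.  The air in the chamber has far less
thermal inertia than the egg's organic interior, so it heats more and
cools faster (tau_air << tau_egg); that difference is exactly what gives
the chamber its raw-image and phase-image contrast, and exponentials
reproduce it with controllable ground truth.  After a brief pulse the
*surface* response of a solid decays fast (t^(-1/2)-like), so the
egg-body constant defaults to a sub-second value (0.7 s) rather than a
bulk-cooling scale; this also keeps realistic low-frequency power in
every pixel, without which the phase would be dominated by sensor
noise.  Flash reflections decay on the ~10 ms scale of the flash
itself, which makes them bright in early raw frames but strongly
attenuated in the phase image — the behaviour the phase transform is
used for.

Default amplitudes anchor to the acquisition hardware: flash contrast
100 digital levels standing in for the < 1 degC overheating, and noise
sd = 2 DL (2% of the flash contrast, the NETD-to-contrast ratio of a
cooled MWIR camera).  Egg outlines are two half-ellipses sharing the
minor axis (a blunter dull pole), adequate for segmentation and
bounding-rectangle behaviour; shell texture and diffusion physics are
deliberately out of scope.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import CalibrationResult, GridSpec, distort_points
from .errors import GeometryError, ParameterError, PhantomError
from .sizing import AirChamberMeasurement
from .thermo_io import Category, ThermogramSequence, View, AcquisitionSet

__all__ = [
    "Reflection",
    "EggPhantom",
    "random_phantom",
    "random_reflections",
    "generate_sequence",
    "generate_grid",
    "generate_cohort",
    "render_acquisition",
    "synthetic_calibration",
]

#: default pixel pitch of the synthetic camera (mm per pixel)
DEFAULT_SCALE = 0.25

#: front-view egg semi-axes (rows, cols) per size category, mm
CATEGORY_FRONT_SEMI_MM = {
    Category.M: (19.0, 20.0),
    Category.L: (20.0, 21.0),
    Category.XL: (21.0, 22.0),
}


@dataclass(frozen=True)
class Reflection:
    """A localized flash-reflection artifact (offsets from image center, mm)."""

    row_mm: float
    col_mm: float
    amplitude: float = 80.0
    radius_mm: float = 0.8
    tau_s: float = 0.01


@dataclass(frozen=True)
class EggPhantom:
    """Ground-truth egg geometry and cooling parameters.

    The front view is an ellipse; the lateral outline is two
    half-ellipses sharing the vertical axis, with the blunter (dull)
    pole on the maximum-column side.  The chamber is a rotated ellipse
    in the front view and a cap of thickness ``c_mm`` inside the dull
    pole in the lateral view.
    """

    scale_mm_per_px: float = DEFAULT_SCALE
    front_semi_mm: tuple[float, float] = (20.0, 21.0)  # (rows, cols)
    lateral_length_mm: float = 57.0
    lateral_width_mm: float = 43.0
    blunt_fraction: float = 0.45  # dull-pole half-length / total length
    chamber_a_mm: float = 6.0  # minor semi-axis
    chamber_b_mm: float = 8.0  # major semi-axis
    chamber_center_offset_mm: tuple[float, float] = (0.0, 0.0)
    chamber_rotation_deg: float = 0.0
    c_mm: float = 3.0
    tau_egg_s: float = 0.7
    tau_air_s: float = 0.12
    flash_amplitude: float = 100.0
    chamber_amplitude: float = 100.0
    ambient_level: float = 1000.0
    noise_sd: float = 2.0
    reflections: tuple[Reflection, ...] = ()
    chamber_hole_mm: tuple[float, float, float] | None = None  # (row, col, radius)
    allow_near_perimeter: bool = False
    margin_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tau_air_s == self.tau_egg_s:
            raise PhantomError("tau_air must differ from tau_egg (zero phase contrast)")
        if min(self.tau_air_s, self.tau_egg_s) <= 0:
            raise PhantomError("decay constants must be positive")
        if not 0 < self.chamber_a_mm <= self.chamber_b_mm:
            raise PhantomError("require 0 < chamber_a_mm <= chamber_b_mm")
        if self.c_mm < 0:
            raise PhantomError("c_mm must be >= 0")
        self._check_chamber_inside()

    def _check_chamber_inside(self) -> None:
        er, ec = self.front_semi_mm
        t = np.linspace(0.0, 2 * math.pi, 73)
        rot = math.radians(self.chamber_rotation_deg)
        # chamber boundary: minor axis along rows at rotation 0
        dr = self.chamber_a_mm * np.cos(t) * math.cos(rot) - self.chamber_b_mm * np.sin(
            t
        ) * math.sin(rot)
        dc = self.chamber_a_mm * np.cos(t) * math.sin(rot) + self.chamber_b_mm * np.sin(
            t
        ) * math.cos(rot)
        rr = self.chamber_center_offset_mm[0] + dr
        cc = self.chamber_center_offset_mm[1] + dc
        outside = (rr / er) ** 2 + (cc / ec) ** 2 > 1.0
        if outside.any() and not self.allow_near_perimeter:
            raise PhantomError(
                "chamber extends outside the egg outline "
                "(set allow_near_perimeter=True for the degraded-case phantom)"
            )

    # ---- pixel-space geometry -------------------------------------------
    def _px(self, mm: float) -> float:
        return mm / self.scale_mm_per_px

    def image_shape(self, view: View | str) -> tuple[int, int]:
        m = self._px(self.margin_mm)
        if View(view) is View.FRONT:
            er, ec = (self._px(v) for v in self.front_semi_mm)
            return (int(math.ceil(2 * (er + m))), int(math.ceil(2 * (ec + m))))
        half_w = self._px(self.lateral_width_mm) / 2.0
        length = self._px(self.lateral_length_mm)
        return (int(math.ceil(2 * (half_w + m))), int(math.ceil(length + 2 * m)))

    def coverage(self, view: View | str, supersample: int = 3):
        """(egg, chamber) area-coverage arrays in [0, 1] for one view."""
        view = View(view)
        shape = self.image_shape(view)
        ss = supersample
        rows = (np.arange(shape[0] * ss) + 0.5) / ss - 0.5
        cols = (np.arange(shape[1] * ss) + 0.5) / ss - 0.5
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        r0 = (shape[0] - 1) / 2.0
        c0 = (shape[1] - 1) / 2.0
        if view is View.FRONT:
            er, ec = (self._px(v) for v in self.front_semi_mm)
            egg = ((rr - r0) / er) ** 2 + ((cc - c0) / ec) ** 2 <= 1.0
            a_px = self._px(self.chamber_a_mm)
            b_px = self._px(self.chamber_b_mm)
            cr = r0 + self._px(self.chamber_center_offset_mm[0])
            ccol = c0 + self._px(self.chamber_center_offset_mm[1])
            rot = math.radians(self.chamber_rotation_deg)
            u = (rr - cr) * math.cos(rot) + (cc - ccol) * math.sin(rot)
            v = -(rr - cr) * math.sin(rot) + (cc - ccol) * math.cos(rot)
            chamber = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
            if self.chamber_hole_mm is not None:
                hr, hc, hrad = (self._px(v) for v in self.chamber_hole_mm)
                hole = (rr - (cr + hr)) ** 2 + (cc - (ccol + hc)) ** 2 <= hrad**2
                chamber &= ~hole
            chamber &= egg
        else:
            egg = self._lateral_inside(rr, cc, r0, c0, shrink_px=0.0)
            if self.c_mm > 0:
                inner = self._lateral_inside(rr, cc, r0, c0, shrink_px=self._px(self.c_mm))
                chamber = egg & ~inner
            else:
                chamber = np.zeros_like(egg)
        egg_cov = egg.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))
        ch_cov = chamber.reshape(shape[0], ss, shape[1], ss).mean(axis=(1, 3))
        return egg_cov, ch_cov

    def _lateral_inside(self, rr, cc, r0, c0, shrink_px: float):
        half_w = self._px(self.lateral_width_mm) / 2.0
        length = self._px(self.lateral_length_mm)
        ax_right = length * self.blunt_fraction - shrink_px  # dull pole (max col)
        ax_left = length * (1.0 - self.blunt_fraction)
        ax_right = max(ax_right, 1.0)
        ax = np.where(cc >= c0, ax_right, ax_left)
        return ((rr - r0) / half_w) ** 2 + ((cc - c0) / ax) ** 2 <= 1.0

    def truth(self, view: View | str) -> dict:
        """Ground-truth masks and parameters for one view."""
        view = View(view)
        egg_cov, ch_cov = self.coverage(view)
        out = {
            "view": view.value,
            "egg_mask": egg_cov >= 0.5,
            "chamber_mask": ch_cov >= 0.5,
            "scale_mm_per_px": self.scale_mm_per_px,
        }
        if view is View.FRONT:
            out.update(
                a_mm=self.chamber_a_mm,
                b_mm=self.chamber_b_mm,
                a_px=self._px(self.chamber_a_mm),
                b_px=self._px(self.chamber_b_mm),
                A_b_mm2=math.pi * self.chamber_a_mm * self.chamber_b_mm,
            )
        else:
            out.update(c_mm=self.c_mm, c_px=self._px(self.c_mm))
        return out


def generate_sequence(
    phantom: EggPhantom,
    view: View | str = View.FRONT,
    T: int = 64,
    frame_rate_hz: float = 100.0,
    flash_frame_index: int = 0,
    egg_id: str = "synthetic",
    category: Category | None = None,
    days_since_laying: int = 0,
    weight_g: float | None = None,
) -> tuple[ThermogramSequence, dict]:
    """Render a thermogram sequence and return it with its ground truth.

    Deterministic for a given (phantom, view) — the noise stream is
    seeded from ``phantom.seed``.
    """
    if T < 8:
        raise ParameterError("need T >= 8 frames")
    view = View(view)
    egg_cov, ch_cov = phantom.coverage(view)
    shape = egg_cov.shape
    rng = np.random.default_rng(phantom.seed)
    dt = 1.0 / frame_rate_hz
    r0 = (shape[0] - 1) / 2.0
    c0 = (shape[1] - 1) / 2.0

    refl_fields = []
    for refl in phantom.reflections:
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
        pr = r0 + refl.row_mm / phantom.scale_mm_per_px
        pc = c0 + refl.col_mm / phantom.scale_mm_per_px
        rad = max(refl.radius_mm / phantom.scale_mm_per_px, 0.5)
        g = np.exp(-((rr - pr) ** 2 + (cc - pc) ** 2) / (2.0 * rad**2))
        refl_fields.append((refl, g))

    frames = np.empty((T,) + shape, dtype=np.float64)
    for n in range(T):
        frame = np.full(shape, phantom.ambient_level, dtype=np.float64)
        if n == flash_frame_index:
            # the flash itself: uniform glare on top of the instant egg response
            frame += 2.0 * phantom.flash_amplitude
            frame += egg_cov * phantom.flash_amplitude
            frame += ch_cov * phantom.chamber_amplitude
            for refl, g in refl_fields:
                frame += refl.amplitude * g
        elif n > flash_frame_index:
            t = (n - flash_frame_index) * dt
            frame += egg_cov * phantom.flash_amplitude * math.exp(-t / phantom.tau_egg_s)
            frame += ch_cov * phantom.chamber_amplitude * math.exp(-t / phantom.tau_air_s)
            for refl, g in refl_fields:
                frame += refl.amplitude * math.exp(-t / refl.tau_s) * g
        frames[n] = frame
    if phantom.noise_sd > 0:
        frames += rng.normal(0.0, phantom.noise_sd, frames.shape)

    seq = ThermogramSequence(
        frames=frames,
        frame_rate_hz=frame_rate_hz,
        flash_frame_index=flash_frame_index,
        view=view,
        egg_id=egg_id,
        category=category,
        days_since_laying=days_since_laying,
        weight_g=weight_g,
    )
    return seq, phantom.truth(view)


def random_reflections(
    seed: int,
    front_semi_mm: tuple[float, float],
    n: int = 2,
) -> tuple[Reflection, ...]:
    """Randomly placed fast-decay reflection spots over the egg region."""
    rng = np.random.default_rng(seed)
    return tuple(
        Reflection(
            row_mm=float(rng.uniform(-0.6 * front_semi_mm[0], 0.6 * front_semi_mm[0])),
            col_mm=float(rng.uniform(-0.6 * front_semi_mm[1], 0.6 * front_semi_mm[1])),
            amplitude=float(rng.uniform(40.0, 90.0)),
            radius_mm=float(rng.uniform(0.5, 1.0)),
        )
        for _ in range(n)
    )


def random_phantom(
    seed: int,
    category: Category | str = Category.L,
    noise_sd: float = 2.0,
    n_reflections: int = 2,
    semi_axis_range_mm: tuple[float, float] = (4.0, 12.0),
) -> EggPhantom:
    """A randomized phantom: chamber semi-axes drawn in ``semi_axis_range_mm``,
    random mild offset/rotation, and fast-decay reflection spots."""
    category = Category(category)
    rng = np.random.default_rng(seed)
    lo, hi = semi_axis_range_mm
    s1, s2 = rng.uniform(lo, hi, size=2)
    a, b = min(s1, s2), max(s1, s2)
    front = CATEGORY_FRONT_SEMI_MM[category]
    # keep the chamber comfortably inside the egg outline
    max_off = max(front[0] - b - 2.0, 0.0) / 2.0
    offset = tuple(rng.uniform(-max_off, max_off, size=2))
    reflections = random_reflections(
        int(rng.integers(0, 2**31 - 1)), front, n=n_reflections
    )
    return EggPhantom(
        front_semi_mm=front,
        chamber_a_mm=float(a),
        chamber_b_mm=float(b),
        chamber_center_offset_mm=(float(offset[0]), float(offset[1])),
        chamber_rotation_deg=float(rng.uniform(0.0, 180.0)),
        c_mm=float(rng.uniform(2.0, 5.0)),
        noise_sd=noise_sd,
        reflections=reflections,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# calibration grid
# ---------------------------------------------------------------------------

def generate_grid(
    spec: GridSpec | None = None,
    scale_mm_per_px: float = DEFAULT_SCALE,
    rows: int = 5,
    cols: int = 5,
    noise_sd: float = 0.0,
    seed: int = 0,
    margin_px: float = 12.0,
    image_shape: tuple[int, int] | None = None,
    k1: float | None = None,
    plate_level: float = 1000.0,
    contrast: float = 200.0,
    omit: set[tuple[int, int]] = frozenset(),
) -> tuple[np.ndarray, np.ndarray]:
    """Render the circular-slot calibration plate; returns (image, centers).

    Dark slots on a bright plate at the spec'd pitch and diameter.  Slot
    edges are linearly feathered over one pixel (area-coverage
    approximation), so intensity-weighted centroids are unbiased.
    ``omit`` skips grid positions (occlusion tests); ``k1`` pre-distorts
    slot positions with the radial model.  True centers are returned
    row-major, after distortion if any.
    """
    spec = spec or GridSpec()
    pitch_px = spec.pitch_mm / scale_mm_per_px
    radius_px = spec.slot_diameter_mm / 2.0 / scale_mm_per_px
    start = margin_px + radius_px
    extent_r = 2 * start + (rows - 1) * pitch_px
    extent_c = 2 * start + (cols - 1) * pitch_px
    if image_shape is None:
        image_shape = (int(math.ceil(extent_r)), int(math.ceil(extent_c)))
    H, W = image_shape
    if extent_r > H + 1e-9 or extent_c > W + 1e-9:
        raise GeometryError(f"{rows}x{cols} grid does not fit in image {image_shape}")
    centers = np.array(
        [
            (start + i * pitch_px, start + j * pitch_px)
            for i in range(rows)
            for j in range(cols)
            if (i, j) not in omit
        ]
    )
    if k1:
        c0 = np.array([(H - 1) / 2.0, (W - 1) / 2.0])
        centers = distort_points(centers, k1, c0)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    cov = np.zeros((H, W), dtype=np.float64)
    for r_c, c_c in centers:
        dist = np.sqrt((rr - r_c) ** 2 + (cc - c_c) ** 2)
        cov = np.maximum(cov, np.clip(radius_px + 0.5 - dist, 0.0, 1.0))
    img = plate_level - contrast * cov
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img, centers


def synthetic_calibration(scale_mm_per_px: float = DEFAULT_SCALE) -> CalibrationResult:
    """An exact calibration result for phantoms rendered at a known scale."""
    return CalibrationResult(
        scale_mm_per_px=scale_mm_per_px, rms_residual_px=0.0, n_slots_used=2
    )


# ---------------------------------------------------------------------------
# aging cohorts
# ---------------------------------------------------------------------------

#: mean daily weight loss (g/day) per category under accelerated storage
_WEIGHT_RATE_G_PER_DAY = {Category.M: 0.16, Category.L: 0.19, Category.XL: 0.22}
#: normalized-area-vs-weight-loss law A/A0 = 1 + b1 dw + b2 dw^2 per category
_AREA_BETA = {
    Category.M: (0.20, -0.010),
    Category.L: (0.18, -0.009),
    Category.XL: (0.16, -0.008),
}
_WEIGHT_RANGE_G = {Category.M: (54.0, 62.0), Category.L: (64.0, 72.0), Category.XL: (74.0, 82.0)}


def generate_cohort(
    n_per_category: int = 10,
    days: tuple[int, ...] = tuple(range(3, 32, 2)),
    seed: int = 0,
    weight_noise_sd: float = 0.05,
    area_noise_frac: float = 0.01,
    c_noise_sd_mm: float = 0.05,
    rate_jitter: float = 0.02,
):
    """Synthetic aging cohort with exact ground truth.

    Per egg, weight falls linearly with elapsed time (category-dependent
    rate) and the normalized chamber area follows a quadratic law in the
    weight loss — almost linear early, flattening late.  The chamber
    height grows linearly.  With all noise/jitter parameters at zero the
    emitted measurements satisfy the area law exactly.

    Returns ``(records, truth)``: a list of
    :class:`~ovitherm.aging.AgingRecord` and a tidy DataFrame of the
    underlying true trajectories.
    """
    from .aging import AgingRecord  # deferred: aging imports sizing types

    if n_per_category < 1:
        raise ParameterError("n_per_category must be >= 1")
    if list(days) != sorted(days):
        raise ParameterError("days must be sorted ascending")
    import pandas as pd

    rng = np.random.default_rng(seed)
    records: list = []
    truth_rows = []
    for category in Category:
        beta1, beta2 = _AREA_BETA[category]
        for idx in range(n_per_category):
            egg_id = f"{category.value}{idx + 1}"
            w0 = rng.uniform(*_WEIGHT_RANGE_G[category])
            rate = _WEIGHT_RATE_G_PER_DAY[category] * (1.0 + rate_jitter * rng.standard_normal())
            a0 = rng.uniform(4.5, 5.5)
            ratio = rng.uniform(1.15, 1.35)
            b0 = a0 * ratio
            A0 = math.pi * a0 * b0
            c0 = rng.uniform(1.8, 2.4)
            c_rate = rng.uniform(0.10, 0.14)
            for day in days:
                elapsed = day - days[0]
                dw = rate * elapsed
                A_true = A0 * (1.0 + beta1 * dw + beta2 * dw**2)
                c_true = c0 + c_rate * elapsed
                A_meas = A_true * (1.0 + area_noise_frac * rng.standard_normal())
                a_meas = math.sqrt(A_meas / (math.pi * ratio))
                b_meas = ratio * a_meas
                c_meas = c_true + c_noise_sd_mm * rng.standard_normal()
                w_meas = w0 - dw + weight_noise_sd * rng.standard_normal()
                records.append(
                    AgingRecord(
                        egg_id=egg_id,
                        category=category,
                        days_since_laying=day,
                        weight_g=float(w_meas),
                        measurement=AirChamberMeasurement(
                            a_mm=float(a_meas), b_mm=float(b_meas), c_mm=float(c_meas)
                        ),
                    )
                )
                truth_rows.append(
                    {
                        "egg_id": egg_id,
                        "category": category.value,
                        "day": day,
                        "weight_g": w0 - dw,
                        "weight_loss_g": dw,
                        "a_mm": math.sqrt(A_true / (math.pi * ratio)),
                        "b_mm": ratio * math.sqrt(A_true / (math.pi * ratio)),
                        "c_mm": c_true,
                        "A_b_mm2": A_true,
                        "beta1": beta1,
                        "beta2": beta2,
                    }
                )
    return records, pd.DataFrame(truth_rows)


def render_acquisition(
    egg_id: str,
    category: Category | str,
    day: int,
    a_mm: float,
    b_mm: float,
    c_mm: float,
    weight_g: float,
    seed: int,
    include_lateral: bool = False,
    noise_sd: float = 2.0,
    scale_mm_per_px: float = DEFAULT_SCALE,
) -> tuple[AcquisitionSet, dict]:
    """Render the (front[, lateral]) acquisition pair for one egg-day."""
    category = Category(category)
    phantom = EggPhantom(
        scale_mm_per_px=scale_mm_per_px,
        front_semi_mm=CATEGORY_FRONT_SEMI_MM[category],
        chamber_a_mm=min(a_mm, b_mm),
        chamber_b_mm=max(a_mm, b_mm),
        c_mm=c_mm,
        noise_sd=noise_sd,
        seed=seed,
    )
    front, truth = generate_sequence(
        phantom,
        view=View.FRONT,
        egg_id=egg_id,
        category=category,
        days_since_laying=day,
        weight_g=weight_g,
    )
    lateral = None
    if include_lateral:
        lateral, lat_truth = generate_sequence(
            replace(phantom, seed=phantom.seed + 1_000_000),
            view=View.LATERAL,
            egg_id=egg_id,
            category=category,
            days_since_laying=day,
            weight_g=weight_g,
        )
        truth = {"front": truth, "lateral": lat_truth}
    acq = AcquisitionSet(
        front=front, lateral=lateral, calibration=synthetic_calibration(scale_mm_per_px)
    )
    return acq, truth
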