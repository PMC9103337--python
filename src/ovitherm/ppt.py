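"""Pulse (PT) and pulse-phase (PPT) thermography transforms.

PT uses a single raw cooling frame captured a fixed delay after the flash
(600 ms by default).  PPT applies a discrete Fourier transform to the
cooling transient of every pixel,

    F_k = sum_{n=0}^{N-1} s_n * exp(-i 2 pi k n / N),

(negative-exponent engineering convention) and keeps the per-pixel
magnitude |F_k| and phase atan2(Im F_k, Re F_k) at a low frequency bin.
The phase image suppresses non-uniform heating, emissivity variation and
flash reflections, which is what makes the air-chamber edge usable.

The transform window is the cooling phase only: from
``flash_frame_index + post_flash_skip`` (skip 1 frame by default, to drop
the saturated flash frame) to the end of the sequence.  The reported
phase image defaults to bin k = 1, the fundamental over the cooling
window — the conventional choice for pulse excitation, where the lowest
non-DC bin carries the deepest-probing thermal wave.  No apodization
window is applied.

Phase values whose supporting magnitude is below 1e-12 of the image
maximum at that bin are numerically meaningless and returned as NaN
("undefined") rather than noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import DataError, InsufficientDataError, ParameterError, RangeError
from .thermo_io import ThermogramSequence

__all__ = [
    "PhaseImage",
    "MagnitudeImage",
    "cooling_window",
    "compute_dft",
    "phase_image",
    "magnitude_image",
    "extract_pt_frame",
    "write_image",
]

#: relative magnitude below which a phase value is flagged undefined (NaN)
UNDEFINED_MAGNITUDE_RTOL = 1e-12


@dataclass
class PhaseImage:
    """Per-pixel DFT phase in degrees at one frequency bin.

    Values lie in (-180, +180]; NaN marks pixels whose magnitude at this
    bin is negligible (undefined phase).
    """

    values: np.ndarray
    frequency_bin: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.window[1] - self.window[0]
        if not 0 <= self.frequency_bin <= n // 2:
            raise ParameterError(
                f"frequency bin {self.frequency_bin} outside the {n}-sample window"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() <= -180.0 - 1e-9 or finite.max() > 180.0 + 1e-9):
            raise ParameterError("phase values must lie in (-180, 180] degrees")


@dataclass
class MagnitudeImage:
    """Per-pixel DFT magnitude (digital levels) at one frequency bin."""

    values: np.ndarray
    frequency_bin: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.any(self.values < 0):
            raise ParameterError("magnitude must be non-negative")


def cooling_window(seq: ThermogramSequence, post_flash_skip: int = 1) -> tuple[int, int]:
    """Frame window (start, end) of the cooling phase used for the DFT."""
    if post_flash_skip < 0:
        raise ParameterError("post_flash_skip must be >= 0")
    start = seq.flash_frame_index + post_flash_skip
    end = seq.n_frames
    if end - start < 2:
        raise InsufficientDataError(
            f"cooling window [{start}, {end}) has fewer than 2 frames"
        )
    return start, end


def compute_dft(
    seq: ThermogramSequence, window: tuple[int, int] | None = None, post_flash_skip: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel DFT of the cooling transient.

    Returns ``(magnitudes, phases_deg)`` as (K, H, W) arrays over bins
    k = 0 .. floor(N/2), where N is the window length.  Phase is in
    degrees; undefined phases (negligible magnitude) are NaN.
    """
    if window is None:
        window = cooling_window(seq, post_flash_skip)
    start, end = window
    if not (0 <= start < end <= seq.n_frames) or end - start < 2:
        raise InsufficientDataError(f"invalid transform window {window}")
    segment = seq.frames[start:end]
    if not np.all(np.isfinite(segment)):
        raise DataError("NaN/inf in cooling-phase frames")
    coeffs = np.fft.rfft(segment, axis=0)  # negative-exponent convention
    mags = np.abs(coeffs)
    phases = np.degrees(np.angle(coeffs))
    for k in range(mags.shape[0]):
        peak = mags[k].max()
        undef = mags[k] <= UNDEFINED_MAGNITUDE_RTOL * peak if peak > 0 else np.ones_like(
            mags[k], dtype=bool
        )
        phases[k][undef] = np.nan
    return mags, phases


def _check_bin(bin: int, n: int) -> None:
    if bin < 1 or bin > n // 2:
        raise ParameterError(
            f"frequency bin must be in [1, {n // 2}] for a {n}-sample window (DC carries no contrast)"
        )


def phase_image(
    seq: ThermogramSequence, bin: int = 1, post_flash_skip: int = 1
) -> PhaseImage:
    """Phase image at the requested bin over the cooling window."""
    window = cooling_window(seq, post_flash_skip)
    _check_bin(bin, window[1] - window[0])
    _, phases = compute_dft(seq, window)
    return PhaseImage(values=phases[bin], frequency_bin=bin, window=window)


def magnitude_image(
    seq: ThermogramSequence, bin: int = 1, post_flash_skip: int = 1
) -> MagnitudeImage:
    """Magnitude image at the requested bin over the cooling window."""
    window = cooling_window(seq, post_flash_skip)
    _check_bin(bin, window[1] - window[0])
    mags, _ = compute_dft(seq, window)
    return MagnitudeImage(values=mags[bin], frequency_bin=bin, window=window)


def extract_pt_frame(seq: ThermogramSequence, delay_ms: float = 600.0) -> np.ndarray:
    """The raw PT frame a given delay after the flash (600 ms default)."""
    if delay_ms < 0:
        raise ParameterError("delay_ms must be >= 0")
    offset = round(delay_ms * seq.frame_rate_hz / 1000.0)
    index = seq.flash_frame_index + offset
    if index >= seq.n_frames:
        raise RangeError(
            f"delay {delay_ms} ms -> frame {index}, beyond sequence of {seq.n_frames} frames"
        )
    return seq.frames[index].copy()


def write_image(
    values: np.ndarray, path: str | Path, preview_path: str | Path | None = None
) -> None:
    """Write a float TIFF, plus an optional 8-bit min-max preview PNG.

    The preview adapts the gray scale per image (display only), the TIFF
    keeps the untouched floating-point values.
    """
    values = np.asarray(values, dtype=np.float64)
    tifffile.imwrite(Path(path), values.astype(np.float32))
    if preview_path is not None:
        finite = values[np.isfinite(values)]
        lo, hi = (finite.min(), finite.max()) if finite.size else (0.0, 1.0)
        span = hi - lo if hi > lo else 1.0
        scaled = np.clip((np.nan_to_num(values, nan=lo) - lo) / span, 0.0, 1.0)
        iio.imwrite(Path(preview_path), (scaled * 255).astype(np.uint8))
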