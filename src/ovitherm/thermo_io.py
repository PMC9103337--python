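"""Thermogram data model and file IO.

A pulse-thermography acquisition is a short stack of infrared frames
recorded while the egg cools after a flash pulse.  Brightness is kept in
raw digital levels: the whole downstream pipeline works on *relative*
contrast only (emissivity is fixed at 1 and never used radiometrically),
so no temperature calibration is applied or expected.

Sequences travel as multi-page TIFF stacks (or directories of equally
shaped single-frame images) with a JSON sidecar carrying the acquisition
metadata; measurement tables are plain CSV with an optional ``#``
provenance header.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``; the paper-style
  "x-coordinate" of a front-view profile maps to the column index;
* lateral views are oriented with the egg long axis horizontal and the
  dull pole (air-chamber end) at the maximum-column side — callers must
  rotate their data into this orientation;
* frames are stored as floating point regardless of the source bit depth
  (spline smoothing and the DFT need continuous values).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError, FormatError, IntegrityError

__all__ = [
    "View",
    "Category",
    "WEIGHT_BANDS_G",
    "category_for_weight",
    "ThermogramSequence",
    "AcquisitionSet",
    "MeasurementRecord",
    "read_sequence",
    "write_sequence",
    "write_measurements",
    "read_measurements",
]


class View(str, Enum):
    FRONT = "front"
    LATERAL = "lateral"


class Category(str, Enum):
    """EU marketing size bands by weight."""

    M = "M"
    L = "L"
    XL = "XL"


#: weight bands (grams, half-open [lo, hi)) defining the size categories
WEIGHT_BANDS_G: dict[Category, tuple[float, float]] = {
    Category.M: (53.0, 63.0),
    Category.L: (63.0, 73.0),
    Category.XL: (73.0, float("inf")),
}


def category_for_weight(weight_g: float) -> Category:
    """Return the size category whose band contains ``weight_g``."""
    for cat, (lo, hi) in WEIGHT_BANDS_G.items():
        if lo <= weight_g < hi:
            return cat
    raise ConfigurationError(f"weight {weight_g} g below the M band (53 g)")


_REQUIRED_META = ("frame_rate_hz", "flash_frame_index", "view")


@dataclass
class ThermogramSequence:
    """A T x H x W brightness stack with its acquisition metadata.

    ``flash_frame_index`` points at the frame containing the flash pulse;
    cooling-phase processing starts after it.  ``emissivity`` is stored
    for provenance but is always 1.0.
    """

    frames: np.ndarray
    frame_rate_hz: float
    flash_frame_index: int
    view: View
    egg_id: str = ""
    category: Category | None = None
    days_since_laying: int = 0
    weight_g: float | None = None
    emissivity: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise FormatError(f"frames must be T x H x W, got ndim={self.frames.ndim}")
        if self.frames.shape[0] < 2:
            raise FormatError("a thermogram sequence needs at least 2 frames")
        if not self.frame_rate_hz > 0:
            raise ConfigurationError("frame_rate_hz must be > 0")
        self.flash_frame_index = int(self.flash_frame_index)
        if not 0 <= self.flash_frame_index < self.frames.shape[0]:
            raise ConfigurationError(
                f"flash_frame_index {self.flash_frame_index} outside [0, {self.frames.shape[0]})"
            )
        self.view = View(self.view)
        if self.category is not None:
            self.category = Category(self.category)
        if self.days_since_laying < 0:
            raise ConfigurationError("days_since_laying must be >= 0")
        if self.emissivity != 1.0:
            raise ConfigurationError("emissivity is fixed at 1.0 in this technique")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def duration_s(self) -> float:
        """Time span (T - 1) / rate between first and last frame."""
        return (self.n_frames - 1) / self.frame_rate_hz

    def time_after_flash_s(self, index: int) -> float:
        return (index - self.flash_frame_index) / self.frame_rate_hz

    def metadata(self) -> dict:
        return {
            "frame_rate_hz": self.frame_rate_hz,
            "flash_frame_index": self.flash_frame_index,
            "view": self.view.value,
            "egg_id": self.egg_id,
            "category": self.category.value if self.category else None,
            "days_since_laying": self.days_since_laying,
            "weight_g": self.weight_g,
            "emissivity": self.emissivity,
        }


@dataclass
class AcquisitionSet:
    """The (front, lateral) pair of views of one egg on one day."""

    front: ThermogramSequence
    lateral: ThermogramSequence | None = None
    calibration: object | None = None  # a calibration.CalibrationResult

    def __post_init__(self) -> None:
        if self.front.view is not View.FRONT:
            raise ConfigurationError("front sequence must have view='front'")
        if self.lateral is not None:
            if self.lateral.view is not View.LATERAL:
                raise ConfigurationError("lateral sequence must have view='lateral'")
            if (
                self.lateral.egg_id != self.front.egg_id
                or self.lateral.days_since_laying != self.front.days_since_laying
            ):
                raise IntegrityError(
                    "front and lateral views must refer to the same egg and day"
                )


def _load_metadata(metadata: Mapping | str | Path) -> dict:
    if isinstance(metadata, (str, Path)):
        with open(metadata, encoding="utf-8") as fh:
            metadata = json.load(fh)
    meta = dict(metadata)
    missing = [k for k in _REQUIRED_META if k not in meta or meta[k] is None]
    if missing:
        raise ConfigurationError(f"sidecar metadata missing fields: {missing}")
    return meta


_FRAME_SUFFIXES = {".tif", ".tiff", ".png"}


def read_sequence(path: str | Path, metadata: Mapping | str | Path) -> ThermogramSequence:
    """Read a thermogram sequence from a stack file or a frame directory.

    ``metadata`` is the sidecar descriptor (mapping or path to JSON); it
    must provide ``frame_rate_hz``, ``flash_frame_index`` and ``view``.
    Frames in a directory are taken in lexical name order, which must be
    acquisition order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _load_metadata(metadata)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _FRAME_SUFFIXES)
        if not files:
            raise FormatError(f"no frame images found in {path}")
        frames_list = [np.asarray(iio.imread(p), dtype=np.float64) for p in files]
        shapes = {f.shape for f in frames_list}
        if len(shapes) != 1 or frames_list[0].ndim != 2:
            raise FormatError(f"inconsistent frame shapes in {path}: {sorted(shapes)}")
        frames = np.stack(frames_list)
    else:
        frames = np.asarray(tifffile.imread(path), dtype=np.float64)
        if frames.ndim == 2:
            raise FormatError("single-frame file: a sequence needs >= 2 frames")
        if frames.ndim != 3:
            raise FormatError(f"unexpected stack dimensionality {frames.ndim}")
    known = {f.name for f in fields(ThermogramSequence)} - {"frames"}
    kwargs = {k: v for k, v in meta.items() if k in known}
    return ThermogramSequence(frames=frames, **kwargs)


def write_sequence(
    seq: ThermogramSequence, path: str | Path, metadata_path: str | Path | None = None
) -> None:
    """Write a sequence as a multi-page float TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, seq.frames, photometric="minisblack")
    if metadata_path is None:
        metadata_path = path.with_suffix(".json")
    with open(metadata_path, "w", encoding="utf-8") as fh:
        json.dump(seq.metadata(), fh, indent=2)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

@dataclass
class MeasurementRecord:
    """One (egg, day, view) row of the output measurement table.

    ``measurement`` is a ``sizing.AirChamberMeasurement`` (duck-typed here
    to keep the IO layer independent of the algorithm layer).
    """

    egg_id: str
    days_since_laying: int
    view: View
    measurement: object
    category: Category | None = None
    weight_g: float | None = None
    grade: str | None = None

    def as_row(self) -> dict:
        m = self.measurement
        flags = getattr(m, "flags", ()) or ()
        return {
            "egg_id": self.egg_id,
            "category": self.category.value if self.category else "",
            "days_since_laying": int(self.days_since_laying),
            "view": View(self.view).value,
            "weight_g": self.weight_g,
            "a_mm": getattr(m, "a_mm", None),
            "b_mm": getattr(m, "b_mm", None),
            "c_mm": getattr(m, "c_mm", None),
            "A_b_mm2": getattr(m, "A_b_mm2", None),
            "V_proxy_mm3": getattr(m, "V_proxy_mm3", None),
            "flags": "|".join(sorted(getattr(f, "value", str(f)) for f in flags)),
            "grade": self.grade or "",
        }


MEASUREMENT_COLUMNS = [
    "egg_id",
    "category",
    "days_since_laying",
    "view",
    "weight_g",
    "a_mm",
    "b_mm",
    "c_mm",
    "A_b_mm2",
    "V_proxy_mm3",
    "flags",
    "grade",
]


def write_measurements(
    records: Sequence[MeasurementRecord],
    path: str | Path,
    provenance: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Write measurement records to CSV, one row per (egg, day, view).

    ``provenance`` lines are emitted as ``#``-prefixed comments before the
    header so that :func:`read_measurements` round-trips the table exactly.
    Duplicate (egg_id, day, view) keys raise :class:`IntegrityError`.
    """
    if not records:
        raise IntegrityError("no measurement records to write")
    rows = [r.as_row() for r in records]
    df = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    keys = df[["egg_id", "days_since_laying", "view"]].apply(tuple, axis=1)
    if keys.duplicated().any():
        dupes = sorted(set(keys[keys.duplicated()]))
        raise IntegrityError(f"duplicate (egg_id, day, view) keys: {dupes}")
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in provenance or ():
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)
    return df


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV written by :func:`write_measurements`."""
    df = pd.read_csv(
        path,
        comment="#",
        dtype={"egg_id": str, "category": str, "view": str, "flags": str, "grade": str},
    )
    for col in ("flags", "grade", "category"):
        if col in df:
            df[col] = df[col].fillna("")
    return df
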