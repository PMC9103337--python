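"""Run configuration shared by the CLI and the batch pipeline.

All thresholds of the sizing algorithm are collected here so a run is
fully described by one serializable object; every output table carries
the resolved configuration in its provenance header.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigurationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Resolved parameters of a processing run.

    delay_ms
        PT raw-frame delay after the flash (ms).
    frequency_bin
        DFT bin of the reported phase image (k >= 1).
    post_flash_skip
        cooling-window start offset after the flash frame (frames).
    n_rows
        profile rows sampled across the chamber for boundary points.
    threshold
        "otsu" or a fixed numeric phase threshold for chamber segmentation.
    dull_pole_band
        lateral dull-pole region width as a fraction of the egg length.
    d_min / hole_frac / min_area
        quality-flag and segmentation thresholds (px / fraction / px).
    """

    delay_ms: float = 600.0
    frequency_bin: int = 1
    post_flash_skip: int = 1
    n_rows: int = 9
    threshold: str | float = "otsu"
    dull_pole_band: float = 0.10
    d_min: float = 3.0
    hole_frac: float = 0.02
    min_area: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frequency_bin < 1:
            raise ConfigurationError("frequency_bin must be >= 1")
        if self.n_rows < 3:
            raise ConfigurationError("n_rows must be >= 3 (an ellipse fit needs 5 points)")
        if not 0 < self.dull_pole_band <= 1:
            raise ConfigurationError("dull_pole_band must be in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2), encoding="utf-8")

    def provenance_lines(self) -> list[str]:
        from . import __version__

        items = ", ".join(f"{k}={v!r}" for k, v in sorted(self.to_dict().items()))
        return [f"ovitherm {__version__}", f"config: {items}"]
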