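"""Run configuration.

Every tunable of the pipeline lives here with a documented default, addressable
by a flat dotted key (``"detect.rmin"``) as used by config files and CLI flags.
Unknown keys are rejected rather than silently ignored.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .errors import ParameterError


@dataclass
class PreprocessConfig:
    #: Edge length (odd, pixels) of the arithmetic-mean background kernel.
    kernel: int = 89
    #: Disc structuring-element radius (pixels) for the grayscale opening that
    #: suppresses thin bright structures before background subtraction.
    open_radius: int = 8
    #: Number of equal-width histogram bins used to locate the modal intensity
    #: of the background-subtracted image.
    hist_bins: int = 256
    #: Half-width of the median prefilter ((2r+1)² window) that removes
    #: impulse noise before morphology; 0 disables it.
    median_radius: int = 1


@dataclass
class DetectConfig:
    #: Circular Hough radius band, in pixels at the working resolution.
    rmin: int = 29
    rmax: int = 50
    #: Images are resized to this width before the Hough transform so the
    #: radius band means the same thing across cameras.
    working_width: int = 565
    #: Disc structuring-element radius (pixels, working-ish scale) of the
    #: grayscale closing that fills in the vasculature.
    close_radius: int = 15
    #: Accumulator thresholds tried from strict to permissive, as fractions of
    #: the theoretical full-perimeter vote count. Detection stops at the first
    #: level that yields a circle.
    sensitivity_ladder: tuple[float, ...] = (
        0.95, 0.90, 0.85, 0.80, 0.70, 0.50, 0.30, 0.15, 0.05,
    )
    #: Gaussian sigma of the edge detector feeding the Hough accumulator.
    canny_sigma: float = 2.0


@dataclass
class GrowCutConfig:
    #: Foreground seed disk radius as a fraction of the detected Hough radius.
    fg_scale: float = 0.4
    #: Pixels farther than ``bg_scale * r`` from the detected center are
    #: background seeds.
    bg_scale: float = 2.5
    #: Cap on synchronous automaton sweeps.
    max_iter: int = 500
    #: Cell neighborhood: 8 (Moore) or 4 (von Neumann).
    neighborhood: int = 8


@dataclass
class Config:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    growcut: GrowCutConfig = field(default_factory=GrowCutConfig)

    def set(self, dotted_key: str, value: Any) -> None:
        """Assign ``value`` to a flat dotted key, e.g. ``"detect.rmin"``."""
        try:
            section_name, key = dotted_key.split(".", 1)
        except ValueError:
            raise ParameterError(f"config key {dotted_key!r} is not of the form section.key")
        try:
            section = getattr(self, section_name)
        except AttributeError:
            raise ParameterError(f"unknown config section {section_name!r}")
        if key not in {f.name for f in dataclasses.fields(section)}:
            raise ParameterError(f"unknown config key {dotted_key!r}")
        current = getattr(section, key)
        if isinstance(current, tuple) and not isinstance(value, tuple):
            value = tuple(value)
        setattr(section, key, type(current)(value) if not isinstance(value, type(current)) else value)

    def update(self, mapping: Mapping[str, Any]) -> "Config":
        for k, v in mapping.items():
            self.set(k, v)
        return self

    def to_flat_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for section_field in dataclasses.fields(self):
            section = getattr(self, section_field.name)
            for f in dataclasses.fields(section):
                v = getattr(section, f.name)
                out[f"{section_field.name}.{f.name}"] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "Config":
        return cls().update(mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        """Load a flat JSON or YAML mapping of dotted keys."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
        if not isinstance(data, Mapping):
            raise ParameterError(f"config file {path} must contain a flat mapping")
        return cls.from_mapping(data)
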