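"""Scan geometry and core volume / annotation containers.

An SD-OCT raster volume is indexed ``(b, z, x)``: B-scan index, depth pixel
(increasing from the vitreous toward the choroid), and A-scan (lateral)
index. All coordinates are 0-based; A-scan ranges are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ValidationError, BoundsError

__all__ = [
    "ScanGeometry",
    "OCTVolume",
    "Disruption",
    "ManualLine",
    "AnnotationSet",
    "N_INTERFACES",
    "LAYERS",
]

#: Retinal layers, superficial to deep. Layer k (1-based) is bounded by
#: interfaces k and k+1 of the 8-interface set (1 = vitreous/NFL,
#: 8 = RPE/choroid).
LAYERS = ("NFL", "GCLIPL", "INL", "OPL", "ONL", "OSL", "RPE")

N_INTERFACES = 8


@dataclass(frozen=True)
class ScanGeometry:
    """Physical geometry of a raster volume scan.

    Defaults follow a 20 deg x 15 deg macular raster: 73 horizontal B-scans
    of 1024 A-scans each, 3.9 um axial pixel size and 62 um spacing between
    B-scans. The lateral A-scan spacing of 5.7 um assumes ~291 um per degree
    in an emmetropic eye (20 deg * 291 / 1024); it is a configurable field so
    nothing downstream depends on that conversion. The axial pixel count per
    A-scan is instrument-dependent and configurable (default 496).
    """

    n_bscans: int = 73
    n_ascans: int = 1024
    n_depth: int = 496
    axial_res_um: float = 3.9
    bscan_spacing_um: float = 62.0
    ascan_spacing_um: float = 5.7
    field_deg: tuple[float, float] = (20.0, 15.0)

    def __post_init__(self):
        for name in ("n_bscans", "n_ascans", "n_depth"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("axial_res_um", "bscan_spacing_um", "ascan_spacing_um"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be > 0, got {v!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume array shape ``(n_bscans, n_depth, n_ascans)``."""
        return (self.n_bscans, self.n_depth, self.n_ascans)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field_deg"] = list(self.field_deg)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        """Build from a (possibly partial) mapping; missing fields use defaults."""
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in d.items() if k in known}
        if "field_deg" in kwargs:
            kwargs["field_deg"] = tuple(kwargs["field_deg"])
        for k in ("n_bscans", "n_ascans", "n_depth"):
            if k in kwargs:
                kwargs[k] = int(kwargs[k])
        return cls(**kwargs)


@dataclass
class OCTVolume:
    """A 3-D OCT intensity volume with its physical geometry.

    ``intensities`` is indexed ``(b, z, x)`` with values in [0, 1].
    """

    intensities: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.shape != self.geometry.shape:
            raise ValidationError(
                f"intensity array shape {self.intensities.shape} does not match "
                f"geometry shape {self.geometry.shape}"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")
        lo, hi = float(self.intensities.min()), float(self.intensities.max())
        if lo < 0.0 or hi > 1.0:
            raise ValidationError(f"intensities must lie in [0, 1], got [{lo}, {hi}]")

    def bscan(self, b: int) -> np.ndarray:
        """The 2-D B-scan image ``(z, x)`` at index ``b``."""
        return self.intensities[b]


@dataclass(frozen=True)
class Disruption:
    """A visually indiscernible stretch of one interface in one B-scan.

    The A-scan range is half-open ``[x_start, x_end)``.
    """

    interface_index: int  # 1..8
    bscan: int
    x_start: int
    x_end: int


@dataclass
class ManualLine:
    """An operator-drawn correction line for one interface in one B-scan."""

    interface_index: int
    bscan: int
    depths: np.ndarray  # depth in px per A-scan

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.float64)


@dataclass
class AnnotationSet:
    """Operator annotations: disruption marks and manual correction lines."""

    disruptions: list[Disruption] = field(default_factory=list)
    manual_lines: list[ManualLine] = field(default_factory=list)

    def validate(self, geometry: ScanGeometry) -> None:
        """Raise :class:`BoundsError` on any out-of-range annotation."""
        for d in self.disruptions:
            if not 1 <= d.interface_index <= N_INTERFACES:
                raise BoundsError(f"interface_index {d.interface_index} not in 1..8")
            if not 0 <= d.bscan < geometry.n_bscans:
                raise BoundsError(f"bscan {d.bscan} outside [0, {geometry.n_bscans})")
            if not (0 <= d.x_start < d.x_end <= geometry.n_ascans):
                raise BoundsError(
                    f"A-scan range [{d.x_start}, {d.x_end}) outside "
                    f"[0, {geometry.n_ascans})"
                )
        for m in self.manual_lines:
            if not 1 <= m.interface_index <= N_INTERFACES:
                raise BoundsError(f"interface_index {m.interface_index} not in 1..8")
            if not 0 <= m.bscan < geometry.n_bscans:
                raise BoundsError(f"bscan {m.bscan} outside [0, {geometry.n_bscans})")
            if m.depths.shape != (geometry.n_ascans,):
                raise BoundsError("manual line length must equal n_ascans")
            if m.depths.min() < 0 or m.depths.max() >= geometry.n_depth:
                raise BoundsError("manual line depths outside [0, n_depth)")

    def to_dict(self) -> dict:
        return {
            "disruptions": [
                [d.interface_index, d.bscan, d.x_start, d.x_end]
                for d in self.disruptions
            ],
            "manual_lines": [
                {
                    "interface_index": m.interface_index,
                    "bscan": m.bscan,
                    "depths": [float(v) for v in m.depths],
                }
                for m in self.manual_lines
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnotationSet":
        return cls(
            disruptions=[Disruption(*map(int, row)) for row in d.get("disruptions", [])],
            manual_lines=[
                ManualLine(int(m["interface_index"]), int(m["bscan"]), m["depths"])
                for m in d.get("manual_lines", [])
            ],
        )


def layer_interfaces(layer: str | int) -> tuple[int, int]:
    """Bounding interface indices (1-based) of a retinal layer.

    Accepts a layer name from :data:`LAYERS` or a 1-based layer index.
    """
    if isinstance(layer, str):
        try:
            k = LAYERS.index(layer) + 1
        except ValueError:
            raise ValidationError(f"unknown layer {layer!r}; expected one of {LAYERS}")
    else:
        k = int(layer)
        if not 1 <= k <= len(LAYERS):
            raise ValidationError(f"layer index {k} not in 1..{len(LAYERS)}")
    return k, k + 1
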