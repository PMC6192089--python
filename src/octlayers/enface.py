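"""Enface maps and central-subfield metrics.

An *enface map* is a 2-D grid over the retinal surface, one value per
(B-scan, A-scan) column: layer thickness in micrometres, or mean layer
reflectance. Columns where a bounding interface is marked disrupted are
left *unassigned* and excluded from every metric.

Metrics are evaluated in the ETDRS central subfield — the central
1-mm-diameter circle of the macular grid — handled in physical units on
the anisotropic enface grid (B-scan spacing is an order of magnitude
coarser than A-scan spacing; no resampling is performed).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.ndimage import uniform_filter

from .errors import BoundsError, InsufficientDataError, ValidationError
from .geometry import LAYERS, N_INTERFACES, OCTVolume, ScanGeometry, layer_interfaces
from .segmentation import InterfaceSet

__all__ = [
    "EnfaceMap",
    "ETDRSMask",
    "LayerMetrics",
    "DisruptionMetrics",
    "thickness_map",
    "total_thickness_map",
    "reflectance_map",
    "central_subfield_mask",
    "layer_metrics",
    "compute_layer_metrics",
    "disruption_percent",
    "find_fovea",
]

#: Interface pairs (1-based) whose disrupted areas define each percent-area
#: disruption metric: inner-retinal boundaries for NFL_d, the boundaries of
#: the INL for INL_d, of the ONL for ONL_d and of the RPE for RPE_d.
DISRUPTION_PAIRS = {
    "NFL_d": (1, 2),
    "INL_d": (3, 4),
    "ONL_d": (5, 6),
    "RPE_d": (7, 8),
}


@dataclass
class EnfaceMap:
    """A (B-scan x A-scan) grid of values with an assigned-mask.

    ``values`` holds NaN wherever ``assigned`` is False.
    """

    values: np.ndarray
    assigned: np.ndarray
    unit: str = "um"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.assigned = np.asarray(self.assigned, dtype=bool)
        if self.values.shape != self.assigned.shape or self.values.ndim != 2:
            raise ValidationError("values and assigned must be 2-D arrays of equal shape")
        if not np.all(np.isfinite(self.values[self.assigned])):
            raise ValidationError("assigned values must be finite")
        self.values = np.where(self.assigned, self.values, np.nan)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ETDRSMask:
    """Boolean enface mask of the ETDRS central subfield (1 mm diameter)."""

    center: tuple[float, float]  # (b-scan, a-scan) position
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class LayerMetrics:
    """Per-eye central-subfield metrics.

    ``*_T``: mean layer thickness (um); ``*_R``: reflectance ratio (mean
    layer intensity / mean RPE intensity, dimensionless); ``CST``: central
    subfield thickness, the mean total retinal thickness (um). A metric is
    ``None`` when no assigned pixel was available inside the subfield —
    missing, never 0. RPE_T and RPE_R (identically 1) are computed but
    excluded from the six-layer statistical family.
    """

    NFL_T: float | None = None
    GCLIPL_T: float | None = None
    INL_T: float | None = None
    OPL_T: float | None = None
    ONL_T: float | None = None
    OSL_T: float | None = None
    RPE_T: float | None = None
    NFL_R: float | None = None
    GCLIPL_R: float | None = None
    INL_R: float | None = None
    OPL_R: float | None = None
    ONL_R: float | None = None
    OSL_R: float | None = None
    RPE_R: float | None = None
    CST: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class DisruptionMetrics:
    """Percent of central-subfield area with a disrupted interface pair."""

    NFL_d: float = 0.0
    INL_d: float = 0.0
    ONL_d: float = 0.0
    RPE_d: float = 0.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(f"{f.name}={v} outside [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _bounding_depths(
    interfaces: InterfaceSet, k_upper: int, k_lower: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Depths of two interfaces (1-based) plus their joint validity."""
    zu = interfaces.depths[k_upper - 1]
    zl = interfaces.depths[k_lower - 1]
    ok = interfaces.valid[k_upper - 1] & interfaces.valid[k_lower - 1]
    return zu, zl, ok


def thickness_map(
    interfaces: InterfaceSet, layer: str | int, geometry: ScanGeometry
) -> EnfaceMap:
    """Enface thickness map of one retinal layer, in micrometres.

    Thickness at (b, x) is ``(z_{k+1} - z_k) * axial_res_um`` from the
    layer's bounding interfaces; unassigned wherever either bounding
    interface is marked disrupted.
    """
    ku, kl = layer_interfaces(layer)
    zu, zl, ok = _bounding_depths(interfaces, ku, kl)
    vals = (zl - zu) * geometry.axial_res_um
    return EnfaceMap(np.where(ok, vals, np.nan), ok, unit="um")


def total_thickness_map(interfaces: InterfaceSet, geometry: ScanGeometry) -> EnfaceMap:
    """Total retinal thickness map: interface 1 (vitreous/NFL) to interface 8
    (RPE/choroid), unassigned where either is disrupted."""
    zu, zl, ok = _bounding_depths(interfaces, 1, N_INTERFACES)
    vals = (zl - zu) * geometry.axial_res_um
    return EnfaceMap(np.where(ok, vals, np.nan), ok, unit="um")


def reflectance_map(
    volume: OCTVolume, interfaces: InterfaceSet, layer: str | int
) -> EnfaceMap:
    """Enface mean-intensity map of one retinal layer.

    The value at (b, x) is the mean intensity of pixel rows
    ``[ceil(z_k), ceil(z_{k+1}))`` of that A-scan — the rows the layer
    occupies under the first-row-of-the-lower-layer depth convention.
    Unassigned on disrupted or zero-thickness columns.
    """
    ku, kl = layer_interfaces(layer)
    zu, zl, ok = _bounding_depths(interfaces, ku, kl)
    n_b, n_z, n_x = volume.geometry.shape
    lo = np.ceil(zu).astype(np.int64)
    hi = np.ceil(zl).astype(np.int64)
    np.clip(lo, 0, n_z, out=lo)
    np.clip(hi, 0, n_z, out=hi)
    ok = ok & (hi > lo)
    # cumulative sums along depth give O(1) per-column range means
    csum = np.concatenate(
        [np.zeros((n_b, 1, n_x)), np.cumsum(volume.intensities, axis=1)], axis=1
    )
    bb, xx = np.meshgrid(np.arange(n_b), np.arange(n_x), indexing="ij")
    sums = csum[bb, hi, xx] - csum[bb, lo, xx]
    counts = (hi - lo).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = sums / counts
    return EnfaceMap(np.where(ok, vals, np.nan), ok, unit="relative intensity")


def central_subfield_mask(
    geometry: ScanGeometry, center: tuple[float, float] | None = None
) -> ETDRSMask:
    """The ETDRS central subfield: enface pixels within 500 um of center.

    Distances use the anisotropic physical pixel spacings
    (``bscan_spacing_um`` vertically, ``ascan_spacing_um`` horizontally).
    ``center`` defaults to the grid centre (scans are fovea-centred).
    """
    n_b, n_x = geometry.n_bscans, geometry.n_ascans
    if center is None:
        center = ((n_b - 1) / 2.0, (n_x - 1) / 2.0)
    cb, cx = float(center[0]), float(center[1])
    if not (0 <= cb <= n_b - 1 and 0 <= cx <= n_x - 1):
        raise BoundsError(f"center {center} outside the enface grid {(n_b, n_x)}")
    b = (np.arange(n_b) - cb) * geometry.bscan_spacing_um
    x = (np.arange(n_x) - cx) * geometry.ascan_spacing_um
    dist2 = b[:, None] ** 2 + x[None, :] ** 2
    return ETDRSMask(center=(cb, cx), mask=dist2 <= 500.0**2)


def _masked_mean(emap: EnfaceMap, mask: ETDRSMask) -> float | None:
    sel = mask.mask & emap.assigned
    if not sel.any():
        return None
    return float(emap.values[sel].mean())


def layer_metrics(
    thickness_maps: dict[str, EnfaceMap],
    reflectance_maps: dict[str, EnfaceMap],
    total_map: EnfaceMap,
    mask: ETDRSMask,
) -> LayerMetrics:
    """Central-subfield metrics from per-layer enface maps.

    ``layer_T`` is the mean assigned thickness inside the mask;
    ``layer_R`` is the ratio of subfield means,
    (mean layer intensity) / (mean RPE intensity) — not a mean of per-pixel
    ratios, which keeps the normalization stable when assigned RPE pixels
    are sparse; ``CST`` is the mean of the total-thickness map inside the
    mask. Metrics with no assigned pixel in the mask are ``None``.
    """
    out: dict[str, float | None] = {}
    for layer in LAYERS:
        emap = thickness_maps.get(layer)
        out[f"{layer}_T"] = _masked_mean(emap, mask) if emap is not None else None
    rpe_mean = (
        _masked_mean(reflectance_maps["RPE"], mask)
        if "RPE" in reflectance_maps
        else None
    )
    for layer in LAYERS:
        emap = reflectance_maps.get(layer)
        val = _masked_mean(emap, mask) if emap is not None else None
        if val is None or rpe_mean is None or rpe_mean == 0:
            out[f"{layer}_R"] = None
        else:
            out[f"{layer}_R"] = val / rpe_mean
    out["CST"] = _masked_mean(total_map, mask)
    return LayerMetrics(**out)


def compute_layer_metrics(
    volume: OCTVolume,
    interfaces: InterfaceSet,
    mask: ETDRSMask | None = None,
) -> tuple[LayerMetrics, DisruptionMetrics]:
    """Convenience pipeline: maps for all 7 layers, then subfield metrics."""
    geom = volume.geometry
    if mask is None:
        mask = central_subfield_mask(geom)
    tmaps = {lay: thickness_map(interfaces, lay, geom) for lay in LAYERS}
    rmaps = {lay: reflectance_map(volume, interfaces, lay) for lay in LAYERS}
    total = total_thickness_map(interfaces, geom)
    return layer_metrics(tmaps, rmaps, total, mask), disruption_percent(interfaces, mask)


def disruption_percent(interfaces: InterfaceSet, mask: ETDRSMask) -> DisruptionMetrics:
    """Percent subfield area with disrupted interfaces, per interface pair.

    Each metric is the *union* of the two named interfaces' disrupted
    enface pixels, intersected with the subfield mask, as a percentage of
    the mask's pixel count (union, not sum: overlap is counted once).
    """
    n_mask = mask.n_pixels
    if n_mask == 0:
        raise InsufficientDataError("subfield mask selects no pixels")
    out = {}
    for name, (ka, kb) in DISRUPTION_PAIRS.items():
        disrupted = (~interfaces.valid[ka - 1]) | (~interfaces.valid[kb - 1])
        out[name] = 100.0 * float((disrupted & mask.mask).sum()) / n_mask
    return DisruptionMetrics(**out)


def find_fovea(total_thickness: EnfaceMap) -> tuple[int, int]:
    """Locate the foveal pit as the argmin of the smoothed total-thickness map.

    A 3x3 boxcar smooths the map (mask-aware: each pixel averages its
    assigned neighbours). Ties are broken toward the pixel closest to the
    grid centre, then by smallest (b, x) indices, so a uniform map returns
    the grid centre. Used only when auto-centering is requested; the
    default subfield centre is the grid centre.
    """
    if not total_thickness.assigned.any():
        raise InsufficientDataError("total-thickness map has no assigned pixels")
    vals = np.where(total_thickness.assigned, total_thickness.values, 0.0)
    w = total_thickness.assigned.astype(np.float64)
    num = uniform_filter(vals, size=3, mode="constant")
    den = uniform_filter(w, size=3, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        sm = num / den
    sm[~total_thickness.assigned] = np.inf
    best = sm.min()
    cand = np.argwhere(sm == best)
    n_b, n_x = sm.shape
    cb, cx = (n_b - 1) / 2.0, (n_x - 1) / 2.0
    d2 = (cand[:, 0] - cb) ** 2 + (cand[:, 1] - cx) ** 2
    order = np.lexsort((cand[:, 1], cand[:, 0], d2))
    b, x = cand[order[0]]
    return int(b), int(x)
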