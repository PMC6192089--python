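"""Graph-based retinal interface segmentation.

Each interface in a B-scan is modelled as a horizontal path through a
gradient-weighted graph whose nodes are pixels and whose edges connect
column ``x`` to ``x+1`` with a row change of -1, 0 or +1. The edge weight
between endpoints with normalized directional-gradient values ``g_a`` and
``g_b`` is ``2 - (g_a + g_b) + w_min``, so high-gradient (strong-edge)
pixels are cheap to traverse. The minimum-total-weight path is found by an
exact dynamic-programming sweep over columns, which on this column-monotone
graph is equivalent to Dijkstra's algorithm. Free endpoints are realized by
letting the path start and end at any in-band row of the border columns
(the classical construction appends two virtual minimal-weight columns;
they contribute the same cost to every path and are therefore elided).

The eight interfaces are detected sequentially, each restricted to the
band of rows left between already-detected interfaces, strongest-contrast
interfaces first, so weak boundaries are searched only where they can be.

Conventions: a path row is the first pixel row of the *lower* layer, so
layer k occupies rows ``[z_k, z_{k+1})``; ties in the shortest path are
broken toward the smaller row (then the smaller row change), making output
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import (
    BoundsError,
    SegmentationFailureError,
    ValidationError,
)
from .geometry import AnnotationSet, N_INTERFACES, OCTVolume, ScanGeometry

__all__ = [
    "DARK_TO_BRIGHT",
    "BRIGHT_TO_DARK",
    "GraphParams",
    "InterfacePath",
    "InterfaceSet",
    "directional_gradient",
    "find_min_weight_path",
    "segment_bscan",
    "segment_volume",
    "refine_with_manual",
    "apply_disruptions",
]

DARK_TO_BRIGHT = "dark_to_bright"
BRIGHT_TO_DARK = "bright_to_dark"

#: Default gradient polarity per interface 1..8, from the relative
#: reflectance ordering of the bounded tissues (vitreous < NFL < GCLIPL,
#: GCLIPL > INL < OPL > ONL < OSL < RPE > choroid).
DEFAULT_POLARITIES = (
    DARK_TO_BRIGHT,  # 1 vitreous/NFL
    DARK_TO_BRIGHT,  # 2 NFL/GCLIPL
    BRIGHT_TO_DARK,  # 3 GCLIPL/INL
    DARK_TO_BRIGHT,  # 4 INL/OPL
    BRIGHT_TO_DARK,  # 5 OPL/ONL
    DARK_TO_BRIGHT,  # 6 ONL/OSL
    DARK_TO_BRIGHT,  # 7 OSL/RPE
    BRIGHT_TO_DARK,  # 8 RPE/choroid
)

#: Default sequential detection order: the vitreous/NFL, ONL/OSL and
#: RPE/choroid interfaces carry the strongest contrast and are found first
#: over wide bands; each remaining interface is then the strongest edge of
#: its polarity inside the band left between its neighbours.
DEFAULT_ORDER = (1, 6, 8, 7, 5, 2, 3, 4)


@dataclass(frozen=True)
class GraphParams:
    """Parameters of the graph construction and sequential detection.

    Pre-smoothing is lateral-only by default (it suppresses noise without
    displacing vertical edges) and *noise-adaptive*: the configured sigmas
    are scaled by ``min(1, sigma_hat / noise_ref_sigma)`` where
    ``sigma_hat`` is a robust estimate of the pixel noise from the median
    absolute vertical difference, so a noise-free image is not smoothed at
    all and retains exact single-pixel edge localization.

    Two anatomical refinements stabilize the weakest boundaries:

    * ``low_contrast_interfaces`` (NFL/GCLIPL and INL/OPL, whose bounded
      tissues are nearly iso-reflectant) use a wider lateral smoothing
      ``low_contrast_sigma_x``, trading lateral resolution for the heavier
      averaging those edges need.
    * ``darkness_interfaces`` (OPL/ONL) multiply the gradient by a
      sub-edge darkness score over ``darkness_depth_px`` rows: the ONL is
      the darkest retinal band, which disambiguates the OPL/ONL boundary
      from the similar-contrast, similar-polarity GCLIPL/INL boundary.
    """

    polarities: tuple[str, ...] = DEFAULT_POLARITIES
    order: tuple[int, ...] = DEFAULT_ORDER
    min_gap_px: int = 1
    w_min: float = 1e-5
    #: Gaussian pre-smoothing (depth, lateral) in pixels, before the gradient.
    smooth_sigma: tuple[float, float] = (0.0, 3.0)
    low_contrast_interfaces: tuple[int, ...] = (2, 4)
    low_contrast_sigma_x: float = 12.0
    darkness_interfaces: tuple[int, ...] = (5,)
    darkness_depth_px: int = 8
    #: Reflect-padding of the B-scan columns before the path search, so
    #: path endpoints are not estimated from a one-sided neighbourhood.
    pad_columns: int = 12
    noise_adaptive: bool = True
    noise_ref_sigma: float = 0.01

    def __post_init__(self):
        if len(self.polarities) != N_INTERFACES:
            raise ValidationError("polarities must list all 8 interfaces")
        if sorted(self.order) != list(range(1, N_INTERFACES + 1)):
            raise ValidationError("order must be a permutation of 1..8")
        for p in self.polarities:
            if p not in (DARK_TO_BRIGHT, BRIGHT_TO_DARK):
                raise ValidationError(f"unknown polarity {p!r}")
        if self.min_gap_px < 1:
            raise ValidationError("min_gap_px must be >= 1")
        if not self.w_min > 0:
            raise ValidationError("w_min must be > 0")
        if self.darkness_depth_px < 1:
            raise ValidationError("darkness_depth_px must be >= 1")
        if self.pad_columns < 0:
            raise ValidationError("pad_columns must be >= 0")


@dataclass
class InterfacePath:
    """One interface trace across a B-scan: sub-pixel depth and validity
    per A-scan. ``valid`` is False inside operator-marked disruptions."""

    depths: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.depths.shape != self.valid.shape or self.depths.ndim != 1:
            raise ValidationError("depths and valid must be 1-D arrays of equal length")


@dataclass
class InterfaceSet:
    """All 8 interface traces for every B-scan of a volume.

    ``depths`` and ``valid`` are arrays of shape
    ``(8, n_bscans, n_ascans)``; interface k (1-based) is row ``k-1``.
    """

    depths: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if (
            self.depths.ndim != 3
            or self.depths.shape[0] != N_INTERFACES
            or self.valid.shape != self.depths.shape
        ):
            raise ValidationError(
                "InterfaceSet arrays must have shape (8, n_bscans, n_ascans)"
            )

    @property
    def n_bscans(self) -> int:
        return self.depths.shape[1]

    @property
    def n_ascans(self) -> int:
        return self.depths.shape[2]

    def path(self, interface_index: int, bscan: int) -> InterfacePath:
        """The trace of interface ``interface_index`` (1-based) in one B-scan."""
        if not 1 <= interface_index <= N_INTERFACES:
            raise BoundsError(f"interface_index {interface_index} not in 1..8")
        k = interface_index - 1
        return InterfacePath(self.depths[k, bscan].copy(), self.valid[k, bscan].copy())

    @classmethod
    def from_paths(cls, paths_per_bscan: list[list[InterfacePath]]) -> "InterfaceSet":
        """Assemble from per-B-scan lists of 8 :class:`InterfacePath`."""
        depths = np.stack(
            [np.stack([p.depths for p in paths]) for paths in paths_per_bscan], axis=1
        )
        valid = np.stack(
            [np.stack([p.valid for p in paths]) for paths in paths_per_bscan], axis=1
        )
        return cls(depths, valid)

    def copy(self) -> "InterfaceSet":
        return InterfaceSet(self.depths.copy(), self.valid.copy())


# ---------------------------------------------------------------------------
# gradient and shortest path
# ---------------------------------------------------------------------------


def directional_gradient(image: np.ndarray, polarity: str) -> np.ndarray:
    """Signed vertical gradient of a B-scan, clipped and normalized to [0, 1].

    The value at row ``z`` is ``I[z, x] - I[z-1, x]`` for dark-to-bright
    (negated for bright-to-dark), with row 0 set to zero, so a step edge
    produces its maximum at the first row of the lower (deeper) region.
    Negative responses are clipped to 0 and the map is rescaled so its
    maximum is 1; a constant image yields an all-zero map.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 2:
        raise ValidationError("image must be 2-D with at least 2 rows")
    if polarity not in (DARK_TO_BRIGHT, BRIGHT_TO_DARK):
        raise ValidationError(f"unknown polarity {polarity!r}")
    g = np.zeros_like(img)
    g[1:] = img[1:] - img[:-1]
    if polarity == BRIGHT_TO_DARK:
        g = -g
    np.clip(g, 0.0, None, out=g)
    m = g.max()
    if m > 0:
        g /= m
    return g


def _resolve_band(
    band, n_rows: int, n_cols: int
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a band spec to per-column (lo, hi) integer arrays."""
    if band is None:
        lo = np.zeros(n_cols, dtype=np.int64)
        hi = np.full(n_cols, n_rows, dtype=np.int64)
    else:
        lo, hi = band
        lo = np.broadcast_to(np.asarray(lo, dtype=np.int64), (n_cols,)).copy()
        hi = np.broadcast_to(np.asarray(hi, dtype=np.int64), (n_cols,)).copy()
    if lo.min() < 0 or hi.max() > n_rows:
        raise BoundsError(
            f"band [{lo.min()}, {hi.max()}) violates image rows [0, {n_rows})"
        )
    if np.any(hi <= lo):
        raise BoundsError("band is empty for at least one column")
    return lo, hi


def find_min_weight_path(
    weights: np.ndarray,
    band=None,
    w_min: float = 1e-5,
) -> InterfacePath:
    """Global minimum-weight left-to-right path through a gradient map.

    ``weights`` is a 2-D map in [0, 1] (rows = depth, columns = A-scans);
    ``band`` is an optional per-column half-open row range ``(lo, hi)``
    (scalars or arrays). The path visits one in-band row per column, moving
    by at most one row between columns, with edge weight
    ``2 - (g_a + g_b) + w_min`` and free endpoints. Among minimum-weight
    paths the one with the lexicographically smallest row sequence is
    returned (prefer the smaller row, then the smaller row change).

    Every path has the same number of edges, so minimizing the total weight
    is equivalent to maximizing the summed gradient along the path; the
    sweep accumulates pure gradient sums (numerically exact for ties, since
    no per-edge constant is folded into the running total) and the constant
    part of the weight enters only through :func:`path_weight`.
    """
    g = np.asarray(weights, dtype=np.float64)
    if g.ndim != 2:
        raise ValidationError("weights must be a 2-D array")
    n_rows, n_cols = g.shape
    lo, hi = _resolve_band(band, n_rows, n_cols)

    if n_cols == 1:
        # single column: pick the max-gradient row (smallest on ties)
        z0 = int(lo[0] + int(np.argmax(g[lo[0] : hi[0], 0])))
        return InterfacePath(np.array([z0], float), np.ones(1, bool))

    NEG = -np.inf
    # gain-to-go: D[z, x] = max sum of edge gradient contributions
    # (g_a + g_b per edge) from (z, x) to the last column; right to left.
    D = np.full((n_rows, n_cols), NEG)
    D[lo[-1] : hi[-1], -1] = 0.0
    for x in range(n_cols - 2, -1, -1):
        nxt = D[:, x + 1] + g[:, x + 1]  # gain-to-go plus endpoint bonus at x+1
        best = np.full(n_rows, NEG)
        np.maximum(best, nxt, out=best)  # dz = 0
        best[:-1] = np.maximum(best[:-1], nxt[1:])  # dz = +1
        best[1:] = np.maximum(best[1:], nxt[:-1])  # dz = -1
        col = best + g[:, x]
        col[: lo[x]] = NEG
        col[hi[x] :] = NEG
        D[:, x] = col

    first = D[lo[0] : hi[0], 0]
    if not np.isfinite(first).any():
        raise SegmentationFailureError("no connected path exists within the band")
    z = int(lo[0] + int(np.argmax(first)))  # argmax returns smallest row on ties
    path = np.empty(n_cols, dtype=np.int64)
    path[0] = z
    for x in range(n_cols - 1):
        best_c = NEG
        best_z = None
        for z2 in (z - 1, z, z + 1):  # ascending row: smaller row wins ties
            if z2 < lo[x + 1] or z2 >= hi[x + 1]:
                continue
            c = (g[z, x] + g[z2, x + 1]) + D[z2, x + 1]
            if c > best_c:
                best_c = c
                best_z = z2
        if best_z is None:
            raise SegmentationFailureError("path became disconnected inside the band")
        z = best_z
        path[x + 1] = z
    return InterfacePath(path.astype(np.float64), np.ones(n_cols, dtype=bool))


def path_weight(weights: np.ndarray, rows: np.ndarray, w_min: float = 1e-5) -> float:
    """Total edge weight of a row sequence under the graph's weighting."""
    g = np.asarray(weights, dtype=np.float64)
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.arange(rows.size)
    vals = g[rows, cols]
    return float(np.sum((2.0 + w_min) - vals[:-1] - vals[1:]))


# ---------------------------------------------------------------------------
# sequential B-scan segmentation
# ---------------------------------------------------------------------------


def estimate_noise_sigma(image: np.ndarray) -> float:
    """Robust pixel-noise estimate from vertical first differences.

    For a piecewise-constant image the vertical differences are zero away
    from edges (which are sparse), so the median absolute difference
    reflects the noise alone: ``sigma = 1.4826 * median(|dI/dz|) / sqrt(2)``.
    """
    d = np.abs(np.diff(np.asarray(image, dtype=np.float64), axis=0))
    return float(1.4826 * np.median(d) / np.sqrt(2.0))


def _darkness_below(image: np.ndarray, depth_px: int) -> np.ndarray:
    """Per-pixel darkness of the ``depth_px`` rows beneath each pixel."""
    n_rows, n_cols = image.shape
    csum = np.vstack([np.zeros((1, n_cols)), np.cumsum(image, axis=0)])
    z = np.arange(n_rows)
    lo = np.minimum(z + 1, n_rows)
    hi = np.minimum(z + 1 + depth_px, n_rows)
    count = np.maximum(hi - lo, 1)
    mean_below = (csum[hi] - csum[lo]) / count[:, None]
    return np.clip(1.0 - mean_below, 0.0, 1.0)


def segment_bscan(
    image: np.ndarray, params: GraphParams | None = None
) -> list[InterfacePath]:
    """Detect the 8 retinal interfaces in one B-scan.

    Interfaces are found sequentially in ``params.order``; each search is
    confined to the rows left between already-detected interfaces (with
    ``min_gap_px`` rows reserved per undetected interface in between), so
    the output is ordered top-down with ``z_k + min_gap_px <= z_{k+1}`` at
    every A-scan. Columns are reflect-padded during the search so path
    endpoints are supported from both sides. Returns the 8 paths in
    interface order 1..8.

    Raises :class:`SegmentationFailureError` when a search band collapses
    or when the image carries no gradient contrast at all (e.g. a constant
    image) — never a silently plausible output.
    """
    params = params or GraphParams()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < N_INTERFACES + 1:
        raise ValidationError("image must be 2-D with enough rows for 8 interfaces")

    pad = min(params.pad_columns, img.shape[1] - 1)
    padded = np.pad(img, ((0, 0), (pad, pad)), mode="reflect") if pad else img
    n_rows, n_cols = padded.shape

    if params.noise_adaptive:
        scale = min(1.0, estimate_noise_sigma(img) / params.noise_ref_sigma)
    else:
        scale = 1.0

    def smoothed(sigma_z: float, sigma_x: float) -> np.ndarray:
        sz, sx = sigma_z * scale, sigma_x * scale
        if max(sz, sx) < 0.01:
            return padded
        return gaussian_filter(padded, sigma=(sz, sx), mode="nearest")

    base = smoothed(*params.smooth_sigma)
    grads = {pol: directional_gradient(base, pol) for pol in (DARK_TO_BRIGHT, BRIGHT_TO_DARK)}
    low = smoothed(params.smooth_sigma[0], params.low_contrast_sigma_x)
    grads_low = {
        pol: directional_gradient(low, pol) for pol in (DARK_TO_BRIGHT, BRIGHT_TO_DARK)
    }
    darkness = _darkness_below(base, params.darkness_depth_px)

    gap = params.min_gap_px
    found: dict[int, np.ndarray] = {}  # interface index -> integer rows (padded)
    for k in params.order:
        pol = params.polarities[k - 1]
        if k in params.low_contrast_interfaces:
            g = grads_low[pol]
        else:
            g = grads[pol]
        if k in params.darkness_interfaces:
            g = g * darkness
            m = g.max()
            if m > 0:
                g = g / m
        if g.max() == 0.0:
            raise SegmentationFailureError(
                f"no {pol} gradient contrast in image while detecting interface {k}",
                interface_index=k,
            )
        lo = np.zeros(n_cols, dtype=np.int64)
        hi = np.full(n_cols, n_rows, dtype=np.int64)
        above = [j for j in found if j < k]
        below = [j for j in found if j > k]
        if above:
            # nearest found interface above, reserving min_gap rows for each
            # not-yet-detected interface in between
            lo = np.max([found[j] + gap * (k - j) for j in above], axis=0)
        if below:
            hi = np.min([found[j] - gap * (j - k) + 1 for j in below], axis=0)
        lo = np.clip(lo, 0, n_rows)
        hi = np.clip(hi, 0, n_rows)
        if np.any(hi <= lo):
            raise SegmentationFailureError(
                f"search band collapsed for interface {k}", interface_index=k
            )
        found[k] = find_min_weight_path(g, (lo, hi), params.w_min).depths.astype(
            np.int64
        )

    stop = n_cols - pad
    return [
        InterfacePath(found[k][pad:stop].astype(np.float64), np.ones(stop - pad, dtype=bool))
        for k in range(1, N_INTERFACES + 1)
    ]


def segment_volume(
    volume: OCTVolume, params: GraphParams | None = None
) -> InterfaceSet:
    """Run :func:`segment_bscan` on every B-scan of a volume."""
    paths = [segment_bscan(volume.bscan(b), params) for b in range(volume.geometry.n_bscans)]
    return InterfaceSet.from_paths(paths)


def refine_with_manual(
    image: np.ndarray,
    drawn: np.ndarray,
    half_band_px: int = 5,
    polarity: str = DARK_TO_BRIGHT,
    w_min: float = 1e-5,
    smooth_sigma: tuple[float, float] = (0.0, 3.0),
) -> InterfacePath:
    """Re-run the graph search in a narrow band around an operator-drawn line.

    This emulates interactive correction: the operator draws an approximate
    line and the minimum-weight path is recomputed inside
    ``[drawn - half_band_px, drawn + half_band_px)`` per column (clipped to
    the image; a band clipped to nothing raises :class:`BoundsError`).
    Pre-smoothing is noise-adaptive as in :func:`segment_bscan`.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError("image must be 2-D")
    if half_band_px < 1:
        raise ValidationError("half_band_px must be >= 1")
    n_rows, n_cols = img.shape
    drawn = np.asarray(drawn, dtype=np.float64)
    if drawn.shape != (n_cols,):
        raise ValidationError("drawn line must have one depth per A-scan")
    if drawn.min() < 0 or drawn.max() >= n_rows:
        raise BoundsError("drawn line leaves the image")
    scale = min(1.0, estimate_noise_sigma(img) / 0.01)
    sz, sx = smooth_sigma[0] * scale, smooth_sigma[1] * scale
    if max(sz, sx) >= 0.01:
        img = gaussian_filter(img, sigma=(sz, sx), mode="nearest")
    g = directional_gradient(img, polarity)
    lo = np.clip(np.floor(drawn).astype(np.int64) - half_band_px, 0, n_rows - 1)
    hi = np.clip(np.floor(drawn).astype(np.int64) + half_band_px, 1, n_rows)
    if np.any(hi <= lo):
        raise BoundsError("clipped band is empty for at least one column")
    return find_min_weight_path(g, (lo, hi), w_min)


def apply_disruptions(
    interfaces: InterfaceSet, annotations: AnnotationSet
) -> InterfaceSet:
    """Mark operator-annotated disruption ranges invalid.

    Returns a new :class:`InterfaceSet` with ``valid=False`` on every
    annotated (interface, B-scan, A-scan) position; depths are untouched.
    Overlapping annotations behave as their union.
    """
    out = interfaces.copy()
    n_b, n_x = out.n_bscans, out.n_ascans
    for d in annotations.disruptions:
        if not 1 <= d.interface_index <= N_INTERFACES:
            raise BoundsError(f"interface_index {d.interface_index} not in 1..8")
        if not 0 <= d.bscan < n_b:
            raise BoundsError(f"bscan {d.bscan} outside [0, {n_b})")
        if not (0 <= d.x_start < d.x_end <= n_x):
            raise BoundsError(f"A-scan range [{d.x_start}, {d.x_end}) outside [0, {n_x})")
        out.valid[d.interface_index - 1, d.bscan, d.x_start : d.x_end] = False
    return out
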