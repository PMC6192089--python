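"""Synthetic OCT phantoms and synthetic cohorts.

No subject data are deposited for this kind of study, so everything
downstream is exercised on two synthetic stand-ins with known ground
truth:

* **Phantoms** — layered B-scan volumes whose eight interface depths are
  cumulative layer thicknesses below a flat inner surface, with a Gaussian
  foveal pit thinning the inner layers (GCLIPL, INL, OPL), per-layer
  reflectance levels normalized to RPE = 1, optional additive Gaussian (or
  multiplicative speckle-style) noise, hypo-reflective intraretinal cysts
  that locally inflate their host layer, and disruption zones where the
  two layers adjacent to an interface are blended to zero contrast.

* **Cohorts** — subject tables whose covariates follow the study
  population's distributions and whose acuity is an exact linear function
  of metrics and covariates plus Gaussian residual, so regression recovery
  can be checked against known coefficients.

Both generators are deterministic under (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import ValidationError
from .geometry import (
    AnnotationSet,
    Disruption,
    LAYERS,
    OCTVolume,
    ScanGeometry,
)
from .segmentation import InterfaceSet
from .stats import RACES, SubjectRecord

__all__ = [
    "Cyst",
    "DisruptionZone",
    "PhantomSpec",
    "CohortSpec",
    "generate_phantom",
    "generate_cohort",
]

#: Pit thinning applies to these inner layers only (the foveal depression
#: reduces GCLIPL to near-zero thickness at the pit centre).
PIT_LAYERS = ("GCLIPL", "INL", "OPL")


@dataclass(frozen=True)
class Cyst:
    """A hypo-reflective ellipsoidal cyst inside one retinal layer.

    ``center`` is the enface position (b-scan, a-scan); ``semi_axes_um`` are
    the (depth, lateral, inter-B-scan) semi-axes in micrometres. The host
    layer is locally inflated by the cyst's vertical chord, so the cyst
    pushes its layer's boundaries apart rather than overwriting neighbours.
    """

    layer: str
    center: tuple[float, float]
    semi_axes_um: tuple[float, float, float]
    level: float = 0.10


@dataclass(frozen=True)
class DisruptionZone:
    """An enface rectangle where one interface is visually indiscernible.

    Both B-scan and A-scan ranges are half-open.
    """

    interface_index: int
    b_start: int
    b_end: int
    x_start: int
    x_end: int


# Central-subfield layer means (um) and reflectance levels relative to
# RPE = 1.0 for NFL, GCLIPL, INL, OPL, ONL, OSL, RPE. The RPE thickness
# (30 um) is a modelling default; the others are typical no-DME values.
DEFAULT_THICKNESS_UM = (18.0, 28.0, 21.0, 21.0, 114.0, 44.0, 30.0)
DEFAULT_LEVELS = (0.54, 0.61, 0.50, 0.52, 0.37, 0.81, 1.00)


@dataclass
class PhantomSpec:
    """Full specification of a layered OCT phantom."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    layer_thickness_um: tuple[float, ...] = DEFAULT_THICKNESS_UM
    layer_level: tuple[float, ...] = DEFAULT_LEVELS
    vitreous_level: float = 0.05
    choroid_level: float = 0.20
    inner_surface_um: float = 390.0
    pit_depth_fraction: float = 0.6
    pit_sigma_um: float = 300.0
    pit_center: tuple[float, float] | None = None  # enface (b, x); None = grid centre
    noise_sigma: float = 0.05
    noise_mode: str = "additive"  # or "speckle" (multiplicative)
    cysts: list[Cyst] = field(default_factory=list)
    disruption_zones: list[DisruptionZone] = field(default_factory=list)

    def __post_init__(self):
        if len(self.layer_thickness_um) != len(LAYERS):
            raise ValidationError(f"need {len(LAYERS)} layer thicknesses")
        if len(self.layer_level) != len(LAYERS):
            raise ValidationError(f"need {len(LAYERS)} layer levels")
        for name, t in zip(LAYERS, self.layer_thickness_um):
            if not t > 0:
                raise ValidationError(f"{name} thickness must be > 0, got {t}")
        for name, lv in zip(LAYERS, self.layer_level):
            if not 0 < lv <= 1:
                raise ValidationError(f"{name} level must be in (0, 1], got {lv}")
        if not 0 <= self.pit_depth_fraction < 1:
            raise ValidationError("pit_depth_fraction must be in [0, 1)")
        if self.pit_sigma_um <= 0:
            raise ValidationError("pit_sigma_um must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.noise_mode not in ("additive", "speckle"):
            raise ValidationError(f"unknown noise_mode {self.noise_mode!r}")
        g = self.geometry
        for z in self.disruption_zones:
            if not 1 <= z.interface_index <= 8:
                raise ValidationError(f"zone interface {z.interface_index} not in 1..8")
            if not (0 <= z.b_start < z.b_end <= g.n_bscans):
                raise ValidationError(f"zone B-scan range outside [0, {g.n_bscans})")
            if not (0 <= z.x_start < z.x_end <= g.n_ascans):
                raise ValidationError(f"zone A-scan range outside [0, {g.n_ascans})")
        for c in self.cysts:
            if c.layer not in LAYERS:
                raise ValidationError(f"cyst layer {c.layer!r} unknown")
            cb, cx = c.center
            if not (0 <= cb < g.n_bscans and 0 <= cx < g.n_ascans):
                raise ValidationError(f"cyst centre {c.center} outside the volume")
            if any(a <= 0 for a in c.semi_axes_um):
                raise ValidationError("cyst semi-axes must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["geometry"] = self.geometry.to_dict()
        d["cysts"] = [asdict(c) for c in self.cysts]
        d["disruption_zones"] = [asdict(z) for z in self.disruption_zones]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = ScanGeometry.from_dict(d["geometry"])
        if "cysts" in d:
            d["cysts"] = [
                Cyst(
                    layer=c["layer"],
                    center=tuple(c["center"]),
                    semi_axes_um=tuple(c["semi_axes_um"]),
                    level=c.get("level", 0.10),
                )
                for c in d["cysts"]
            ]
        if "disruption_zones" in d:
            d["disruption_zones"] = [DisruptionZone(**z) for z in d["disruption_zones"]]
        for k in ("layer_thickness_um", "layer_level", "pit_center"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in d.items() if k in known})


def _interface_depths_um(spec: PhantomSpec) -> np.ndarray:
    """Ground-truth interface depths in um, shape (8, n_bscans, n_ascans)."""
    g = spec.geometry
    n_b, n_x = g.n_bscans, g.n_ascans
    if spec.pit_center is None:
        cb, cx = (n_b - 1) / 2.0, (n_x - 1) / 2.0
    else:
        cb, cx = spec.pit_center
    bb = (np.arange(n_b)[:, None] - cb) * g.bscan_spacing_um
    xx = (np.arange(n_x)[None, :] - cx) * g.ascan_spacing_um
    pit = spec.pit_depth_fraction * np.exp(
        -(bb**2 + xx**2) / (2.0 * spec.pit_sigma_um**2)
    )

    thick = np.empty((len(LAYERS), n_b, n_x))
    for i, name in enumerate(LAYERS):
        t = np.full((n_b, n_x), spec.layer_thickness_um[i])
        if name in PIT_LAYERS:
            t = t * (1.0 - pit)
        thick[i] = t
    for c in spec.cysts:
        i = LAYERS.index(c.layer)
        az, ax, ab = c.semi_axes_um  # (depth, lateral, inter-B-scan)
        ccb, ccx = c.center
        u2 = ((np.arange(n_b)[:, None] - ccb) * g.bscan_spacing_um / ab) ** 2 + (
            (np.arange(n_x)[None, :] - ccx) * g.ascan_spacing_um / ax
        ) ** 2
        chord = 2.0 * az * np.sqrt(np.clip(1.0 - u2, 0.0, None))
        thick[i] = thick[i] + chord

    z = np.empty((len(LAYERS) + 1, n_b, n_x))
    z[0] = spec.inner_surface_um
    np.cumsum(thick, axis=0, out=z[1:])
    z[1:] += spec.inner_surface_um
    return z  # interface k (1-based) is z[k-1]


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[OCTVolume, InterfaceSet, AnnotationSet]:
    """Render a phantom volume plus ground-truth interfaces and annotations.

    Pixel row ``r`` of A-scan (b, x) takes the reflectance level of the
    region containing it under the convention that layer k occupies rows
    ``[z_k, z_{k+1})`` (vitreous above interface 1, choroid below
    interface 8). Inside disruption zones the two layers adjacent to the
    zone's interface are set to the mean of their levels, so the interface
    has zero contrast there; the zones are also emitted as ground-truth
    annotations with ``valid=False`` in the interface set. Identical
    (spec, seed) pairs produce identical output.
    """
    g = spec.geometry
    n_b, n_z, n_x = g.shape
    z_um = _interface_depths_um(spec)
    z_px = z_um / g.axial_res_um
    if z_px.max() >= n_z:
        raise ValidationError(
            f"deepest interface ({z_px.max():.1f} px) exceeds n_depth={n_z}; "
            "reduce inner_surface_um or thicknesses, or increase n_depth"
        )

    # region levels: 0 = vitreous, 1..7 = layers, 8 = choroid
    base_levels = np.array(
        [spec.vitreous_level, *spec.layer_level, spec.choroid_level]
    )
    rows = np.arange(n_z)
    intensities = np.empty((n_b, n_z, n_x))
    # per-column level table lets disruption zones blend adjacent layers
    for b in range(n_b):
        levels = np.tile(base_levels[:, None], (1, n_x))
        for zone in spec.disruption_zones:
            if zone.b_start <= b < zone.b_end:
                k = zone.interface_index  # regions k-1 (above) and k (below)
                sl = slice(zone.x_start, zone.x_end)
                blend = 0.5 * (levels[k - 1, sl] + levels[k, sl])
                levels[k - 1, sl] = blend
                levels[k, sl] = blend
        region = (rows[:, None, None] >= z_px[:, b][None, :, :]).sum(axis=1)
        intensities[b] = np.take_along_axis(levels, region, axis=0)

    for c in spec.cysts:
        i = LAYERS.index(c.layer)
        az, ax, ab = c.semi_axes_um
        ccb, ccx = c.center
        zc_px = 0.5 * (z_px[i] + z_px[i + 1])  # mid-layer, after inflation
        db = ((np.arange(n_b)[:, None, None] - ccb) * g.bscan_spacing_um / ab) ** 2
        dx = ((np.arange(n_x)[None, None, :] - ccx) * g.ascan_spacing_um / ax) ** 2
        dz = ((rows[None, :, None] - zc_px[:, None, :]) * g.axial_res_um / az) ** 2
        inside = db + dx + dz <= 1.0
        intensities[inside] = c.level

    rng = np.random.default_rng(seed)
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=intensities.shape)
        if spec.noise_mode == "additive":
            intensities += noise
        else:  # speckle: multiplicative perturbation proportional to signal
            intensities *= 1.0 + noise
    np.clip(intensities, 0.0, 1.0, out=intensities)

    volume = OCTVolume(intensities, g)
    valid = np.ones((8, n_b, n_x), dtype=bool)
    annotations = AnnotationSet(
        disruptions=[
            Disruption(z.interface_index, b, z.x_start, z.x_end)
            for z in spec.disruption_zones
            for b in range(z.b_start, z.b_end)
        ]
    )
    for d in annotations.disruptions:
        valid[d.interface_index - 1, d.bscan, d.x_start : d.x_end] = False
    truth = InterfaceSet(z_px.copy(), valid)
    return volume, truth, annotations


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

# Study-population covariate distributions: age 56.0 (11.8) y, 58.4% female,
# race mix White/African American/Hispanic or Latino/Asian, 91.9% type 2,
# duration 16.3 (10.1) y, HbA1c 7.9 (1.7)%.
DEFAULT_RACE_PROBS = {
    "White": 0.168,
    "African American": 0.517,
    "Hispanic or Latino": 0.282,
    "Asian": 0.034,
}

# Default metric means/sds: the no-DME column (thickness um, reflectance
# ratio, CST um).
DEFAULT_METRIC_DISTS = {
    "NFL_T": (18.0, 3.0),
    "GCLIPL_T": (28.0, 12.0),
    "INL_T": (21.0, 8.0),
    "OPL_T": (21.0, 8.0),
    "ONL_T": (114.0, 22.0),
    "OSL_T": (44.0, 7.0),
    "NFL_R": (0.54, 0.07),
    "GCLIPL_R": (0.61, 0.07),
    "INL_R": (0.50, 0.06),
    "OPL_R": (0.52, 0.06),
    "ONL_R": (0.37, 0.05),
    "OSL_R": (0.81, 0.07),
    "CST": (263.0, 23.0),
}


@dataclass
class CohortSpec:
    """Specification of a synthetic subject cohort.

    Acuity is generated as
    ``va = intercept + sum_m beta[m] * metric_m + gamma . covariates
    + N(0, residual_sd)``
    with ``beta`` in logMAR per unit metric (per um, per ratio unit, per
    percentage point) and ``gamma`` keyed by design-column names
    (``age``, ``sex_female``, ``race_<level>``, ``dm_type2``,
    ``dm_duration``, ``hba1c``).
    """

    n_subjects: int = 121
    age_mean_sd: tuple[float, float] = (56.0, 11.8)
    female_fraction: float = 0.584
    race_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RACE_PROBS)
    )
    type2_fraction: float = 0.919
    duration_mean_sd: tuple[float, float] = (16.3, 10.1)
    hba1c_mean_sd: tuple[float, float] = (7.9, 1.7)
    anti_vegf_fraction: float = 0.309
    metric_dists: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_METRIC_DISTS)
    )
    beta: dict[str, float] = field(default_factory=dict)
    gamma: dict[str, float] = field(default_factory=dict)
    intercept: float = 0.02
    residual_sd: float = 0.11
    seed: int | None = None

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        total = sum(self.race_probs.values())
        if not np.isclose(total, 1.0, atol=0.01):
            raise ValidationError(f"race probabilities sum to {total}, not 1")
        for r in self.race_probs:
            if r not in RACES:
                raise ValidationError(f"unknown race category {r!r}")
        for pair in (self.age_mean_sd, self.duration_mean_sd, self.hba1c_mean_sd):
            if pair[1] < 0:
                raise ValidationError("sds must be >= 0")
        for m, (_, sd) in self.metric_dists.items():
            if sd < 0:
                raise ValidationError(f"{m} sd must be >= 0")
        if self.residual_sd < 0:
            raise ValidationError("residual_sd must be >= 0")
        for frac_name in ("female_fraction", "type2_fraction", "anti_vegf_fraction"):
            v = getattr(self, frac_name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{frac_name} must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metric_dists"] = {k: list(v) for k, v in self.metric_dists.items()}
        for k in ("age_mean_sd", "duration_mean_sd", "hba1c_mean_sd"):
            d[k] = list(getattr(self, k))
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for k in ("age_mean_sd", "duration_mean_sd", "hba1c_mean_sd"):
            if k in d:
                d[k] = tuple(d[k])
        if "metric_dists" in d:
            d["metric_dists"] = {k: tuple(v) for k, v in d["metric_dists"].items()}
        known = set(cls.__dataclass_fields__)
        return cls(**{k: v for k, v in d.items() if k in known})


def generate_cohort(spec: CohortSpec, seed: int | None = None) -> list[SubjectRecord]:
    """Draw a synthetic cohort with known linear acuity structure.

    Covariates and metrics are drawn independently from their stated
    distributions (thickness metrics truncated at 0); acuity follows the
    spec's linear model. ``seed`` overrides ``spec.seed``; the same
    (spec, seed) always yields the identical table.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    n = spec.n_subjects

    age = rng.normal(*spec.age_mean_sd, size=n)
    female = rng.random(n) < spec.female_fraction
    race_levels = list(spec.race_probs)
    probs = np.asarray([spec.race_probs[r] for r in race_levels], dtype=float)
    probs = probs / probs.sum()
    race = rng.choice(race_levels, size=n, p=probs)
    type2 = rng.random(n) < spec.type2_fraction
    duration = np.clip(rng.normal(*spec.duration_mean_sd, size=n), 0.0, None)
    hba1c = np.clip(rng.normal(*spec.hba1c_mean_sd, size=n), 4.0, None)
    anti_vegf = rng.random(n) < spec.anti_vegf_fraction

    metrics = {}
    for m, (mu, sd) in spec.metric_dists.items():
        vals = rng.normal(mu, sd, size=n)
        if m.endswith("_T") or m == "CST":
            vals = np.clip(vals, 0.0, None)
        elif m.endswith("_R"):
            vals = np.clip(vals, 1e-6, None)
        elif m.endswith("_d"):
            vals = np.clip(vals, 0.0, 100.0)
        metrics[m] = vals

    va = np.full(n, spec.intercept, dtype=np.float64)
    for m, b in spec.beta.items():
        if m not in metrics:
            raise ValidationError(f"beta refers to unknown metric {m!r}")
        va += b * metrics[m]
    cov_columns = {
        "age": age,
        "sex_female": female.astype(float),
        "dm_type2": type2.astype(float),
        "dm_duration": duration,
        "hba1c": hba1c,
    }
    for r in RACES:
        cov_columns[f"race_{r.replace(' ', '_')}"] = (race == r).astype(float)
    for cname, gcoef in spec.gamma.items():
        if cname not in cov_columns:
            raise ValidationError(f"gamma refers to unknown covariate {cname!r}")
        va += gcoef * cov_columns[cname]
    if spec.residual_sd > 0:
        va += rng.normal(0.0, spec.residual_sd, size=n)

    records = []
    for i in range(n):
        records.append(
            SubjectRecord(
                id=f"S{i:04d}",
                age=float(age[i]),
                sex="female" if female[i] else "male",
                race=str(race[i]),
                dm_type=2 if type2[i] else 1,
                dm_duration=float(duration[i]),
                hba1c=float(hba1c[i]),
                va_logmar=float(va[i]),
                anti_vegf=bool(anti_vegf[i]),
                metrics={m: float(v[i]) for m, v in metrics.items()},
            )
        )
    return records
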