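"""Reading and writing pipeline artifacts in open formats.

Volumes are multi-page TIFF (one page per B-scan, rows = depth pixels,
columns = A-scans) with a JSON geometry sidecar; interface sets and
enface maps are CSV; annotations are JSON; cohorts are CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    FormatError,
    GeometryMismatchError,
    SchemaError,
    ValidationError,
)
from .geometry import AnnotationSet, N_INTERFACES, OCTVolume, ScanGeometry
from .enface import EnfaceMap
from .segmentation import InterfaceSet
from .stats import SubjectRecord

__all__ = [
    "read_geometry",
    "write_geometry",
    "read_volume",
    "write_volume",
    "read_annotations",
    "write_annotations",
    "read_interface_set",
    "write_interface_set",
    "read_enface_map",
    "write_enface_map",
    "read_cohort_table",
    "write_cohort_table",
    "render_enface_rgb",
]

COHORT_REQUIRED_COLUMNS = (
    "id",
    "age",
    "sex",
    "race",
    "dm_type",
    "dm_duration",
    "hba1c",
    "va_logmar",
    "anti_vegf",
)


def write_geometry(geometry: ScanGeometry, path) -> None:
    Path(path).write_text(json.dumps(geometry.to_dict(), indent=2))


def read_geometry(path) -> ScanGeometry:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"geometry sidecar {path} is not valid JSON: {e}") from e
    return ScanGeometry.from_dict(d)


def write_volume(volume: OCTVolume, path, geometry_path=None) -> None:
    """Write a volume as multi-page uint8 TIFF (+ optional geometry JSON).

    Intensities in [0, 1] are quantized to uint8, so a round trip is exact
    to within 1/255.
    """
    data = np.round(volume.intensities * 255.0).astype(np.uint8)
    tifffile.imwrite(path, data, photometric="minisblack")
    if geometry_path is not None:
        write_geometry(volume.geometry, geometry_path)


def read_volume(path, geometry_path) -> OCTVolume:
    """Read a multi-page TIFF volume with its JSON geometry sidecar.

    Integer intensities are rescaled to [0, 1] by the dtype's full range;
    float pages are taken as already being in [0, 1]. Missing geometry
    fields fall back to the standard raster defaults. A page count other
    than ``n_bscans`` raises :class:`GeometryMismatchError`.
    """
    geometry = read_geometry(geometry_path)
    try:
        data = tifffile.imread(path)
    except Exception as e:  # tifffile raises various types on bad input
        raise FormatError(f"{path} is not a readable TIFF volume: {e}") from e
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a stack of 2-D pages, got shape {data.shape}")
    if data.shape[0] != geometry.n_bscans:
        raise GeometryMismatchError(
            f"TIFF has {data.shape[0]} pages but geometry declares "
            f"{geometry.n_bscans} B-scans"
        )
    if data.shape[1:] != (geometry.n_depth, geometry.n_ascans):
        raise GeometryMismatchError(
            f"page shape {data.shape[1:]} does not match geometry "
            f"({geometry.n_depth}, {geometry.n_ascans})"
        )
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        intensities = data.astype(np.float64) / float(info.max)
    else:
        intensities = data.astype(np.float64)
    return OCTVolume(intensities, geometry)


def write_annotations(annotations: AnnotationSet, path) -> None:
    Path(path).write_text(json.dumps(annotations.to_dict(), indent=2))


def read_annotations(path) -> AnnotationSet:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"annotation file {path} is not valid JSON: {e}") from e
    return AnnotationSet.from_dict(d)


def write_interface_set(interfaces: InterfaceSet, path) -> None:
    """CSV with one row per (interface, B-scan, A-scan): columns
    interface_index, bscan, ascan, depth_px, valid (1/0)."""
    k, b, x = np.meshgrid(
        np.arange(1, N_INTERFACES + 1),
        np.arange(interfaces.n_bscans),
        np.arange(interfaces.n_ascans),
        indexing="ij",
    )
    df = pd.DataFrame(
        {
            "interface_index": k.ravel(),
            "bscan": b.ravel(),
            "ascan": x.ravel(),
            "depth_px": interfaces.depths.ravel(),
            "valid": interfaces.valid.ravel().astype(int),
        }
    )
    # %.17g keeps every float64 exactly round-trippable
    df.to_csv(path, index=False, float_format="%.17g")


def read_interface_set(path) -> InterfaceSet:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"interface_index", "bscan", "ascan", "depth_px", "valid"}
    if not required.issubset(df.columns):
        raise SchemaError(f"interface CSV missing columns {required - set(df.columns)}")
    n_b = int(df["bscan"].max()) + 1
    n_x = int(df["ascan"].max()) + 1
    depths = np.zeros((N_INTERFACES, n_b, n_x))
    valid = np.zeros((N_INTERFACES, n_b, n_x), dtype=bool)
    ki = df["interface_index"].to_numpy() - 1
    bi = df["bscan"].to_numpy()
    xi = df["ascan"].to_numpy()
    depths[ki, bi, xi] = df["depth_px"].to_numpy()
    valid[ki, bi, xi] = df["valid"].to_numpy().astype(bool)
    return InterfaceSet(depths, valid)


UNASSIGNED_SENTINEL = "NA"


def write_enface_map(emap: EnfaceMap, path) -> None:
    """Grid CSV; unassigned pixels written as the NA sentinel."""
    df = pd.DataFrame(emap.values)
    df.to_csv(path, index=False, header=False, na_rep=UNASSIGNED_SENTINEL)


def read_enface_map(path, unit: str = "um") -> EnfaceMap:
    df = pd.read_csv(path, header=None, na_values=[UNASSIGNED_SENTINEL])
    values = df.to_numpy(dtype=np.float64)
    return EnfaceMap(values, ~np.isnan(values), unit=unit)


def render_enface_rgb(
    emap: EnfaceMap,
    vmax: float | None = None,
    disrupted_color: tuple[int, int, int] = (255, 255, 0),
) -> np.ndarray:
    """Render an enface map to an RGB uint8 image.

    Assigned pixels are greyscale (0..vmax); unassigned (disrupted) pixels
    take ``disrupted_color`` — yellow by default for reflectance images,
    pass ``(0, 0, 0)`` for the black convention on thickness maps.
    """
    if vmax is None:
        vmax = float(np.nanmax(emap.values)) if emap.assigned.any() else 1.0
    if vmax <= 0:
        vmax = 1.0
    grey = np.clip(np.nan_to_num(emap.values) / vmax, 0.0, 1.0)
    rgb = np.repeat((grey * 255).astype(np.uint8)[..., None], 3, axis=2)
    rgb[~emap.assigned] = np.asarray(disrupted_color, dtype=np.uint8)
    return rgb


def write_cohort_table(records: list[SubjectRecord], path) -> None:
    metric_names: list[str] = []
    for r in records:
        for m in r.metrics:
            if m not in metric_names:
                metric_names.append(m)
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age": r.age,
            "sex": r.sex,
            "race": r.race,
            "dm_type": r.dm_type,
            "dm_duration": r.dm_duration,
            "hba1c": r.hba1c,
            "va_logmar": r.va_logmar,
            "anti_vegf": int(r.anti_vegf),
        }
        for m in metric_names:
            row[m] = r.metrics.get(m)
        rows.append(row)
    pd.DataFrame(rows, columns=list(COHORT_REQUIRED_COLUMNS) + metric_names).to_csv(
        path, index=False
    )


def read_cohort_table(path) -> list[SubjectRecord]:
    """Read a subject table CSV into typed records.

    Requires the covariate/acuity columns; any additional numeric columns
    are treated as metrics. Categorical fields are validated against the
    study's category levels; a non-numeric acuity raises
    :class:`FormatError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    metric_cols = [c for c in df.columns if c not in COHORT_REQUIRED_COLUMNS]
    records = []
    for _, row in df.iterrows():
        try:
            va = float(row["va_logmar"])
        except (TypeError, ValueError) as e:
            raise FormatError(
                f"non-numeric va_logmar {row['va_logmar']!r} for id {row['id']!r}"
            ) from e
        metrics = {}
        for m in metric_cols:
            v = row[m]
            metrics[m] = None if pd.isna(v) else float(v)
        records.append(
            SubjectRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                race=str(row["race"]),
                dm_type=int(row["dm_type"]),
                dm_duration=float(row["dm_duration"]),
                hba1c=float(row["hba1c"]),
                va_logmar=va,
                anti_vegf=bool(int(row["anti_vegf"])),
                metrics=metrics,
            )
        )
    return records
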