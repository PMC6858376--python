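"""Readers and writers for profile and cohort files.

Two profile dialects carry the same payload:

* CSV — columns ``x_um,z_um``; scan metadata (orientation, axial length,
  scaled flag) lives in a JSON sidecar named ``<file>.meta.json``.
* JSON — a single object
  ``{"orientation", "axial_length_mm", "scaled", "x_um": [...], "z_um": [...]}``.

A cohort is a per-eye CSV table (one row per eye, columns mirroring
:class:`~staphycurve.core.EyeRecord`) whose ``profile_h_path`` /
``profile_v_path`` columns reference profile files by path relative to the
cohort file; provenance and seed live in ``<file>.meta.json``.

Elevations are re-centered on read so that z at the sample nearest x = 0
is exactly 0 (the subfoveal RPE reference level).
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .core import (
    Cohort,
    CurvatureMetrics,
    EyeRecord,
    Provenance,
    RpeProfile,
)
from .errors import ParseError, ValidationError

PathLike = Union[str, Path]

_PROFILE_COLUMNS = ("x_um", "z_um")
_METRIC_PREFIX = "m_"


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def read_profile(path: PathLike, format: str = "csv") -> RpeProfile:
    """Read a profile file, validate it, and center z on the fovea.

    Parameters
    ----------
    path
        Profile file path.
    format
        ``"csv"`` (with JSON metadata sidecar) or ``"json"``.
    """
    path = Path(path)
    if format == "csv":
        xs: list[float] = []
        zs: list[float] = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise ParseError(f"{path}: empty file") from None
            header = [h.strip() for h in header]
            for col in _PROFILE_COLUMNS:
                if col not in header:
                    raise ParseError(f"{path}: line 1: missing column {col!r}")
            ix, iz = header.index("x_um"), header.index("z_um")
            for lineno, row in enumerate(reader, start=2):
                if not row or all(not c.strip() for c in row):
                    continue
                try:
                    xs.append(float(row[ix]))
                    zs.append(float(row[iz]))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
        meta_file = _meta_path(path)
        if not meta_file.exists():
            raise ParseError(f"{path}: metadata sidecar {meta_file} not found")
        meta = json.loads(meta_file.read_text())
    elif format == "json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from None
        xs, zs = payload.get("x_um"), payload.get("z_um")
        if xs is None or zs is None:
            raise ParseError(f"{path}: missing x_um/z_um arrays")
        meta = payload
    else:
        raise ValueError(f"unknown profile format {format!r}")

    try:
        profile = RpeProfile(
            orientation=meta["orientation"],
            x=np.asarray(xs, dtype=float),
            z=np.asarray(zs, dtype=float),
            axial_length_mm=float(meta["axial_length_mm"]),
            scaled=bool(meta.get("scaled", False)),
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing metadata field {exc}") from None
    return profile.centered()


def write_profile(profile: RpeProfile, path: PathLike, format: str = "csv") -> None:
    """Write a profile in the CSV or JSON dialect (see module docstring)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "orientation": profile.orientation.value,
        "axial_length_mm": profile.axial_length_mm,
        "scaled": profile.scaled,
    }
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_PROFILE_COLUMNS)
            for x, z in zip(profile.x, profile.z):
                writer.writerow([repr(float(x)), repr(float(z))])
        _meta_path(path).write_text(json.dumps(meta, indent=1))
    elif format == "json":
        payload = dict(meta)
        payload["x_um"] = [float(v) for v in profile.x]
        payload["z_um"] = [float(v) for v in profile.z]
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown profile format {format!r}")


_COHORT_COLUMNS = [
    "patient_id", "eye", "group", "age_years", "sex", "bcva_logmar",
    "axial_length_mm", "refractive_error_d", "pseudophakic",
    "staphyloma_type", "metapm_category", "sct_um", "fsh_um", "cnv_size_da",
    "profile_h_path", "profile_v_path",
]


def write_cohort(cohort: Cohort, path: PathLike) -> None:
    """Write a cohort CSV plus per-eye profile files and a metadata sidecar.

    Profiles (when present) are written as CSV under ``<stem>_profiles/``
    next to the cohort file and referenced by relative path.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    profile_dir_name = path.stem + "_profiles"
    rows = []
    for rec in cohort.records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "eye": rec.eye.value,
            "group": rec.group.value,
            "age_years": rec.age_years,
            "sex": rec.sex.value,
            "bcva_logmar": rec.bcva_logmar,
            "axial_length_mm": rec.axial_length_mm,
            "refractive_error_d": rec.refractive_error_d,
            "pseudophakic": rec.pseudophakic,
            "staphyloma_type": rec.staphyloma_type.value,
            "metapm_category": rec.metapm_category,
            "sct_um": rec.sct_um,
            "fsh_um": rec.fsh_um,
            "cnv_size_da": rec.cnv_size_da,
            "profile_h_path": "",
            "profile_v_path": "",
        }
        for tag, prof in (("h", rec.profile_h), ("v", rec.profile_v)):
            if prof is not None:
                rel = f"{profile_dir_name}/{rec.patient_id}_{rec.eye.value}_{tag}.csv"
                write_profile(prof, path.parent / rel, format="csv")
                row[f"profile_{tag}_path"] = rel
        if rec.metrics is not None:
            for k, v in rec.metrics.as_dict().items():
                row[_METRIC_PREFIX + k] = v
        rows.append(row)
    columns = list(_COHORT_COLUMNS)
    if any(_METRIC_PREFIX + "h_total" in r for r in rows):
        columns += [_METRIC_PREFIX + k for k in CurvatureMetrics.field_names()]
    frame = pd.DataFrame(rows, columns=columns)
    frame.to_csv(path, index=False)
    _meta_path(path).write_text(
        json.dumps({"provenance": cohort.provenance.value, "seed": cohort.seed})
    )


def _opt_float(value: object) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort(path: PathLike, one_eye_per_patient: bool = True) -> Cohort:
    """Read a cohort CSV and its referenced profile files.

    ``one_eye_per_patient=True`` (default) rejects cohorts in which a
    patient contributes both eyes; pass False for pre-screening cohorts
    that still await the one-eye rule.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"cohort file {path} not found")
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=_COHORT_COLUMNS)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from None
    meta = {}
    if _meta_path(path).exists():
        meta = json.loads(_meta_path(path).read_text())

    records: list[EyeRecord] = []
    for _, row in frame.iterrows():
        profiles: dict[str, Optional[RpeProfile]] = {}
        for tag in ("h", "v"):
            rel = row.get(f"profile_{tag}_path")
            if isinstance(rel, str) and rel:
                pfile = path.parent / rel
                if not pfile.exists():
                    raise ParseError(
                        f"{path}: profile file {rel} for eye "
                        f"{row['patient_id']}/{row['eye']} not found"
                    )
                profiles[tag] = read_profile(pfile, format="csv")
            else:
                profiles[tag] = None
        metric_values = {
            k: row[_METRIC_PREFIX + k]
            for k in CurvatureMetrics.field_names()
            if _METRIC_PREFIX + k in row and pd.notna(row[_METRIC_PREFIX + k])
        }
        metrics = (
            CurvatureMetrics(**{k: float(v) for k, v in metric_values.items()})
            if len(metric_values) == len(CurvatureMetrics.field_names())
            else None
        )
        records.append(
            EyeRecord(
                patient_id=str(row["patient_id"]),
                eye=row["eye"],
                group=row["group"],
                age_years=float(row["age_years"]),
                sex=row["sex"],
                bcva_logmar=float(row["bcva_logmar"]),
                axial_length_mm=float(row["axial_length_mm"]),
                refractive_error_d=float(row["refractive_error_d"]),
                pseudophakic=bool(row["pseudophakic"]),
                staphyloma_type=row["staphyloma_type"],
                metapm_category=int(row["metapm_category"]),
                sct_um=float(row["sct_um"]),
                fsh_um=_opt_float(row.get("fsh_um")),
                cnv_size_da=_opt_float(row.get("cnv_size_da")),
                profile_h=profiles["h"],
                profile_v=profiles["v"],
                metrics=metrics,
            )
        )
    cohort = Cohort(
        records=records,
        provenance=meta.get("provenance", Provenance.MEASURED),
        seed=meta.get("seed"),
    )
    cohort.validate(one_eye_per_patient=one_eye_per_patient)
    return cohort
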