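"""File formats: landmark CSV, measurement TSV, reference JSON, YAML config.

All files are UTF-8 text.  The landmark dialect is one row per placed
landmark (subject_id, code, side, x_mm, y_mm, z_mm, excluded); the
measurement dialect is a long-format TSV (subject_id, age_years, sex,
ancestry, measurement, value, units, usable).  Fitted reference sets are
serialized as a versioned JSON document that round-trips coefficients
and grids to better than 1e-9.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .anthropometry import DEFAULT_TEMPLATE, LandmarkSet, MeasurementRecord
from .errors import FormatError, SchemaVersionError
from .reference import (
    CiBand,
    GrowthCurveModel,
    ReferenceConfig,
    ReferenceCurve,
    ReferenceSet,
    SdProfile,
)

__all__ = [
    "LANDMARK_COLUMNS",
    "MEASUREMENT_COLUMNS",
    "REFERENCE_SCHEMA_VERSION",
    "read_landmarks",
    "write_landmarks",
    "read_measurements",
    "write_measurements",
    "read_reference",
    "write_reference",
    "RunConfig",
    "load_run_config",
    "config_hash",
]

PathLike = Union[str, Path]

LANDMARK_COLUMNS = ["subject_id", "code", "side", "x_mm", "y_mm", "z_mm", "excluded"]
MEASUREMENT_COLUMNS = ["subject_id", "age_years", "sex", "ancestry",
                       "measurement", "value", "units", "usable"]
REFERENCE_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Landmark CSV


def write_landmarks(sets: Sequence[LandmarkSet], path: PathLike) -> None:
    """Write landmark sets to the CSV dialect (one row per landmark)."""
    rows = []
    for ls in sets:
        for (code, side), p in sorted(ls.points.items(), key=lambda kv: (kv[0][0], kv[0][1] or "")):
            rows.append({
                "subject_id": ls.subject_id,
                "code": code,
                "side": side or "",
                "x_mm": repr(float(p[0])),
                "y_mm": repr(float(p[1])),
                "z_mm": repr(float(p[2])),
                "excluded": int((code, side) in ls.excluded),
            })
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(path, index=False)


def read_landmarks(path: PathLike, template=DEFAULT_TEMPLATE) -> list[LandmarkSet]:
    """Read landmark CSV into one LandmarkSet per subject.

    Malformed rows are collected and reported together in a FormatError
    naming the offending line numbers (header = line 1).
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in LANDMARK_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    problems: list[str] = []
    per_subject: dict[str, dict] = {}
    seen: set[tuple[str, str, Optional[str]]] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2  # header on line 1
        side = row.side or None
        if side not in (None, "L", "R"):
            problems.append(f"line {line}: invalid side {row.side!r}")
            continue
        key = (row.subject_id, row.code, side)
        if key in seen:
            raise FormatError(f"{path}: duplicate landmark {key[1:]} for subject "
                              f"{row.subject_id!r} at line {line}")
        seen.add(key)
        try:
            xyz = np.array([float(row.x_mm), float(row.y_mm), float(row.z_mm)])
        except ValueError:
            problems.append(f"line {line}: non-numeric coordinate "
                            f"({row.x_mm!r}, {row.y_mm!r}, {row.z_mm!r})")
            continue
        if row.excluded not in ("0", "1"):
            problems.append(f"line {line}: excluded must be 0 or 1, got {row.excluded!r}")
            continue
        entry = per_subject.setdefault(row.subject_id, {"points": {}, "excluded": set()})
        entry["points"][(row.code, side)] = xyz
        if row.excluded == "1":
            entry["excluded"].add((row.code, side))
    if problems:
        raise FormatError(f"{path}: {len(problems)} malformed row(s):\n  " + "\n  ".join(problems))
    return [
        LandmarkSet(subject_id=sid, points=entry["points"],
                    excluded=entry["excluded"], template=template)
        for sid, entry in sorted(per_subject.items())
    ]


# ---------------------------------------------------------------------------
# Measurement TSV


def write_measurements(frame: pd.DataFrame, path: PathLike) -> None:
    """Write a long-format measurement table as TSV (ages to 3 decimals)."""
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"measurement frame missing columns {missing}")
    out = frame[MEASUREMENT_COLUMNS].copy()
    out["age_years"] = out["age_years"].astype(float).round(3)
    out.to_csv(path, sep="\t", index=False)


def read_measurements(path: PathLike) -> pd.DataFrame:
    """Read a measurement TSV, validating the dialect."""
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in MEASUREMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    frame["usable"] = frame["usable"].astype(int)
    return frame


def records_from_file(path: PathLike) -> list[MeasurementRecord]:
    from .synthetic import records_from_frame

    return records_from_frame(read_measurements(path))


# ---------------------------------------------------------------------------
# Reference JSON


def _curve_to_dict(curve: ReferenceCurve) -> dict:
    d = {
        "measurement": curve.measurement,
        "sex": curve.sex,
        "model": {
            "family": curve.model.family,
            "coefficients": list(curve.model.coefficients),
            "rss": curve.model.rss,
            "n_points": curve.model.n_points,
        },
        "sd_grid": {
            "ages": curve.sd_profile.ages.tolist(),
            "sd": curve.sd_profile.sd.tolist(),
            "bandwidth": curve.sd_profile.bandwidth,
            "low_confidence": curve.sd_profile.low_confidence.astype(int).tolist(),
        },
        "age_range_sampled": list(curve.age_range_sampled),
        "n_subjects": curve.n_subjects,
        "outliers_removed": curve.outliers_removed,
        "ci_grid": None,
    }
    if curve.ci is not None:
        d["ci_grid"] = {
            "ages": curve.ci.ages.tolist(),
            "lower": curve.ci.lower.tolist(),
            "upper": curve.ci.upper.tolist(),
            "level": curve.ci.level,
        }
    return d


def write_reference(refset: ReferenceSet, path: PathLike) -> None:
    """Serialize a fitted reference set as versioned JSON."""
    doc = {
        "schema_version": REFERENCE_SCHEMA_VERSION,
        "ancestry": refset.ancestry,
        "provenance": refset.provenance,
        "curves": [_curve_to_dict(c) for c in refset.curves],
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def read_reference(path: PathLike) -> ReferenceSet:
    """Read a reference JSON document, checking the schema version."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != REFERENCE_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r} is incompatible with "
            f"supported version {REFERENCE_SCHEMA_VERSION}"
        )
    refset = ReferenceSet(ancestry=doc.get("ancestry", ""),
                          provenance=doc.get("provenance", {}))
    for cd in doc.get("curves", []):
        for required in ("model", "sd_grid", "age_range_sampled"):
            if required not in cd or cd[required] is None:
                raise SchemaVersionError(
                    f"{path}: curve for ({cd.get('measurement')}, {cd.get('sex')}) "
                    f"missing required field {required!r}"
                )
        md = cd["model"]
        model = GrowthCurveModel(family=md["family"],
                                 coefficients=tuple(md["coefficients"]),
                                 rss=float(md["rss"]), n_points=int(md["n_points"]))
        sg = cd["sd_grid"]
        sd_profile = SdProfile(ages=np.asarray(sg["ages"], float),
                               sd=np.asarray(sg["sd"], float),
                               bandwidth=float(sg["bandwidth"]),
                               low_confidence=np.asarray(sg["low_confidence"], bool))
        ci = None
        if cd.get("ci_grid"):
            cg = cd["ci_grid"]
            ci = CiBand(ages=np.asarray(cg["ages"], float),
                        lower=np.asarray(cg["lower"], float),
                        upper=np.asarray(cg["upper"], float),
                        level=float(cg["level"]))
        refset.add(ReferenceCurve(
            measurement=cd["measurement"], sex=cd["sex"], model=model,
            sd_profile=sd_profile, ci=ci,
            age_range_sampled=tuple(cd["age_range_sampled"]),
            n_subjects=int(cd["n_subjects"]),
            outliers_removed=int(cd["outliers_removed"]),
        ))
    return refset


# ---------------------------------------------------------------------------
# Assessment exports


def report_to_dict(report) -> dict:
    """JSON-serializable form of an AssessmentReport."""
    return {
        "subject_id": report.subject_id,
        "reference_ancestry": report.reference_ancestry,
        "n_flags": report.n_flags,
        "zscores": [
            {
                "measurement": z.measurement,
                "value": z.value,
                "ref_mean": z.ref_mean,
                "ref_sd": z.ref_sd,
                "z": z.z,
                "z_display": z.z_display,
                "extrapolated": z.extrapolated,
            }
            for z in report.zscores
        ],
        "flags": [
            {"measurement": f.measurement, "direction": f.direction,
             "label": f.label, "z": f.z}
            for f in report.flags
        ],
        "uncovered": list(report.uncovered),
    }


def format_report(report) -> str:
    """Human-readable text rendering of an AssessmentReport."""
    lines = [
        f"Subject {report.subject_id} vs {report.reference_ancestry} reference",
        f"  atypical traits flagged (|z| > 2): {report.n_flags}",
    ]
    for f in report.flags:
        lines.append(f"    {f.label} ({f.measurement}, z={f.z:+.1f})")
    lines.append("  z-scores:")
    for z in report.zscores:
        extra = " [extrapolated]" if z.extrapolated else ""
        lines.append(
            f"    {z.measurement}: {z.value:.1f} mm "
            f"(mean {z.ref_mean:.1f}, SD {z.ref_sd:.1f}) z={z.z_display}{extra}"
        )
    if report.uncovered:
        lines.append(f"  not covered by reference: {', '.join(sorted(set(report.uncovered)))}")
    return "\n".join(lines)


def write_comparison(cmp, path: PathLike) -> None:
    """Write a ReferenceComparison as TSV (subject_id, flags_a, flags_b)."""
    pd.DataFrame({
        "subject_id": cmp.subject_ids,
        "flags_a": cmp.flags_a,
        "flags_b": cmp.flags_b,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Pipeline configuration; serialized in output provenance."""

    seed: int = 0
    reference: ReferenceConfig = field(default_factory=ReferenceConfig)
    flag_threshold: float = 2.0
    verbosity: int = 1


def load_run_config(path: PathLike) -> RunConfig:
    """Load a YAML run configuration (missing keys take defaults)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: config must be a mapping")
    ref_raw = raw.pop("reference_model", {}) or {}
    known_ref = {f for f in ReferenceConfig.__dataclass_fields__}
    bad = set(ref_raw) - known_ref
    if bad:
        raise FormatError(f"{path}: unknown reference_model keys {sorted(bad)}")
    assessment_raw = raw.pop("assessment", {}) or {}
    cfg = RunConfig(
        seed=int(raw.pop("seed", 0)),
        reference=ReferenceConfig(**ref_raw),
        flag_threshold=float(assessment_raw.get("threshold", 2.0)),
        verbosity=int(raw.pop("verbosity", 1)),
    )
    if raw:
        raise FormatError(f"{path}: unknown config keys {sorted(raw)}")
    return cfg


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the configuration, for provenance."""
    canon = json.dumps(asdict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
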