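"""Facial anthropometry from 3D landmark coordinates.

Measurements (interlandmark distances, angles, depths and left/right
asymmetries) are computed from named anatomical landmarks placed on a 3D
facial surface.  The coordinate convention is right-handed with mm units:
+x toward the subject's anatomical right, +y superior, +z anterior.
Midline ("medial") landmarks define the midsagittal plane used for depth
and asymmetry measurements.

A landmark placed poorly (occlusion, surface artefacts) can be marked
excluded; only the measurements that reference it become unusable, all
others are still computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import _template
from .errors import ConfigurationError, DegenerateGeometryError

__all__ = [
    "LandmarkKey",
    "LandmarkTemplate",
    "LandmarkSet",
    "MeasurementDefinition",
    "MeasurementRecord",
    "Plane",
    "QcReport",
    "DEFAULT_TEMPLATE",
    "DEFAULT_REGISTRY",
    "QC_DISCREPANCY_MM",
    "fit_midsagittal_plane",
    "compute_measurement",
    "measure_subject",
    "qc_landmarks",
]

#: (code, side) — side is "L"/"R" for bilateral landmarks, None for medial.
LandmarkKey = tuple[str, Optional[str]]

#: Landmark placement discrepancy (mm) above which QC fails, strictly.
QC_DISCREPANCY_MM = 5.0


@dataclass(frozen=True)
class LandmarkTemplate:
    """Set of landmark codes a study protocol expects to be placed."""

    medial_codes: tuple[str, ...]
    bilateral_codes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.medial_codes)) != len(self.medial_codes):
            raise ConfigurationError("duplicate medial landmark codes")
        if len(set(self.bilateral_codes)) != len(self.bilateral_codes):
            raise ConfigurationError("duplicate bilateral landmark codes")
        overlap = set(self.medial_codes) & set(self.bilateral_codes)
        if overlap:
            raise ConfigurationError(f"codes both medial and bilateral: {sorted(overlap)}")

    @property
    def count_medial(self) -> int:
        return len(self.medial_codes)

    @property
    def count_bilateral(self) -> int:
        return len(self.bilateral_codes)

    def keys(self) -> set[LandmarkKey]:
        """All (code, side) keys the template defines."""
        out: set[LandmarkKey] = {(c, None) for c in self.medial_codes}
        for c in self.bilateral_codes:
            out.add((c, "L"))
            out.add((c, "R"))
        return out


#: Default template: 19 medial and 25 bilateral landmarks.
DEFAULT_TEMPLATE = LandmarkTemplate(
    medial_codes=_template.MEDIAL_CODES,
    bilateral_codes=_template.BILATERAL_CODES,
)


@dataclass
class LandmarkSet:
    """One subject's landmark coordinates (mm) against a template."""

    subject_id: str
    points: dict[LandmarkKey, np.ndarray]
    excluded: set[LandmarkKey] = field(default_factory=set)
    template: LandmarkTemplate = DEFAULT_TEMPLATE

    def __post_init__(self) -> None:
        valid = self.template.keys()
        for key, p in self.points.items():
            if key not in valid:
                raise ConfigurationError(f"landmark {key} not in template")
            arr = np.asarray(p, dtype=float)
            if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"landmark {key} has invalid coordinates")
            self.points[key] = arr
        bad = self.excluded - valid
        if bad:
            raise ConfigurationError(f"excluded keys not in template: {sorted(bad)}")

    def usable_point(self, key: LandmarkKey) -> Optional[np.ndarray]:
        """Coordinates of *key*, or None if absent or excluded."""
        if key in self.excluded:
            return None
        return self.points.get(key)


@dataclass(frozen=True)
class MeasurementDefinition:
    """How to derive one scalar measurement from landmarks.

    ``operands`` are (code, side) keys; side "B" is a placeholder meaning
    "evaluate once per side" and requires ``bilateral=True`` (the reported
    value is the mean of the left and right values).  Kinds:

    - ``distance``: Euclidean distance between two operands (mm)
    - ``angle``: interior angle at the middle of three operands (degrees)
    - ``depth``: signed distance of one operand from a reference plane,
      the midsagittal plane by default (mm, positive toward the normal)
    - ``asymmetry``: distance between the left landmark of a bilateral
      pair and the mirror image of the right landmark across the
      midsagittal plane (mm; 0 for a perfectly symmetric pair)
    """

    name: str
    kind: str
    operands: tuple[tuple[str, Optional[str]], ...]
    bilateral: bool = False
    units: str = "mm"

    def __post_init__(self) -> None:
        n = {"distance": 2, "angle": 3, "depth": 1, "asymmetry": 1}.get(self.kind)
        if n is None:
            raise ConfigurationError(f"unknown measurement kind {self.kind!r}")
        if len(self.operands) != n:
            raise ConfigurationError(
                f"{self.name}: kind {self.kind!r} needs {n} operands, got {len(self.operands)}"
            )
        if self.kind == "angle" and self.units != "degrees":
            raise ConfigurationError(f"{self.name}: angles are reported in degrees")
        if self.kind != "angle" and self.units != "mm":
            raise ConfigurationError(f"{self.name}: {self.kind} measurements are in mm")
        uses_placeholder = any(side == "B" for _, side in self.operands)
        if self.kind == "asymmetry":
            if self.operands[0][1] != "B":
                raise ConfigurationError(f"{self.name}: asymmetry takes one bilateral code")
        elif uses_placeholder and not self.bilateral:
            raise ConfigurationError(f"{self.name}: side placeholder requires bilateral=True")
        if self.bilateral and not uses_placeholder:
            raise ConfigurationError(f"{self.name}: bilateral=True but no side placeholder")

    def validate_against(self, template: LandmarkTemplate) -> None:
        for code, side in self.operands:
            if side in ("L", "R", "B"):
                if code not in template.bilateral_codes:
                    raise ConfigurationError(f"{self.name}: {code} is not bilateral in template")
            else:
                if code not in template.medial_codes:
                    raise ConfigurationError(f"{self.name}: {code} is not medial in template")

    def referenced_keys(self) -> set[LandmarkKey]:
        """Concrete landmark keys this definition depends on."""
        keys: set[LandmarkKey] = set()
        for code, side in self.operands:
            if side == "B":
                keys.add((code, "L"))
                keys.add((code, "R"))
            else:
                keys.add((code, side))
        return keys


def _defn(name: str, kind: str, *operands, bilateral: bool = False) -> MeasurementDefinition:
    units = "degrees" if kind == "angle" else "mm"
    return MeasurementDefinition(name, kind, tuple(operands), bilateral=bilateral, units=units)


#: The eight named measurements shipped by default (Farkas-style
#: interlandmark definitions); user registries may extend this list.
DEFAULT_REGISTRY: tuple[MeasurementDefinition, ...] = (
    _defn("palpebral_fissure_length", "distance", ("ex", "B"), ("en", "B"), bilateral=True),
    _defn("innercanthal_width", "distance", ("en", "L"), ("en", "R")),
    _defn("bizygomatic_width", "distance", ("zy", "L"), ("zy", "R")),
    _defn("nasal_protrusion", "distance", ("sn", None), ("prn", None)),
    _defn("nasal_bridge_length", "distance", ("n", None), ("prn", None)),
    _defn("facial_height", "distance", ("n", None), ("gn", None)),
    _defn("labial_fissure_width", "distance", ("ch", "L"), ("ch", "R")),
    _defn("philtral_length", "distance", ("sn", None), ("ls", None)),
)

MEASUREMENT_NAMES: tuple[str, ...] = tuple(d.name for d in DEFAULT_REGISTRY)


@dataclass
class MeasurementRecord:
    """One (subject, measurement) observation with its metadata."""

    subject_id: str
    measurement: str
    value: Optional[float]
    age: float
    sex: str
    ancestry: str = ""
    units: str = "mm"
    usable: bool = True


@dataclass(frozen=True)
class Plane:
    """A plane given by a point on it and a unit normal."""

    point: np.ndarray
    normal: np.ndarray

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.dot(np.asarray(p, float) - self.point, self.normal))

    def mirror(self, p: np.ndarray) -> np.ndarray:
        """Reflect *p* across the plane."""
        p = np.asarray(p, float)
        return p - 2.0 * self.signed_distance(p) * self.normal


def fit_midsagittal_plane(landmarks: LandmarkSet) -> Plane:
    """Least-squares plane through the usable medial landmarks.

    The plane minimises orthogonal distances (total least squares, via the
    SVD of the centred coordinates); the normal is oriented toward the
    subject's right (+x).
    """
    pts = [
        landmarks.usable_point((c, None))
        for c in landmarks.template.medial_codes
        if landmarks.usable_point((c, None)) is not None
    ]
    if len(pts) < 3:
        raise DegenerateGeometryError(
            f"need >= 3 usable medial landmarks to fit a plane, have {len(pts)}"
        )
    coords = np.vstack(pts)
    centroid = coords.mean(axis=0)
    _, s, vt = np.linalg.svd(coords - centroid, full_matrices=False)
    # collinear points: only one direction of spread
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("medial landmarks are collinear; plane undefined")
    normal = vt[2]
    if normal[0] < 0:
        normal = -normal
    return Plane(point=centroid, normal=normal / np.linalg.norm(normal))


def _interior_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateGeometryError("coincident landmarks in angle measurement")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def compute_measurement(
    landmarks: LandmarkSet,
    defn: MeasurementDefinition,
    plane: Optional[Plane] = None,
) -> tuple[Optional[float], bool]:
    """Evaluate one measurement; returns ``(value, usable)``.

    A missing or excluded operand landmark yields ``(None, False)`` rather
    than raising.  Depth and asymmetry kinds need the midsagittal plane;
    it is fitted on demand when not supplied.
    """
    defn.validate_against(landmarks.template)
    needed = defn.referenced_keys()
    resolved = {k: landmarks.usable_point(k) for k in needed}
    if any(v is None for v in resolved.values()):
        return None, False

    if defn.kind in ("depth", "asymmetry") and plane is None:
        try:
            plane = fit_midsagittal_plane(landmarks)
        except DegenerateGeometryError:
            return None, False

    if defn.kind == "distance":
        if defn.bilateral:
            vals = []
            for side in ("L", "R"):
                pts = [resolved[(code, side if s == "B" else s)] for code, s in defn.operands]
                vals.append(float(np.linalg.norm(pts[0] - pts[1])))
            return float(np.mean(vals)), True
        a, b = (resolved[(code, s)] for code, s in defn.operands)
        return float(np.linalg.norm(a - b)), True

    if defn.kind == "angle":
        a, b, c = (resolved[(code, s)] for code, s in defn.operands)
        return _interior_angle(a, b, c), True

    if defn.kind == "depth":
        (key,) = defn.operands
        return plane.signed_distance(resolved[key]), True

    # asymmetry
    code = defn.operands[0][0]
    left, right = resolved[(code, "L")], resolved[(code, "R")]
    return float(np.linalg.norm(left - plane.mirror(right))), True


def measure_subject(
    landmarks: LandmarkSet,
    registry: Sequence[MeasurementDefinition] = DEFAULT_REGISTRY,
    metadata: Optional[Mapping[str, object]] = None,
) -> list[MeasurementRecord]:
    """Evaluate a measurement registry for one subject.

    An excluded landmark renders only its dependent measurements unusable;
    all other measurements are still reported.
    """
    if not registry:
        raise ConfigurationError("measurement registry is empty")
    meta = dict(metadata or {})
    plane: Optional[Plane] = None
    if any(d.kind in ("depth", "asymmetry") for d in registry):
        try:
            plane = fit_midsagittal_plane(landmarks)
        except DegenerateGeometryError:
            plane = None
    records = []
    for defn in registry:
        value, usable = compute_measurement(landmarks, defn, plane=plane)
        records.append(
            MeasurementRecord(
                subject_id=landmarks.subject_id,
                measurement=defn.name,
                value=value,
                age=float(meta.get("age", np.nan)),
                sex=str(meta.get("sex", "")),
                ancestry=str(meta.get("ancestry", "")),
                units=defn.units,
                usable=usable,
            )
        )
    return records


@dataclass
class QcReport:
    """Placement discrepancies of a candidate landmark set vs ground truth."""

    discrepancies: dict[LandmarkKey, float]
    failed_keys: list[LandmarkKey]
    passed: bool
    threshold_mm: float = QC_DISCREPANCY_MM


def qc_landmarks(candidate: LandmarkSet, ground_truth: LandmarkSet) -> QcReport:
    """Compare candidate landmark placements against ground truth.

    Fails if any per-landmark Euclidean discrepancy strictly exceeds
    5 mm (a placement at exactly 5 mm passes).
    """
    if candidate.template != ground_truth.template:
        raise ConfigurationError("candidate and ground truth use different templates")
    shared = set(candidate.points) & set(ground_truth.points)
    disc = {
        k: float(np.linalg.norm(candidate.points[k] - ground_truth.points[k]))
        for k in sorted(shared)
    }
    failed = [k for k, d in disc.items() if d > QC_DISCREPANCY_MM]
    return QcReport(discrepancies=disc, failed_keys=failed, passed=not failed)
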