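"""Synthetic cohort generation for testing the reference pipeline.

The generator inverts the analysis model: each subject draws an age from
a pediatric-heavy mixture (most of the cohort under 18), a sex, and for
each facial measurement a value on a sex-specific exponential-decay
growth curve plus Gaussian age-dependent noise.  Gross outliers
(mis-placed landmarks) and per-record fallout (unusable measurements)
can be injected at configurable rates.

Two calibrated ancestry presets ship with the package.  The ``chinese``
preset anchors the features the downstream pipeline must recover: a
male-minus-female bizygomatic-width gap of exactly 3.5/5.2/7.2 mm at
ages 5/10/15, the printed age-specific bizygomatic SDs (females
6.8/6.6/6.7 mm and males 7.4/7.2/7.6 mm at those ages), and a palpebral
fissure length sex gap of exactly 1 mm at every age.  The ``european``
preset applies smooth offsets in the direction of published
cross-ancestry comparisons (narrower face, longer palpebral fissures,
more protrusive nose; facial height and mouth width unchanged; a faster
philtral growth rate).

Optionally, a subject's drawn measurement values can be realised as a 3D
landmark set by rescaling a built-in symmetric template face, so the
landmark-to-measurement stage is testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import _template
from .anthropometry import (
    DEFAULT_REGISTRY,
    DEFAULT_TEMPLATE,
    LandmarkSet,
    MeasurementRecord,
)
from .errors import ConfigurationError

__all__ = [
    "CohortSpec",
    "ANCESTRY_PRESETS",
    "EUROPEAN_OFFSETS",
    "DEFAULT_ANCESTRY_CENSUS",
    "make_cohort_spec",
    "simulate_cohort",
    "simulate_landmarks",
    "cohort_landmark_sets",
    "records_from_frame",
    "frame_from_records",
    "ancestry_census_summary",
]

_E = math.e

#: Default ancestry composition of a multi-ancestry recruitment census
#: (counts of recruited subjects per self-reported ancestry label), used
#: for demographic summaries and for labelling mixed simulated cohorts.
DEFAULT_ANCESTRY_CENSUS: dict[str, int] = {
    "Chinese": 879,
    "Malay": 179,
    "Indian": 96,
    "Filipino": 13,
    "Nepalese": 6,
    "Caucasian": 5,
    "Sri Lankan": 4,
    "Myanmar": 3,
    "Arab": 3,
    "Bangladeshi": 3,
    "Pakistani": 3,
    "Vietnamese": 3,
    "Boyanese": 3,
    "African": 3,
    "Indonesian": 3,
    "Javanese": 2,
    "Korean": 2,
    "Burmese": 2,
    "Chinese-thai": 1,
    "Unknown": 1,
    "Singhalese-chinese": 1,
    "Jew-chinese": 1,
    "Chinese-burmese": 1,
    "Chinese-japanese": 1,
}


def ancestry_census_summary(census: Mapping[str, int] = DEFAULT_ANCESTRY_CENSUS) -> dict:
    """Total recruitment and the largest group's percentage share."""
    total = sum(census.values())
    largest, count = max(census.items(), key=lambda kv: kv[1])
    return {
        "total": total,
        "largest_group": largest,
        "largest_count": count,
        "largest_share_pct": round(100.0 * count / total, 1),
    }


# ---------------------------------------------------------------------------
# Cohort specification


@dataclass(frozen=True)
class GeneratingCurve:
    """Exponential-decay generating curve, parameterised for readability.

    ``y(age) = asymptote - drop * exp(-rate * age)`` — equivalently the
    fitted family ``y = a(c - e^(1-b*age))`` with a = drop/e, b = rate,
    c = asymptote*e/drop.  ``drop`` is asymptote minus the birth value.
    """

    asymptote: float
    drop: float
    rate: float

    def __call__(self, age):
        return self.asymptote - self.drop * np.exp(-self.rate * np.asarray(age, float))

    def as_coefficients(self) -> tuple[float, float, float]:
        """(a, b, c) of the equivalent ``y = a(c - e^(1-b*age))`` form."""
        a = self.drop / _E
        return (a, self.rate, self.asymptote / a)


@dataclass(frozen=True)
class SdSpec:
    """Piecewise-linear SD (mm) over age; a single knot means constant."""

    knots: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        # sd = 0 allowed: the degenerate noiseless case used in testing
        if not self.knots or any(sd < 0 for _, sd in self.knots):
            raise ConfigurationError("SD knots must be non-empty and non-negative")

    def at(self, age) -> np.ndarray:
        ages = np.array([a for a, _ in self.knots], float)
        sds = np.array([s for _, s in self.knots], float)
        return np.interp(np.asarray(age, float), ages, sds)


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one cohort deterministically."""

    ancestry: str
    curves: Mapping[tuple[str, str], GeneratingCurve]  # (measurement, sex) ->
    sd_specs: Mapping[tuple[str, str], SdSpec]
    n: int = 760
    w_child: float = 0.86
    child_ages: tuple[float, float] = (0.0, 18.0)
    adult_ages: tuple[float, float] = (18.0, 55.0)
    sex_ratio: float = 0.5  # fraction male
    outlier_rate: float = 0.0
    outlier_magnitude: float = 6.0  # in SD units
    landmark_fallout: float = 0.0
    noise_scale: float = 1.0  # multiplies every SD; 0 = noiseless
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be >= 1")
        if not (0.0 <= self.w_child <= 1.0):
            raise ConfigurationError("w_child must lie in [0, 1]")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ConfigurationError("sex_ratio must lie in [0, 1]")
        for p, name in [(self.outlier_rate, "outlier_rate"),
                        (self.landmark_fallout, "landmark_fallout")]:
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ConfigurationError("noise_scale must be >= 0")
        missing = set(self.curves) ^ set(self.sd_specs)
        if missing:
            raise ConfigurationError(f"curves and SD specs disagree on strata: {sorted(missing)}")

    @property
    def measurements(self) -> list[str]:
        return sorted({m for m, _ in self.curves})

    def mean(self, measurement: str, sex: str, age) -> np.ndarray:
        return self.curves[(measurement, sex)](age)

    def sd(self, measurement: str, sex: str, age) -> np.ndarray:
        return self.noise_scale * self.sd_specs[(measurement, sex)].at(age)


def _sex_curves(asym_m, drop_m, rate_m, asym_f, drop_f, rate_f):
    return (GeneratingCurve(asym_m, drop_m, rate_m),
            GeneratingCurve(asym_f, drop_f, rate_f))


def _chinese_spec() -> CohortSpec:
    curves: dict[tuple[str, str], GeneratingCurve] = {}
    sds: dict[tuple[str, str], SdSpec] = {}

    def put(meas, male: GeneratingCurve, female: GeneratingCurve, sd_m, sd_f):
        curves[(meas, "M")], curves[(meas, "F")] = male, female
        sds[(meas, "M")] = SdSpec(tuple(sd_m) if isinstance(sd_m, (list, tuple)) else ((0.0, sd_m),))
        sds[(meas, "F")] = SdSpec(tuple(sd_f) if isinstance(sd_f, (list, tuple)) else ((0.0, sd_f),))

    # Male bizygomatic curve solved so the male-minus-female gap is exactly
    # 3.5 / 5.2 / 7.2 mm at ages 5 / 10 / 15 given the female curve.
    put("bizygomatic_width",
        GeneratingCurve(135.809955779934, 52.09278965515298, 0.13651346824767305),
        GeneratingCurve(125.0, 47.0, 0.181),
        sd_m=[(5.0, 7.4), (10.0, 7.2), (15.0, 7.6)],
        sd_f=[(5.0, 6.8), (10.0, 6.6), (15.0, 6.7)])
    # Shared drop and rate make the sex gap exactly 1.0 mm at every age.
    put("palpebral_fissure_length",
        GeneratingCurve(30.5, 12.0, 0.18), GeneratingCurve(29.5, 12.0, 0.18),
        sd_m=1.3, sd_f=1.3)
    put("innercanthal_width",
        GeneratingCurve(33.0, 13.0, 0.25), GeneratingCurve(32.0, 12.5, 0.25),
        sd_m=2.0, sd_f=2.0)
    put("nasal_protrusion",
        GeneratingCurve(18.5, 9.5, 0.12), GeneratingCurve(17.5, 9.0, 0.12),
        sd_m=1.5, sd_f=1.5)
    put("nasal_bridge_length",
        GeneratingCurve(50.0, 26.0, 0.11), GeneratingCurve(47.5, 24.0, 0.11),
        sd_m=3.0, sd_f=3.0)
    put("facial_height",
        GeneratingCurve(122.0, 42.0, 0.10), GeneratingCurve(113.0, 35.0, 0.115),
        sd_m=6.0, sd_f=6.0)
    put("labial_fissure_width",
        GeneratingCurve(53.0, 26.0, 0.12), GeneratingCurve(50.5, 24.5, 0.13),
        sd_m=3.0, sd_f=3.0)
    put("philtral_length",
        GeneratingCurve(16.0, 8.0, 0.15), GeneratingCurve(15.0, 7.5, 0.15),
        sd_m=2.0, sd_f=2.0)
    return CohortSpec(ancestry="chinese", curves=curves, sd_specs=sds)


#: Uniform vertical offsets (mm) applied to the chinese curves to obtain
#: the european preset; a vertical shift keeps the exponential-decay form.
EUROPEAN_OFFSETS: dict[str, float] = {
    "bizygomatic_width": -8.0,
    "palpebral_fissure_length": +2.6,
    "innercanthal_width": +4.0,
    "nasal_protrusion": +3.0,
    "nasal_bridge_length": +4.5,
    "facial_height": 0.0,
    "labial_fissure_width": 0.0,
    "philtral_length": 0.0,
}

#: Philtral length grows faster in the european preset (same birth value
#: and adult magnitude, different trajectory through childhood).
_EUROPEAN_PHILTRAL_RATE = 0.28


def _european_spec(offsets: Optional[Mapping[str, float]] = None) -> CohortSpec:
    base = _chinese_spec()
    offs = dict(EUROPEAN_OFFSETS)
    if offsets:
        offs.update(offsets)
    curves: dict[tuple[str, str], GeneratingCurve] = {}
    for (meas, sex), curve in base.curves.items():
        rate = _EUROPEAN_PHILTRAL_RATE if meas == "philtral_length" else curve.rate
        curves[(meas, sex)] = GeneratingCurve(curve.asymptote + offs.get(meas, 0.0),
                                              curve.drop, rate)
    return replace(base, ancestry="european", curves=curves)


ANCESTRY_PRESETS = ("chinese", "european")


def make_cohort_spec(preset: str, **overrides) -> CohortSpec:
    """Return a named ancestry preset, with field overrides applied.

    ``offsets`` (european only) adjusts the cross-ancestry offset
    magnitudes; all other keyword arguments override ``CohortSpec``
    fields (n, seed, outlier_rate, ...).
    """
    offsets = overrides.pop("offsets", None)
    if preset == "chinese":
        if offsets is not None:
            raise ConfigurationError("offsets only apply to the european preset")
        spec = _chinese_spec()
    elif preset == "european":
        spec = _european_spec(offsets)
    else:
        raise ConfigurationError(f"unknown preset {preset!r}; choose from {ANCESTRY_PRESETS}")
    bad = set(overrides) - {f for f in spec.__dataclass_fields__}
    if bad:
        raise ConfigurationError(f"unknown CohortSpec overrides: {sorted(bad)}")
    return replace(spec, **overrides)


# ---------------------------------------------------------------------------
# Simulation

_DISTANCE_KINDS = {d.name for d in DEFAULT_REGISTRY if d.kind == "distance"}


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort measurement table.

    Returns a long-format frame (subject_id, age_years, sex, ancestry,
    measurement, value, units, usable), byte-identical for identical
    (spec, seed).  Values are curve(age, sex) + N(0, SD(age)) noise;
    injected outliers add ±magnitude·SD; fallout marks records unusable.
    Distance values are clipped at 0 mm.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    is_male = rng.random(n) < spec.sex_ratio
    sexes = np.where(is_male, "M", "F")
    is_child = rng.random(n) < spec.w_child
    ages = np.where(
        is_child,
        rng.uniform(*spec.child_ages, size=n),
        rng.uniform(*spec.adult_ages, size=n),
    )
    width = len(str(n))
    subject_ids = np.array([f"S{i + 1:0{width}d}" for i in range(n)])

    rows = []
    for meas in spec.measurements:
        means = np.where(is_male, spec.mean(meas, "M", ages), spec.mean(meas, "F", ages))
        sds = np.where(is_male, spec.sd(meas, "M", ages), spec.sd(meas, "F", ages))
        values = means + sds * rng.standard_normal(n)
        is_outlier = rng.random(n) < spec.outlier_rate
        signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        values = values + is_outlier * signs * spec.outlier_magnitude * sds
        if meas in _DISTANCE_KINDS:
            values = np.maximum(values, 0.0)
        usable = rng.random(n) >= spec.landmark_fallout
        rows.append(pd.DataFrame({
            "subject_id": subject_ids,
            "age_years": np.round(ages, 3),
            "sex": sexes,
            "ancestry": spec.ancestry,
            "measurement": meas,
            "value": np.round(values, 6),
            "units": "mm",
            "usable": usable.astype(int),
        }))
    frame = pd.concat(rows, ignore_index=True)
    return frame.sort_values(["subject_id", "measurement"], kind="stable").reset_index(drop=True)


def records_from_frame(frame: pd.DataFrame) -> list[MeasurementRecord]:
    """Convert a long-format measurement table to MeasurementRecord objects."""
    return [
        MeasurementRecord(
            subject_id=str(r.subject_id),
            measurement=str(r.measurement),
            value=float(r.value) if pd.notna(r.value) else None,
            age=float(r.age_years),
            sex=str(r.sex),
            ancestry=str(r.ancestry),
            units=str(r.units),
            usable=bool(r.usable),
        )
        for r in frame.itertuples(index=False)
    ]


def frame_from_records(records: Sequence[MeasurementRecord]) -> pd.DataFrame:
    """Inverse of :func:`records_from_frame`."""
    return pd.DataFrame({
        "subject_id": [r.subject_id for r in records],
        "age_years": [round(r.age, 3) for r in records],
        "sex": [r.sex for r in records],
        "ancestry": [r.ancestry for r in records],
        "measurement": [r.measurement for r in records],
        "value": [r.value for r in records],
        "units": [r.units for r in records],
        "usable": [int(r.usable) for r in records],
    })


# ---------------------------------------------------------------------------
# Landmark realisation

_MIRROR = np.array([-1.0, 1.0, 1.0])


def simulate_landmarks(
    values: Mapping[str, float],
    subject_id: str = "synthetic",
    placement_noise: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    excluded: Optional[set] = None,
) -> LandmarkSet:
    """Realise target measurement values as a 3D landmark set.

    Starts from the built-in symmetric template, rescales it isotropically
    to the subjects' overall size, then repositions the landmarks that the
    eight default measurements reference so each target is met exactly
    (before optional Gaussian placement noise).  The construction is
    symmetric, so all asymmetry measurements are 0 without noise.

    Raises ConfigurationError for infeasible targets (non-positive or
    missing values).
    """
    needed = [d.name for d in DEFAULT_REGISTRY]
    missing = [m for m in needed if m not in values]
    if missing:
        raise ConfigurationError(f"missing target measurements: {missing}")
    if any(not np.isfinite(values[m]) or values[m] <= 0 for m in needed):
        raise ConfigurationError("target measurements must be positive and finite")

    tpl = _template.template_points()

    def tdist(k1, k2):
        return float(np.linalg.norm(tpl[k1] - tpl[k2]))

    # overall isotropic scale from the size-bearing targets
    ratios = [
        values["facial_height"] / tdist(("n", None), ("gn", None)),
        values["bizygomatic_width"] / tdist(("zy", "L"), ("zy", "R")),
        values["innercanthal_width"] / tdist(("en", "L"), ("en", "R")),
    ]
    s = float(np.mean(ratios))
    pts = {k: p * s for k, p in tpl.items()}

    def unit(a, b):
        v = pts[b] - pts[a]
        return v / np.linalg.norm(v)

    # midline chain anchored at nasion
    n_key = ("n", None)
    pts[("gn", None)] = pts[n_key] + values["facial_height"] * unit(n_key, ("gn", None))
    pts[("prn", None)] = pts[n_key] + values["nasal_bridge_length"] * unit(n_key, ("prn", None))
    pts[("sn", None)] = pts[("prn", None)] + values["nasal_protrusion"] * unit(("prn", None), ("sn", None))
    pts[("ls", None)] = pts[("sn", None)] + values["philtral_length"] * unit(("sn", None), ("ls", None))

    # paired landmarks: set the right side, mirror the left
    for code, half in [("en", values["innercanthal_width"] / 2.0),
                       ("zy", values["bizygomatic_width"] / 2.0),
                       ("ch", values["labial_fissure_width"] / 2.0)]:
        p = pts[(code, "R")].copy()
        p[0] = half
        pts[(code, "R")] = p
        pts[(code, "L")] = p * _MIRROR
    ex = pts[("en", "R")] + values["palpebral_fissure_length"] * unit(("en", "R"), ("ex", "R"))
    pts[("ex", "R")] = ex
    pts[("ex", "L")] = ex * _MIRROR

    if placement_noise > 0.0:
        rng = np.random.default_rng() if rng is None else rng
        for k in pts:
            pts[k] = pts[k] + rng.normal(0.0, placement_noise, size=3)

    return LandmarkSet(subject_id=subject_id, points=pts,
                       excluded=set(excluded or ()), template=DEFAULT_TEMPLATE)


def cohort_landmark_sets(
    frame: pd.DataFrame,
    placement_noise: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[list[LandmarkSet], list[str]]:
    """Realise every subject of a simulated cohort as a landmark set.

    Unusable measurement records are represented by excluding one operand
    landmark of the corresponding definition.  Subjects whose targets are
    infeasible are skipped and reported in the second return value.
    """
    by_defn = {d.name: d for d in DEFAULT_REGISTRY}
    sets: list[LandmarkSet] = []
    failures: list[str] = []
    for sid, sub in frame.groupby("subject_id", sort=True):
        values = dict(zip(sub["measurement"], sub["value"]))
        excluded = set()
        for _, row in sub.iterrows():
            if not row["usable"]:
                defn = by_defn.get(row["measurement"])
                if defn is not None:
                    excluded.add(sorted(defn.referenced_keys())[0])
        try:
            sets.append(simulate_landmarks(values, subject_id=str(sid),
                                           placement_noise=placement_noise,
                                           rng=rng, excluded=excluded))
        except ConfigurationError as exc:
            failures.append(f"{sid}: {exc}")
    return sets, failures
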