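"""Sex-specific normative growth-curve references.

For each facial measurement and each sex, a growth curve (expected value
as a function of age) is fitted by least squares from cross-sectional
data.  Five candidate functional forms compete:

- exponential decay  ``y = a(c - e^(1 - b*age))``  (3 coefficients),
- linear, quadratic, cubic and quartic polynomials.

The winner is chosen either by raw residual sum of squares (ties broken
toward fewer coefficients) or by AICc; an age-varying residual SD profile
is estimated with a Gaussian kernel, gross outliers (beyond 3 SD of the
fitted mean, strictly) are removed and the model refitted until the set
stabilises, and a subject-level bootstrap provides 95% confidence bands
for the mean curve.  Individuals are later scored against these
references by age- and sex-matched Z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .anthropometry import MeasurementRecord
from .errors import CiError, FitError, SampleSizeError

__all__ = [
    "FAMILIES",
    "GrowthCurveModel",
    "SdProfile",
    "CiBand",
    "ReferenceCurve",
    "ReferenceSet",
    "ReferenceConfig",
    "eval_curve",
    "fit_curve",
    "select_model",
    "estimate_sd_profile",
    "estimate_ci",
    "detect_outliers",
    "fit_reference",
    "fit_reference_set",
    "required_sample_size",
]

#: family name -> number of coefficients
FAMILIES: dict[str, int] = {
    "expdecay": 3,
    "linear": 2,
    "quadratic": 3,
    "cubic": 4,
    "quartic": 5,
}

_COEF_NAMES = "abcde"


@dataclass(frozen=True)
class GrowthCurveModel:
    """A fitted functional form: family, coefficients and achieved RSS."""

    family: str
    coefficients: tuple[float, ...]
    rss: float
    n_points: int

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FitError(f"unknown model family {self.family!r}")
        k = FAMILIES[self.family]
        if len(self.coefficients) != k:
            raise FitError(f"{self.family} needs {k} coefficients, got {len(self.coefficients)}")

    @property
    def n_coefficients(self) -> int:
        return FAMILIES[self.family]

    def coef_dict(self) -> dict[str, float]:
        return dict(zip(_COEF_NAMES, self.coefficients))

    def __call__(self, age):
        return eval_curve(self, age)


def eval_curve(model: GrowthCurveModel, age) -> np.ndarray | float:
    """Evaluate the fitted curve at *age* (scalar or array, years)."""
    coefs = np.asarray(model.coefficients, dtype=float)
    if not np.all(np.isfinite(coefs)):
        raise FitError(f"non-finite coefficients in {model.family} model")
    x = np.asarray(age, dtype=float)
    if model.family == "expdecay":
        a, b, c = coefs
        y = a * (c - np.exp(1.0 - b * x))
    else:
        # coefficients are highest-degree first, matching the printed forms
        y = np.polyval(coefs, x)
    return y if isinstance(age, np.ndarray) else float(y)


def _expdecay_profile_solve(x: np.ndarray, y: np.ndarray, b: float) -> tuple[float, float, float]:
    """For fixed decay rate b, solve the remaining two coefficients linearly.

    With u = e^(1-b*x) the model is y = a*c - a*u, linear in (p, q) =
    (a*c, -a).  Returns (p, q, rss).
    """
    u = np.exp(1.0 - b * x)
    n = x.size
    su, suu, sy, suy = u.sum(), (u * u).sum(), y.sum(), (u * y).sum()
    det = n * suu - su * su
    if det <= 1e-12 * max(suu * n, 1.0):
        return np.nan, np.nan, np.inf
    p = (suu * sy - su * suy) / det
    q = (n * suy - su * sy) / det
    resid = y - (p + q * u)
    return p, q, float(resid @ resid)


_B_GRID = np.geomspace(0.05, 2.0, 25)


def _fit_expdecay(x: np.ndarray, y: np.ndarray) -> tuple[tuple[float, float, float], float]:
    """Profiled nonlinear least squares for ``y = a(c - e^(1-b*x))``.

    The decay rate b is the only nonlinear coefficient: for each b the
    other two are solved in closed form, so fitting reduces to a 1-D
    minimisation initialised on a log-spaced grid of b values.
    """
    rss_grid = np.array([_expdecay_profile_solve(x, y, b)[2] for b in _B_GRID])
    if not np.any(np.isfinite(rss_grid)):
        raise FitError("expdecay fit failed to converge from any initialisation")
    i = int(np.argmin(rss_grid))
    lo = _B_GRID[i - 1] if i > 0 else _B_GRID[0] / 2.0
    hi = _B_GRID[i + 1] if i < len(_B_GRID) - 1 else _B_GRID[-1] * 1.5
    res = optimize.minimize_scalar(
        lambda b: _expdecay_profile_solve(x, y, b)[2],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-10},
    )
    b = float(res.x)
    p, q, rss = _expdecay_profile_solve(x, y, b)
    if not np.isfinite(rss):
        raise FitError("expdecay fit degenerate at optimum")
    a = -q
    if abs(a) < 1e-12:
        raise FitError("expdecay fit collapsed to a constant (a ~ 0)")
    c = p / a
    return (a, b, c), rss


def fit_curve(points: Sequence[tuple[float, float]], family: str) -> GrowthCurveModel:
    """Least-squares fit of one candidate family to (age, value) points.

    Polynomial families are solved in closed form; the exponential-decay
    family by profiled nonlinear least squares (see ``_fit_expdecay``).
    """
    if family not in FAMILIES:
        raise FitError(f"unknown model family {family!r}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be a sequence of (age, value) pairs")
    x, y = pts[:, 0], pts[:, 1]
    k = FAMILIES[family]
    if x.size < k:
        raise FitError(f"{family} needs at least {k} points, got {x.size}")
    if family == "expdecay":
        coefs, rss = _fit_expdecay(x, y)
    else:
        deg = k - 1
        coefs_arr = np.polyfit(x, y, deg)
        resid = y - np.polyval(coefs_arr, x)
        coefs, rss = tuple(float(v) for v in coefs_arr), float(resid @ resid)
    return GrowthCurveModel(family=family, coefficients=tuple(map(float, coefs)),
                            rss=max(rss, 0.0), n_points=int(x.size))


def _aicc(rss: float, n: int, k: int) -> float:
    """AICc for a least-squares fit with k mean coefficients (+1 for variance)."""
    kk = k + 1
    if n - kk - 1 <= 0:
        return np.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * kk + (2 * kk * (kk + 1)) / (n - kk - 1)


def select_model(
    points: Sequence[tuple[float, float]],
    families: Iterable[str] = tuple(FAMILIES),
    criterion: str = "rss",
) -> GrowthCurveModel:
    """Fit every candidate family and return the winner.

    ``criterion="rss"`` picks the minimum residual sum of squares, with
    ties (to within a 1e-9 relative margin) broken toward the family with
    fewest coefficients.  Because the polynomial families are nested, raw
    RSS can never prefer a lower-order polynomial to the quartic, so an
    ``"aicc"`` criterion penalising coefficient count is also available.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 6:
        raise FitError(f"model selection needs >= 6 points, got {pts.shape[0]}")
    if criterion not in ("rss", "aicc"):
        raise FitError(f"unknown selection criterion {criterion!r}")
    fits: list[GrowthCurveModel] = []
    errors: list[str] = []
    for fam in families:
        try:
            fits.append(fit_curve(points, fam))
        except FitError as exc:  # a family may individually fail
            errors.append(str(exc))
    if not fits:
        raise FitError("all candidate families failed: " + "; ".join(errors))
    n = pts.shape[0]
    if criterion == "aicc":
        return min(fits, key=lambda m: (_aicc(m.rss, n, m.n_coefficients), m.n_coefficients))
    best_rss = min(m.rss for m in fits)
    tol = 1e-9 * max(best_rss, 1.0)
    tied = [m for m in fits if m.rss <= best_rss + tol]
    return min(tied, key=lambda m: m.n_coefficients)


@dataclass
class SdProfile:
    """Age-varying residual SD on a regular age grid (0.5-year spacing)."""

    ages: np.ndarray
    sd: np.ndarray
    bandwidth: float
    low_confidence: np.ndarray  # bool mask: kernel-effective n < 3 at this age

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, float)
        self.sd = np.asarray(self.sd, float)
        self.low_confidence = np.asarray(self.low_confidence, bool)
        if np.any(np.diff(self.ages) <= 0):
            raise FitError("SD profile grid must be strictly increasing")
        if np.any(self.sd < 0):
            raise FitError("SD profile must be non-negative")

    def at(self, age) -> np.ndarray | float:
        """SD linearly interpolated at *age* (clamped beyond the grid)."""
        out = np.interp(np.asarray(age, float), self.ages, self.sd)
        return out if isinstance(age, np.ndarray) else float(out)


def _age_grid(lo: float, hi: float, step: float = 0.5) -> np.ndarray:
    n = max(int(math.floor((hi - lo) / step + 1e-9)), 0)
    grid = lo + step * np.arange(n + 1)
    if grid[-1] < hi - 1e-9:
        grid = np.append(grid, hi)
    return grid


def estimate_sd_profile(
    points: Sequence[tuple[float, float]],
    model: GrowthCurveModel,
    bandwidth: float = 2.0,
) -> SdProfile:
    """Kernel estimate of the residual SD as a function of age.

    At each grid age g, SD(g) is the square root of the Gaussian-kernel
    weighted mean squared residual about the fitted curve.  Grid points
    where the kernel-effective sample size (Kish) falls below 3 are kept
    but flagged low-confidence.
    """
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    resid2 = (y - eval_curve(model, x)) ** 2
    grid = _age_grid(float(x.min()), float(x.max()))
    sd = np.empty_like(grid)
    lowconf = np.zeros_like(grid, dtype=bool)
    for i, g in enumerate(grid):
        w = np.exp(-0.5 * ((x - g) / bandwidth) ** 2)
        sw = w.sum()
        sd[i] = math.sqrt(float((w * resid2).sum() / sw)) if sw > 0 else 0.0
        n_eff = (sw * sw) / float((w * w).sum()) if sw > 0 else 0.0
        lowconf[i] = n_eff < 3.0
    return SdProfile(ages=grid, sd=sd, bandwidth=float(bandwidth), low_confidence=lowconf)


@dataclass
class CiBand:
    """Bootstrap percentile confidence band for the mean curve."""

    ages: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float = 0.95

    @property
    def halfwidth(self) -> np.ndarray:
        return (self.upper - self.lower) / 2.0

    def contains(self, age: float, value: float) -> bool:
        lo = float(np.interp(age, self.ages, self.lower))
        hi = float(np.interp(age, self.ages, self.upper))
        return lo <= value <= hi


def estimate_ci(
    points: Sequence[tuple[float, float]],
    family: str,
    level: float = 0.95,
    B: int = 500,
    rng: Optional[np.random.Generator] = None,
    grid: Optional[np.ndarray] = None,
) -> CiBand:
    """Nonparametric bootstrap CI for the fitted mean curve.

    Subjects (rows) are resampled with replacement B times; the same
    family is refitted to each resample, and at each grid age the band is
    the percentile interval of the refitted curve values.
    """
    if B < 100:
        raise CiError(f"bootstrap needs B >= 100, got {B}")
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    rng = np.random.default_rng() if rng is None else rng
    if grid is None:
        grid = _age_grid(float(pts[:, 0].min()), float(pts[:, 0].max()))
    curves = np.empty((B, grid.size))
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            m = fit_curve(pts[idx], family)
            curves[b] = eval_curve(m, grid)
        except FitError:
            curves[b] = np.nan
            failures += 1
    if failures > 0.10 * B:
        raise CiError(f"{failures}/{B} bootstrap refits failed")
    alpha = 1.0 - level
    lower = np.nanpercentile(curves, 100 * alpha / 2.0, axis=0)
    upper = np.nanpercentile(curves, 100 * (1.0 - alpha / 2.0), axis=0)
    return CiBand(ages=grid, lower=lower, upper=upper, level=level)


def detect_outliers(
    points: Sequence[tuple[float, float]],
    model: GrowthCurveModel,
    sd_profile: SdProfile,
) -> np.ndarray:
    """Indices of points lying strictly more than 3 SD from the fitted mean."""
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    resid = np.abs(y - eval_curve(model, x))
    return np.flatnonzero(resid > 3.0 * sd_profile.at(x))


@dataclass(frozen=True)
class ReferenceConfig:
    """Tunable parameters for reference-curve construction."""

    criterion: str = "aicc"
    bandwidth: float = 2.0
    B: int = 500
    max_iter: int = 5
    min_stratum_n: int = 30
    compute_ci: bool = True
    families: tuple[str, ...] = tuple(FAMILIES)


@dataclass
class ReferenceCurve:
    """Normative reference for one measurement in one sex."""

    measurement: str
    sex: str
    model: GrowthCurveModel
    sd_profile: SdProfile
    ci: Optional[CiBand]
    age_range_sampled: tuple[float, float]
    n_subjects: int
    outliers_removed: int

    def mean_at(self, age) -> np.ndarray | float:
        return eval_curve(self.model, age)

    def sd_at(self, age) -> np.ndarray | float:
        return self.sd_profile.at(age)

    def is_extrapolated(self, age: float) -> bool:
        lo, hi = self.age_range_sampled
        return age < lo or age > hi


@dataclass
class ReferenceSet:
    """All reference curves for one ancestry group, plus provenance."""

    ancestry: str
    curves: list[ReferenceCurve] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def add(self, curve: ReferenceCurve) -> None:
        if self.get(curve.measurement, curve.sex) is not None:
            raise FitError(f"duplicate curve for ({curve.measurement}, {curve.sex})")
        self.curves.append(curve)

    def get(self, measurement: str, sex: str) -> Optional[ReferenceCurve]:
        for c in self.curves:
            if c.measurement == measurement and c.sex == sex:
                return c
        return None

    @property
    def measurements(self) -> list[str]:
        return sorted({c.measurement for c in self.curves})


def _records_to_points(records: Iterable[MeasurementRecord]) -> np.ndarray:
    pts = [(r.age, r.value) for r in records if r.usable and r.value is not None]
    return np.asarray(pts, dtype=float)


def fit_reference(
    records: Iterable[MeasurementRecord],
    measurement: str,
    sex: str,
    config: ReferenceConfig = ReferenceConfig(),
    rng: Optional[np.random.Generator] = None,
) -> ReferenceCurve:
    """Build the reference curve for one (measurement, sex) stratum.

    Iterates fit -> SD profile -> 3 SD outlier detection -> exclusion ->
    refit until the outlier set stabilises (or ``max_iter``).  The study
    workflow this models sent flagged outliers back for landmark
    reappraisal; here they are excluded from the refit.
    """
    stratum = [
        r for r in records
        if r.measurement == measurement and r.sex == sex and r.usable and r.value is not None
    ]
    if len(stratum) < config.min_stratum_n:
        raise SampleSizeError(
            f"({measurement}, {sex}): {len(stratum)} usable records, "
            f"below the configured minimum of {config.min_stratum_n}"
        )
    pts = _records_to_points(stratum)
    removed = 0
    model = select_model(pts, families=config.families, criterion=config.criterion)
    sd = estimate_sd_profile(pts, model, bandwidth=config.bandwidth)
    for _ in range(config.max_iter):
        out = detect_outliers(pts, model, sd)
        if out.size == 0:
            break
        removed += int(out.size)
        pts = np.delete(pts, out, axis=0)
        model = select_model(pts, families=config.families, criterion=config.criterion)
        sd = estimate_sd_profile(pts, model, bandwidth=config.bandwidth)
    ci = None
    if config.compute_ci:
        ci = estimate_ci(pts, model.family, B=config.B, rng=rng, grid=sd.ages)
    return ReferenceCurve(
        measurement=measurement,
        sex=sex,
        model=model,
        sd_profile=sd,
        ci=ci,
        age_range_sampled=(float(pts[:, 0].min()), float(pts[:, 0].max())),
        n_subjects=int(pts.shape[0]),
        outliers_removed=removed,
    )


def fit_reference_set(
    records: Sequence[MeasurementRecord],
    ancestry: str,
    config: ReferenceConfig = ReferenceConfig(),
    rng: Optional[np.random.Generator] = None,
    measurements: Optional[Sequence[str]] = None,
    sexes: Sequence[str] = ("M", "F"),
) -> ReferenceSet:
    """Fit references for every (measurement, sex) stratum in *records*.

    Strata below the minimum sample size are skipped (recorded in
    provenance) rather than failing the whole set.
    """
    if measurements is None:
        measurements = sorted({r.measurement for r in records})
    refset = ReferenceSet(ancestry=ancestry)
    skipped: list[str] = []
    for meas in measurements:
        for sex in sexes:
            try:
                refset.add(fit_reference(records, meas, sex, config=config, rng=rng))
            except SampleSizeError as exc:
                skipped.append(str(exc))
    refset.provenance["skipped_strata"] = skipped
    refset.provenance["criterion"] = config.criterion
    return refset


def required_sample_size(
    effect_sd: float = 0.5,
    alpha: float = 0.05,
    power: float = 0.80,
    sided: str = "one",
    fallout: float = 0.15,
) -> int:
    """Recruited subjects needed per age/sex band to resolve a mean shift.

    Uses the normal approximation for a one-sample test of a mean shift of
    ``effect_sd`` standard deviations: usable n = ceil(((z_{1-a} +
    z_{power}) / effect_sd)^2), then inflated by the expected fall-out
    (unusable-image) rate.  Defaults (one-sided 5%, 80% power, half-SD
    effect, 15% fall-out) give 30.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if effect_sd <= 0:
        raise ValueError("effect_sd must be positive")
    if not (0 <= fallout < 1):
        raise ValueError("fallout must lie in [0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    z_alpha = stats.norm.ppf(1 - alpha / (1 if sided == "one" else 2))
    z_power = stats.norm.ppf(power)
    usable = math.ceil(((z_alpha + z_power) / effect_sd) ** 2)
    return math.ceil(usable / (1.0 - fallout))
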