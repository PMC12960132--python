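"""Growth-curve fitting, model selection, SD/CI estimation, outlier loop."""

import numpy as np
import pytest
from scipy import stats

from facenorms.anthropometry import MeasurementRecord
from facenorms.errors import CiError, FitError, SampleSizeError
from facenorms.reference import (
    GrowthCurveModel,
    ReferenceConfig,
    SdProfile,
    detect_outliers,
    estimate_ci,
    estimate_sd_profile,
    eval_curve,
    fit_curve,
    fit_reference,
    required_sample_size,
    select_model,
)


def expdecay_points(a, b, c, ages):
    """Noiseless samples of y = a(c - e^(1-b*age))."""
    ages = np.asarray(ages, float)
    return np.c_[ages, a * (c - np.exp(1.0 - b * ages))]


class TestEvalCurve:
    def test_expdecay_exponent_cancels(self):
        m = GrowthCurveModel("expdecay", (1.0, 1.0, 4.5), rss=0.0, n_points=0)
        assert eval_curve(m, 1.0) == pytest.approx(4.5 - 1.0)

    def test_linear(self):
        m = GrowthCurveModel("linear", (2.0, 3.0), rss=0.0, n_points=0)
        assert eval_curve(m, 4.0) == pytest.approx(11.0)

    def test_quartic(self):
        m = GrowthCurveModel("quartic", (1.0, 0.0, 0.0, 0.0, 5.0), rss=0.0, n_points=0)
        assert eval_curve(m, 2.0) == pytest.approx(21.0)

    def test_nonfinite_coefficients_rejected(self):
        m = GrowthCurveModel("linear", (np.nan, 0.0), rss=0.0, n_points=0)
        with pytest.raises(FitError):
            eval_curve(m, 1.0)


def _expdecay_grid_oracle(x, y):
    """Brute-force grid search over b with a linear solve for (a*c, a):
    an independent check on the profiled fit."""
    best = (np.inf, None)
    for b in np.linspace(0.01, 2.5, 4981):
        u = np.exp(1.0 - b * x)
        design = np.c_[np.ones_like(u), -u]
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        rss = float(((design @ coef - y) ** 2).sum())
        if rss < best[0]:
            best = (rss, (coef[1], b, coef[0] / coef[1]))
    return best


class TestFitCurve:
    def test_exact_line(self):
        m = fit_curve([(0, 1), (1, 3), (2, 5)], "linear")
        assert m.coefficients == pytest.approx([2.0, 1.0])
        assert m.rss == pytest.approx(0.0, abs=1e-20)

    def test_three_point_quadratic_interpolates(self):
        m = fit_curve([(0, 1), (1, 0), (2, 3)], "quadratic")
        assert m.rss == pytest.approx(0.0, abs=1e-20)

    def test_noiseless_expdecay_recovery_vs_grid_oracle(self):
        pts = expdecay_points(10.0, 0.5, 1.2, np.linspace(0, 20, 40))
        m = fit_curve(pts, "expdecay")
        assert m.rss < 1e-8
        assert m.coefficients == pytest.approx([10.0, 0.5, 1.2], abs=1e-4)
        oracle_rss, oracle_coef = _expdecay_grid_oracle(pts[:, 0], pts[:, 1])
        assert oracle_rss < 1e-4  # the coarse grid agrees the truth fits
        assert m.rss <= oracle_rss + 1e-12
        assert m.coefficients[1] == pytest.approx(oracle_coef[1], abs=1e-3)

    def test_insufficient_points(self):
        with pytest.raises(FitError):
            fit_curve([(0, 1), (1, 2)], "quadratic")


class TestSelectModel:
    def test_rss_tie_broken_to_fewest_coefficients(self):
        pts = [(x, 2.0 * x + 1.0) for x in range(8)]
        m = select_model(pts, criterion="rss")
        assert m.family == "linear"
        assert m.rss == pytest.approx(0.0, abs=1e-12)

    def test_nested_polynomial_rss_monotone(self):
        rng = np.random.default_rng(5)
        pts = np.c_[rng.uniform(0, 20, 60), rng.normal(50, 8, 60)]
        rss = {f: fit_curve(pts, f).rss for f in ("linear", "quadratic", "cubic", "quartic")}
        assert rss["quartic"] <= rss["cubic"] <= rss["quadratic"] <= rss["linear"]

    def test_aicc_prefers_expdecay_on_expdecay_truth(self):
        wins = 0
        for seed in range(1, 51):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 20, 200)
            y = 10.0 * (1.2 - np.exp(1.0 - 0.5 * x)) + rng.normal(0, 0.5, 200)
            if select_model(np.c_[x, y], criterion="aicc").family == "expdecay":
                wins += 1
        assert wins >= 40  # >= 80% of 50 replicates

    def test_too_few_points(self):
        with pytest.raises(FitError):
            select_model([(0, 1)] * 5)


class TestSdProfile:
    @staticmethod
    def _flat_model():
        return GrowthCurveModel("linear", (0.0, 0.0), rss=0.0, n_points=0)

    def test_constant_residuals_give_constant_profile(self):
        x = np.linspace(0, 10, 50)
        prof = estimate_sd_profile(np.c_[x, np.full_like(x, -3.0)], self._flat_model())
        assert prof.sd == pytest.approx(np.full_like(prof.sd, 3.0))

    def test_homoscedastic_recovery(self):
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 20, 1000)
            prof = estimate_sd_profile(np.c_[x, rng.normal(0, 2.0, 1000)], self._flat_model())
            assert np.all(prof.sd >= 1.7) and np.all(prof.sd <= 2.3)

    def test_scaling_homogeneity(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 15, 200)
        r = rng.normal(0, 1.5, 200)
        p1 = estimate_sd_profile(np.c_[x, r], self._flat_model())
        p2 = estimate_sd_profile(np.c_[x, 2.0 * r], self._flat_model())
        assert p2.sd == pytest.approx(2.0 * p1.sd)

    def test_sparse_ages_flag_low_confidence(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 30.0])
        prof = estimate_sd_profile(np.c_[x, np.ones_like(x)], self._flat_model())
        assert prof.low_confidence[-1]  # lone point at age 30
        assert not prof.low_confidence[0]  # five clustered points near age 0


class TestCi:
    def test_noiseless_data_degenerate_band(self):
        pts = expdecay_points(10.0, 0.4, 1.5, np.linspace(0, 20, 60))
        ci = estimate_ci(pts, "expdecay", B=100, rng=np.random.default_rng(0))
        assert np.all(ci.halfwidth < 1e-6)

    def test_halfwidth_shrinks_with_n(self):
        def halfwidth(n, seed):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0, 20, n)
            y = 3.0 * x + 10.0 + rng.normal(0, 5.0, n)
            ci = estimate_ci(np.c_[x, y], "linear", B=200, rng=rng)
            return float(np.interp(10.0, ci.ages, ci.halfwidth))

        assert halfwidth(800, 21) < halfwidth(200, 20)

    def test_b_minimum_enforced(self):
        with pytest.raises(CiError):
            estimate_ci([(0, 1), (1, 2)], "linear", B=50)


class TestOutliers:
    @staticmethod
    def _setup(residuals):
        x = np.arange(len(residuals), dtype=float)
        model = GrowthCurveModel("linear", (0.0, 0.0), rss=0.0, n_points=len(residuals))
        prof = SdProfile(ages=np.array([0.0, float(len(residuals))]),
                         sd=np.array([1.0, 1.0]), bandwidth=2.0,
                         low_confidence=np.zeros(2, bool))
        return np.c_[x, residuals], model, prof

    def test_only_beyond_three_sd_flagged(self):
        pts, model, prof = self._setup([0.5, -3.5, 0.1, 2.9])
        assert detect_outliers(pts, model, prof).tolist() == [1]

    def test_all_within_three_sd_empty(self):
        pts, model, prof = self._setup([0.5, -2.9, 1.0])
        assert detect_outliers(pts, model, prof).size == 0

    def test_exactly_three_sd_not_flagged(self):
        pts, model, prof = self._setup([3.0, -3.0, 0.0])
        assert detect_outliers(pts, model, prof).size == 0


def _records(x, y, measurement="bizygomatic_width", sex="M"):
    return [
        MeasurementRecord(subject_id=f"s{i}", measurement=measurement, value=float(v),
                          age=float(a), sex=sex)
        for i, (a, v) in enumerate(zip(x, y))
    ]


class TestFitReference:
    CFG = ReferenceConfig(compute_ci=False)

    def test_gross_outliers_all_removed_and_mean_recovered(self):
        # palpebral fissure length stratum: sigma = 1.3 mm, +10 SD injections
        A, D, b, sigma = 30.5, 12.0, 0.18, 1.3
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            n = 760
            x = rng.uniform(0, 18, n)
            y = A - D * np.exp(-b * x) + rng.normal(0, sigma, n)
            idx = set(rng.choice(n, 5, replace=False).tolist())
            y[list(idx)] += 10.0 * sigma
            # run the loop by hand to verify the injected points themselves go
            pts = np.c_[x, y]
            alive = np.arange(n)
            for _ in range(5):
                model = select_model(pts, criterion="aicc")
                prof = estimate_sd_profile(pts, model)
                out = detect_outliers(pts, model, prof)
                if out.size == 0:
                    break
                alive = np.delete(alive, out)
                pts = np.delete(pts, out, axis=0)
            assert not (idx & set(alive.tolist())), "an injected +10 SD outlier survived"
            ref = fit_reference(_records(x, y, "palpebral_fissure_length"),
                                "palpebral_fissure_length", "M", self.CFG)
            assert ref.outliers_removed >= 5
            assert abs(ref.mean_at(10.0) - (A - D * np.exp(-b * 10.0))) < 0.5

    def test_outlier_free_cohort_converges_immediately(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 18, 100)
        y = 50.0 + 2.0 * x + rng.uniform(-1, 1, 100)  # bounded noise: no 3 SD points
        ref = fit_reference(_records(x, y), "bizygomatic_width", "M", self.CFG)
        assert ref.outliers_removed == 0

    def test_outlier_detection_idempotent_after_convergence(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 18, 300)
        pts = np.c_[x, 100.0 + 1.5 * x + rng.normal(0, 5.0, 300)]
        for _ in range(10):  # run the loop by hand to a fixed point
            model = select_model(pts, criterion="aicc")
            prof = estimate_sd_profile(pts, model)
            out = detect_outliers(pts, model, prof)
            if out.size == 0:
                break
            pts = np.delete(pts, out, axis=0)
        # converged: re-running detection on the cleaned set flags nothing
        assert detect_outliers(pts, model, prof).size == 0

    def test_small_stratum_refused(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 18, 25)
        with pytest.raises(SampleSizeError):
            fit_reference(_records(x, x + 50.0), "bizygomatic_width", "M", self.CFG)


class TestRequiredSampleSize:
    @staticmethod
    def _power_iteration_oracle(effect_sd, alpha, power, sided, fallout):
        """Increment n until normal-approximation power reaches the target."""
        z_alpha = stats.norm.ppf(1 - alpha / (1 if sided == "one" else 2))
        n = 1
        while True:
            achieved = stats.norm.cdf(effect_sd * np.sqrt(n) - z_alpha)
            if achieved >= power:
                break
            n += 1
        return int(np.ceil(n / (1 - fallout)))

    def test_default_band_size_is_thirty(self):
        assert required_sample_size() == 30

    @pytest.mark.parametrize("sided,fallout", [("one", 0.15), ("two", 0.15), ("one", 0.0),
                                               ("two", 0.0), ("one", 0.30)])
    def test_matches_power_iteration_oracle(self, sided, fallout):
        got = required_sample_size(sided=sided, fallout=fallout)
        assert got == self._power_iteration_oracle(0.5, 0.05, 0.80, sided, fallout)

    def test_two_sided_is_thirty_eight(self):
        assert required_sample_size(sided="two") == 38

    def test_no_fallout_is_twenty_five(self):
        assert required_sample_size(fallout=0.0) == 25

    def test_invalid_fallout(self):
        with pytest.raises(ValueError):
            required_sample_size(fallout=1.0)
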