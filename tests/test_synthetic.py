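"""Cohort generator: preset calibration, determinism, landmark realisation."""

import io

import numpy as np
import pytest

from facenorms.anthropometry import DEFAULT_REGISTRY, measure_subject, qc_landmarks
from facenorms.errors import ConfigurationError
from facenorms.synthetic import (
    DEFAULT_ANCESTRY_CENSUS,
    ancestry_census_summary,
    cohort_landmark_sets,
    make_cohort_spec,
    records_from_frame,
    simulate_cohort,
    simulate_landmarks,
)


class TestPresets:
    def test_chinese_bizygomatic_sex_gap_anchors(self):
        spec = make_cohort_spec("chinese")
        gap = lambda age: float(spec.mean("bizygomatic_width", "M", age)
                                - spec.mean("bizygomatic_width", "F", age))
        assert gap(5) == pytest.approx(3.5, abs=1e-9)
        assert gap(10) == pytest.approx(5.2, abs=1e-9)
        assert gap(15) == pytest.approx(7.2, abs=1e-9)

    def test_chinese_bizygomatic_sd_anchors(self):
        spec = make_cohort_spec("chinese")
        for age, sd_f, sd_m in [(5, 6.8, 7.4), (10, 6.6, 7.2), (15, 6.7, 7.6)]:
            assert float(spec.sd("bizygomatic_width", "F", age)) == pytest.approx(sd_f)
            assert float(spec.sd("bizygomatic_width", "M", age)) == pytest.approx(sd_m)

    def test_pfl_sex_gap_is_one_mm_at_all_ages(self):
        spec = make_cohort_spec("chinese")
        ages = np.linspace(0, 55, 56)
        gap = spec.mean("palpebral_fissure_length", "M", ages) \
            - spec.mean("palpebral_fissure_length", "F", ages)
        assert gap == pytest.approx(np.full_like(gap, 1.0), abs=1e-9)

    def test_cross_preset_directions(self):
        cn, eu = make_cohort_spec("chinese"), make_cohort_spec("european")
        for age in (5.0, 10.0, 15.0, 20.0):
            assert cn.mean("bizygomatic_width", "M", age) > eu.mean("bizygomatic_width", "M", age)
            assert cn.mean("palpebral_fissure_length", "F", age) \
                < eu.mean("palpebral_fissure_length", "F", age)
            assert cn.mean("facial_height", "M", age) == pytest.approx(
                eu.mean("facial_height", "M", age))

    def test_philtral_growth_rate_differs_but_endpoints_match(self):
        cn, eu = make_cohort_spec("chinese"), make_cohort_spec("european")
        c, e = cn.curves[("philtral_length", "M")], eu.curves[("philtral_length", "M")]
        assert e.rate > c.rate
        assert c.asymptote == e.asymptote and c.drop == e.drop

    def test_overrides_and_unknown_preset(self):
        spec = make_cohort_spec("chinese", n=50)
        assert spec.n == 50
        assert spec.ancestry == "chinese"
        with pytest.raises(ConfigurationError):
            make_cohort_spec("martian")
        with pytest.raises(ConfigurationError):
            make_cohort_spec("chinese", not_a_field=1)


class TestSimulateCohort:
    def test_zero_noise_lands_exactly_on_curves(self):
        spec = make_cohort_spec("chinese", n=50, seed=1, noise_scale=0.0)
        frame = simulate_cohort(spec)
        # ages are written to 3 decimals; curve slopes are < 10 mm/yr so the
        # re-evaluation at the rounded age can move by at most ~5e-3 mm
        for row in frame.itertuples(index=False):
            truth = float(spec.mean(row.measurement, row.sex, row.age_years))
            assert row.value == pytest.approx(truth, abs=5e-3)

    def test_empirical_sex_gap_at_age_ten(self):
        frame = simulate_cohort(make_cohort_spec("chinese", n=10000, seed=1))
        bz = frame[(frame.measurement == "bizygomatic_width")
                   & frame.age_years.between(9.5, 10.5)]
        gap = bz[bz.sex == "M"].value.mean() - bz[bz.sex == "F"].value.mean()
        assert gap == pytest.approx(5.2, abs=0.5)

    def test_empirical_sd_within_five_percent(self):
        spec = make_cohort_spec("chinese", n=10000, seed=2)
        frame = simulate_cohort(spec)
        bz = frame[(frame.measurement == "bizygomatic_width")
                   & frame.age_years.between(9.5, 10.5) & (frame.sex == "F")]
        resid = bz.value - spec.mean("bizygomatic_width", "F", bz.age_years.to_numpy())
        assert resid.std() == pytest.approx(6.6, rel=0.05)

    def test_fallout_rate_realised(self):
        frame = simulate_cohort(make_cohort_spec("chinese", n=10000, seed=3,
                                                 landmark_fallout=0.15))
        assert 0.84 <= frame.usable.mean() <= 0.86

    def test_outlier_injection_inflates_tails(self):
        base = simulate_cohort(make_cohort_spec("chinese", n=4000, seed=4))
        spiked = simulate_cohort(make_cohort_spec("chinese", n=4000, seed=4,
                                                  outlier_rate=0.05, outlier_magnitude=8.0))
        spec = make_cohort_spec("chinese")

        def gross_fraction(frame):
            bz = frame[frame.measurement == "bizygomatic_width"]
            mean = np.where(bz.sex == "M",
                            spec.mean("bizygomatic_width", "M", bz.age_years.to_numpy()),
                            spec.mean("bizygomatic_width", "F", bz.age_years.to_numpy()))
            sd = np.where(bz.sex == "M",
                          spec.sd("bizygomatic_width", "M", bz.age_years.to_numpy()),
                          spec.sd("bizygomatic_width", "F", bz.age_years.to_numpy()))
            return np.mean(np.abs(bz.value - mean) > 4.0 * sd)

        assert gross_fraction(base) < 0.001
        assert gross_fraction(spiked) > 0.03

    def test_seed_determinism_byte_identical(self, tmp_path):
        from facenorms.io import write_measurements

        outs = []
        for _ in range(2):
            frame = simulate_cohort(make_cohort_spec("chinese", n=100, seed=42))
            path = tmp_path / f"t{len(outs)}.tsv"
            write_measurements(frame, path)
            outs.append(path.read_bytes())
        assert outs[0] == outs[1]

    def test_pediatric_weighting(self):
        frame = simulate_cohort(make_cohort_spec("chinese", n=5000, seed=6))
        ages = frame.drop_duplicates("subject_id").age_years
        child_frac = (ages < 18).mean()
        assert child_frac == pytest.approx(0.86, abs=0.02)


class TestSimulateLandmarks:
    def test_roundtrip_through_measurement_within_tenth_mm(self, chinese_spec):
        for age, sex in [(2.0, "F"), (10.0, "M"), (30.0, "F")]:
            values = {d.name: float(chinese_spec.mean(d.name, sex, age))
                      for d in DEFAULT_REGISTRY}
            face = simulate_landmarks(values)
            measured = {r.measurement: r.value for r in measure_subject(face)}
            for name, target in values.items():
                assert measured[name] == pytest.approx(target, abs=0.1)

    def test_symmetric_template_zero_asymmetry(self, symmetric_face):
        from facenorms.anthropometry import MeasurementDefinition, compute_measurement

        face, _ = symmetric_face
        for code in ("zy", "en", "ch", "ex"):
            defn = MeasurementDefinition(f"asym_{code}", "asymmetry", ((code, "B"),))
            value, usable = compute_measurement(face, defn)
            assert usable and abs(value) < 1e-9

    def test_six_mm_placement_noise_fails_qc(self, symmetric_face):
        truth, _ = symmetric_face
        noisy = simulate_landmarks(
            {r.measurement: r.value for r in measure_subject(truth)}, subject_id="demo")
        noisy.points[("prn", None)] = noisy.points[("prn", None)] + np.array([0, 0, 6.0])
        assert not qc_landmarks(noisy, truth).passed

    def test_infeasible_targets_rejected(self):
        values = {d.name: 10.0 for d in DEFAULT_REGISTRY}
        values["facial_height"] = -1.0
        with pytest.raises(ConfigurationError):
            simulate_landmarks(values)

    def test_cohort_landmark_sets_respect_fallout(self):
        frame = simulate_cohort(make_cohort_spec("chinese", n=20, seed=13,
                                                 landmark_fallout=0.3))
        sets, failures = cohort_landmark_sets(frame)
        assert not failures
        for ls in sets:
            unusable = set(frame[(frame.subject_id == ls.subject_id)
                                 & (frame.usable == 0)].measurement)
            measured = {r.measurement: r for r in measure_subject(ls)}
            for name in unusable:
                assert not measured[name].usable


class TestCensus:
    def test_recruitment_census_totals(self):
        summary = ancestry_census_summary()
        assert summary["total"] == 1218
        assert summary["largest_group"] == "Chinese"
        assert summary["largest_share_pct"] == pytest.approx(72.2)

    def test_custom_census(self):
        summary = ancestry_census_summary({"a": 3, "b": 1})
        assert summary["total"] == 4 and summary["largest_share_pct"] == 75.0


class TestRecordsRoundtrip:
    def test_frame_records_frame(self, small_cohort):
        from facenorms.synthetic import frame_from_records

        recs = records_from_frame(small_cohort)
        back = frame_from_records(recs)
        assert len(back) == len(small_cohort)
        assert np.allclose(back.value.to_numpy(), small_cohort.value.to_numpy())
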