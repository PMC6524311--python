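"""Monte Carlo DVH estimation: sphere sampling, per-point doses,
D_V / V_D queries, per-patient curves, and consistency with the
closed-form coverage."""

import numpy as np
import pytest

from iplboost import (
    ConfigurationError,
    DataError,
    DVHCurve,
    SphereGeometry,
    compute_dvh,
    coverage_ipl,
    dvh_frame,
    dvh_per_patient,
    dvh_query_D,
    dvh_query_V,
    geometry_grid,
    sample_sphere,
)

from conftest import constant_displacement_set, make_trajectory_set


class TestSampleSphere:
    def test_all_points_inside_sphere(self):
        ps = sample_sphere(4.0, 5000, seed=1)
        assert np.all(np.linalg.norm(ps.points, axis=1) <= 4.0 + 1e-12)

    def test_same_seed_identical_points(self):
        a = sample_sphere(3.0, 1000, seed=5)
        b = sample_sphere(3.0, 1000, seed=5)
        assert np.array_equal(a.points, b.points)

    def test_uniformity_radius_volume_ratio(self):
        """Fraction of points within r/2 estimates the volume ratio
        (1/2)³ = 1/8, within 3 binomial standard errors."""
        n = 100_000
        ps = sample_sphere(2.0, n, seed=11)
        frac = np.mean(np.linalg.norm(ps.points, axis=1) <= 1.0)
        se = np.sqrt(0.125 * 0.875 / n)
        assert abs(frac - 0.125) < 3 * se

    def test_coordinate_means_near_zero(self):
        ps = sample_sphere(5.0, 100_000, seed=2)
        assert np.all(np.abs(ps.points.mean(axis=0)) < 0.05)

    @pytest.mark.parametrize("kwargs", [dict(r=0.0, n=10), dict(r=3.0, n=0)])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ConfigurationError):
            sample_sphere(**kwargs)


class TestComputeDvh:
    def test_zero_motion_step_curve(self):
        ts = make_trajectory_set(np.zeros((6, 3)))
        geom = SphereGeometry(5.0, 2.0)
        curve = compute_dvh(sample_sphere(5.0, 500, seed=3), ts, geom)
        assert np.all(curve.point_doses == 1.0)
        assert curve.volume_at(1.0) == 1.0
        assert curve.dose_at(0.8) == 1.0

    def test_out_of_range_motion_gives_zero_dose(self):
        geom = SphereGeometry(3.0, 2.0)
        ts = constant_displacement_set([9.0, 10.0, 12.0])  # all d ≥ 2r+m
        curve = compute_dvh(sample_sphere(3.0, 500, seed=4), ts, geom)
        assert np.all(curve.point_doses == 0.0)

    def test_half_half_mixture_gives_flat_half_dose(self):
        """Half the samples at the origin, half far out of range: every
        point is covered exactly half the time."""
        geom = SphereGeometry(5.0, 0.0)
        ts = constant_displacement_set([0.0, 0.0, 20.0, 20.0])
        curve = compute_dvh(sample_sphere(5.0, 800, seed=5), ts, geom)
        assert np.all(curve.point_doses == 0.5)
        assert curve.dose_at(1.0) == 0.5
        assert curve.volume_at(0.5) == 1.0
        assert curve.volume_at(0.6) == 0.0

    def test_radius_mismatch_rejected(self):
        ts = constant_displacement_set([0.0])
        with pytest.raises(ConfigurationError):
            compute_dvh(sample_sphere(3.0, 10, seed=0), ts, SphereGeometry(5.0, 0.0))

    def test_curve_monotone_with_unit_endpoint(self, small_cohort):
        geom = SphereGeometry(5.0, 2.0)
        curve = compute_dvh(sample_sphere(5.0, 2000, seed=8), small_cohort, geom)
        frame = dvh_frame(curve)
        assert frame["volume_percent"].iloc[0] == 100.0
        assert np.all(np.diff(frame["volume_percent"]) <= 1e-12)

    def test_margin_monotonicity(self, small_cohort):
        """At every dose level the curve for a larger margin dominates."""
        pts = sample_sphere(5.0, 2000, seed=9)
        doses = np.linspace(0, 1, 51)
        prev = None
        for m in (0.0, 2.0, 5.0):
            curve = compute_dvh(pts, small_cohort, SphereGeometry(5.0, m))
            vols = np.array([curve.volume_at(d) for d in doses])
            if prev is not None:
                assert np.all(vols >= prev - 1e-12)
            prev = vols

    def test_mean_dose_matches_mean_coverage(self, small_cohort):
        """The mean per-point dose and the trajectory-mean of the
        closed-form lesion coverage estimate the same volume integral."""
        geom = SphereGeometry(5.0, 0.0)
        curve = compute_dvh(sample_sphere(5.0, 5000, seed=10), small_cohort, geom)
        expected = coverage_ipl(geom, small_cohort.radial()).mean()
        se = curve.point_doses.std(ddof=1) / np.sqrt(curve.n_points)
        assert abs(curve.mean_dose() - expected) < 4 * se + 1e-6


class TestQueries:
    def _curve(self, doses):
        return DVHCurve(SphereGeometry(5.0, 0.0), np.asarray(doses, float), n_motion_samples=10)

    def test_dose_query_lower_order_statistic(self):
        curve = self._curve(np.arange(1, 11) / 10.0)
        assert dvh_query_D(curve, 0.5) == pytest.approx(0.6)
        assert dvh_query_D(curve, 1.0) == pytest.approx(0.1)
        assert dvh_query_D(curve, 0.05) == pytest.approx(1.0)

    def test_volume_query(self):
        curve = self._curve(np.arange(1, 11) / 10.0)
        assert dvh_query_V(curve, 0.0) == 1.0
        assert dvh_query_V(curve, 0.65) == pytest.approx(0.4)

    @pytest.mark.parametrize("v", [0.0, -0.1, 1.5])
    def test_dose_query_range_errors(self, v):
        with pytest.raises(DataError):
            dvh_query_D(self._curve([0.5]), v)

    @pytest.mark.parametrize("d", [-0.1, 1.01])
    def test_volume_query_range_errors(self, d):
        with pytest.raises(DataError):
            dvh_query_V(self._curve([0.5]), d)

    def test_out_of_range_doses_rejected(self):
        with pytest.raises(DataError):
            self._curve([0.2, 1.3])


class TestPerPatient:
    def test_single_patient_matches_pooled(self, small_cohort):
        sub = small_cohort.for_patient("P01")
        geoms = [SphereGeometry(5.0, 2.0)]
        per = dvh_per_patient(sub, geoms, n=1000, seed=21)
        pooled = dvh_per_patient(small_cohort, geoms, n=1000, seed=21)["P01"]
        assert np.array_equal(per["P01"][0].point_doses, pooled[0].point_doses)

    def test_low_motility_curve_dominates_high(self):
        """A nearly still patient's DVH lies above a highly mobile
        patient's at every dose level (same geometry, same points)."""
        rng = np.random.default_rng(3)
        low = np.vstack([np.zeros((1, 3)), rng.normal(0, 0.2, (40, 3))])
        high = np.vstack([np.zeros((1, 3)), rng.normal(0, 4.0, (40, 3))])
        ts = make_trajectory_set(low, patient_id="LOW")
        ts2 = make_trajectory_set(high, patient_id="HIGH")
        import pandas as pd

        from iplboost import TrajectorySet

        both = TrajectorySet(pd.concat([ts.data, ts2.data], ignore_index=True))
        curves = dvh_per_patient(both, [SphereGeometry(5.0, 2.0)], n=2000, seed=6)
        doses = np.linspace(0, 1, 41)
        v_low = np.array([curves["LOW"][0].volume_at(d) for d in doses])
        v_high = np.array([curves["HIGH"][0].volume_at(d) for d in doses])
        assert np.all(v_low >= v_high - 1e-12)

    def test_geometry_grid_cardinality(self, small_cohort):
        geoms = geometry_grid([3, 5, 7], [0, 2, 5])
        per = dvh_per_patient(small_cohort, geoms, n=200, seed=1)
        assert all(len(curves) == 9 for curves in per.values())
        assert set(per) == set(small_cohort.patients)
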