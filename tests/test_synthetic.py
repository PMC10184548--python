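"""Synthetic mesh and cohort generators against their analytic ground truth."""

import math

import numpy as np
import pytest

from paleoneuro import (
    Polyline,
    encephalization,
    hearing_estimate,
    make_ellipsoid_mesh,
    make_specimen_cohort,
    make_tube_mesh,
    mesh_volume,
    midbrain_medulla_ratio,
    olfactory_ratio,
    body_mass_bipedal,
)


class TestEllipsoidMesh:
    def test_sphere_volume_within_half_percent(self):
        result = make_ellipsoid_mesh(10.0, 10.0, 10.0, subdivisions=4)
        vol_cm3 = mesh_volume(result.mesh)
        true_cm3 = result.true_volume_mm3 / 1000.0
        assert abs(vol_cm3 - true_cm3) / true_cm3 < 0.005

    def test_true_volume_formula(self):
        result = make_ellipsoid_mesh(10.0, 5.0, 2.0)
        assert result.true_volume_mm3 == pytest.approx(
            4.0 / 3.0 * math.pi * 100.0
        )

    def test_inscribed_polyhedron_underestimates(self):
        for level in (0, 1, 2, 3):
            result = make_ellipsoid_mesh(10.0, 10.0, 10.0, subdivisions=level)
            assert mesh_volume(result.mesh) * 1000.0 < result.true_volume_mm3

    def test_volume_converges_with_subdivision(self):
        errors = []
        for level in (1, 2, 3):
            res = make_ellipsoid_mesh(8.0, 6.0, 4.0, subdivisions=level)
            vol = mesh_volume(res.mesh) * 1000.0
            errors.append(abs(vol - res.true_volume_mm3))
        assert errors[0] > errors[1] > errors[2]

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            make_ellipsoid_mesh(-1.0, 5.0, 2.0)
        with pytest.raises(ValueError):
            make_ellipsoid_mesh(1.0, 5.0, 2.0, subdivisions=-1)


class TestTubeMesh:
    def test_straight_tube_volume_near_cylinder(self):
        path = np.array([[0.0, 0.0, 0.0], [20.0, 0.0, 0.0]])
        result = make_tube_mesh(path, radius=1.0)
        vol_mm3 = mesh_volume(result.mesh) * 1000.0
        assert abs(vol_mm3 - math.pi * 20.0) / (math.pi * 20.0) < 0.01

    def test_straight_tube_matches_prism_closed_form(self):
        # flat caps make the tube an exact n-gonal prism
        n = 32
        path = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 17.0]])
        result = make_tube_mesh(path, radius=2.0, segments=n)
        exact = 0.5 * n * 4.0 * math.sin(2.0 * math.pi / n) * 17.0
        assert mesh_volume(result.mesh) * 1000.0 == pytest.approx(exact, rel=1e-9)

    def test_degenerate_path_rejected(self):
        with pytest.raises(ValueError, match="repeated|zero-length"):
            make_tube_mesh(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]), 0.5)

    def test_quarter_circle_centreline_length(self):
        theta = np.linspace(0.0, math.pi / 2.0, 16)
        path = np.column_stack(
            [10.0 * np.cos(theta), 10.0 * np.sin(theta), np.zeros_like(theta)]
        )
        result = make_tube_mesh(Polyline(path), radius=0.5)
        assert abs(result.true_centreline_mm - 5.0 * math.pi) / (
            5.0 * math.pi
        ) < 1e-3

    def test_oversized_radius_warns(self):
        path = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
        with pytest.warns(UserWarning, match="self-intersect"):
            make_tube_mesh(path, radius=0.9)


class TestCohort:
    def test_fixed_seed_reproduces_cohort(self):
        a = make_specimen_cohort(50, seed=1)
        b = make_specimen_cohort(50, seed=1)
        for sa, sb in zip(a, b):
            assert sa.measurements == sb.measurements
            assert sa.truth == sb.truth

    def test_different_seeds_differ(self):
        a = make_specimen_cohort(5, seed=1)
        b = make_specimen_cohort(5, seed=2)
        assert a[0].measurements.ecd_mm != b[0].measurements.ecd_mm

    def test_pipeline_agrees_with_independent_oracle(self):
        """Generator ground truths (straight-line formulas) match the
        pipeline to 1e-9 relative on a 120-specimen cohort."""
        for s in make_specimen_cohort(120, seed=7):
            m = s.measurements
            mass = body_mass_bipedal(m.femoral_circumference_mm).mass_g
            assert mass == pytest.approx(s.truth["mass_g"], rel=1e-9)
            for fill_key, fill in (("0.37", 0.37), ("0.5", 0.50)):
                res = encephalization(m.endocast_volume_cm3, mass, fill)
                assert res.REQ == pytest.approx(
                    s.truth["req"][fill_key], rel=1e-9
                )
            est = hearing_estimate(m.ecd_mm, m.bcl_mm)
            assert est.best_range_hz == pytest.approx(
                s.truth["best_range_hz"], rel=1e-9
            )
            assert est.mean_freq_hz == pytest.approx(
                s.truth["mean_freq_hz"], rel=1e-9
            )
            assert olfactory_ratio(
                m.bulb_length_mm, m.cerebrum_diameter_mm
            ) == pytest.approx(s.truth["olfactory_pct"], rel=1e-9)
            assert midbrain_medulla_ratio(
                m.midbrain_length_mm, m.medulla_length_mm
            ) == pytest.approx(s.truth["midbrain_ratio"], rel=1e-9)

    def test_best_frequencies_within_saurischian_band(self):
        """With duct/basicranium quotients spanning the comparative table,
        best hearing frequencies stay within [2000, 4800] Hz."""
        for s in make_specimen_cohort(200, seed=3):
            assert 2000.0 <= s.truth["best_range_hz"] <= 4800.0

    def test_measurements_respect_ranges(self):
        from paleoneuro.synthetic import DEFAULT_RANGES

        for s in make_specimen_cohort(100, seed=11):
            m = s.measurements
            lo, hi = DEFAULT_RANGES["bcl_mm"]
            assert lo <= m.bcl_mm <= hi
            lo, hi = DEFAULT_RANGES["ecd_mm"]
            assert lo <= m.ecd_mm <= hi
            r_lo, r_hi = DEFAULT_RANGES["ecd_bcl_ratio"]
            assert r_lo <= m.ecd_mm / m.bcl_mm <= r_hi

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            make_specimen_cohort(0, seed=1)
        with pytest.raises(ValueError, match="invalid range"):
            make_specimen_cohort(5, seed=1, ranges={"bcl_mm": (10.0, 5.0)})
        with pytest.raises(ValueError, match="unknown range"):
            make_specimen_cohort(5, seed=1, ranges={"femur": (1.0, 2.0)})


class TestMeshPipelineRecovery:
    def test_req_from_mesh_volume_close_to_truth(self):
        """REQ computed from a discretised ellipsoid endocast agrees with
        REQ from the analytic volume within the mesh discretisation error."""
        result = make_ellipsoid_mesh(70.0, 35.0, 30.0, subdivisions=4)
        vol_cm3 = mesh_volume(result.mesh)
        true_cm3 = result.true_volume_mm3 / 1000.0
        mass = 2_011_000.0
        req_mesh = encephalization(vol_cm3, mass, 0.5).REQ
        req_true = encephalization(true_cm3, mass, 0.5).REQ
        assert abs(req_mesh - req_true) / req_true < 0.005
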