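from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aneuscale.errors import FeasibilityError, GeometryError
from aneuscale.mesh_core import LABEL_SAC, check_validity
from aneuscale.morphometry import measure
from aneuscale.neck_geometry import extract_neck_curve
from aneuscale.scaling import (
    DEFAULT_SCHEDULE,
    ScalingParams,
    generate_series,
    scale_point,
    scale_points,
    scale_sac,
    solve_k,
    validate_params,
)


def brute_force_map(point, params):
    """Independent scalar implementation of the height-graded transform."""
    x, y, z = float(point[0]), float(point[1]), float(point[2])
    if z <= params.z_m:
        return np.array([x, y, z])
    g = (z - params.z_m) * (params.k - 1.0) / params.h
    return np.array(
        [
            params.x_m + (1.0 + params.a * g) * (x - params.x_m),
            params.y_m + (1.0 + params.b * g) * (y - params.y_m),
            params.z_m + (1.0 + params.c * g) * (z - params.z_m),
        ]
    )


def make_params(**kw):
    defaults = dict(a=2.0, b=2.0, c=1.0, k=1.5, x_m=0.0, y_m=0.0, z_m=0.0, h=1.0)
    defaults.update(kw)
    return ScalingParams(**defaults)


def remeasure(model):
    """Fresh neck-curve extraction + morphometry on a (scaled) model."""
    return measure(extract_neck_curve(replace(model, neck_curve=None)))


class TestScalePoint:
    def test_k1_identity(self):
        params = make_params(k=1.0)
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(100, 3))
        np.testing.assert_array_equal(scale_points(pts, params), pts)

    def test_apex_maps_to_kh(self):
        params = make_params(k=1.7, c=1.0, h=2.5)
        out = scale_point([0.0, 0.0, 2.5], params)
        np.testing.assert_allclose(out, [0.0, 0.0, 1.7 * 2.5], rtol=1e-14)

    def test_mid_height_example(self):
        # frozen by direct evaluation: z - z_m = h/2, a=2, k=1.5 gives
        # lateral factor 1 + 2*(1/2)*(0.5) = 1.5 and z factor 1.25
        params = make_params(a=2.0, b=2.0, c=1.0, k=1.5, h=1.0)
        out = scale_point([1.0, 0.0, 0.5], params)
        np.testing.assert_allclose(out, [1.5, 0.0, 0.625], rtol=1e-14)

    def test_below_plane_untouched(self):
        params = make_params(k=3.0)
        pts = np.array([[1.0, 2.0, -0.5], [3.0, -1.0, 0.0]])
        np.testing.assert_array_equal(scale_points(pts, params), pts)

    def test_oracle_agreement_random_points(self):
        rng = np.random.default_rng(42)
        params = make_params(
            a=2.0, b=2.0, c=1.0, k=1.3, x_m=0.7, y_m=-0.2, z_m=1.5, h=2.0
        )
        pts = rng.uniform(-3, 5, size=(10_000, 3))
        got = scale_points(pts, params)
        expected = np.array([brute_force_map(p, params) for p in pts])
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    @given(
        k=st.floats(0.55, 4.0),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=20, deadline=None)
    def test_oracle_agreement_property(self, k, seed):
        rng = np.random.default_rng(seed)
        params = make_params(k=k)
        pts = rng.uniform(-2, 2, size=(50, 3))
        got = scale_points(pts, params)
        expected = np.array([brute_force_map(p, params) for p in pts])
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_invalid_h(self):
        with pytest.raises(GeometryError):
            make_params(h=0.0)


class TestValidateParams:
    def test_k_half_infeasible(self):
        report = validate_params(make_params(k=0.5))
        assert report.lateral_x == pytest.approx(0.0, abs=1e-15)
        assert not report.feasible

    def test_k_06_feasible(self):
        report = validate_params(make_params(k=0.6))
        assert report.lateral_x == pytest.approx(0.2)
        assert report.min_z_derivative == pytest.approx(0.2)
        assert report.feasible

    def test_k1_all_ones(self):
        report = validate_params(make_params(k=1.0))
        assert report.lateral_x == 1.0
        assert report.lateral_y == 1.0
        assert report.min_z_derivative == 1.0
        assert report.feasible

    def test_growth_always_feasible(self):
        assert validate_params(make_params(k=10.0)).feasible


class TestSolveK:
    def test_quadruple(self):
        assert solve_k(0.5, 2.0) == 4.0

    def test_identity(self):
        assert solve_k(0.8, 0.8) == 1.0

    def test_shrink_feasible(self):
        k = solve_k(0.5, 0.3)
        assert k == pytest.approx(0.6)
        assert validate_params(make_params(k=k)).feasible

    def test_nonpositive_errors(self):
        with pytest.raises(GeometryError):
            solve_k(0.0, 1.0)
        with pytest.raises(GeometryError):
            solve_k(1.0, -0.5)


class TestScaleSac:
    def test_k1_identity(self, hemi_model):
        params = ScalingParams.from_model(hemi_model, k=1.0)
        out = scale_sac(hemi_model, params).model
        np.testing.assert_allclose(
            out.mesh.vertices, hemi_model.mesh.vertices, atol=1e-12
        )

    def test_height_exactness(self, hemi_model):
        m0 = measure(hemi_model)
        for k in (0.7, 1.0, 1.5, 2.0, 3.0):
            params = ScalingParams.from_model(hemi_model, k=k)
            out = scale_sac(hemi_model, params).model
            m1 = remeasure(out)
            assert m1.h == pytest.approx(k * m0.h, rel=1e-12)

    def test_neck_and_vessel_invariant(self, hemi_model):
        params = ScalingParams.from_model(hemi_model, k=2.0)
        out = scale_sac(hemi_model, params).model
        unmoved = hemi_model.mesh.labels != LABEL_SAC
        np.testing.assert_array_equal(
            out.mesh.vertices[unmoved], hemi_model.mesh.vertices[unmoved]
        )
        m1 = remeasure(out)
        m0 = measure(hemi_model)
        assert m1.neck_perimeter == pytest.approx(m0.neck_perimeter, rel=1e-12)

    def test_asr_multiplicativity(self, hemi_model):
        m0 = measure(hemi_model)
        for k in (0.8, 1.3, 2.5):
            params = ScalingParams.from_model(hemi_model, k=k)
            m1 = remeasure(scale_sac(hemi_model, params).model)
            assert m1.asr == pytest.approx(k * m0.asr, rel=1e-12)

    def test_continuity_at_neck(self, hemi_model):
        # displacement of vertices within eps of the plane is O(eps)
        params = ScalingParams.from_model(hemi_model, k=2.0)
        out = scale_sac(hemi_model, params).model
        disp = np.linalg.norm(out.mesh.vertices - hemi_model.mesh.vertices, axis=1)
        height = hemi_model.mesh.vertices[:, 2] - hemi_model.d
        for eps in (0.3, 0.15, 0.05):
            near = (height > 0) & (height < eps)
            if near.any():
                # factor deviation is (a * height / h) * |k-1|-ish; bound
                # displacement by C * eps with a generous constant
                assert disp[near].max() < 10.0 * eps

    def test_z_map_monotone_under_feasibility(self):
        params = make_params(k=0.6)
        z = np.linspace(1e-6, 1.0, 1000)
        pts = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        out = scale_points(pts, params)[:, 2]
        assert (np.diff(out) > 0).all()

    def test_composition_in_z(self, hemi_model):
        m0 = measure(hemi_model)
        k1, k2 = 1.4, 0.9
        p1 = ScalingParams.from_model(hemi_model, k=k1)
        step1 = scale_sac(hemi_model, p1).model
        step1 = extract_neck_curve(replace(step1, neck_curve=None))
        p2 = ScalingParams.from_model(step1, k=k2)
        step2 = scale_sac(step1, p2).model
        m2 = remeasure(step2)
        assert m2.h == pytest.approx(k1 * k2 * m0.h, rel=1e-12)

    def test_lateral_bulge_bound(self, hemi_model):
        # with a=b=2, k=1.5 the lateral factor lies in (1, 2) over the sac
        params = ScalingParams.from_model(hemi_model, k=1.5)
        out = scale_sac(hemi_model, params).model
        sac = hemi_model.mesh.labels == LABEL_SAC
        r0 = np.linalg.norm(hemi_model.mesh.vertices[sac, :2], axis=1)
        r1 = np.linalg.norm(out.mesh.vertices[sac, :2], axis=1)
        ok = r0 > 1e-9
        ratio = r1[ok] / r0[ok]
        assert ratio.max() < 2.0 + 1e-9
        assert ratio.min() > 1.0 - 1e-9
        assert ratio.max() > 1.0 + 1e-6  # it does bulge

    def test_strict_infeasible_raises(self, hemi_model):
        params = ScalingParams.from_model(hemi_model, k=0.4)
        with pytest.raises(FeasibilityError, match="lateral|factor"):
            scale_sac(hemi_model, params, mode="strict")

    def test_stepwise_reaches_deep_shrink(self, hemi_model):
        m0 = measure(hemi_model)
        params = ScalingParams.from_model(hemi_model, k=0.3)
        result = scale_sac(hemi_model, params, mode="stepwise")
        assert result.n_steps > 1
        k_step = 0.3 ** (1.0 / result.n_steps)
        assert 1.0 + 2.0 * (k_step - 1.0) > 0.05  # per-step factors positive
        m1 = remeasure(result.model)
        assert m1.h == pytest.approx(0.3 * m0.h, rel=1e-9)

    def test_watertight_preserved(self, hemi_model):
        params = ScalingParams.from_model(hemi_model, k=2.0)
        out = scale_sac(hemi_model, params).model
        assert check_validity(out.mesh).watertight

    def test_unlabeled_model_rejected(self, hemi_phantom):
        from aneuscale.neck_geometry import build_neck_frame

        frame = extract_neck_curve(
            build_neck_frame(hemi_phantom.mesh, hemi_phantom.plane)
        )
        with pytest.raises(GeometryError):
            scale_sac(frame, make_params())


class TestGenerateSeries:
    def test_identity_entry(self, hemi_model):
        m0 = measure(hemi_model)
        series = generate_series(hemi_model, [m0.asr])
        entry = series.entries[0]
        assert entry.k == pytest.approx(1.0, rel=1e-12)
        np.testing.assert_allclose(
            entry.model.mesh.vertices, hemi_model.mesh.vertices, atol=1e-12
        )

    def test_default_schedule(self, hemi_model):
        series = generate_series(hemi_model, DEFAULT_SCHEDULE)
        assert len(series.entries) == 8
        for entry in series.entries:
            assert entry.measured_asr == pytest.approx(
                entry.target_asr, rel=1e-6
            )
            assert entry.watertight
        manifest = series.manifest()
        assert list(manifest["target_asr"]) == list(DEFAULT_SCHEDULE)
        assert set(manifest.columns) >= {
            "target_asr", "k", "steps", "measured_asr", "watertight",
        }

    def test_entries_independent_of_order(self, hemi_model):
        fwd = generate_series(hemi_model, [0.5, 2.0])
        rev = generate_series(hemi_model, [2.0, 0.5])
        np.testing.assert_allclose(
            fwd.entries[1].model.mesh.vertices,
            rev.entries[0].model.mesh.vertices,
            atol=0,
        )

    def test_zero_entry_rejected(self, hemi_model):
        with pytest.raises(GeometryError):
            generate_series(hemi_model, [0.5, 0.0])
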