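"""Coil field basis, superposition, gradient tensors, actuation matrix,
current allocation and the command mapping."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capsnav import (CoilSpec, DesiredWrench, allocate_currents,
                     build_actuation_matrix, coil_basis, command_to_desired,
                     default_ema_config, ema_field, field_gradient_tensor)
from capsnav.coils import (FilamentProximityError, coil_gradient_tensor,
                           coil_unit_field, loop_field_circular,
                           loop_field_rectangular)
from capsnav.magnetics import MU0, heading_from_angles


def biot_savart_quadrature(coil: CoilSpec, point, n_seg=10_000):
    """Oracle: brute-force Biot–Savart quadrature of the loop filament."""
    point = np.asarray(point, float)
    u, v, w = coil.frame()
    if coil.shape == "circular":
        theta = np.linspace(0, 2 * np.pi, n_seg + 1)
        pts = (coil.center[None, :]
               + coil.radius * (np.cos(theta)[:, None] * u[None, :]
                                + np.sin(theta)[:, None] * v[None, :]))
    else:
        a, b = coil.half_width, coil.half_height
        corners = np.array([coil.center + sx * a * u + sy * b * v
                            for sx, sy in ((1, 1), (-1, 1), (-1, -1),
                                           (1, -1), (1, 1))])
        per_side = n_seg // 4
        pts = np.vstack([np.linspace(corners[i], corners[i + 1],
                                     per_side + 1)[:-1] for i in range(4)])
        pts = np.vstack([pts, pts[:1]])
    dl = np.diff(pts, axis=0)
    mid = 0.5 * (pts[:-1] + pts[1:])
    r = point[None, :] - mid
    rn = np.linalg.norm(r, axis=1)
    dB = np.cross(dl, r) / rn[:, None] ** 3
    return coil.turns * MU0 / (4 * np.pi) * dB.sum(axis=0)


@pytest.fixture
def circ():
    return CoilSpec("circular", center=[0, 0, 0], axis=[0, 0, 1], turns=1,
                    radius=0.1, label="test")


@pytest.fixture
def rect():
    return CoilSpec("rectangular", center=[0, 0, 0], axis=[0, 0, 1], turns=1,
                    half_width=0.08, half_height=0.05, label="rtest")


class TestCircularLoop:
    def test_center_field(self, circ):
        B = loop_field_circular(circ, [0, 0, 0])
        np.testing.assert_allclose(B, [0, 0, MU0 / (2 * circ.radius)],
                                   rtol=1e-12, atol=1e-20)

    def test_helmholtz_midpoint(self):
        """Two coaxial loops separated by one radius: the textbook
        (4/5)^{3/2} mu0 n / R closed form at the midpoint."""
        R, n = 0.25, 200
        up = CoilSpec("circular", [0, 0, R / 2], [0, 0, 1], n, radius=R)
        lo = CoilSpec("circular", [0, 0, -R / 2], [0, 0, 1], n, radius=R)
        B = loop_field_circular(up, [0, 0, 0]) + loop_field_circular(lo, [0, 0, 0])
        assert B[2] == pytest.approx((4 / 5) ** 1.5 * MU0 * n / R, rel=1e-12)

    def test_off_axis_matches_quadrature(self, circ, rng):
        for _ in range(5):
            pt = rng.uniform(-0.06, 0.06, 3)
            expected = biot_savart_quadrature(circ, pt, n_seg=100_000)
            got = loop_field_circular(circ, pt)
            assert np.linalg.norm(got - expected) <= 1e-8 * np.linalg.norm(expected)

    def test_filament_proximity_error(self, circ):
        with pytest.raises(FilamentProximityError):
            loop_field_circular(circ, [circ.radius + 1e-4, 0, 0])


class TestRectangularLoop:
    def test_square_center_closed_form(self):
        a = 0.07
        sq = CoilSpec("rectangular", [0, 0, 0], [0, 0, 1], 1,
                      half_width=a, half_height=a)
        B = loop_field_rectangular(sq, [0, 0, 0])
        assert B[2] == pytest.approx(np.sqrt(2) * MU0 / (np.pi * a), rel=1e-12)

    def test_far_field_dipole(self, rect):
        """At >= 10 loop sizes the rectangle matches a point dipole of
        moment = area x turns to 2%."""
        m = 4 * rect.half_width * rect.half_height * rect.turns
        for pt in ([0, 0, 1.8], [1.2, 0.9, 1.1], [0.4, -1.6, 0.9]):
            pt = np.asarray(pt, float)
            r = np.linalg.norm(pt)
            r_hat = pt / r
            dip = MU0 / (4 * np.pi) * (3 * (m * r_hat[2]) * r_hat
                                       - np.array([0, 0, m])) / r**3
            got = loop_field_rectangular(rect, pt)
            assert np.linalg.norm(got - dip) < 0.02 * np.linalg.norm(dip)

    def test_matches_quadrature(self, rect, rng):
        for _ in range(5):
            pt = rng.uniform(-0.12, 0.12, 3)
            expected = biot_savart_quadrature(rect, pt, n_seg=100_000)
            got = loop_field_rectangular(rect, pt)
            assert np.linalg.norm(got - expected) <= 1e-8 * np.linalg.norm(expected)

    def test_filament_proximity_error(self, rect):
        with pytest.raises(FilamentProximityError):
            loop_field_rectangular(rect, [rect.half_width, 0.0, 1e-4])


class TestBasisAndSuperposition:
    def test_basis_deterministic(self, ema_config, array):
        b1 = coil_basis(ema_config, array.positions)
        b2 = coil_basis(ema_config, array.positions)
        assert b1.shape == (10, 36, 3)
        np.testing.assert_array_equal(b1, b2)

    def test_linearity_in_current(self, ema_config):
        # field of coil k at current i equals i x the unit-current basis entry
        pt = np.asarray([0.01, 0.02, 0.0])
        single = coil_unit_field(ema_config.coils[3], pt)
        i_vec = np.zeros(10)
        i_vec[3] = 2.75
        np.testing.assert_allclose(ema_field(ema_config, i_vec, pt),
                                   2.75 * single, rtol=1e-14)

    def test_unit_current_sum_equals_superposition(self, ema_config, array,
                                                   sensor_basis):
        ones = np.ones(10)
        for j in (0, 14, 35):
            direct = ema_field(ema_config, ones, array.positions[j])
            np.testing.assert_allclose(direct, sensor_basis[:, j, :].sum(axis=0),
                                       rtol=1e-13)

    def test_zero_currents(self, ema_config):
        np.testing.assert_array_equal(
            ema_field(ema_config, np.zeros(10), [0, 0, 0.02]), np.zeros(3))

    def test_doubling_currents(self, ema_config, rng):
        i = rng.uniform(-3, 3, 10)
        p = [0.01, -0.02, 0.015]
        np.testing.assert_allclose(ema_field(ema_config, 2 * i, p),
                                   2 * ema_field(ema_config, i, p), rtol=1e-14)

    def test_additive_superposition(self, ema_config, rng):
        i1 = rng.uniform(-3, 3, 10)
        i2 = rng.uniform(-3, 3, 10)
        p = [-0.02, 0.01, 0.03]
        lhs = ema_field(ema_config, i1 + i2, p)
        rhs = ema_field(ema_config, i1, p) + ema_field(ema_config, i2, p)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_wrong_current_length(self, ema_config):
        with pytest.raises(ValueError):
            ema_field(ema_config, np.zeros(7), [0, 0, 0.02])

    def test_current_limit_warns(self, ema_config):
        i = np.zeros(10)
        i[0] = ema_config.current_limit + 5
        with pytest.warns(UserWarning, match="limit"):
            ema_field(ema_config, i, [0, 0, 0.02])


class TestGradientTensor:
    def test_maxwell_pair_diagonal_structure(self):
        """An opposed coaxial pair gives diag(-g/2, -g/2, g) about its axis
        with trace below 1e-6 of g."""
        R = 0.25
        d = np.sqrt(3) * R / 2
        up = CoilSpec("circular", [0, 0, d], [0, 0, 1], 200, radius=R)
        lo = CoilSpec("circular", [0, 0, -d], [0, 0, 1], 200, radius=R)
        G = coil_gradient_tensor(up, [0, 0, 0]) - coil_gradient_tensor(lo, [0, 0, 0])
        g = G[2, 2]
        assert abs(g) > 0
        np.testing.assert_allclose(np.diag(G), [-g / 2, -g / 2, g],
                                   rtol=1e-6)
        assert abs(np.trace(G)) < 1e-6 * abs(g)
        offdiag = G - np.diag(np.diag(G))
        assert np.max(np.abs(offdiag)) < 1e-6 * abs(g)

    def test_symmetric_and_traceless(self, ema_config, rng):
        for _ in range(5):
            i = rng.uniform(-5, 5, 10)
            p = rng.uniform([-0.04, -0.04, 0.005], [0.04, 0.04, 0.035])
            G = field_gradient_tensor(ema_config, i, p)
            scale = np.linalg.norm(G)
            assert np.linalg.norm(G - G.T) < 1e-6 * scale
            assert abs(np.trace(G)) < 1e-6 * scale

    def test_richardson_step_halving(self, ema_config):
        i = np.array([1.0, -1, 2, -2, 1.5, 0.5, 1, -1, 0.3, -0.3])
        p = [0.015, -0.01, 0.02]
        G1 = field_gradient_tensor(ema_config, i, p, step=1e-4)
        G2 = field_gradient_tensor(ema_config, i, p, step=5e-5)
        assert np.max(np.abs(G1 - G2)) < 1e-4 * np.linalg.norm(G2)


class TestActuationMatrix:
    def test_z_heading_selects_z_gradient_rows(self, ema_config):
        P = np.array([0.01, 0.005, 0.02])
        X = build_actuation_matrix(ema_config, P, np.array([0.0, 0, 1]))
        for k, coil in enumerate(ema_config.coils):
            G = coil_gradient_tensor(coil, P)
            np.testing.assert_allclose(X.matrix[3:, k], G[2], rtol=1e-12)

    def test_forward_model_consistency(self, ema_config, rng):
        """X i reproduces (B, (M̂·∇)B) computed directly from the field model."""
        P = np.array([-0.02, 0.01, 0.025])
        h = heading_from_angles(0.5, -0.3)
        X = build_actuation_matrix(ema_config, P, h)
        i = rng.uniform(-4, 4, 10)
        pred = X.matrix @ i
        B = ema_field(ema_config, i, P)
        G = field_gradient_tensor(ema_config, i, P)
        direct = np.concatenate([B, h @ G])
        assert np.linalg.norm(pred - direct) < 1e-9

    def test_point_outside_roi_rejected(self, ema_config):
        with pytest.raises(ValueError, match="outside"):
            build_actuation_matrix(ema_config, [0.2, 0, 0.02],
                                   np.array([1.0, 0, 0]))


class TestAllocation:
    def test_zero_desired_gives_zero_currents(self, ema_config):
        X = build_actuation_matrix(ema_config, [0, 0, 0.02],
                                   np.array([1.0, 0, 0]))
        i = allocate_currents(X, DesiredWrench(np.zeros(3), np.zeros(3)))
        np.testing.assert_array_equal(i, np.zeros(10))

    def test_orthonormal_rows_pseudoinverse_is_transpose(self, rng):
        from capsnav.coils import ActuationMatrix
        A = rng.normal(size=(6, 10))
        Q, _ = np.linalg.qr(A.T)
        M = Q.T[:6]            # orthonormal rows
        X = ActuationMatrix(matrix=M, eval_point=np.zeros(3),
                            heading_used=np.array([1.0, 0, 0]))
        d = rng.normal(size=6)
        np.testing.assert_allclose(
            allocate_currents(X, DesiredWrench(d[:3], d[3:])), M.T @ d,
            rtol=1e-10, atol=1e-12)

    def test_min_norm_against_null_space_perturbations(self, rng):
        from capsnav.coils import ActuationMatrix
        from scipy.linalg import null_space
        M = rng.normal(size=(6, 10))
        X = ActuationMatrix(matrix=M, eval_point=np.zeros(3),
                            heading_used=np.array([1.0, 0, 0]))
        d = rng.normal(size=6)
        i = allocate_currents(X, DesiredWrench(d[:3], d[3:]))
        assert np.linalg.norm(M @ i - d) < 1e-9
        N = null_space(M)
        for _ in range(20):
            alt = i + N @ rng.normal(size=N.shape[1])
            assert np.linalg.norm(M @ alt - d) < 1e-8   # still a solution
            assert np.linalg.norm(i) <= np.linalg.norm(alt) + 1e-12

    def test_closed_loop_allocation_roundtrip(self, ema_config, rng):
        """Allocate then forward-evaluate: the physical coil set reproduces
        random in-ROI set-points; condition numbers stay moderate."""
        conds = []
        for _ in range(25):
            P = rng.uniform(ema_config.roi.lo + 1e-3, ema_config.roi.hi - 1e-3)
            h = heading_from_angles(rng.uniform(-np.pi, np.pi),
                                    rng.uniform(-1.0, 1.0))
            X = build_actuation_matrix(ema_config, P, h)
            conds.append(X.condition_number)
            d = DesiredWrench(rng.uniform(-5e-3, 5e-3, 3),
                              rng.uniform(-0.05, 0.05, 3))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                i = allocate_currents(X, d)
            target = d.as_vector()
            assert (np.linalg.norm(X.matrix @ i - target)
                    < 1e-6 * np.linalg.norm(target))
        assert np.median(conds) < 1e3

    def test_nonfinite_desired_rejected(self, ema_config):
        X = build_actuation_matrix(ema_config, [0, 0, 0.02],
                                   np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            allocate_currents(X, DesiredWrench(np.array([np.nan, 0, 0]),
                                               np.zeros(3)))


class TestCommandMapping:
    def test_free_space_preset_magnitudes(self):
        """The 1:10 ratio turns a 0.05 T/m push into 5 mT field and
        50 mT/m gradient."""
        d = command_to_desired(0.0, 0.0, 0.05, gamma=0.1)
        assert np.linalg.norm(d.field) == pytest.approx(5e-3, rel=1e-12)
        assert np.linalg.norm(d.gradient_along_heading) == pytest.approx(
            50e-3, rel=1e-12)

    def test_vertical_pole(self):
        for yaw in (0.0, 1.0, -2.5):
            d = command_to_desired(yaw, np.pi / 2, 0.03)
            np.testing.assert_allclose(d.field, [0, 0, 0.1 * 0.03 * 1.0],
                                       atol=1e-18)
            np.testing.assert_allclose(d.gradient_along_heading,
                                       [0, 0, 0.03], atol=1e-17)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(yaw=st.floats(-np.pi, np.pi), pitch=st.floats(-1.5, 1.5),
           F=st.floats(1e-4, 0.5), gamma=st.floats(0.01, 1.0))
    def test_ratio_is_exactly_gamma(self, yaw, pitch, F, gamma):
        d = command_to_desired(yaw, pitch, F, gamma)
        assert np.linalg.norm(d.field) == pytest.approx(
            gamma * np.linalg.norm(d.gradient_along_heading), rel=1e-12)
        # both parallel to the commanded heading
        h = heading_from_angles(yaw, pitch)
        np.testing.assert_allclose(np.cross(d.field, h), 0,
                                   atol=1e-15 * (1 + gamma * F))

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            command_to_desired(0.0, 0.0, -0.01)


class TestConfigSerialization:
    def test_yaml_round_trip_reproduces_fields(self, ema_config, tmp_path):
        """The bundled declarative layout reloads to an identical field
        model."""
        import yaml
        from capsnav.coils import config_from_dict, config_to_dict
        text = yaml.safe_dump(config_to_dict(ema_config))
        rebuilt = config_from_dict(yaml.safe_load(text))
        assert rebuilt.current_limit == ema_config.current_limit
        p = [0.013, -0.021, 0.027]
        i = np.linspace(-3, 3, 10)
        np.testing.assert_array_equal(ema_field(rebuilt, i, p),
                                      ema_field(ema_config, i, p))

    def test_bundled_example_file_loads(self):
        import pathlib
        import yaml
        from capsnav.coils import config_from_dict
        path = (pathlib.Path(__file__).resolve().parents[1] / "examples"
                / "ema_default.yaml")
        cfg = config_from_dict(yaml.safe_load(path.read_text())["ema"])
        assert cfg.n_coils == 10
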