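"""SVF exponential, log-Jacobian, Lie bracket and BCH against closed forms."""

import numpy as np
import pytest
from scipy.linalg import expm

from svfmorph import Svf, bch_compose, exponentiate, lie_bracket, log_jacobian
from svfmorph.algebra import compose_displacements

from conftest import centered_coords, linear_svf, smooth_random_svf


def interior(arr, m=5):
    return arr[m:-m, m:-m, m:-m]


class TestExponentiate:
    def test_zero_field_gives_identity(self):
        d = exponentiate(Svf(np.zeros((12, 12, 12, 3))))
        assert np.all(d.data == 0.0)

    @pytest.mark.parametrize("scheme", ["euler", "scaling_squaring"])
    def test_constant_field_integrates_to_translation(self, scheme):
        v = Svf(np.broadcast_to(np.array([1.2, 0, 0]), (24, 24, 24, 3)).copy())
        d = exponentiate(v, scheme)
        err = np.abs(interior(d.data) - np.array([1.2, 0, 0]))
        assert err.max() < 1e-4

    @pytest.mark.parametrize("scheme,steps", [("euler", 256),
                                              ("scaling_squaring", 9)])
    def test_linear_field_matches_matrix_exponential(self, scheme, steps):
        A = np.diag([0.1, 0.1, 0.1])
        v = linear_svf(32, A)
        d = exponentiate(v, scheme, steps)
        target = centered_coords(32) @ (expm(A) - np.eye(3)).T
        assert np.abs(interior(d.data - target)).max() < 1e-3

    def test_nonfinite_rejected(self):
        v = Svf(np.zeros((8, 8, 8, 3)))
        v.data[0, 0, 0, 0] = np.nan  # bypass constructor check
        with pytest.raises(ValueError):
            exponentiate(v)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            exponentiate(Svf(np.zeros((8, 8, 8, 3))), "rk4")

    def test_inverse_consistency(self):
        v = smooth_random_svf(32, 2.5, seed=3, scale=6.0)
        fwd = exponentiate(v, steps=32)
        bwd = exponentiate(Svf(-v.data), steps=32)
        comp = compose_displacements(fwd.data, bwd.data)
        assert np.sqrt((interior(comp, 4) ** 2).sum(-1)).max() < 0.1

    def test_scaling_relation_half_step(self):
        v = smooth_random_svf(32, 2.0, seed=4)
        full = exponentiate(v)
        half = exponentiate(Svf(0.5 * v.data))
        comp = compose_displacements(half.data, half.data)
        assert np.abs(interior(comp - full.data)).max() < 0.05


class TestLogJacobian:
    def test_zero_field_zero_map(self):
        lj = log_jacobian(Svf(np.zeros((12, 12, 12, 3))))
        np.testing.assert_allclose(lj, 0.0, atol=1e-12)

    def test_isotropic_linear_field_gives_trace(self):
        lj = log_jacobian(linear_svf(32, np.diag([0.1, 0.1, 0.1])), steps=128)
        assert abs(interior(lj, 10).mean() - 0.3) < 1e-2
        assert np.abs(interior(lj, 10) - 0.3).max() < 1e-2

    def test_rotation_generator_is_volume_preserving(self):
        W = np.array([[0, -0.05, 0], [0.05, 0, 0], [0, 0, 0]])
        lj = log_jacobian(linear_svf(32, W), steps=64)
        assert np.abs(interior(lj, 8)).max() < 1e-2

    def test_sign_convention_expansion_vs_contraction(self):
        lj_exp = log_jacobian(linear_svf(24, np.diag([0.05] * 3)), steps=64)
        lj_con = log_jacobian(linear_svf(24, np.diag([-0.05] * 3)), steps=64)
        assert interior(lj_exp).min() > 0
        assert interior(lj_con).max() < 0

    def test_antisymmetry_under_inversion(self):
        from svfmorph.image import warp_vector_field
        v = smooth_random_svf(32, 2.0, seed=7, scale=6.0)
        lj_f = log_jacobian(v)
        lj_b = log_jacobian(Svf(-v.data))
        # -log|J|(exp(v)) evaluated at the warped positions
        disp = exponentiate(v).data
        lj_b_warped = warp_vector_field(
            np.repeat(lj_b[..., None], 3, axis=-1), disp)[..., 0]
        err = interior(lj_f + lj_b_warped, 6)
        assert np.abs(err).max() < 5e-2

    def test_folding_detected(self):
        # a high-frequency wave whose single-step map folds space
        n = 16
        x = np.arange(n, dtype=float)
        data = np.zeros((n, n, n, 3))
        data[..., 0] = -1.5 * np.sin(2 * np.pi * 4 * x / n)[:, None, None]
        with pytest.raises(ValueError, match="non-diffeomorphic"):
            log_jacobian(Svf(data), steps=1)


class TestLieBracket:
    def test_self_bracket_is_exactly_zero(self):
        v = smooth_random_svf(16, 1.0, seed=0)
        assert np.all(lie_bracket(v, v).data == 0.0)

    def test_constant_fields_commute(self):
        a = Svf(np.broadcast_to(np.array([1.0, 2.0, 3.0]), (12, 12, 12, 3)).copy())
        b = Svf(np.broadcast_to(np.array([-1.0, 0.5, 0.0]), (12, 12, 12, 3)).copy())
        np.testing.assert_allclose(lie_bracket(a, b).data, 0.0, atol=1e-12)

    def test_linear_fields_give_matrix_commutator(self):
        A = np.diag([0.1, 0.1, 0.1]) + np.array([[0, 0.05, 0], [0, 0, 0],
                                                 [0.02, 0, 0]])
        B = np.array([[0.0, 0.02, 0], [0, 0.01, 0], [0.03, 0, 0.05]])
        br = lie_bracket(linear_svf(24, A), linear_svf(24, B))
        expected = centered_coords(24) @ (A @ B - B @ A).T
        assert np.abs(interior(br.data - expected, 2)).max() < 1e-6

    def test_antisymmetry(self):
        v = smooth_random_svf(16, 1.0, seed=1)
        w = smooth_random_svf(16, 1.0, seed=2)
        np.testing.assert_allclose(lie_bracket(v, w).data,
                                   -lie_bracket(w, v).data, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lie_bracket(Svf(np.zeros((8, 8, 8, 3))),
                        Svf(np.zeros((9, 9, 9, 3))))


class TestBch:
    def test_identity_element(self):
        v = smooth_random_svf(16, 1.0, seed=5)
        zero = Svf(np.zeros_like(v.data))
        for order in (0, 1, 2):
            np.testing.assert_allclose(bch_compose(v, zero, order).data,
                                       v.data, atol=1e-12)

    def test_commuting_fields_orders_agree(self):
        a = Svf(np.broadcast_to(np.array([0.5, 0.0, 0.2]), (12, 12, 12, 3)).copy())
        b = Svf(np.broadcast_to(np.array([0.0, 0.3, 0.1]), (12, 12, 12, 3)).copy())
        np.testing.assert_allclose(bch_compose(a, b, 0).data,
                                   bch_compose(a, b, 2).data, atol=1e-12)

    def test_second_order_beats_zeroth_on_composition(self):
        v = smooth_random_svf(32, 0.5, seed=8)
        w = smooth_random_svf(32, 0.5, seed=9)
        ref = compose_displacements(exponentiate(v).data,
                                    exponentiate(w).data)
        errs = {}
        for order in (0, 2):
            d = exponentiate(bch_compose(v, w, order)).data
            errs[order] = np.abs(interior(d - ref)).max()
        assert errs[2] <= errs[0]

    def test_unsupported_order_rejected(self):
        v = Svf(np.zeros((8, 8, 8, 3)))
        with pytest.raises(ValueError):
            bch_compose(v, v, 3)
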