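import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import turbodyn as td
from turbodyn.phases import pairwise_distances
from turbodyn.turbulence import (
    LocalOrderField,
    ScaleGrid,
    amplitude_turbulence,
    fit_loglog_slope,
    information_cascade,
    information_cascade_flow,
    information_transfer,
    local_order,
    node_metastability,
    rsn_turbulence,
)

from oracles import local_order_loop, nlm_loop, pooled_std_loop


class TestLocalOrder:
    def test_full_synchrony_gives_R_one(self, small_geometry):
        phi = np.full((small_geometry.n_nodes, 10), 0.7)
        fld = local_order(phi, small_geometry.distances, 0.05)
        np.testing.assert_allclose(fld.R, 1.0, atol=1e-12)

    def test_large_lambda_kernel_collapses_to_self(self, small_geometry, random_phase_field):
        fld = local_order(random_phase_field, small_geometry.distances, 100.0)
        np.testing.assert_allclose(fld.R, 1.0, atol=1e-6)

    def test_two_node_antiphase_closed_form(self):
        # R = (1 - e^{-lam r}) / (1 + e^{-lam r}) for phases (0, pi)
        phi = np.array([[0.0], [np.pi]])
        d = np.array([[0.0, 10.0], [10.0, 0.0]])
        fld = local_order(phi, d, 0.03)
        expect = (1 - np.exp(-0.3)) / (1 + np.exp(-0.3))
        assert fld.R[0, 0] == pytest.approx(expect, abs=1e-12)
        assert fld.R[1, 0] == pytest.approx(expect, abs=1e-12)

    def test_matches_loop_oracle(self, small_geometry, random_phase_field):
        fld = local_order(random_phase_field, small_geometry.distances, 0.07)
        R, theta = local_order_loop(random_phase_field, small_geometry.distances, 0.07)
        np.testing.assert_allclose(fld.R, R, atol=1e-10)
        np.testing.assert_allclose(
            np.angle(np.exp(1j * (fld.theta - theta))), 0.0, atol=1e-10
        )

    def test_nonfinite_phase_reported(self, small_geometry, random_phase_field):
        bad = random_phase_field.copy()
        bad[3, 5] = np.nan
        with pytest.raises(ValueError, match="node 3"):
            local_order(bad, small_geometry.distances, 0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 1.0))
    def test_R_bounded_in_unit_interval(self, seed, lam):
        r = np.random.default_rng(seed)
        pts = r.uniform(0, 100, (8, 3))
        phi = r.uniform(-np.pi, np.pi, (8, 5))
        fld = local_order(phi, pairwise_distances(pts), lam)
        assert np.all(fld.R >= 0) and np.all(fld.R <= 1 + 1e-12)

    def test_mean_R_decreases_with_smaller_lambda(self):
        # more spatial averaging of independent phases lowers the modulus
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            pts = r.uniform(0, 120, (80, 3))
            d = pairwise_distances(pts)
            phi = r.uniform(-np.pi, np.pi, (80, 20))
            r_small = local_order(phi, d, 0.01).R.mean()
            r_large = local_order(phi, d, 0.3).R.mean()
            wins += r_small < r_large
        assert wins >= 9


class TestAmplitudeTurbulence:
    def test_constant_field_is_zero(self):
        fld = LocalOrderField(R=np.full((4, 6), 0.3), theta=np.zeros((4, 6)), lam=0.1)
        assert amplitude_turbulence(fld) == 0.0

    def test_two_point_population_std(self):
        R = np.concatenate([np.full(12, 0.2), np.full(12, 0.4)]).reshape(4, 6)
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        assert amplitude_turbulence(fld) == pytest.approx(0.1, abs=1e-14)

    def test_matches_pooled_loop_oracle(self, rng):
        R = rng.uniform(0, 1, (15, 30))
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        assert amplitude_turbulence(fld) == pytest.approx(pooled_std_loop(R), abs=1e-12)

    def test_invariant_under_global_phase_rotation(self, small_geometry, random_phase_field):
        d = small_geometry.distances
        d0 = amplitude_turbulence(local_order(random_phase_field, d, 0.05))
        d1 = amplitude_turbulence(local_order(random_phase_field + 1.234, d, 0.05))
        assert d1 == pytest.approx(d0, abs=1e-12)


class TestCascade:
    def _field(self, R, lam):
        return LocalOrderField(R=R, theta=np.zeros_like(R), lam=lam)

    def test_exact_lag_gives_unit_flow(self, rng):
        T = 60
        hi = rng.uniform(0.2, 0.8, (5, T))
        lo = np.empty_like(hi)
        lo[:, : T - 1] = hi[:, 1:]  # lo(t) = hi(t+1)
        lo[:, -1] = hi[:, -1]
        f = information_cascade_flow(self._field(hi, 0.04), self._field(lo, 0.01))
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_anticorrelated_gives_minus_one(self, rng):
        T = 60
        hi = rng.uniform(0.2, 0.8, (5, T))
        lo = np.empty_like(hi)
        shifted = hi[:, 1:]
        lo[:, : T - 1] = 2 * shifted.mean(axis=1, keepdims=True) - shifted
        lo[:, -1] = 0.5
        f = information_cascade_flow(self._field(hi, 0.04), self._field(lo, 0.01))
        assert f == pytest.approx(-1.0, abs=1e-12)

    def test_independent_fields_near_zero(self):
        r = np.random.default_rng(7)
        hi = r.uniform(0, 1, (20, 1000))
        lo = r.uniform(0, 1, (20, 1000))
        f = information_cascade_flow(self._field(hi, 0.04), self._field(lo, 0.01))
        assert abs(f) < 0.1

    def test_zero_variance_nodes_excluded_with_warning(self, rng):
        hi = rng.uniform(0, 1, (4, 30))
        lo = rng.uniform(0, 1, (4, 30))
        hi[0] = 0.5
        with pytest.warns(UserWarning, match="zero-variance"):
            information_cascade_flow(self._field(hi, 0.04), self._field(lo, 0.01))

    def test_cascade_is_arithmetic_mean(self):
        assert information_cascade([0.2, 0.4]) == pytest.approx(0.3)
        assert information_cascade([0.7] * 5) == pytest.approx(0.7)
        grid = ScaleGrid()
        assert len(grid) == 10  # default grid yields 9 transitions
        with pytest.raises(ValueError):
            information_cascade([])


class TestInformationTransfer:
    def test_exact_power_laws(self):
        r = np.array([10.0, 20.0, 40.0, 80.0])
        A, B = fit_loglog_slope(list(zip(r, r**-0.5)), (5, 100))
        assert A == pytest.approx(-0.5, abs=1e-12)
        A, B = fit_loglog_slope(list(zip(r, np.full(4, 0.3))), (5, 100))
        assert A == pytest.approx(0.0, abs=1e-12)
        A, B = fit_loglog_slope(list(zip(r, 2.0 * r**-1)), (5, 100))
        assert A == pytest.approx(-1.0, abs=1e-12)
        assert B == pytest.approx(np.log(2), abs=1e-12)

    def test_degenerate_fit_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_loglog_slope([(20.0, -0.1), (30.0, -0.2), (40.0, 0.5)], (10, 100))

    def test_identical_timecourses_give_zero_slope(self, small_geometry, rng):
        R = np.tile(rng.uniform(0.2, 0.8, 40), (small_geometry.n_nodes, 1))
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        A, B = information_transfer(fld, small_geometry.distances)
        assert A == 0.0

    def test_recovers_prescribed_power_law_decay(self):
        # Gaussian field whose pair correlation decays ~ r^{-0.8}
        rng = np.random.default_rng(42)
        n, T = 40, 4000
        pos = rng.uniform(0, 120, (n, 3))
        d = pairwise_distances(pos)
        K = np.where(d > 0, (np.maximum(d, 5.0) / 5.0) ** -0.8, 1.0)
        np.fill_diagonal(K, 1.0)
        w, V = np.linalg.eigh(K)
        K_psd = (V * np.clip(w, 1e-6, None)) @ V.T
        dg = np.sqrt(np.diag(K_psd))
        L = np.linalg.cholesky(K_psd / np.outer(dg, dg) + 1e-10 * np.eye(n))
        z = L @ rng.standard_normal((n, T))
        R = 0.5 + 0.1 * np.tanh(z)
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        A, _ = information_transfer(fld, d, bins=30, range_mm=(10, 100))
        assert A == pytest.approx(-0.8, abs=0.1)

    def test_binned_equals_unbinned_with_singleton_bins(self):
        # 3 nodes -> 3 pairs; with enough bins each pair is alone in its bin
        rng = np.random.default_rng(5)
        pos = np.array([[0, 0, 0], [30, 0, 0], [0, 55, 0.0]])
        d = pairwise_distances(pos)
        common = rng.standard_normal(200)  # shared drive keeps correlations positive
        R = np.clip(0.5 + 0.1 * (common + rng.standard_normal((3, 200))), 0, 1)
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        A1, B1 = information_transfer(fld, d, bins=2000, range_mm=(10, 100))
        x = R - R.mean(axis=1, keepdims=True)
        s = np.sqrt((x**2).sum(axis=1))
        corr = (x @ x.T) / np.outer(s, s)
        pairs = [(d[i, j], corr[i, j]) for i in range(3) for j in range(i + 1, 3)]
        A2, B2 = fit_loglog_slope(pairs, (10, 100))
        # agreement up to the bin-midpoint discretisation of r
        assert A1 == pytest.approx(A2, abs=2e-3)
        assert B1 == pytest.approx(B2, abs=1e-2)


class TestNodeMetastability:
    def test_trivial_values_and_oracle(self, rng):
        R = np.vstack([np.full(10, 0.4), np.tile([0.0, 1.0], 5)])
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        nlm = node_metastability(fld)
        assert nlm[0] == pytest.approx(0.0)
        assert nlm[1] == pytest.approx(0.5)
        R2 = rng.uniform(0, 1, (12, 25))
        np.testing.assert_allclose(
            node_metastability(LocalOrderField(R=R2, theta=np.zeros_like(R2), lam=0.1)),
            nlm_loop(R2),
            atol=1e-12,
        )


class TestRsnTurbulence:
    def test_constant_network_and_global_reduction(self, rng):
        R = rng.uniform(0, 1, (10, 20))
        R[:5] = 0.3
        labels = np.array(["A"] * 5 + ["B"] * 5)
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        by_net = rsn_turbulence(fld, labels)
        assert by_net["A"] == pytest.approx(0.0)
        all_same = rsn_turbulence(fld, np.array(["X"] * 10))
        assert all_same["X"] == pytest.approx(amplitude_turbulence(fld), abs=1e-14)

    def test_matches_masked_loop_oracle(self, rng):
        R = rng.uniform(0, 1, (12, 15))
        labels = rng.choice(["U", "V", "W"], size=12)
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        by_net = rsn_turbulence(fld, labels)
        for name, val in by_net.items():
            assert val == pytest.approx(pooled_std_loop(R[labels == name]), abs=1e-12)

    def test_tiny_network_excluded(self, rng):
        R = rng.uniform(0, 1, (5, 10))
        labels = np.array(["A", "A", "A", "A", "B"])
        fld = LocalOrderField(R=R, theta=np.zeros_like(R), lam=0.1)
        with pytest.warns(UserWarning, match="<2 nodes"):
            by_net = rsn_turbulence(fld, labels)
        assert "B" not in by_net
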