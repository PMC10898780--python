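import numpy as np
import pytest

import turbodyn as td
from turbodyn.hopf import (
    HopfConfig,
    IntegrationDivergedError,
    StructuralConnectome,
    build_edr_connectome,
    estimate_frequencies,
    simulate,
    simulate_batch,
)
from turbodyn.phases import BoldTimeseries


def _single_node_connectome():
    return StructuralConnectome(np.zeros((1, 1)), distances=np.zeros((1, 1)))


class TestEdrConnectome:
    def test_edr_weight_at_10mm(self, small_geometry):
        conn = build_edr_connectome(small_geometry, lambda_c=0.18)
        # any pair at distance r has weight e^{-0.18 r}
        i, j = 0, 1
        r = small_geometry.distances[i, j]
        assert conn.C[i, j] == pytest.approx(np.exp(-0.18 * r), rel=1e-12)
        assert np.exp(-0.18 * 10.0) == pytest.approx(0.1653, abs=1e-4)
        assert np.all(np.diag(conn.C) == 0)
        assert conn.provenance == "edr"

    def test_long_range_exception_overrides_edr(self, small_geometry):
        n = small_geometry.n_nodes
        sc = np.zeros((n, n))
        far = np.unravel_index(np.argmax(small_geometry.distances), (n, n))
        sc[far] = sc[far[::-1]] = 0.9
        conn = build_edr_connectome(small_geometry, empirical_sc=sc)
        r = small_geometry.distances[far]
        assert conn.C[far] == pytest.approx(0.9 / 0.9)  # max-normalised to 1
        assert conn.C[far] > np.exp(-0.18 * r)
        assert conn.provenance == "edr+lr"

    def test_coincident_centroids_flagged(self):
        d = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="degenerate"):
            conn = build_edr_connectome(d)
        # e^0 = 1 before diagonal zeroing
        assert conn.C[0, 1] == 1.0 and conn.C[0, 0] == 0.0


class TestEstimateFrequencies:
    def test_recovers_pure_tone_and_two_nodes(self):
        tr, T = 2.0, 512
        t = np.arange(T) * tr
        x = np.vstack(
            [np.sin(2 * np.pi * 0.05 * t), np.sin(2 * np.pi * 0.02 * t), np.sin(2 * np.pi * 0.06 * t)]
        )
        omega = estimate_frequencies(BoldTimeseries(x, tr=tr))
        f = omega / (2 * np.pi)
        df = 1.0 / (T * tr)
        assert abs(f[0] - 0.05) <= df
        assert abs(f[1] - 0.02) <= df
        assert abs(f[2] - 0.06) <= df

    def test_white_noise_stays_in_band(self):
        r = np.random.default_rng(2)
        omega = estimate_frequencies(BoldTimeseries(r.standard_normal((4, 256)), tr=2.0))
        f = omega / (2 * np.pi)
        assert np.all((f >= 0.008) & (f <= 0.08))


class TestSimulate:
    def test_subcritical_uncoupled_decays_to_zero(self):
        cfg = HopfConfig(a=-0.1, omega=2 * np.pi * 0.05, G=0.0, nu=0.0,
                         dt=0.01, duration=100.0, burn_in=0.0, tr=1.0, seed=0)
        ts = simulate(_single_node_connectome(), cfg)
        amp = np.abs(ts.values[0])
        # envelope decays: compare successive 10-sample maxima
        env = [amp[i : i + 10].max() for i in range(0, 90, 10)]
        assert all(a > b for a, b in zip(env, env[1:]))
        assert env[-1] < 0.05

    def test_limit_cycle_radius_and_period(self):
        # uncoupled noiseless node with a=0.25 settles on radius sqrt(a)=0.5
        # with angular frequency omega
        a, f = 0.25, 0.05
        cfg = HopfConfig(a=a, omega=2 * np.pi * f, G=0.0, nu=0.0,
                         dt=0.002, duration=100.0, burn_in=200.0, tr=0.5, seed=1)
        ts = simulate(_single_node_connectome(), cfg)
        x = ts.values[0]
        # amplitude from rms over whole periods (robust to sample phase)
        amplitude = np.sqrt(2) * np.sqrt(np.mean(x**2))
        assert amplitude == pytest.approx(np.sqrt(a), abs=1e-3)
        # period from zero crossings of the steady orbit
        sign_changes = np.where(np.diff(np.sign(x)) != 0)[0]
        period = 2 * np.mean(np.diff(sign_changes)) * cfg.tr
        assert period == pytest.approx(1 / f, rel=1e-2)

    def test_fixed_seed_bit_identical(self, small_geometry):
        conn = build_edr_connectome(small_geometry)
        cfg = HopfConfig(G=1.0, duration=60.0, tr=2.0, seed=42)
        a = simulate(conn, cfg).values
        b = simulate(conn, cfg).values
        np.testing.assert_array_equal(a, b)

    def test_node_permutation_equivariance(self, small_geometry):
        # the coupling term commutes with node relabelling
        conn = build_edr_connectome(small_geometry)
        n = conn.n_nodes
        rng = np.random.default_rng(3)
        perm = rng.permutation(n)
        conn_p = StructuralConnectome(
            conn.C[np.ix_(perm, perm)], distances=conn.distances[np.ix_(perm, perm)]
        )
        x = rng.standard_normal((1, n))
        cx1 = x @ conn.C.T - conn.C.sum(1) * x
        cx2 = (x[:, perm] @ conn_p.C.T - conn_p.C.sum(1) * x[:, perm])[:, np.argsort(perm)]
        np.testing.assert_allclose(cx1, cx2, atol=1e-12)

    def test_dt_halving_converges(self):
        # noiseless trajectory error shrinks roughly linearly with dt
        conn = _single_node_connectome()
        outs = {}
        for dt in (0.02, 0.01, 0.005):
            cfg = HopfConfig(a=0.25, omega=2 * np.pi * 0.05, nu=0.0, dt=dt,
                             duration=40.0, burn_in=0.0, tr=0.2, seed=9)
            outs[dt] = simulate(conn, cfg).values[0]
        e1 = np.abs(outs[0.02] - outs[0.005]).max()
        e2 = np.abs(outs[0.01] - outs[0.005]).max()
        assert e2 < e1

    def test_divergence_raises_helpful_error(self):
        conn = _single_node_connectome()
        cfg = HopfConfig(a=5.0, omega=1.0, nu=0.0, dt=2.0, duration=100.0,
                         burn_in=0.0, tr=2.0, seed=0)
        with pytest.raises(IntegrationDivergedError, match="dt"):
            simulate(conn, cfg)

    def test_batch_matches_single_runs_in_shape(self, small_geometry):
        conn = build_edr_connectome(small_geometry)
        cfg = HopfConfig(duration=60.0, tr=2.0)
        out = simulate_batch(conn, cfg, G_values=np.array([0.5, 1.0, 1.5]), seed=0)
        assert out.shape == (3, small_geometry.n_nodes, 30)

    def test_uncoupled_amplitude_matches_sqrt_a(self):
        # closed-form limit: asymptotic radius sqrt(max(a, 0))
        for a, expect in ((0.09, 0.3), (-0.5, 0.0)):
            cfg = HopfConfig(a=a, omega=2 * np.pi * 0.05, G=0.0, nu=0.0,
                             dt=0.01, duration=50.0, burn_in=300.0, tr=0.5, seed=2)
            ts = simulate(_single_node_connectome(), cfg)
            assert np.abs(ts.values).max() == pytest.approx(expect, abs=2e-3)
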