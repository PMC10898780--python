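"""Whole-brain model of coupled Stuart-Landau (Hopf normal form) oscillators.

Each parcel n obeys the normal form of a supercritical Hopf bifurcation,

    dx_n = [a_n x_n - (x_n^2 + y_n^2) x_n - w_n y_n
            + G sum_p C_np (x_p - x_n)] dt + nu dW,
    dy_n = [a_n y_n - (x_n^2 + y_n^2) y_n + w_n x_n
            + G sum_p C_np (y_p - y_n)] dt + nu dW,

where a_n is the local bifurcation parameter (a < 0: noisy fixed point,
a > 0: limit cycle of radius sqrt(a)), w_n the intrinsic angular
frequency taken from the empirical power-spectrum peak, G a global
coupling scaling the structural connectome C, and nu the additive noise
amplitude (default 0.01).  The real part x is read out as BOLD.

The structural connectome follows the exponential distance rule (EDR),
C_np = exp(-lambda_c r_np) with lambda_c = 0.18 mm^-1 by default,
optionally augmented with long-range exceptions from an empirical SC:
pairs where the (max-normalised) empirical weight exceeds the EDR
prediction keep the empirical value.

Integration is Euler-Maruyama.  For grid searches and perturbation
protocols a batched integrator evolves many (G, noise-realisation)
replicates simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .phases import BoldTimeseries

__all__ = [
    "StructuralConnectome",
    "HopfConfig",
    "build_edr_connectome",
    "estimate_frequencies",
    "simulate",
    "simulate_batch",
]

#: EDR decay rate (mm^-1) that best fits empirical long-range statistics.
DEFAULT_EDR_LAMBDA = 0.18

#: Resting baseline of the bifurcation parameter: just below criticality.
BASELINE_A = -0.02

_DIVERGENCE_LIMIT = 1e6


class IntegrationDivergedError(RuntimeError):
    """State norm exceeded the overflow guard; try a smaller dt."""


@dataclass
class StructuralConnectome:
    """Symmetric nonnegative coupling matrix with provenance metadata."""

    C: np.ndarray
    provenance: str = "external"  # edr | edr+lr | external | attacked
    lambda_c: float | None = None
    distances: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if self.C.ndim != 2 or self.C.shape[0] != self.C.shape[1]:
            raise ValueError("connectome must be square")
        if not np.isfinite(self.C).all():
            raise ValueError("connectome contains non-finite weights")
        if np.any(self.C < 0):
            raise ValueError("connectome weights must be nonnegative")
        if not np.allclose(self.C, self.C.T):
            raise ValueError("connectome must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.C.shape[0]


@dataclass
class HopfConfig:
    """Simulation parameters for one whole-brain run.

    ``a`` and ``omega`` may be scalars (broadcast over nodes) or
    per-node arrays; ``omega`` is in rad/s.  ``duration`` excludes the
    ``burn_in`` that is discarded before decimating to ``tr``.
    """

    a: float | np.ndarray = BASELINE_A
    omega: float | np.ndarray = 2 * np.pi * 0.05
    G: float = 0.0
    nu: float = 0.01
    dt: float = 0.1
    duration: float = 290.0
    burn_in: float = 20.0
    tr: float = 2.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("noise amplitude must be nonnegative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > 0 or self.burn_in < 0:
            raise ValueError("require duration > 0 and burn_in >= 0")
        if self.tr < self.dt:
            raise ValueError("tr must be at least dt")


def build_edr_connectome(
    geometry_or_distances,
    lambda_c: float = DEFAULT_EDR_LAMBDA,
    empirical_sc: np.ndarray | None = None,
) -> StructuralConnectome:
    """Exponential-distance-rule connectome, optionally with long-range exceptions.

    C_np = exp(-lambda_c r_np).  When an empirical SC is supplied it is
    divided by its maximum and each pair keeps the larger of the EDR
    prediction and the empirical weight (symmetrised) — strong long
    connections survive the exponential fall-off.  The diagonal is zero.
    """
    if lambda_c <= 0:
        raise ValueError("lambda_c must be positive")
    distances = getattr(geometry_or_distances, "distances", geometry_or_distances)
    distances = np.asarray(distances, dtype=float)
    n = distances.shape[0]
    off = distances[~np.eye(n, dtype=bool)]
    if off.size and off.min() <= 0:
        import warnings

        warnings.warn("coincident centroids: off-diagonal zero distance (degenerate geometry)")
    C = np.exp(-lambda_c * distances)
    if empirical_sc is not None:
        sc = np.asarray(empirical_sc, dtype=float)
        if sc.shape != distances.shape:
            raise ValueError("empirical SC shape does not match geometry")
        if np.any(sc < 0):
            raise ValueError("empirical SC must be nonnegative")
        if sc.max() > 0:
            sc = sc / sc.max()
        sc = 0.5 * (sc + sc.T)
        C = np.maximum(C, sc)
        provenance = "edr+lr"
    else:
        provenance = "edr"
    np.fill_diagonal(C, 0.0)
    return StructuralConnectome(C=C, provenance=provenance, lambda_c=lambda_c, distances=distances)


def estimate_frequencies(
    ts: BoldTimeseries,
    band: tuple[float, float] = (0.008, 0.08),
) -> np.ndarray:
    """Per-node intrinsic angular frequency from the power-spectrum peak.

    The periodogram peak within ``band`` gives f_n; returns
    omega_n = 2 pi f_n (rad/s).  A node whose in-band spectrum is flat
    falls back to the band midpoint with a warning.
    """
    if ts.n_volumes < 32:
        raise ValueError("need at least 32 volumes for a usable spectrum")
    freqs, pxx = signal.periodogram(ts.values, fs=1.0 / ts.tr, axis=1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("frequency band contains no spectral bins at this TR/T")
    sub = pxx[:, sel]
    fsub = freqs[sel]
    fpeak = fsub[np.argmax(sub, axis=1)]
    flat = sub.max(axis=1) <= 0
    if flat.any():
        import warnings

        warnings.warn(f"{int(flat.sum())} flat-spectrum nodes; using band midpoint")
        fpeak = np.where(flat, 0.5 * (band[0] + band[1]), fpeak)
    return 2 * np.pi * fpeak


def _prepare(connectome: StructuralConnectome, config: HopfConfig):
    n = connectome.n_nodes
    a = np.broadcast_to(np.asarray(config.a, dtype=float), (n,)).copy()
    omega = np.broadcast_to(np.asarray(config.omega, dtype=float), (n,)).copy()
    C = connectome.C
    row = C.sum(axis=1)
    n_burn = int(round(config.burn_in / config.dt))
    stride = int(round(config.tr / config.dt))
    n_keep = int(round(config.duration / config.dt))
    return a, omega, C, row, n_burn, stride, n_keep


def simulate(connectome: StructuralConnectome, config: HopfConfig) -> BoldTimeseries:
    """Integrate the coupled system and return the real part as BOLD.

    Euler-Maruyama with step ``dt``; noise enters both components with
    std nu*sqrt(dt) per step.  The burn-in is discarded and x is
    decimated to TR by stride.  Deterministic for a fixed seed.
    """
    out = simulate_batch(connectome, config, G_values=np.array([config.G]), seed=config.seed)
    return BoldTimeseries(values=out[0], tr=config.tr)


def simulate_batch(
    connectome: StructuralConnectome,
    config: HopfConfig,
    G_values: np.ndarray,
    seed: int | None = None,
    a_values: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Integrate B replicates simultaneously; returns (B, N, T) BOLD.

    Each batch element has its own global coupling ``G_values[b]`` (and,
    optionally, its own per-node bifurcation vector ``a_values[b]``) but
    shares the connectome.  Noise realisations are independent across
    the batch unless a custom generator (e.g. a paired one) is passed.
    """
    a, omega, C, row, n_burn, stride, n_keep = _prepare(connectome, config)
    n = connectome.n_nodes
    G = np.asarray(G_values, dtype=float).reshape(-1, 1)
    B = G.shape[0]
    if a_values is None:
        a_b = np.broadcast_to(a, (B, n))
    else:
        a_b = np.asarray(a_values, dtype=float).reshape(B, n)
    if rng is None:
        rng = np.random.default_rng(seed)

    dt = config.dt
    sd = config.nu * np.sqrt(dt)
    x = 0.1 * rng.standard_normal((B, n))
    y = 0.1 * rng.standard_normal((B, n))
    n_steps = n_burn + n_keep
    n_out = n_keep // stride
    out = np.empty((B, n, n_out))
    k_out = 0
    for step in range(n_steps):
        r2 = x * x + y * y
        cx = x @ C.T - row * x
        cy = y @ C.T - row * y
        wx = rng.standard_normal((B, n))
        wy = rng.standard_normal((B, n))
        x_new = x + dt * ((a_b - r2) * x - omega * y + G * cx) + sd * wx
        y_new = y + dt * ((a_b - r2) * y + omega * x + G * cy) + sd * wy
        x, y = x_new, y_new
        m = max(np.abs(x).max(), np.abs(y).max())
        if not np.isfinite(m) or m > _DIVERGENCE_LIMIT:
            raise IntegrationDivergedError(
                f"state magnitude exceeded {_DIVERGENCE_LIMIT:g} at step {step}; "
                "reduce dt or coupling"
            )
        k = step - n_burn
        if k >= 0 and k % stride == 0 and k_out < n_out:
            out[:, :, k_out] = x
            k_out += 1
    return out


def run_replicates(
    connectome: StructuralConnectome,
    config: HopfConfig,
    n_reps: int,
    seed: int | None = None,
) -> np.ndarray:
    """``n_reps`` independent simulations at the config's G; (reps, N, T)."""
    return simulate_batch(
        connectome, config, G_values=np.full(n_reps, config.G), seed=seed
    )


def with_params(config: HopfConfig, **kwargs) -> HopfConfig:
    """Copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
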