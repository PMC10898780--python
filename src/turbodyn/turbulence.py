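"""Model-free turbulence measures on BOLD phase fields.

The central object is the Kuramoto *local* order parameter: at each node
n and volume t, the phase vectors of all nodes are averaged with an
exponential spatial kernel

    R_n(t) e^{i nu_n(t)} = sum_p C_np e^{i phi_p(t)} / sum_q C_nq,
    C_np = exp(-lambda * r_np),

where r_np is the Euclidean centroid distance in mm and lambda (mm^-1)
sets the spatial scale: small lambda averages over long distances, large
lambda is nearly local.  The self-term C_nn = 1 is included.

From the modulus field R the package derives:

- amplitude turbulence D: the std of R pooled over nodes and time;
- node-level metastability: the temporal std of R per node;
- information cascade flow: the lagged correlation of R between
  adjacent scales, and its scale-average (the information cascade);
- information transfer: the log-log slope of the spatial correlation
  of R against distance within the inertial subrange;
- per-network (RSN) turbulence.

All standard deviations are population (divide-by-N) moments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .phases import PhaseField

__all__ = [
    "ScaleGrid",
    "LocalOrderField",
    "local_order",
    "amplitude_turbulence",
    "information_cascade_flow",
    "information_cascade",
    "fit_loglog_slope",
    "information_transfer",
    "node_metastability",
    "rsn_turbulence",
    "turbulence_summary",
]

#: Default inertial subrange (mm) for log-log fits; the power-law regime
#: assumed between very short and very long connections.
DEFAULT_SUBRANGE = (10.0, 100.0)


@dataclass
class ScaleGrid:
    """Ordered grid of spatial scales lambda (mm^-1).

    The default spans 0.01 (~100 mm neighbourhoods) to 0.30 (~3 mm) in
    steps of 0.03.
    """

    lambdas: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 0.301, 0.03), 10)
    )

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.ndim != 1 or len(self.lambdas) == 0:
            raise ValueError("lambdas must be a non-empty 1-D sequence")
        if np.any(self.lambdas <= 0):
            raise ValueError("all scales must be positive")
        if np.any(np.diff(self.lambdas) <= 0):
            raise ValueError("scales must be strictly increasing")

    @property
    def step(self) -> float:
        return float(self.lambdas[1] - self.lambdas[0]) if len(self.lambdas) > 1 else np.nan

    def __iter__(self):
        return iter(self.lambdas)

    def __len__(self) -> int:
        return len(self.lambdas)


@dataclass
class LocalOrderField:
    """Modulus R and phase theta of the local order parameter at one scale."""

    R: np.ndarray
    theta: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.R.shape != self.theta.shape or self.R.ndim != 2:
            raise ValueError("R and theta must be equal-shape nodes x volumes arrays")
        if np.any(self.R < -1e-12) or np.any(self.R > 1 + 1e-9):
            raise ValueError("R must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.R.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.R.shape[1]


def local_order(phases: PhaseField | np.ndarray, distances: np.ndarray, lam: float) -> LocalOrderField:
    """Kuramoto local order parameter at spatial scale ``lam``.

    Parameters
    ----------
    phases : PhaseField or (N, T) array of angles in radians.
    distances : (N, N) Euclidean distance matrix in mm.
    lam : float
        Kernel decay rate in mm^-1 (> 0).
    """
    phi = phases.phases if isinstance(phases, PhaseField) else np.asarray(phases, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if phi.ndim != 2:
        raise ValueError("phases must be nodes x volumes")
    n = phi.shape[0]
    if distances.shape != (n, n):
        raise ValueError(f"distance matrix shape {distances.shape} does not match {n} nodes")
    if not np.isfinite(phi).all():
        bad = np.argwhere(~np.isfinite(phi))[0]
        raise ValueError(f"non-finite phase at node {bad[0]}, volume {bad[1]}")

    kernel = np.exp(-lam * distances)  # C_nn = exp(0) = 1: self-term included
    z = kernel @ np.exp(1j * phi)
    z /= kernel.sum(axis=1, keepdims=True)
    return LocalOrderField(R=np.abs(z), theta=np.angle(z), lam=float(lam))


def amplitude_turbulence(fld: LocalOrderField | np.ndarray) -> float:
    """Amplitude turbulence D: population std of R pooled over nodes and time."""
    R = fld.R if isinstance(fld, LocalOrderField) else np.asarray(fld, dtype=float)
    # population std via the stable two-pass form (= sqrt(<R^2> - <R>^2))
    return float(np.std(R))


def node_metastability(fld: LocalOrderField | np.ndarray) -> np.ndarray:
    """Node-level metastability: temporal population std of R per node."""
    R = fld.R if isinstance(fld, LocalOrderField) else np.asarray(fld, dtype=float)
    return np.std(R, axis=1)


def information_cascade_flow(
    field_hi: LocalOrderField,
    field_lo: LocalOrderField,
    dt_steps: int = 1,
) -> float:
    """Cross-scale lagged correlation F(lambda).

    Per node, the Pearson correlation over time of R at the higher scale
    shifted forward by ``dt_steps`` samples against R at the adjacent
    lower scale; F is the node average.  Nodes with zero temporal
    variance in either series are excluded (a warning reports the count).
    """
    if field_hi.R.shape != field_lo.R.shape:
        raise ValueError("fields must share shape")
    if field_hi.lam <= field_lo.lam:
        raise ValueError("field_hi must be at the larger lambda")
    T = field_hi.n_volumes
    if T - dt_steps < 3:
        raise ValueError("too few volumes for the requested lag")
    a = field_hi.R[:, dt_steps:]  # R_lambda(t + dt)
    b = field_lo.R[:, : T - dt_steps]  # R_{lambda - dlambda}(t)
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    sa = np.sqrt((a**2).sum(axis=1))
    sb = np.sqrt((b**2).sum(axis=1))
    valid = (sa > 0) & (sb > 0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} zero-variance nodes excluded from cascade flow")
    if not valid.any():
        return float("nan")
    r = (a[valid] * b[valid]).sum(axis=1) / (sa[valid] * sb[valid])
    return float(r.mean())


def information_cascade(flows) -> float:
    """Average of the cascade flow over scale transitions."""
    flows = np.asarray(list(flows), dtype=float)
    if flows.size == 0:
        raise ValueError("need at least one scale transition")
    return float(flows.mean())


def fit_loglog_slope(
    pairs,
    range_mm: tuple[float, float] = DEFAULT_SUBRANGE,
) -> tuple[float, float]:
    """Least-squares line log(corr) = A log(r) + B within the subrange.

    ``pairs`` is a sequence of (distance_mm, correlation).  Pairs outside
    ``range_mm`` or with non-positive correlation (log undefined) are
    excluded; the excluded count is reported via a warning.  At least
    three usable pairs are required.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (distance, correlation) tuples")
    r, c = arr[:, 0], arr[:, 1]
    in_range = (r >= range_mm[0]) & (r <= range_mm[1])
    positive = c > 0
    use = in_range & positive
    n_nonpos = int((in_range & ~positive).sum())
    if n_nonpos:
        warnings.warn(f"{n_nonpos} non-positive correlations excluded from log-log fit")
    if use.sum() < 3:
        raise ValueError(
            f"degenerate fit: only {int(use.sum())} usable pairs in range {range_mm}"
        )
    A, B = np.polyfit(np.log(r[use]), np.log(c[use]), 1)
    return float(A), float(B)


def information_transfer(
    fld: LocalOrderField,
    distances: np.ndarray,
    bins: int = 50,
    range_mm: tuple[float, float] = DEFAULT_SUBRANGE,
) -> tuple[float, float]:
    """Information transfer: power-law decay exponent of R-R correlation.

    Pairwise temporal correlations of R are averaged in ``bins``
    equal-width distance bins inside the inertial subrange; the binned
    (midpoint, mean correlation) points feed :func:`fit_loglog_slope`.
    Returns (A, B): slope and intercept on the log-log scale.
    """
    R = fld.R
    distances = np.asarray(distances, dtype=float)
    n = R.shape[0]
    x = R - R.mean(axis=1, keepdims=True)
    s = np.sqrt((x**2).sum(axis=1))
    # zero-variance rows yield nan correlations and are dropped pairwise
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x @ x.T) / np.outer(s, s)
    iu, ju = np.triu_indices(n, k=1)
    d_pair = distances[iu, ju]
    c_pair = corr[iu, ju]
    ok = np.isfinite(c_pair) & (d_pair >= range_mm[0]) & (d_pair <= range_mm[1])
    if np.allclose(c_pair[ok], 1.0):
        return 0.0, 0.0  # all pairs perfectly correlated: flat profile
    edges = np.linspace(range_mm[0], range_mm[1], bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(d_pair[ok], edges) - 1, 0, bins - 1)
    sums = np.bincount(idx, weights=c_pair[ok], minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    have = counts > 0
    pairs = list(zip(mids[have], sums[have] / counts[have]))
    return fit_loglog_slope(pairs, range_mm)


def rsn_turbulence(fld: LocalOrderField, rsn_labels) -> dict[str, float]:
    """Amplitude turbulence restricted to each resting-state network.

    Networks with fewer than two nodes are excluded with a warning.
    """
    labels = np.asarray(rsn_labels)
    if labels.shape[0] != fld.n_nodes:
        raise ValueError("labels must cover all nodes")
    out: dict[str, float] = {}
    for name in np.unique(labels):
        mask = labels == name
        if mask.sum() < 2:
            warnings.warn(f"network {name!r} has <2 nodes; excluded")
            continue
        out[str(name)] = amplitude_turbulence(fld.R[mask])
    return out


def turbulence_summary(
    phases: PhaseField,
    distances: np.ndarray,
    grid: ScaleGrid | None = None,
    rsn_labels=None,
    subrange_mm: tuple[float, float] = DEFAULT_SUBRANGE,
    transfer_bins: int = 50,
) -> dict:
    """Compute every scale-resolved measure over a lambda grid.

    Returns a dict with keys ``D`` (lambda -> D), ``NLM`` (lambda ->
    per-node array), ``F`` (lambda -> cascade flow into the next smaller
    scale), ``cascade`` (scalar), ``transfer`` (lambda -> (A, B) or None
    when the fit is degenerate), and ``rsn_D`` when labels are given.
    """
    grid = grid or ScaleGrid()
    fields = {lam: local_order(phases, distances, lam) for lam in grid}
    lams = list(grid)
    D = {lam: amplitude_turbulence(fields[lam]) for lam in lams}
    NLM = {lam: node_metastability(fields[lam]) for lam in lams}
    F = {
        lams[i]: information_cascade_flow(fields[lams[i]], fields[lams[i - 1]])
        for i in range(1, len(lams))
    }
    transfer = {}
    for lam in lams:
        try:
            transfer[lam] = information_transfer(
                fields[lam], distances, bins=transfer_bins, range_mm=subrange_mm
            )
        except ValueError:
            transfer[lam] = None
    out = {
        "D": D,
        "NLM": NLM,
        "F": F,
        "cascade": information_cascade(F.values()) if F else float("nan"),
        "transfer": transfer,
    }
    if rsn_labels is not None:
        out["rsn_D"] = {lam: rsn_turbulence(fields[lam], rsn_labels) for lam in lams}
    return out
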