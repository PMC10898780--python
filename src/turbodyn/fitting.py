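"""Fitting the whole-brain model by distance-resolved functional connectivity.

The comparison statistic is the spatial correlation profile FC(r): the
Pearson correlation of z-scored node time courses, averaged over node
pairs whose Euclidean distance falls in each bin.  Kolmogorov's
structure function follows as S(r) = 2 (FC(0) - FC(r)) with FC(0) = 1
for z-scored signals.  The model's global coupling G is selected by a
grid search: the working point G* minimises the Euclidean distance
between simulated and empirical FC(r) within the inertial subrange,
averaged over noise-realisation repetitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hopf import HopfConfig, IntegrationDivergedError, StructuralConnectome, simulate_batch
from .phases import BoldTimeseries
from .turbulence import DEFAULT_SUBRANGE

__all__ = [
    "FcProfile",
    "SweepResult",
    "fc_profile",
    "group_fc_profile",
    "fitting_error",
    "sweep_G",
    "compare_working_points",
]


@dataclass
class FcProfile:
    """Binned spatial-correlation profile FC(r) and structure function S(r)."""

    r: np.ndarray  # bin midpoints, mm
    fc: np.ndarray  # mean pair correlation per bin (nan for empty bins)
    counts: np.ndarray
    range_mm: tuple[float, float]

    @property
    def s(self) -> np.ndarray:
        """Structure function S(r) = 2 (1 - FC(r)) for z-scored signals."""
        return 2.0 * (1.0 - self.fc)

    def same_grid(self, other: "FcProfile") -> bool:
        return (
            self.r.shape == other.r.shape
            and np.allclose(self.r, other.r)
            and self.range_mm == other.range_mm
        )


@dataclass
class SweepResult:
    """Outcome of a global-coupling grid search."""

    G_grid: np.ndarray
    mean_error: np.ndarray
    rep_errors: np.ndarray  # (len(grid), reps); nan where a rep diverged
    G_star: float
    reps: int
    seed: int | None
    n_diverged: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"G": self.G_grid, "error": self.mean_error})


def _pair_correlations(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Upper-triangle pair correlations of z-scored rows.

    Returns (pair index arrays, correlations, n zero-variance nodes
    excluded)."""
    x = values - values.mean(axis=1, keepdims=True)
    s = np.sqrt((x**2).sum(axis=1))
    ok = s > 0
    n_excl = int((~ok).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (x @ x.T) / np.outer(s, s)
    return corr, ok, n_excl


def fc_profile(
    ts: BoldTimeseries | np.ndarray,
    distances: np.ndarray,
    bins: int = 30,
    range_mm: tuple[float, float] = DEFAULT_SUBRANGE,
) -> FcProfile:
    """Distance-binned FC(r) from node time courses.

    Node signals are z-scored (correlation is scale-free, so only the
    zero-variance exclusion matters); pair correlations are averaged in
    ``bins`` equal-width distance bins over ``range_mm``.
    """
    values = ts.values if isinstance(ts, BoldTimeseries) else np.asarray(ts, dtype=float)
    if values.shape[1] < 3:
        raise ValueError("need at least 3 volumes")
    distances = np.asarray(distances, dtype=float)
    corr, ok, n_excl = _pair_correlations(values)
    if n_excl:
        warnings.warn(f"{n_excl} zero-variance nodes excluded from FC profile")
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    keep = ok[iu] & ok[ju]
    d = distances[iu, ju][keep]
    c = corr[iu, ju][keep]
    lo, hi = range_mm
    edges = np.linspace(lo, hi, bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    sel = (d >= lo) & (d <= hi)
    idx = np.clip(np.digitize(d[sel], edges) - 1, 0, bins - 1)
    sums = np.bincount(idx, weights=c[sel], minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    fc = np.full(bins, np.nan)
    nz = counts > 0
    fc[nz] = sums[nz] / counts[nz]
    return FcProfile(r=mids, fc=fc, counts=counts, range_mm=range_mm)


def fitting_error(sim: FcProfile, emp: FcProfile) -> float:
    """Euclidean distance between FC(r) profiles over shared non-empty bins."""
    if not sim.same_grid(emp):
        raise ValueError("profiles are on different bin grids")
    use = np.isfinite(sim.fc) & np.isfinite(emp.fc)
    return float(np.sqrt(np.sum((sim.fc[use] - emp.fc[use]) ** 2)))


class _TiledRng:
    """Repeats every Gaussian draw across equal blocks of a batch.

    With the batch ordered G-major (all repetitions of G_0, then of
    G_1, ...), tiling makes repetition r share its noise realisation
    across every grid value — common random numbers, which cancels the
    correlated part of the Monte-Carlo error when comparing fitting
    levels between G values.
    """

    def __init__(self, base: np.random.Generator, n_tiles: int):
        self._base = base
        self._tiles = n_tiles

    def standard_normal(self, shape):
        b, n = shape
        block = self._base.standard_normal((b // self._tiles, n))
        return np.tile(block, (self._tiles, 1))


def group_fc_profile(
    series,
    distances: np.ndarray,
    bins: int = 30,
    range_mm: tuple[float, float] = DEFAULT_SUBRANGE,
) -> FcProfile:
    """Group-averaged FC(r): per-subject profiles averaged bin-wise."""
    profs = [fc_profile(ts, distances, bins=bins, range_mm=range_mm) for ts in series]
    out = profs[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out.fc = np.nanmean(np.stack([p.fc for p in profs]), axis=0)
    out.counts = np.sum(np.stack([p.counts for p in profs]), axis=0)
    return out


def sweep_G(
    connectome: StructuralConnectome,
    config: HopfConfig,
    empirical: FcProfile,
    G_grid: np.ndarray,
    reps: int = 5,
    seed: int | None = None,
    bins: int | None = None,
    crn: bool = True,
) -> SweepResult:
    """Grid-search the global coupling against an empirical FC(r) profile.

    For each G the model is simulated ``reps`` times (all replicates
    integrated in one batch); each run's FC(r) profile is scored by
    :func:`fitting_error` and the mean over repetitions is the fitting
    level.  G* is the grid value with the minimal mean error, ties
    broken toward smaller G.  With ``crn`` (default) repetition r
    shares its noise realisation across all grid values — common random
    numbers, a pure variance-reduction device for the argmin.  Diverged
    repetitions are dropped and counted; a G whose repetitions all
    diverge raises.
    """
    G_grid = np.asarray(G_grid, dtype=float)
    if G_grid.size == 0:
        raise ValueError("G grid must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if bins is None:
        bins = len(empirical.r)
    if connectome.distances is None:
        raise ValueError("connectome needs distance metadata for FC profiles")

    all_G = np.repeat(G_grid, reps)
    try:
        if crn:
            rng = _TiledRng(np.random.default_rng(seed), G_grid.size)
            sims = simulate_batch(connectome, config, G_values=all_G, rng=rng)
        else:
            sims = simulate_batch(connectome, config, G_values=all_G, seed=seed)
        diverged_mask = np.zeros(all_G.size, dtype=bool)
    except IntegrationDivergedError:
        # fall back to per-replicate integration so healthy G values survive
        sims = np.zeros((all_G.size, connectome.n_nodes, 0))
        per = []
        diverged_mask = np.zeros(all_G.size, dtype=bool)
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(all_G.size)
        for b, g in enumerate(all_G):
            try:
                per.append(
                    simulate_batch(
                        connectome,
                        config,
                        G_values=np.array([g]),
                        rng=np.random.default_rng(children[b]),
                    )[0]
                )
            except IntegrationDivergedError:
                per.append(None)
                diverged_mask[b] = True
        T = next(p.shape[1] for p in per if p is not None)
        sims = np.zeros((all_G.size, connectome.n_nodes, T))
        for b, p in enumerate(per):
            if p is not None:
                sims[b] = p

    rep_errors = np.full((G_grid.size, reps), np.nan)
    for b in range(all_G.size):
        gi, ri = divmod(b, reps)
        if diverged_mask[b]:
            continue
        prof = fc_profile(sims[b], connectome.distances, bins=bins, range_mm=empirical.range_mm)
        rep_errors[gi, ri] = fitting_error(prof, empirical)

    n_div = int(diverged_mask.sum())
    if n_div:
        warnings.warn(f"{n_div} diverged repetitions excluded from the sweep")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_error = np.nanmean(rep_errors, axis=1)
    if np.isnan(mean_error).any():
        bad = G_grid[np.isnan(mean_error)]
        raise IntegrationDivergedError(f"all repetitions diverged at G = {bad}")
    # argmin returns the first (smallest-G) minimiser on ties
    G_star = float(G_grid[int(np.argmin(mean_error))])
    return SweepResult(
        G_grid=G_grid,
        mean_error=mean_error,
        rep_errors=rep_errors,
        G_star=G_star,
        reps=reps,
        seed=seed,
        n_diverged=n_div,
    )


def compare_working_points(sweeps: dict[str, SweepResult]) -> pd.DataFrame:
    """Tabulate (condition, G*, min error) for two or more sweeps.

    Reporting only; inference on group differences lives in
    :mod:`turbodyn.stats`.
    """
    if len(sweeps) < 2:
        raise ValueError("need at least two sweeps to compare")
    rows = [
        {"condition": name, "G_star": sw.G_star, "min_error": float(sw.mean_error.min())}
        for name, sw in sweeps.items()
    ]
    return pd.DataFrame(rows)
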