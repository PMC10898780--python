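"""Band-limited instantaneous phases of parcellated BOLD.

Every turbulence measure in this package starts from the instantaneous
phase of the band-passed BOLD signal at each parcel.  The canonical
pipeline is

    bold -> bandpass (0.008-0.08 Hz, zero-phase Butterworth) -> Hilbert
         -> PhaseField

The band limits bracket the slow hemodynamic fluctuations of interest:
the high-pass removes scanner drift, the low-pass suppresses
physiological noise that dominates above ~0.1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BoldTimeseries",
    "PhaseField",
    "bandpass",
    "extract_phases",
    "pairwise_distances",
]


@dataclass
class BoldTimeseries:
    """Parcellated BOLD: ``values`` is nodes x volumes, ``tr`` in seconds."""

    values: np.ndarray
    tr: float
    node_ids: np.ndarray | None = None
    band: tuple[float, float] | None = None  # set by bandpass()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("BOLD values must be a 2-D (nodes x volumes) array")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 volumes")
        if not np.isfinite(self.values).all():
            raise ValueError("BOLD values contain non-finite entries")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.node_ids is None:
            self.node_ids = np.arange(self.values.shape[0])

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.tr


@dataclass
class PhaseField:
    """Instantaneous phases (radians, in (-pi, pi]) per node and volume.

    ``degenerate_nodes`` lists nodes whose input signal was identically
    zero; their phase is undefined and must not be interpreted.
    """

    phases: np.ndarray
    tr: float
    amplitudes: np.ndarray | None = None
    degenerate_nodes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValueError("phases must be nodes x volumes")

    @property
    def n_nodes(self) -> int:
        return self.phases.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.phases.shape[1]


def bandpass(
    ts: BoldTimeseries,
    low: float = 0.008,
    high: float = 0.08,
    order: int = 2,
) -> BoldTimeseries:
    """Zero-phase Butterworth band-pass per node.

    Each node is demeaned and then filtered forward-backward
    (``sosfiltfilt``, odd reflective padding), so the filter contributes
    no phase distortion to the subsequent Hilbert step.  The effective
    magnitude response is the squared response of an ``order``-order
    Butterworth design.

    Parameters
    ----------
    ts : BoldTimeseries
    low, high : float
        Pass-band edges in Hz; must satisfy 0 < low < high < Nyquist.
    order : int
        Design order of the underlying Butterworth filter.
    """
    nyq = ts.nyquist
    if not 0 < low < high:
        raise ValueError("require 0 < low < high")
    if high >= nyq:
        raise ValueError(
            f"high cutoff {high} Hz is at or above the Nyquist frequency "
            f"{nyq} Hz for TR={ts.tr} s"
        )
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / ts.tr, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=1)
    return BoldTimeseries(values=y, tr=ts.tr, node_ids=ts.node_ids, band=(low, high))


def extract_phases(ts: BoldTimeseries) -> PhaseField:
    """Instantaneous phase of the analytic (Hilbert) signal per node.

    The input is expected to be band-passed already (``bandpass`` tags
    the series; untagged input is accepted but the phases of broadband
    data are not meaningful).  Nodes whose signal is identically zero
    have no defined phase and are reported in ``degenerate_nodes``.
    """
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    scale = np.abs(ts.values).max()
    degenerate = np.flatnonzero(np.abs(x).max(axis=1) <= 1e-12 * max(scale, 1.0))
    analytic = signal.hilbert(x, axis=1)
    return PhaseField(
        phases=np.angle(analytic),
        tr=ts.tr,
        amplitudes=np.abs(analytic),
        degenerate_nodes=degenerate,
    )


def pairwise_distances(centroids: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix (mm) between parcel centroids."""
    c = np.asarray(centroids, dtype=float)
    if c.ndim != 2:
        raise ValueError("centroids must be an n x d array")
    if not np.isfinite(c).all():
        raise ValueError("centroids contain non-finite coordinates")
    diff = c[:, None, :] - c[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return d
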