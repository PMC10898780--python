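"""Simulated attack: translate focal lesions into connectome disconnections.

Pipeline: per-patient lesion masks are overlapped with the parcellation
and normalised by node volume; nodes whose overlap exceeds a threshold
(mean + k SD of the pooled positive overlaps) form each patient's attack
set; the per-node lesion frequency across patients defines a node
factor — 0 for a binary deletion, 1 - frequency/n_patients for the
weighted down-regulation — and the node factors are combined into a
symmetric N x N multiplicative mask applied elementwise to the
structural connectome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hopf import StructuralConnectome

__all__ = [
    "LesionMaskMatrix",
    "compute_overlap",
    "nodes_to_attack",
    "lesion_mask_matrix",
    "apply_attack",
]


@dataclass
class LesionMaskMatrix:
    """N x N multiplicative disconnection factors in [0, 1]."""

    M: np.ndarray
    mode: str  # binary | weighted
    threshold_sd: float | None
    attacked: np.ndarray  # union attack set (node indices)

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != self.M.shape[1]:
            raise ValueError("mask must be square")
        if np.any(self.M < 0) or np.any(self.M > 1):
            raise ValueError("mask entries must lie in [0, 1]")
        if not np.allclose(self.M, self.M.T):
            raise ValueError("mask must be symmetric")


def _as_array(img):
    """Accept a numpy array or anything with get_fdata (e.g. a NIfTI image)."""
    if hasattr(img, "get_fdata"):
        return np.asanyarray(img.get_fdata())
    return np.asarray(img)


def compute_overlap(lesion_masks, parcellation) -> pd.DataFrame:
    """Lesion/node overlap fractions from voxel grids.

    Parameters
    ----------
    lesion_masks : sequence of boolean/binary voxel grids (or NIfTI
        images), one per patient, aligned with ``parcellation``.
    parcellation : integer-labelled voxel grid (or NIfTI image); label 0
        is background, labels 1..N are nodes.

    Returns a patients x nodes DataFrame of fractions: lesioned voxels
    inside the node divided by the node's voxel count.
    """
    parc = _as_array(parcellation).astype(int)
    labels = np.unique(parc)
    labels = labels[labels > 0]
    n_nodes = int(labels.max())
    node_counts = np.bincount(parc.ravel(), minlength=n_nodes + 1)[1:]
    rows = []
    for mask in lesion_masks:
        m = _as_array(mask)
        if m.shape != parc.shape:
            raise ValueError("lesion mask and parcellation grids are misaligned")
        lesioned = np.bincount(parc[m.astype(bool)].ravel(), minlength=n_nodes + 1)[1:]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(node_counts > 0, lesioned / node_counts, 0.0)
        rows.append(frac)
    return pd.DataFrame(rows, columns=[f"node{i}" for i in range(1, n_nodes + 1)])


def nodes_to_attack(table: pd.DataFrame | np.ndarray, k_sd: float):
    """Threshold the overlap table into per-patient attack sets.

    The threshold is tau = mean + k_sd * SD (population SD) of the
    positive overlap values pooled across all patients and nodes; node n
    is attacked for patient p when overlap(p, n) >= tau.

    Returns (per-patient list of node-index arrays, union array,
    per-node lesion frequency array).
    """
    if k_sd <= 0:
        raise ValueError("k_sd must be positive")
    values = table.to_numpy() if isinstance(table, pd.DataFrame) else np.asarray(table, dtype=float)
    if np.any(values < 0) or np.any(values > 1) or not np.isfinite(values).all():
        raise ValueError("overlap fractions must be finite and in [0, 1]")
    pos = values[values > 0]
    if pos.size == 0:
        warnings.warn("all-zero overlap table: empty attack sets")
        n_nodes = values.shape[1]
        return (
            [np.array([], dtype=int) for _ in range(values.shape[0])],
            np.array([], dtype=int),
            np.zeros(n_nodes, dtype=int),
        )
    tau = pos.mean() + k_sd * pos.std()  # population SD
    per_patient = [np.flatnonzero(row >= tau) for row in values]
    freq = (values >= tau).sum(axis=0).astype(int)
    union = np.flatnonzero(freq > 0)
    return per_patient, union, freq


def lesion_mask_matrix(
    attack_sets,
    n_nodes: int,
    n_patients: int,
    mode: str = "binary",
    threshold_sd: float | None = None,
    pair_combine: str = "min",
) -> LesionMaskMatrix:
    """Build the multiplicative disconnection mask from attack sets.

    Each attacked node n gets a factor f_n: 0 in binary mode, or
    1 - freq_n / n_patients in weighted mode, where freq_n counts the
    patients attacking n.  Unattacked nodes have f = 1.  The pair entry
    M[n, p] combines the endpoint factors by ``pair_combine`` (min by
    default; 'product' double-penalises doubly-attacked pairs).
    """
    if mode not in ("binary", "weighted"):
        raise ValueError("mode must be 'binary' or 'weighted'")
    if pair_combine not in ("min", "product"):
        raise ValueError("pair_combine must be 'min' or 'product'")
    freq = np.zeros(n_nodes, dtype=int)
    for s in attack_sets:
        freq[np.asarray(s, dtype=int)] += 1
    f = np.ones(n_nodes)
    attacked = np.flatnonzero(freq > 0)
    if mode == "binary":
        f[attacked] = 0.0
    else:
        f[attacked] = 1.0 - freq[attacked] / n_patients
    if pair_combine == "min":
        M = np.minimum(f[:, None], f[None, :])
    else:
        M = np.outer(f, f)
    return LesionMaskMatrix(M=M, mode=mode, threshold_sd=threshold_sd, attacked=attacked)


def apply_attack(connectome: StructuralConnectome, mask: LesionMaskMatrix) -> StructuralConnectome:
    """Multiply the connectome elementwise by the disconnection mask."""
    if mask.M.shape != connectome.C.shape:
        raise ValueError("mask and connectome shapes differ")
    return StructuralConnectome(
        C=connectome.C * mask.M,
        provenance="attacked",
        lambda_c=connectome.lambda_c,
        distances=connectome.distances,
    )
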