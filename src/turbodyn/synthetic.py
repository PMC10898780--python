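"""Synthetic brain geometries, connectomes, lesions and BOLD cohorts.

Everything downstream of raw fMRI is exercisable without downloads:

- :func:`make_geometry` samples parcel centroids inside two mirrored
  ellipsoidal hemispheres (~150 mm total span, matching the 3-150 mm
  pairwise-distance range the spatial-scale grid is annotated with),
  assigns seven spatially contiguous resting-state-network labels by
  k-means, and draws per-node volumes in voxel counts;
- :func:`make_lesion_cohort` plants spherical focal lesions and returns
  the per-patient node-overlap table (analytic sphere-sphere overlap;
  a voxelised oracle cross-checks it in the test suite);
- :func:`make_cohort` generates a two-group BOLD cohort with the Hopf
  whole-brain simulator: a control-like group at coupling ``G_control``
  on the intact exponential-distance-rule connectome, and an
  injury-like group at the strictly lower ``G_injury`` on a
  lesion-attacked connectome — the direction of effect reported for
  traumatic brain injury.

Defaults emulate a typical resting-state acquisition: 145 retained
volumes at TR = 2 s, 10-14 subjects per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hopf import BASELINE_A, HopfConfig, StructuralConnectome, build_edr_connectome, simulate_batch
from .lesions import lesion_mask_matrix, apply_attack, nodes_to_attack
from .phases import BoldTimeseries, pairwise_distances

__all__ = [
    "ParcelGeometry",
    "SyntheticCohort",
    "make_geometry",
    "make_lesion_cohort",
    "make_cohort",
    "write_geometry",
    "read_geometry",
    "write_cohort",
]

RSN_NAMES = ("VIS", "SM", "DAT", "VAT", "LIM", "CNT", "DMN")

#: Hemisphere ellipsoid semi-axes (mm) and centre offset along x (mm).
#: Two mirrored ellipsoids spanning ~150 mm left-right overall.
HEMI_SEMI_AXES = (35.0, 42.5, 30.0)
HEMI_OFFSET_X = 40.0


@dataclass
class ParcelGeometry:
    """Parcel centroids (mm), distances, network labels and volumes."""

    centroids: np.ndarray  # (N, 3) mm
    rsn_labels: np.ndarray  # (N,) strings from RSN_NAMES
    node_volumes: np.ndarray  # (N,) voxel counts, > 0
    hemisphere: np.ndarray  # (N,) 0 = left, 1 = right
    distances: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.node_volumes = np.asarray(self.node_volumes)
        if np.any(self.node_volumes <= 0):
            raise ValueError("all node volumes must be positive")
        self.distances = pairwise_distances(self.centroids)

    @property
    def n_nodes(self) -> int:
        return self.centroids.shape[0]


@dataclass
class SyntheticCohort:
    """Two-group synthetic BOLD cohort with ground-truth couplings."""

    bold: list[BoldTimeseries]
    subject_ids: list[str]
    groups: list[str]  # control-like | injury-like
    g_true: list[float]
    tr: float
    geometry: ParcelGeometry
    connectome: StructuralConnectome
    attacked_connectome: StructuralConnectome | None
    overlap_table: pd.DataFrame | None
    omega: np.ndarray

    def by_group(self, group: str) -> list[BoldTimeseries]:
        return [b for b, g in zip(self.bold, self.groups) if g == group]


def _sample_in_ellipsoid(rng: np.random.Generator, n: int, semi_axes, center) -> np.ndarray:
    """Uniform points inside an axis-aligned ellipsoid (rejection-free)."""
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    r = rng.uniform(0, 1, n) ** (1 / 3)
    return u * r[:, None] * np.asarray(semi_axes) + np.asarray(center)


def make_geometry(n_nodes: int, seed: int) -> ParcelGeometry:
    """Brain-like parcel geometry: two mirrored hemispheric ellipsoids.

    Nodes are split (near-)evenly between hemispheres; seven RSN labels
    come from a seeded spatial k-means so networks are contiguous.
    Deterministic for a fixed seed.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    n_left = n_nodes // 2
    n_right = n_nodes - n_left
    left = _sample_in_ellipsoid(rng, n_left, HEMI_SEMI_AXES, (-HEMI_OFFSET_X, 0.0, 0.0))
    right = _sample_in_ellipsoid(rng, n_right, HEMI_SEMI_AXES, (HEMI_OFFSET_X, 0.0, 0.0))
    centroids = np.vstack([left, right])
    hemisphere = np.concatenate([np.zeros(n_left, dtype=int), np.ones(n_right, dtype=int)])

    if n_nodes >= len(RSN_NAMES):
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=len(RSN_NAMES), n_init=4, random_state=int(seed) % (2**31))
        cluster = km.fit_predict(centroids)
        # name clusters back-to-front so labels are spatially ordered
        order = np.argsort(km.cluster_centers_[:, 1])
        name_of = {int(c): RSN_NAMES[i] for i, c in enumerate(order)}
        labels = np.array([name_of[int(c)] for c in cluster])
    else:
        labels = np.array([RSN_NAMES[i % len(RSN_NAMES)] for i in range(n_nodes)])

    # node volumes (1 mm^3 voxels) partition the brain volume on average,
    # with log-normal spread as in real parcellations
    brain_vol = 2 * (4.0 / 3.0) * np.pi * np.prod(HEMI_SEMI_AXES)
    volumes = np.maximum(
        np.round((brain_vol / n_nodes) * rng.lognormal(-0.045, 0.3, size=n_nodes)), 1
    ).astype(int)
    return ParcelGeometry(
        centroids=centroids, rsn_labels=labels, node_volumes=volumes, hemisphere=hemisphere
    )


def _sphere_intersection_volume(R: float, r: float, d: float) -> float:
    """Volume of the intersection of two spheres with radii R, r at distance d."""
    if d >= R + r:
        return 0.0
    if d <= abs(R - r):
        rmin = min(R, r)
        return 4.0 / 3.0 * np.pi * rmin**3
    return (
        np.pi
        * (R + r - d) ** 2
        * (d**2 + 2 * d * (r + R) - 3 * (r - R) ** 2)
        / (12 * d)
    )


def node_radius_mm(node_volume_voxels: float, voxel_mm: float = 1.0) -> float:
    """Equivalent-sphere radius for a node of given voxel volume."""
    return (3.0 * node_volume_voxels * voxel_mm**3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def make_lesion_cohort(
    geometry: ParcelGeometry,
    n_patients: int,
    foci: int = 2,
    radius_mm: float = 15.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Spherical focal lesions per patient -> node overlap fractions.

    Each focus centre is placed at a randomly chosen parcel centroid
    (lesions arise in tissue, not in empty space).  A node's overlap is
    the lesioned share of its equivalent-sphere volume, summed over foci
    and clipped to [0, 1].
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be nonnegative")
    if n_patients < 1 or foci < 0:
        raise ValueError("need n_patients >= 1 and foci >= 0")
    rng = np.random.default_rng(seed)
    n = geometry.n_nodes
    node_r = np.array([node_radius_mm(v) for v in geometry.node_volumes])
    rows = np.zeros((n_patients, n))
    if radius_mm > 0 and foci > 0:
        for p in range(n_patients):
            centers = geometry.centroids[rng.integers(0, n, size=foci)]
            for c in centers:
                d = np.linalg.norm(geometry.centroids - c, axis=1)
                for j in range(n):
                    vol = _sphere_intersection_volume(radius_mm, node_r[j], d[j])
                    rows[p, j] += vol / (4.0 / 3.0 * np.pi * node_r[j] ** 3)
        rows = np.clip(rows, 0.0, 1.0)
    return pd.DataFrame(
        rows,
        index=[f"patient{p}" for p in range(n_patients)],
        columns=[f"node{j}" for j in range(n)],
    )


def make_cohort(
    geometry: ParcelGeometry,
    n_per_group: int = 6,
    G_control: float = 1.6,
    G_injury: float = 0.9,
    T: int = 145,
    TR: float = 2.0,
    seed: int = 0,
    lesion_kwargs: dict | None = None,
    attack_k_sd: float = 1.5,
    attack_mode: str = "weighted",
) -> SyntheticCohort:
    """Two-group synthetic BOLD cohort from the Hopf simulator.

    Control-like subjects run at ``G_control`` on the intact EDR
    connectome; injury-like subjects at ``G_injury`` (< G_control) on a
    connectome attacked with a lesion mask derived from a synthetic
    focal-lesion cohort.  Subject i of both groups shares a noise
    sub-seed, so group contrasts are paired by subject index.
    """
    if not G_injury < G_control:
        raise ValueError("require G_injury < G_control")
    for g in (G_control, G_injury):
        if not 0 <= g <= 3:
            raise ValueError("G values must lie in the sweep range [0, 3]")
    if T < 50:
        raise ValueError("need at least 50 volumes")

    rng = np.random.default_rng(seed)
    n = geometry.n_nodes
    omega = 2 * np.pi * rng.uniform(0.04, 0.07, size=n)  # Hz -> rad/s

    connectome = build_edr_connectome(geometry)
    overlap = make_lesion_cohort(
        geometry,
        n_patients=n_per_group,
        seed=int(rng.integers(2**31)),
        **(lesion_kwargs or {}),
    )
    sets, _, _ = nodes_to_attack(overlap, k_sd=attack_k_sd)
    mask = lesion_mask_matrix(sets, n, n_per_group, mode=attack_mode, threshold_sd=attack_k_sd)
    attacked = apply_attack(connectome, mask)

    base = HopfConfig(a=BASELINE_A, omega=omega, nu=0.01, duration=T * TR, tr=TR)
    subject_seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n_per_group)]

    bold: list[BoldTimeseries] = []
    ids, groups, g_true = [], [], []
    for group, G, conn in (
        ("control-like", G_control, connectome),
        ("injury-like", G_injury, attacked),
    ):
        cfg = HopfConfig(a=BASELINE_A, omega=omega, G=G, nu=base.nu, duration=T * TR, tr=TR)
        for i in range(n_per_group):
            out = simulate_batch(conn, cfg, G_values=np.array([G]), seed=subject_seeds[i])
            bold.append(BoldTimeseries(values=out[0][:, :T], tr=TR))
            ids.append(f"{'ctrl' if group == 'control-like' else 'inj'}{i:02d}")
            groups.append(group)
            g_true.append(G)

    return SyntheticCohort(
        bold=bold,
        subject_ids=ids,
        groups=groups,
        g_true=g_true,
        tr=TR,
        geometry=geometry,
        connectome=connectome,
        attacked_connectome=attacked,
        overlap_table=overlap,
        omega=omega,
    )


# ---------------------------------------------------------------------------
# text I/O

def write_geometry(geometry: ParcelGeometry, path) -> None:
    """Write the centroid table: node, x, y, z, volume, rsn, hemisphere."""
    df = pd.DataFrame(
        {
            "node": np.arange(geometry.n_nodes),
            "x": geometry.centroids[:, 0],
            "y": geometry.centroids[:, 1],
            "z": geometry.centroids[:, 2],
            "volume": geometry.node_volumes,
            "rsn": geometry.rsn_labels,
            "hemisphere": geometry.hemisphere,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_geometry(path) -> ParcelGeometry:
    df = pd.read_csv(path, sep="\t")
    return ParcelGeometry(
        centroids=df[["x", "y", "z"]].to_numpy(),
        rsn_labels=df["rsn"].to_numpy(),
        node_volumes=df["volume"].to_numpy(),
        hemisphere=df["hemisphere"].to_numpy(),
    )


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """One delimited matrix per subject plus a manifest and geometry table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for sid, group, g, ts in zip(cohort.subject_ids, cohort.groups, cohort.g_true, cohort.bold):
        fname = f"{sid}_bold.tsv"
        np.savetxt(out / fname, ts.values, delimiter="\t")
        rows.append({"subject": sid, "group": group, "g_true": g, "tr": cohort.tr, "file": fname})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    write_geometry(cohort.geometry, out / "geometry.tsv")


def export_nifti(geometry: ParcelGeometry, out_dir, lesion_centers=None, lesion_radius_mm: float = 15.0,
                 voxel_mm: float = 4.0):
    """Optional NIfTI export of a voxelised parcellation (+ lesion masks).

    Exercises the volumetric ingestion path: voxels inside either
    hemisphere ellipsoid are labelled by nearest centroid; lesion masks
    are spheres.  Coarse voxels keep the files small.
    """
    import nibabel as nib

    lim = np.array([HEMI_OFFSET_X + HEMI_SEMI_AXES[0], HEMI_SEMI_AXES[1], HEMI_SEMI_AXES[2]])
    axes = [np.arange(-l, l + voxel_mm, voxel_mm) for l in lim]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    inside = np.zeros(gx.shape, dtype=bool)
    for sign in (-1, 1):
        q = (pts - np.array([sign * HEMI_OFFSET_X, 0, 0])) / np.array(HEMI_SEMI_AXES)
        inside |= (q**2).sum(axis=-1) <= 1.0
    flat = pts[inside]
    d2 = ((flat[:, None, :] - geometry.centroids[None, :, :]) ** 2).sum(axis=-1)
    label = np.zeros(gx.shape, dtype=np.int16)
    label[inside] = np.argmin(d2, axis=1) + 1
    affine = np.diag([voxel_mm] * 3 + [1.0])
    affine[:3, 3] = -lim
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(label, affine), out / "parcellation.nii")
    masks = []
    for k, c in enumerate(lesion_centers or []):
        m = ((pts - np.asarray(c)) ** 2).sum(axis=-1) <= lesion_radius_mm**2
        m &= inside
        img = nib.Nifti1Image(m.astype(np.uint8), affine)
        nib.save(img, out / f"lesion{k}.nii")
        masks.append(img)
    return label, masks
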