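"""Straight-loop reference implementations used as independent oracles.

These deliberately mirror the defining formulas with explicit Python
loops and stay independent of the vectorised package code paths.
"""

import numpy as np


def local_order_loop(phases, distances, lam):
    n, T = phases.shape
    R = np.zeros((n, T))
    theta = np.zeros((n, T))
    for i in range(n):
        w = np.array([np.exp(-lam * distances[i, p]) for p in range(n)])
        for t in range(T):
            z = 0j
            for p in range(n):
                z += w[p] * np.exp(1j * phases[p, t])
            z /= w.sum()
            R[i, t] = abs(z)
            theta[i, t] = np.angle(z)
    return R, theta


def pooled_std_loop(R):
    vals = [R[i, t] for i in range(R.shape[0]) for t in range(R.shape[1])]
    m = sum(vals) / len(vals)
    m2 = sum(v * v for v in vals) / len(vals)
    return np.sqrt(max(m2 - m * m, 0.0))


def nlm_loop(R):
    out = []
    for i in range(R.shape[0]):
        row = R[i]
        m = sum(row) / len(row)
        m2 = sum(v * v for v in row) / len(row)
        out.append(np.sqrt(max(m2 - m * m, 0.0)))
    return np.array(out)


def pearson_loop(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / np.sqrt(sxx * syy)


def fc_profile_loop(values, distances, bins, range_mm):
    """Binned mean pair correlation, double loop over pairs."""
    n = values.shape[0]
    lo, hi = range_mm
    edges = np.linspace(lo, hi, bins + 1)
    sums = np.zeros(bins)
    counts = np.zeros(bins, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = distances[i, j]
            if d < lo or d > hi:
                continue
            b = min(int(np.searchsorted(edges, d, side="right")) - 1, bins - 1)
            sums[b] += pearson_loop(values[i], values[j])
            counts[b] += 1
    fc = np.full(bins, np.nan)
    fc[counts > 0] = sums[counts > 0] / counts[counts > 0]
    return fc


def fitting_error_loop(fc_a, fc_b):
    s = 0.0
    for a, b in zip(fc_a, fc_b):
        if np.isfinite(a) and np.isfinite(b):
            s += (a - b) ** 2
    return np.sqrt(s)


def chi_loop(diffs):
    """diffs: trials x nodes array of time-mean perturbed - unperturbed R."""
    trials, nodes = diffs.shape
    node_means = []
    for nidx in range(nodes):
        node_means.append(sum(diffs[t, nidx] for t in range(trials)) / trials)
    return sum(node_means) / nodes


def capability_loop(diffs, moment="std"):
    trials, nodes = diffs.shape
    out = []
    for nidx in range(nodes):
        vals = [diffs[t, nidx] for t in range(trials)]
        m = sum(vals) / trials
        m2 = sum(v * v for v in vals) / trials
        var = max(m2 - m * m, 0.0)
        out.append(np.sqrt(var) if moment == "std" else var)
    return sum(out) / nodes


def ksd_loop(a, b):
    grid = sorted(list(a) + list(b))
    best = 0.0
    for x in grid:
        ea = sum(1 for v in a if v <= x) / len(a)
        eb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(ea - eb))
    return best


def bh_loop(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(p[i] * m / rank, prev)
        adj[i] = min(val, 1.0)
        prev = adj[i]
    return np.array(adj)


def voxel_overlap_loop(centroids, node_radii, focus, lesion_radius, voxel=1.0):
    """Voxelised lesion/node overlap fractions (brute force).

    Each node is the sphere of radius node_radii[j] around its centroid;
    the lesion is a sphere at ``focus``.  Voxels are sampled on a cubic
    grid of spacing ``voxel`` inside each node's bounding box.
    """
    fracs = []
    for c, rn in zip(centroids, node_radii):
        ax = [np.arange(c[k] - rn, c[k] + rn + voxel, voxel) for k in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        inside_node = ((pts - c) ** 2).sum(1) <= rn**2
        n_node = inside_node.sum()
        if n_node == 0:
            fracs.append(0.0)
            continue
        inside_lesion = ((pts - focus) ** 2).sum(1) <= lesion_radius**2
        fracs.append(float((inside_node & inside_lesion).sum() / n_node))
    return np.array(fracs)
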