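"""Independent oracles used by the tests.

Deliberately written with different algorithms from the package code paths
they check (plane-projection/2D tests instead of Voronoi-region case
analysis; grid search plus local refinement instead of SVD), so agreement is
evidence, not tautology.
"""

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation


def closest_point_plane_method(p, a, b, c):
    """Closest point on one triangle via plane projection + edge clamping."""
    n = np.cross(b - a, c - a)
    n = n / np.linalg.norm(n)
    q = p - np.dot(p - a, n) * n
    # barycentric coordinates of the projection
    m = np.column_stack([b - a, c - a])
    uv, *_ = np.linalg.lstsq(m, q - a, rcond=None)
    u, v = uv
    if u >= 0 and v >= 0 and u + v <= 1:
        return q
    best, bd = None, np.inf
    for p0, p1 in ((a, b), (a, c), (b, c)):
        d01 = p1 - p0
        t = np.clip(np.dot(p - p0, d01) / np.dot(d01, d01), 0.0, 1.0)
        cand = p0 + t * d01
        dist = np.linalg.norm(p - cand)
        if dist < bd:
            best, bd = cand, dist
    return best


def brute_force_nearest(mesh, p):
    """Exhaustive loop over all faces; returns (point, distance)."""
    v, f = mesh.vertices, mesh.faces
    best, bd = None, np.inf
    for i in range(len(f)):
        cand = closest_point_plane_method(p, v[f[i, 0]], v[f[i, 1]], v[f[i, 2]])
        dist = np.linalg.norm(p - cand)
        if dist < bd:
            best, bd = cand, dist
    return best, bd


def brute_force_rigid_residual(src, dst, n_grid=12):
    """Min sum-of-squares rigid residual by rotation-space grid + refinement.

    For each candidate rotation the optimal translation is closed-form
    (centroid match), so only SO(3) is searched: a coarse rotation-vector
    grid followed by Nelder-Mead polish from the best grid points.
    """
    src, dst = np.asarray(src, float), np.asarray(dst, float)
    sc, dc = src.mean(0), dst.mean(0)
    s0, d0 = src - sc, dst - dc

    def cost(rv):
        r = Rotation.from_rotvec(rv).as_matrix()
        return float(np.sum((s0 @ r.T - d0) ** 2))

    # Fibonacci-ish axis sampling x angle grid
    golden = np.pi * (3 - np.sqrt(5))
    axes = []
    for i in range(n_grid):
        z = 1 - 2 * (i + 0.5) / n_grid
        r = np.sqrt(1 - z * z)
        th = golden * i
        axes.append([r * np.cos(th), r * np.sin(th), z])
    angles = np.linspace(0, np.pi, n_grid)
    cands = sorted(((cost(np.asarray(ax) * an), np.asarray(ax) * an)
                    for ax in axes for an in angles), key=lambda t: t[0])
    best = np.inf
    for _, rv in cands[:5]:
        res = minimize(cost, rv, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14,
                                "maxiter": 5000})
        best = min(best, float(res.fun))
    return best


def folded_normal_mean(sigma):
    """E|N(0, sigma^2)| — expected distance of Gaussian offsets to a plane."""
    return sigma * np.sqrt(2.0 / np.pi)


def two_pass_mean_sd(values):
    """From-scratch two-pass mean and n-1 SD."""
    values = list(values)
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, var ** 0.5
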