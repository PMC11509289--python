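"""Exact closest-point-on-mesh queries via an AABB tree.

A median-split bounding-box hierarchy over the faces, traversed
branch-and-bound with the current best squared distance as the pruning
bound, with an exact scalar closest-point-on-triangle (Voronoi-region case
analysis) at the leaves. The traversal visits every leaf whose box could
contain a closer point, so results are exact for any triangle soup,
including the long sliver faces produced by carved surfaces.

Numba-compiled; the first query in a process pays the JIT cost.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LEAF_SIZE = 8


def build_aabb_tree(vertices: np.ndarray, faces: np.ndarray):
    """Flat AABB-tree arrays: (bbmin, bbmax, left, right, start, count, perm).

    Internal nodes store child indices; leaves store a slice of ``perm``
    (face ids). Built by median split along the widest centroid axis.
    """
    tri = vertices[faces]
    fmin = tri.min(axis=1)
    fmax = tri.max(axis=1)
    cent = tri.mean(axis=1)

    bbmin, bbmax, left, right, start, count = [], [], [], [], [], []
    perm_out = []

    # iterative stack of (face-index-array, parent-slot) to avoid deep recursion
    stack = [(np.arange(len(faces)), -1, False)]
    while stack:
        idx, parent, is_right = stack.pop()
        node = len(bbmin)
        bbmin.append(fmin[idx].min(axis=0))
        bbmax.append(fmax[idx].max(axis=0))
        left.append(-1)
        right.append(-1)
        start.append(-1)
        count.append(0)
        if parent >= 0:
            (right if is_right else left)[parent] = node
        if len(idx) <= _LEAF_SIZE:
            start[node] = len(perm_out)
            count[node] = len(idx)
            perm_out.extend(idx.tolist())
        else:
            c = cent[idx]
            axis = int(np.argmax(c.max(axis=0) - c.min(axis=0)))
            order = np.argsort(c[:, axis], kind="stable")
            half = len(idx) // 2
            # push right first so the left child is processed (numbered) first
            stack.append((idx[order[half:]], node, True))
            stack.append((idx[order[:half]], node, False))

    return (np.asarray(bbmin, float), np.asarray(bbmax, float),
            np.asarray(left, np.int64), np.asarray(right, np.int64),
            np.asarray(start, np.int64), np.asarray(count, np.int64),
            np.asarray(perm_out, np.int64))


@njit(cache=False)
def _closest_on_tri(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Exact closest point on one triangle (Ericson 5.1.5), scalar form."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        return ax + t * abx, ay + t * aby, az + t * abz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        return ax + t * acx, ay + t * acy, az + t * acz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (bx + t * (cx - bx), by + t * (cy - by), bz + t * (cz - bz))
    denom = va + vb + vc
    v = vb / denom
    w = vc / denom
    return (ax + v * abx + w * acx, ay + v * aby + w * acy,
            az + v * abz + w * acz)


@njit(cache=False)
def _box_dist2(px, py, pz, bmin, bmax):
    d = 0.0
    t = bmin[0] - px
    if t > 0.0:
        d += t * t
    t = px - bmax[0]
    if t > 0.0:
        d += t * t
    t = bmin[1] - py
    if t > 0.0:
        d += t * t
    t = py - bmax[1]
    if t > 0.0:
        d += t * t
    t = bmin[2] - pz
    if t > 0.0:
        d += t * t
    t = pz - bmax[2]
    if t > 0.0:
        d += t * t
    return d


@njit(cache=False)
def query_aabb_tree(points, vertices, faces, bbmin, bbmax, left, right,
                    start, count, perm):
    n = points.shape[0]
    out_cp = np.empty((n, 3))
    out_d = np.empty(n)
    out_f = np.empty(n, np.int64)
    stack = np.empty(128, np.int64)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        best = 1e300
        bqx = bqy = bqz = 0.0
        bf = -1
        sp = 0
        stack[sp] = 0
        sp += 1
        while sp > 0:
            sp -= 1
            node = stack[sp]
            if _box_dist2(px, py, pz, bbmin[node], bbmax[node]) >= best:
                continue
            if count[node] > 0:
                for k in range(start[node], start[node] + count[node]):
                    f = perm[k]
                    ia, ib, ic = faces[f, 0], faces[f, 1], faces[f, 2]
                    qx, qy, qz = _closest_on_tri(
                        px, py, pz,
                        vertices[ia, 0], vertices[ia, 1], vertices[ia, 2],
                        vertices[ib, 0], vertices[ib, 1], vertices[ib, 2],
                        vertices[ic, 0], vertices[ic, 1], vertices[ic, 2])
                    dx, dy, dz = qx - px, qy - py, qz - pz
                    d2 = dx * dx + dy * dy + dz * dz
                    if d2 < best:
                        best = d2
                        bqx, bqy, bqz = qx, qy, qz
                        bf = f
            else:
                l, r = left[node], right[node]
                dl = _box_dist2(px, py, pz, bbmin[l], bbmax[l])
                dr = _box_dist2(px, py, pz, bbmin[r], bbmax[r])
                # push the farther child first so the nearer is visited next
                if dl <= dr:
                    if dr < best:
                        stack[sp] = r
                        sp += 1
                    if dl < best:
                        stack[sp] = l
                        sp += 1
                else:
                    if dl < best:
                        stack[sp] = l
                        sp += 1
                    if dr < best:
                        stack[sp] = r
                        sp += 1
        out_cp[i, 0], out_cp[i, 1], out_cp[i, 2] = bqx, bqy, bqz
        out_d[i] = np.sqrt(best)
        out_f[i] = bf
    return out_cp, out_d, out_f
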