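"""Numba kernels for the Monte Carlo canopy tracer.

Randomness is a counter-based splitmix64 stream derived from (seed, ray
index), so tallies are bit-identical for a fixed seed no matter how rays
are batched or in what order surfaces were assembled.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SPLITMIX_GAMMA = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True, inline="always")
def _splitmix_next(state):
    state = state + _SPLITMIX_GAMMA
    z = state
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True, inline="always")
def _uniform(state):
    state, z = _splitmix_next(state)
    return state, (z >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(cache=True, inline="always")
def _ray_stream(seed, ray_index):
    s = (np.uint64(seed) * np.uint64(0x2545F4914F6CDD1D)) ^ (
        np.uint64(ray_index) * _SPLITMIX_GAMMA
    )
    # burn one step to decorrelate low-entropy seeds
    s, _ = _splitmix_next(s)
    return s


@njit(cache=True, inline="always")
def _cosine_hemisphere(nx, ny, nz, u1, u2):
    """Cosine-weighted direction about unit normal (nx, ny, nz)."""
    r = np.sqrt(u1)
    phi = 2.0 * np.pi * u2
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    z = np.sqrt(max(0.0, 1.0 - u1))
    # orthonormal basis around the normal (Frisvad-style branch)
    if nz < -0.9999999:
        t0x, t0y, t0z = 0.0, -1.0, 0.0
        t1x, t1y, t1z = -1.0, 0.0, 0.0
    else:
        a = 1.0 / (1.0 + nz)
        b = -nx * ny * a
        t0x, t0y, t0z = 1.0 - nx * nx * a, b, -nx
        t1x, t1y, t1z = b, 1.0 - ny * ny * a, -ny
    dx = x * t0x + y * t1x + z * nx
    dy = x * t0y + y * t1y + z * ny
    dz = x * t0z + y * t1z + z * nz
    return dx, dy, dz


@njit(cache=True, inline="always")
def _intersect_tri(ox, oy, oz, dx, dy, dz, v0, e1, e2):
    """Moller-Trumbore, two-sided. Returns t (inf when missed)."""
    px = dy * e2[2] - dz * e2[1]
    py = dz * e2[0] - dx * e2[2]
    pz = dx * e2[1] - dy * e2[0]
    det = e1[0] * px + e1[1] * py + e1[2] * pz
    if abs(det) < 1e-14:
        return np.inf
    inv = 1.0 / det
    tx = ox - v0[0]
    ty = oy - v0[1]
    tz = oz - v0[2]
    u = (tx * px + ty * py + tz * pz) * inv
    if u < -1e-9 or u > 1.0 + 1e-9:
        return np.inf
    qx = ty * e1[2] - tz * e1[1]
    qy = tz * e1[0] - tx * e1[2]
    qz = tx * e1[1] - ty * e1[0]
    v = (dx * qx + dy * qy + dz * qz) * inv
    if v < -1e-9 or u + v > 1.0 + 1e-9:
        return np.inf
    t = (e2[0] * qx + e2[1] * qy + e2[2] * qz) * inv
    if t < 1e-7:
        return np.inf
    return t


@njit(cache=True, inline="always")
def _slab_hit(ox, oy, oz, inv_dx, inv_dy, inv_dz, bmin, bmax, t_best):
    t1 = (bmin[0] - ox) * inv_dx
    t2 = (bmax[0] - ox) * inv_dx
    tmin = min(t1, t2)
    tmax = max(t1, t2)
    t1 = (bmin[1] - oy) * inv_dy
    t2 = (bmax[1] - oy) * inv_dy
    tmin = max(tmin, min(t1, t2))
    tmax = min(tmax, max(t1, t2))
    t1 = (bmin[2] - oz) * inv_dz
    t2 = (bmax[2] - oz) * inv_dz
    tmin = max(tmin, min(t1, t2))
    tmax = min(tmax, max(t1, t2))
    return tmax >= max(tmin, 0.0) and tmin < t_best


@njit(cache=True)
def trace_rays(
    v0,
    e1,
    e2,
    normal,
    tri_surface,
    node_min,
    node_max,
    node_left,
    node_right,
    node_start,
    node_count,
    tri_order,
    surf_alpha,
    surf_rho,
    src_cum,
    src_center,
    src_size,
    n_rays,
    max_bounces,
    seed,
):
    """Forward-trace n_rays; return (absorbed counts per surface, escaped)."""
    n_surf = surf_alpha.shape[0]
    counts = np.zeros(n_surf, dtype=np.int64)
    escaped = 0
    stack = np.empty(128, dtype=np.int64)

    for i in range(n_rays):
        state = _ray_stream(seed, i)

        # pick a source proportional to its power
        state, u = _uniform(state)
        si = src_cum.shape[0] - 1
        for k in range(src_cum.shape[0]):
            if u <= src_cum[k]:
                si = k
                break
        state, u1 = _uniform(state)
        state, u2 = _uniform(state)
        ox = src_center[si, 0] + (u1 - 0.5) * src_size[si, 0]
        oy = src_center[si, 1] + (u2 - 0.5) * src_size[si, 1]
        oz = src_center[si, 2]
        state, u1 = _uniform(state)
        state, u2 = _uniform(state)
        dx, dy, dz = _cosine_hemisphere(0.0, 0.0, -1.0, u1, u2)

        alive = True
        for _bounce in range(max_bounces + 1):
            # nearest hit via BVH
            inv_dx = 1.0 / dx if dx != 0.0 else np.inf
            inv_dy = 1.0 / dy if dy != 0.0 else np.inf
            inv_dz = 1.0 / dz if dz != 0.0 else np.inf
            t_best = np.inf
            hit_tri = -1
            sp = 0
            stack[sp] = 0
            sp = 1
            while sp > 0:
                sp -= 1
                node = stack[sp]
                if not _slab_hit(
                    ox, oy, oz, inv_dx, inv_dy, inv_dz,
                    node_min[node], node_max[node], t_best,
                ):
                    continue
                cnt = node_count[node]
                if cnt > 0:
                    start = node_start[node]
                    for j in range(start, start + cnt):
                        ti = tri_order[j]
                        t = _intersect_tri(ox, oy, oz, dx, dy, dz, v0[ti], e1[ti], e2[ti])
                        if t < t_best:
                            t_best = t
                            hit_tri = ti
                else:
                    stack[sp] = node_left[node]
                    sp += 1
                    stack[sp] = node_right[node]
                    sp += 1

            if hit_tri < 0:
                escaped += 1
                alive = False
                break

            sid = tri_surface[hit_tri]
            state, u = _uniform(state)
            a = surf_alpha[sid]
            r = surf_rho[sid]
            if u < a:
                counts[sid] += 1
                alive = False
                break

            # move to the hit point
            ox = ox + dx * t_best
            oy = oy + dy * t_best
            oz = oz + dz * t_best
            nx0 = normal[hit_tri, 0]
            ny0 = normal[hit_tri, 1]
            nz0 = normal[hit_tri, 2]
            # normal on the incident side
            if dx * nx0 + dy * ny0 + dz * nz0 > 0.0:
                nx0, ny0, nz0 = -nx0, -ny0, -nz0
            state, u1 = _uniform(state)
            state, u2 = _uniform(state)
            if u < a + r:  # diffuse reflection back into the incident hemisphere
                dx, dy, dz = _cosine_hemisphere(nx0, ny0, nz0, u1, u2)
            else:  # diffuse transmission into the far hemisphere
                dx, dy, dz = _cosine_hemisphere(-nx0, -ny0, -nz0, u1, u2)
            # nudge off the surface
            ox += dx * 1e-9
            oy += dy * 1e-9
            oz += dz * 1e-9
        if alive:  # exceeded max_bounces
            escaped += 1

    return counts, escaped


def build_bvh(triangles: np.ndarray, leaf_size: int = 4):
    """Median-split BVH over triangle centroids (numpy build, numba traverse).

    Returns arrays: node_min, node_max, node_left, node_right, node_start,
    node_count, tri_order. Internal nodes have count 0.
    """
    n = len(triangles)
    lo = triangles.min(axis=1)
    hi = triangles.max(axis=1)
    centroids = triangles.mean(axis=1)
    order = np.arange(n)

    node_min, node_max = [], []
    node_left, node_right = [], []
    node_start, node_count = [], []

    def new_node():
        node_min.append(np.zeros(3))
        node_max.append(np.zeros(3))
        node_left.append(-1)
        node_right.append(-1)
        node_start.append(-1)
        node_count.append(0)
        return len(node_min) - 1

    root = new_node()
    stack = [(root, 0, n)]
    while stack:
        node, start, end = stack.pop()
        idx = order[start:end]
        node_min[node] = lo[idx].min(axis=0)
        node_max[node] = hi[idx].max(axis=0)
        if end - start <= leaf_size:
            node_start[node] = start
            node_count[node] = end - start
            continue
        cmin = centroids[idx].min(axis=0)
        cmax = centroids[idx].max(axis=0)
        axis = int(np.argmax(cmax - cmin))
        if cmax[axis] - cmin[axis] <= 1e-12:
            node_start[node] = start
            node_count[node] = end - start
            continue
        local = np.argsort(centroids[idx, axis], kind="stable")
        order[start:end] = idx[local]
        mid = start + (end - start) // 2
        left = new_node()
        right = new_node()
        node_left[node] = left
        node_right[node] = right
        stack.append((left, start, mid))
        stack.append((right, mid, end))

    return (
        np.asarray(node_min, dtype=np.float64),
        np.asarray(node_max, dtype=np.float64),
        np.asarray(node_left, dtype=np.int64),
        np.asarray(node_right, dtype=np.int64),
        np.asarray(node_start, dtype=np.int64),
        np.asarray(node_count, dtype=np.int64),
        order.astype(np.int64),
    )
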