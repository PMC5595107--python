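"""Exact geometric primitives for needle–mesh proximity queries.

All routines operate on plain numpy arrays in millimetres.  The needle is a
straight segment (tip + exposed shaft); triangles come from watertight scene
meshes with outward-oriented normals.  These primitives are shared by the
octree index and the brute-force oracle so that the two paths agree to
floating-point precision.
"""

from __future__ import annotations

import numpy as np

# Tolerance for parallel/coplanar classification, relative to geometry scale.
_EPS = 1e-12


def closest_point_on_triangle(p: np.ndarray, a: np.ndarray, b: np.ndarray,
                              c: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``abc`` to point ``p`` (Ericson's method)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0.0 and d2 <= 0.0:
        return a
    bp = p - b
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0.0 and d4 <= d3:
        return b
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return a + v * ab
    cp = p - c
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0.0 and d5 <= d6:
        return c
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return a + w * ac
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w


def point_triangle_distance(p, a, b, c):
    """Distance and closest point from ``p`` to triangle ``abc``."""
    q = closest_point_on_triangle(np.asarray(p, dtype=float), a, b, c)
    return float(np.linalg.norm(p - q)), q


def segment_segment_closest(p1, q1, p2, q2):
    """Closest points between segments ``p1q1`` and ``p2q2``.

    Returns ``(distance, point_on_seg1, point_on_seg2)``.  Standard clamped
    parametric solution; degenerate (zero-length) segments are handled.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = d1 @ d1
    e = d2 @ d2
    f = d2 @ r
    if a <= _EPS and e <= _EPS:
        return float(np.linalg.norm(p1 - p2)), p1, p2
    if a <= _EPS:
        s = 0.0
        t = min(1.0, max(0.0, f / e))
    else:
        c = d1 @ r
        if e <= _EPS:
            t = 0.0
            s = min(1.0, max(0.0, -c / a))
        else:
            b = d1 @ d2
            denom = a * e - b * b
            if denom > _EPS * a * e:
                s = min(1.0, max(0.0, (b * f - c * e) / denom))
            else:
                s = 0.0
            t = (b * s + f) / e
            if t < 0.0:
                t = 0.0
                s = min(1.0, max(0.0, -c / a))
            elif t > 1.0:
                t = 1.0
                s = min(1.0, max(0.0, (b - c) / a))
    c1 = p1 + s * d1
    c2 = p2 + t * d2
    return float(np.linalg.norm(c1 - c2)), c1, c2


def _point_in_triangle_2d(p, a, b, c, tol):
    """Boundary-inclusive 2-D point-in-triangle via signed areas."""
    def cross(o, u, v):
        return (u[0] - o[0]) * (v[1] - o[1]) - (u[1] - o[1]) * (v[0] - o[0])
    d1 = cross(a, b, p)
    d2 = cross(b, c, p)
    d3 = cross(c, a, p)
    has_neg = (d1 < -tol) or (d2 < -tol) or (d3 < -tol)
    has_pos = (d1 > tol) or (d2 > tol) or (d3 > tol)
    return not (has_neg and has_pos)


def segment_triangle_intersection(p, q, a, b, c):
    """Parametric segment–triangle intersection; boundary touches count.

    Returns the intersection point closest to ``p``, or ``None``.  The
    coplanar case is resolved by projecting onto the triangle plane; a
    coplanar segment that does not cross the triangle region yields ``None``.

    Raises ``ValueError`` for a degenerate (zero-area) triangle.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    n = np.cross(b - a, c - a)
    n_norm = np.linalg.norm(n)
    scale = max(np.linalg.norm(b - a), np.linalg.norm(c - a), 1.0)
    if n_norm <= _EPS * scale * scale:
        raise ValueError("degenerate (zero-area) triangle")
    d = q - p
    denom = n @ d
    num = n @ (a - p)
    tol = _EPS * max(n_norm, 1.0) * max(np.linalg.norm(d), 1.0)
    if abs(denom) <= tol:
        # Segment parallel to the triangle plane.
        if abs(num) > _EPS * n_norm * max(scale, np.linalg.norm(p - a), 1.0):
            return None  # parallel, off-plane
        # Coplanar: work in the dominant-axis 2-D projection.
        k = int(np.argmax(np.abs(n)))
        idx = [i for i in range(3) if i != k]
        p2, q2 = p[idx], q[idx]
        a2, b2, c2 = a[idx], b[idx], c[idx]
        tol2 = _EPS * scale * scale
        if _point_in_triangle_2d(p2, a2, b2, c2, tol2):
            return p.copy()
        if _point_in_triangle_2d(q2, a2, b2, c2, tol2):
            # March from p: closest crossing is an edge hit; fall through to
            # the edge-intersection scan below to report the entry point.
            pass
        best_t = None
        for e0, e1 in ((a2, b2), (b2, c2), (c2, a2)):
            r = q2 - p2
            s = e1 - e0
            den = r[0] * s[1] - r[1] * s[0]
            if abs(den) <= tol2:
                continue
            t = ((e0[0] - p2[0]) * s[1] - (e0[1] - p2[1]) * s[0]) / den
            u = ((e0[0] - p2[0]) * r[1] - (e0[1] - p2[1]) * r[0]) / den
            if -_EPS <= t <= 1 + _EPS and -_EPS <= u <= 1 + _EPS:
                if best_t is None or t < best_t:
                    best_t = min(1.0, max(0.0, t))
        if best_t is None:
            return None
        return p + best_t * (q - p)
    t = num / denom
    if t < -_EPS or t > 1.0 + _EPS:
        return None
    t = min(1.0, max(0.0, t))
    x = p + t * d
    # Barycentric inside test with a boundary-inclusive tolerance.
    v0 = b - a
    v1 = c - a
    v2 = x - a
    d00 = v0 @ v0
    d01 = v0 @ v1
    d11 = v1 @ v1
    d20 = v2 @ v0
    d21 = v2 @ v1
    den = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    btol = 1e-10
    if v >= -btol and w >= -btol and v + w <= 1.0 + btol:
        return x
    return None


def segment_triangle_distance(p, q, a, b, c):
    """Minimum distance between segment ``pq`` and triangle ``abc``.

    Returns ``(distance, closest_point_on_triangle)``.  Zero iff the segment
    touches the triangle.  The non-intersecting minimum is attained either at
    a segment endpoint against the triangle, or between the segment and a
    triangle edge; all five candidates are evaluated.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    hit = segment_triangle_intersection(p, q, a, b, c)
    if hit is not None:
        return 0.0, hit
    best_d, best_pt = point_triangle_distance(p, a, b, c)
    d, pt = point_triangle_distance(q, a, b, c)
    if d < best_d:
        best_d, best_pt = d, pt
    for e0, e1 in ((a, b), (b, c), (c, a)):
        d, _, c2 = segment_segment_closest(p, q, e0, e1)
        if d < best_d:
            best_d, best_pt = d, c2
    return best_d, best_pt


def point_aabb_distance(p, lo, hi) -> float:
    """Distance from point ``p`` to axis-aligned box ``[lo, hi]``."""
    d = np.maximum(np.maximum(lo - p, 0.0), p - hi)
    return float(np.linalg.norm(d))


def segment_intersects_aabb(p, q, lo, hi) -> bool:
    """Slab test: does segment ``pq`` intersect the box ``[lo, hi]``?"""
    d = q - p
    tmin, tmax = 0.0, 1.0
    for i in range(3):
        if abs(d[i]) < _EPS:
            if p[i] < lo[i] or p[i] > hi[i]:
                return False
        else:
            inv = 1.0 / d[i]
            t1 = (lo[i] - p[i]) * inv
            t2 = (hi[i] - p[i]) * inv
            if t1 > t2:
                t1, t2 = t2, t1
            tmin = max(tmin, t1)
            tmax = min(tmax, t2)
            if tmin > tmax:
                return False
    return True


_BOX_EDGES = [
    (0, 1), (2, 3), (4, 5), (6, 7),   # x-aligned
    (0, 2), (1, 3), (4, 6), (5, 7),   # y-aligned
    (0, 4), (1, 5), (2, 6), (3, 7),   # z-aligned
]


def segment_aabb_distance(p, q, lo, hi) -> float:
    """Exact minimum distance between segment ``pq`` and box ``[lo, hi]``.

    Zero if the segment enters the box.  Otherwise the minimum is attained at
    a segment endpoint against the box, or between the segment and one of the
    12 box edges (segment-interior vs face-interior minima only occur for
    segments parallel to a face, which the endpoint case already covers).
    Used as the pruning lower bound in best-first octree descent.
    """
    if segment_intersects_aabb(p, q, lo, hi):
        return 0.0
    corners = np.array([[lo[0] if i & 1 == 0 else hi[0],
                         lo[1] if i & 2 == 0 else hi[1],
                         lo[2] if i & 4 == 0 else hi[2]] for i in range(8)])
    best = min(point_aabb_distance(p, lo, hi), point_aabb_distance(q, lo, hi))
    for i, j in _BOX_EDGES:
        d, _, _ = segment_segment_closest(p, q, corners[i], corners[j])
        if d < best:
            best = d
    return best


def triangle_aabb_overlap(a, b, c, lo, hi) -> bool:
    """Conservative triangle–box overlap: triangle AABB vs box.

    A superset of true overlap, which is sufficient (and safe) for octree
    triangle assignment.
    """
    tlo = np.minimum(np.minimum(a, b), c)
    thi = np.maximum(np.maximum(a, b), c)
    return bool(np.all(tlo <= hi) and np.all(thi >= lo))


# -- batched kernels ---------------------------------------------------------
# Vectorised counterparts of the scalar primitives above.  The octree query,
# the brute-force oracle and the crossing extraction all run on these, so the
# two proximity paths produce bit-identical per-triangle distances.

def _point_triangles_closest(p: np.ndarray, A, B, C) -> np.ndarray:
    """Closest point on each triangle ``(A[i], B[i], C[i])`` to point ``p``."""
    ab = B - A
    ac = C - A
    ap = p - A
    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - B
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - C
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    out = np.empty_like(A)
    done = np.zeros(len(A), dtype=bool)

    def take(mask, pts):
        mask = mask & ~done
        out[mask] = pts[mask]
        done[mask] = True

    def safe_div(num, den):
        return num / np.where(den != 0.0, den, 1.0)

    take((d1 <= 0) & (d2 <= 0), A)
    take((d3 >= 0) & (d4 <= d3), B)
    v = safe_div(d1, d1 - d3)
    take((vc <= 0) & (d1 >= 0) & (d3 <= 0), A + v[:, None] * ab)
    take((d6 >= 0) & (d5 <= d6), C)
    w = safe_div(d2, d2 - d6)
    take((vb <= 0) & (d2 >= 0) & (d6 <= 0), A + w[:, None] * ac)
    w = safe_div(d4 - d3, (d4 - d3) + (d5 - d6))
    take((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
         B + w[:, None] * (C - B))
    den = safe_div(np.ones_like(va), va + vb + vc)
    v = vb * den
    w = vc * den
    take(np.ones(len(A), dtype=bool), A + ab * v[:, None] + ac * w[:, None])
    return out


def _segment_segments_closest(p, q, E0, E1):
    """Closest approach of segment ``pq`` to each segment ``E0[i]E1[i]``.

    Returns ``(distances, points_on_pq, points_on_edges)``; assumes
    ``pq`` is non-degenerate.
    """
    d1 = q - p
    d2 = E1 - E0
    r = p - E0
    a = float(d1 @ d1)
    e = (d2 * d2).sum(1)
    f = (d2 * r).sum(1)
    c = r @ d1
    b = d2 @ d1
    denom = a * e - b * b
    s = np.where(denom > _EPS * a * e,
                 np.clip((b * f - c * e) / np.where(denom != 0, denom, 1.0),
                         0.0, 1.0),
                 0.0)
    e_safe = np.where(e > _EPS, e, 1.0)
    t = (b * s + f) / e_safe
    small_e = e <= _EPS
    s = np.where(small_e, np.clip(-c / a, 0.0, 1.0), s)
    t = np.where(small_e, 0.0, t)
    low = (~small_e) & (t < 0.0)
    s = np.where(low, np.clip(-c / a, 0.0, 1.0), s)
    t = np.where(low, 0.0, t)
    high = (~small_e) & (t > 1.0)
    s = np.where(high, np.clip((b - c) / a, 0.0, 1.0), s)
    t = np.where(high, 1.0, t)
    c1 = p + s[:, None] * d1
    c2 = E0 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1), c1, c2


def segment_triangles_hits(p, q, tris):
    """Batched segment–triangle intersection (non-parallel fast path).

    Returns ``(hit, t, X, parallel)``: per-row hit flag, segment parameter,
    intersection point, and a flag for rows parallel to the segment (those
    rows are never reported as hits here; callers needing the coplanar case
    must fall back to the scalar routine).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    A, B, C = tris[:, 0], tris[:, 1], tris[:, 2]
    n = np.cross(B - A, C - A)
    d = q - p
    denom = n @ d
    num = ((A - p) * n).sum(1)
    n_norm = np.linalg.norm(n, axis=1)
    tol = _EPS * np.maximum(n_norm, 1.0) * max(float(np.linalg.norm(d)), 1.0)
    parallel = np.abs(denom) <= tol
    t = num / np.where(parallel, 1.0, denom)
    in_range = (~parallel) & (t >= -_EPS) & (t <= 1.0 + _EPS)
    t = np.clip(t, 0.0, 1.0)
    X = p + t[:, None] * d
    v0 = B - A
    v1 = C - A
    v2 = X - A
    d00 = (v0 * v0).sum(1)
    d01 = (v0 * v1).sum(1)
    d11 = (v1 * v1).sum(1)
    d20 = (v2 * v0).sum(1)
    d21 = (v2 * v1).sum(1)
    den = d00 * d11 - d01 * d01
    den = np.where(den != 0.0, den, 1.0)
    v = (d11 * d20 - d01 * d21) / den
    w = (d00 * d21 - d01 * d20) / den
    btol = 1e-10
    hit = in_range & (v >= -btol) & (w >= -btol) & (v + w <= 1.0 + btol)
    return hit, t, X, parallel


def segment_triangles_distance(p, q, tris):
    """Minimum distance from segment ``pq`` to each triangle in ``tris``.

    ``tris`` has shape (m, 3, 3).  Returns ``(distances, closest_points)``
    with closest points on the triangles.  Rows parallel to the segment are
    resolved through the scalar coplanar-aware routine.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    tris = np.asarray(tris, dtype=float)
    m = len(tris)
    A, B, C = tris[:, 0], tris[:, 1], tris[:, 2]
    hit, _, X, parallel = segment_triangles_hits(p, q, tris)
    # Coplanar crossings are invisible to the batched plane test.
    for i in np.nonzero(parallel)[0]:
        x = segment_triangle_intersection(p, q, A[i], B[i], C[i])
        if x is not None:
            hit[i] = True
            X[i] = x

    cand_pts = np.empty((5, m, 3))
    cand_d = np.empty((5, m))
    for j, endpoint in enumerate((p, q)):
        cp = _point_triangles_closest(endpoint, A, B, C)
        cand_pts[j] = cp
        cand_d[j] = np.linalg.norm(endpoint - cp, axis=1)
    for j, (E0, E1) in enumerate(((A, B), (B, C), (C, A))):
        dd, _, c2 = _segment_segments_closest(p, q, E0, E1)
        cand_pts[2 + j] = c2
        cand_d[2 + j] = dd
    best = np.argmin(cand_d, axis=0)
    rows = np.arange(m)
    dist = cand_d[best, rows]
    pts = cand_pts[best, rows]
    dist = np.where(hit, 0.0, dist)
    pts = np.where(hit[:, None], X, pts)
    return dist, pts


def segments_aabbs_intersect(p, q, los, his):
    """Vectorised slab test of one segment against many boxes."""
    d = q - p
    nbox = len(los)
    ok = np.ones(nbox, dtype=bool)
    tmin = np.zeros(nbox)
    tmax = np.ones(nbox)
    for i in range(3):
        if abs(d[i]) < _EPS:
            ok &= (p[i] >= los[:, i]) & (p[i] <= his[:, i])
        else:
            inv = 1.0 / d[i]
            t1 = (los[:, i] - p[i]) * inv
            t2 = (his[:, i] - p[i]) * inv
            lo_ = np.minimum(t1, t2)
            hi_ = np.maximum(t1, t2)
            tmin = np.maximum(tmin, lo_)
            tmax = np.minimum(tmax, hi_)
    return ok & (tmin <= tmax)


def _points_aabbs_distance(pt, los, his):
    d = np.maximum(np.maximum(los - pt, 0.0), pt - his)
    return np.linalg.norm(d, axis=1)


def segment_aabbs_distance(p, q, los, his):
    """Exact segment-to-box lower bounds for many boxes at once.

    Same candidate structure as :func:`segment_aabb_distance` (intersection,
    endpoints, 12 box edges), evaluated with the batched kernels.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    los = np.asarray(los, dtype=float)
    his = np.asarray(his, dtype=float)
    nbox = len(los)
    out = np.zeros(nbox)
    inside = segments_aabbs_intersect(p, q, los, his)
    todo = ~inside
    if not todo.any():
        return out
    lo_t, hi_t = los[todo], his[todo]
    best = np.minimum(_points_aabbs_distance(p, lo_t, hi_t),
                      _points_aabbs_distance(q, lo_t, hi_t))
    corners = np.stack([np.where([i & 1, i & 2, i & 4], hi_t, lo_t)
                        for i in range(8)], axis=1)  # (n, 8, 3)
    E0 = corners[:, [e[0] for e in _BOX_EDGES], :].reshape(-1, 3)
    E1 = corners[:, [e[1] for e in _BOX_EDGES], :].reshape(-1, 3)
    dd, _, _ = _segment_segments_closest(p, q, E0, E1)
    best = np.minimum(best, dd.reshape(-1, 12).min(axis=1))
    out[todo] = best
    return out
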