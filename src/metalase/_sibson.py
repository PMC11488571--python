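"""Sibson natural-neighbor coordinates on a Delaunay triangulation.

For a query point q strictly inside the convex hull, conceptually inserting
q into the triangulation (Bowyer-Watson) carves a new Voronoi cell out of
the cells of q's natural neighbors.  The Sibson weight of neighbor v is the
area v loses, normalized by the total stolen area.  The interpolant is
linearly precise (reproduces affine fields exactly) and smooth away from
the data sites.

Implementation (Watson's method), per query:

1. locate the simplex containing q, then flood-fill the *cavity* — all
   triangles whose circumcircle contains q;
2. every cavity vertex is a natural neighbor; the area stolen from neighbor
   v is the intersection of v's old Voronoi cell with q's new cell.  That
   intersection is a convex polygon whose vertices are (a) the circumcenters
   of the cavity triangles incident to v (old Voronoi vertices captured by
   q) and (b) the circumcenters of (q, a, b) for the cavity boundary edges
   incident to v (new Voronoi vertices);
3. order each polygon's vertices angularly about its centroid (valid since
   it is convex) and take its shoelace area.

All geometry is computed in coordinates relative to q for conditioning.
Degenerate queries (on the hull boundary, collapsed polygons from
cocircular ties) fall back to barycentric interpolation on the containing
simplex, which preserves linear precision.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Delaunay


def _circumcircles(points: np.ndarray, simplices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Circumcenters and squared radii for all simplices."""
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    ab = b - a
    ac = c - a
    d = 2.0 * (ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    ab2 = (ab ** 2).sum(axis=1)
    ac2 = (ac ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = (ac[:, 1] * ab2 - ab[:, 1] * ac2) / d
        uy = (ab[:, 0] * ac2 - ac[:, 0] * ab2) / d
    centers = a + np.column_stack([ux, uy])
    r2 = ux ** 2 + uy ** 2
    return centers, r2


def _circumcenter_origin(ax: float, ay: float, bx: float, by: float) -> tuple[float, float]:
    """Circumcenter of (origin, a, b); a, b relative to the query point."""
    d = 2.0 * (ax * by - ay * bx)
    if d == 0.0:
        return math.inf, math.inf
    a2 = ax * ax + ay * ay
    b2 = bx * bx + by * by
    return (by * a2 - ay * b2) / d, (ax * b2 - bx * a2) / d


def _convex_area(pts: list[tuple[float, float]]) -> float:
    """Shoelace area of a convex vertex set, ordered about its centroid."""
    m = len(pts)
    if m < 3:
        return 0.0
    cx = sum(p[0] for p in pts) / m
    cy = sum(p[1] for p in pts) / m
    pts = sorted(pts, key=lambda p: math.atan2(p[1] - cy, p[0] - cx))
    s = 0.0
    for i in range(m):
        x0, y0 = pts[i]
        x1, y1 = pts[(i + 1) % m]
        s += x0 * y1 - x1 * y0
    return 0.5 * abs(s)


class NaturalNeighborInterpolator:
    """Sibson interpolation of one or more value columns over scattered sites.

    Parameters
    ----------
    tri:
        A scipy ``Delaunay`` triangulation of the data sites.
    values:
        Array of shape (n_sites, n_channels).

    Queries outside the convex hull return NaN.  Queries for which the
    Sibson construction degenerates numerically use barycentric (linear)
    interpolation on the containing simplex instead; the count is kept in
    ``n_fallback``.
    """

    def __init__(self, tri: Delaunay, values: np.ndarray):
        self.tri = tri
        self.values = np.atleast_2d(np.asarray(values, dtype=float))
        if self.values.shape[0] != tri.points.shape[0]:
            self.values = self.values.T
        if self.values.shape[0] != tri.points.shape[0]:
            raise ValueError("values must have one row per triangulation point")
        self._cc, self._r2 = _circumcircles(tri.points, tri.simplices)
        scale2 = float(((tri.points.max(axis=0) - tri.points.min(axis=0)) ** 2).sum())
        self._snap2 = scale2 * 1e-24  # coincidence tolerance (squared)
        self.n_fallback = 0

    def __call__(self, queries: np.ndarray) -> np.ndarray:
        queries = np.atleast_2d(np.asarray(queries, dtype=float))
        found = self.tri.find_simplex(queries)
        out = np.full((queries.shape[0], self.values.shape[1]), np.nan)
        for j in range(queries.shape[0]):
            s0 = found[j]
            if s0 < 0:
                continue
            out[j] = self._interp_one(queries[j], int(s0))
        return out

    # -- per-query machinery -------------------------------------------------

    def _barycentric(self, q: np.ndarray, s: int) -> np.ndarray:
        T = self.tri.transform[s]
        bc = T[:2].dot(q - T[2])
        w = np.concatenate([bc, [1.0 - bc.sum()]])
        return w @ self.values[self.tri.simplices[s]]

    def _interp_one(self, q: np.ndarray, s0: int) -> np.ndarray:
        pts = self.tri.points
        simplices = self.tri.simplices
        neighbors = self.tri.neighbors
        qx, qy = float(q[0]), float(q[1])

        # coincidence with a data site: weight 1 on that site
        for v in simplices[s0]:
            dx = pts[v, 0] - qx
            dy = pts[v, 1] - qy
            if dx * dx + dy * dy <= self._snap2:
                return self.values[v].copy()

        # cavity flood-fill over circumcircle membership
        cavity = {s0}
        stack = [s0]
        while stack:
            s = stack.pop()
            for nb in neighbors[s]:
                nb = int(nb)
                if nb >= 0 and nb not in cavity:
                    dx = qx - self._cc[nb, 0]
                    dy = qy - self._cc[nb, 1]
                    if dx * dx + dy * dy < self._r2[nb] * (1.0 + 1e-12):
                        cavity.add(nb)
                        stack.append(nb)

        # per natural neighbor: captured old circumcenters + new circumcenters
        # of the boundary edges incident to it (all relative to q)
        poly: dict[int, list[tuple[float, float]]] = {}
        hull_boundary = False
        for s in cavity:
            verts = simplices[s]
            zx = self._cc[s, 0] - qx
            zy = self._cc[s, 1] - qy
            if not (math.isfinite(zx) and math.isfinite(zy)):
                hull_boundary = True
                break
            for v in verts:
                poly.setdefault(int(v), []).append((zx, zy))
            for k in range(3):
                nb = int(neighbors[s, k])
                if nb >= 0 and nb in cavity:
                    continue
                if nb < 0:
                    hull_boundary = True
                    break
                a = int(verts[(k + 1) % 3])
                b = int(verts[(k + 2) % 3])
                cxy = _circumcenter_origin(
                    pts[a, 0] - qx, pts[a, 1] - qy,
                    pts[b, 0] - qx, pts[b, 1] - qy)
                if not (math.isfinite(cxy[0]) and math.isfinite(cxy[1])):
                    hull_boundary = True
                    break
                poly[a].append(cxy)
                poly[b].append(cxy)
            if hull_boundary:
                break

        if hull_boundary:
            self.n_fallback += 1
            return self._barycentric(q, s0)

        neigh = sorted(poly)
        weights = np.array([_convex_area(poly[v]) for v in neigh])
        total = weights.sum()
        if not np.isfinite(total) or total <= 0.0:
            self.n_fallback += 1
            return self._barycentric(q, s0)
        weights /= total
        return weights @ self.values[neigh]
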