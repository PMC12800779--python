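"""Independent brute-force / closed-form oracles used by the tests.

These deliberately avoid the code paths they check: the hull oracle tests
every point pair as a supporting edge and fans triangles for the area; the
geodesic oracles are closed forms on the authalic sphere; the
point-in-polygon oracle is plain ray casting.
"""

from __future__ import annotations

import math

import numpy as np

EARTH_RADIUS_KM = 6371.0072


def brute_force_hull_area(points: np.ndarray, eps: float = 1e-12) -> float:
    """Convex-hull area by supporting-edge enumeration + triangle fan."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    hull_idx: set[int] = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = pts[j] - pts[i]
            rel = pts - pts[i]
            cross = d[0] * rel[:, 1] - d[1] * rel[:, 0]
            if np.all(cross >= -eps):
                hull_idx.add(i)
                hull_idx.add(j)
    verts = pts[sorted(hull_idx)]
    c = verts.mean(axis=0)
    order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
    v = verts[order]
    area = 0.0
    for k in range(1, len(v) - 1):
        a, b, d = v[0], v[k], v[k + 1]
        area += 0.5 * abs(
            (b[0] - a[0]) * (d[1] - a[1]) - (d[0] - a[0]) * (b[1] - a[1])
        )
    return area


def haversine_km(lon1: float, lat1: float, lon2: float, lat2: float) -> float:
    """Great-circle distance on the authalic sphere."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def spherical_triangle_area_km2(
    p1: tuple[float, float], p2: tuple[float, float], p3: tuple[float, float]
) -> float:
    """Geodesic triangle area by spherical excess (l'Huilier), points lon-lat."""
    a = haversine_km(*p2, *p3) / EARTH_RADIUS_KM
    b = haversine_km(*p1, *p3) / EARTH_RADIUS_KM
    c = haversine_km(*p1, *p2) / EARTH_RADIUS_KM
    s = (a + b + c) / 2
    t = math.sqrt(
        max(
            0.0,
            math.tan(s / 2)
            * math.tan((s - a) / 2)
            * math.tan((s - b) / 2)
            * math.tan((s - c) / 2),
        )
    )
    excess = 4 * math.atan(t)
    return excess * EARTH_RADIUS_KM**2


def ray_cast_inside(x: float, y: float, ring: np.ndarray) -> bool:
    """Point-in-polygon by ray casting (boundary behaviour undefined)."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside
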