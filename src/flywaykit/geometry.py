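"""Simple-polygon geometry: area, perimeter, shape complexity, containment.

Corridor polygons live in projected meters.  Areas are reported in hectares
and perimeters in kilometers, the units used for corridor summaries.  Shape
complexity uses the patch fractal dimension index from landscape ecology,

    FRAC = 2 * ln(0.25 * P) / ln(A),

with perimeter P and area A both in meters; FRAC is 1 for a square and
approaches 2 for highly convoluted shapes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

__all__ = [
    "ring_polygon",
    "polygon_metrics",
    "fractal_dimension",
    "containment_fraction",
]


def _first_crossing(coords: np.ndarray) -> tuple[int, int] | None:
    """Brute-force search for the first pair of crossing ring segments."""
    n = len(coords) - 1  # closed ring
    segs = [shapely.LineString(coords[i : i + 2]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through ring closure
            if segs[i].crosses(segs[j]):
                return i, j
    return None


def ring_polygon(vertices) -> Polygon:
    """Build a polygon from an ordered (x, y) ring, validating simplicity."""
    coords = np.asarray(vertices, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2 or len(coords) < 3:
        raise ValueError("ring needs >= 3 (x, y) vertices")
    poly = Polygon(coords)
    if not poly.is_valid:
        closed = np.vstack([coords, coords[:1]]) if not np.array_equal(coords[0], coords[-1]) else coords
        pair = _first_crossing(closed)
        if pair is not None:
            raise ValueError(f"self-intersecting ring: segments {pair[0]} and {pair[1]} cross")
        raise ValueError("invalid ring (degenerate or zero area)")
    if poly.area <= 0:
        raise ValueError("ring has zero area")
    return poly


def polygon_metrics(poly: Polygon) -> dict[str, float]:
    """Area in hectares and perimeter in kilometers of a polygon in meters."""
    if not isinstance(poly, Polygon):
        poly = ring_polygon(poly)
    return {"area_ha": poly.area / 1e4, "perimeter_km": poly.exterior.length / 1e3}


def fractal_dimension(poly: Polygon) -> float:
    """Patch fractal dimension index, dimensionless (1 for squares).

    Computed from perimeter and area in meters.  Values outside the nominal
    [1, 2] range (possible for very small or thin patches) are returned
    unaltered with a warning.
    """
    if not isinstance(poly, Polygon):
        poly = ring_polygon(poly)
    P = poly.exterior.length
    A = poly.area
    if A <= 1.0:
        raise ValueError("area <= 1 m^2: fractal dimension log degeneracy")
    frac = 2.0 * np.log(0.25 * P) / np.log(A)
    if not 1.0 <= frac <= 2.0:
        warnings.warn(f"fractal dimension {frac:.3f} outside nominal [1, 2]", stacklevel=2)
    return float(frac)


def containment_fraction(poly: Polygon, points) -> float:
    """Fraction of points inside or on the boundary of the polygon.

    ``points`` is a frame with x/y columns or an (n, 2) array.  Boundary
    points count as contained.
    """
    if isinstance(points, pd.DataFrame):
        xy = points[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.asarray(points, dtype=float)
    if xy.size == 0:
        raise ValueError("empty point set")
    geoms = shapely.points(xy[:, 0], xy[:, 1])
    shapely.prepare(poly)
    inside = shapely.covers(poly, geoms)
    return float(np.mean(inside))
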