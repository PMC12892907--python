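"""Independent oracles used by the geometry and statistics tests."""

import numpy as np


def ray_cast_inside(px: float, py: float, ring: np.ndarray) -> bool:
    """Classic even-odd ray-casting point-in-polygon (boundary-exclusive).

    ``ring`` is an (n, 2) array of exterior vertices (open, not repeated).
    Independent of shapely: pure crossing-number arithmetic.
    """
    n = len(ring)
    inside = False
    j = n - 1
    for i in range(n):
        xi, yi = ring[i]
        xj, yj = ring[j]
        if (yi > py) != (yj > py):
            x_cross = (xj - xi) * (py - yi) / (yj - yi) + xi
            if px < x_cross:
                inside = not inside
        j = i
    return inside


def random_star_polygon(rng: np.random.Generator, n_vertices: int = 12) -> np.ndarray:
    """Random simple (star-shaped) polygon around the origin."""
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vertices))
    radii = rng.uniform(0.5, 3.0, n_vertices)
    return np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])


def fan_triangulation_area(ring: np.ndarray, apex: np.ndarray) -> float:
    """Polygon area as a sum of signed triangle areas fanned from ``apex``.

    Exact for star-shaped polygons viewed from ``apex``.
    """
    total = 0.0
    n = len(ring)
    for i in range(n):
        a = ring[i] - apex
        b = ring[(i + 1) % n] - apex
        total += 0.5 * (a[0] * b[1] - a[1] * b[0])
    return abs(total)
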