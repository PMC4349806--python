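"""2-D binary-mask primitives shared by the shape and texture descriptors.

All operators take boolean (or 0/1) arrays indexed ``(row, col)``, 0-based.
Pixels outside the image are background for every operator. The convex hull
is computed on pixel *centers* and rasterized by an exact integer
center-in-polygon test in which points on a hull edge count as inside, so a
convex pixel set equals its own hull rasterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "StructuringElement",
    "disk_element",
    "dilate",
    "erode",
    "perimeter_mask",
    "perimeter_pixels",
    "convex_hull_mask",
]

# 4-connectivity cross, used for perimeter extraction
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool)


@dataclass(frozen=True)
class StructuringElement:
    """A flat disk-shaped structuring element.

    The footprint is the exact Euclidean lattice disk: ``footprint[i, j]`` is
    True iff the center-to-center distance is at most ``radius``. It is a
    ``(2r+1, 2r+1)`` boolean array, symmetric under 90-degree rotation and
    reflection.
    """

    radius: int
    footprint: np.ndarray


def disk_element(radius: int) -> StructuringElement:
    """Exact Euclidean disk footprint of the given integer radius (>= 1)."""
    if radius != int(radius) or radius < 1:
        raise ValueError(f"radius must be an integer >= 1, got {radius!r}")
    r = int(radius)
    ii, jj = np.mgrid[-r : r + 1, -r : r + 1]
    return StructuringElement(r, ii * ii + jj * jj <= r * r)


def _as_bool(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return mask.astype(bool)


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Minkowski dilation; pixels outside the image are background."""
    return ndimage.binary_dilation(_as_bool(mask), structure=se.footprint)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Minkowski erosion; pixels outside the image are background, so a
    full-frame mask erodes to the frame minus a rim."""
    return ndimage.binary_erosion(_as_bool(mask), structure=se.footprint, border_value=0)


def perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Boolean mask of foreground pixels with a background 4-neighbor.

    Out-of-image neighbors count as background, so pixels on the image frame
    are perimeter pixels. An empty mask yields an empty perimeter.
    """
    m = _as_bool(mask)
    interior = ndimage.binary_erosion(m, structure=_CROSS, border_value=0)
    return m & ~interior


def perimeter_pixels(mask: np.ndarray) -> set[tuple[int, int]]:
    """Perimeter of a mask as a set of ``(row, col)`` coordinates."""
    return {(int(r), int(c)) for r, c in np.argwhere(perimeter_mask(mask))}


def _rasterize_segment(shape, a, b):
    """Pixels whose center lies exactly on the closed segment a-b (integer
    endpoints); exact integer arithmetic."""
    out = np.zeros(shape, bool)
    a = np.asarray(a, np.int64)
    b = np.asarray(b, np.int64)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    d = b - a
    cross = d[0] * (cc - a[1]) - d[1] * (rr - a[0])
    out[rr[cross == 0], cc[cross == 0]] = True
    return out


def convex_hull_mask(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Convex hull of the foreground pixel centers and its rasterization.

    Returns ``(hull_vertices, hull_mask)`` where ``hull_vertices`` is an
    ``(k, 2)`` integer array of extreme points in traversal order and
    ``hull_mask`` contains every pixel whose center lies inside or on the
    hull polygon. ``mask <= hull_mask`` always holds; degenerate inputs
    (single pixel, collinear points) rasterize to the segment through the
    points, which for gap-free inputs equals the mask itself.
    """
    m = _as_bool(mask)
    pts = np.argwhere(m).astype(np.int64)
    if len(pts) == 0:
        raise ValueError("convex hull of an empty mask is undefined")
    if len(pts) == 1:
        return pts.copy(), m.copy()
    try:
        hull = ConvexHull(pts.astype(float))
        verts = pts[hull.vertices]
    except QhullError:
        # collinear point set: hull degenerates to a segment between the
        # two extreme points along the common direction
        d = pts - pts[0]
        proj = d @ (pts[-1] - pts[0])
        verts = np.stack([pts[np.argmin(proj)], pts[np.argmax(proj)]])
        return verts, _rasterize_segment(m.shape, verts[0], verts[1])

    # exact integer half-plane rasterization over the hull bounding box;
    # cross == 0 (center on an edge) counts as inside
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    rr, cc = np.mgrid[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1]
    inside = np.ones(rr.shape, bool)
    n = len(verts)
    # orientation of the vertex cycle (shoelace sign)
    area2 = 0
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        area2 += a[0] * b[1] - b[0] * a[1]
    sign = 1 if area2 > 0 else -1
    for i in range(n):
        a, b = verts[i], verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (cc - a[1]) - (b[1] - a[1]) * (rr - a[0])
        inside &= sign * cross >= 0
    hull_mask = np.zeros(m.shape, bool)
    hull_mask[rr[inside], cc[inside]] = True
    return verts, hull_mask
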