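"""Planar geometry primitives for capsule (thick-segment) fiber networks.

Coordinates are physical (μm). The image frame is ``[0, W·px] × [0, H·px]``
with the pixel at row ``i``, column ``j`` centred at
``((j + 0.5)·px, (i + 0.5)·px)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "segment_length",
    "clip_segment_to_frame",
    "segment_intersection_point",
    "count_interior_intersections",
    "paint_capsule",
    "capsule_union_mask",
]


def segment_length(p1, p2) -> float:
    """Euclidean length of a segment given as two (x, y) points."""
    return float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))


def clip_segment_to_frame(p1, p2, width: float, height: float):
    """Clip segment ``p1–p2`` to the axis-aligned frame ``[0,width]×[0,height]``.

    Returns the clipped endpoint pair, or ``None`` if the segment lies
    entirely outside.  Liang–Barsky parametric clipping.
    """
    x1, y1 = p1
    x2, y2 = p2
    dx, dy = x2 - x1, y2 - y1
    t0, t1 = 0.0, 1.0
    for p, q in (
        (-dx, x1),
        (dx, width - x1),
        (-dy, y1),
        (dy, height - y1),
    ):
        if p == 0.0:
            if q < 0.0:
                return None
            continue
        t = q / p
        if p < 0.0:
            if t > t1:
                return None
            t0 = max(t0, t)
        else:
            if t < t0:
                return None
            t1 = min(t1, t)
    return (
        (x1 + t0 * dx, y1 + t0 * dy),
        (x1 + t1 * dx, y1 + t1 * dy),
    )


def segment_intersection_point(p1, p2, q1, q2):
    """Proper interior crossing point of two open segments, or ``None``.

    Touching at endpoints (t exactly 0 or 1) and collinear overlap are not
    counted — only transversal crossings with ``0 < t < 1`` on both segments.
    """
    r = (p2[0] - p1[0], p2[1] - p1[1])
    s = (q2[0] - q1[0], q2[1] - q1[1])
    denom = r[0] * s[1] - r[1] * s[0]
    if denom == 0.0:
        return None
    qp = (q1[0] - p1[0], q1[1] - p1[1])
    t = (qp[0] * s[1] - qp[1] * s[0]) / denom
    u = (qp[0] * r[1] - qp[1] * r[0]) / denom
    if 0.0 < t < 1.0 and 0.0 < u < 1.0:
        return (p1[0] + t * r[0], p1[1] + t * r[1])
    return None


def count_interior_intersections(segments, width: float, height: float) -> int:
    """All-pairs count of centerline crossings strictly inside the frame.

    ``segments`` is a sequence of ``(p1, p2)`` or ``(p1, p2, radius)``
    tuples; the radius, if present, is ignored. O(n²) by design: this is
    the ground-truth side and must stay simple.
    """
    pts = [(s[0], s[1]) for s in segments]
    n = len(pts)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            pt = segment_intersection_point(*pts[i], *pts[j])
            if pt is not None and 0.0 < pt[0] < width and 0.0 < pt[1] < height:
                count += 1
    return count


def segment_min_distance(p1, p2, q1, q2) -> float:
    """Minimum distance between two segments (0 when they intersect)."""
    if segment_intersection_point(p1, p2, q1, q2) is not None:
        return 0.0
    dists = []
    for a1, a2, pts in ((p1, p2, (q1, q2)), (q1, q2, (p1, p2))):
        ax, ay = a2[0] - a1[0], a2[1] - a1[1]
        aa = ax * ax + ay * ay
        for pt in pts:
            if aa == 0.0:
                dists.append(np.hypot(pt[0] - a1[0], pt[1] - a1[1]))
                continue
            t = np.clip(((pt[0] - a1[0]) * ax + (pt[1] - a1[1]) * ay) / aa, 0.0, 1.0)
            dists.append(
                np.hypot(pt[0] - a1[0] - t * ax, pt[1] - a1[1] - t * ay)
            )
    return float(min(dists))


def _dist_to_segment(px_x, px_y, p1, p2):
    """Vectorised point-to-segment distance over coordinate grids."""
    vx, vy = p2[0] - p1[0], p2[1] - p1[1]
    wx, wy = px_x - p1[0], px_y - p1[1]
    vv = vx * vx + vy * vy
    if vv == 0.0:
        return np.hypot(wx, wy)
    t = np.clip((wx * vx + wy * vy) / vv, 0.0, 1.0)
    return np.hypot(wx - t * vx, wy - t * vy)


def paint_capsule(target: np.ndarray, p1, p2, radius: float, pixel_size: float,
                  value=True) -> None:
    """Set ``value`` on all pixels of ``target`` whose centre lies within
    ``radius`` of segment ``p1–p2``.  Restricted to the capsule's bounding
    box for speed; ``target`` is modified in place."""
    h, w = target.shape
    pad = radius + pixel_size
    j0 = max(int((min(p1[0], p2[0]) - pad) / pixel_size), 0)
    j1 = min(int((max(p1[0], p2[0]) + pad) / pixel_size) + 1, w)
    i0 = max(int((min(p1[1], p2[1]) - pad) / pixel_size), 0)
    i1 = min(int((max(p1[1], p2[1]) + pad) / pixel_size) + 1, h)
    if i0 >= i1 or j0 >= j1:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    cx = (jj + 0.5) * pixel_size
    cy = (ii + 0.5) * pixel_size
    inside = _dist_to_segment(cx, cy, p1, p2) <= radius
    block = target[i0:i1, j0:j1]
    block[inside] = value


def capsule_union_mask(segments_with_radii, shape_px, pixel_size: float,
                       supersample: int = 1) -> np.ndarray:
    """Boolean raster of the union of capsules on a (possibly refined) grid.

    ``shape_px`` is the base ``(rows, cols)`` shape; with supersampling the
    returned array has ``supersample``-times finer pixels covering the same
    physical frame.
    """
    if supersample < 1:
        raise ValueError("supersample_factor must be >= 1")
    h, w = shape_px
    fine = np.zeros((h * supersample, w * supersample), dtype=bool)
    fine_px = pixel_size / supersample
    for p1, p2, r in segments_with_radii:
        paint_capsule(fine, p1, p2, r, fine_px)
    return fine
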