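"""Anti-aliased rasterization primitives for synthetic microscopy scenes.

Objects (fiber rods, elongated cells, nuclei, spheroid bodies) are drawn
with 4x4 supersampled coverage fractions and composited by per-pixel
maximum, which keeps intensities bounded and makes the noise-free support
of a scene exactly the union of the individual object supports — so the
ground-truth geometry tables fully determine the rendered support.

For speed, coverage is evaluated in two passes: a coarse pass at pixel
resolution finds candidate pixels within one pixel of the object, and only
those are supersampled. Long thin rods therefore cost O(bbox) + O(area)
rather than O(16 x bbox).

Coordinate convention (used package-wide): 0-based pixel indices, origin at
the top-left corner, x = column, y = row (y increases downward); angles in
degrees from the +x axis toward +y. Geometry arguments are in pixel units.
"""

from __future__ import annotations

import numpy as np

SUPERSAMPLE = 4

# subpixel sample offsets relative to the pixel center
_SUB = ((np.arange(SUPERSAMPLE) + 0.5) / SUPERSAMPLE - 0.5)
_SUB_X, _SUB_Y = np.meshgrid(_SUB, _SUB)
_SUB_X = _SUB_X.ravel()
_SUB_Y = _SUB_Y.ravel()


def _bbox(img_shape, x_lo, x_hi, y_lo, y_hi):
    h, w = img_shape
    r0 = max(int(np.floor(y_lo)), 0)
    r1 = min(int(np.ceil(y_hi)) + 1, h)
    c0 = max(int(np.floor(x_lo)), 0)
    c1 = min(int(np.ceil(x_hi)) + 1, w)
    if r1 <= r0 or c1 <= c0:
        return None
    return r0, r1, c0, c1


def _paint(img, inside_fn, x_lo, x_hi, y_lo, y_hi, value):
    """Two-pass supersampled coverage for the region {inside_fn(x, y)}.

    inside_fn must accept broadcastable x, y arrays of *pixel* coordinates
    and return a signed distance-like quantity <= 0 inside the object; a
    coarse pixel is a candidate when the value is below +1.5 px.
    """
    box = _bbox(img.shape, x_lo, x_hi, y_lo, y_hi)
    if box is None:
        return
    r0, r1, c0, c1 = box
    yy, xx = np.mgrid[r0:r1, c0:c1]
    coarse = inside_fn(xx.astype(float), yy.astype(float))
    rows, cols = np.nonzero(coarse <= 1.5)
    if rows.size == 0:
        return
    sx = (cols + c0)[:, None] + _SUB_X[None, :]
    sy = (rows + r0)[:, None] + _SUB_Y[None, :]
    frac = (inside_fn(sx, sy) <= 0.0).mean(axis=1)
    keep = frac > 0
    rr = rows[keep] + r0
    cc = cols[keep] + c0
    img[rr, cc] = np.maximum(img[rr, cc], value * frac[keep])


def draw_capsule(img, p0, p1, radius, value=1.0):
    """Draw a filled capsule (segment p0-p1 dilated by `radius`) onto img.

    p0, p1 are (x, y) pixel coordinates; anti-aliased, max-composited.
    """
    x0, y0 = float(p0[0]), float(p0[1])
    x1, y1 = float(p1[0]), float(p1[1])
    dx, dy = x1 - x0, y1 - y0
    seg2 = dx * dx + dy * dy

    def sdist(X, Y):
        if seg2 == 0:
            return np.hypot(X - x0, Y - y0) - radius
        t = np.clip(((X - x0) * dx + (Y - y0) * dy) / seg2, 0.0, 1.0)
        return np.hypot(X - (x0 + t * dx), Y - (y0 + t * dy)) - radius

    _paint(img, sdist,
           min(x0, x1) - radius - 1, max(x0, x1) + radius + 1,
           min(y0, y1) - radius - 1, max(y0, y1) + radius + 1, value)


def draw_ellipse(img, center, semi_axes, angle_deg, value=1.0):
    """Draw a filled rotated ellipse. center=(x, y), semi_axes=(a, b) px."""
    cx, cy = float(center[0]), float(center[1])
    a, b = float(semi_axes[0]), float(semi_axes[1])
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)

    def sdist(X, Y):
        u = (X - cx) * ct + (Y - cy) * st
        v = -(X - cx) * st + (Y - cy) * ct
        # approximate signed distance: scaled radial excess times min axis
        q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
        return (q - 1.0) * min(a, b)

    r = max(a, b)
    _paint(img, sdist, cx - r - 1, cx + r + 1, cy - r - 1, cy + r + 1, value)


def draw_disk(img, center, radius, value=1.0):
    draw_ellipse(img, center, (radius, radius), 0.0, value)


def capsule_from_axis(center, length, angle_deg, width):
    """Endpoints and radius of a capsule with tip-to-tip extent `length`
    along `angle_deg` and transverse width `width` (spindle/rod model).

    The core segment has length `length - width` so the overall extent is
    `length`; degenerates to a disk when length <= width.
    """
    radius = width / 2.0
    half = max(length - width, 0.0) / 2.0
    th = np.deg2rad(angle_deg)
    u = np.array([np.cos(th), np.sin(th)])
    c = np.asarray(center, dtype=float)
    return c - half * u, c + half * u, radius


def segment_segment_distance(p0, p1, q0s, q1s):
    """Exact minimum distance from segment (p0, p1) to each segment in a
    batch (q0s, q1s of shape (n, 2)); used for non-overlap rejection
    sampling of capsule-shaped objects.

    2D specialization: if the segments properly intersect the distance is
    zero; otherwise the minimum is attained at an endpoint, so it is the
    least of the four endpoint-to-segment distances.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    q0s = np.atleast_2d(np.asarray(q0s, float))
    q1s = np.atleast_2d(np.asarray(q1s, float))

    d_end = np.minimum(
        _point_to_segments(np.vstack([p0, p1]), q0s, q1s).min(axis=0),
        np.minimum(
            _point_to_segments(q0s, p0[None, :], p1[None, :])[:, 0],
            _point_to_segments(q1s, p0[None, :], p1[None, :])[:, 0]))

    # proper-intersection test via signed orientations
    def cross(o, a, b):
        return ((a[..., 0] - o[..., 0]) * (b[..., 1] - o[..., 1])
                - (a[..., 1] - o[..., 1]) * (b[..., 0] - o[..., 0]))

    d1 = cross(q0s, q1s, p0[None, :])
    d2 = cross(q0s, q1s, p1[None, :])
    d3 = cross(p0[None, :], p1[None, :], q0s)
    d4 = cross(p0[None, :], p1[None, :], q1s)
    intersects = (d1 * d2 < 0) & (d3 * d4 < 0)
    return np.where(intersects, 0.0, d_end)


def _point_to_segments(points, q0s, q1s):
    """Exact distances from each point (m,2) to each segment (n,2) -> (m,n)."""
    d = q1s - q0s
    seg2 = (d * d).sum(axis=1)
    seg2 = np.where(seg2 == 0, 1.0, seg2)
    w = points[:, None, :] - q0s[None, :, :]
    t = np.clip((w * d[None, :, :]).sum(axis=2) / seg2[None, :], 0.0, 1.0)
    proj = q0s[None, :, :] + t[..., None] * d[None, :, :]
    return np.linalg.norm(points[:, None, :] - proj, axis=2)
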