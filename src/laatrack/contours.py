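"""Contour representation and geometric primitives.

A :class:`Contour` is an ordered list of 2D points in millimetres with a
boundary mode: ``"constant"`` for open curves (the left atrial appendage
wall, an arc across the ostium) and ``"periodic"`` for closed curves (the
thrombus outline).  These primitives — arc-length resampling, polyline
length, vertex centroid — are shared by the tracker, the strain module and
the mobility metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Contour",
    "MotionField",
    "resample_contour",
    "contour_length",
    "contour_centroid",
    "ensure_ccw",
]

_MODES = ("constant", "periodic")


@dataclass(frozen=True)
class Contour:
    """Ordered 2D point list in mm with an open/closed boundary mode.

    Parameters
    ----------
    points
        ``(N, 2)`` array of ``(x, y)`` positions in mm, ``N >= 3``.
    mode
        ``"constant"`` (open curve) or ``"periodic"`` (closed curve).
    """

    points: np.ndarray
    mode: str = "constant"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"contour points must be (N, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise ValueError("a contour needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour points contain NaN/inf")
        if self.mode not in _MODES:
            raise ValueError(f"boundary mode must be one of {_MODES}")
        if self.mode == "periodic" and not _is_simple(pts):
            warnings.warn("periodic contour is self-intersecting", stacklevel=3)
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def closed(self) -> bool:
        return self.mode == "periodic"

    def translated(self, offset) -> "Contour":
        return Contour(self.points + np.asarray(offset, dtype=float), self.mode)


@dataclass(frozen=True)
class MotionField:
    """Per-anchor displacement vectors for one frame-to-frame step.

    ``anchors`` are a contour's points at the step's source frame (mm);
    ``vectors`` map each anchor to its tracked position at the target frame,
    so ``anchors + vectors`` is the tracked contour, exactly.
    """

    anchors: np.ndarray
    vectors: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.anchors, dtype=float)
        v = np.asarray(self.vectors, dtype=float)
        if a.shape != v.shape or a.ndim != 2 or a.shape[1] != 2:
            raise ValueError("anchors and vectors must both be (N, 2)")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(v))):
            raise ValueError("motion field contains NaN/inf")
        object.__setattr__(self, "anchors", a)
        object.__setattr__(self, "vectors", v)

    @property
    def targets(self) -> np.ndarray:
        return self.anchors + self.vectors


def _is_simple(pts: np.ndarray) -> bool:
    try:
        from shapely.geometry import LinearRing

        return LinearRing(pts).is_simple
    except Exception:  # degenerate ring; leave it to downstream checks
        return True


def _segment_lengths(pts: np.ndarray, closed: bool) -> np.ndarray:
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    if closed:
        seg = np.append(seg, np.hypot(*(pts[0] - pts[-1])))
    return seg


def resample_contour(raw_points, n: int, mode: str = "constant") -> Contour:
    """Resample a polyline to ``n`` points equally spaced in arc length.

    Open (``constant``) contours keep their endpoints exactly; closed
    (``periodic``) contours are sampled at ``n`` uniform arc-length stations
    starting from the first input point (the closing segment included).
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 input points of shape (N, 2)")
    if n < 3:
        raise ValueError("target point count must be >= 3")
    closed = mode == "periodic"
    loop = np.vstack([pts, pts[:1]]) if closed else pts
    seg = _segment_lengths(loop, closed=False)
    total = float(seg.sum())
    if total <= 0.0:
        raise ValueError("degenerate (zero-length) polyline")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if closed:
        stations = np.arange(n) * total / n
    else:
        stations = np.linspace(0.0, total, n)
    x = np.interp(stations, cum, loop[:, 0])
    y = np.interp(stations, cum, loop[:, 1])
    out = np.column_stack([x, y])
    if not closed:  # endpoints exact, immune to float accumulation
        out[0] = pts[0]
        out[-1] = pts[-1]
    return Contour(out, mode)


def contour_length(c: Contour) -> float:
    """Total polyline length in mm.

    Periodic contours include the closing segment; constant (open) contours
    do not.
    """
    return float(_segment_lengths(c.points, c.closed).sum())


def contour_centroid(c: Contour) -> np.ndarray:
    """Vertex centroid (arithmetic mean of the contour points), in mm."""
    return c.points.mean(axis=0)


def ensure_ccw(c: Contour) -> Contour:
    """Return a periodic contour with counterclockwise point order.

    Open contours are returned unchanged.  Orientation is measured by the
    shoelace signed area in the (x, y) plane.
    """
    if not c.closed:
        return c
    p = c.points
    area2 = float(np.sum(p[:, 0] * np.roll(p[:, 1], -1) - np.roll(p[:, 0], -1) * p[:, 1]))
    if area2 < 0.0:
        return Contour(p[::-1].copy(), c.mode)
    return c
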