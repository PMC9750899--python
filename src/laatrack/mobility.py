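"""Isolated thrombus mobility via motion-component decomposition.

A thrombus inside the appendage moves for two reasons: it is carried along
by the appendage wall (and by bulk cardiac/probe motion), and it may also
move on its own.  Only the second component is of interest.  The metric
separates them with a double-step construction at every frame-to-frame
tracking step:

1. *compliant propagation* — the thrombus contour at the step's source
   frame is moved by the LAA motion field alone, interpolated from the LAA
   contour points (the anchors) to each thrombus point by inverse-distance
   weighting with global support (all anchors, no cutoff).  The result is
   where the thrombus would sit under full compliance with the wall, all
   external motion components and none of its own;
2. *deviation* — the Euclidean distance ``d_t`` (mm) between the centroid
   of that compliant contour and the centroid of the directly tracked
   thrombus at the target frame.

``d_t`` is zero whenever the thrombus is fully compliant (the two contours
coincide).  The per-case summaries are the mean and maximum of ``d_t`` over
all non-reference frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import Contour, MotionField, contour_centroid
from .tracking import TrackingResult

__all__ = [
    "CompliantContour",
    "MobilitySeries",
    "idw_interpolate",
    "compliant_contour",
    "mobility_series",
]

IDW_POWER = 2.0
IDW_EPSILON_MM = 1e-6


@dataclass(frozen=True)
class CompliantContour:
    """Thrombus position predicted under full compliance with the LAA wall."""

    contour: Contour
    source_frame: int


@dataclass(frozen=True)
class MobilitySeries:
    """Per-frame centroid deviation d_t (mm) with mean/max summaries.

    ``d[ref_index]`` is defined as 0 (no step exists there) and the mean and
    max are taken over the non-reference frames only.
    """

    d: np.ndarray
    ref_index: int
    mean_mm: float
    max_mm: float

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if np.any(d < 0):
            raise ValueError("centroid distances must be non-negative")
        if self.mean_mm > self.max_mm + 1e-12:
            raise ValueError("mean mobility cannot exceed the maximum")
        object.__setattr__(self, "d", d)


def idw_interpolate(
    anchors: np.ndarray,
    vectors: np.ndarray,
    queries: np.ndarray,
    power: float = IDW_POWER,
    epsilon_mm: float = IDW_EPSILON_MM,
) -> np.ndarray:
    """Shepard (inverse-distance-weighted) interpolation of a vector field.

    Each query displacement is ``sum_i w_i v_i / sum_i w_i`` with
    ``w_i = 1 / (||q - a_i|| + eps)^power`` over *all* anchors — global
    support, no cutoff — which reproduces constant fields exactly and keeps
    the result smooth.
    """
    a = np.atleast_2d(np.asarray(anchors, dtype=float))
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    q = np.atleast_2d(np.asarray(queries, dtype=float))
    if a.shape[0] == 0:
        raise ValueError("need at least one anchor")
    if a.shape != v.shape:
        raise ValueError("anchors and vectors must have matching shapes")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(v)) and np.all(np.isfinite(q))):
        raise ValueError("non-finite positions in IDW input")
    dist = np.linalg.norm(q[:, None, :] - a[None, :, :], axis=2)
    w = 1.0 / (dist + epsilon_mm) ** power
    return (w @ v) / w.sum(axis=1, keepdims=True)


def compliant_contour(
    thrombus_prev: Contour,
    laa_field: MotionField,
    power: float = IDW_POWER,
    epsilon_mm: float = IDW_EPSILON_MM,
    source_frame: int = -1,
) -> CompliantContour:
    """Propagate the thrombus by the LAA motion field alone.

    Anchors are the LAA contour points at the step's source frame; each
    thrombus point moves by its interpolated displacement.  The result is
    the intermediate contour with all external motion components applied
    and the thrombus-specific component removed.
    """
    disp = idw_interpolate(
        laa_field.anchors, laa_field.vectors, thrombus_prev.points, power, epsilon_mm
    )
    return CompliantContour(
        Contour(thrombus_prev.points + disp, thrombus_prev.mode), source_frame
    )


def mobility_series(
    laa_track: TrackingResult,
    thr_track: TrackingResult,
    power: float = IDW_POWER,
    epsilon_mm: float = IDW_EPSILON_MM,
) -> MobilitySeries:
    """Per-frame isolated thrombus mobility d_t from the two tracks.

    For every propagation step into frame ``t``: the thrombus contour at the
    step's source frame is compliant-propagated under the LAA field of the
    same step, and ``d_t`` is the centroid distance to the directly tracked
    thrombus at ``t``.  Both tracks must share frame count, reference frame
    and propagation plan.
    """
    if laa_track.frame_count != thr_track.frame_count:
        raise ValueError("tracks have different frame counts")
    if laa_track.ref_index != thr_track.ref_index:
        raise ValueError("tracks have different reference frames")
    if laa_track.plan != thr_track.plan:
        raise ValueError("tracks were propagated with different plans")

    T = laa_track.frame_count
    d = np.zeros(T)
    for src, tgt in laa_track.plan:
        comp = compliant_contour(
            thr_track.contours[src], laa_track.fields[tgt], power, epsilon_mm, src
        )
        d[tgt] = float(
            np.linalg.norm(
                contour_centroid(comp.contour)
                - contour_centroid(thr_track.contours[tgt])
            )
        )
    others = np.delete(d, laa_track.ref_index)
    return MobilitySeries(d, laa_track.ref_index, float(others.mean()), float(others.max()))
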