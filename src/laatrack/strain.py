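"""LAA longitudinal strain from a tracking result.

Longitudinal strain at frame ``t`` is the fractional change of the tracked
contour's length relative to its end-diastolic reference length,

    strain_t = 100 * (L_t - L_ref) / L_ref   [%]

with ``L_t`` the sum of consecutive-point distances of the frame-``t``
contour (open contour: no closing segment).  This whole-contour form equals
the length-weighted mean of segmental strains; per-segment values are
available as a diagnostic but are not part of the headline metric.  The
minimal peak (most negative value) marks the strongest appendage
contraction, the maximal peak the strongest relaxation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contours import contour_length
from .tracking import TrackingResult

__all__ = ["StrainCurve", "strain_curve", "peak_strain", "segmental_strain"]


@dataclass(frozen=True)
class StrainCurve:
    """Per-frame longitudinal strain (%), zero at the reference frame."""

    values: np.ndarray
    ref_index: int
    lengths: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        L = np.asarray(self.lengths, dtype=float)
        if v.shape != L.shape or v.ndim != 1:
            raise ValueError("values and lengths must be equal-length 1D arrays")
        if v[self.ref_index] != 0.0:
            raise ValueError("strain at the reference frame must be exactly 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "lengths", L)

    @property
    def ref_length_mm(self) -> float:
        return float(self.lengths[self.ref_index])


def strain_curve(track: TrackingResult, ref_index: int | None = None) -> StrainCurve:
    """Longitudinal strain curve of a tracked (open) LAA contour."""
    ref = track.ref_index if ref_index is None else ref_index
    lengths = np.array([contour_length(c) for c in track.contours])
    L_ref = lengths[ref]
    if L_ref <= 0:
        raise ValueError("reference contour has zero length")
    values = 100.0 * (lengths - L_ref) / L_ref
    values[ref] = 0.0  # exact, not just to rounding
    return StrainCurve(values, ref, lengths)


def peak_strain(curve: StrainCurve) -> tuple[float, float]:
    """(minimal, maximal) peak strain in %.

    The minimum is never above 0 and the maximum never below 0 because the
    reference frame contributes an exact zero.
    """
    if curve.values.size == 0:
        raise ValueError("empty strain curve")
    return float(curve.values.min()), float(curve.values.max())


def segmental_strain(track: TrackingResult, ref_index: int | None = None) -> np.ndarray:
    """Per-segment strain (%), shape (T, N-1) for an N-point open contour.

    Diagnostic output: segment ``i`` compares the distance between points
    ``i`` and ``i+1`` at frame ``t`` with the same distance at the reference
    frame.
    """
    ref = track.ref_index if ref_index is None else ref_index

    def seglen(c):
        d = np.diff(c.points, axis=0)
        return np.hypot(d[:, 0], d[:, 1])

    ref_seg = seglen(track.contours[ref])
    if np.any(ref_seg <= 0):
        raise ValueError("degenerate reference segment")
    return np.array([100.0 * (seglen(c) - ref_seg) / ref_seg for c in track.contours])
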