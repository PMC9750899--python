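"""Anatomically constrained affine optical-flow contour tracking.

Motion between consecutive frames is estimated only inside Gaussian-weighted
regions of interest (ROIs) anchored on the contour points, not over the full
image.  Each frame-to-frame step is a two-stage fit:

1. a single *global* affine model pooled over every contour point's ROI,
   capturing bulk cardiac motion (fast appendage contraction, probe motion);
2. a *localized* affine model per contour point, fitted in the ROI centred
   on the stage-1 position and applied to that point only, refining the
   contour to the anatomy.

Both fits are single-scale Gauss–Newton on the affine warp (the affine
Lucas–Kanade construction): the warp minimizes the Gaussian-weighted sum of
squared intensity differences between the source ROI and the warped target
frame.  Tracking over a cycle is pairwise with a bidirectional propagation
scheme — half of the frames forward from the end-diastolic reference, half
backward — which bounds accumulated drift symmetrically around the
reference.  Out-of-field-of-view regularization is not used: a point whose
stage-1 position leaves the image keeps its global-stage result.

Everything here is deterministic; no randomness is involved.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .contours import Contour, MotionField
from .io import ImageSequence

__all__ = [
    "AffineParams",
    "TrackerConfig",
    "TrackingResult",
    "gaussian_roi_weights",
    "estimate_roi_affine",
    "estimate_global_affine",
    "track_pair",
    "propagation_plan",
    "track_sequence",
]


@dataclass(frozen=True)
class AffineParams:
    """A 2D affine warp: ``x -> center + A (x - center) + b``.

    ``A`` is the dimensionless 2x2 linear part, ``b`` the translation in mm.
    Accepted solutions are orientation-preserving (``det A > 0``); the
    identity is ``A = I, b = 0``.
    """

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float).reshape(2, 2)
        b = np.asarray(self.b, dtype=float).reshape(2)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)

    @classmethod
    def identity(cls) -> "AffineParams":
        return cls(np.eye(2), np.zeros(2))

    def apply(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        """Apply the warp, parameterized about ``center``, to (N, 2) points."""
        center = np.asarray(center, dtype=float)
        return center + (np.asarray(points) - center) @ self.A.T + self.b


@dataclass(frozen=True)
class TrackerConfig:
    """Tracking parameters.

    ROI windows have a half-width (``*_window_radius_mm``) per structure; the
    Gaussian weight kernel has ``kernel_sigma_mm`` and is truncated to zero
    beyond ``support_fraction`` of the window radius (localized support).
    The Gauss–Newton solver stops when the largest point-displacement update
    falls below ``tol_px`` or after ``max_iterations``.  Images are
    pre-smoothed with a small Gaussian (``presmooth_sigma_px``) for gradient
    stability.
    """

    laa_points: int = 80
    thrombus_points: int = 40
    laa_window_radius_mm: float = 6.0
    thrombus_window_radius_mm: float = 3.0
    kernel_sigma_mm: float = 0.4
    support_fraction: float = 0.25
    max_iterations: int = 50
    tol_px: float = 0.01
    presmooth_sigma_px: float = 1.0
    oov_regularization: bool = False

    def __post_init__(self) -> None:
        if min(self.laa_window_radius_mm, self.thrombus_window_radius_mm) <= 0:
            raise ValueError("window radii must be positive")
        if self.kernel_sigma_mm <= 0:
            raise ValueError("kernel sigma must be positive")
        if not 0 < self.support_fraction <= 1:
            raise ValueError("support_fraction must be in (0, 1]")
        if self.oov_regularization:
            raise NotImplementedError(
                "out-of-field-of-view regularization is intentionally not provided"
            )

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TrackerConfig":
        return cls(**json.loads(text))

    def window_radius_for(self, contour: Contour) -> float:
        """LAA radius for open contours, thrombus radius for closed ones."""
        return (
            self.thrombus_window_radius_mm
            if contour.closed
            else self.laa_window_radius_mm
        )


@dataclass(frozen=True)
class TrackingResult:
    """Per-frame contours plus the motion field of every propagation step.

    ``contours[t]`` is the tracked contour at frame ``t`` (the entry at the
    reference index is the input contour).  ``fields[t]`` describes the step
    *into* frame ``t`` in propagation order: anchors are the contour at the
    step's source frame, ``anchors + vectors`` the contour at ``t``.
    ``provenance[t]`` is ``"forward"`` or ``"backward"``.
    """

    contours: list
    fields: dict
    plan: list
    provenance: dict
    ref_index: int

    @property
    def frame_count(self) -> int:
        return len(self.contours)

    def centroid_track(self) -> np.ndarray:
        return np.array([c.points.mean(axis=0) for c in self.contours])


def gaussian_roi_weights(
    window_radius_mm: float,
    sigma_mm: float,
    support_fraction: float,
    spacing_mm: float,
) -> np.ndarray:
    """Square Gaussian ROI weight mask, truncated to its localized support.

    The mask half-width is ``round(window_radius_mm / spacing_mm)`` pixels;
    the isotropic Gaussian is centred on the mask; weights beyond
    ``support_fraction * window_radius_mm`` from the centre are set to zero;
    the mask is normalized to sum 1.
    """
    if min(window_radius_mm, sigma_mm, support_fraction, spacing_mm) <= 0:
        raise ValueError("all ROI weight parameters must be positive")
    half = int(round(window_radius_mm / spacing_mm))
    if 2 * half + 1 < 3:
        raise ValueError("ROI window smaller than 3 px after rounding")
    ax = np.arange(-half, half + 1, dtype=float)
    dy, dx = np.meshgrid(ax, ax, indexing="ij")
    r_mm = np.hypot(dx, dy) * spacing_mm
    w = np.exp(-0.5 * (r_mm / sigma_mm) ** 2)
    w[r_mm > support_fraction * window_radius_mm] = 0.0
    s = w.sum()
    if s <= 0:
        raise ValueError("empty ROI support; increase support_fraction or window")
    return w / s


def _mask_offsets(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Nonzero mask entries as (k, 2) pixel offsets (x, y) and weights."""
    h = weights.shape[0] // 2
    rr, cc = np.nonzero(weights)
    offs = np.column_stack([cc - h, rr - h]).astype(float)
    return offs, weights[rr, cc]


def _prep_frame(frame: np.ndarray, sigma_px: float):
    """Pre-smooth a frame and compute its intensity gradients."""
    sm = ndimage.gaussian_filter(np.asarray(frame, dtype=float), sigma_px)
    gy, gx = np.gradient(sm)
    return sm, gx, gy


def _sample(img: np.ndarray, pos_xy: np.ndarray) -> np.ndarray:
    """Bilinear sampling at (k, 2) pixel positions given as (x, y)."""
    coords = np.stack([pos_xy[:, 1], pos_xy[:, 0]])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def _gauss_newton_affine(
    prep_a,
    prep_b,
    positions_px: np.ndarray,
    weights: np.ndarray,
    center_px: np.ndarray,
    init: AffineParams,
    spacing_mm: float,
    max_iterations: int,
    tol_px: float,
) -> AffineParams:
    """Weighted affine Lucas–Kanade fit over fixed template sample positions.

    Minimizes sum_k w_k [I_b(W(x_k)) - I_a(x_k)]^2 over the 6 affine
    parameters, with W parameterized about ``center_px``.  Returns ``init``
    unchanged (with a warning) if the normal equations are degenerate or the
    solution loses orientation.
    """
    sm_a, _, _ = prep_a
    sm_b, gx_b, gy_b = prep_b
    template = _sample(sm_a, positions_px)
    d = positions_px - center_px
    A = init.A.copy()
    b = init.b / spacing_mm  # solver works in px

    for _ in range(max_iterations):
        q = center_px + d @ A.T + b
        resid = _sample(sm_b, q) - template
        gx = _sample(gx_b, q)
        gy = _sample(gy_b, q)
        J = np.column_stack(
            [gx * d[:, 0], gx * d[:, 1], gy * d[:, 0], gy * d[:, 1], gx, gy]
        )
        Jw = J * weights[:, None]
        H = J.T @ Jw
        g = Jw.T @ resid
        try:
            if np.linalg.cond(H) > 1e12:
                raise np.linalg.LinAlgError("ill-conditioned normal equations")
            delta = -np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            warnings.warn("degenerate affine flow system; keeping initial warp")
            return init
        if not np.all(np.isfinite(delta)):
            warnings.warn("non-finite affine flow update; keeping initial warp")
            return init
        dA = delta[:4].reshape(2, 2)
        db = delta[4:]
        A = A + dA
        b = b + db
        step = d @ dA.T + db
        if np.hypot(step[:, 0], step[:, 1]).max() < tol_px:
            break

    if np.linalg.det(A) <= 0:
        warnings.warn("affine flow lost orientation (det <= 0); keeping initial warp")
        return init
    return AffineParams(A, b * spacing_mm)


def estimate_roi_affine(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    center_mm: np.ndarray,
    weights: np.ndarray,
    spacing_mm: float,
    init: AffineParams | None = None,
    *,
    max_iterations: int = 50,
    tol_px: float = 0.01,
    presmooth_sigma_px: float = 1.0,
    _prep_a=None,
    _prep_b=None,
) -> AffineParams:
    """Fit one affine warp in a single Gaussian-weighted ROI.

    The ROI is centred at ``center_mm`` in ``frame_a``; the returned warp
    maps frame_a positions to frame_b positions (``b`` in mm).
    """
    for fr in (frame_a, frame_b):
        if not np.all(np.isfinite(fr)):
            raise ValueError("non-finite intensities")
    if init is None:
        init = AffineParams.identity()
    prep_a = _prep_a if _prep_a is not None else _prep_frame(frame_a, presmooth_sigma_px)
    prep_b = _prep_b if _prep_b is not None else _prep_frame(frame_b, presmooth_sigma_px)
    center_px = np.asarray(center_mm, dtype=float) / spacing_mm
    offs, w = _mask_offsets(weights)
    return _gauss_newton_affine(
        prep_a, prep_b, center_px + offs, w, center_px, init, spacing_mm,
        max_iterations, tol_px,
    )


def estimate_global_affine(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    contour_a: Contour,
    cfg: TrackerConfig,
    spacing_mm: float,
    *,
    window_radius_mm: float | None = None,
    _prep_a=None,
    _prep_b=None,
) -> AffineParams:
    """Fit a single affine over the union of all per-point ROIs.

    One joint weighted least-squares problem pools every contour point's ROI
    pixels; the warp is parameterized about the contour's vertex centroid.
    This global stage captures bulk cardiac motion before local refinement.
    """
    radius = window_radius_mm or cfg.window_radius_for(contour_a)
    weights = gaussian_roi_weights(
        radius, cfg.kernel_sigma_mm, cfg.support_fraction, spacing_mm
    )
    prep_a = _prep_a if _prep_a is not None else _prep_frame(frame_a, cfg.presmooth_sigma_px)
    prep_b = _prep_b if _prep_b is not None else _prep_frame(frame_b, cfg.presmooth_sigma_px)
    offs, w = _mask_offsets(weights)
    centers_px = contour_a.points / spacing_mm
    positions = (centers_px[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    pooled_w = np.tile(w, centers_px.shape[0])
    center_px = centers_px.mean(axis=0)
    return _gauss_newton_affine(
        prep_a, prep_b, positions, pooled_w, center_px,
        AffineParams.identity(), spacing_mm, cfg.max_iterations, cfg.tol_px,
    )


def track_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    contour_a: Contour,
    cfg: TrackerConfig,
    spacing_mm: float,
    *,
    window_radius_mm: float | None = None,
    _prep_a=None,
    _prep_b=None,
) -> tuple[Contour, MotionField]:
    """Two-stage (global + localized) tracking of one contour between frames.

    Stage 1 applies the pooled global affine to every contour point; stage 2
    fits a local affine per point — ROI centred on the stage-1 position,
    identity initialization — and moves each point by its own local warp.
    A point whose stage-1 position leaves the image skips its local stage
    (the global result is kept) and is flagged with a warning.
    """
    radius = window_radius_mm or cfg.window_radius_for(contour_a)
    prep_a = _prep_a if _prep_a is not None else _prep_frame(frame_a, cfg.presmooth_sigma_px)
    prep_b = _prep_b if _prep_b is not None else _prep_frame(frame_b, cfg.presmooth_sigma_px)
    weights = gaussian_roi_weights(
        radius, cfg.kernel_sigma_mm, cfg.support_fraction, spacing_mm
    )
    offs, w = _mask_offsets(weights)

    g = estimate_global_affine(
        frame_a, frame_b, contour_a, cfg, spacing_mm,
        window_radius_mm=radius, _prep_a=prep_a, _prep_b=prep_b,
    )
    centroid = contour_a.points.mean(axis=0)
    stage1 = g.apply(contour_a.points, centroid)

    H, W = np.asarray(frame_a).shape
    final = stage1.copy()
    for i, p_mm in enumerate(stage1):
        p_px = p_mm / spacing_mm
        if not (0 <= p_px[0] <= W - 1 and 0 <= p_px[1] <= H - 1):
            warnings.warn(
                f"contour point {i} left the field of view after the global "
                "stage; local refinement skipped"
            )
            continue
        # Template samples live in frame_a at the point's source ROI; the
        # initial warp places the frame_b ROI at the stage-1 position (the
        # global warp re-parameterized about this point), so the local stage
        # starts from the global prediction and refines the residual motion.
        src_px = contour_a.points[i] / spacing_mm
        loc = _gauss_newton_affine(
            prep_a, prep_b, src_px + offs, w, src_px,
            AffineParams(g.A, stage1[i] - contour_a.points[i]),
            spacing_mm, cfg.max_iterations, cfg.tol_px,
        )
        final[i] = contour_a.points[i] + loc.b

    field = MotionField(contour_a.points, final - contour_a.points)
    return Contour(final, contour_a.mode), field


def propagation_plan(T: int, ref_index: int) -> list[tuple[int, int]]:
    """Bidirectional pairwise propagation order around the reference frame.

    The forward chain ``ref -> ref+1 -> ...`` covers ``ceil((T-1)/2)`` steps
    (cyclic indexing); the backward chain ``ref -> ref-1 -> ...`` covers the
    remaining ``floor((T-1)/2)`` frames.  Every non-reference frame appears
    as a target exactly once.
    """
    if T < 2:
        raise ValueError("need at least 2 frames")
    if not 0 <= ref_index < T:
        raise ValueError("ref_index out of range")
    n_fwd = math.ceil((T - 1) / 2)
    n_bwd = (T - 1) - n_fwd
    plan = []
    for k in range(1, n_fwd + 1):
        plan.append(((ref_index + k - 1) % T, (ref_index + k) % T))
    for k in range(1, n_bwd + 1):
        plan.append(((ref_index - k + 1) % T, (ref_index - k) % T))
    return plan


def track_sequence(
    seq: ImageSequence,
    contour0: Contour,
    cfg: TrackerConfig | None = None,
    *,
    window_radius_mm: float | None = None,
) -> TrackingResult:
    """Track a contour defined at the reference frame through the cycle.

    The contour (segmented at end-diastole, ``seq.ref_index``) is propagated
    pairwise along the bidirectional plan; each step stores its motion
    field.  LAA and thrombus contours are tracked independently — call this
    once per structure, each with its own window radius.
    """
    cfg = cfg or TrackerConfig()
    T = seq.frame_count
    H, W = seq.shape
    extent = np.array([(W - 1) * seq.spacing_mm, (H - 1) * seq.spacing_mm])
    if np.any(contour0.points < 0) or np.any(contour0.points > extent):
        raise ValueError("initial contour extends outside the image")

    plan = propagation_plan(T, seq.ref_index)
    preps: dict[int, tuple] = {}

    def prep(t: int):
        if t not in preps:
            preps[t] = _prep_frame(seq.frames[t], cfg.presmooth_sigma_px)
        return preps[t]

    contours: list = [None] * T
    contours[seq.ref_index] = contour0
    fields: dict[int, MotionField] = {}
    provenance: dict[int, str] = {}
    n_fwd = math.ceil((T - 1) / 2)

    for step, (src, tgt) in enumerate(plan):
        c_tgt, field = track_pair(
            seq.frames[src], seq.frames[tgt], contours[src], cfg, seq.spacing_mm,
            window_radius_mm=window_radius_mm,
            _prep_a=prep(src), _prep_b=prep(tgt),
        )
        pts_px = c_tgt.points / seq.spacing_mm
        inside = (
            (pts_px[:, 0] >= 0) & (pts_px[:, 0] <= W - 1)
            & (pts_px[:, 1] >= 0) & (pts_px[:, 1] <= H - 1)
        )
        if not inside.any():
            raise RuntimeError(
                f"tracked contour left the image entirely at frame {tgt} "
                f"(step {src}->{tgt}); aborting"
            )
        contours[tgt] = c_tgt
        fields[tgt] = field
        provenance[tgt] = "forward" if step < n_fwd else "backward"

    return TrackingResult(contours, fields, plan, provenance, seq.ref_index)
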