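"""Shared fixtures: cached phantom renders and tracked runs.

Full phantom tracking runs take a few seconds each, so they are rendered
and tracked once per session and shared across test modules.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pytest

from laatrack import (
    default_scenarios,
    render_sequence,
    track_sequence,
)


@dataclasses.dataclass
class PhantomRun:
    cfg: object
    seq: object
    gt: object
    laa: object  # TrackingResult
    thr: object  # TrackingResult

    def laa_error_mm(self) -> float:
        """Mean point-to-truth distance of the tracked LAA over all frames."""
        errs = [
            np.linalg.norm(c.points - g.points, axis=1).mean()
            for c, g in zip(self.laa.contours, self.gt.laa_contours)
        ]
        return float(np.mean(errs))

    def thr_error_mm(self) -> float:
        errs = [
            np.linalg.norm(c.points - g.points, axis=1).mean()
            for c, g in zip(self.thr.contours, self.gt.thrombus_contours)
        ]
        return float(np.mean(errs))


@pytest.fixture(scope="session")
def run_phantom():
    """Factory returning a cached rendered + fully tracked phantom run."""
    cache: dict = {}

    def _run(preset: str, seed: int = 0, **overrides) -> PhantomRun:
        key = (preset, seed, tuple(sorted(overrides.items())))
        if key not in cache:
            cfg = dataclasses.replace(
                default_scenarios()[preset], seed=seed, **overrides
            )
            seq, gt = render_sequence(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                laa = track_sequence(seq, cfg.reference_laa_contour())
                thr = track_sequence(seq, cfg.reference_thrombus_contour())
            cache[key] = PhantomRun(cfg, seq, gt, laa, thr)
        return cache[key]

    return _run


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
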