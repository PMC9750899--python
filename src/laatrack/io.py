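"""Reading and writing image sequences, contours and result reports.

On-disk formats are deliberately plain so results can be inspected without
this tool:

* image sequences — multi-page grayscale TIFF plus a JSON sidecar
  ``{"spacing_mm": ..., "ref_index": ...}`` (a directory of per-frame
  PNG/TIFF files is accepted too);
* contours — CSV with columns ``frame,point,x_mm,y_mm`` and a
  ``# boundary_mode: ...`` comment header, or an equivalent JSON dialect;
* reports — JSON.

Coordinate convention used throughout the package: ``x = column * spacing``,
``y = row * spacing``, origin at the centre of the top-left pixel, 0-based
indices.  Contour files always store mm, never pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .contours import Contour, ensure_ccw

__all__ = [
    "ImageSequence",
    "load_sequence",
    "save_sequence",
    "read_contours",
    "write_contours",
    "write_report",
]


@dataclass(frozen=True)
class ImageSequence:
    """T frames of scalar intensity with physical pixel spacing.

    ``frames`` is a ``(T, H, W)`` float array scaled to [0, 1];
    ``spacing_mm`` is the physical size of one (isotropic) pixel;
    ``ref_index`` is the end-diastolic reference frame.  The sequence is
    assumed to span exactly one cardiac cycle — a contract this class
    cannot check.
    """

    frames: np.ndarray
    spacing_mm: float
    ref_index: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=np.float64)
        if fr.ndim != 3:
            raise ValueError(f"frames must be (T, H, W), got shape {fr.shape}")
        if fr.shape[0] < 2:
            raise ValueError("a sequence needs at least 2 frames")
        if not np.all(np.isfinite(fr)):
            raise ValueError("frames contain NaN/inf")
        if not self.spacing_mm > 0:
            raise ValueError("spacing_mm must be positive")
        if not 0 <= int(self.ref_index) < fr.shape[0]:
            raise ValueError(
                f"ref_index {self.ref_index} out of range for T={fr.shape[0]}"
            )
        object.__setattr__(self, "frames", fr)
        object.__setattr__(self, "spacing_mm", float(self.spacing_mm))
        object.__setattr__(self, "ref_index", int(self.ref_index))

    @property
    def frame_count(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _normalize(stack: np.ndarray) -> np.ndarray:
    """Cast to float64 scaled to [0, 1]; integer dtypes scale by dtype max."""
    if np.issubdtype(stack.dtype, np.integer):
        return stack.astype(np.float64) / float(np.iinfo(stack.dtype).max)
    out = stack.astype(np.float64)
    mx = float(out.max(initial=0.0))
    if mx > 1.0:
        out = out / mx
    return out


def load_sequence(path, spacing_override: float | None = None) -> ImageSequence:
    """Load a multi-page TIFF stack (or frame directory) plus its sidecar.

    Physical pixel spacing is mandatory — strain and mobility are reported
    in physical units — so a missing sidecar without ``spacing_override``
    is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    meta: dict = {}
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in {".tif", ".tiff", ".png"}
        )
        if not files:
            raise ValueError(f"no image frames found in directory {path}")
        import imageio.v3 as iio

        frames = [np.asarray(iio.imread(f)) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"frame dimensions differ across files: {shapes}")
        stack = np.stack(frames)
        sidecar = path / "sequence.json"
    else:
        pages = tifffile.imread(path)
        stack = np.asarray(pages)
        if stack.ndim == 2:
            stack = stack[None]
        if stack.ndim != 3:
            raise ValueError(f"expected a grayscale stack, got shape {stack.shape}")
        sidecar = _sidecar_path(path)

    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    spacing = spacing_override if spacing_override is not None else meta.get("spacing_mm")
    if spacing is None:
        raise ValueError(
            "pixel spacing not found: provide a JSON sidecar with 'spacing_mm' "
            "or pass spacing_override (physical units are mandatory)"
        )
    ref_index = int(meta.get("ref_index", 0))
    return ImageSequence(_normalize(stack), float(spacing), ref_index)


def save_sequence(seq: ImageSequence, path) -> None:
    """Write a float32 multi-page TIFF and its JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames.astype(np.float32))
    _sidecar_path(path).write_text(
        json.dumps({"spacing_mm": seq.spacing_mm, "ref_index": seq.ref_index}, indent=1)
    )


def read_contours(path) -> list[tuple[int, Contour]]:
    """Read ``(frame_index, Contour)`` pairs from CSV or JSON.

    CSV layout: comment header lines (``# boundary_mode: constant``), then
    ``frame,point,x_mm,y_mm`` rows.  Point indices must be contiguous from 0
    within each frame block.  Periodic contours are normalized to
    counterclockwise order.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        mode = payload.get("boundary_mode", "constant")
        out = []
        for rec in payload["contours"]:
            pts = np.asarray(rec["points_mm"], dtype=float)
            out.append((int(rec["frame"]), ensure_ccw(Contour(pts, mode))))
        return out

    mode = "constant"
    rows: list[tuple[int, int, float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "boundary_mode" in line:
                    mode = line.split(":", 1)[1].strip()
                continue
            if line.lower().startswith("frame"):
                continue
            f, p, x, y = line.split(",")
            rows.append((int(f), int(p), float(x), float(y)))
    if not rows:
        raise ValueError(f"no contour rows in {path}")

    out = []
    frames = sorted({r[0] for r in rows})
    for f in frames:
        block = sorted((r for r in rows if r[0] == f), key=lambda r: r[1])
        indices = [r[1] for r in block]
        if indices != list(range(len(block))):
            raise ValueError(
                f"point indices for frame {f} are not contiguous from 0: {indices}"
            )
        pts = np.array([(r[2], r[3]) for r in block], dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"NaN coordinates in frame {f}")
        out.append((f, ensure_ccw(Contour(pts, mode))))
    return out


def write_contours(tracks: list[tuple[int, Contour]], path) -> None:
    """Write ``(frame_index, Contour)`` pairs as CSV (mirror of read_contours)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mode = tracks[0][1].mode if tracks else "constant"
    lines = [f"# boundary_mode: {mode}", "frame,point,x_mm,y_mm"]
    for frame, contour in tracks:
        for i, (x, y) in enumerate(contour.points):
            lines.append(f"{frame},{i},{x:.6f},{y:.6f}")
    path.write_text("\n".join(lines) + "\n")


def write_report(results: dict, path) -> None:
    """Serialize strain/mobility summaries and per-frame curves to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    path.write_text(json.dumps(_clean(results), indent=1))
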