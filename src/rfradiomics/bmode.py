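"""B-mode image formation and ROI materialisation in scan-line coordinates.

The grayscale image is formed the conventional way: per scan line, the
magnitude of the analytic signal (Hilbert envelope), then logarithmic
compression to a display dynamic range.  The region of interest is given as
four corner markers in scan-line coordinates (the sonographer's "fork"
points) and rasterised to a boolean mask.
"""

from __future__ import annotations

from typing import Tuple, Union

import numpy as np
from scipy.signal import hilbert

from .core import ROIRegion, RFFrame

__all__ = ["hilbert_envelope", "log_compress", "roi_from_markers"]


def hilbert_envelope(frame: Union[RFFrame, np.ndarray]) -> np.ndarray:
    """Per-scan-line envelope: magnitude of the analytic signal.

    Accepts an RFFrame or a bare (samples x lines) matrix.  The transform
    runs along axis 0 (the axial/time axis).  No edge tapering is applied;
    edge samples carry the usual analytic-signal edge error.
    """
    rf = frame.samples if isinstance(frame, RFFrame) else np.asarray(frame, dtype=float)
    if rf.ndim != 2 or rf.size == 0:
        raise ValueError("RF input must be a nonempty 2-D matrix")
    if not np.all(np.isfinite(rf)):
        raise ValueError("RF input contains non-finite values")
    return np.abs(hilbert(rf, axis=0))


def log_compress(envelope: np.ndarray, dynamic_range_db: float = 60.0) -> np.ndarray:
    """Log-compress an envelope to an 8-bit image.

    20*log10(envelope/max) is clipped to [-DR, 0] and affinely mapped to
    [0, 255]; the envelope maximum maps to 255, anything at or below
    -DR dB maps to 0.
    """
    env = np.asarray(envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    if dynamic_range_db <= 0:
        raise ValueError("dynamic_range_db must be positive")
    peak = env.max()
    if peak <= 0:
        raise ValueError("all-zero envelope: log compression undefined")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(env / peak)
    db = np.clip(db, -dynamic_range_db, 0.0)
    img = 255.0 * (1.0 + db / dynamic_range_db)
    return np.floor(img + 0.5).astype(np.uint8)


def _point_in_quad(
    points_r: np.ndarray, points_c: np.ndarray, quad: np.ndarray
) -> np.ndarray:
    """Vectorised point-in-polygon for a convex-ordered quadrilateral.

    Boundary points count as inside.  quad is (4, 2) in (row, col) order
    (counter-clockwise or clockwise; handled by sign normalisation).
    """
    inside = np.ones(points_r.shape, dtype=bool)
    on_edge = np.zeros(points_r.shape, dtype=bool)
    # orientation sign from the polygon area
    r, c = quad[:, 0], quad[:, 1]
    area2 = np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c)
    sign = 1.0 if area2 > 0 else -1.0
    for k in range(4):
        r0, c0 = quad[k]
        r1, c1 = quad[(k + 1) % 4]
        cross = (r1 - r0) * (points_c - c0) - (c1 - c0) * (points_r - r0)
        on_seg = (
            (np.abs(cross) < 1e-9)
            & (points_r >= min(r0, r1) - 1e-9)
            & (points_r <= max(r0, r1) + 1e-9)
            & (points_c >= min(c0, c1) - 1e-9)
            & (points_c <= max(c0, c1) + 1e-9)
        )
        on_edge |= on_seg
        inside &= sign * cross >= -1e-9
    return inside | on_edge


def roi_from_markers(
    markers: np.ndarray, frame_shape: Tuple[int, int]
) -> ROIRegion:
    """Build a ROI from four corner markers.

    The markers are ordered by angle about their centroid (so any input
    permutation yields the same quadrilateral) and the filled quadrilateral
    is rasterised with a pixel-centre-inside rule; boundary pixels count as
    inside.
    """
    pts = np.asarray(markers, dtype=float)
    if pts.shape != (4, 2):
        raise ValueError("exactly four (row, col) markers are required")
    n_rows, n_cols = frame_shape
    if (
        np.any(pts[:, 0] < 0) or np.any(pts[:, 0] > n_rows - 1)
        or np.any(pts[:, 1] < 0) or np.any(pts[:, 1] > n_cols - 1)
    ):
        raise ValueError("markers lie outside the frame")

    centroid = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1]))
    quad = pts[order]

    # degeneracy: all four points (near-)collinear => zero area
    r, c = quad[:, 0], quad[:, 1]
    area2 = abs(np.sum(r * np.roll(c, -1) - np.roll(r, -1) * c))
    if area2 < 1e-9:
        raise ValueError("markers are collinear or coincident")

    r0 = int(np.floor(pts[:, 0].min()))
    r1 = int(np.ceil(pts[:, 0].max()))
    c0 = int(np.floor(pts[:, 1].min()))
    c1 = int(np.ceil(pts[:, 1].max()))
    rr, cc = np.meshgrid(
        np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij"
    )
    sub = _point_in_quad(rr.astype(float), cc.astype(float), quad)
    mask = np.zeros(frame_shape, dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = sub
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)
    return ROIRegion(marker_points=pts, mask=mask, bounding_box=bbox)
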