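"""Readers/writers for frames, maps and results.

RF frames are exchanged as a bare matrix file — either a flat binary of
32-bit floats in column-major scan-line order (``.bin``) or a plain-text
matrix (``.txt``, one axial sample per row, one column per scan line) —
plus a JSON sidecar named ``<base>.json`` carrying the acquisition metadata
and, when present, the label and the four ROI marker points.  On load the
ROI mask is re-derived from the markers (the mask itself is not stored).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
from PIL import Image

from .bmode import roi_from_markers
from .core import AcquisitionGeometry, FeatureMap, RFFrame
from .selection import SelectionResult

__all__ = [
    "save_frame",
    "load_frame",
    "save_bmp",
    "save_map",
    "save_selection",
]


def save_frame(frame: RFFrame, base: Union[str, Path], fmt: str = "binary") -> Path:
    """Write a frame as <base>.bin or <base>.txt plus <base>.json sidecar."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "binary":
        data_path = base.with_suffix(".bin")
        frame.samples.astype("<f4").T.tofile(data_path)  # column-major scan lines
    elif fmt == "text":
        data_path = base.with_suffix(".txt")
        np.savetxt(data_path, frame.samples, fmt="%.7g")
    else:
        raise ValueError("fmt must be 'binary' or 'text'")
    g = frame.geometry
    sidecar = {
        "sampling_frequency": g.sampling_frequency,
        "center_frequency": g.center_frequency,
        "n_scanlines": g.n_scanlines,
        "samples_per_line": g.samples_per_line,
        "pulse_bandwidth": g.pulse_bandwidth,
        "label": frame.label,
        "roi_markers": (
            frame.lesion_roi.marker_points.tolist() if frame.lesion_roi else None
        ),
        "format": fmt,
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return data_path


def load_frame(base: Union[str, Path]) -> RFFrame:
    """Load a frame written by save_frame (either format)."""
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    geometry = AcquisitionGeometry(
        sampling_frequency=meta["sampling_frequency"],
        center_frequency=meta["center_frequency"],
        n_scanlines=meta["n_scanlines"],
        samples_per_line=meta["samples_per_line"],
        pulse_bandwidth=meta.get("pulse_bandwidth", 0.6),
    )
    shape = (geometry.samples_per_line, geometry.n_scanlines)
    if meta.get("format", "binary") == "binary":
        raw = np.fromfile(base.with_suffix(".bin"), dtype="<f4")
        samples = raw.reshape(geometry.n_scanlines, geometry.samples_per_line).T
    else:
        samples = np.loadtxt(base.with_suffix(".txt")).reshape(shape)
    roi = None
    if meta.get("roi_markers"):
        roi = roi_from_markers(np.asarray(meta["roi_markers"]), shape)
    return RFFrame(
        samples=samples.astype(float), geometry=geometry,
        label=meta.get("label"), lesion_roi=roi,
    )


def save_bmp(image: np.ndarray, path: Union[str, Path]) -> Path:
    """Write an 8-bit grayscale image as BMP."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="L").save(path, "BMP")
    return path


def save_map(fmap: FeatureMap, base: Union[str, Path]) -> Tuple[Path, Path]:
    """Write a feature map as BMP + JSON sidecar with the raw value range.

    The sidecar makes the 8-bit rendering invertible up to quantisation.
    """
    base = Path(base)
    bmp = save_bmp(fmap.rendering, base.with_suffix(".bmp"))
    w = fmap.window
    sidecar = {
        "kind": fmap.kind,
        "value_min": float(fmap.values.min()),
        "value_max": float(fmap.values.max()),
        "n_imputed": fmap.n_imputed,
        "window": {
            "axial_len": w.axial_len, "lateral_len": w.lateral_len,
            "axial_step": w.axial_step, "lateral_step": w.lateral_step,
        },
    }
    json_path = base.with_suffix(".map.json")
    json_path.write_text(json.dumps(sidecar, indent=1))
    return bmp, json_path


def save_selection(sel: SelectionResult, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(sel.to_dict(), indent=1))
    return path
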