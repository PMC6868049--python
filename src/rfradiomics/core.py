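"""Core domain types shared across the pipeline.

The data model follows the scan-line representation of beamformed ultrasound
radio-frequency (RF) data: a rectangular matrix of axial samples (rows) by
acquisition lines (columns), before any geometric scan conversion.  All
spatial coordinates in this package are (row, col) = (axial sample index,
scan-line index) in that matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

SOUND_SPEED_M_S = 1540.0  # assumed soft-tissue sound speed


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Acquisition context of an RF frame.

    Parameters
    ----------
    sampling_frequency : float
        RF sampling rate in Hz.  Must be at least 4x the pulse centre
        frequency (Nyquist with margin).
    center_frequency : float
        Pulse centre frequency in Hz.
    n_scanlines : int
        Number of acquisition lines (matrix columns).
    samples_per_line : int
        Axial samples per line (matrix rows).
    pulse_bandwidth : float
        Fractional -6 dB two-sided bandwidth of the Gaussian pulse
        envelope, relative to the centre frequency.
    """

    sampling_frequency: float = 20e6
    center_frequency: float = 3e6
    n_scanlines: int = 128
    samples_per_line: int = 2048
    pulse_bandwidth: float = 0.6

    def __post_init__(self) -> None:
        if self.sampling_frequency < 4 * self.center_frequency:
            raise ValueError(
                "sampling_frequency must be >= 4 x center_frequency "
                f"(got {self.sampling_frequency:g} < 4 x {self.center_frequency:g})"
            )
        if self.n_scanlines < 1 or self.samples_per_line < 1:
            raise ValueError("scan-line and sample counts must be >= 1")
        if self.center_frequency <= 0 or self.pulse_bandwidth <= 0:
            raise ValueError("center_frequency and pulse_bandwidth must be positive")

    @property
    def axial_step_mm(self) -> float:
        """Axial extent of one sample in mm (echo round trip at 1540 m/s)."""
        return SOUND_SPEED_M_S / (2.0 * self.sampling_frequency) * 1e3

    @property
    def depth_axis_cm(self) -> np.ndarray:
        """Depth of each axial sample in cm."""
        return np.arange(self.samples_per_line) * self.axial_step_mm / 10.0


@dataclass(frozen=True)
class TissueClassParams:
    """Acoustic parameters of one tissue class.

    attenuation_db_per_cm_mhz
        Frequency-normalised amplitude attenuation coefficient alpha
        (dB cm^-1 MHz^-1); the RF amplitude decays as
        10^(-alpha * f_c[MHz] * z[cm] / 20).
    nakagami_m, nakagami_omega
        Shape and scale of the Nakagami envelope law: the local echo
        envelope R satisfies R^2 ~ Gamma(m, omega/m), so E[R^2] = omega.
    scatterer_density
        Scatterers per resolution cell.  At the default 1 the drawn
        Nakagami amplitude is carried by a single resolvable scatterer;
        larger values split it over diffuse sub-scatterers (envelope
        statistics then drift toward Rayleigh, as in real tissue).
    spectral_jitter_sd
        Fractional SD of the per-cell perturbation of the pulse centre
        frequency; models local spectral heterogeneity.
    """

    attenuation_db_per_cm_mhz: float = 0.5
    nakagami_m: float = 1.0
    nakagami_omega: float = 1.0
    scatterer_density: float = 1.0
    spectral_jitter_sd: float = 0.03

    def __post_init__(self) -> None:
        if self.attenuation_db_per_cm_mhz < 0:
            raise ValueError("attenuation must be >= 0")
        if self.nakagami_m <= 0 or self.nakagami_omega <= 0:
            raise ValueError("Nakagami m and omega must be > 0")
        if self.scatterer_density < 1:
            raise ValueError("scatterer_density must be >= 1")
        if self.spectral_jitter_sd < 0:
            raise ValueError("spectral_jitter_sd must be >= 0")


@dataclass
class ROIRegion:
    """A region of interest in scan-line coordinates.

    marker_points are four (row, col) corner markers (the sonographer's
    "fork" points); mask is a boolean matrix of the full frame shape;
    bounding_box is half-open (row0, row1, col0, col1).
    """

    marker_points: np.ndarray
    mask: np.ndarray
    bounding_box: Tuple[int, int, int, int]

    def __post_init__(self) -> None:
        self.marker_points = np.asarray(self.marker_points, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")
        r0, r1, c0, c1 = self.bounding_box
        rows, cols = np.nonzero(self.mask)
        if rows.min() < r0 or rows.max() >= r1 or cols.min() < c0 or cols.max() >= c1:
            raise ValueError("mask extends outside the bounding box")
        if r0 < 0 or c0 < 0 or r1 > self.mask.shape[0] or c1 > self.mask.shape[1]:
            raise ValueError("bounding box outside the frame")

    @property
    def mask_in_box(self) -> np.ndarray:
        r0, r1, c0, c1 = self.bounding_box
        return self.mask[r0:r1, c0:c1]

    def crop(self, array: np.ndarray) -> np.ndarray:
        """Crop a frame-shaped array to the ROI bounding box."""
        r0, r1, c0, c1 = self.bounding_box
        return array[r0:r1, c0:c1]


@dataclass
class RFFrame:
    """One RF acquisition: samples (axial sample x scan line) + metadata."""

    samples: np.ndarray
    geometry: AcquisitionGeometry
    label: Optional[int] = None
    lesion_roi: Optional[ROIRegion] = None
    sim_info: dict = field(default_factory=dict)  # simulator provenance (if synthetic)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("RF samples must be a 2-D matrix")
        expected = (self.geometry.samples_per_line, self.geometry.n_scanlines)
        if self.samples.shape != expected:
            raise ValueError(
                f"RF matrix shape {self.samples.shape} does not match geometry {expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF matrix contains non-finite values")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding analysis window over the ROI RF matrix.

    Lengths/steps are in axial samples and scan lines.  Defaults: 128
    samples x 8 lines with 50% overlap on both axes — standard
    quantitative-ultrasound window sizing at a 20 MHz sampling rate.
    """

    axial_len: int = 128
    lateral_len: int = 8
    axial_step: int = 64
    lateral_step: int = 4

    def __post_init__(self) -> None:
        if self.axial_len < 8 or self.lateral_len < 2:
            raise ValueError("window must be >= 8 samples axially and >= 2 lines")
        if self.axial_step < 1 or self.lateral_step < 1:
            raise ValueError("window steps must be >= 1")

    def grid_shape(self, roi_shape: Tuple[int, int]) -> Tuple[int, int]:
        """Number of window positions (rows, cols) over a ROI of roi_shape."""
        n_r, n_c = roi_shape
        if n_r < self.axial_len or n_c < self.lateral_len:
            raise ValueError(
                f"ROI {roi_shape} smaller than one window "
                f"({self.axial_len} x {self.lateral_len})"
            )
        return (
            (n_r - self.axial_len) // self.axial_step + 1,
            (n_c - self.lateral_len) // self.lateral_step + 1,
        )


@dataclass
class FeatureMap:
    """A 2-D parametric map over sliding-window positions.

    kind is one of {"DEA", "SDSD", "OND"}; values is the raw map on the
    window grid; rendering its 8-bit min-max image; n_imputed counts
    windows whose value was undefined and mean-imputed.
    """

    kind: str
    values: np.ndarray
    window: WindowSpec
    rendering: Optional[np.ndarray] = None
    diagnostics: dict = field(default_factory=dict)
    n_imputed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in {"DEA", "SDSD", "OND"}:
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values after imputation")
        if self.kind == "OND" and np.any(self.values <= 0):
            raise ValueError("OND values must be positive")
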