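"""Synthetic RF cohort generator.

Stands in for clinical RF acquisitions: each scan line is a train of
resolvable point scatterers convolved with a Gaussian-modulated sinusoidal
pulse, multiplied by depth-dependent attenuation.  Scatterer amplitudes are
drawn directly from the Nakagami(m, omega) envelope law of the enclosing
tissue (gamma-distributed power, square root), which guarantees the envelope
statistics the Nakagami-scale (OND) estimator assumes without tuning
scatterer counts.  Attenuation follows the single-band model
amplitude ∝ 10^(-alpha · f_c · z / 20) with alpha in dB cm^-1 MHz^-1 and z
the depth in cm, so the envelope log-power declines at alpha·f_c dB per cm.

Two tissue classes emulate a case/control lesion cohort: the positive class
has larger-magnitude attenuation, lower Nakagami shape and stronger local
spectral jitter than the negative class, so all three parametric maps
(DEA, OND, SDSD) carry class signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .core import AcquisitionGeometry, ROIRegion, RFFrame, TissueClassParams

__all__ = [
    "EllipseSpec",
    "CohortJitter",
    "MVI_POS_PARAMS",
    "MVI_NEG_PARAMS",
    "BACKGROUND_PARAMS",
    "pulse_sigma_samples",
    "resolution_cell_length",
    "default_lesion_shape",
    "simulate_rf_frame",
    "make_cohort",
]

#: Default class contrast: the positive (MVI+) class attenuates more
#: strongly, is more pre-Rayleigh (lower m) and spectrally noisier.
MVI_POS_PARAMS = TissueClassParams(
    attenuation_db_per_cm_mhz=0.9, nakagami_m=0.8, nakagami_omega=1.2,
    spectral_jitter_sd=0.08,
)
MVI_NEG_PARAMS = TissueClassParams(
    attenuation_db_per_cm_mhz=0.5, nakagami_m=1.1, nakagami_omega=1.2,
    spectral_jitter_sd=0.03,
)
#: Surrounding liver parenchyma.
BACKGROUND_PARAMS = TissueClassParams(
    attenuation_db_per_cm_mhz=0.5, nakagami_m=1.0, nakagami_omega=1.0,
    spectral_jitter_sd=0.03,
)


@dataclass(frozen=True)
class EllipseSpec:
    """Lesion footprint: an axis-aligned ellipse in (row, col) coordinates."""

    center_row: float
    center_col: float
    semi_rows: float
    semi_cols: float

    def __post_init__(self) -> None:
        if self.semi_rows <= 0 or self.semi_cols <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        return (
            ((rows - self.center_row) / self.semi_rows) ** 2
            + ((cols - self.center_col) / self.semi_cols) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class CohortJitter:
    """Per-frame (between-lesion) variability around the class means.

    attenuation_sd is absolute (dB cm^-1 MHz^-1); m_sd is absolute;
    omega_rel_sd and spectral_jitter_rel_sd are sigmas of multiplicative
    lognormal factors; shape_rel_sd scales the lesion semi-axes
    multiplicatively.
    """

    attenuation_sd: float = 0.05
    m_sd: float = 0.25
    omega_rel_sd: float = 0.10
    spectral_jitter_rel_sd: float = 0.40
    shape_rel_sd: float = 0.10


def pulse_sigma_samples(geometry: AcquisitionGeometry) -> float:
    """Temporal sigma of the Gaussian pulse envelope, in samples.

    Chosen so the -6 dB (half-amplitude) two-sided spectral width equals
    pulse_bandwidth x center_frequency.
    """
    sigma_t = math.sqrt(2.0 * math.log(2.0)) / (
        math.pi * geometry.pulse_bandwidth * geometry.center_frequency
    )
    return sigma_t * geometry.sampling_frequency


def resolution_cell_length(geometry: AcquisitionGeometry) -> int:
    """Axial scatterer-cell length in samples (= pulse support, 2x4 sigma)."""
    half = int(math.ceil(4.0 * pulse_sigma_samples(geometry)))
    return 2 * half + 1


def default_lesion_shape(geometry: AcquisitionGeometry) -> EllipseSpec:
    """Mid-depth, mid-aperture ellipse covering ~23% of depth, ~37% of lines.

    At the default geometry this is ~1.8 cm axially — a desk-scale stand-in
    for a sub-5-cm hepatic lesion.
    """
    return EllipseSpec(
        center_row=geometry.samples_per_line / 2.0,
        center_col=geometry.n_scanlines / 2.0,
        semi_rows=round(geometry.samples_per_line * 240 / 2048),
        semi_cols=round(geometry.n_scanlines * 24 / 128),
    )


def _nakagami_amplitudes(
    rng: np.random.Generator, m: float, omega: float, size: int
) -> np.ndarray:
    # R^2 ~ Gamma(m, omega/m)  =>  E[R^2] = omega
    return np.sqrt(rng.gamma(shape=m, scale=omega / m, size=size))


def _ellipse_roi(shape: EllipseSpec, frame_shape: Tuple[int, int]) -> ROIRegion:
    n_rows, n_cols = frame_shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    mask = shape.contains(rr, cc)
    rows, cols = np.nonzero(mask)
    bbox = (int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1)
    markers = np.array(
        [
            (shape.center_row - shape.semi_rows, shape.center_col),
            (shape.center_row + shape.semi_rows, shape.center_col),
            (shape.center_row, shape.center_col - shape.semi_cols),
            (shape.center_row, shape.center_col + shape.semi_cols),
        ]
    )
    return ROIRegion(marker_points=markers, mask=mask, bounding_box=bbox)


def simulate_rf_frame(
    geometry: AcquisitionGeometry,
    background: TissueClassParams,
    lesion: Optional[TissueClassParams] = None,
    lesion_shape: Optional[EllipseSpec] = None,
    seed: int = 0,
    label: Optional[int] = None,
    tgc_error_sd_db: float = 2.5,
) -> RFFrame:
    """Simulate one RF frame with an optional elliptical lesion.

    With ``lesion=None`` the frame is homogeneous background tissue and no
    ROI is attached.  Reproducible: identical arguments give a bit-identical
    matrix.

    Alongside the RF matrix, the acquisition's *display* time-gain curve is
    emulated and stored in ``sim_info["display_gain_db"]``: the operator's
    TGC roughly compensates the background attenuation but with a smooth
    per-acquisition error (linear interpolation of 6 knots drawn
    N(0, tgc_error_sd_db)).  The raw RF is NOT affected — only the
    displayed grayscale image downstream applies this curve, mirroring the
    fact that clinical display processing never reaches the RF data.
    """
    if (lesion is None) != (lesion_shape is None):
        raise ValueError("lesion and lesion_shape must be given together")
    n_rows, n_cols = geometry.samples_per_line, geometry.n_scanlines
    if lesion_shape is not None:
        if (
            lesion_shape.center_row - lesion_shape.semi_rows < 0
            or lesion_shape.center_row + lesion_shape.semi_rows > n_rows - 1
            or lesion_shape.center_col - lesion_shape.semi_cols < 0
            or lesion_shape.center_col + lesion_shape.semi_cols > n_cols - 1
        ):
            raise ValueError("lesion ellipse does not fit inside the frame")

    rng = np.random.default_rng(seed)
    sigma_s = pulse_sigma_samples(geometry)
    half = int(math.ceil(4.0 * sigma_s))
    cell_len = 2 * half + 1
    # scatterer lattice: one cell per pulse support, with an independent
    # random phase per scan line (a fixed lattice aliases against the
    # analysis windows and leaves deterministic energy-slope artifacts);
    # the lattice overruns the bottom edge so pulse coverage is complete
    lattice_phase = rng.integers(0, cell_len, size=n_cols)
    max_cells = int(math.ceil(n_rows / cell_len)) + 1
    grid = (
        lattice_phase[:, None] - cell_len + half
        + np.arange(max_cells + 1)[None, :] * cell_len
    )                                                          # (n_cols, K)
    valid = (grid - half < n_rows) & (grid + half >= 0)
    cell_rows = grid[valid]
    cell_cols = np.broadcast_to(
        np.arange(n_cols)[:, None], grid.shape
    )[valid]
    if lesion_shape is not None:
        in_lesion = lesion_shape.contains(cell_rows.astype(float), cell_cols.astype(float))
    else:
        in_lesion = np.zeros(cell_rows.size, dtype=bool)

    n_total = cell_rows.size
    amp = np.empty(n_total)
    freq_sd = np.where(
        in_lesion,
        lesion.spectral_jitter_sd if lesion else 0.0,
        background.spectral_jitter_sd,
    )
    for params, sel in ((background, ~in_lesion), (lesion, in_lesion)):
        if params is None or not sel.any():
            continue
        amp[sel] = _nakagami_amplitudes(
            rng, params.nakagami_m, params.nakagami_omega, int(sel.sum())
        )

    density = int(round(background.scatterer_density))
    if lesion is not None:
        density = max(density, int(round(lesion.scatterer_density)))

    # expand each cell draw over `density` diffuse sub-scatterers
    jitter_range = max(1, cell_len // 8)
    pos = np.repeat(cell_rows, density) + rng.integers(
        -jitter_range, jitter_range + 1, size=n_total * density
    )  # may overhang both frame edges; padding below absorbs it
    line = np.repeat(cell_cols, density)
    s_amp = np.repeat(amp / math.sqrt(density), density) * rng.choice(
        (-1.0, 1.0), size=n_total * density
    )
    eps = rng.standard_normal(n_total * density) * np.repeat(freq_sd, density)
    s_freq = geometry.center_frequency * (1.0 + eps)

    # per-scatterer pulse waveforms, vectorised
    offsets = np.arange(-half, half + 1)
    t = offsets / geometry.sampling_frequency                  # (L,)
    envelope = np.exp(-(t**2) / (2.0 * (sigma_s / geometry.sampling_frequency) ** 2))
    waves = s_amp[:, None] * envelope[None, :] * np.cos(
        2.0 * math.pi * s_freq[:, None] * t[None, :]
    )

    shift = 3 * half
    pad_len = n_rows + 6 * half
    padded = np.zeros((n_cols, pad_len))
    flat_idx = line[:, None] * pad_len + (pos[:, None] + offsets[None, :] + shift)
    np.add.at(padded.ravel(), flat_idx.ravel(), waves.ravel())
    rf = padded[:, shift : shift + n_rows].T                   # (rows, cols)

    # cumulative single-band attenuation along each line
    alpha = np.full((n_rows, n_cols), background.attenuation_db_per_cm_mhz)
    roi = None
    if lesion_shape is not None:
        roi = _ellipse_roi(lesion_shape, (n_rows, n_cols))
        alpha[roi.mask] = lesion.attenuation_db_per_cm_mhz
    dz_cm = geometry.axial_step_mm / 10.0
    atten_db = geometry.center_frequency / 1e6 * np.cumsum(alpha * dz_cm, axis=0)
    rf *= 10.0 ** (-atten_db / 20.0)

    # operator TGC curve for the displayed image: compensates background
    # attenuation up to a smooth random slider error
    depth_cm = geometry.depth_axis_cm
    knots = np.linspace(0.0, depth_cm[-1], 6)
    knot_err = rng.normal(0.0, tgc_error_sd_db, size=knots.size)
    display_gain_db = (
        background.attenuation_db_per_cm_mhz
        * (geometry.center_frequency / 1e6)
        * depth_cm
        + np.interp(depth_cm, knots, knot_err)
    )

    return RFFrame(
        samples=rf, geometry=geometry, label=label, lesion_roi=roi,
        sim_info={
            "lattice_phase": lattice_phase,
            "cell_len": cell_len,
            "half": half,
            "seed": seed,
            "display_gain_db": display_gain_db,
        },
    )


def envelope_cell_peaks(frame: RFFrame, envelope: np.ndarray) -> np.ndarray:
    """Per-resolution-cell envelope maxima of a simulated frame.

    Each scatterer cell of the simulation lattice contributes its envelope
    peak, which (for resolvable scatterers, density 1) equals the drawn
    Nakagami amplitude up to attenuation.  Edge cells are dropped.  Only
    valid for frames produced by simulate_rf_frame (uses sim_info).
    """
    if "lattice_phase" not in frame.sim_info:
        raise ValueError("frame carries no simulation lattice information")
    phases = frame.sim_info["lattice_phase"]
    cell_len = frame.sim_info["cell_len"]
    n_rows = envelope.shape[0]
    peaks = []
    for col, phase in enumerate(phases):
        starts = np.arange(phase, n_rows - cell_len, cell_len)[1:-1]
        for s in starts:
            peaks.append(envelope[s : s + cell_len, col].max())
    return np.asarray(peaks)


def _jittered(
    params: TissueClassParams, jitter: CohortJitter, rng: np.random.Generator
) -> TissueClassParams:
    alpha = max(0.0, params.attenuation_db_per_cm_mhz + rng.normal(0, jitter.attenuation_sd))
    m = max(0.1, params.nakagami_m + rng.normal(0, jitter.m_sd))
    omega = params.nakagami_omega * math.exp(rng.normal(0, jitter.omega_rel_sd))
    sj = params.spectral_jitter_sd * math.exp(
        rng.normal(0, jitter.spectral_jitter_rel_sd)
    )
    return replace(
        params, attenuation_db_per_cm_mhz=alpha, nakagami_m=m,
        nakagami_omega=omega, spectral_jitter_sd=sj,
    )


def make_cohort(
    n_pos: int,
    n_neg: int,
    pos_params: TissueClassParams = MVI_POS_PARAMS,
    neg_params: TissueClassParams = MVI_NEG_PARAMS,
    geometry: AcquisitionGeometry = AcquisitionGeometry(),
    seed: int = 0,
    background: TissueClassParams = BACKGROUND_PARAMS,
    jitter: CohortJitter = CohortJitter(),
    lesion_shape: Optional[EllipseSpec] = None,
) -> List[RFFrame]:
    """Simulate a labelled cohort of n_pos positive + n_neg negative frames.

    Per-frame lesion parameters are jittered around the class means (so
    within-class variability exists) and the lesion ellipse is jittered in
    size and centre.  All randomness flows from one generator seeded with
    ``seed``; the cohort is fully reproducible.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    base_shape = lesion_shape or default_lesion_shape(geometry)
    rng = np.random.default_rng(seed)
    frames: List[RFFrame] = []
    for label, class_params in [(1, pos_params)] * n_pos + [(0, neg_params)] * n_neg:
        lesion = _jittered(class_params, jitter, rng)
        scale_r = math.exp(rng.normal(0, jitter.shape_rel_sd))
        scale_c = math.exp(rng.normal(0, jitter.shape_rel_sd))
        shape = EllipseSpec(
            center_row=base_shape.center_row + rng.normal(0, base_shape.semi_rows * 0.05),
            center_col=base_shape.center_col + rng.normal(0, base_shape.semi_cols * 0.05),
            semi_rows=base_shape.semi_rows * scale_r,
            semi_cols=base_shape.semi_cols * scale_c,
        )
        frame_seed = int(rng.integers(0, 2**31 - 1))
        frames.append(
            simulate_rf_frame(
                geometry, background, lesion, shape, seed=frame_seed, label=label
            )
        )
    return frames
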