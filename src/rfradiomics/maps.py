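"""First feature extraction: parametric ultrasound maps over sliding windows.

Three maps are computed from the ROI RF data, one per signal domain:

DEA (direct energy attenuation, time domain)
    Per window, the least-squares slope (dB/cm) of 10*log10(windowed mean
    squared RF) against axial depth across sub-windows; negative values mean
    energy loss with depth.

SDSD (standard deviation of spectrum difference, frequency domain)
    Per window, the standard deviation over the pulse band of the window's
    mean magnitude spectrum (dB) minus a reference spectrum — the mean
    spectrum of the shallowest window row of the same ROI.  A pure amplitude
    change shifts the dB spectrum uniformly and leaves SDSD at zero; only
    spectral-shape differences register.

OND (omega of the Nakagami distribution, statistical domain)
    Per window, the moment estimate of the Nakagami scale on the envelope R:
    omega_hat = mean(R^2); the shape m_hat = mean(R^2)^2 / var(R^2) is kept
    as a diagnostic.

Window positions with undefined values (zero energy) are recorded and
mean-imputed from the rest of the map before rendering.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import SOUND_SPEED_M_S, FeatureMap, WindowSpec

__all__ = ["dea_map", "sdsd_map", "ond_map", "render_map"]


def _windows(roi: np.ndarray, w: WindowSpec) -> np.ndarray:
    """View of shape (grid_r, grid_c, axial_len, lateral_len)."""
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2:
        raise ValueError("ROI input must be 2-D")
    w.grid_shape(roi.shape)  # validates size
    sw = sliding_window_view(roi, (w.axial_len, w.lateral_len))
    return sw[:: w.axial_step, :: w.lateral_step]


def _impute(values: np.ndarray, kind: str) -> Tuple[np.ndarray, int]:
    bad = ~np.isfinite(values)
    n_bad = int(bad.sum())
    if n_bad == values.size:
        raise ValueError(f"all {kind} windows undefined; cannot impute")
    if n_bad:
        values = values.copy()
        values[bad] = values[~bad].mean()
    return values, n_bad


def dea_map(roi_rf: np.ndarray, window: WindowSpec = WindowSpec(),
            fs: float = 20e6) -> FeatureMap:
    """Direct-energy-attenuation map (dB/cm) of a ROI RF matrix."""
    sw = _windows(roi_rf, window)
    n_sub = 8
    sub_len = max(1, window.axial_len // n_sub)
    n_sub = window.axial_len // sub_len
    trimmed = sw[:, :, : n_sub * sub_len, :]
    # energy per sub-window: mean square over (sub_len, lateral)
    e = (
        trimmed.reshape(sw.shape[0], sw.shape[1], n_sub, sub_len, -1) ** 2
    ).mean(axis=(3, 4))
    dz_cm = SOUND_SPEED_M_S / (2.0 * fs) * 1e2
    depth = (np.arange(n_sub) + 0.5) * sub_len * dz_cm      # relative depth, cm
    with np.errstate(divide="ignore"):
        e_db = 10.0 * np.log10(e)
    e_db[e <= 0] = np.nan
    x = depth - depth.mean()
    denom = (x**2).sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        centred = e_db - np.nanmean(e_db, axis=2, keepdims=True)
    slope = np.einsum("rck,k->rc", centred, x) / denom
    slope[np.any(~np.isfinite(e_db), axis=2)] = np.nan
    values, n_bad = _impute(slope, "DEA")
    fmap = FeatureMap(kind="DEA", values=values, window=window, n_imputed=n_bad)
    fmap.rendering = render_map(fmap)
    return fmap


def sdsd_map(roi_rf: np.ndarray, window: WindowSpec = WindowSpec(),
             fs: float = 20e6, band_drop_db: float = 20.0) -> FeatureMap:
    """Standard-deviation-of-spectrum-difference map of a ROI RF matrix.

    The pulse band is estimated from the data as the frequencies within
    ``band_drop_db`` of the peak of the ROI-mean magnitude spectrum; the
    reference spectrum is the mean dB spectrum of the shallowest window row.
    """
    sw = _windows(roi_rf, window)
    taper = np.hanning(window.axial_len)
    spec = np.abs(np.fft.rfft(sw * taper[None, None, :, None], axis=2))
    mag = spec.mean(axis=3)                                  # (gr, gc, F)
    zero_energy = ~(mag.sum(axis=2) > 0)
    mean_mag = mag.mean(axis=(0, 1))
    band = mean_mag >= mean_mag.max() * 10.0 ** (-band_drop_db / 20.0)
    with np.errstate(divide="ignore"):
        mag_db = 20.0 * np.log10(mag[:, :, band])
    ref = mag_db[0].mean(axis=0)                             # shallowest window row
    sd = np.std(mag_db - ref[None, None, :], axis=2)
    sd[zero_energy] = np.nan
    sd[~np.all(np.isfinite(mag_db), axis=2)] = np.nan
    values, n_bad = _impute(sd, "SDSD")
    fmap = FeatureMap(
        kind="SDSD", values=values, window=window, n_imputed=n_bad,
        diagnostics={"band_bins": int(band.sum())},
    )
    fmap.rendering = render_map(fmap)
    return fmap


def ond_map(roi_envelope: np.ndarray, window: WindowSpec = WindowSpec()) -> FeatureMap:
    """Nakagami-scale (omega) map of a ROI envelope matrix.

    Moment estimators per window on the envelope R: omega_hat = mean(R^2),
    m_hat = mean(R^2)^2 / var(R^2) (diagnostic).  Requires >= 64 samples per
    window and a nonnegative envelope.
    """
    env = np.asarray(roi_envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    if window.axial_len * window.lateral_len < 64:
        raise ValueError("OND windows must hold >= 64 samples")
    sw = _windows(env, window)
    power = sw.reshape(sw.shape[0], sw.shape[1], -1) ** 2
    omega = power.mean(axis=2)
    var = power.var(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        m_hat = np.where(var > 0, omega**2 / var, np.nan)
    omega[omega <= 0] = np.nan
    values, n_bad = _impute(omega, "OND")
    fmap = FeatureMap(
        kind="OND", values=values, window=window, n_imputed=n_bad,
        diagnostics={"m_hat": m_hat},
    )
    fmap.rendering = render_map(fmap)
    return fmap


def render_map(fmap: FeatureMap) -> np.ndarray:
    """Min-max render of a map to 8-bit (round half up); constant maps -> 128."""
    v = np.asarray(fmap.values, dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full(v.shape, 128, dtype=np.uint8)
    img = 255.0 * (v - lo) / (hi - lo)
    return np.floor(img + 0.5).astype(np.uint8)
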