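"""Parametric map estimators (DEA / SDSD / OND) and rendering."""

import numpy as np
import pytest

import rfradiomics as rf
from rfradiomics.core import FeatureMap, WindowSpec
from rfradiomics.maps import dea_map, ond_map, render_map, sdsd_map

FS = 20e6
DZ_CM = 1540.0 / (2 * FS) * 1e2


def decaying_noise(rng, n_rows=512, n_cols=16, db_per_cm=3.0):
    """White noise with an imposed exponential amplitude decay."""
    x = rng.standard_normal((n_rows, n_cols))
    depth = np.arange(n_rows) * DZ_CM
    return x * 10 ** (-db_per_cm * depth / 20.0)[:, None]


class TestDEA:
    def test_recovers_imposed_decay(self, small_window):
        # amplitude factor 10^(-3 z / 20) <=> log-power slope of -3 dB/cm
        means = []
        for seed in range(5):
            roi = decaying_noise(np.random.default_rng(seed), db_per_cm=3.0)
            means.append(dea_map(roi, small_window, fs=FS).values.mean())
        assert np.mean(means) == pytest.approx(-3.0, rel=0.15)

    def test_stationary_noise_near_zero(self, rng, small_window):
        roi = rng.standard_normal((512, 16))
        fmap = dea_map(roi, small_window, fs=FS)
        assert abs(fmap.values.mean()) < 0.5

    def test_zero_energy_windows_imputed(self, rng, small_window):
        roi = rng.standard_normal((512, 16))
        roi[:128, :4] = 0.0  # kill the first window completely
        fmap = dea_map(roi, small_window, fs=FS)
        assert fmap.n_imputed >= 1
        assert np.all(np.isfinite(fmap.values))

    def test_roi_smaller_than_window_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller than one window"):
            dea_map(rng.standard_normal((32, 4)), WindowSpec(), fs=FS)


class TestSDSD:
    def test_window_identical_to_reference_is_zero(self, rng, small_window):
        # tile a pattern with the window-step period on both axes so every
        # window holds identical content
        tile = rng.standard_normal((small_window.axial_step, small_window.lateral_step))
        roi = np.tile(tile, (16, 8))
        fmap = sdsd_map(roi, small_window, fs=FS)
        assert np.allclose(fmap.values, 0.0, atol=1e-9)

    def test_spectral_mixture_raises_sdsd(self, rng, small_window):
        """Windows whose spectra differ from the shallow reference score
        higher than spectrally homogeneous ones."""
        n_rows, n_cols = 512, 16
        t = np.arange(n_rows)[:, None]
        homo = np.sin(2 * np.pi * 0.15 * t) * np.ones((1, n_cols))
        homo += 0.05 * rng.standard_normal((n_rows, n_cols))
        hetero = homo.copy()
        deep = slice(256, None)
        hetero[deep] += np.sin(2 * np.pi * 0.23 * t[deep])  # extra tone at depth
        v_homo = sdsd_map(homo, small_window, fs=FS).values.mean()
        v_het = sdsd_map(hetero, small_window, fs=FS).values.mean()
        assert v_het > v_homo


class TestOND:
    def test_constant_envelope_moment_identity(self, small_window):
        env = np.full((512, 16), 3.0)
        fmap = ond_map(env, small_window)
        assert np.allclose(fmap.values, 9.0)
        # zero-variance window: m_hat undefined, omega still emitted
        assert np.all(np.isnan(fmap.diagnostics["m_hat"]))

    def test_nakagami_moment_recovery(self, rng):
        r = np.sqrt(rng.gamma(1.0, 2.0, size=10**5)).reshape(500, 200)
        w = WindowSpec(axial_len=500, lateral_len=200, axial_step=1, lateral_step=1)
        fmap = ond_map(r, w)
        assert fmap.values[0, 0] == pytest.approx(2.0, rel=0.02)
        assert fmap.diagnostics["m_hat"][0, 0] == pytest.approx(1.0, rel=0.05)

    def test_scaling_homogeneity(self, rng, small_window):
        env = rng.random((512, 16))
        a = ond_map(env, small_window).values
        b = ond_map(3.0 * env, small_window).values
        assert np.allclose(b, 9.0 * a)

    def test_negative_envelope_rejected(self, small_window):
        with pytest.raises(ValueError, match="nonnegative"):
            ond_map(np.full((512, 16), -1.0), small_window)

    def test_too_small_window_rejected(self):
        w = WindowSpec(axial_len=8, lateral_len=2, axial_step=1, lateral_step=1)
        with pytest.raises(ValueError, match="64 samples"):
            ond_map(np.ones((64, 8)), w)


class TestRenderMap:
    def _fmap(self, values):
        return FeatureMap(kind="SDSD", values=np.asarray(values, float),
                          window=WindowSpec())

    def test_binary_values(self):
        img = render_map(self._fmap([[0.0, 1.0]]))
        assert img.tolist() == [[0, 255]]

    def test_constant_map_is_midgray(self):
        img = render_map(self._fmap([[2.5, 2.5], [2.5, 2.5]]))
        assert np.all(img == 128)

    def test_round_half_up(self):
        img = render_map(self._fmap([[0.0, 0.5, 1.0]]))
        assert img.tolist() == [[0, 128, 255]]


class TestInvariants:
    def test_grid_shape_closed_form(self, rng):
        w = WindowSpec(axial_len=128, lateral_len=8, axial_step=64, lateral_step=4)
        roi = rng.standard_normal((480, 48))
        fmap = dea_map(roi, w, fs=FS)
        assert fmap.values.shape == ((480 - 128) // 64 + 1, (48 - 8) // 4 + 1)
        assert fmap.values.shape == w.grid_shape(roi.shape)

    def test_amplitude_invariance(self, rng, small_window):
        roi = decaying_noise(rng)
        k = 7.3
        dea_a = dea_map(roi, small_window, fs=FS).values
        dea_b = dea_map(k * roi, small_window, fs=FS).values
        assert np.allclose(dea_a, dea_b)
        sdsd_a = sdsd_map(roi, small_window, fs=FS).values
        sdsd_b = sdsd_map(k * roi, small_window, fs=FS).values
        assert np.allclose(sdsd_a, sdsd_b, atol=1e-9)
        env = np.abs(roi)
        ond_a = ond_map(env, small_window).values
        ond_b = ond_map(k * env, small_window).values
        assert np.allclose(ond_b, k**2 * ond_a)
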