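"""Dynamic filter (ZCA), whitening, and divisive gain control."""

import numpy as np
import pytest

from illusim import decorrelation, encoding, pipeline
from illusim.decorrelation import (
    DynamicFilter,
    GainParams,
    WhitenedEnergyMap,
    apply_gain_control,
    gain_control_map,
    learn_dynamic_filter,
    whiten_energy,
)
from illusim.encoding import ChannelResponseSet, EnergyMap
from illusim.stimuli import StimulusSpec, generate


def _delta(size):
    k = np.zeros((size, size))
    k[size // 2, size // 2] = 1.0
    return k


class TestLearnDynamicFilter:
    def test_white_noise_gives_delta_kernel(self, rng):
        """Spatially white energy has ~identity covariance, so the whitening
        kernel approaches a scaled delta."""
        E = EnergyMap(rng.uniform(0, 1, (200, 200)))
        F = learn_dynamic_filter(E, patch_size=9, n_patches=10000, seed=0)
        k = F.kernel / np.abs(F.kernel).max()
        center = np.abs(k[4, 4])
        off = np.abs(np.delete(k.ravel(), 9 * 4 + 4)).max()
        assert center == pytest.approx(1.0)
        assert off < 0.35

    def test_zero_phase_centro_symmetry(self):
        img = generate(StimulusSpec("sbc"))
        bank = pipeline.build_banks()[0]
        E = encoding.local_energy(img, bank)
        F = learn_dynamic_filter(E, patch_size=21, n_patches=2000, seed=3)
        rot = F.kernel[::-1, ::-1]
        assert np.abs(F.kernel - rot).max() <= 1e-6 * np.abs(F.kernel).max()

    def test_kernel_dft_is_real(self):
        """Zero-phase property: the filter's Fourier transform is real."""
        img = generate(StimulusSpec("white"))
        bank = pipeline.build_banks()[0]
        E = encoding.local_energy(img, bank)
        F = learn_dynamic_filter(E, patch_size=15, n_patches=2000, seed=1)
        spectrum = np.fft.fft2(np.fft.ifftshift(F.kernel))
        assert np.abs(spectrum.imag).max() < 1e-9 * np.abs(spectrum.real).max()

    def test_seeded_determinism(self, rng):
        E = EnergyMap(rng.uniform(0, 1, (100, 100)))
        a = learn_dynamic_filter(E, patch_size=9, n_patches=500, seed=11)
        b = learn_dynamic_filter(E, patch_size=9, n_patches=500, seed=11)
        assert np.array_equal(a.kernel, b.kernel)

    def test_constant_energy_returns_delta_with_warning(self):
        E = EnergyMap(np.full((64, 64), 3.0))
        with pytest.warns(UserWarning, match="no spatial structure"):
            F = learn_dynamic_filter(E, patch_size=9, n_patches=200, seed=0)
        assert np.array_equal(F.kernel, _delta(9))

    def test_even_patch_size_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            learn_dynamic_filter(EnergyMap(rng.uniform(0, 1, (64, 64))), patch_size=16)


class TestWhitenEnergy:
    def test_identity_kernel_with_zero_mean(self, rng):
        E = rng.uniform(-1, 1, (40, 40))
        E -= E.mean()
        F = DynamicFilter(kernel=_delta(9), patch_size=9, eigen_floor=0.0, seed=0)
        out = whiten_energy(EnergyMap(E), F, omega_frac=0.1)
        omega = 0.1 * E.max()
        on = E >= omega
        assert np.allclose(out.values[on], E[on], atol=1e-12)
        assert np.all(out.values[~on] == 0)

    def test_subthreshold_pixels_are_zero(self, rng):
        E = rng.uniform(0, 1, (50, 50))
        F = DynamicFilter(kernel=_delta(5), patch_size=5, eigen_floor=0.0, seed=0)
        out = whiten_energy(EnergyMap(E), F, omega_frac=0.3)
        assert np.all(out.values[E < out.threshold_used] == 0)
        assert out.threshold_used == pytest.approx(0.3 * E.max())

    def test_all_zero_energy(self):
        F = DynamicFilter(kernel=_delta(5), patch_size=5, eigen_floor=0.0, seed=0)
        out = whiten_energy(EnergyMap(np.zeros((30, 30))), F)
        assert np.all(out.values == 0)

    @pytest.mark.parametrize("family", ["sbc", "white"])
    def test_spectrum_flattening_on_structured_display(self, family):
        """Whitening a redundant edge map raises its spectral flatness."""
        img = generate(StimulusSpec(family))
        bank = pipeline.build_banks()[0]
        E = encoding.local_energy(img, bank).values
        F = learn_dynamic_filter(EnergyMap(E), seed=0)
        from illusim._conv import conv_same

        centered = E - E.mean()
        flat_raw = decorrelation.spectral_flatness(centered)
        flat_whitened = decorrelation.spectral_flatness(conv_same(centered, F.kernel))
        assert flat_whitened > flat_raw


class TestGainControlMap:
    def test_zero_whitened_gives_zero_gain(self, rng):
        w = rng.standard_normal((30, 30))
        w[5:10, 5:10] = 0.0
        G = gain_control_map(WhitenedEnergyMap(values=w, threshold_used=0.0))
        assert np.all(G.values[5:10, 5:10] == 0)

    def test_peak_value_closed_form(self):
        """At the pixel attaining max |whitened| with a=5, b=0.3 the gain is
        2 / (1 + exp(-5 * 0.7)) - 1 under the soft-threshold sigmoid."""
        w = np.zeros((10, 10))
        w[3, 3] = 2.0
        w[7, 7] = -1.0
        G = gain_control_map(WhitenedEnergyMap(values=w, threshold_used=0.0), a=5.0, b=0.3)
        assert G.values[3, 3] == pytest.approx(2.0 / (1.0 + np.exp(-5.0 * 0.7)) - 1.0)

    def test_range_is_open_interval(self, rng):
        w = rng.standard_normal((40, 40))
        G = gain_control_map(WhitenedEnergyMap(values=w, threshold_used=0.0)).values
        on = w != 0
        assert np.all(G[on] > -1) and np.all(G[on] < 1)

    def test_all_zero_map(self):
        G = gain_control_map(WhitenedEnergyMap(values=np.zeros((8, 8)), threshold_used=0.0))
        assert np.all(G.values == 0)


class TestApplyGainControl:
    def _responses(self, grid):
        return ChannelResponseSet(responses={0.0: grid}, channel="contrast_only")

    def _gain(self, values):
        return decorrelation.GainControlMap(values=values, slope=5.0, inflection=0.3)

    def test_identity_at_zero_gain(self, rng):
        R = rng.uniform(-0.4, 0.4, (20, 20))
        out = apply_gain_control(self._responses(R), self._gain(np.zeros((20, 20))), smooth_sd=0)
        assert np.allclose(out.responses[0.0], R)

    @pytest.mark.parametrize("g", [-0.9, -0.3, 0.4, 0.95])
    def test_fixed_point_at_tau(self, g):
        """|R| = tau is a fixed point of the modulation for any admissible G."""
        tau = 0.5
        R = np.full((8, 8), tau)
        R[::2] = -tau
        out = apply_gain_control(self._responses(R), self._gain(np.full((8, 8), g)), tau=tau, smooth_sd=0)
        assert np.allclose(out.responses[0.0], R, atol=1e-12)

    def test_zero_response_stays_zero(self, rng):
        out = apply_gain_control(
            self._responses(np.zeros((10, 10))), self._gain(rng.uniform(-0.9, 0.9, (10, 10))), smooth_sd=0
        )
        assert np.all(out.responses[0.0] == 0)

    def test_full_suppression_at_minus_one(self, rng):
        R = rng.uniform(-0.45, 0.45, (12, 12))
        out = apply_gain_control(self._responses(R), self._gain(np.full((12, 12), -1.0)), smooth_sd=0)
        assert np.abs(out.responses[0.0]).max() < 1e-12

    @pytest.mark.parametrize("g,expect_boost", [(0.5, True), (-0.5, False)])
    def test_sign_of_modulation_below_tau(self, g, expect_boost, rng):
        """For 0 < |R| < tau: positive G amplifies, negative G attenuates."""
        R = rng.uniform(0.05, 0.45, (15, 15)) * np.sign(rng.standard_normal((15, 15)))
        out = apply_gain_control(self._responses(R), self._gain(np.full((15, 15), g)), smooth_sd=0)
        ratio = out.responses[0.0] / R
        if expect_boost:
            assert np.all(ratio > 1)
        else:
            assert np.all(ratio < 1)
        assert np.all(ratio > 0)

    def test_invalid_tau(self, rng):
        with pytest.raises(ValueError):
            apply_gain_control(self._responses(np.ones((4, 4))), self._gain(np.zeros((4, 4))), tau=0)


def test_gain_params_validation():
    with pytest.raises(ValueError):
        GainParams(a=-1)
    with pytest.raises(ValueError):
        GainParams(tau=0)
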