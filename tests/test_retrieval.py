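import numpy as np
import pytest
from scipy import ndimage

from xpct.forward import ExitWave, fresnel_propagate
from xpct.retrieval import (
    RetrievalParams,
    bac,
    chi_grid,
    ctf_multi_cg,
    ctf_single,
    min_ctf_power,
    paganin,
    paganin_generalized,
    select_method,
)


def _weak_phase(rng, n=128, amplitude=0.05, sigma=3):
    phi = ndimage.gaussian_filter(rng.normal(size=(n, n)), sigma)
    return phi * amplitude / np.abs(phi).max()


class TestCtfSingle:
    def test_zero_contrast_gives_zero_phase(self):
        params = RetrievalParams(fresnel_numbers=(0.01,))
        out = ctf_single(np.ones((32, 32)), params)
        assert np.allclose(out, 0.0, atol=1e-14)

    def test_weak_phantom_band_recovery(self, rng):
        bod = 1 / 15
        phi = _weak_phase(rng)
        F = 0.01
        img = fresnel_propagate(ExitWave(phi, -bod * phi, 1e-6), F, pad=1)
        params = RetrievalParams(fresnel_numbers=(F,), beta_over_delta=bod,
                                 alpha_low=1e-4, alpha_high=1e-2, pad=1)
        rec = ctf_single(img, params)
        chi = chi_grid(phi.shape, F)
        band = (chi > 0.1) & (chi < 3.0)
        fr, ft = np.fft.fft2(rec), np.fft.fft2(phi)
        rmse = np.sqrt(np.mean(np.abs(fr - ft)[band] ** 2))
        norm = np.sqrt(np.mean(np.abs(ft[band]) ** 2))
        assert rmse / norm < 0.02

    def test_pure_absorption_matched_ratio(self, rng):
        # homogeneous object: absorption implies phase via delta/beta
        bod = 1 / 27
        phi = _weak_phase(rng, amplitude=0.02)
        b_map = -bod * phi
        F = 0.02
        img = fresnel_propagate(ExitWave(np.zeros_like(phi) + phi, b_map,
                                         1e-6), F, pad=1)
        params = RetrievalParams(fresnel_numbers=(F,), beta_over_delta=bod,
                                 alpha_low=1e-5, alpha_high=1e-3, pad=1)
        rec = ctf_single(img, params)
        # recovered phase is proportional to -B * (delta/beta)
        target = -b_map / bod
        chi = chi_grid(phi.shape, F)
        band = (chi > 0.1) & (chi < 3.0)
        fr, ft = np.fft.fft2(rec), np.fft.fft2(target)
        assert np.abs(fr - ft)[band].sum() / np.abs(ft[band]).sum() < 0.02

    def test_operator_linearity(self, rng):
        params = RetrievalParams(fresnel_numbers=(0.05,))
        i1 = 1.0 + 0.01 * rng.normal(size=(32, 32))
        i2 = 1.0 + 0.01 * rng.normal(size=(32, 32))
        a = 0.3
        lhs = ctf_single(a * i1 + (1 - a) * i2, params)
        rhs = a * ctf_single(i1, params) + (1 - a) * ctf_single(i2, params)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_roundtrip_reproduces_intensity(self, rng):
        bod = 1 / 15
        phi = _weak_phase(rng, amplitude=0.04)
        F = 0.01
        img = fresnel_propagate(ExitWave(phi, -bod * phi, 1e-6), F, pad=1)
        params = RetrievalParams(fresnel_numbers=(F,), beta_over_delta=bod,
                                 alpha_low=1e-5, alpha_high=1e-3, pad=1)
        rec = ctf_single(img, params)
        img2 = fresnel_propagate(ExitWave(rec, -bod * rec, 1e-6), F, pad=1)
        rmse = np.sqrt(np.mean((img2 - img) ** 2))
        assert rmse / np.sqrt(np.mean((img - 1) ** 2)) < 0.01


class TestCtfMulti:
    FNS = tuple(4.2e-3 * np.geomspace(1.0, 2.6, 4))

    def test_single_distance_reduces_to_ctf_single(self, rng):
        img = 1.0 + 0.02 * rng.normal(size=(32, 32))
        params = RetrievalParams(fresnel_numbers=(0.01,),
                                 beta_over_delta=1 / 27)
        assert np.array_equal(ctf_multi_cg(img[None], params),
                              ctf_single(img, params))

    def test_defocus_series_has_no_common_zeros(self):
        assert min_ctf_power(self.FNS) > 0.01
        assert min_ctf_power((self.FNS[0],)) < 1e-3   # single distance does

    def test_cg_objective_monotone(self, rng):
        bod = 1 / 27
        phi = _weak_phase(rng, n=64, amplitude=0.2)
        imgs = np.stack([fresnel_propagate(ExitWave(phi, -bod * phi, 1e-6),
                                           F, pad=1) for F in self.FNS])
        params = RetrievalParams(fresnel_numbers=self.FNS,
                                 beta_over_delta=bod, cg_iterations=8, pad=1)
        rec, objs = ctf_multi_cg(imgs, params, return_objectives=True)
        assert len(objs) >= 2
        assert all(b <= a * (1 + 1e-12) for a, b in zip(objs, objs[1:]))

    def test_identical_distances_warn(self, rng):
        img = 1.0 + 0.01 * rng.normal(size=(16, 16))
        params = RetrievalParams(fresnel_numbers=(0.01, 0.01))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            ctf_multi_cg(np.stack([img, img]), params)


class TestPaganin:
    @staticmethod
    def _slab_params(F, delta_over_beta=100.0, wl=1e-10, pix=1e-6,
                     beta=1e-9):
        return RetrievalParams(fresnel_numbers=(F,),
                               beta_over_delta=1 / delta_over_beta,
                               wavelength_m=wl, pixel_m=pix, beta=beta,
                               delta=beta * delta_over_beta)

    def test_unit_intensity_zero_thickness(self):
        params = self._slab_params(0.5)
        t = paganin(np.ones((32, 32)), params)
        assert np.allclose(t, 0.0, atol=1e-12)
        assert np.allclose(paganin_generalized(np.ones((32, 32)), params),
                           0.0, atol=1e-12)

    def test_pure_absorption_limit(self, rng):
        # delta = 0: the filter collapses and t = -ln(I)/mu exactly
        params = RetrievalParams(fresnel_numbers=(0.5,),
                                 beta_over_delta=np.inf, wavelength_m=1e-10,
                                 beta=1e-9)
        intensity = rng.uniform(0.3, 1.0, (32, 32))
        t = paganin(intensity, params)
        expected = -np.log(intensity) / params.mu
        assert np.allclose(t, expected, rtol=1e-7)

    def test_slab_plateau_thickness(self):
        n = 256
        tmap = np.zeros((n, n))
        tmap[:, 80:176] = 1.0
        tmap = ndimage.gaussian_filter(tmap, 1.0)
        t_m = tmap * 20e-6
        params = self._slab_params(0.5)
        k = 2 * np.pi / params.wavelength_m
        img = fresnel_propagate(
            ExitWave(-k * params.delta * t_m, k * params.beta * t_m, 1e-6),
            0.5, pad=2)
        rec = paganin(img, params)
        plateau = rec[n // 2, 100:156].mean()
        assert plateau == pytest.approx(20e-6, rel=0.03)

    def test_zero_beta_rejected(self):
        params = RetrievalParams(fresnel_numbers=(0.5,), wavelength_m=1e-10,
                                 beta=0.0)
        with pytest.raises(ValueError):
            paganin(np.ones((8, 8)), params)


class TestGeneralizedPaganin:
    def test_converges_to_paganin_quadratically(self):
        # filter symbols at a fixed physical frequency, refining pixel size
        dob = 50.0
        diffs = []
        pixels = [1.0, 0.5, 0.25]
        f_phys = 0.2    # cycles per unit length
        lam_z = 1.0
        for dx in pixels:
            F = dx**2 / lam_z
            f_pix = f_phys * dx
            chi = np.pi * f_pix**2 / F
            pag = 1.0 + dob * chi
            gpm = 1.0 + dob * (1.0 - np.cos(2 * np.pi * f_pix)) / (
                2 * np.pi * F)
            diffs.append(abs(gpm - pag))
        orders = np.log2(np.array(diffs[:-1]) / np.array(diffs[1:]))
        assert np.all(orders > 1.7)   # observed order ~2 in pixel size

    def test_less_suppression_at_nyquist(self):
        # at f = 1/2 per pixel the discrete Laplacian symbol is below chi
        F, dob = 0.1, 50.0
        chi_nyq = np.pi * 0.25 / F
        gpm_nyq = (1.0 - np.cos(np.pi)) / (2 * np.pi * F)
        assert gpm_nyq < chi_nyq
        assert 1 + dob * gpm_nyq < 1 + dob * chi_nyq


class TestBAC:
    def test_zero_gamma_is_identity(self, rng):
        img = 1.0 + 0.1 * rng.normal(size=(32, 32))
        params = RetrievalParams(method="bac", fresnel_numbers=(1.37,),
                                 bac_gamma=0.0)
        assert np.allclose(bac(img, params), img)

    def test_huge_alpha_is_identity(self, rng):
        img = 1.0 + 0.1 * rng.normal(size=(32, 32))
        params = RetrievalParams(method="bac", fresnel_numbers=(1.37,),
                                 bac_alpha=1e12, bac_gamma=0.5)
        assert np.allclose(bac(img, params), img, atol=1e-8)

    def test_negative_gamma_rejected(self):
        with pytest.raises(ValueError):
            RetrievalParams(method="bac", bac_gamma=-0.1)

    def test_edge_overshoot_reduced(self):
        n = 256
        t = np.zeros((n, n))
        t[:, 90:166] = 1.0
        img = fresnel_propagate(ExitWave(-0.3 * t, 0.02 * t, 1e-6),
                                1.3651, pad=2)
        overshoot0 = img[n // 2].max() - 1.0
        params = RetrievalParams(method="bac", fresnel_numbers=(1.3651,),
                                 bac_alpha=0.003)
        from dataclasses import replace
        best = min(
            (bac(img, replace(params, bac_gamma=g))[n // 2].max() - 1.0
             for g in np.linspace(0.0, 0.2, 41)))
        assert best <= 0.2 * overshoot0


class TestMethodSelection:
    @pytest.mark.parametrize("preset,method", [
        ("SR-PB2", "gpm"),
        ("muCT1-overview", "bac"),
        ("muCT1-temporal-bone", "bac"),
        ("SR-CB3", "ctf_multi_cg"),
        ("SR-PB", "ctf_single"),
        ("muCT2-overview", "none"),
    ])
    def test_published_method_per_instrument(self, preset, method):
        assert select_method(preset).method == method

    def test_multi_distance_preset_has_four_distances(self):
        p = select_method("SR-CB3")
        assert len(p.fresnel_numbers) == 4
        assert min_ctf_power(p.fresnel_numbers) > 0.01

    def test_unknown_preset_error(self):
        with pytest.raises(KeyError):
            select_method("SR-XX")
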