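"""Spectral pipeline: 2-D PSD, radial sampling, and the clustering factor."""

import numpy as np
import pytest

from assemblyscope.imgio import minmax_normalize
from assemblyscope.ncf import (PSDCurve, compute_psd2d, ncf, ncf_image,
                               ncf_per_channel, radial_psd)
from assemblyscope.synth import (SceneConfig, ThomasParams, generate_cell_scene,
                                 generate_gaussian_clump, generate_white_noise)

# Independent frozen oracle: plain-Python sum over the analytic radial curve
# power_k = f_k^-2, counts ~ f_k on f_k = k/600, k = 1..300 (computed by a
# standalone script before the pipeline was wired).
POWER_LAW_CURVE_NCF = 0.5478365616290714


class TestComputePsd2d:
    def test_constant_image_all_power_in_dc(self):
        psd = compute_psd2d(np.full((600, 600), 2.0))
        off_dc = psd.psd.copy()
        off_dc[300, 300] = 0.0
        assert psd.dc_power == pytest.approx((2.0 * 600 * 600) ** 2)
        assert np.abs(off_dc).max() <= 1e-10 * psd.total_power

    def test_parseval_identity(self):
        img = np.random.default_rng(0).random((600, 600))
        psd = compute_psd2d(img)
        assert psd.total_power / 600**2 == pytest.approx((img**2).sum(), rel=1e-8)

    def test_rotation_preserves_radial_curve(self):
        img = np.random.default_rng(1).random((600, 600))
        a = radial_psd(compute_psd2d(img))
        b = radial_psd(compute_psd2d(np.rot90(img)))
        np.testing.assert_allclose(a.power, b.power, rtol=1e-10)

    def test_cosine_period_100_peaks_at_0p01(self):
        # a 100-px feature corresponds to spatial frequency 0.01 px^-1
        img = np.tile(np.cos(2 * np.pi * np.arange(600) / 100.0), (600, 1))
        curve = radial_psd(compute_psd2d(img))
        assert curve.frequencies[np.argmax(curve.power)] == pytest.approx(0.01)

    def test_non_standard_shape_rejected(self):
        with pytest.raises(ValueError, match="standardize"):
            compute_psd2d(np.ones((128, 128)))


class TestRadialPsd:
    def test_white_noise_curve_is_flat(self):
        curves = [radial_psd(compute_psd2d(generate_white_noise((600, 600), s))).power
                  for s in range(10)]
        mean = np.mean(curves, axis=0)[9:290]      # annuli k in [10, 290]
        assert mean.max() / mean.min() < 1.5

    def test_gaussian_clump_power_concentrated_at_low_k(self):
        curve = radial_psd(compute_psd2d(generate_gaussian_clump((600, 600), 100.0)))
        w = curve.counts * curve.power
        assert w[:5].sum() / w.sum() >= 0.99

    def test_annulus_counts_bounded_by_pixel_budget(self):
        curve = radial_psd(compute_psd2d(np.random.default_rng(2).random((600, 600))))
        assert curve.counts.sum() <= 600 * 600 - 1

    def test_matches_brute_force_dft_oracle_on_8x8(self):
        """Radial sampling agrees with an explicit double-loop DFT + radius
        binning oracle (binning exactly; power to float precision)."""
        rng = np.random.default_rng(3)
        img = rng.random((8, 8))
        # -- independent oracle ------------------------------------------
        n = 8
        sums = np.zeros(n // 2 + 1)
        counts = np.zeros(n // 2 + 1, dtype=int)
        for u in range(-n // 2, n // 2):
            for v in range(-n // 2, n // 2):
                acc = 0.0 + 0.0j
                for r in range(n):
                    for c in range(n):
                        acc += img[r, c] * np.exp(-2j * np.pi * (u * r + v * c) / n)
                k = int(np.floor(np.hypot(u, v) + 0.5))
                if 1 <= k <= n // 2:
                    sums[k] += abs(acc) ** 2
                    counts[k] += 1
        # ----------------------------------------------------------------
        curve = radial_psd(compute_psd2d(img, allow_any_shape=True))
        np.testing.assert_array_equal(curve.counts, counts[1:])
        np.testing.assert_allclose(curve.power, sums[1:] / counts[1:], rtol=1e-10)


class TestNcf:
    def test_white_noise_anchor_near_zero(self):
        res = ncf_image(generate_white_noise((600, 600), 1))
        assert abs(res.ncf - 0.0) < 0.1

    def test_gaussian_clump_anchor_near_one(self):
        res = ncf_image(generate_gaussian_clump((600, 600), 100.0))
        assert abs(res.ncf - 1.0) < 0.1

    def test_analytic_power_law_curve_matches_frozen_oracle(self):
        k = np.arange(1, 301)
        f = k / 600.0
        curve = PSDCurve(frequencies=f, power=f**-2.0, counts=f)
        assert ncf(curve).ncf == pytest.approx(POWER_LAW_CURVE_NCF, abs=1e-12)

    def test_intensity_scaling_invariance(self):
        img = generate_white_noise((600, 600), 4) + 0.3
        base = ncf_image(img).ncf
        for c in (1e-3, 7.0, 1e4):
            assert abs(ncf_image(c * img).ncf - base) <= 1e-10

    def test_rotation_and_flip_invariance(self):
        img, _ = generate_cell_scene(SceneConfig(seed=11))
        dapi = img["nuclei"]
        base = ncf_image(dapi).ncf
        for tx in (np.rot90(dapi), dapi[::-1], dapi[:, ::-1]):
            assert abs(ncf_image(np.ascontiguousarray(tx)).ncf - base) <= 1e-10

    def test_result_always_within_unit_interval(self):
        for seed in range(5):
            img = generate_white_noise((600, 600), seed) ** 3
            assert 0.0 <= ncf_image(img).ncf <= 1.0

    def test_degenerate_spectrum_raises(self):
        curve = PSDCurve(frequencies=np.array([1 / 600, 0.5]),
                         power=np.zeros(2), counts=np.array([8.0, 16.0]))
        with pytest.raises(ValueError, match="degenerate"):
            ncf(curve)

    def test_f_bar_log_within_frequency_bounds(self):
        res = ncf_image(generate_white_noise((600, 600), 5))
        assert np.log(1 / 600) <= res.f_bar_log <= np.log(0.5)


class TestNcfPerChannel:
    def test_identical_channels_identical_values(self, default_scene):
        scene, _ = default_scene
        from assemblyscope.imgio import StandardizedImage
        dup = StandardizedImage(channels={"neuron": scene["nuclei"].copy(),
                                          "astrocyte": scene["nuclei"].copy()})
        out = ncf_per_channel(dup)
        assert out["neuron"].ncf == out["astrocyte"].ncf

    def test_missing_channel_absent_from_output(self, default_scene):
        scene, _ = default_scene
        from assemblyscope.imgio import StandardizedImage
        out = ncf_per_channel(StandardizedImage(channels={"neuron": scene["neuron"]}))
        assert set(out) == {"neuron"}

    def test_error_names_offending_channel(self):
        from assemblyscope.imgio import StandardizedImage
        flat = StandardizedImage(channels={"astrocyte": np.zeros((600, 600))})
        with pytest.raises(ValueError, match="astrocyte"):
            with pytest.warns(UserWarning):
                ncf_per_channel(flat)

    def test_thomas_more_clustered_than_poisson(self):
        """Aggregated (Thomas) scenes score higher than uniform ones on the
        neuron channel, averaged over 20 seeds at equal counts."""
        def mean_ncf(arrangement):
            vals = []
            for s in range(20):
                cfg = SceneConfig(seed=300 + s, arrangement=arrangement,
                                  thomas_params=ThomasParams(cluster_sigma_px=15.0))
                scene, _ = generate_cell_scene(cfg)
                vals.append(ncf_image(minmax_normalize(scene["neuron"])).ncf)
            return np.mean(vals)
        assert mean_ncf("thomas") > mean_ncf("poisson")
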