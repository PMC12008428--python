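"""Discretization, filters, first-order, shape, and extraction schema."""

import numpy as np
import pytest

import oracles
from octomics.features import (
    BScanImage,
    ExtractionConfig,
    InputError,
    ROIMask,
    apply_filter,
    discretize,
    extract_all,
    feature_count,
    first_order_features,
    shape2d_features,
)


class TestDiscretize:
    def test_full_8bit_range_bin25(self):
        raw = np.arange(256, dtype=float).reshape(16, 16)
        d = discretize(raw, np.ones((16, 16), bool), 25.0)
        assert d.ng == 11  # floor(255/25) + 1

    def test_constant_region_single_level(self):
        d = discretize(np.full((5, 5), 9.0), np.ones((5, 5), bool), 3.0)
        assert d.ng == 1
        assert (d.in_mask == 1).all()

    @pytest.mark.parametrize("bw", [0.0, -1.0])
    def test_nonpositive_bin_width_rejected(self, bw):
        with pytest.raises(InputError):
            discretize(np.ones((5, 5)), np.ones((5, 5), bool), bw)

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            discretize(np.ones((5, 5)), np.zeros((5, 5), bool), 25.0)


class TestFilters:
    def _img(self, px):
        return BScanImage(np.asarray(px, dtype=float), (1.0, 1.0))

    def test_gradient_of_constant_is_zero(self):
        out = apply_filter(self._img(np.full((8, 8), 5.0)), "gradient")
        assert np.allclose(out["gradient"], 0.0)

    def test_logarithm_of_constant_is_constant(self):
        out = apply_filter(self._img(np.full((8, 8), 5.0)), "logarithm")
        assert np.ptp(out["logarithm"]) == pytest.approx(0.0)

    def test_wavelet_step_edge_energy_in_one_detail_band(self):
        # horizontal step edge (changes along rows): detail energy lands in
        # the row-highpass band; the other detail bands stay ~0. The edge is
        # placed at an odd row so the length-2 analysis window straddles it.
        px = np.zeros((8, 8))
        px[3:, :] = 1.0
        out = apply_filter(self._img(px), "wavelet", wavelet="haar")
        energies = {k: float((v**2).sum()) for k, v in out.items() if k != "wavelet-LL"}
        nonzero = [k for k, e in energies.items() if e > 1e-12]
        assert len(nonzero) == 1

    def test_unknown_filter_rejected(self):
        with pytest.raises(InputError):
            apply_filter(self._img(np.zeros((8, 8))), "nope")

    def test_log_sigma_names_carry_scale(self):
        out = apply_filter(self._img(np.random.default_rng(0).random((16, 16))),
                           "log_sigma", sigmas_mm=(3.0, 5.0))
        assert set(out) == {"log-sigma-3-0-mm-3D", "log-sigma-5-0-mm-3D"}


class TestFirstOrder:
    def test_constant_region_flagged_moments(self):
        f = first_order_features(np.full((4, 4), 2.0), np.ones((4, 4), bool))
        assert f["Mean"] == 2.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0

    def test_small_closed_form(self):
        px = np.array([[1.0, 2.0], [3.0, 4.0]])
        f = first_order_features(px, np.ones((2, 2), bool))
        assert f["Mean"] == 2.5
        assert f["Median"] == 2.5
        assert f["Minimum"] == 1.0

    def test_matches_per_formula_oracle_on_random_patch(self):
        rng = np.random.default_rng(5)
        px = rng.integers(0, 256, (16, 16)).astype(float)
        f = first_order_features(px, np.ones((16, 16), bool), bin_width=25.0,
                                 spacing_mm=(0.5, 0.25))
        ref = oracles.first_order_oracle(px.ravel(), area_per_px=0.125, bin_width=25.0)
        for k, v in ref.items():
            assert f[k] == pytest.approx(v, rel=1e-9, abs=1e-12), k

    def test_empty_mask_rejected(self):
        with pytest.raises(InputError):
            first_order_features(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestShape2D:
    def test_square_pixel_surface(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        f = shape2d_features(m, (1.0, 1.0))
        assert f["PixelSurface"] == pytest.approx(100.0)

    def test_disk_sphericity_approaches_one(self):
        yy, xx = np.mgrid[0:48, 0:48]
        disk = (yy - 24) ** 2 + (xx - 24) ** 2 <= 20**2
        f = shape2d_features(disk, (1.0, 1.0))
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.05)

    def test_thin_line_elongation_near_zero(self):
        m = np.zeros((6, 40), bool)
        m[3, 2:38] = True
        f = shape2d_features(m, (1.0, 1.0))
        assert f["Elongation"] < 0.1


class TestExtractAll:
    def _eye(self, seed=0):
        rng = np.random.default_rng(seed)
        img = BScanImage(rng.integers(0, 256, (32, 32)).astype(np.uint8), (0.011, 0.011))
        mask = np.zeros((32, 32), bool)
        mask[8:24, :] = True
        return img, ROIMask(mask)

    def test_schema_matches_config_count(self):
        img, mask = self._eye()
        cfg = ExtractionConfig.fast()
        assert len(extract_all(img, mask, cfg)) == feature_count(cfg)

    def test_firstorder_only_column_count(self):
        img, mask = self._eye()
        cfg = ExtractionConfig.original_firstorder_only()
        assert len(extract_all(img, mask, cfg)) == 18 + 9

    def test_extraction_is_deterministic(self):
        img, mask = self._eye()
        cfg = ExtractionConfig.fast()
        assert extract_all(img, mask, cfg) == extract_all(img, mask, cfg)

    def test_names_carry_provenance(self):
        img, mask = self._eye()
        v = extract_all(img, mask, ExtractionConfig(filters=("logarithm",),
                                                    families=("gldm",),
                                                    include_shape=False))
        assert "logarithm_gldm_DependenceVariance" in v
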