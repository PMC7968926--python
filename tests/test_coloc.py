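"""Cytoneme masking and masked / puncta-referenced Pearson correlation."""

import numpy as np
import pytest

from cytoquant.coloc import (
    ChannelImage,
    coloc_batch,
    mask_cytonemes,
    pearson_in_mask,
    puncta_referenced_pearson,
)
from cytoquant.config import AnalysisConfig
from cytoquant.errors import ParameterError
from cytoquant.simulate import gen_coloc_images

PX = 0.05  # um/px


def ridge_image(length_um, width_px=3, shape=(300, 340), signal=100.0):
    img = np.full(shape, 10.0)
    length_px = int(length_um / PX)
    r = shape[0] // 2
    img[r : r + width_px, 10 : 10 + length_px] += signal
    return ChannelImage(img, PX, "membrane")


class TestMaskCytonemes:
    def test_long_thin_ridge_retained(self):
        mask = mask_cytonemes(ridge_image(15.0))
        assert mask.n_objects == 1
        obj = mask.objects[0]
        assert obj.length_um >= 10.0
        assert obj.width_um <= 0.2

    def test_short_ridge_rejected(self):
        mask = mask_cytonemes(ridge_image(5.0))
        assert mask.n_objects == 0
        assert not mask.mask.any()

    def test_wide_ridge_rejected(self):
        mask = mask_cytonemes(ridge_image(15.0, width_px=12))
        assert mask.n_objects == 0

    def test_coarse_pixels_rejected(self):
        img = ChannelImage(np.zeros((40, 40)) + 10.0, pixel_size=1.0)
        with pytest.raises(ParameterError, match="pixel"):
            mask_cytonemes(img)

    def test_masking_is_deterministic(self):
        fld = gen_coloc_images(0.3, seed=8)
        mem = ChannelImage(fld.membrane, fld.pixel_size)
        m1 = mask_cytonemes(mem)
        m2 = mask_cytonemes(mem)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_simulated_mask_recovery_jaccard(self):
        scores = []
        for s in range(10):
            fld = gen_coloc_images(0.0, seed=s)
            m = mask_cytonemes(ChannelImage(fld.membrane, fld.pixel_size))
            inter = (m.mask & fld.true_mask).sum()
            union = (m.mask | fld.true_mask).sum()
            scores.append(inter / union)
        assert np.mean(scores) >= 0.8


class TestPearsonInMask:
    def _pair(self, rng):
        a = rng.normal(100, 20, size=(60, 60))
        mask = np.zeros((60, 60), dtype=bool)
        mask[20:23, 5:55] = True
        return a, mask

    def test_affine_channel_gives_r_one(self, rng):
        a, mask = self._pair(rng)
        b = 2.0 * a + 7.0
        res = pearson_in_mask(ChannelImage(a, PX), ChannelImage(b, PX), mask)
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_negated_channel_gives_r_minus_one(self, rng):
        a, mask = self._pair(rng)
        res = pearson_in_mask(ChannelImage(a, PX), ChannelImage(-a, PX), mask)
        assert res.pearson_r == pytest.approx(-1.0, abs=1e-12)

    def test_affine_invariance_of_r(self, rng):
        a, mask = self._pair(rng)
        b = rng.normal(100, 20, size=a.shape)
        r0 = pearson_in_mask(ChannelImage(a, PX), ChannelImage(b, PX), mask)
        r1 = pearson_in_mask(
            ChannelImage(3.0 * a - 40.0, PX), ChannelImage(0.5 * b + 9.0, PX),
            mask,
        )
        assert r0.pearson_r == pytest.approx(r1.pearson_r, abs=1e-9)

    def test_matches_bruteforce_pixel_loop(self, rng):
        a, mask = self._pair(rng)
        b = rng.normal(100, 20, size=a.shape)
        res = pearson_in_mask(ChannelImage(a, PX), ChannelImage(b, PX), mask)
        xs, ys = [], []
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                if mask[i, j]:
                    xs.append(a[i, j])
                    ys.append(b[i, j])
        assert res.pearson_r == pytest.approx(np.corrcoef(xs, ys)[0, 1],
                                              abs=1e-12)
        assert res.n_pixels == len(xs)

    def test_constant_channel_flagged_undefined(self):
        a = np.full((30, 30), 5.0)
        b = np.arange(900, dtype=float).reshape(30, 30)
        mask = np.ones((30, 30), dtype=bool)
        res = pearson_in_mask(ChannelImage(a, PX), ChannelImage(b, PX), mask)
        assert not res.defined

    def test_designed_rho_recovered(self):
        rs = []
        for s in range(10):
            fld = gen_coloc_images(0.6, seed=40 + s)
            m = mask_cytonemes(ChannelImage(fld.membrane, fld.pixel_size))
            res = pearson_in_mask(
                ChannelImage(fld.ch_a, fld.pixel_size),
                ChannelImage(fld.ch_b, fld.pixel_size), m,
            )
            assert res.n_pixels >= 2000
            rs.append(res.pearson_r)
        assert np.mean(rs) == pytest.approx(0.6, abs=0.05)


class TestPunctaReferenced:
    def test_empty_reference_flagged(self):
        ref = ChannelImage(np.full((60, 60), 20.0), PX)
        a = ChannelImage(np.random.default_rng(0).normal(size=(60, 60)), PX)
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:13, 5:55] = True
        res = puncta_referenced_pearson(ref, a, a, mask)
        assert not res.defined

    def test_identical_channels_at_puncta_give_r_one(self, rng):
        ref_img = np.full((60, 60), 20.0)
        ref_img[11, 20] = 200.0
        ref_img[11, 40] = 200.0
        a = rng.normal(100, 20, size=(60, 60))
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:13, 5:55] = True
        res = puncta_referenced_pearson(
            ChannelImage(ref_img, PX), ChannelImage(a, PX),
            ChannelImage(a, PX), mask,
        )
        assert res.defined
        assert res.pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_correlation_confined_to_puncta_detected(self):
        # channels correlated only at ligand puncta: the puncta-referenced
        # r must exceed the whole-mask r by a wide margin
        pr, wm = [], []
        for s in range(8):
            fld = gen_coloc_images(
                0.0, seed=60 + s, puncta_density=0.5, rho_puncta=0.8
            )
            m = mask_cytonemes(ChannelImage(fld.membrane, fld.pixel_size))
            ca = ChannelImage(fld.ch_a, fld.pixel_size)
            cb = ChannelImage(fld.ch_b, fld.pixel_size)
            ref = ChannelImage(fld.reference, fld.pixel_size)
            pr.append(puncta_referenced_pearson(ref, ca, cb, m).pearson_r)
            wm.append(pearson_in_mask(ca, cb, m).pearson_r)
        assert np.mean(pr) > 0.5
        assert abs(np.mean(wm)) < 0.15
        assert np.mean(pr) - np.mean(wm) > 0.4


class TestColocBatch:
    def test_single_field_summary_equals_field_values(self):
        fld = gen_coloc_images(0.6, seed=70)
        field = {
            "condition": "ctrl",
            "membrane": ChannelImage(fld.membrane, fld.pixel_size),
            "ch_a": ChannelImage(fld.ch_a, fld.pixel_size),
            "ch_b": ChannelImage(fld.ch_b, fld.pixel_size),
        }
        res = coloc_batch([field])
        assert len(res.per_condition) == 1
        row = res.per_condition.iloc[0]
        rs = res.per_object["pearson_r"]
        assert row["median_r"] == pytest.approx(rs.median())
        assert row["min_r"] == pytest.approx(rs.min())
        assert row["n"] == len(rs)

    def test_differing_conditions_detected(self):
        fields = []
        for cond, rho, seed0 in (("ctrl", 0.0, 200), ("shh", 0.6, 300)):
            for s in range(10):
                fld = gen_coloc_images(rho, seed=seed0 + s)
                fields.append(
                    {
                        "condition": cond,
                        "membrane": ChannelImage(fld.membrane, fld.pixel_size),
                        "ch_a": ChannelImage(fld.ch_a, fld.pixel_size),
                        "ch_b": ChannelImage(fld.ch_b, fld.pixel_size),
                    }
                )
        res = coloc_batch(fields)
        assert res.comparison["t_test"]["p"] < 0.05

    def test_empty_field_list_rejected(self):
        with pytest.raises(ParameterError):
            coloc_batch([])
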