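"""Vegetation-index math, band-pair selection and model-input packaging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bloomspec as bs
from bloomspec.spectral import select_band_pair, to_model_input
from tests.conftest import constant_scene


class TestNormalizedDifference:
    def test_equal_bands_give_zero(self):
        scene = constant_scene({b: 0.3 for b in bs.BAND_IDS})
        idx = bs.normalized_difference(scene, "B5", "B3")
        np.testing.assert_array_equal(idx.values, 0.0)

    def test_hand_value(self):
        scene = constant_scene({"B5": 0.6, "B1": 0.2})
        idx = bs.normalized_difference(scene, "B5", "B1")
        np.testing.assert_allclose(idx.values, 0.5)  # (0.6-0.2)/(0.6+0.2)

    def test_boundary_value_one(self):
        scene = constant_scene({"B5": 0.4, "B1": 0.0})
        idx = bs.normalized_difference(scene, "B5", "B1")
        np.testing.assert_allclose(idx.values, 1.0)

    def test_zero_denominator_becomes_sentinel(self):
        scene = constant_scene({"B5": 0.0, "B1": 0.0})
        idx = bs.normalized_difference(scene, "B5", "B1")
        assert not idx.valid.any()
        np.testing.assert_array_equal(idx.values, 0.0)

    def test_identical_bands_rejected(self):
        scene = constant_scene({})
        with pytest.raises(ValueError):
            bs.normalized_difference(scene, "B3", "B3")

    @pytest.mark.parametrize("pair", [("B5", "B1"), ("B4", "B2")])
    def test_antisymmetric_in_band_order(self, pair):
        rng = np.random.default_rng(0)
        scene = bs.MultispectralScene(
            bands={b: rng.random((6, 6)) for b in bs.BAND_IDS}
        )
        fwd = bs.normalized_difference(scene, *pair)
        rev = bs.normalized_difference(scene, pair[1], pair[0])
        np.testing.assert_allclose(fwd.values, -rev.values)


class TestSignedSqrt:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, 0.0), (0.25, 0.5), (-0.25, -0.5), (1.0, 1.0), (-1.0, -1.0)]
    )
    def test_pointwise_values(self, x, expected):
        idx = bs.IndexMap(
            values=np.full((2, 2), x), band_pair=("B5", "B1"),
            valid=np.ones((2, 2), bool),
        )
        out = bs.enhance_signed_sqrt(idx)
        np.testing.assert_allclose(out.values, expected)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=-1.0, max_value=1.0))
    def test_odd_and_range_preserving(self, x):
        f = lambda v: np.sign(v) * np.sqrt(abs(v))
        assert f(-x) == -f(x)
        assert -1.0 <= f(x) <= 1.0
        assert abs(f(x)) >= abs(x)  # the gap-widening claim

    def test_strictly_monotone_on_grid(self):
        xs = np.linspace(-1, 1, 1001)
        ys = np.sign(xs) * np.sqrt(np.abs(xs))
        assert np.all(np.diff(ys) > 0)

    def test_sentinel_propagates(self):
        valid = np.array([[True, False]])
        idx = bs.IndexMap(values=np.array([[0.25, 0.0]]),
                          band_pair=("B5", "B1"), valid=valid)
        out = bs.enhance_signed_sqrt(idx)
        np.testing.assert_array_equal(out.valid, valid)
        assert out.values[0, 1] == 0.0


class TestNdviSqrt:
    def test_equals_composition(self):
        rng = np.random.default_rng(1)
        scene = bs.MultispectralScene(
            bands={b: rng.random((5, 5)) for b in bs.BAND_IDS}
        )
        direct = bs.ndvi_sqrt(scene)
        composed = bs.enhance_signed_sqrt(
            bs.normalized_difference(scene, "B5", "B1")
        )
        np.testing.assert_allclose(direct.values, composed.values)

    def test_hand_value(self):
        scene = constant_scene({"B5": 0.5, "B1": 0.3})
        out = bs.ndvi_sqrt(scene)
        np.testing.assert_allclose(out.values, 0.5)  # sgn(0.25)*sqrt(0.25)

    def test_amplifies_plain_index_pixelwise(self):
        rng = np.random.default_rng(2)
        scene = bs.MultispectralScene(
            bands={b: rng.random((8, 8)) for b in bs.BAND_IDS}
        )
        plain = bs.normalized_difference(scene, "B5", "B1")
        enhanced = bs.ndvi_sqrt(scene)
        assert np.all(np.abs(enhanced.values) >= np.abs(plain.values) - 1e-12)


def naive_band_pair_scores(scenes):
    """Exhaustive reference: all 10 pairs, worst-case Fisher ratio."""
    scheme = scenes[0][1].scheme
    scores = {}
    for a, b in itertools.combinations(bs.BAND_IDS, 2):
        by_class = {}
        for scene, labels in scenes:
            va = scene.bands[a]
            vb = scene.bands[b]
            denom = va + vb
            for ci in range(scheme.n_classes):
                if ci == scheme.ignore_index:
                    continue
                sel = (labels.data == ci) & (denom > 0)
                if sel.any():
                    by_class.setdefault(ci, []).append(
                        ((va - vb)[sel] / denom[sel])
                    )
        stats = {c: np.concatenate(v) for c, v in by_class.items()}
        score = np.inf
        for c1, c2 in itertools.combinations(sorted(stats), 2):
            x, y = stats[c1], stats[c2]
            gap = abs(x.mean() - y.mean())
            dof = x.size + y.size - 2
            pooled = np.sqrt(
                ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / dof
            ) if dof > 0 else 0.0
            if pooled == 0:
                s = np.inf if gap > 0 else 0.0
            else:
                s = gap / pooled
            score = min(score, s)
        scores[(a, b)] = score
    return scores


class TestSelectBandPair:
    def _two_class_fixture(self):
        scheme = bs.DEFAULT_SCHEME
        h = w = 8
        labels = np.zeros((h, w), dtype=int)
        labels[:, 4:] = scheme.bloom_index
        bands_bloom = {"B1": 0.05, "B2": 0.2, "B3": 0.2, "B4": 0.2, "B5": 0.6}
        bands_water = {"B1": 0.3, "B2": 0.2, "B3": 0.2, "B4": 0.2, "B5": 0.1}
        rng = np.random.default_rng(3)
        bands = {}
        for b in bs.BAND_IDS:
            g = np.where(labels == scheme.bloom_index, bands_bloom[b], bands_water[b])
            bands[b] = np.clip(g + 0.001 * rng.standard_normal((h, w)), 0, 1)
        scene = bs.MultispectralScene(bands=bands)
        return [(scene, bs.LabelRaster(data=labels, scheme=scheme))]

    def test_b1_b5_ranked_first_on_designed_fixture(self):
        scenes = self._two_class_fixture()
        report = select_band_pair(scenes)
        assert report.best_pair == ("B1", "B5")
        assert len(report.ranking) == 10

    def test_matches_exhaustive_oracle(self):
        scenes = self._two_class_fixture()
        report = select_band_pair(scenes)
        expected = naive_band_pair_scores(scenes)
        got = dict(report.ranking)
        for pair, s in expected.items():
            assert got[pair] == pytest.approx(s, rel=1e-9)

    def test_identical_classes_score_zero(self):
        scheme = bs.DEFAULT_SCHEME
        labels = np.zeros((6, 6), dtype=int)
        labels[:, 3:] = scheme.bloom_index
        scene = constant_scene({b: 0.4 for b in bs.BAND_IDS}, shape=(6, 6))
        report = select_band_pair([(scene, bs.LabelRaster(data=labels, scheme=scheme))])
        assert all(score == 0.0 for _, score in report.ranking)

    def test_single_class_rejected(self):
        scheme = bs.DEFAULT_SCHEME
        labels = np.zeros((4, 4), dtype=int)
        scene = constant_scene({b: 0.4 for b in bs.BAND_IDS}, shape=(4, 4))
        with pytest.raises(ValueError):
            select_band_pair([(scene, bs.LabelRaster(data=labels, scheme=scheme))])


class TestToModelInput:
    def _index(self, h, w, seed=0):
        rng = np.random.default_rng(seed)
        return bs.IndexMap(
            values=rng.uniform(-1, 1, (h, w)),
            band_pair=("B5", "B1"),
            valid=np.ones((h, w), bool),
        )

    def test_identity_when_sizes_match(self):
        idx = self._index(32, 32)
        out = to_model_input(idx, (32, 32))
        assert out.data.shape == (32, 32, 3)
        for c in range(3):
            np.testing.assert_allclose(out.data[:, :, c], idx.values)

    def test_downscales_large_scene_to_target(self):
        idx = self._index(160, 130)
        out = to_model_input(idx, (96, 96))
        assert out.data.shape == (96, 96, 3)

    def test_augmented_crop_deterministic_given_seed(self):
        idx = self._index(64, 64)
        a = to_model_input(idx, (48, 48), seed=9, augment=True)
        b = to_model_input(idx, (48, 48), seed=9, augment=True)
        np.testing.assert_array_equal(a.data, b.data)

    def test_sentinel_pixels_become_ignore(self):
        idx = self._index(16, 16)
        idx = bs.IndexMap(
            values=idx.values, band_pair=idx.band_pair,
            valid=np.zeros((16, 16), bool),
        )
        out = to_model_input(idx, (16, 16))
        assert out.ignore_mask.all()
        np.testing.assert_array_equal(out.data, 0.0)

    def test_upscale_disabled_rejected(self):
        idx = self._index(32, 32)
        with pytest.raises(ValueError):
            to_model_input(idx, (64, 64), allow_scale=False)
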