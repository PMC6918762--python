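import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nestcam as nc
from nestcam import camouflage as cam
from nestcam import scene_io
from nestcam import texture_features as tf


def _sig(*weights):
    w = np.zeros(14)
    w[: len(weights)] = weights
    return cam.ClusterSignature(region=1, weights=w)


class TestChi2Distance:
    def test_identical_signatures_are_zero(self):
        g = _sig(25, 25, 25, 25)
        assert cam.chi2_distance(g, g).value == 0.0

    def test_disjoint_support_is_100(self):
        g = _sig(100)
        h = cam.ClusterSignature(region=2, weights=np.r_[0.0, 100.0, np.zeros(12)])
        # hand computation: 0.5 * (100^2/100 + 100^2/100) = 100
        assert abs(cam.chi2_distance(g, h).value - 100.0) < 1e-9

    def test_half_split_vs_concentrated(self):
        g = _sig(50, 50)
        h = _sig(100, 0)
        # 0.5 * (2500/150 + 2500/50) = 33.3333...
        assert abs(cam.chi2_distance(g, h).value - 100.0 / 3.0) < 1e-9

    def test_no_half_variant_doubles_the_value(self):
        g, h = _sig(50, 50), _sig(100, 0)
        full = cam.chi2_distance(g, h, half=False).value
        assert abs(full - 200.0 / 3.0) < 1e-9

    def test_unnormalized_input_errors(self):
        bad = cam.ClusterSignature(region=1, weights=np.r_[50.0, np.zeros(13)])
        with pytest.raises(ValueError, match="sum to 100"):
            cam.chi2_distance(bad, _sig(100))

    def test_length_mismatch_errors(self):
        g = cam.ClusterSignature(region=1, weights=np.array([100.0]))
        with pytest.raises(ValueError, match="length"):
            cam.chi2_distance(g, _sig(100))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5),
           st.lists(st.floats(0.0, 1.0), min_size=5, max_size=5))
    def test_symmetry_nonnegativity_bound(self, raw_g, raw_h):
        def norm(v):
            v = np.asarray(v) + 1e-6
            return 100.0 * v / v.sum()

        g = cam.ClusterSignature(region=1, weights=norm(raw_g))
        h = cam.ClusterSignature(region=2, weights=norm(raw_h))
        d_gh = cam.chi2_distance(g, h).value
        d_hg = cam.chi2_distance(h, g).value
        assert d_gh == pytest.approx(d_hg, abs=1e-12)
        assert 0.0 <= d_gh <= 100.0 + 1e-9
        if np.allclose(g.weights, h.weights):
            assert d_gh < 1e-9


def _texmap(labels, n_clusters):
    labels = np.asarray(labels)
    return cam.TextureMap(labels=labels, n_clusters=n_clusters,
                          boundaries=cam._texture_boundaries(labels))


class TestSignature:
    def _mask(self, labels):
        return scene_io.RegionMask(labels=np.asarray(labels))

    def test_pure_region_concentrates_in_one_cluster(self):
        tex = _texmap(np.full((10, 10), 3), n_clusters=14)
        mask = self._mask(np.full((10, 10), scene_io.NEST))
        sig = cam.signature(tex, mask, scene_io.NEST)
        expected = np.zeros(14)
        expected[2] = 100.0
        np.testing.assert_allclose(sig.weights, expected)

    def test_half_half_region(self):
        labels = np.ones((10, 10), dtype=int)
        labels[:, 5:] = 2
        tex = _texmap(labels, n_clusters=14)
        mask = self._mask(np.full((10, 10), scene_io.EGG))
        sig = cam.signature(tex, mask, scene_io.EGG)
        assert sig.weights[0] == 50.0 and sig.weights[1] == 50.0

    def test_signatures_sum_to_100_over_all_regions(self, rng):
        labels = rng.integers(1, 5, size=(30, 30))
        tex = _texmap(rng.integers(1, 7, size=(30, 30)), n_clusters=6)
        mask = self._mask(labels)
        for code in (1, 2, 3, 4):
            s = cam.signature(tex, mask, code)
            assert abs(s.weights.sum() - 100.0) < 1e-6

    def test_empty_region_errors(self):
        tex = _texmap(np.ones((5, 5), dtype=int), n_clusters=2)
        mask = self._mask(np.full((5, 5), scene_io.NEST))
        with pytest.raises(ValueError):
            cam.signature(tex, mask, scene_io.EGG)


class TestClusterTextures:
    def test_same_seed_is_bitwise_deterministic(self, rng, small_bank):
        lab, _ = nc.make_two_texture_scene(size=(48, 48), seed=3)
        stack = tf.apply_bank(lab, small_bank)
        t1 = cam.cluster_textures(stack, lab.mask, n_clusters=3, seed=9)
        t2 = cam.cluster_textures(stack, lab.mask, n_clusters=3, seed=9)
        np.testing.assert_array_equal(t1.labels, t2.labels)
        np.testing.assert_array_equal(t1.boundaries, t2.boundaries)

    def test_constant_image_reduces_to_single_label(self, small_bank):
        mask = scene_io.RegionMask(labels=np.full((40, 40), scene_io.NEST, int))
        scene = scene_io.LabScene(L=np.full((40, 40), 30.0),
                                  a=np.zeros((40, 40)), b=np.zeros((40, 40)),
                                  pixel_scale=1.0, mask=mask)
        stack = tf.apply_bank(scene, small_bank)
        with pytest.warns(UserWarning, match="reducing clusters"):
            tex = cam.cluster_textures(stack, mask, n_clusters=3, seed=0)
        assert tex.n_clusters == 1
        assert set(np.unique(tex.labels)) == {1}
        assert tex.boundaries.sum() == 0

    def test_two_texture_scene_recovered(self, small_bank):
        lab, truth = nc.make_two_texture_scene(size=(96, 96), seed=1)
        stack = tf.apply_bank(lab, small_bank)
        tex = cam.cluster_textures(stack, lab.mask, n_clusters=2, seed=0)
        pred = tex.labels - 1
        agree = max(np.mean(pred == truth), np.mean(pred == 1 - truth))
        assert agree >= 0.95

    def test_matches_bruteforce_lloyd_oracle_on_separated_blobs(self, rng):
        # three tight, well-separated blobs: any correct K-means finds the
        # exact partition, so the implementation must match a brute-force
        # Lloyd iteration up to label permutation
        n_per = 60
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pts = np.concatenate([c + 0.1 * rng.standard_normal((n_per, 2))
                              for c in centers])
        feats = np.zeros((1, n_per * 3, 2))
        feats[0, :, :] = pts
        stack = tf.FeatureStack(features=feats)
        mask = scene_io.RegionMask(
            labels=np.full((1, n_per * 3), scene_io.NEST, int))
        tex = cam.cluster_textures(stack, mask, n_clusters=3, seed=0)

        oracle = _lloyd_oracle(pts, k=3, seed=0)
        got = tex.labels[0] - 1
        # compare as partitions
        assert _same_partition(got, oracle)

    def test_too_few_pixels_errors(self, rng):
        stack = tf.FeatureStack(features=rng.random((1, 2, 4)))
        mask = scene_io.RegionMask(labels=np.full((1, 2), scene_io.NEST, int))
        with pytest.raises(ValueError):
            cam.cluster_textures(stack, mask, n_clusters=5, seed=0)


def _lloyd_oracle(pts, k, seed, iters=100):
    """Plain Lloyd K-means with deterministic farthest-point init."""
    rng = np.random.default_rng(seed)
    centers = [pts[rng.integers(len(pts))]]
    for _ in range(k - 1):
        d = np.min([((pts - c) ** 2).sum(1) for c in centers], axis=0)
        centers.append(pts[np.argmax(d)])
    centers = np.array(centers)
    for _ in range(iters):
        d = ((pts[:, None, :] - centers[None]) ** 2).sum(-1)
        lbl = d.argmin(1)
        new = np.array([pts[lbl == j].mean(0) for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return lbl


def _same_partition(a, b):
    import itertools

    for perm in itertools.permutations(sorted(set(b))):
        mapping = {old: new for old, new in zip(sorted(set(b)), perm)}
        if np.array_equal(a, np.vectorize(mapping.get)(b)):
            return True
    return False


class TestSelectNClusters:
    def _scenes(self, n=2, egg_app=None, ext_app=None):
        scenes = []
        for s in range(n):
            kwargs = {}
            if egg_app is not None:
                kwargs["egg"] = egg_app
            if ext_app is not None:
                kwargs["external"] = ext_app
                kwargs["internal"] = ext_app
            spec = nc.SceneSpec(size=(96, 96), egg_axes_px=(24.0, 16.0),
                                nest_radius_px=30.0, internal_width_px=2,
                                standard_patch_px=6, seed=100 + s, **kwargs)
            scene, mask, std, _ = nc.make_scene(spec)
            mask = scene_io.exclude_border(mask, 0.02)
            scenes.append(scene_io.rgb_to_lab(scene, std, mask=mask))
        return scenes

    def test_single_candidate_returned_with_its_correlation(self, small_bank):
        scenes = self._scenes(2)
        chosen, curve = cam.select_n_clusters(scenes, candidates=(2,),
                                              seed=0, bank=small_bank)
        assert chosen == 2 and set(curve) == {2}

    def test_identical_egg_and_external_textures_correlate_near_one(self, small_bank):
        app = nc.RegionAppearance(L=28.0, grain_px=3.0, contrast=3.0)
        scenes = self._scenes(2, egg_app=app, ext_app=app)
        _, curve = cam.select_n_clusters(scenes, candidates=(2, 4), seed=0,
                                         bank=small_bank)
        # egg and microhabitat share one texture process -> signatures agree
        assert all(r > 0.8 for r in curve.values())

    def test_distinct_textures_decorrelate_with_more_clusters(self, small_bank):
        scenes = self._scenes(2)
        chosen, curve = cam.select_n_clusters(scenes, candidates=(2, 4, 8),
                                              seed=0, bank=small_bank)
        assert curve[8] <= curve[2] + 0.1
        assert chosen in (2, 4, 8)

    def test_empty_candidates_error(self, small_bank):
        with pytest.raises(ValueError):
            cam.select_n_clusters([], candidates=(), seed=0, bank=small_bank)
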