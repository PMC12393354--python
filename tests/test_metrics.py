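import numpy as np
import pytest

from conftest import random_bundle, random_streamline
from tractshape.metrics import (
    BAParams,
    bundle_adjacency,
    coverage,
    extract_bundle,
    mdf,
    pairwise_ba_matrix,
    resample,
)


# -- independent oracles ------------------------------------------------------

def naive_mdf(s1, s2, K):
    """Literal double-sum MDF, independent of the vectorized path."""
    a, b = resample(s1, K), resample(s2, K)
    direct = sum(np.linalg.norm(a[i] - b[i]) for i in range(K)) / K
    flipped = sum(np.linalg.norm(a[i] - b[K - 1 - i]) for i in range(K)) / K
    return min(direct, flipped)


def naive_coverage(B1, B2, theta, K):
    hits = 0
    for s1 in B1:
        if any(naive_mdf(s1, s2, K) <= theta for s2 in B2):
            hits += 1
    return hits / len(B1)


def naive_ba(B1, B2, theta, K):
    return 0.5 * (naive_coverage(B1, B2, theta, K) + naive_coverage(B2, B1, theta, K))


def straight(start, direction, length, n=2):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    ts = np.linspace(0.0, length, n)
    return np.asarray(start, float) + ts[:, None] * direction


class TestResample:
    def test_uniform_spacing_on_segment(self):
        s = straight((0, 0, 0), (1, 0, 0), 10.0)
        out = resample(s, 5)
        np.testing.assert_allclose(out[:, 0], [0, 2.5, 5, 7.5, 10], atol=1e-12)

    @pytest.mark.parametrize("K", [2, 3, 20, 101])
    def test_endpoints_preserved(self, rng, K):
        s = random_streamline(rng)
        out = resample(s, K)
        np.testing.assert_array_equal(out[0], s[0])
        np.testing.assert_array_equal(out[-1], s[-1])

    def test_idempotence_on_equispaced_input(self):
        s = straight((1, 2, 3), (0, 1, 0), 12.0, n=7)
        np.testing.assert_allclose(resample(s, 7), s, atol=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            resample(np.zeros((3, 3)), 5)


class TestMDF:
    def test_identity_and_flip_invariance(self, rng):
        s = random_streamline(rng)
        assert mdf(s, s) == 0.0
        assert mdf(s, s[::-1]) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_offset_segments(self):
        a = straight((0, 0, 0), (1, 0, 0), 20.0)
        b = straight((0, 3, 0), (1, 0, 0), 20.0)
        assert mdf(a, b) == pytest.approx(3.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            s1, s2 = random_streamline(rng), random_streamline(rng)
            assert mdf(s1, s2, K=12) == pytest.approx(naive_mdf(s1, s2, 12), abs=1e-12)

    def test_metric_properties_on_random_triples(self, rng):
        """Nonnegativity, symmetry, and the empirical triangle inequality."""
        K = 12
        for _ in range(1000):
            a, b, c = (random_streamline(rng, n_points=8) for _ in range(3))
            dab, dba = mdf(a, b, K), mdf(b, a, K)
            dac, dcb = mdf(a, c, K), mdf(c, b, K)
            assert dab >= 0
            assert dab == pytest.approx(dba, abs=1e-12)
            assert dab <= dac + dcb + 1e-9


class TestCoverage:
    def test_self_coverage_is_one(self, rng):
        B = random_bundle(rng)
        assert coverage(B, B) == 1.0

    def test_half_coverage(self):
        a = straight((0, 0, 0), (1, 0, 0), 20.0)
        B1 = [a, a + np.array([0, 10.0, 0])]
        assert coverage(B1, [a], BAParams(theta=5.0)) == 0.5

    def test_empty_target_convention(self, rng):
        B = random_bundle(rng)
        assert coverage(B, []) == 0.0
        with pytest.raises(ValueError):
            coverage([], B)


class TestBundleAdjacency:
    def test_identical_bundles_score_one(self, rng):
        B = random_bundle(rng)
        assert bundle_adjacency(B, B) == 1.0

    def test_threshold_decides_single_pair(self):
        a = straight((0, 0, 0), (1, 0, 0), 20.0)
        near = [a + np.array([0, 3.0, 0])]
        far = [a + np.array([0, 6.0, 0])]
        assert bundle_adjacency([a], near, BAParams(theta=5.0)) == 1.0
        assert bundle_adjacency([a], far, BAParams(theta=5.0)) == 0.0

    def test_asymmetric_coverages_average(self):
        a = straight((0, 0, 0), (1, 0, 0), 20.0)
        far = a + np.array([0, 50.0, 0])
        assert bundle_adjacency([a], [a, far], BAParams(theta=5.0)) == 0.75

    def test_empty_bundle_scores_zero_with_warning(self, rng):
        with pytest.warns(UserWarning):
            assert bundle_adjacency(random_bundle(rng), []) == 0.0

    def test_symmetry_on_random_pairs(self, rng):
        for _ in range(100):
            B1, B2 = random_bundle(rng, 5), random_bundle(rng, 7)
            assert bundle_adjacency(B1, B2) == bundle_adjacency(B2, B1)

    def test_monotone_in_theta_and_in_range(self, rng):
        for _ in range(25):
            B1, B2 = random_bundle(rng, 6), random_bundle(rng, 6)
            vals = [
                bundle_adjacency(B1, B2, BAParams(theta=th))
                for th in range(1, 11)
            ]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestPairwiseMatrix:
    def test_matches_brute_force_oracle(self, rng):
        K, theta = 20, 5.0
        bundles = [random_bundle(rng, 5) for _ in range(4)]
        M = pairwise_ba_matrix(bundles, BAParams(theta=theta, n_resample_points=K))
        for i in range(4):
            for j in range(4):
                expected = 1.0 if i == j else naive_ba(bundles[i], bundles[j], theta, K)
                assert M.scores[i, j] == pytest.approx(expected, abs=1e-12)

    def test_shape_symmetry_diagonal(self, rng):
        bundles = [random_bundle(rng, 4) for _ in range(10)]
        M = pairwise_ba_matrix(bundles)
        assert M.scores.shape == (10, 10)
        np.testing.assert_array_equal(M.scores, M.scores.T)
        np.testing.assert_array_equal(np.diag(M.scores), np.ones(10))

    def test_empty_bundle_flagged_and_zeroed(self, rng):
        bundles = [random_bundle(rng, 4), [], random_bundle(rng, 4)]
        M = pairwise_ba_matrix(bundles)
        assert M.empty_subjects == [M.subject_ids[1]]
        np.testing.assert_array_equal(M.scores[1], 0.0)
        np.testing.assert_array_equal(M.scores[:, 1], 0.0)

    def test_subsampling_is_seeded_and_reproducible(self, rng):
        bundles = [random_bundle(rng, 40) for _ in range(3)]
        params = BAParams(subsample=10, subsample_seed=3)
        a = pairwise_ba_matrix(bundles, params)
        b = pairwise_ba_matrix(bundles, params)
        np.testing.assert_array_equal(a.scores, b.scores)


class TestExtractBundle:
    def test_model_members_always_kept(self, rng):
        model = random_bundle(rng, 4)
        extra = random_bundle(rng, 3)
        kept = extract_bundle(model + extra, model, theta_extract=1e-6)
        for s in model:
            assert any(np.array_equal(s, k) for k in kept)

    def test_far_streamline_rejected(self):
        a = straight((0, 0, 0), (1, 0, 0), 20.0)
        near = a + np.array([0, 1.0, 0])
        far = a + np.array([0, 30.0, 0])
        kept = extract_bundle([near, far], [a], theta_extract=5.0)
        assert len(kept) == 1
        np.testing.assert_array_equal(kept[0], near)

    def test_infinite_threshold_keeps_everything(self, rng):
        tract = random_bundle(rng, 9)
        kept = extract_bundle(tract, random_bundle(rng, 2), theta_extract=1e6)
        assert len(kept) == 9

    def test_empty_tractogram_gives_empty_bundle(self, rng):
        with pytest.warns(UserWarning):
            assert extract_bundle([], random_bundle(rng), 5.0) == []
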