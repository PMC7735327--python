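"""Label propagation, LNCC, STAPLE EM and STEPS fusion equivalences."""

import numpy as np
import pytest

from faceatlas import (
    AffineTransform,
    FusionParams,
    ProbabilisticLabel,
    SegmentationMask,
    SimilarityMap,
    Volume3D,
    lncc_map,
    majority_vote,
    propagate_label,
    random_smooth_warp,
    staple_em,
    steps_fuse,
)
from faceatlas.registration import BSplineTransform, GridSpec

NOSMOOTH = FusionParams(posterior_smoothing_sigma_vox=0.0)


def _identity_bspline(grid_like, affine=None):
    grid = GridSpec.of(grid_like)
    return BSplineTransform.zero(grid, (8.0, 8.0, 8.0), affine)


def _uniform_sims(n, shape):
    return [SimilarityMap(np.zeros(shape), 2.0) for _ in range(n)]


def _random_votes(rng, n, shape=(16, 16, 16)):
    return [
        ProbabilisticLabel(rng.integers(0, 2, shape).astype(float)) for _ in range(n)
    ]


class TestPropagate:
    def test_identity_returns_binary_mask(self, phantom_32):
        _, msk = phantom_32
        out = propagate_label(msk, _identity_bspline(msk))
        np.testing.assert_array_equal(out.probabilities, msk.labels.astype(float))

    def test_half_voxel_shift_gives_half_probability(self):
        lab = np.zeros((8, 8, 8), np.uint8)
        lab[2:6, 2:6, 2:6] = 1
        msk = SegmentationMask(lab)
        t = _identity_bspline(msk, AffineTransform.from_translation((0.5, 0, 0)))
        out = propagate_label(msk, t)
        # flat face orthogonal to x: boundary plane interpolates to exactly 0.5
        assert out.probabilities[1, 3, 3] == pytest.approx(0.5)
        assert out.probabilities[5, 3, 3] == pytest.approx(0.5)
        assert out.probabilities[3, 3, 3] == pytest.approx(1.0)

    def test_empty_mask_propagates_to_zero(self, phantom_32):
        _, msk = phantom_32
        empty = SegmentationMask(np.zeros(msk.shape, np.uint8), msk.spacing)
        out = propagate_label(empty, _identity_bspline(msk))
        assert np.all(out.probabilities == 0)


class TestLNCC:
    def test_self_correlation_is_one(self, phantom_32):
        img, _ = phantom_32
        sim = lncc_map(img, img, 2.0)
        varied = sim.values[8:-8, 8:-8, 8:-8]
        assert np.all(varied > 0.99)

    def test_anticorrelation_is_minus_one(self, phantom_32):
        img, _ = phantom_32
        neg = Volume3D(-img.data + 3.0, img.spacing, img.origin)
        sim = lncc_map(img, neg, 2.0)
        assert np.all(sim.values[8:-8, 8:-8, 8:-8] < -0.99)

    def test_constant_target_defined_as_zero(self):
        rng = np.random.default_rng(0)
        a = Volume3D(np.full((12, 12, 12), 5.0))
        b = Volume3D(rng.random((12, 12, 12)))
        assert np.all(lncc_map(a, b, 2.0).values == 0.0)

    def test_bounded_in_unit_interval(self, phantom_32):
        img, _ = phantom_32
        rng = np.random.default_rng(1)
        b = Volume3D(rng.random(img.shape), img.spacing)
        sim = lncc_map(img, b, 2.0)
        assert np.abs(sim.values).max() <= 1.0 + 1e-6


class TestStapleEM:
    def test_unanimous_raters(self, phantom_32):
        _, msk = phantom_32
        votes = [ProbabilisticLabel.from_mask(msk) for _ in range(4)]
        post, perf = staple_em(votes, NOSMOOTH)
        np.testing.assert_array_equal(post.threshold().labels, msk.labels)
        assert np.all(perf.sensitivity >= 0.999)
        assert np.all(perf.specificity >= 0.999)

    def test_single_vote_passthrough(self, phantom_32):
        _, msk = phantom_32
        vote = ProbabilisticLabel.from_mask(msk)
        post, _ = staple_em([vote], NOSMOOTH)
        np.testing.assert_array_equal(post.threshold().labels, msk.labels)

    def test_empty_vote_list_rejected(self):
        with pytest.raises(ValueError):
            staple_em([], NOSMOOTH)

    def test_parameter_recovery_from_simulated_raters(self):
        n = 30
        idx = np.indices((n, n, n))
        c = (n - 1) / 2
        truth = (
            ((idx[0] - c) / 12) ** 2 + ((idx[1] - c) / 13) ** 2 + ((idx[2] - c) / 11) ** 2
            <= 1
        ).astype(float)
        for seed in range(3):
            rng = np.random.default_rng(seed)
            votes = [
                ProbabilisticLabel(
                    np.where(
                        truth == 1, rng.random(truth.shape) < 0.9, rng.random(truth.shape) < 0.05
                    ).astype(float)
                )
                for _ in range(6)
            ]
            _, perf = staple_em(votes, NOSMOOTH)
            assert np.abs(perf.sensitivity - 0.9).max() < 0.02
            assert np.abs(perf.specificity - 0.95).max() < 0.02


class TestStepsFuse:
    def test_single_atlas_identity(self, phantom_32):
        img, msk = phantom_32
        vote = ProbabilisticLabel.from_mask(msk)
        fused = steps_fuse(
            img, [img], [vote], FusionParams(top_k=1, posterior_smoothing_sigma_vox=0.0)
        )
        np.testing.assert_array_equal(fused.labels, msk.labels)

    def test_majority_vote_equivalence_under_uniform_similarity(self):
        rng = np.random.default_rng(5)
        for n_atlas in (3, 4, 5):
            votes = _random_votes(rng, n_atlas)
            imgs = [Volume3D(rng.standard_normal((16, 16, 16))) for _ in range(n_atlas)]
            tgt = Volume3D(rng.standard_normal((16, 16, 16)))
            fused = steps_fuse(
                tgt,
                imgs,
                votes,
                FusionParams(
                    top_k=n_atlas, em_enabled=False, posterior_smoothing_sigma_vox=0.0
                ),
                similarity_maps=_uniform_sims(n_atlas, (16, 16, 16)),
            )
            mv = majority_vote(votes)
            np.testing.assert_array_equal(fused.labels, mv.labels)

    def test_top1_equals_locally_best_atlas(self):
        rng = np.random.default_rng(6)
        votes = _random_votes(rng, 5)
        imgs = [Volume3D(rng.standard_normal((16, 16, 16))) for _ in range(5)]
        tgt = Volume3D(rng.standard_normal((16, 16, 16)))
        sims = [SimilarityMap(rng.uniform(-1, 1, (16, 16, 16)), 2.0) for _ in range(5)]
        fused = steps_fuse(
            tgt,
            imgs,
            votes,
            FusionParams(top_k=1, em_enabled=False, posterior_smoothing_sigma_vox=0.0),
            similarity_maps=sims,
        )
        best = np.argmax(np.stack([s.values for s in sims]), axis=0)
        stacked = np.stack([v.probabilities for v in votes])
        oracle = (np.take_along_axis(stacked, best[None], 0)[0] >= 0.5).astype(np.uint8)
        np.testing.assert_array_equal(fused.labels, oracle)

    def test_perfect_copies_reproduce_truth_exactly(self, phantom_32):
        img, msk = phantom_32
        votes = [ProbabilisticLabel.from_mask(msk) for _ in range(5)]
        fused = steps_fuse(
            img,
            [img] * 5,
            votes,
            FusionParams(top_k=3, em_enabled=True, posterior_smoothing_sigma_vox=0.0),
        )
        np.testing.assert_array_equal(fused.labels, msk.labels)

    def test_atlas_order_invariance(self):
        rng = np.random.default_rng(7)
        votes = _random_votes(rng, 4)
        imgs = [Volume3D(rng.standard_normal((16, 16, 16))) for _ in range(4)]
        tgt = Volume3D(rng.standard_normal((16, 16, 16)))
        sims = [SimilarityMap(rng.uniform(-1, 1, (16, 16, 16)), 2.0) for _ in range(4)]
        params = FusionParams(top_k=2, posterior_smoothing_sigma_vox=0.0)
        fused = steps_fuse(tgt, imgs, votes, params, similarity_maps=sims)
        perm = [2, 0, 3, 1]
        fused_p = steps_fuse(
            tgt,
            [imgs[i] for i in perm],
            [votes[i] for i in perm],
            params,
            similarity_maps=[sims[i] for i in perm],
        )
        np.testing.assert_array_equal(fused.labels, fused_p.labels)

    def test_count_mismatch_and_topk_bounds(self, phantom_32):
        img, msk = phantom_32
        vote = ProbabilisticLabel.from_mask(msk)
        with pytest.raises(ValueError):
            steps_fuse(img, [img, img], [vote], NOSMOOTH)
        with pytest.raises(ValueError):
            steps_fuse(img, [img], [vote], FusionParams(top_k=3))

    def test_output_binary_on_target_grid(self, phantom_32):
        img, msk = phantom_32
        warp = random_smooth_warp(img, amplitude_mm=1.5, seed=3)
        vote = propagate_label(msk, warp)
        warped_img = Volume3D(np.roll(img.data, 1, 0), img.spacing, img.origin)
        fused = steps_fuse(img, [warped_img], [vote], FusionParams(top_k=1))
        assert set(np.unique(fused.labels)) <= {0, 1}
        assert fused.shape == img.shape
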