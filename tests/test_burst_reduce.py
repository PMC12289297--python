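"""Registration, score layer and merge of burst stacks."""

import numpy as np
import pytest

from fundusburst import (
    BurstConfig,
    BurstStack,
    burst_reduce,
    compute_score_layer,
    estimate_gaze_shifts,
    generate_phantom,
    merge_burst,
    simulate_burst,
)
from fundusburst.burst_reduce import ScoreLayer, default_reference_index
from fundusburst.synthetic import ArtifactSpec, IlluminationSchedule, LashSpec, \
    SaturationSpec
from fundusburst.utils import integer_shift, masked_psnr


def _stack(phantom, shifts, noise_sd=0.0, seed=0, jitter=0.0):
    cfg = BurstConfig(n_frames=len(shifts), gaze_model=shifts, noise_sd=noise_sd,
                      illumination=IlluminationSchedule(0.25, jitter), seed=seed)
    return simulate_burst(phantom, cfg)


def _eroded_fov(fov, margin=10):
    from scipy import ndimage

    return ndimage.binary_erosion(fov, iterations=margin)


def _truth_psnr(img, true_shift, phantom, core):
    """PSNR against the phantom after compensating the known gaze shift;
    the composite is anchored at the reference frame's (true) position."""
    dy, dx = true_shift
    return masked_psnr(integer_shift(np.asarray(img, float), -dy, -dx),
                       phantom.image, core)


class TestRegistration:
    def test_zero_shifts_estimated_as_identity(self, phantom):
        stack = _stack(phantom, [(0, 0)] * 3)
        est = estimate_gaze_shifts(stack, reference_index=0)
        assert est.shifts == [(0, 0)] * 3
        assert est.confidences[0] == 1.0

    def test_exact_recovery_of_integer_shifts(self, phantom):
        truth = [(0, 0), (3, -2), (-4, 1), (8, 8), (-8, 5)]
        stack = _stack(phantom, truth)
        est = estimate_gaze_shifts(stack, reference_index=0)
        assert est.shifts == truth

    def test_default_reference_is_middle_frame(self):
        assert default_reference_index(1) == 0
        assert default_reference_index(4) == 1
        assert default_reference_index(5) == 2

    def test_noise_frames_have_low_confidence(self):
        """Empirical null: peak correlation of pure-noise frames stays < 0.5."""
        confs = []
        for seed in range(100):
            r = np.random.default_rng(seed)
            frames = [np.clip(r.normal(0.5, 0.1, (128, 128)), 0, 1) for _ in range(3)]
            stack = BurstStack(frames=frames,
                               metadata=BurstConfig(n_frames=3, gaze_model=[(0, 0)] * 3))
            est = estimate_gaze_shifts(stack, reference_index=0)
            confs.extend(est.confidences[1:])
        assert max(confs) < 0.5

    def test_shape_mismatch_errors(self, phantom):
        stack = _stack(phantom, [(0, 0)] * 2)
        stack.frames[1] = stack.frames[1][:-2, :-2]
        with pytest.raises(ValueError, match="shape"):
            estimate_gaze_shifts(stack, reference_index=0)


class TestScoreLayer:
    def test_identical_frames_get_weight_one(self, clean_stack):
        est = estimate_gaze_shifts(clean_stack)
        layer = compute_score_layer(clean_stack, est)
        fov = clean_stack.fov_mask
        assert np.array_equal(layer.weights[:, fov],
                              np.ones_like(layer.weights[:, fov]))

    def test_saturated_blob_frame_downweighted_inside_blob(self, phantom):
        stack = _stack(phantom, [(0, 0)] * 4)
        n = phantom.side
        yy, xx = np.mgrid[0:n, 0:n]
        blob = ((yy - n // 2) ** 2 + (xx - n // 3) ** 2 <= 14 ** 2) & phantom.fov_mask
        stack.frames[1] = np.where(blob, 1.0, stack.frames[1])
        est = estimate_gaze_shifts(stack)
        layer = compute_score_layer(stack, est)
        assert layer.weights[1][blob].mean() < 0.5
        assert layer.weights[0][blob].mean() > 0.5
        assert layer.weights[2][blob].mean() > 0.5

    def test_black_frame_among_clean_gets_floor_weight(self, phantom):
        stack = _stack(phantom, [(0, 0)] * 4)
        stack.frames[2] = np.zeros_like(stack.frames[2])
        est = estimate_gaze_shifts(stack, reference_index=0)
        layer = compute_score_layer(stack, est)
        assert layer.weights[2][phantom.fov_mask].mean() < 0.1

    def test_single_frame_stack_gets_all_ones(self, phantom):
        stack = _stack(phantom, [(0, 0)])
        est = estimate_gaze_shifts(stack)
        layer = compute_score_layer(stack, est)
        assert (layer.weights[0][phantom.fov_mask] == 1.0).all()

    def test_weights_bounded(self, phantom):
        stack = _stack(phantom, [(0, 0), (2, 1), (-1, 3)], noise_sd=0.02, seed=5)
        layer = compute_score_layer(stack, estimate_gaze_shifts(stack))
        assert layer.weights.min() >= 0.0 and layer.weights.max() <= 1.0


class TestMerge:
    def test_identical_frames_merge_to_single_frame(self, clean_stack):
        comp = burst_reduce(clean_stack)
        assert np.allclose(comp.image, clean_stack.frames[0], atol=1e-12)
        assert not comp.unrecoverable_mask.any()

    def test_constant_frames_give_constant_output(self):
        """Convexity plus no-sharpening: constant in, constant out."""
        frames = [np.full((128, 128), v) for v in (0.2, 0.4, 0.6)]
        stack = BurstStack(frames=frames,
                           metadata=BurstConfig(n_frames=3, gaze_model=[(0, 0)] * 3))
        comp = burst_reduce(stack)
        fov = stack.fov_mask
        # constant up to one ulp of the per-pixel weight normalization
        assert np.ptp(comp.image[fov]) <= 1e-12
        assert 0.2 <= comp.image[fov][0] <= 0.6

    def test_all_zero_scores_fall_back_to_temporal_median(self, clean_stack):
        est = estimate_gaze_shifts(clean_stack)
        zeros = ScoreLayer(weights=np.zeros((clean_stack.n_frames,)
                                            + clean_stack.shape))
        comp = merge_burst(clean_stack, est, zeros)
        fov = clean_stack.fov_mask
        assert comp.unrecoverable_mask[fov].all()
        assert np.allclose(comp.image, np.median(np.stack(clean_stack.frames), axis=0))

    def test_convexity_of_composite(self, phantom):
        stack = _stack(phantom, [(0, 0), (3, -1), (-2, 2)], noise_sd=0.02, seed=9)
        est = estimate_gaze_shifts(stack)
        layer = compute_score_layer(stack, est)
        comp = merge_burst(stack, est, layer)
        from fundusburst.utils import integer_shift

        aligned = np.stack([integer_shift(f, -dy, -dx)
                            for f, (dy, dx) in zip(stack.frames, est.shifts)])
        valid = np.stack([integer_shift(np.ones_like(f), -dy, -dx) > 0.5
                          for f, (dy, dx) in zip(stack.frames, est.shifts)])
        ok = ~comp.unrecoverable_mask & stack.fov_mask & valid.all(axis=0)
        lo = np.min(np.where(valid, aligned, np.inf), axis=0)
        hi = np.max(np.where(valid, aligned, -np.inf), axis=0)
        assert (comp.image[ok] >= lo[ok] - 1e-9).all()
        assert (comp.image[ok] <= hi[ok] + 1e-9).all()

    def test_permutation_equivariance(self, phantom):
        stack = _stack(phantom, [(0, 0), (2, 1), (-1, -2), (3, 0)],
                       noise_sd=0.02, seed=2)
        comp = burst_reduce(stack, reference_index=0)
        order = [2, 0, 3, 1]
        shuffled = BurstStack(frames=[stack.frames[i] for i in order],
                              metadata=stack.metadata,
                              truth={"shifts": [stack.truth["shifts"][i] for i in order],
                                     "artifact_masks": {}},
                              fov_mask=stack.fov_mask)
        comp2 = burst_reduce(shuffled, reference_index=order.index(0))
        assert np.allclose(comp.image, comp2.image, atol=1e-9)

    def test_complementary_artifacts_beat_every_frame_psnr(self, phantom):
        """Regions clean in different frames: fusion beats each frame."""
        stack = _stack(phantom, [(0, 0)] * 4)
        n = phantom.side
        yy, xx = np.mgrid[0:n, 0:n]
        left = (xx < n // 2) & phantom.fov_mask
        right = ~left & phantom.fov_mask
        stack.frames[0] = np.where(left, 0.0, stack.frames[0])   # left ruined in 0
        stack.frames[1] = np.where(right, 1.0, stack.frames[1])  # right ruined in 1
        comp = burst_reduce(stack, reference_index=2)
        truth = stack.frames[2]
        fov = phantom.fov_mask
        comp_psnr = masked_psnr(comp.image, truth, fov)
        for f in stack.frames[:2]:
            assert comp_psnr > masked_psnr(f, truth, fov)


class TestPipeline:
    def test_clean_twenty_frame_stack_uses_all_frames(self, phantom, still_illumination):
        cfg = BurstConfig(n_frames=20, gaze_model={"kind": "random_walk", "step_px": 1},
                          noise_sd=0.01, illumination=still_illumination, seed=4)
        comp = burst_reduce(simulate_burst(phantom, cfg))
        assert comp.n_frames_used == 20

    def test_single_frame_stack_returns_that_frame(self, phantom):
        stack = _stack(phantom, [(0, 0)])
        comp = burst_reduce(stack)
        assert np.allclose(comp.image, stack.frames[0], atol=1e-12)

    def test_black_frames_not_counted_as_used(self, phantom, still_illumination):
        cfg = BurstConfig(n_frames=30, frame_interval_ms=6.0,
                          gaze_model=[(0, 0)] * 30, noise_sd=0.0,
                          illumination=still_illumination, seed=6)
        stack = simulate_burst(phantom, cfg)
        for i in range(10):
            stack.frames[i] = np.zeros_like(stack.frames[i])
        comp = burst_reduce(stack)
        assert comp.n_frames_used <= 20

    def test_denoising_gain_over_seeded_grid(self, still_illumination):
        """Composite PSNR >= median single-frame PSNR on every grid point."""
        specs = [
            ArtifactSpec(),
            ArtifactSpec(lash_occlusion=LashSpec(count=2, thickness_px=6, opacity=0.9)),
            ArtifactSpec(saturation=SaturationSpec(spot_count=2, radius_px=12)),
        ]
        from fundusburst.burst_reduce import default_reference_index

        for seed in (0, 1):
            phantom = generate_phantom(300 + seed, side_px=128)
            core = _eroded_fov(phantom.fov_mask)
            for k, spec in enumerate(specs):
                cfg = BurstConfig(n_frames=6, noise_sd=0.03, seed=10 * seed + k,
                                  illumination=IlluminationSchedule(0.25, 3.0))
                stack = simulate_burst(phantom, cfg, spec)
                comp = burst_reduce(stack)
                truth = stack.truth["shifts"]
                ref_shift = truth[default_reference_index(stack.n_frames)]
                frame_psnrs = [_truth_psnr(f, s, phantom, core)
                               for f, s in zip(stack.frames, truth)]
                assert (_truth_psnr(comp.image, ref_shift, phantom, core)
                        >= np.median(frame_psnrs))

    def test_registration_recovery_with_noise(self):
        """>= 95% of shifts recovered exactly at noise_sd = 0.02 over 100 stacks."""
        ok = total = 0
        for s in range(100):
            phantom = generate_phantom(500 + s, side_px=128)
            cfg = BurstConfig(n_frames=4, gaze_model={"kind": "random_walk", "step_px": 2},
                              noise_sd=0.02, seed=s,
                              illumination=IlluminationSchedule(0.25, 2.0))
            stack = simulate_burst(phantom, cfg)
            est = estimate_gaze_shifts(stack, reference_index=0)
            for e, t in zip(est.shifts, stack.truth["shifts"]):
                total += 1
                ok += e == tuple(t)
        assert ok / total >= 0.95
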