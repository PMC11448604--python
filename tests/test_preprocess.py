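"""Flat-field, hot-pixel, downsampling, bleach and alignment preprocessing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from optrecon.io_stack import ProjectionStack
from optrecon.phantom import PhantomSpec, simulate_projections
from optrecon.preprocess import (
    AlignmentParams,
    BleachModel,
    apply_alignment,
    apply_bleach,
    downsample,
    estimate_alignment,
    estimate_bleach,
    flat_field_correct,
    hot_pixel_filter,
)


def _stack(frames, **kw):
    return ProjectionStack(np.asarray(frames, dtype=float), angular_range=360, **kw)


class TestFlatField:
    def test_frame_equal_background_gives_uniform_mean(self):
        rng = np.random.default_rng(0)
        bg = rng.uniform(50, 150, (8, 8))
        stack = _stack(np.stack([bg, bg]))
        out = flat_field_correct(stack, bg)
        assert np.allclose(out.frames, bg.mean())

    def test_offset_only_input_is_zeroed(self):
        off = np.full((6, 6), 10.0)
        stack = _stack(off[None])
        out = flat_field_correct(stack, np.full((6, 6), 200.0), off)
        assert np.all(out.frames == 0.0)

    def test_synthetic_vignette_removed(self):
        n = 32
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        gain = 1.0 - 0.4 * ((xx - c) ** 2 + (yy - c) ** 2) / (2 * c**2)
        scene = np.full((n, n), 7.0)
        stack = _stack((scene * gain)[None])
        out = flat_field_correct(stack, 100.0 * gain)
        flat = out.frames[0]
        assert np.ptp(flat) / flat.mean() < 1e-6

    def test_bad_background_rejected(self):
        stack = _stack(np.ones((1, 4, 4)))
        with pytest.raises(ValueError):
            flat_field_correct(stack, np.zeros((4, 4)), np.ones((4, 4)))


class TestHotPixels:
    def test_constant_frame_unchanged(self):
        stack = _stack(np.full((2, 16, 16), 5.0))
        out = hot_pixel_filter(stack)
        assert np.array_equal(out.frames, stack.frames)

    def test_single_spike_replaced(self):
        frames = np.full((1, 16, 16), 5.0)
        frames[0, 7, 9] = 500.0
        out = hot_pixel_filter(_stack(frames))
        assert out.frames[0, 7, 9] == 5.0
        assert (out.frames != frames).sum() == 1

    def test_planted_defects_in_poisson_noise(self):
        rng = np.random.default_rng(42)
        frame = rng.poisson(100.0, (128, 128)).astype(float)
        sigma = np.sqrt(100.0)
        coords = rng.choice(128 * 128, size=50, replace=False)
        ys, xs = np.unravel_index(coords, (128, 128))
        frame[ys, xs] = 100.0 + 20.0 * sigma
        out = hot_pixel_filter(_stack(frame[None]), threshold_sigmas=6.0)
        replaced = out.frames[0] != frame
        assert replaced[ys, xs].sum() >= 48
        false_pos = replaced.sum() - replaced[ys, xs].sum()
        assert false_pos < 0.001 * frame.size

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            hot_pixel_filter(_stack(np.ones((1, 8, 8))), window=4)


class TestDownsample:
    def test_factor_one_is_identity(self):
        stack = _stack(np.arange(32, dtype=float).reshape(2, 4, 4))
        out = downsample(stack, 1)
        assert np.array_equal(out.frames, stack.frames)

    def test_checkerboard_averages_to_half(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        out = downsample(_stack(board[None].astype(float)), 2)
        assert np.all(out.frames == 0.5)

    def test_pixel_size_scales(self):
        stack = _stack(np.ones((1, 8, 8)), pixel_size=2.0)
        assert downsample(stack, 4).pixel_size == pytest.approx(8.0)

    @given(st.integers(min_value=1, max_value=4))
    def test_intensity_conserved_on_cropped_region(self, factor):
        rng = np.random.default_rng(9)
        frames = rng.uniform(size=(2, 12, 12))
        out = downsample(_stack(frames), factor)
        v2 = (12 // factor) * factor
        assert np.allclose(
            out.frames.sum() * factor**2, frames[:, :v2, :v2].sum(), rtol=1e-9
        )


class TestBleach:
    def test_constant_totals_give_zero_rate(self):
        stack = _stack(np.ones((5, 8, 8)))
        model = estimate_bleach(stack)
        assert model.k == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(model.scales, 1.0)

    def test_known_decay_recovered_and_corrected(self, vessel_truth, vessel_stack_spec):
        spec = PhantomSpec(**vessel_stack_spec, bleach_rate=0.002)
        stack = simulate_projections(vessel_truth, spec)
        model = estimate_bleach(stack)
        assert model.k == pytest.approx(0.002, rel=0.05)
        corrected = apply_bleach(stack, model)
        totals = corrected.frames.sum(axis=(1, 2))
        slope, _ = np.polyfit(np.arange(len(totals)), np.log(totals), 1)
        assert abs(slope) < 1e-4
        assert np.ptp(totals) / totals.mean() < 0.01

    def test_identity_and_doubling_models(self):
        frames = np.random.default_rng(1).uniform(1, 2, (4, 6, 6))
        stack = _stack(frames)
        ident = BleachModel(k=0.0, n_projections=4)
        assert np.array_equal(apply_bleach(stack, ident).frames, frames)
        double = BleachModel(k=np.log(2.0), n_projections=4)
        out = apply_bleach(stack, double)
        assert out.frames[1].sum() == pytest.approx(2 * frames[1].sum())

    def test_too_few_projections_rejected(self):
        with pytest.raises(ValueError):
            estimate_bleach(_stack(np.ones((2, 4, 4))))


class TestAlignment:
    def test_aligned_stack_estimates_zero(self, vessel_truth, vessel_stack_spec):
        stack = simulate_projections(vessel_truth, PhantomSpec(**vessel_stack_spec))
        p = estimate_alignment(stack)
        assert abs(p.offset) < 0.1
        assert abs(p.tilt) < 0.05

    def test_known_offset_recovered(self, vessel_truth, vessel_stack_spec):
        spec = PhantomSpec(**vessel_stack_spec, misalign_offset_px=3.5)
        stack = simulate_projections(vessel_truth, spec)
        p = estimate_alignment(stack)
        assert p.offset == pytest.approx(3.5, abs=0.25)

    def test_known_tilt_recovered(self, vessel_truth, vessel_stack_spec):
        spec = PhantomSpec(**vessel_stack_spec, misalign_tilt_deg=1.0)
        stack = simulate_projections(vessel_truth, spec)
        p = estimate_alignment(stack)
        assert p.tilt == pytest.approx(1.0, abs=0.1)

    def test_180_degree_data_requires_manual_params(self):
        frames = np.random.default_rng(0).uniform(size=(8, 8, 8))
        stack = ProjectionStack(frames, angular_range=180)
        with pytest.raises(ValueError, match="360"):
            estimate_alignment(stack)

    def test_apply_identity_and_inverse(self, small_bead_stack):
        stack, *_ = small_bead_stack
        same = apply_alignment(stack, AlignmentParams(0.0, 0.0))
        assert np.array_equal(same.frames, stack.frames)
        fwd = apply_alignment(stack, AlignmentParams(3.0, 0.0))
        back = apply_alignment(fwd, AlignmentParams(-3.0, 0.0))
        span = np.ptp(stack.frames)
        interior = (slice(None), slice(None), slice(4, -4))
        rmse = np.sqrt(np.mean((back.frames[interior] - stack.frames[interior]) ** 2))
        assert rmse < 0.01 * span

    def test_estimate_after_apply_returns_negated_params(
        self, vessel_truth, vessel_stack_spec
    ):
        stack = simulate_projections(vessel_truth, PhantomSpec(**vessel_stack_spec))
        moved = apply_alignment(stack, AlignmentParams(offset=-4.0, tilt=0.0))
        p = estimate_alignment(moved)
        assert p.offset == pytest.approx(4.0, abs=0.25)

    def test_shape_and_metadata_preserved(self, small_bead_stack):
        stack, *_ = small_bead_stack
        out = apply_alignment(stack, AlignmentParams(1.5, 0.3))
        assert out.frames.shape == stack.frames.shape
        assert out.pixel_size == stack.pixel_size
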