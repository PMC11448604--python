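"""Parallel-beam forward projection and filtered back projection."""

import numpy as np
import pytest

from optrecon.io_stack import ProjectionStack
from optrecon.metrics import ssim
from optrecon.recon_parallel import FBPConfig, fbp_slice, fbp_volume, forward_project


def _centroids(sino):
    u = np.arange(sino.shape[0], dtype=float)
    return (sino * u[:, None]).sum(axis=0) / sino.sum(axis=0)


class TestForwardProject:
    def test_mass_conserved_at_every_angle(self, disc_slice):
        disc, *_ = disc_slice
        angles = np.arange(0, 360, 9.0)
        sino = forward_project(disc, angles)
        assert np.allclose(sino.sum(axis=0), disc.sum(), rtol=1e-3)

    def test_center_pixel_stays_at_rotation_center(self):
        n = 129
        img = np.zeros((n, n))
        img[64, 64] = 1.0
        sino = forward_project(img, np.arange(0, 360, 10.0))
        cent = _centroids(sino)
        assert np.all(np.abs(cent - 64.0) < 0.05)

    def test_off_axis_pixel_traces_cosine(self):
        n = 129
        img = np.zeros((n, n))
        img[64, 64 + 30] = 1.0
        angles = np.arange(0, 360, 9.0)
        cent = _centroids(forward_project(img, angles))
        pred = 64 + 30 * np.cos(np.deg2rad(angles))
        assert np.all(np.abs(cent - pred) < 0.2)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            forward_project(np.zeros((8, 10)), [0.0])

    def test_matches_skimage_radon_oracle(self):
        from skimage.transform import radon

        # smooth blob centred on skimage's rotation centre (n // 2, not the
        # geometric (n - 1) / 2) so the two conventions coincide
        n = 256
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        blob = np.exp(-((xx - 128.0) ** 2 + (yy - 128.0) ** 2) / (2 * 20.0**2))
        theta = np.arange(0, 180, 4.0)
        ours = forward_project(blob, theta, rotation_center=128.0)
        ref = radon(blob, theta=theta)
        # independent implementation: agree to a small fraction of the peak
        assert np.abs(ours - ref).max() < 0.02 * ref.max()


class TestFBPSlice:
    def test_zero_sinogram_gives_zero_slice(self):
        out = fbp_slice(np.zeros((32, 8)), FBPConfig(), angles=np.arange(0, 360, 45.0))
        assert np.all(out == 0)

    def test_disc_recovered_with_absolute_values(self, disc_slice):
        disc, inside, outside = disc_slice
        angles = np.arange(400) * 0.9
        rec = fbp_slice(forward_project(disc, angles), FBPConfig(), angles=angles)
        assert rec[inside].mean() == pytest.approx(1.0, abs=0.05)
        assert np.abs(rec[outside]).mean() < 0.02
        assert ssim(rec, disc, data_range=1.0) >= 0.90

    def test_sparse_angles_increase_error(self, disc_slice):
        disc, *_ = disc_slice
        angles400 = np.arange(400) * 0.9
        angles20 = angles400[::20]
        sino = forward_project(disc, angles400)
        r400 = fbp_slice(sino, FBPConfig(), angles=angles400)
        r20 = fbp_slice(sino[:, ::20], FBPConfig(), angles=angles20)
        rmse = lambda a: np.sqrt(np.mean((a - disc) ** 2))
        assert rmse(r20) > rmse(r400)

    def test_rmse_nonincreasing_in_projection_count(self, disc_slice):
        disc, *_ = disc_slice
        angles400 = np.arange(400) * 0.9
        sino = forward_project(disc, angles400)
        errs = []
        for p in (20, 40, 80, 200, 400):
            step = 400 // p
            rec = fbp_slice(sino[:, ::step], FBPConfig(), angles=angles400[::step])
            errs.append(np.sqrt(np.mean((rec - disc) ** 2)))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))

    def test_linearity(self):
        rng = np.random.default_rng(0)
        angles = np.arange(0, 360, 15.0)
        s1 = rng.uniform(size=(32, angles.size))
        s2 = rng.uniform(size=(32, angles.size))
        cfg = FBPConfig()
        lhs = fbp_slice(2.0 * s1 + 3.0 * s2, cfg, angles=angles)
        rhs = 2.0 * fbp_slice(s1, cfg, angles=angles) + 3.0 * fbp_slice(s2, cfg, angles=angles)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_rotation_center_equivariance(self, bead_slice):
        sl, _ = bead_slice
        angles = np.arange(0, 360, 4.5)
        delta = 3
        sino = forward_project(sl, angles)
        shifted = np.roll(sino, delta, axis=0)
        base = fbp_slice(sino, FBPConfig(), angles=angles)
        moved = fbp_slice(
            shifted,
            FBPConfig(rotation_center=(sl.shape[0] - 1) / 2.0 + delta),
            angles=angles,
        )
        span = base.max() - base.min()
        assert np.sqrt(np.mean((base - moved) ** 2)) < 0.02 * span

    def test_matches_skimage_iradon_oracle(self, disc_slice):
        from skimage.transform import iradon, radon

        disc, inside, _ = disc_slice
        theta = np.arange(0, 180, 0.9)
        ref = iradon(radon(disc, theta=theta), theta=theta, filter_name="ramp", circle=True)
        ours = fbp_slice(forward_project(disc, theta), FBPConfig(), angles=theta)
        assert np.sqrt(np.mean((ref - ours) ** 2)) < 0.01

    def test_fold360_matches_full360_on_aligned_data(self, disc_slice):
        disc, inside, _ = disc_slice
        angles = np.arange(0, 360, 1.8)
        sino = forward_project(disc, angles)
        full = fbp_slice(sino, FBPConfig(angular_usage="full360"), angles=angles)
        folded = fbp_slice(sino, FBPConfig(angular_usage="fold360to180"), angles=angles)
        span = full.max() - full.min()
        assert np.sqrt(np.mean((full - folded) ** 2)) < 0.01 * span
        assert folded[inside].mean() == pytest.approx(1.0, abs=0.05)

    def test_unequal_angle_spacing_rejected(self):
        with pytest.raises(ValueError, match="equally spaced"):
            fbp_slice(np.zeros((16, 3)), FBPConfig(), angles=np.array([0.0, 10.0, 30.0]))

    @pytest.mark.parametrize("filter_name", ["shepp-logan", "cosine", "hamming", "hann"])
    def test_apodized_filters_still_recover_disc(self, disc_slice, filter_name):
        disc, inside, _ = disc_slice
        angles = np.arange(0, 360, 1.8)
        rec = fbp_slice(
            forward_project(disc, angles), FBPConfig(filter=filter_name), angles=angles
        )
        assert rec[inside].mean() == pytest.approx(1.0, abs=0.08)


class TestFBPVolume:
    def test_chunking_is_bit_identical(self, small_bead_stack):
        stack, *_ = small_bead_stack
        cfg = FBPConfig()
        full = fbp_volume(stack, cfg)
        per_slice_bytes = 8 * (64 * 60 + 4 * 256 * 60 + 3 * 64 * 64)
        small = fbp_volume(stack, cfg, max_ram_bytes=per_slice_bytes + 1024)
        mid = fbp_volume(stack, cfg, max_ram_bytes=4 * per_slice_bytes)
        assert np.array_equal(full.voxels, small.voxels)
        assert np.array_equal(full.voxels, mid.voxels)

    def test_bead_centers_recovered_within_one_voxel(self, small_bead_stack):
        from optrecon.metrics import detect_and_fit_beads, match_beads

        stack, truth, table, spec = small_bead_stack
        vol = fbp_volume(stack, FBPConfig())
        hits = 0
        for z in np.unique(table[:, 0].astype(int)):
            rows = table[table[:, 0].astype(int) == z]
            beads = detect_and_fit_beads(vol.voxels[z], expected_sigma_px=1.5)
            hits += len(match_beads(beads, rows[:, [2, 1]], tolerance_px=1.0))
        assert hits >= 0.9 * len(table)

    def test_ram_bound_below_one_slice_rejected(self, small_bead_stack):
        stack, *_ = small_bead_stack
        with pytest.raises(MemoryError):
            fbp_volume(stack, FBPConfig(), max_ram_bytes=1024)

    def test_volume_metadata(self, small_bead_stack):
        stack, *_ = small_bead_stack
        vol = fbp_volume(stack, FBPConfig(filter="hann"))
        assert vol.voxel_size == stack.pixel_size
        assert vol.provenance["filter"] == "hann"
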