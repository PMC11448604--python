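"""Fan-beam geometry: calibration, reconstruction and origin estimation."""

import math

import numpy as np
import pytest

from optrecon.io_stack import extract_sinogram
from optrecon.metrics import detect_and_fit_beads
from optrecon.phantom import PhantomSpec, make_phantom, simulate_projections
from optrecon.recon_fanbeam import (
    FanBeamGeometry,
    calibrate_magnification,
    estimate_fan_origin,
    fan_forward_project,
    fanbeam_reconstruct,
)
from optrecon.recon_parallel import FBPConfig, fbp_slice, forward_project


@pytest.fixture(scope="module")
def fan_phantom():
    """14 mm bead phantom imaged with a 50 mm fan origin: beads on rings."""
    c = (256 - 1) / 2.0
    rings = [20, 40, 60, 80]
    pos = [[0, c, c]]
    for k, r in enumerate(rings):
        for a in np.arange(0, 360, 72.0) + 20.0 * k:
            pos.append([0, c + r * math.sin(math.radians(a)),
                        c + r * math.cos(math.radians(a))])
    spec = PhantomSpec(
        kind="beads", field_size=14.0, grid=256, n_slices=1,
        geometry="fan", fan_D_mm=50.0, n_projections=400, seed=3,
        bead_positions=np.array(pos),
    )
    truth, table = make_phantom(spec)
    stack = simulate_projections(truth, spec)
    return spec, stack, table, rings, c


def _ring_fwhm(recon, rings, c, tol=9.0):
    beads = detect_and_fit_beads(recon, expected_sigma_px=3.0)
    means = {}
    for r in rings:
        sel = [
            b.fwhm_px
            for b in beads
            if abs(math.hypot(b.center[0] - c, b.center[1] - c) - r) < tol
        ]
        means[r] = float(np.mean(sel)) if sel else float("nan")
    return means


class TestCalibration:
    def test_exact_line(self):
        z = np.linspace(-3, 3, 7)
        samples = np.column_stack([z, 100.0 + 2.0 * z])
        geom = calibrate_magnification(samples, true_size_px=100.0)
        cal = geom.calibration
        assert cal.slope == pytest.approx(2.0)
        assert cal.intercept == pytest.approx(100.0)
        assert cal.residual_rms < 1e-9
        assert geom.D == pytest.approx(50.0)  # m0 / g = 1 / 0.02

    def test_constant_size_is_telecentric(self):
        samples = [(z, 100.0) for z in np.linspace(-2, 2, 5)]
        geom = calibrate_magnification(samples)
        assert geom.telecentric
        assert geom.g == 0.0
        assert math.isinf(geom.D)

    def test_noisy_line_slope_within_5pct(self):
        rng = np.random.default_rng(12)
        z = np.linspace(-5, 5, 11)
        size = 100.0 + 2.0 * z + rng.normal(0, 0.5, z.size)
        geom = calibrate_magnification(np.column_stack([z, size]), true_size_px=100.0)
        assert geom.calibration.slope == pytest.approx(2.0, rel=0.05)

    def test_degenerate_z_rejected(self):
        with pytest.raises(ValueError):
            calibrate_magnification([(1.0, 10.0), (1.0, 12.0)])


class TestFanForward:
    def test_parallel_limit_matches_parallel_projector(self, bead_slice):
        sl, _ = bead_slice
        angles = np.arange(0, 360, 9.0)
        par = forward_project(sl, angles)
        fan = fan_forward_project(sl, angles, 1e6 * sl.shape[0])
        assert np.abs(fan - par).max() < 1e-3 * par.max()

    def test_origin_inside_field_rejected(self):
        with pytest.raises(ValueError):
            fan_forward_project(np.zeros((32, 32)), [0.0], D=10.0)


class TestFanReconstruction:
    def test_parallel_limit_matches_fbp(self, bead_slice):
        sl, _ = bead_slice
        angles = np.arange(0, 360, 1.8)
        sino = forward_project(sl, angles)
        par = fbp_slice(sino, FBPConfig(), angles=angles)
        fan = fanbeam_reconstruct(sino, 1e6 * sl.shape[0], FBPConfig(), angles=angles)
        span = par.max() - par.min()
        assert np.sqrt(np.mean((fan - par) ** 2)) < 0.01 * span

    def test_rmse_to_parallel_decreases_with_distance(self, bead_slice):
        sl, _ = bead_slice
        angles = np.arange(0, 360, 4.5)
        sino = forward_project(sl, angles)
        par = fbp_slice(sino, FBPConfig(), angles=angles)
        n = sl.shape[0]
        errs = [
            np.sqrt(np.mean((fanbeam_reconstruct(sino, d, FBPConfig(), angles=angles) - par) ** 2))
            for d in (10.0 * n, 100.0 * n, 1000.0 * n)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_telecentric_geometry_delegates_to_parallel(self, bead_slice):
        sl, _ = bead_slice
        angles = np.arange(0, 360, 9.0)
        sino = forward_project(sl, angles)
        geom = FanBeamGeometry(m0=1.0, g=0.0, D=math.inf)
        fan = fanbeam_reconstruct(sino, geom, FBPConfig(), angles=angles, pixel_size_um=50.0)
        par = fbp_slice(sino, FBPConfig(), angles=angles)
        assert np.array_equal(fan, par)

    def test_fan_data_needs_fan_reconstruction(self, fan_phantom):
        """Off-axis beads smear under a parallel assumption; the matched fan
        geometry keeps their width flat across the field (Fig 11 contrast)."""
        spec, stack, table, rings, c = fan_phantom
        sino = extract_sinogram(stack, 0)
        rec_fan = fanbeam_reconstruct(sino, spec.fan_D_px, FBPConfig())
        rec_par = fbp_slice(sino, FBPConfig())
        fwhm_fan = _ring_fwhm(rec_fan, rings, c)
        fwhm_par = _ring_fwhm(rec_par, rings, c)
        # parallel: strictly increasing with radius
        vals = [fwhm_par[r] for r in rings]
        assert all(np.isfinite(vals))
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # fan at true D: off-axis width within 25% of on-axis
        on_axis = fwhm_fan[rings[0]]
        assert fwhm_fan[rings[-1]] < 1.25 * on_axis
        # beads beyond half-field radius: >= 30% narrower with fan geometry
        assert fwhm_fan[80] <= 0.7 * fwhm_par[80]

    def test_origin_smaller_than_field_rejected(self):
        with pytest.raises(ValueError):
            fanbeam_reconstruct(
                np.zeros((64, 8)), 20.0, FBPConfig(), angles=np.arange(0, 360, 45.0)
            )


class TestOriginEstimation:
    def test_recovers_true_origin_with_unimodal_curve(self, fan_phantom):
        spec, stack, *_ = fan_phantom
        px = spec.pixel_size_um
        cand_mm = [25.0, 40.0, 50.0, 65.0, 100.0, math.inf]
        cands = [d * 1000.0 / px if math.isfinite(d) else math.inf for d in cand_mm]
        best, curve = estimate_fan_origin(stack, 0, cands, expected_sigma_px=3.0)
        assert best == pytest.approx(50.0 * 1000.0 / px)
        k = int(np.argmin(curve))
        assert all(a >= b for a, b in zip(curve[: k + 1], curve[1 : k + 1]))
        assert all(a <= b for a, b in zip(curve[k:], curve[k + 1 :]))

    def test_telecentric_data_prefers_parallel(self):
        # enough beads in the slice for a stable artifact metric
        spec = PhantomSpec(kind="beads", field_size=7.0, grid=96, n_slices=1,
                           n_beads=12, n_projections=120, seed=6)
        truth, _ = make_phantom(spec)
        stack = simulate_projections(truth, spec)
        n = 96
        cands = [2.0 * n, 8.0 * n, math.inf]
        best, curve = estimate_fan_origin(stack, 0, cands, expected_sigma_px=1.5)
        assert math.isinf(best), curve
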