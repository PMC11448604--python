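"""Quantitative evaluation of reconstructions.

Three measurement families cover the evaluation needs of the pipeline:
SSIM between reconstructions (undersampling studies are referenced to the
fully sampled FBP reconstruction), bead detection with 2-D Gaussian fitting
(sigma -> FWHM = 2 sqrt(2 ln 2) sigma, convertible to micrometres through
the voxel size), and per-region resolution maps binning bead FWHMs across
the field of view.  Volume-level bead analysis operates on a maximum
intensity projection, matching how reconstructed bead sizes are normally
quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from skimage.metrics import structural_similarity

__all__ = [
    "BeadMeasurement",
    "ssim",
    "detect_and_fit_beads",
    "match_beads",
    "resolution_map",
    "FWHM_PER_SIGMA",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class BeadMeasurement:
    """One fitted point feature: centre (x, y) px, Gaussian sigma px,
    amplitude, constant offset and RMS fit residual."""

    center: tuple[float, float]
    sigma_px: float
    amplitude: float
    offset: float
    residual: float

    @property
    def fwhm_px(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_px

    def fwhm_um(self, pixel_size_um: float) -> float:
        return self.fwhm_px * pixel_size_um


def ssim(
    image_a: np.ndarray,
    image_b: np.ndarray,
    data_range: float | None = None,
    win_size: int | None = None,
) -> float:
    """Structural similarity index with the canonical constants.

    K1 = 0.01, K2 = 0.03, Gaussian weighting with sigma = 1.5 (11 x 11
    support); symmetric in its arguments; 1.0 for identical images.
    3-D inputs (volumes) are scored as the mean over per-slice 2-D SSIMs.
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    if data_range is None:
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        data_range = hi - lo if hi > lo else 1.0
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    if a.ndim == 3:
        return float(
            np.mean([ssim(a[z], b[z], data_range, win_size) for z in range(a.shape[0])])
        )
    return float(
        structural_similarity(
            a,
            b,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=win_size,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


# ---------------------------------------------------------------------------
# bead detection and Gaussian fitting


def _gauss2d(params, xx, yy):
    x0, y0, sigma, amp, off = params
    return off + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sigma**2))


def _fit_window(img, cy, cx, half, sigma0):
    n_rows, n_cols = img.shape
    y0, y1 = max(0, cy - half), min(n_rows, cy + half + 1)
    x0, x1 = max(0, cx - half), min(n_cols, cx + half + 1)
    patch = img[y0:y1, x0:x1].astype(float)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(float)
    off0 = float(np.median(patch))
    amp0 = float(patch.max() - off0)
    p0 = [float(cx), float(cy), sigma0, max(amp0, 1e-12), off0]

    def resid(p):
        return (_gauss2d(p, xx, yy) - patch).ravel()

    lo = [x0 - 1, y0 - 1, 0.3, 0.0, -np.inf]
    hi = [x1, y1, max(4.0 * half, 1.0), np.inf, np.inf]
    try:
        sol = optimize.least_squares(resid, p0, bounds=(lo, hi), max_nfev=200)
    except ValueError:
        return None
    x_c, y_c, sigma, amp, off = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return BeadMeasurement(
        center=(float(x_c), float(y_c)),
        sigma_px=float(sigma),
        amplitude=float(amp),
        offset=float(off),
        residual=rms,
    )


def detect_and_fit_beads(
    image: np.ndarray,
    detection_threshold: float | None = None,
    threshold_sigmas: float = 8.0,
    expected_sigma_px: float = 2.0,
    min_separation_px: float | None = None,
) -> list[BeadMeasurement]:
    """Detect isolated point-like maxima and fit each with a symmetric
    2-D Gaussian plus constant offset.

    The detection threshold defaults to robust background (median) +
    ``threshold_sigmas`` x MAD-sigma.  The fit window spans about four
    expected FWHMs; overlapping detections keep only the brighter peak.
    Returns an empty list on a blank image.
    """
    img = np.asarray(image, dtype=float)
    if detection_threshold is None:
        med = float(np.median(img))
        mad = float(np.median(np.abs(img - med)))
        detection_threshold = med + threshold_sigmas * 1.4826 * max(mad, 1e-12)
    half = max(int(round(2.0 * FWHM_PER_SIGMA * expected_sigma_px)), 3)
    if min_separation_px is None:
        min_separation_px = half

    footprint = np.ones((3, 3), bool)
    local_max = (img == ndimage.maximum_filter(img, footprint=footprint)) & (
        img > detection_threshold
    )
    peaks = np.argwhere(local_max)
    if peaks.size == 0:
        return []
    # brighter-peak-wins suppression of overlapping candidates
    order = np.argsort(img[peaks[:, 0], peaks[:, 1]])[::-1]
    kept: list[np.ndarray] = []
    for idx in order:
        p = peaks[idx]
        if all(np.hypot(*(p - q)) >= min_separation_px for q in kept):
            kept.append(p)
    out = []
    for cy, cx in kept:
        m = _fit_window(img, int(cy), int(cx), half, expected_sigma_px)
        if m is not None and m.amplitude > 0 and m.sigma_px > 0:
            out.append(m)
    return out


def match_beads(
    measurements: list[BeadMeasurement],
    truth_xy: np.ndarray,
    tolerance_px: float = 1.0,
) -> list[tuple[int, BeadMeasurement]]:
    """Greedy nearest-neighbour match of detections to true (x, y) centres."""
    truth_xy = np.asarray(truth_xy, dtype=float).reshape(-1, 2)
    taken = set()
    matches = []
    for ti, (tx, ty) in enumerate(truth_xy):
        best, best_d = None, tolerance_px
        for mi, m in enumerate(measurements):
            if mi in taken:
                continue
            d = math.hypot(m.center[0] - tx, m.center[1] - ty)
            if d <= best_d:
                best, best_d = mi, d
        if best is not None:
            taken.add(best)
            matches.append((ti, measurements[best]))
    return matches


def resolution_map(
    measurements: list[BeadMeasurement],
    field_shape: tuple[int, int],
    pixel_size_um: float = 1.0,
    n_radial_bins: int = 5,
    savefig: str | None = None,
):
    """Bin bead FWHMs by radial distance from the field centre.

    Returns a dict with bin edges (px), per-bin mean and standard deviation
    of FWHM (um) and counts; optionally saves a colour-coded scatter map of
    the measurements (matplotlib, headless).
    """
    if not measurements:
        raise ValueError("no measurements to map")
    cy = (field_shape[0] - 1) / 2.0
    cx = (field_shape[1] - 1) / 2.0
    r = np.array([math.hypot(m.center[0] - cx, m.center[1] - cy) for m in measurements])
    fwhm = np.array([m.fwhm_um(pixel_size_um) for m in measurements])
    edges = np.linspace(0.0, max(r.max(), 1e-9) * (1 + 1e-9), n_radial_bins + 1)
    idx = np.clip(np.digitize(r, edges) - 1, 0, n_radial_bins - 1)
    mean = np.full(n_radial_bins, np.nan)
    std = np.full(n_radial_bins, np.nan)
    counts = np.zeros(n_radial_bins, dtype=int)
    for b in range(n_radial_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean[b] = float(fwhm[sel].mean())
            std[b] = float(fwhm[sel].std())
    result = {"bin_edges_px": edges, "mean_fwhm_um": mean, "std_fwhm_um": std, "counts": counts}
    if savefig:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        xs = [m.center[0] for m in measurements]
        ys = [m.center[1] for m in measurements]
        sc = ax.scatter(xs, ys, c=fwhm, cmap="viridis", s=18)
        fig.colorbar(sc, ax=ax, label="bead FWHM (µm)")
        ax.set_xlabel("x (px)")
        ax.set_ylabel("y (px)")
        ax.set_title("Effective resolution across the field")
        ax.set_aspect("equal")
        fig.tight_layout()
        fig.savefig(savefig, dpi=150)
        plt.close(fig)
    return result
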