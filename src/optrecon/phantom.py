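"""Ground-truthed synthetic OPT data: phantoms and a forward imaging simulator.

Every reconstruction path in this package is testable without external data:
:func:`make_phantom` builds a 3-D ground-truth volume (sub-voxel fluorescent
beads, a uniform disc, or smooth vessel-like tubes) together with an exact
bead table, and :func:`simulate_projections` images it through the same
physics the reconstructions assume — parallel or fan-beam geometry, optional
focal-sweep blur, monoexponential photobleaching, rotation-axis
misalignment, and seeded Gaussian or Poisson noise, applied in that order
(noise last, so bleach estimation sees realistic totals).

All randomness flows from the single ``seed`` in the spec; two runs with the
same spec are bit-identical.

Beads are rendered as integrated Gaussians: the nominal bead diameter sets a
physical sigma (diameter / 2.3548) which is combined in quadrature with a
band-limiting render sigma (default 0.8 px) so that sub-voxel beads remain
representable on the grid without aliasing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_stack import ProjectionStack, ReconstructionVolume
from .recon_fanbeam import fan_forward_project
from .recon_parallel import forward_project

__all__ = ["PhantomSpec", "make_phantom", "simulate_projections"]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class PhantomSpec:
    """Declarative description of a synthetic sample and its acquisition.

    field_size : physical side of the (square) field in mm.
    grid : voxels per side; slices are grid x grid, ``n_slices`` rows tall.
    kind : ``beads`` (point-like fluorophores, the focal-scan test object),
        ``disc`` (uniform cylinder, the absolute-value calibration object),
        or ``vessels`` (smooth random tubes, a vasculature-like object).
    bead_positions : explicit (z, y, x) voxel coordinates; otherwise
        ``n_beads`` seeded-random positions inside the inscribed cylinder.
    geometry : ``parallel`` or ``fan``; fan needs ``fan_D_mm``.
    noise : ``none``, ``gaussian`` (additive, ``noise_level`` = sigma as a
        fraction of the max projection value) or ``poisson``
        (``noise_level`` = expected photons at the max projection value).
    """

    kind: str = "beads"
    field_size: float = 14.0
    grid: int = 256
    n_slices: int = 1
    n_beads: int = 50
    bead_diameter_um: float = 1.0
    bead_intensity: float = 1.0
    bead_positions: np.ndarray | None = None
    bead_min_separation_px: float = 6.0
    render_sigma_px: float = 0.8
    disc_radius_frac: float = 0.25
    disc_value: float = 1.0
    n_vessels: int = 4
    vessel_radius_px: float = 2.0
    noise: str = "none"
    noise_level: float = 0.0
    bleach_rate: float = 0.0
    misalign_offset_px: float = 0.0
    misalign_tilt_deg: float = 0.0
    geometry: str = "parallel"
    fan_D_mm: float = math.inf
    n_projections: int = 400
    angular_range: float = 360.0
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("beads", "disc", "vessels"):
            raise ValueError("kind must be beads, disc or vessels")
        if self.geometry not in ("parallel", "fan"):
            raise ValueError("geometry must be parallel or fan")
        if self.noise not in ("none", "gaussian", "poisson"):
            raise ValueError("noise must be none, gaussian or poisson")
        if self.noise != "none" and self.seed is None:
            raise ValueError("a seed is mandatory when randomness is requested")

    @property
    def pixel_size_um(self) -> float:
        return self.field_size * 1000.0 / self.grid

    @property
    def fan_D_px(self) -> float:
        if math.isinf(self.fan_D_mm):
            return math.inf
        return self.fan_D_mm * 1000.0 / self.pixel_size_um

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_projections) * (self.angular_range / self.n_projections)


def _render_bead(volume: np.ndarray, z: float, y: float, x: float,
                 sigma_px: float, intensity: float) -> None:
    """Add an integrated-Gaussian bead footprint (in-plane) at (z, y, x)."""
    from scipy.special import erf

    n = volume.shape[1]
    zi = int(round(z))
    if not 0 <= zi < volume.shape[0]:
        raise ValueError("bead z outside volume")
    half = max(int(math.ceil(4 * sigma_px)) + 1, 3)
    y0, y1 = max(0, int(y) - half), min(n, int(y) + half + 1)
    x0, x1 = max(0, int(x) - half), min(n, int(x) + half + 1)
    ys = np.arange(y0, y1, dtype=float)
    xs = np.arange(x0, x1, dtype=float)
    s = sigma_px * math.sqrt(2.0)
    wy = 0.5 * (erf((ys - y + 0.5) / s) - erf((ys - y - 0.5) / s))
    wx = 0.5 * (erf((xs - x + 0.5) / s) - erf((xs - x - 0.5) / s))
    volume[zi, y0:y1, x0:x1] += intensity * np.outer(wy, wx)


def make_phantom(spec: PhantomSpec) -> tuple[ReconstructionVolume, np.ndarray]:
    """Build the ground-truth volume and its bead table.

    Returns ``(volume, bead_table)`` where the table rows are
    (z_vox, y_vox, x_vox, intensity); empty (0, 4) for disc/vessel phantoms
    or ``n_beads == 0``.
    """
    n = spec.grid
    vol = np.zeros((spec.n_slices, n, n), dtype=float)
    c = (n - 1) / 2.0
    radius = n / 2.0
    rng = np.random.default_rng(spec.seed)
    table = np.empty((0, 4))

    if spec.kind == "disc":
        yy, xx = np.mgrid[0:n, 0:n]
        disc = ((xx - c) ** 2 + (yy - c) ** 2) <= (spec.disc_radius_frac * n) ** 2
        vol[:] = spec.disc_value * disc[None]
    elif spec.kind == "vessels":
        # smooth 3-D tubes: random walks through the volume rendered with a
        # Gaussian cross-section, kept inside ~0.4 of the field radius so
        # small misalignments never clip content at the frame edge
        nz = spec.n_slices
        for _ in range(spec.n_vessels):
            npts = 40 * max(nz, 8)
            pos_zyx = np.array([
                rng.uniform(0.2 * nz, 0.8 * nz) if nz > 1 else 0.0,
                rng.uniform(c - 0.2 * n, c + 0.2 * n),
                rng.uniform(c - 0.2 * n, c + 0.2 * n),
            ])
            step = rng.standard_normal(3)
            for _ in range(npts):
                step = 0.9 * step + 0.45 * rng.standard_normal(3)
                pos_zyx = pos_zyx + step * np.array([0.25 if nz > 1 else 0.0, 0.5, 0.5])
                rr = math.hypot(pos_zyx[1] - c, pos_zyx[2] - c)
                if rr > 0.4 * n:
                    # reflect back toward the centre
                    pos_zyx[1] = c + (pos_zyx[1] - c) * 0.4 * n / rr * 0.98
                    pos_zyx[2] = c + (pos_zyx[2] - c) * 0.4 * n / rr * 0.98
                    step[1:] = -step[1:]
                zi = int(round(pos_zyx[0]))
                if 0 <= zi < nz:
                    vol[zi, int(round(pos_zyx[1])) % n, int(round(pos_zyx[2])) % n] = 1.0
        sig = spec.vessel_radius_px
        vol = ndimage.gaussian_filter(vol, (sig if nz > 1 else 0.0, sig, sig))
        if vol.max() > 0:
            vol /= vol.max()
    else:  # beads
        sigma_phys = (spec.bead_diameter_um / spec.pixel_size_um) / FWHM_PER_SIGMA
        sigma_px = math.hypot(sigma_phys, spec.render_sigma_px)
        if spec.bead_positions is not None:
            pos = np.asarray(spec.bead_positions, dtype=float)
        elif spec.n_beads > 0:
            # rejection-sample an in-plane minimum separation so beads stay
            # individually resolvable (real bead phantoms are dilute)
            placed: list[list[float]] = []
            attempts = 0
            while len(placed) < spec.n_beads and attempts < 10000 * spec.n_beads:
                attempts += 1
                r = radius * 0.85 * math.sqrt(rng.uniform())
                th = rng.uniform(0, 2 * np.pi)
                z = rng.uniform(0, spec.n_slices - 1e-9)
                y, x = c + r * math.sin(th), c + r * math.cos(th)
                if all(
                    math.hypot(y - q[1], x - q[2]) >= spec.bead_min_separation_px
                    for q in placed
                    if int(q[0]) == int(z)
                ):
                    placed.append([math.floor(z), y, x])
            if len(placed) < spec.n_beads:
                raise ValueError("could not place beads at the requested separation")
            pos = np.asarray(placed)
        else:
            pos = np.empty((0, 3))
        rows = []
        for zyx in pos:
            rr = math.hypot(zyx[1] - c, zyx[2] - c)
            if rr > radius:
                raise ValueError("bead outside the inscribed cylinder")
            _render_bead(vol, zyx[0], zyx[1], zyx[2], sigma_px, spec.bead_intensity)
            rows.append([zyx[0], zyx[1], zyx[2], spec.bead_intensity])
        table = np.asarray(rows, dtype=float).reshape(-1, 4)

    volume = ReconstructionVolume(
        vol, voxel_size=spec.pixel_size_um, provenance={"method": "phantom", "kind": spec.kind}
    )
    return volume, table


def simulate_projections(truth: ReconstructionVolume, spec: PhantomSpec) -> ProjectionStack:
    """Image a ground-truth volume into a projection stack.

    Order of effects: geometry (parallel/fan forward projection per row) ->
    optional focal blur -> bleaching exp(-k p) -> misalignment (shift +
    rotation) -> noise.  Deterministic given ``spec.seed``.
    """
    vol = np.asarray(truth.voxels, dtype=float)
    if vol.shape[1] != spec.grid or vol.shape[1] != vol.shape[2]:
        raise ValueError("truth grid inconsistent with spec")
    if spec.geometry == "fan" and spec.fan_D_px <= spec.grid / 2.0:
        raise ValueError("fan origin distance must exceed the field radius")
    angles = spec.angles
    P = spec.n_projections
    Z, n = vol.shape[0], vol.shape[1]
    frames = np.zeros((P, Z, n), dtype=float)
    for z in range(Z):
        if vol[z].any():
            if spec.geometry == "fan" and math.isfinite(spec.fan_D_px):
                sino = fan_forward_project(vol[z], angles, spec.fan_D_px)
            else:
                sino = forward_project(vol[z], angles)
            frames[:, z, :] = sino.T

    blur = spec.extras.get("focal_blur_kernel")
    if blur is not None:
        k = np.asarray(blur, dtype=float)
        k = k / k.sum()
        for p in range(P):
            frames[p] = ndimage.convolve(frames[p], k, mode="constant", cval=0.0)

    if spec.bleach_rate:
        frames *= np.exp(-spec.bleach_rate * np.arange(P))[:, None, None]

    if spec.misalign_offset_px or spec.misalign_tilt_deg:
        for p in range(P):
            f = frames[p]
            if spec.misalign_offset_px:
                f = ndimage.shift(f, (0.0, spec.misalign_offset_px), order=1,
                                  mode="constant", cval=0.0)
            if spec.misalign_tilt_deg:
                f = ndimage.rotate(f, spec.misalign_tilt_deg, reshape=False, order=1,
                                   mode="constant", cval=0.0)
            frames[p] = f

    if spec.noise != "none" and spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed + 1)
        peak = frames.max() or 1.0
        if spec.noise == "gaussian":
            frames = frames + rng.normal(0.0, spec.noise_level * peak, frames.shape)
        else:  # poisson: noise_level = photons at peak intensity
            gain = spec.noise_level / peak
            frames = rng.poisson(np.maximum(frames, 0.0) * gain).astype(float) / gain

    return ProjectionStack(
        frames,
        angular_range=spec.angular_range,
        pixel_size=spec.pixel_size_um,
    )
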