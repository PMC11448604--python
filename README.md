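# optrecon

Reconstruction toolkit for **optical projection tomography (OPT)** — the
optical analogue of X-ray CT, used for 3-D fluorescence (or absorption)
imaging of mm–cm scale biological samples such as zebrafish embryos and
cleared tissue. A rotating sample is imaged from many angles with a
wide-field camera; each detector row traces an x–θ *sinogram*, and slices
are reconstructed row by row into a volume.

`optrecon` covers the full post-acquisition path:

* **I/O** — OME-TIFF / multi-page TIFF / per-angle TIFF directories for
  stacks, OME-TIFF / TIFF / HDF5 for volumes, plus a headless sinogram
  quality check.
* **Preprocessing** — flat-field and offset correction, robust hot-pixel
  removal, mean-binning downsampling, monoexponential photobleaching
  compensation, and automatic rotation-axis alignment (offset + tilt) from
  opposed-projection mirror symmetry.
* **FBP** — filtered back projection with selectable frequency filters
  (Ram-Lak, Shepp–Logan, cosine, Hamming, Hann), absolute-intensity
  normalisation, and RAM-bounded row chunking for volumes larger than
  memory.
* **TwIST** — compressive-sensing reconstruction of *undersampled*
  sinograms by two-step iterative shrinkage/thresholding with isotropic
  total-variation regularisation, minimising ½‖y − Ax‖² + λ·TV(x) over an
  adjoint-exact projector pair.
* **Fan-beam** — reconstruction for focal-scanning (liquid-lens) data whose
  magnification varies with depth: magnification-vs-depth calibration, the
  fan-origin distance D = m0/g, flat-detector fan-beam FBP valid in the
  central plane, and empirical origin estimation by artifact minimisation.
* **PSF / deconvolution** — Gaussian-beam focal-sweep PSF model, its axial
  projection, Richardson–Lucy and Wiener pre-reconstruction deconvolution,
  and the DOF/resolution trade-off calculator for fixed-focus OPT.
* **Phantoms & metrics** — a seeded ground-truth simulator (beads, discs,
  vessel-like tubes; parallel or fan geometry; blur, bleaching,
  misalignment, noise) and quantitative evaluation (SSIM, bead detection
  with Gaussian-fit FWHM, radial resolution maps), so every reconstruction
  path is testable without any external data.

## Worked example

Simulate a sparse bead slice, reconstruct it from 40 of 400 projections
with both FBP and TwIST, and compare against the fully sampled FBP
reference:

```python
import numpy as np
from optrecon import (PhantomSpec, make_phantom, forward_project,
                      fbp_slice, FBPConfig, twist_reconstruct, TwistConfig, ssim)

spec = PhantomSpec(kind="beads", field_size=14.0, grid=128, n_slices=1,
                   n_beads=40, n_projections=400, seed=11)
truth, table = make_phantom(spec)
sino = forward_project(truth.voxels[0], spec.angles)

ref = fbp_slice(sino, FBPConfig(), angles=spec.angles)          # 400 views
sub = sino[:, ::10]                                             # keep 40 views
angles40 = spec.angles[::10]
rec_fbp = fbp_slice(sub, FBPConfig(), angles=angles40)
rec_tw = twist_reconstruct(sub, TwistConfig(), angles=angles40).image

dr = ref.max() - ref.min()
print(f"SSIM FBP@40   = {ssim(rec_fbp, ref, data_range=dr):.3f}")
print(f"SSIM TwIST@40 = {ssim(rec_tw, ref, data_range=dr):.3f}")
```

Output:

```
SSIM FBP@40   = 0.217
SSIM TwIST@40 = 0.969
```

With only a tenth of the projections, FBP is dominated by streak artifacts
(SSIM 0.22 against the fully sampled reference) while the TV-regularised
TwIST reconstruction remains essentially faithful (SSIM 0.97) — the reason
compressive sensing lets OPT acquisitions be shortened, reducing
photobleaching and phototoxicity for live samples.

The same machinery is available from the shell:

```bash
optrecon simulate spec.yaml out/          # phantom + projections + bead table
optrecon fbp out/projections.ome.tif rec.ome.tif --filter ram-lak --range 360
optrecon twist out/projections.ome.tif rec.ome.tif --subset 40
optrecon fanbeam out/projections.ome.tif rec.ome.tif --d 50 --range 360
optrecon evaluate rec.ome.tif --truth out/truth.ome.tif --report report.json
optrecon run pipeline.yaml               # multi-step YAML pipeline + manifest
```

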