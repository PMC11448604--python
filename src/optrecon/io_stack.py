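"""Projection-stack and volume I/O, sinogram extraction, headless sinogram QC.

An OPT acquisition is a set of wide-field projection images recorded while
the sample rotates through 180 or 360 degrees.  The containers here carry the
raw stack (:class:`ProjectionStack`), the single-row x-theta dataset used for
2-D reconstruction (:class:`Sinogram`), and the reconstructed volume
(:class:`ReconstructionVolume`).

Conventions
-----------
* Angles are in degrees, counter-clockwise when viewed down the rotation
  axis; the first frame defines theta = 0 and frame order defines angle
  order, theta_p = p * angular_range / P.
* The rotation axis is vertical in the frame: rows index z, columns index
  the detector coordinate u.
* Supported formats: OME-TIFF, plain multi-page TIFF, a directory of
  per-angle TIFFs (sorted by the last integer group in each filename), and
  HDF5 for volumes (dataset ``volume``, attrs ``voxel_size_um``/``method``).
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

__all__ = [
    "ProjectionStack",
    "Sinogram",
    "ReconstructionVolume",
    "QCReport",
    "read_projection_stack",
    "write_projection_stack",
    "write_volume",
    "read_volume",
    "extract_sinogram",
    "qc_check",
]


@dataclass
class ProjectionStack:
    """Ordered set of 2-D projection images plus angular/pixel metadata.

    Parameters
    ----------
    frames : ndarray, shape (P, V, U)
        Intensity frames indexed (projection, row, column), photon-count-like
        arbitrary units.
    angular_range : float
        Total angular coverage in degrees (180 or 360).
    pixel_size : float
        Pixel pitch at the sample plane, micrometres per pixel.
    exposure : float, optional
        Exposure time per frame, seconds.
    wavelength : float, optional
        Emission wavelength, nanometres.
    """

    frames: np.ndarray
    angular_range: float
    pixel_size: float = 1.0
    exposure: float | None = None
    wavelength: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (P, V, U) array")
        if self.frames.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.angular_range is None:
            raise ValueError("angular_range is required (180 or 360)")

    @property
    def n_projections(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def angles(self) -> np.ndarray:
        """Projection angles in degrees: theta_p = p * angular_range / P."""
        p = self.frames.shape[0]
        return np.arange(p) * (float(self.angular_range) / p)

    def copy_with(self, frames: np.ndarray, **meta) -> "ProjectionStack":
        """New stack with replaced frames, metadata carried over."""
        kw = dict(
            angular_range=self.angular_range,
            pixel_size=self.pixel_size,
            exposure=self.exposure,
            wavelength=self.wavelength,
        )
        kw.update(meta)
        return ProjectionStack(frames, **kw)


@dataclass
class Sinogram:
    """Single-row x-theta dataset: ``values[u, p]`` for one detector row."""

    values: np.ndarray
    angles: np.ndarray
    row_index: int = 0
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("sinogram values must be 2-D (U, P)")
        if self.values.shape[1] != self.angles.size:
            raise ValueError("sinogram column count must match angle count")

    @property
    def n_detectors(self) -> int:
        return self.values.shape[0]

    @property
    def n_projections(self) -> int:
        return self.values.shape[1]


@dataclass
class ReconstructionVolume:
    """Stack of reconstructed x-y slices indexed by z, with voxel size in um."""

    voxels: np.ndarray
    voxel_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D (z, y, x)")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


@dataclass
class QCReport:
    """Headless sinogram quality-check report.

    ``continuity`` holds, per detector row, the mean absolute column shift of
    the intensity centroid between adjacent projections: a smoothly rotating
    sample traces a continuous sinusoid in each sinogram, so large jumps flag
    skipped frames, shuffled ordering or stage slip.  The quantitative
    criteria are this package's own stand-in for an interactive checker and
    are documented as such.
    """

    frame_saturation: np.ndarray
    row_saturation: np.ndarray
    dead_rows: np.ndarray
    continuity: np.ndarray
    passed: bool
    thresholds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# reading / writing

_INT_GROUP = re.compile(r"(\d+)")


def _sort_key(path: Path) -> int:
    groups = _INT_GROUP.findall(path.stem)
    if not groups:
        raise ValueError(f"no integer index in filename {path.name!r}")
    return int(groups[-1])


def _ome_pixel_size(tf: tifffile.TiffFile) -> float | None:
    xml = tf.ome_metadata
    if not xml:
        return None
    try:
        root = ET.fromstring(xml)
    except ET.ParseError:
        return None
    for elem in root.iter():
        if elem.tag.endswith("Pixels"):
            ps = elem.get("PhysicalSizeX")
            if ps is not None:
                return float(ps)
    return None


def read_projection_stack(
    path: str | Path,
    metadata_overrides: Mapping | None = None,
) -> ProjectionStack:
    """Read a projection stack from a multi-page (OME-)TIFF or a directory.

    Directories are read as one frame per TIFF, ordered by the last integer
    group in each filename (zero-padded per-angle naming).  Pixel size is
    taken from the OME XML when present; ``angular_range`` must come from the
    OME write path of this package or from ``metadata_overrides`` — a missing
    angular range is an error, never a silent default.
    """
    path = Path(path)
    overrides = dict(metadata_overrides or {})
    meta: dict = {}

    if path.is_dir():
        files = sorted(
            [p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")],
            key=_sort_key,
        )
        if not files:
            raise ValueError(f"no TIFF files in directory {path}")
        frames = [tifffile.imread(f) for f in files]
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent frame shapes in {path}: {shapes}")
        data = np.stack(frames)
    else:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            ps = _ome_pixel_size(tf)
            if ps is not None:
                meta["pixel_size"] = ps
            desc = tf.pages[0].description
        if desc:
            try:
                stored = json.loads(desc)
                if isinstance(stored, dict):
                    meta.update(
                        {
                            k: stored[k]
                            for k in ("angular_range", "pixel_size", "exposure", "wavelength")
                            if stored.get(k) is not None
                        }
                    )
            except (json.JSONDecodeError, TypeError):
                pass
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"expected a stack of 2-D frames, got shape {data.shape}")

    meta.update({k: v for k, v in overrides.items() if v is not None})
    if "angular_range" not in meta:
        raise ValueError(
            "angular_range not found in file metadata; pass "
            "metadata_overrides={'angular_range': 180 or 360}"
        )
    return ProjectionStack(
        data,
        angular_range=float(meta["angular_range"]),
        pixel_size=float(meta.get("pixel_size", 1.0)),
        exposure=meta.get("exposure"),
        wavelength=meta.get("wavelength"),
    )


def write_projection_stack(stack: ProjectionStack, path: str | Path) -> None:
    """Write a stack as OME-TIFF (``.ome.tif(f)``) or plain multi-page TIFF.

    Plain TIFF carries the acquisition metadata as JSON in the image
    description so that read-back restores it.
    """
    path = Path(path)
    meta_json = {
        "angular_range": stack.angular_range,
        "pixel_size": stack.pixel_size,
        "exposure": stack.exposure,
        "wavelength": stack.wavelength,
    }
    if path.name.lower().endswith((".ome.tif", ".ome.tiff")):
        tifffile.imwrite(
            path,
            stack.frames,
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeX": stack.pixel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": stack.pixel_size,
                "PhysicalSizeYUnit": "µm",
                "Description": json.dumps(meta_json),
            },
        )
    else:
        tifffile.imwrite(path, stack.frames, description=json.dumps(meta_json))


def write_volume(volume: ReconstructionVolume, path: str | Path, format: str = "ome-tiff") -> None:
    """Write a reconstruction volume as OME-TIFF, multi-page TIFF or HDF5.

    Read-back (:func:`read_volume`) reproduces voxels exactly for integer
    data and to 32-bit float precision otherwise; the voxel size travels in
    the metadata of every format.
    """
    path = Path(path)
    if volume.voxels.shape[0] == 0 or volume.voxels.size == 0:
        raise ValueError("refusing to write an empty volume")
    if format == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=volume.voxels)
            ds.attrs["voxel_size_um"] = float(volume.voxel_size)
            ds.attrs["method"] = json.dumps(volume.provenance)
        return
    data = volume.voxels
    if data.dtype.kind == "f" and data.dtype.itemsize > 4:
        data = data.astype(np.float32)
    desc = json.dumps({"voxel_size_um": volume.voxel_size, "method": volume.provenance})
    if format == "ome-tiff":
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "ZYX",
                "PhysicalSizeX": volume.voxel_size,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": volume.voxel_size,
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeZ": volume.voxel_size,
                "PhysicalSizeZUnit": "µm",
                "Description": desc,
            },
        )
    elif format == "tiff-stack":
        tifffile.imwrite(path, data, description=desc)
    else:
        raise ValueError(f"unsupported format {format!r}; use ome-tiff, tiff-stack or hdf5")


def read_volume(path: str | Path, format: str | None = None) -> ReconstructionVolume:
    """Read a volume written by :func:`write_volume`."""
    path = Path(path)
    if format is None:
        format = "hdf5" if path.suffix in (".h5", ".hdf5") else "tiff"
    if format == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            ds = f["volume"]
            voxels = ds[...]
            vs = float(ds.attrs.get("voxel_size_um", 1.0))
            prov = json.loads(ds.attrs.get("method", "{}"))
        return ReconstructionVolume(voxels, voxel_size=vs, provenance=prov)
    with tifffile.TiffFile(path) as tf:
        voxels = tf.asarray()
        ps = _ome_pixel_size(tf)
        desc = tf.pages[0].description
    vs, prov = 1.0, {}
    if desc:
        try:
            stored = json.loads(desc)
            vs = float(stored.get("voxel_size_um", ps or 1.0))
            prov = stored.get("method", {})
        except (json.JSONDecodeError, TypeError, AttributeError):
            vs = ps or 1.0
    elif ps:
        vs = ps
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ReconstructionVolume(voxels, voxel_size=vs, provenance=prov)


# ---------------------------------------------------------------------------
# sinogram extraction and QC


def extract_sinogram(stack: ProjectionStack, row_index: int) -> Sinogram:
    """Extract the x-theta dataset of one detector row: values[u, p] =
    frames[p, row_index, u]."""
    P, V, U = stack.frames.shape
    if not 0 <= row_index < V:
        raise IndexError(f"row_index {row_index} out of range [0, {V})")
    values = np.ascontiguousarray(stack.frames[:, row_index, :].T)
    return Sinogram(
        values,
        angles=stack.angles,
        row_index=row_index,
        pixel_size=stack.pixel_size,
    )


def _row_centroids(sino: np.ndarray) -> np.ndarray:
    """Intensity-weighted column centroid per projection; NaN where empty."""
    u = np.arange(sino.shape[0], dtype=float)
    tot = sino.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cent = (sino * u[:, None]).sum(axis=0) / tot
    cent[tot <= 0] = np.nan
    return cent


def qc_check(
    stack: ProjectionStack,
    saturation_value: float | None = None,
    saturation_fraction_threshold: float = 0.05,
    continuity_threshold: float = 2.0,
) -> QCReport:
    """Deterministic post-acquisition quality check of a projection stack.

    Flags saturated frames/rows, dead detector rows, and sinogram
    discontinuities (mean absolute centroid shift between adjacent
    projections, per row).  Report-only: never raises on bad data.
    """
    frames = np.asarray(stack.frames, dtype=float)
    P, V, U = frames.shape
    if saturation_value is None:
        # no ADC ceiling given: skip the saturation part of the check
        frame_sat = np.zeros(P)
        row_sat = np.zeros(V)
    else:
        sat = frames >= saturation_value
        frame_sat = sat.reshape(P, -1).mean(axis=1)
        row_sat = sat.mean(axis=(0, 2))

    row_range = frames.max(axis=(0, 2)) - frames.min(axis=(0, 2))
    dead = row_range <= 1e-12 * max(1.0, float(abs(frames).max()))

    continuity = np.zeros(V)
    for v in range(V):
        cent = _row_centroids(frames[:, v, :].T)
        d = np.abs(np.diff(cent))
        continuity[v] = float(np.nanmean(d)) if np.isfinite(d).any() else 0.0

    live = ~dead
    passed = bool(
        (frame_sat <= saturation_fraction_threshold).all()
        and (row_sat <= saturation_fraction_threshold).all()
        and (continuity[live] <= continuity_threshold).all()
    )
    return QCReport(
        frame_saturation=frame_sat,
        row_saturation=row_sat,
        dead_rows=dead,
        continuity=continuity,
        passed=passed,
        thresholds={
            "saturation_value": saturation_value,
            "saturation_fraction": saturation_fraction_threshold,
            "continuity": continuity_threshold,
        },
    )
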