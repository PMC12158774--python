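"""Domain types, volume/point I/O and shared intensity primitives.

Axis order is (z, y, x) everywhere: ``shape`` triples, voxel sizes, point
coordinates and all array indexing. Voxel indices are 0-based and a point at
continuous coordinate ``i`` sits at the centre of voxel ``i``.

The intensity primitives implement the preprocessing chain used by the
detection pipelines: percentile contrast rescaling with a fixed camera-offset
floor, plane-wise contrast-limited adaptive histogram equalization (CLAHE),
and difference-of-Gaussians (DoG) background subtraction with negative values
clipped to zero.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import zarr
from scipy import ndimage
from skimage import exposure

from .errors import ConfigurationError, FormatError, GeometryError

logger = logging.getLogger(__name__)

#: Roles a channel can play in the pipeline.
ROLES = ("structural", "molecular", "prediction", "label")

#: Camera offset of the sCMOS detector, in counts.  Used as the default lower
#: contrast bound throughout detection.
CAMERA_OFFSET_COUNTS = 101.0

POINT_CSV_COLUMNS = ["id", "kind", "z", "y", "x", "source", "region_id"]


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry of a 3D imaging volume.

    Parameters
    ----------
    shape
        (planes, rows, cols) = (z, y, x) extents, each >= 1.
    voxel_size_nm
        Effective voxel size (dz, dy, dx) in nm, i.e. the imaging step
        divided by the expansion factor.
    z_step_nm_imaging
        Raw microscope z step in nm (pre-division); selects detection
        parameter presets. Optional.
    """

    shape: tuple[int, int, int]
    voxel_size_nm: tuple[float, float, float]
    z_step_nm_imaging: float | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ConfigurationError(f"shape must be a positive triple, got {self.shape}")
        if len(self.voxel_size_nm) != 3 or any(v <= 0 for v in self.voxel_size_nm):
            raise ConfigurationError(
                f"voxel sizes must be positive, got {self.voxel_size_nm}"
            )
        if self.z_step_nm_imaging is not None and self.z_step_nm_imaging <= 0:
            raise ConfigurationError("z_step_nm_imaging must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size_nm", tuple(float(v) for v in self.voxel_size_nm))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical extent (z, y, x) in µm at effective (biological) scale."""
        return tuple(s * v / 1000.0 for s, v in zip(self.shape, self.voxel_size_nm))

    @property
    def volume_um3(self) -> float:
        ez, ey, ex = self.extent_um
        return ez * ey * ex

    def contains(self, location: Sequence[float]) -> bool:
        return all(0 <= c <= s - 1 for c, s in zip(location, self.shape))

    def check_effective(self, imaging_size_nm: Sequence[float], expansion_factor: float,
                        tol_nm: float = 0.05) -> bool:
        """Check effective size = imaging size / expansion factor within tol."""
        return all(
            abs(eff - img / expansion_factor) <= tol_nm
            for eff, img in zip(self.voxel_size_nm, imaging_size_nm)
        )


@dataclass
class Volume:
    """A 3D intensity (or integer label) array bound to a voxel grid."""

    grid: VoxelGrid
    data: np.ndarray
    role: str = "structural"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.role not in ROLES:
            raise ConfigurationError(f"unknown channel role {self.role!r}; expected one of {ROLES}")
        if tuple(self.data.shape) != self.grid.shape:
            raise GeometryError(
                f"data shape {self.data.shape} does not match grid shape {self.grid.shape}"
            )
        if self.data.dtype.kind == "f" and not np.isfinite(self.data).all():
            raise FormatError("volume contains non-finite intensities")

    def astype_float(self) -> "Volume":
        """Promote integer acquisition counts to float32 (no copy if float)."""
        if self.data.dtype.kind == "f":
            return self
        return replace(self, data=self.data.astype(np.float32))


@dataclass
class PointAnnotation:
    """A pre- or postsynaptic point in continuous 0-based voxel coordinates."""

    location: tuple[float, float, float]
    kind: str
    source: str = ""
    region_id: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("pre", "post"):
            raise ConfigurationError(f"kind must be 'pre' or 'post', got {self.kind!r}")
        self.location = tuple(float(c) for c in self.location)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _grid_for(data: np.ndarray, voxel_size_nm, z_step_nm_imaging) -> VoxelGrid:
    return VoxelGrid(tuple(data.shape), tuple(voxel_size_nm), z_step_nm_imaging)


def read_volume(
    path: str | os.PathLike,
    channel_layout: Mapping[int, str],
    voxel_size_nm: Sequence[float] = (1.0, 1.0, 1.0),
    z_step_nm_imaging: float | None = None,
) -> list[Volume]:
    """Read a multi-page TIFF or a zarr store into one Volume per channel.

    ``channel_layout`` maps channel index -> role. A 3D array is a single
    channel (index 0); a 4D array is (channel, z, y, x). 16-bit integer data
    are promoted to float32 except for ``label`` channels, which stay integer.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or store: {path}")
    if path.is_dir() or path.suffix in (".zarr", ".n5"):
        try:
            arr = np.asarray(zarr.open(str(path), mode="r"))
        except Exception as exc:  # pragma: no cover - zarr error classes vary
            raise FormatError(f"cannot open array store {path}: {exc}") from exc
    else:
        try:
            arr = tifffile.imread(str(path))
        except ValueError as exc:
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[np.newaxis]
    if arr.ndim != 4:
        raise FormatError(f"expected 3D or 4D data in {path}, got shape {arr.shape}")
    volumes = []
    for idx, role in sorted(channel_layout.items()):
        if not 0 <= idx < arr.shape[0]:
            raise ConfigurationError(
                f"channel index {idx} out of range for {arr.shape[0]}-channel file {path}"
            )
        data = np.asarray(arr[idx])
        if role != "label" and data.dtype.kind in "ui":
            data = data.astype(np.float32)
        volumes.append(Volume(_grid_for(data, voxel_size_nm, z_step_nm_imaging), data, role))
    return volumes


def write_volume(path: str | os.PathLike, volume: Volume | Sequence[Volume]) -> None:
    """Write one or more same-grid volumes to TIFF (stacked on axis 0) or zarr."""
    path = Path(path)
    vols = [volume] if isinstance(volume, Volume) else list(volume)
    data = vols[0].data if len(vols) == 1 else np.stack([v.data for v in vols])
    if path.suffix in (".zarr", ".n5"):
        za = zarr.open(str(path), mode="w", shape=data.shape, dtype=data.dtype)
        za[:] = data
    else:
        tifffile.imwrite(str(path), data)


def points_to_frame(points: Sequence[PointAnnotation]) -> pd.DataFrame:
    rows = [
        {
            "id": i,
            "kind": p.kind,
            "z": p.location[0],
            "y": p.location[1],
            "x": p.location[2],
            "source": p.source,
            "region_id": -1 if p.region_id is None else int(p.region_id),
        }
        for i, p in enumerate(points)
    ]
    return pd.DataFrame(rows, columns=POINT_CSV_COLUMNS)


def frame_to_points(frame: pd.DataFrame) -> list[PointAnnotation]:
    points = []
    for _, row in frame.iterrows():
        rid = int(row.get("region_id", -1))
        points.append(
            PointAnnotation(
                (float(row["z"]), float(row["y"]), float(row["x"])),
                str(row["kind"]),
                source=str(row.get("source", "")),
                region_id=None if rid < 0 else rid,
            )
        )
    return points


def write_points_csv(path: str | os.PathLike, points: Sequence[PointAnnotation]) -> None:
    # %.17g guarantees float64 round-trips through the text format
    points_to_frame(points).to_csv(path, index=False, float_format="%.17g")


def read_points_csv(path: str | os.PathLike) -> list[PointAnnotation]:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    return frame_to_points(
        pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    )


# ---------------------------------------------------------------------------
# Intensity primitives
# ---------------------------------------------------------------------------

def rescale_intensity(
    vol: Volume,
    lo: float = CAMERA_OFFSET_COUNTS,
    hi_percentile: float = 99.5,
    lo_percentile: float | None = None,
) -> Volume:
    """Linearly map [lo, P(hi_percentile)] to [0, 1], clipping outside.

    ``lo`` is an absolute count (the camera offset) unless ``lo_percentile``
    is given, in which case the lower bound is that percentile of the data.
    A degenerate range (all values <= lower bound) yields an all-zero volume
    and a warning. Percentiles use linear interpolation over all voxels.
    """
    if not 0 < hi_percentile <= 100:
        raise ConfigurationError("hi_percentile must be in (0, 100]")
    data = vol.astype_float().data
    lo_val = float(np.percentile(data, lo_percentile)) if lo_percentile is not None else float(lo)
    hi_val = float(np.percentile(data, hi_percentile))
    if hi_val <= lo_val:
        logger.warning(
            "degenerate intensity range (lo=%g >= P%g=%g); returning zeros",
            lo_val, hi_percentile, hi_val,
        )
        return replace(vol, data=np.zeros_like(data, dtype=np.float32))
    out = (data - lo_val) / (hi_val - lo_val)
    np.clip(out, 0.0, 1.0, out=out)
    return replace(vol, data=out.astype(np.float32, copy=False))


def clahe_planewise(
    vol: Volume,
    clip_limit: float = 0.03,
    clip_range: tuple[float, float] | None = None,
    kernel_size: int | None = None,
) -> Volume:
    """Plane-wise CLAHE, output scaled by 255 and stored as uint8.

    The intensity range is first clipped to ``clip_range`` (required for raw
    acquisition counts; there is no sensible default window, so it must be
    chosen per dataset, typically between 120 and 350 counts) and normalized
    to [0, 1]. Adaptive histogram equalization is then applied independently
    to every z plane.
    """
    if clip_limit <= 0:
        raise ConfigurationError("clip_limit must be positive")
    data = vol.astype_float().data
    if clip_range is not None:
        lo, hi = map(float, clip_range)
        if hi <= lo:
            raise ConfigurationError("clip_range must be increasing")
        data = np.clip(data, lo, hi)
    else:
        lo, hi = float(data.min()), float(data.max())
    span = hi - lo
    out = np.empty(data.shape, dtype=np.uint8)
    for z in range(data.shape[0]):
        plane = data[z]
        if span == 0 or plane.max() == plane.min():
            # flat plane: equalization is the identity on a constant image
            norm = (plane - lo) / span if span else np.zeros_like(plane)
            eq = norm
        else:
            norm = (plane - lo) / span
            eq = exposure.equalize_adapthist(
                norm, clip_limit=clip_limit,
                kernel_size=kernel_size,
            )
        out[z] = np.clip(np.round(eq * 255.0), 0, 255).astype(np.uint8)
    return replace(vol, data=out)


def dog_subtract(vol: Volume, sigma_signal: float, sigma_background: float) -> Volume:
    """Difference-of-Gaussians background subtraction.

    output = G(sigma_signal) * vol - G(sigma_background) * vol, negatives set
    to zero. Sigmas are isotropic in voxel units; boundaries are reflective.
    """
    if not sigma_signal < sigma_background:
        raise ConfigurationError(
            f"sigma_signal ({sigma_signal}) must be smaller than "
            f"sigma_background ({sigma_background})"
        )
    data = vol.astype_float().data
    out = ndimage.gaussian_filter(data, sigma_signal, mode="reflect")
    out -= ndimage.gaussian_filter(data, sigma_background, mode="reflect")
    np.clip(out, 0.0, None, out=out)
    return replace(vol, data=out)
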