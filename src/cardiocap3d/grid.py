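"""3D image container with anisotropic voxel size.

All volumes in this package are stored in ``(z, y, x)`` axis order with
0-based voxel indices; world positions are in micrometres (µm) at voxel
centres, so voxel index ``(k, j, i)`` sits at ``(k*dz, j*dy, i*dx)`` µm.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelGrid", "read_channel_tiff", "write_channel_tiff"]

#: Maximum value of a 12-bit intensity channel.
BIT_MAX_12 = 4095


@dataclass
class VoxelGrid:
    """A 3D image (binary mask or intensity) with voxel size in µm.

    Parameters
    ----------
    values
        3D array, ``(z, y, x)``.  Boolean arrays are masks; numeric arrays
        are intensities and must lie within ``[0, bit_max]``.
    voxel_size_um
        ``(dz, dy, dx)`` in µm, all positive.
    channel_name
        Free-form label, e.g. ``"endothelium"``.
    bit_max
        Declared intensity ceiling for non-boolean grids (default 4095,
        the 12-bit range used for hypoxia maps).
    """

    values: np.ndarray
    voxel_size_um: tuple[float, float, float] = (2.0, 0.6, 0.6)
    channel_name: str = ""
    bit_max: int = BIT_MAX_12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError(f"all shape entries must be >= 1, got {self.values.shape}")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive reals, got {self.voxel_size_um}")
        self.voxel_size_um = vs
        if self.is_mask:
            pass  # bool arrays are {0,1} by construction
        else:
            vmin, vmax = float(self.values.min()), float(self.values.max())
            if vmin < 0 or vmax > self.bit_max:
                raise ValueError(
                    f"intensity values [{vmin}, {vmax}] outside declared range [0, {self.bit_max}]"
                )

    # -- basic properties -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_mask(self) -> bool:
        return self.values.dtype == bool

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size_um
        return dz * dy * dx

    @property
    def domain_um(self) -> tuple[float, float, float]:
        """Physical extent of the grid in µm (shape × voxel size)."""
        return tuple(n * d for n, d in zip(self.shape, self.voxel_size_um))  # type: ignore[return-value]

    def with_values(self, values: np.ndarray, channel_name: str | None = None) -> "VoxelGrid":
        """Same geometry, new voxel values."""
        return replace(
            self,
            values=values,
            channel_name=self.channel_name if channel_name is None else channel_name,
        )

    def as_mask(self, threshold: float = 0) -> "VoxelGrid":
        if self.is_mask:
            return self
        return self.with_values(self.values > threshold)

    def voxel_to_um(self, voxels: np.ndarray) -> np.ndarray:
        """Convert ``(..., 3)`` voxel indices to µm positions at voxel centres."""
        return np.asarray(voxels, dtype=float) * np.asarray(self.voxel_size_um)

    def um_to_voxel(self, points_um: np.ndarray) -> np.ndarray:
        """Convert µm positions to (float) voxel indices."""
        return np.asarray(points_um, dtype=float) / np.asarray(self.voxel_size_um)


# -- TIFF round trip -------------------------------------------------------
#
# Channels are written as one multi-page grayscale TIFF each: 8-bit {0,255}
# for masks, 16-bit for intensities.  The in-plane voxel size goes into the
# TIFF resolution tags; the z spacing has no standard baseline TIFF tag, so
# the full (dz, dy, dx) triple is mirrored in a sidecar JSON next to the file
# (and in the ImageJ-style metadata block).


def write_channel_tiff(grid: VoxelGrid, path: str | Path) -> Path:
    path = Path(path)
    dz, dy, dx = grid.voxel_size_um
    if grid.is_mask:
        data = (grid.values.astype(np.uint8)) * np.uint8(255)
    else:
        data = np.round(grid.values).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        photometric="minisblack",
        resolution=(1.0 / dx, 1.0 / dy),
        resolutionunit="MICROMETER",
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    sidecar = {
        "channel_name": grid.channel_name,
        "voxel_size_um": list(grid.voxel_size_um),
        "shape": list(grid.shape),
        "is_mask": grid.is_mask,
        "bit_max": grid.bit_max,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_channel_tiff(path: str | Path) -> VoxelGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing channel file: {path}")
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        voxel_size = tuple(meta["voxel_size_um"])
        name = meta.get("channel_name", path.stem)
        is_mask = meta.get("is_mask", False)
        bit_max = meta.get("bit_max", BIT_MAX_12)
    else:
        warnings.warn(f"no sidecar JSON for {path}; assuming default voxel size")
        voxel_size = (2.0, 0.6, 0.6)
        name, is_mask, bit_max = path.stem, data.dtype == np.uint8, BIT_MAX_12
    values = (data > 0) if is_mask else data.astype(float)
    return VoxelGrid(values, voxel_size, channel_name=name, bit_max=bit_max)
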