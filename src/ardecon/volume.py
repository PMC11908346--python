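"""Cubic density volumes, FFT conventions, masks and filters.

All Fourier-domain arrays in this package are DC-centered: for an N-cubed
grid the zero-frequency component sits at voxel (N//2, N//2, N//2), and the
spatial frequency of the voxel at integer offset ``v`` from that center is
``|v| / (N * pixel_size)`` in 1/Angstrom.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .mrc import read_mrc, write_mrc

__all__ = [
    "VoxelGrid",
    "FourierVolume",
    "MaskVolume",
    "read_map",
    "write_map",
    "fft3",
    "ifft3",
    "normalize_map",
    "lowpass_filter",
    "spherical_mask",
    "apply_mask",
    "fourier_amplitude",
    "freq_offsets",
    "radius_grid",
    "shell_index",
]


@dataclass
class VoxelGrid:
    """Real scalar field on a cubic grid with a physical pixel size (A)."""

    data: np.ndarray
    pixel_size: float
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if self.data.shape[0] < 8:
            raise ValueError(f"grid too small: N={self.data.shape[0]} < 8")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.data.copy(), self.pixel_size, self.name)


@dataclass
class FourierVolume:
    """DC-centered complex spectrum of a :class:`VoxelGrid`."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"spectrum must be cubic, got shape {self.data.shape}")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class MaskVolume:
    """Soft mask with values in [0, 1]."""

    data: np.ndarray
    edge_width: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.min() < -1e-12 or self.data.max() > 1 + 1e-12:
            raise ValueError("mask values must lie in [0, 1]")
        self.data = np.clip(self.data, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Fourier-layout helpers shared across the package

def freq_offsets(n: int) -> np.ndarray:
    """Integer voxel offsets from the DC-centered origin along one axis."""
    return np.arange(n) - n // 2


def radius_grid(n: int) -> np.ndarray:
    """Radial distance (in Fourier voxels) of every voxel from the center."""
    ax = freq_offsets(n).astype(np.float64)
    return np.sqrt(
        ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    )


def shell_index(n: int) -> np.ndarray:
    """Nearest-integer radial shell index per voxel."""
    return np.rint(radius_grid(n)).astype(np.intp)


# ---------------------------------------------------------------------------
# I/O

def read_map(path: str | os.PathLike) -> VoxelGrid:
    """Read an MRC2014 volume; raises on non-cubic data."""
    data, voxel = read_mrc(path)
    if len(set(data.shape)) != 1:
        raise ValueError(f"non-cubic volume in {path}: shape {data.shape}")
    name = os.path.basename(os.fspath(path))
    return VoxelGrid(data.astype(np.float64), voxel if voxel > 0 else 1.0, name)


def write_map(grid: VoxelGrid, path: str | os.PathLike) -> None:
    write_mrc(path, grid.data.astype(np.float32), grid.pixel_size)


# ---------------------------------------------------------------------------
# FFT with DC-centered layout

def fft3(grid: VoxelGrid) -> FourierVolume:
    """Forward FFT; output DC-centered, real-space origin at the grid center."""
    ft = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(grid.data)))
    return FourierVolume(ft, grid.pixel_size)


def ifft3(fv: FourierVolume) -> VoxelGrid:
    """Inverse of :func:`fft3`; imaginary residue is discarded."""
    vol = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(fv.data)))
    return VoxelGrid(vol.real, fv.pixel_size)


def fourier_amplitude(grid: VoxelGrid) -> VoxelGrid:
    """|FT| as a real DC-centered volume (missing-cone QC rendering)."""
    return VoxelGrid(np.abs(fft3(grid).data), grid.pixel_size, name="amplitude")


# ---------------------------------------------------------------------------
# Normalization and filtering

def normalize_map(grid: VoxelGrid) -> VoxelGrid:
    """Shift/scale to zero mean and unit standard deviation."""
    sd = grid.data.std()
    if sd == 0:
        raise ValueError("cannot normalize a constant volume (zero variance)")
    out = (grid.data - grid.data.mean()) / sd
    return VoxelGrid(out, grid.pixel_size, grid.name)


def lowpass_filter(grid: VoxelGrid, resolution: float) -> VoxelGrid:
    """Lowpass with a raised-cosine transition band of 2 Fourier voxels.

    ``resolution`` is the cutoff in Angstrom; frequencies above 1/resolution
    are removed. Requires resolution >= 2 * pixel_size (Nyquist).
    """
    if resolution < 2 * grid.pixel_size:
        raise ValueError(
            f"resolution {resolution} A is beyond Nyquist "
            f"({2 * grid.pixel_size} A at pixel size {grid.pixel_size} A)"
        )
    n = grid.n
    r = radius_grid(n)
    rc = n * grid.pixel_size / resolution  # cutoff radius in Fourier voxels
    lo, hi = rc - 1.0, rc + 1.0
    weight = np.ones_like(r)
    band = (r > lo) & (r < hi)
    weight[band] = 0.5 * (1.0 + np.cos(np.pi * (r[band] - lo) / 2.0))
    weight[r >= hi] = 0.0
    fv = fft3(grid)
    return ifft3(FourierVolume(fv.data * weight, grid.pixel_size))


# ---------------------------------------------------------------------------
# Masks

def spherical_mask(
    grid: VoxelGrid, threshold: float, edge_width: int = 20
) -> MaskVolume:
    """Soft-edged bounding sphere of the suprathreshold density.

    The sphere is centered on the bounding box of voxels above ``threshold``
    and sized to enclose all of them; a raised-cosine falloff of
    ``edge_width`` voxels is appended outside the sphere.
    """
    above = grid.data > threshold
    if not above.any():
        raise ValueError(f"no voxel above threshold {threshold}")
    coords = np.argwhere(above).astype(np.float64)
    center = (coords.min(axis=0) + coords.max(axis=0)) / 2.0
    radius = float(np.sqrt(((coords - center) ** 2).sum(axis=1)).max())
    idx = np.indices(grid.data.shape, dtype=np.float64)
    dist = np.sqrt(((idx - center[:, None, None, None]) ** 2).sum(axis=0))
    mask = np.ones_like(dist)
    if edge_width > 0:
        band = (dist > radius) & (dist < radius + edge_width)
        mask[band] = 0.5 * (1.0 + np.cos(np.pi * (dist[band] - radius) / edge_width))
        mask[dist >= radius + edge_width] = 0.0
    else:
        mask[dist > radius] = 0.0
    return MaskVolume(mask, edge_width=edge_width)


def apply_mask(grid: VoxelGrid, mask: MaskVolume) -> VoxelGrid:
    if grid.data.shape != mask.data.shape:
        raise ValueError(
            f"shape mismatch: map {grid.data.shape} vs mask {mask.data.shape}"
        )
    return VoxelGrid(grid.data * mask.data, grid.pixel_size, grid.name)
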