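"""Optical transfer function construction.

The OTF is the voxelwise product of the rendered dFSC volume and the Fourier
transform of a spherical Gaussian whose width is tied to the half-map
resolution estimate: the transfer falls to 1/e of its DC value at frequency
1/res.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .volume import FourierVolume, VoxelGrid, ifft3, radius_grid

__all__ = [
    "GaussianModel",
    "OTFVolume",
    "gaussian_sigma",
    "gaussian_attenuation",
    "gaussian_transfer",
    "build_otf",
    "psf_from_otf",
]


@dataclass
class GaussianModel:
    """Spherical real-space Gaussian parameterized by target resolution."""

    res: float  # A
    ps: float  # A / voxel
    mu: float = 0.0

    @property
    def sigma(self) -> float:
        return gaussian_sigma(self.res, self.ps)


@dataclass
class OTFVolume:
    """Real, nonnegative, centro-symmetric, DC-normalized transfer function."""

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"OTF must be cubic, got shape {self.data.shape}")

    @property
    def n(self) -> int:
        return self.data.shape[0]


def gaussian_sigma(res: float, ps: float) -> float:
    """Real-space sigma (voxels) so the transfer hits 1/e at frequency 1/res."""
    if res <= 0 or ps <= 0:
        raise ValueError(f"res and ps must be positive, got res={res}, ps={ps}")
    return res / (math.pi * math.sqrt(2.0) * ps)


def gaussian_attenuation(freq: float, res: float, ps: float) -> float:
    """Transfer value at spatial frequency ``freq`` (1/A), DC value 1."""
    sigma = gaussian_sigma(res, ps)
    k_vox = freq * ps  # cycles per voxel
    return math.exp(-2.0 * math.pi**2 * sigma**2 * k_vox**2)


def gaussian_transfer(shape: int, res: float, ps: float) -> VoxelGrid:
    """DC-centered Fourier transform of the spherical Gaussian.

    Constructed analytically in Fourier space: exp(-2 pi^2 sigma^2 |k|^2)
    with |k| in cycles/voxel, so the DC value is exactly 1.
    """
    if shape < 8:
        raise ValueError(f"grid too small: {shape}")
    sigma = gaussian_sigma(res, ps)
    if res < 2 * ps:
        warnings.warn(
            f"res={res} A is finer than Nyquist ({2 * ps} A); the 1/e point "
            "lies beyond the representable frequency range",
            stacklevel=2,
        )
    k_vox = radius_grid(shape) / shape
    data = np.exp(-2.0 * math.pi**2 * sigma**2 * k_vox**2)
    return VoxelGrid(data, ps, name="gaussian_transfer")


def build_otf(dfsc_volume: VoxelGrid, gauss: VoxelGrid) -> OTFVolume:
    """Voxelwise product of dFSC volume and Gaussian transfer, DC-normalized
    to 1, clamped to [0, 1], zeroed beyond Nyquist."""
    if dfsc_volume.data.shape != gauss.data.shape:
        raise ValueError(
            f"shape mismatch: dfsc {dfsc_volume.data.shape} vs "
            f"gaussian {gauss.data.shape}"
        )
    n = dfsc_volume.n
    prod = dfsc_volume.data * gauss.data
    dc = prod[n // 2, n // 2, n // 2]
    if dc == 0:
        raise ValueError("DC component of the OTF product is zero")
    otf = np.clip(prod / dc, 0.0, 1.0)
    otf[radius_grid(n) > n // 2] = 0.0
    return OTFVolume(otf, dfsc_volume.pixel_size)


def psf_from_otf(otf: OTFVolume) -> VoxelGrid:
    """Real-space point spread function (centered) of the OTF."""
    grid = ifft3(FourierVolume(otf.data.astype(np.complex128), otf.pixel_size))
    grid.name = "psf"
    return grid
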