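"""Synthetic phantoms, orientation tables and missing-cone degradation.

Volume-level emulation of preferred-orientation damage: a Fourier coverage
weight (typically the complement of a double cone about z) multiplies the
spectrum of a noisy phantom, producing full/half maps whose directional FSC
shows the expected anisotropy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import FourierVolume, VoxelGrid, fft3, ifft3, freq_offsets

__all__ = [
    "OrientationTable",
    "DegradedSet",
    "make_phantom",
    "sample_uniform_orientations",
    "filter_by_tilt",
    "sampling_weight_volume",
    "missing_cone_mask",
    "cone_coverage",
    "degrade",
    "read_star_orientations",
    "write_star_orientations",
]

logger = logging.getLogger(__name__)

_STAR_COLUMNS = {"rot": "_rlnAngleRot", "tilt": "_rlnAngleTilt", "psi": "_rlnAnglePsi"}


@dataclass
class OrientationTable:
    """Projection orientations as ZYZ-intrinsic Euler angles in degrees.

    ``tilt`` is the angle between the projection direction and +z; the
    direction vector of a row is Rz(rot) @ Ry(tilt) @ z_hat.
    """

    angles: pd.DataFrame  # columns rot, tilt, psi

    def __post_init__(self) -> None:
        missing = {"rot", "tilt", "psi"} - set(self.angles.columns)
        if missing:
            raise ValueError(f"orientation table missing columns {sorted(missing)}")
        tilt = self.angles["tilt"].to_numpy()
        if np.any((tilt < 0) | (tilt > 180)):
            raise ValueError("tilt angles must lie in [0, 180] degrees")

    @property
    def count(self) -> int:
        return len(self.angles)

    def directions(self) -> np.ndarray:
        """(count, 3) array of unit projection-direction vectors."""
        rot = np.radians(self.angles["rot"].to_numpy())
        tilt = np.radians(self.angles["tilt"].to_numpy())
        return np.column_stack(
            [np.cos(rot) * np.sin(tilt), np.sin(rot) * np.sin(tilt), np.cos(tilt)]
        )


@dataclass
class DegradedSet:
    truth: VoxelGrid
    full: VoxelGrid
    half1: VoxelGrid
    half2: VoxelGrid
    coverage: VoxelGrid
    noise_sigma: float
    seed: int


# ---------------------------------------------------------------------------

def make_phantom(
    shape: int = 64, pixel_size: float = 1.0, n_blobs: int = 30, seed: int = 0
) -> VoxelGrid:
    """Sum of anisotropic Gaussian blobs with random centers and widths.

    Blob widths span 1-3 voxels (secondary-structure scale); centers stay in
    the central 60% of the box so that the support is compact.
    """
    if shape < 32:
        raise ValueError(f"phantom grid must be at least 32, got {shape}")
    rng = np.random.default_rng(seed)
    data = np.zeros((shape, shape, shape))
    idx = np.indices(data.shape, dtype=np.float64)
    for _ in range(n_blobs):
        center = rng.uniform(0.2 * shape, 0.8 * shape, size=3)
        widths = rng.uniform(1.0, 3.0, size=3)
        amp = rng.uniform(0.5, 1.0)
        expo = sum(
            (idx[a] - center[a]) ** 2 / (2.0 * widths[a] ** 2) for a in range(3)
        )
        data += amp * np.exp(-np.clip(expo, 0.0, 50.0))
    return VoxelGrid(data, pixel_size, name=f"phantom(seed={seed})")


def sample_uniform_orientations(n: int, seed: int = 0) -> OrientationTable:
    """Orientations uniform on the sphere (tilt = arccos of a uniform)."""
    if n < 1:
        raise ValueError(f"need n >= 1 orientations, got {n}")
    rng = np.random.default_rng(seed)
    rot = rng.uniform(0.0, 360.0, size=n)
    psi = rng.uniform(0.0, 360.0, size=n)
    tilt = np.degrees(np.arccos(rng.uniform(-1.0, 1.0, size=n)))
    return OrientationTable(pd.DataFrame({"rot": rot, "tilt": tilt, "psi": psi}))


def filter_by_tilt(
    table: OrientationTable, keep_low: float = 60.0, keep_high: float = 120.0
) -> OrientationTable:
    """Keep rows with tilt in [0, keep_low] or [keep_high, 180], preserving
    order. Mirrors a tilt-band particle selection about the equator."""
    if not 0 < keep_low < keep_high < 180:
        raise ValueError(
            f"need 0 < keep_low < keep_high < 180, got {keep_low}, {keep_high}"
        )
    tilt = table.angles["tilt"].to_numpy()
    keep = (tilt <= keep_low) | (tilt >= keep_high)
    if not keep.any():
        logger.warning("tilt filter removed every orientation")
    return OrientationTable(table.angles.loc[keep].reset_index(drop=True))


def sampling_weight_volume(
    table: OrientationTable, shape: int, slab_halfwidth: float = 1.0
) -> VoxelGrid:
    """Fourier sampling weights from central slices.

    For each orientation the central plane perpendicular to its projection
    direction (thickness 2 * slab_halfwidth voxels) accumulates weight 1;
    the result is normalized to a maximum of 1.
    """
    if table.count < 1:
        raise ValueError("empty orientation table")
    ax = freq_offsets(shape).astype(np.float64)
    vx = np.broadcast_to(ax[None, None, :], (shape,) * 3).ravel()
    vy = np.broadcast_to(ax[None, :, None], (shape,) * 3).ravel()
    vz = np.broadcast_to(ax[:, None, None], (shape,) * 3).ravel()
    coords = np.stack([vx, vy, vz], axis=1)
    dirs = table.directions()
    weights = np.zeros(coords.shape[0])
    chunk = 64
    for start in range(0, dirs.shape[0], chunk):
        block = dirs[start : start + chunk]  # (c, 3)
        dots = np.abs(coords @ block.T)  # (n^3, c)
        weights += (dots <= slab_halfwidth).sum(axis=1)
    if weights.max() > 0:
        weights /= weights.max()
    return VoxelGrid(weights.reshape((shape,) * 3), 1.0, name="coverage")


def missing_cone_mask(
    shape: int, half_angle: float, axis: np.ndarray = (0.0, 0.0, 1.0)
) -> VoxelGrid:
    """Binary Fourier volume: 1 inside the double cone about ``axis``.

    The DC voxel is outside (information at DC is never missing).
    """
    if not 0 <= half_angle < 90:
        raise ValueError(f"half angle must be in [0, 90), got {half_angle}")
    a = np.asarray(axis, dtype=np.float64)
    a = a / np.linalg.norm(a)
    ax = freq_offsets(shape).astype(np.float64)
    vx = np.broadcast_to(ax[None, None, :], (shape,) * 3)
    vy = np.broadcast_to(ax[None, :, None], (shape,) * 3)
    vz = np.broadcast_to(ax[:, None, None], (shape,) * 3)
    dot = np.abs(vx * a[0] + vy * a[1] + vz * a[2])
    r = np.sqrt(vx**2 + vy**2 + vz**2)
    cos_lim = math.cos(math.radians(half_angle))
    inside = (r > 0) & (dot > cos_lim * r)
    return VoxelGrid(inside.astype(np.float64), 1.0, name="missing_cone")


def cone_coverage(
    shape: int, half_angle: float, axis: np.ndarray = (0.0, 0.0, 1.0)
) -> VoxelGrid:
    """Coverage weight with an empty double cone: 1 - missing_cone_mask."""
    cone = missing_cone_mask(shape, half_angle, axis)
    return VoxelGrid(1.0 - cone.data, 1.0, name="cone_coverage")


def degrade(
    truth: VoxelGrid,
    coverage: VoxelGrid,
    noise_sigma: float,
    seed: int = 0,
) -> DegradedSet:
    """Produce full/half maps by Fourier-weighting independently noised copies.

    Each half map is ifft3(fft3(truth + noise_i) * coverage) with independent
    white Gaussian noise of standard deviation ``noise_sigma * rms(truth)``;
    applying the coverage after the noise reproduces reconstructions whose
    unsampled Fourier region is empty rather than noise-filled. The full map
    is the mean of the halves.
    """
    if truth.data.shape != coverage.data.shape:
        raise ValueError(
            f"shape mismatch: truth {truth.data.shape} vs "
            f"coverage {coverage.data.shape}"
        )
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    rng1, rng2 = [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)]
    sigma = noise_sigma * float(np.sqrt((truth.data**2).mean()))
    halves = []
    for rng in (rng1, rng2):
        noisy = truth.data + (
            rng.standard_normal(truth.data.shape) * sigma if sigma > 0 else 0.0
        )
        fv = fft3(VoxelGrid(noisy, truth.pixel_size))
        half = ifft3(FourierVolume(fv.data * coverage.data, truth.pixel_size))
        halves.append(half)
    full = VoxelGrid(
        (halves[0].data + halves[1].data) / 2.0, truth.pixel_size, name="full"
    )
    halves[0].name, halves[1].name = "half1", "half2"
    return DegradedSet(
        truth=truth,
        full=full,
        half1=halves[0],
        half2=halves[1],
        coverage=coverage,
        noise_sigma=noise_sigma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# STAR-like text I/O for orientation tables

def write_star_orientations(table: OrientationTable, path) -> None:
    """Write a minimal STAR loop with _rlnAngleRot/Tilt/Psi columns."""
    with open(path, "w") as fh:
        fh.write("\ndata_particles\n\nloop_\n")
        for i, (key, col) in enumerate(_STAR_COLUMNS.items(), start=1):
            fh.write(f"{col} #{i}\n")
        for _, row in table.angles.iterrows():
            fh.write(
                f"{row['rot']:12.6f} {row['tilt']:12.6f} {row['psi']:12.6f}\n"
            )


def read_star_orientations(path) -> OrientationTable:
    """Parse the minimal STAR loop written by :func:`write_star_orientations`.

    Only the three Euler-angle columns are interpreted; extra columns are
    ignored.
    """
    columns: list[str] = []
    rows: list[list[float]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                columns = []
                continue
            if in_loop and line.startswith("_"):
                columns.append(line.split()[0])
                continue
            if in_loop:
                parts = line.split()
                if len(parts) < len(columns):
                    continue
                rows.append([float(p) for p in parts[: len(columns)]])
    name_to_idx = {c: i for i, c in enumerate(columns)}
    try:
        idx = {k: name_to_idx[v] for k, v in _STAR_COLUMNS.items()}
    except KeyError as exc:
        raise ValueError(f"missing STAR column {exc} in {path}") from exc
    arr = np.asarray(rows, dtype=np.float64)
    if arr.size == 0:
        raise ValueError(f"no orientation rows found in {path}")
    return OrientationTable(
        pd.DataFrame({k: arr[:, i] for k, i in idx.items()})
    )
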