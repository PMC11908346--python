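"""Directional Fourier shell correlation (dFSC).

Conical-shell FSC between two half-maps over a Fibonacci direction set, a
rendered 3D dFSC volume in Fourier layout, and resolution estimation from
threshold crossings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .volume import (
    FourierVolume,
    MaskVolume,
    VoxelGrid,
    apply_mask,
    fft3,
    freq_offsets,
)

__all__ = [
    "DirectionSet",
    "FSCCurve",
    "DFSCResult",
    "ConePartitionStats",
    "fibonacci_directions",
    "conical_fsc",
    "compute_dfsc",
    "render_dfsc_volume",
    "global_fsc",
    "estimate_resolution",
    "cone_partition_stats",
]

logger = logging.getLogger(__name__)

DEFAULT_N_DIRECTIONS = 500
DEFAULT_APEX_ANGLE = 40.0


@dataclass
class DirectionSet:
    """A set of unit vectors on the sphere."""

    vectors: np.ndarray  # (count, 3)

    def __post_init__(self) -> None:
        self.vectors = np.atleast_2d(np.asarray(self.vectors, dtype=np.float64))
        if self.vectors.shape[1] != 3 or self.vectors.shape[0] < 1:
            raise ValueError(f"expected (n, 3) vectors, got {self.vectors.shape}")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("direction vectors must be unit length")

    @property
    def count(self) -> int:
        return self.vectors.shape[0]


@dataclass
class FSCCurve:
    """Per-shell correlation curve; shell centers in 1/A, ascending."""

    frequencies: np.ndarray
    correlations: np.ndarray
    shell_width: float
    n_voxels: np.ndarray | None = None
    valid_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.correlations = np.asarray(self.correlations, dtype=np.float64)
        if self.frequencies.shape != self.correlations.shape:
            raise ValueError("frequencies and correlations must align")
        if self.n_voxels is not None:
            self.n_voxels = np.asarray(self.n_voxels, dtype=np.intp)
        if self.valid_mask is not None:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def valid(self) -> np.ndarray:
        """Shells that actually contained voxels with meaningful power."""
        if self.valid_mask is not None:
            return self.valid_mask
        if self.n_voxels is None:
            return np.ones_like(self.correlations, dtype=bool)
        return self.n_voxels > 0


@dataclass
class DFSCResult:
    directions: DirectionSet
    curves: list[FSCCurve]
    apex_angle: float
    volume: VoxelGrid

    def curve_matrix(self) -> np.ndarray:
        """(n_directions, n_shells) matrix of correlations."""
        return np.stack([c.correlations for c in self.curves])


@dataclass
class ConePartitionStats:
    axis: np.ndarray
    half_angle: float
    mean_curve_inside: FSCCurve
    mean_curve_outside: FSCCurve
    resolution_inside: float
    resolution_outside: float
    resolution_overall: float
    inside_indices: np.ndarray = field(default=None)  # type: ignore[assignment]
    outside_indices: np.ndarray = field(default=None)  # type: ignore[assignment]


# ---------------------------------------------------------------------------

def fibonacci_directions(n: int = DEFAULT_N_DIRECTIONS) -> DirectionSet:
    """Deterministic golden-angle spiral sampling of the unit sphere."""
    if n < 1:
        raise ValueError(f"need at least one direction, got {n}")
    i = np.arange(n, dtype=np.float64)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    vecs = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
    return DirectionSet(vecs)


def _voxel_geometry(
    n: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unit direction, shell index, radius and Friedel-pairing of each voxel.

    The DC voxel gets a zero direction vector; callers treat it as belonging
    to every cone. For even n, voxels with any offset component equal to
    -n/2 are aliased Nyquist-edge frequencies without a representable
    Friedel mate; ``paired`` is False there and they are excluded from
    shells and rendering so all outputs stay exactly centro-symmetric.
    """
    ax = freq_offsets(n).astype(np.float64)
    vx = np.broadcast_to(ax[None, None, :], (n, n, n))
    vy = np.broadcast_to(ax[None, :, None], (n, n, n))
    vz = np.broadcast_to(ax[:, None, None], (n, n, n))
    # index order is (z, y, x): first axis varies slowest
    coords = np.stack(
        [vx.ravel(), vy.ravel(), vz.ravel()], axis=1
    )  # (n^3, 3) as (x, y, z)
    r = np.linalg.norm(coords, axis=1)
    shells = np.rint(r).astype(np.intp)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(r[:, None] > 0, coords / np.maximum(r, 1e-300)[:, None], 0.0)
    if n % 2 == 0:
        paired = (coords > -(n // 2)).all(axis=1)
    else:
        paired = np.ones(coords.shape[0], dtype=bool)
    return unit, shells, r, paired


def _shell_sums(
    values: np.ndarray, shells: np.ndarray, nshell: int
) -> np.ndarray:
    return np.bincount(shells, weights=values, minlength=nshell)[:nshell]


# Shells whose per-voxel power is below this fraction of the volume's mean
# per-voxel power carry no information: their correlation is pinned to 0
# rather than computed from FFT round-trip residue (~1e-13 garbage). This is
# what makes regions destroyed by a coverage mask read as "no correlation".
POWER_FLOOR = 1e-12


def _shell_power_ok(
    p1: np.ndarray,
    p2: np.ndarray,
    counts: np.ndarray,
    mean_pw1: float,
    mean_pw2: float,
) -> np.ndarray:
    n = np.maximum(counts, 1)
    return (
        (counts > 0)
        & (p1 / n > POWER_FLOOR * mean_pw1)
        & (p2 / n > POWER_FLOOR * mean_pw2)
    )


def _fsc_from_sums(
    cross: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    power_ok: np.ndarray,
    counts: np.ndarray,
) -> np.ndarray:
    corr = np.zeros_like(cross)
    denom = np.sqrt(p1 * p2)
    good = power_ok & (denom > 0)
    corr[good] = cross[good] / denom[good]
    if np.any((counts > 0) & ~good):
        logger.warning("zero-power shells encountered; correlation set to 0")
    return np.clip(corr, -1.0, 1.0)


def conical_fsc(
    f1: FourierVolume,
    f2: FourierVolume,
    direction: np.ndarray,
    apex_angle: float = DEFAULT_APEX_ANGLE,
) -> FSCCurve:
    """FSC over voxels within a cone (full opening ``apex_angle``) about
    ``direction``; the Friedel mate of each voxel counts as inside."""
    if f1.data.shape != f2.data.shape:
        raise ValueError(
            f"shape mismatch: {f1.data.shape} vs {f2.data.shape}"
        )
    if not 0 < apex_angle <= 180:
        raise ValueError(f"apex angle must be in (0, 180], got {apex_angle}")
    n = f1.n
    d = np.asarray(direction, dtype=np.float64)
    d = d / np.linalg.norm(d)
    unit, shells, r, paired = _voxel_geometry(n)
    nshell = n // 2 + 1
    cos_lim = math.cos(math.radians(apex_angle / 2.0))
    inside = np.abs(unit @ d) >= cos_lim - 1e-12
    inside |= r == 0  # DC belongs to every cone
    inside &= (shells < nshell) & paired
    a = f1.data.ravel()[inside]
    b = f2.data.ravel()[inside]
    s = shells[inside]
    cross = _shell_sums((a * np.conj(b)).real, s, nshell)
    p1 = _shell_sums(np.abs(a) ** 2, s, nshell)
    p2 = _shell_sums(np.abs(b) ** 2, s, nshell)
    counts = np.bincount(s, minlength=nshell)[:nshell]
    power_ok = _shell_power_ok(
        p1, p2, counts,
        float((np.abs(f1.data) ** 2).mean()),
        float((np.abs(f2.data) ** 2).mean()),
    )
    corr = _fsc_from_sums(cross, p1, p2, power_ok, counts)
    freqs = np.arange(nshell) / (n * f1.pixel_size)
    return FSCCurve(freqs, corr, 1.0 / (n * f1.pixel_size), n_voxels=counts)


def global_fsc(f1: FourierVolume, f2: FourierVolume) -> FSCCurve:
    """Standard spherical-shell FSC."""
    if f1.data.shape != f2.data.shape:
        raise ValueError(
            f"shape mismatch: {f1.data.shape} vs {f2.data.shape}"
        )
    n = f1.n
    nshell = n // 2 + 1
    _, shells, _, paired = _voxel_geometry(n)
    keep = (shells < nshell) & paired
    a = f1.data.ravel()[keep]
    b = f2.data.ravel()[keep]
    s = shells[keep]
    cross = _shell_sums((a * np.conj(b)).real, s, nshell)
    p1 = _shell_sums(np.abs(a) ** 2, s, nshell)
    p2 = _shell_sums(np.abs(b) ** 2, s, nshell)
    counts = np.bincount(s, minlength=nshell)[:nshell]
    power_ok = _shell_power_ok(
        p1, p2, counts,
        float((np.abs(f1.data) ** 2).mean()),
        float((np.abs(f2.data) ** 2).mean()),
    )
    corr = _fsc_from_sums(cross, p1, p2, power_ok, counts)
    freqs = np.arange(nshell) / (n * f1.pixel_size)
    return FSCCurve(freqs, corr, 1.0 / (n * f1.pixel_size), n_voxels=counts)


def _all_conical_curves(
    f1: FourierVolume,
    f2: FourierVolume,
    directions: DirectionSet,
    apex_angle: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized conical FSC for every direction.

    Returns (curve matrix, frequencies, counts matrix).
    """
    n = f1.n
    nshell = n // 2 + 1
    unit, shells, r, paired = _voxel_geometry(n)
    keep = (shells < nshell) & paired
    unit = unit[keep]
    shells_k = shells[keep]
    r_k = r[keep]
    a = f1.data.ravel()[keep]
    b = f2.data.ravel()[keep]
    cross_v = (a * np.conj(b)).real
    p1_v = np.abs(a) ** 2
    p2_v = np.abs(b) ** 2
    cos_lim = math.cos(math.radians(apex_angle / 2.0))
    mean_pw1 = float((np.abs(f1.data) ** 2).mean())
    mean_pw2 = float((np.abs(f2.data) ** 2).mean())
    curves = np.zeros((directions.count, nshell))
    counts = np.zeros((directions.count, nshell), dtype=np.intp)
    for j, d in enumerate(directions.vectors):
        inside = np.abs(unit @ d) >= cos_lim - 1e-12
        inside |= r_k == 0
        s = shells_k[inside]
        cross = _shell_sums(cross_v[inside], s, nshell)
        p1 = _shell_sums(p1_v[inside], s, nshell)
        p2 = _shell_sums(p2_v[inside], s, nshell)
        counts[j] = np.bincount(s, minlength=nshell)[:nshell]
        power_ok = _shell_power_ok(p1, p2, counts[j], mean_pw1, mean_pw2)
        denom = np.sqrt(p1 * p2)
        good = power_ok & (denom > 0)
        curves[j, good] = np.clip(cross[good] / denom[good], -1.0, 1.0)
    freqs = np.arange(nshell) / (n * f1.pixel_size)
    return curves, freqs, counts


def render_dfsc_volume(
    curves: np.ndarray,
    directions: DirectionSet,
    shape: int,
    pixel_size: float,
    apex_angle: float = DEFAULT_APEX_ANGLE,
) -> VoxelGrid:
    """Render per-direction curves into a DC-centered 3D dFSC volume.

    Each voxel takes the weighted average, over the directions whose cones
    contain it, of that direction's curve evaluated at the voxel's shell;
    weights are the cosine of the angular distance to the cone axis. Voxels
    covered by no cone fall back to the angularly nearest direction. Values
    are clamped to [0, 1]; voxels beyond Nyquist are 0.
    """
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float64))
    if curves.shape[0] != directions.count:
        raise ValueError("one curve per direction required")
    n = shape
    nshell = n // 2 + 1
    if curves.shape[1] < nshell:
        raise ValueError(
            f"curves have {curves.shape[1]} shells; need {nshell} for N={n}"
        )
    unit, shells, r, paired = _voxel_geometry(n)
    keep = (shells < nshell) & paired
    cos_lim = math.cos(math.radians(apex_angle / 2.0))
    num = np.zeros(unit.shape[0])
    den = np.zeros(unit.shape[0])
    best_w = np.full(unit.shape[0], -1.0)
    best_val = np.zeros(unit.shape[0])
    for j, d in enumerate(directions.vectors):
        w = np.abs(unit @ d)
        vals = curves[j, np.minimum(shells, nshell - 1)]
        inside = (w >= cos_lim - 1e-12) | (r == 0)
        num[inside] += w[inside] * vals[inside]
        den[inside] += w[inside]
        better = w > best_w
        best_w[better] = w[better]
        best_val[better] = vals[better]
    out = np.where(den > 0, num / np.maximum(den, 1e-300), best_val)
    out = np.clip(out, 0.0, 1.0)
    out[~keep] = 0.0
    return VoxelGrid(out.reshape(n, n, n), pixel_size, name="dfsc")


def compute_dfsc(
    half1: VoxelGrid,
    half2: VoxelGrid,
    mask: MaskVolume | None = None,
    n_dirs: int = DEFAULT_N_DIRECTIONS,
    apex_angle: float = DEFAULT_APEX_ANGLE,
) -> DFSCResult:
    """Directional FSC between two half-maps.

    If ``mask`` is given it is applied to both halves before transforming.
    """
    if half1.data.shape != half2.data.shape:
        raise ValueError(
            f"half-map shape mismatch: {half1.data.shape} vs {half2.data.shape}"
        )
    if half1.pixel_size != half2.pixel_size:
        raise ValueError(
            f"pixel size mismatch: {half1.pixel_size} vs {half2.pixel_size}"
        )
    if mask is not None:
        half1 = apply_mask(half1, mask)
        half2 = apply_mask(half2, mask)
    f1, f2 = fft3(half1), fft3(half2)
    directions = fibonacci_directions(n_dirs)
    curve_mat, freqs, counts = _all_conical_curves(f1, f2, directions, apex_angle)
    shell_width = 1.0 / (half1.n * half1.pixel_size)
    curves = [
        FSCCurve(freqs, curve_mat[j], shell_width, n_voxels=counts[j])
        for j in range(directions.count)
    ]
    volume = render_dfsc_volume(
        curve_mat, directions, half1.n, half1.pixel_size, apex_angle
    )
    return DFSCResult(directions, curves, apex_angle, volume)


# ---------------------------------------------------------------------------

def estimate_resolution(curve: FSCCurve, threshold: float = 0.143) -> float:
    """Resolution (A) at the first downward threshold crossing.

    Linear interpolation between shell centers; a curve that never crosses
    reports the Nyquist resolution, a curve already below threshold at the
    first finite-frequency shell reports the coarsest shell's resolution.
    """
    if not 0 < threshold < 1:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    freqs = curve.frequencies
    corr = curve.correlations
    if freqs.size == 0:
        raise ValueError("empty FSC curve")
    pos = (freqs > 0) & curve.valid  # skip empty (flagged) shells
    if not pos.any():
        raise ValueError("curve has no finite-frequency shells")
    f = freqs[pos]
    c = corr[pos]
    if c[0] < threshold:
        logger.warning(
            "FSC already below threshold %.3f at the coarsest shell", threshold
        )
        return 1.0 / f[0]
    for i in range(1, len(c)):
        if c[i] < threshold:
            f_cross = f[i - 1] + (f[i] - f[i - 1]) * (threshold - c[i - 1]) / (
                c[i] - c[i - 1]
            )
            return 1.0 / f_cross
    return 1.0 / f[-1]  # never crossed: Nyquist


def cone_partition_stats(
    dfsc: DFSCResult,
    axis: np.ndarray,
    half_angle: float,
    threshold: float = 0.5,
) -> ConePartitionStats:
    """Mean dFSC curves and resolutions inside/outside a double cone."""
    if not 0 < half_angle < 90:
        raise ValueError(f"half angle must be in (0, 90), got {half_angle}")
    axis = np.asarray(axis, dtype=np.float64)
    axis = axis / np.linalg.norm(axis)
    cosang = np.abs(dfsc.directions.vectors @ axis)
    inside = cosang >= math.cos(math.radians(half_angle))
    if not inside.any():
        raise ValueError("no sampling direction inside the cone")
    if inside.all():
        raise ValueError("no sampling direction outside the cone")
    mat = dfsc.curve_matrix()
    freqs = dfsc.curves[0].frequencies
    width = dfsc.curves[0].shell_width
    valid = np.stack([c.valid for c in dfsc.curves])

    def _mean_curve(sel: np.ndarray) -> FSCCurve:
        # average each shell over the directions whose cone populated it
        have = valid[sel]
        den = have.sum(axis=0)
        corr = np.where(
            den > 0, (mat[sel] * have).sum(axis=0) / np.maximum(den, 1), 0.0
        )
        return FSCCurve(freqs, corr, width, valid_mask=den > 0)

    curve_in = _mean_curve(inside)
    curve_out = _mean_curve(~inside)
    curve_all = FSCCurve(freqs, mat.mean(axis=0), width)
    return ConePartitionStats(
        axis=axis,
        half_angle=half_angle,
        mean_curve_inside=curve_in,
        mean_curve_outside=curve_out,
        resolution_inside=estimate_resolution(curve_in, threshold),
        resolution_outside=estimate_resolution(curve_out, threshold),
        resolution_overall=estimate_resolution(curve_all, threshold),
        inside_indices=np.flatnonzero(inside),
        outside_indices=np.flatnonzero(~inside),
    )
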