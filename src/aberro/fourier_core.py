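"""Central-slice projection, slice insertion, reconstruction and FSC.

The projection theorem links a particle image to the 3D reference: the 2D
Fourier transform of a projection is a central section through the 3D
transform, rotated by the particle's viewing direction.  Reconstruction
inverts this by spreading each image's Fourier pixels back onto a 3D
accumulator grid and dividing by the accumulated weights.

Geometry: Euler angles (rot, tilt, psi) in degrees, ZYZ convention.  The
matrix A = Rz(psi)·Ry(tilt)·Rz(rot) maps reference-frame coordinates to
projection-frame coordinates; a 2D slice point (kx, ky, 0) in the
projection frame sits at Aᵀ·(kx, ky, 0) in the reference frame.  In-plane
shifts are applied as Fourier phase ramps (a particle displaced by +s in
real space carries the factor e^{-2πi k·s}).

Interpolation is trilinear for both slice extraction and insertion, with
no gridding-kernel correction beyond the weights division; the reference
transform is oversampled (zero-padded, factor 2 by default) to keep the
interpolation error small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import FourierGrid, VolumeGrid, fft_centered, freq_axis, ifft_centered, shell_radius_grid

__all__ = [
    "Orientation",
    "rotation_matrix",
    "volume_to_fourier",
    "project_volume",
    "ReconstructionAccumulator",
    "insert_slice",
    "finalize",
    "fsc",
    "ResolutionResult",
    "resolution_at",
]


@dataclass
class Orientation:
    """Euler angles (degrees, ZYZ) and in-plane shifts (Å) of one particle."""

    rot: float = 0.0
    tilt: float = 0.0
    psi: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rot", "tilt", "psi", "shift_x", "shift_y"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_matrix(ori: Orientation) -> np.ndarray:
    """A = Rz(psi)·Ry(tilt)·Rz(rot): reference frame → projection frame."""
    return _rz(np.radians(ori.psi)) @ _ry(np.radians(ori.tilt)) @ _rz(np.radians(ori.rot))


def volume_to_fourier(volume: VolumeGrid, pad_factor: int = 2) -> FourierGrid:
    """Oversampled centred Fourier transform of a cubic real volume.

    The volume is zero-padded symmetrically by ``pad_factor`` before the
    transform so that trilinear slice interpolation stays accurate.
    """
    if not volume.is_cubic:
        raise ValueError(f"reference volume must be cubic, got {volume.shape}")
    n = volume.shape[0]
    if pad_factor < 1:
        raise ValueError(f"pad_factor must be >= 1, got {pad_factor}")
    big = int(round(n * pad_factor))
    padded = np.zeros((big,) * 3, dtype=volume.data.dtype)
    lo = big // 2 - n // 2
    padded[lo:lo + n, lo:lo + n, lo:lo + n] = volume.data
    return FourierGrid(fft_centered(padded), volume.pixel_size)


def _slice_points(box: int, n3: int, pixel_size: float, ori: Orientation, z_offsets):
    """Reference-frame 3D grid coordinates of each 2D slice pixel.

    Returns an array of shape (box, box, 3) in (x, y, z) grid units of the
    oversampled 3D transform; ``z_offsets`` (Å⁻¹, per-pixel, signed) add a
    displacement along the beam axis before rotation.
    """
    scale = n3 / box
    u = np.arange(box) - box // 2
    uy, ux = np.meshgrid(u.astype(float), u.astype(float), indexing="ij")
    if z_offsets is None:
        uz = np.zeros_like(ux)
    else:
        uz = np.asarray(z_offsets, dtype=float) * (n3 * pixel_size)
    pts = np.stack([ux * scale, uy * scale, uz], axis=-1)  # (box, box, 3)
    rot = rotation_matrix(ori)
    return pts @ rot  # == (Aᵀ @ p) per pixel


def _shift_ramp(box: int, pixel_size: float, shift_x: float, shift_y: float) -> np.ndarray:
    k = freq_axis(box, pixel_size)
    ky, kx = np.meshgrid(k, k, indexing="ij")
    return np.exp(-2j * np.pi * (kx * shift_x + ky * shift_y))


def project_volume(volume_ft: FourierGrid, ori: Orientation, box: int,
                   z_offsets=None) -> FourierGrid:
    """Extract a (possibly curved) slice through an oversampled 3D transform.

    With ``z_offsets=None`` this is the central-section projection of the
    reference: the 2D transform of the particle viewed at ``ori``, shifted
    by the orientation's in-plane shifts.  ``z_offsets`` (per-pixel, Å⁻¹,
    signed) sample off the central section, as needed for an Ewald-sphere
    forward model.
    """
    vals = volume_ft.values
    if vals.ndim != 3 or len(set(vals.shape)) != 1:
        raise ValueError(f"volume transform must be cubic 3D, got {vals.shape}")
    n3 = vals.shape[0]
    pts = _slice_points(box, n3, volume_ft.pixel_size, ori, z_offsets)
    out = _trilinear_gather(vals, pts)
    out *= _shift_ramp(box, volume_ft.pixel_size, ori.shift_x, ori.shift_y)
    return FourierGrid(out, volume_ft.pixel_size)


def _trilinear_gather(grid: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Trilinearly interpolate ``grid`` at (x, y, z) grid-unit points."""
    n3 = grid.shape[0]
    ctr = n3 // 2
    coords = pts + ctr  # array-index space, (…, 3) as (x, y, z)
    f = np.floor(coords).astype(np.int64)
    t = coords - f
    out = np.zeros(pts.shape[:-1], dtype=np.complex128)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix = f[..., 0] + dx
                iy = f[..., 1] + dy
                iz = f[..., 2] + dz
                w = (np.where(dx, t[..., 0], 1 - t[..., 0])
                     * np.where(dy, t[..., 1], 1 - t[..., 1])
                     * np.where(dz, t[..., 2], 1 - t[..., 2]))
                ok = ((ix >= 0) & (ix < n3) & (iy >= 0) & (iy < n3)
                      & (iz >= 0) & (iz < n3))
                vals = np.zeros_like(out)
                vals[ok] = grid[iz[ok], iy[ok], ix[ok]]
                out += w * vals
    return out


class ReconstructionAccumulator:
    """CTF-weighted Fourier sums and accumulated squared weights.

    ``data`` collects weight·value contributions, ``weights`` collects
    weight² contributions, both spread trilinearly onto an oversampled
    (``pad_factor``) 3D grid.  ``finalize`` divides, inverse-transforms
    and crops back to the requested box.
    """

    def __init__(self, box: int, pixel_size: float, pad_factor: int = 2):
        if box < 2:
            raise ValueError(f"box must be >= 2, got {box}")
        if pad_factor < 1:
            raise ValueError(f"pad_factor must be >= 1, got {pad_factor}")
        self.box = int(box)
        self.pixel_size = float(pixel_size)
        self.pad_factor = pad_factor
        n3 = int(round(box * pad_factor))
        self.data = np.zeros((n3,) * 3, dtype=np.complex128)
        self.weights = np.zeros((n3,) * 3, dtype=np.float64)
        self.n_inserted = 0


def insert_slice(acc: ReconstructionAccumulator, slice_ft, ori: Orientation,
                 weight_grid, z_offsets=None) -> ReconstructionAccumulator:
    """Spread one 2D transform into the 3D accumulator.

    Each 2D frequency lands at its rotated 3D position, displaced by the
    per-pixel ``z_offsets`` (Å⁻¹, signed) along the beam axis before
    rotation; ``data`` gains weight·value and ``weights`` gains weight²,
    both via trilinear spreading.  ``z_offsets=None`` is the ordinary
    central-section (flat Ewald sphere) case.
    """
    vals = slice_ft.values if isinstance(slice_ft, FourierGrid) else np.asarray(slice_ft)
    w = np.asarray(weight_grid, dtype=float)
    if vals.shape != (acc.box, acc.box) or w.shape != vals.shape:
        raise ValueError(
            f"slice/weight shape {vals.shape}/{w.shape} does not match box {acc.box}"
        )
    if np.any(w < 0):
        raise ValueError("weight_grid must be non-negative")
    # undo the particle's in-plane shift before inserting
    vals = vals * np.conj(_shift_ramp(acc.box, acc.pixel_size, ori.shift_x, ori.shift_y))
    n3 = acc.data.shape[0]
    pts = _slice_points(acc.box, n3, acc.pixel_size, ori, z_offsets)
    _trilinear_scatter(acc.data, acc.weights, pts, w * vals, w * w)
    acc.n_inserted += 1
    return acc


def _trilinear_scatter(data, weights, pts, values, wsq) -> None:
    n3 = data.shape[0]
    ctr = n3 // 2
    coords = (pts + ctr).reshape(-1, 3)
    vals = values.ravel()
    wts = wsq.ravel()
    f = np.floor(coords).astype(np.int64)
    t = coords - f
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                ix = f[:, 0] + dx
                iy = f[:, 1] + dy
                iz = f[:, 2] + dz
                w = (np.where(dx, t[:, 0], 1 - t[:, 0])
                     * np.where(dy, t[:, 1], 1 - t[:, 1])
                     * np.where(dz, t[:, 2], 1 - t[:, 2]))
                ok = ((ix >= 0) & (ix < n3) & (iy >= 0) & (iy < n3)
                      & (iz >= 0) & (iz < n3))
                idx = (iz[ok], iy[ok], ix[ok])
                np.add.at(data, idx, w[ok] * vals[ok])
                np.add.at(weights, idx, w[ok] * wts[ok])


def finalize(acc: ReconstructionAccumulator, eps_rel: float = 1e-3) -> VolumeGrid:
    """Divide data by weights, inverse-transform and crop to the box.

    The division is regularised as data / max(weights, ε) with
    ε = ``eps_rel`` × mean positive weight, which bounds the output where
    the accumulator was barely touched.  The imaginary residue left by
    interpolation is discarded (real part taken).
    """
    if acc.n_inserted == 0 or not np.any(acc.weights > 0):
        raise ValueError("empty accumulator: insert at least one slice before finalize")
    eps = eps_rel * acc.weights[acc.weights > 0].mean()
    vol_ft = acc.data / np.maximum(acc.weights, eps)
    real = ifft_centered(vol_ft).real
    n3 = real.shape[0]
    lo = n3 // 2 - acc.box // 2
    crop = real[lo:lo + acc.box, lo:lo + acc.box, lo:lo + acc.box]
    return VolumeGrid(np.ascontiguousarray(crop), acc.pixel_size)


# ---------------------------------------------------------------------------
# Fourier shell correlation and resolution
# ---------------------------------------------------------------------------


def fsc(map_a: VolumeGrid, map_b: VolumeGrid) -> pd.DataFrame:
    """Fourier shell correlation between two maps of equal geometry.

    Shell ``s`` covers radii [s, s+1) in grid units; the returned table
    has columns ``shell``, ``freq`` (Å⁻¹), ``n_voxels`` and ``fsc``.
    """
    if map_a.shape != map_b.shape:
        raise ValueError(f"map dims differ: {map_a.shape} vs {map_b.shape}")
    if not np.isclose(map_a.pixel_size, map_b.pixel_size):
        raise ValueError("map pixel sizes differ")
    fa = fft_centered(map_a.data)
    fb = fft_centered(map_b.data)
    radius = shell_radius_grid(fa.shape)
    shells = np.floor(radius).astype(int)
    n = map_a.shape[0]
    smax = n // 2
    keep = shells <= smax
    shells_f = shells[keep].ravel()
    a = fa[keep].ravel()
    b = fb[keep].ravel()
    cross = np.bincount(shells_f, weights=(a * np.conj(b)).real, minlength=smax + 1)
    pa = np.bincount(shells_f, weights=np.abs(a) ** 2, minlength=smax + 1)
    pb = np.bincount(shells_f, weights=np.abs(b) ** 2, minlength=smax + 1)
    counts = np.bincount(shells_f, minlength=smax + 1)
    denom = np.sqrt(pa * pb)
    vals = np.divide(cross, denom, out=np.zeros_like(cross), where=denom > 0)
    s = np.arange(smax + 1)
    return pd.DataFrame({
        "shell": s,
        "freq": s / (n * map_a.pixel_size),
        "n_voxels": counts[: smax + 1],
        "fsc": vals[: smax + 1],
    })


@dataclass
class ResolutionResult:
    resolution: float  # Å
    nyquist_limited: bool

    def __float__(self) -> float:
        return self.resolution


def resolution_at(fsc_table: pd.DataFrame, threshold: float = 0.143) -> ResolutionResult:
    """Resolution (Å) at the first FSC crossing below ``threshold``.

    The crossing frequency is linearly interpolated between the last shell
    above and the first shell below the threshold.  If the FSC never drops
    below the threshold the Nyquist resolution is returned with the
    ``nyquist_limited`` flag set.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    curve = fsc_table[fsc_table["n_voxels"] > 0].reset_index(drop=True)
    freqs = curve["freq"].to_numpy()
    vals = curve["fsc"].to_numpy()
    below = np.nonzero(vals < threshold)[0]
    below = below[below > 0]  # ignore a pathological DC shell
    if len(below) == 0:
        nyq_freq = fsc_table["freq"].iloc[-1]
        return ResolutionResult(1.0 / nyq_freq, True)
    i = below[0]
    f_lo, f_hi = freqs[i - 1], freqs[i]
    v_lo, v_hi = vals[i - 1], vals[i]
    if v_lo == v_hi:
        f_cross = f_hi
    else:
        f_cross = f_lo + (v_lo - threshold) / (v_lo - v_hi) * (f_hi - f_lo)
    return ResolutionResult(1.0 / f_cross, False)
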