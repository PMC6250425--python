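"""Single-side-band Ewald sphere correction during reconstruction.

At high resolution, or for large particles, the flat central-section
approximation breaks down: the scattered wave samples the 3D transform on
a curved (Ewald) surface.  The single-side-band algorithm models this by
splitting each particle transform into two side-bands, multiplied by the
unit-modulus CTFs

    CTF_P = e^{+i(ψ+π/2)},   CTF_Q = e^{-i(ψ+π/2)}

(ψ the lens phase, π/2 the phase shift upon scattering), and inserting
them off the central section at the per-frequency displacement

    Δz* = (λ/2)·|k|²   (Å⁻¹, along the beam axis).

The multiplication is done in sectors by rotating the dividing line
through the origin and assembling, per pixel, the rotation whose edge is
farthest from that pixel — this keeps the P/Q discontinuity away from the
pixels that matter.  Each assembled side-band is back-transformed, softly
masked in real space to remove noise around the particle, and transformed
back before insertion.

Because mirroring operations during acquisition/processing make the true
curvature direction unknowable a priori, the reconstruction can be run
with either direction (``curvature="normal" | "reverse"``); if curvature
limits resolution, the correct direction yields the better map.  The
frequency where curvature becomes limiting for a particle of diameter d
is k* = sqrt(1.4/(d·λ)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import particles as pt
from .ctf import CtfParams, lens_phase, ssb_ctfs
from .fourier_core import ReconstructionAccumulator, finalize, insert_slice
from .grids import FourierGrid, VolumeGrid, fft_centered, freq_grids_2d, ifft_centered

__all__ = ["SidebandPair", "delta_z", "ewald_limit", "split_sideband", "reconstruct"]


@dataclass
class SidebandPair:
    """The two side-band transforms of one particle plus the sector map.

    ``side`` is +1 where the chosen sector rotation put the pixel on the
    CTF_P half of ``p_ft`` (and the CTF_Q half of ``q_ft``), -1 on the
    other half.  Before masking, |p_ft| = |q_ft| = |input| elementwise.
    """

    p_ft: FourierGrid
    q_ft: FourierGrid
    side: np.ndarray
    n_sectors: int
    curvature: int = +1


def delta_z(k_mag, lam: float):
    """Off-central-section displacement Δz* = (λ/2)·|k|² (Å⁻¹)."""
    k_mag = np.asarray(k_mag, dtype=float)
    return 0.5 * lam * k_mag**2


def ewald_limit(diameter: float, lam: float) -> float:
    """Resolution (Å) where Ewald curvature becomes limiting for a
    particle of the given diameter (Å): 1/k* with k* = sqrt(1.4/(d·λ))."""
    if not (diameter > 0 and lam > 0):
        raise ValueError(f"diameter and wavelength must be > 0, got ({diameter}, {lam})")
    k_star = np.sqrt(1.4 / (diameter * lam))
    return float(1.0 / k_star)


def _sector_sides(shape: tuple, n_sectors: int) -> np.ndarray:
    """Per-pixel ±1 side map using the sector rotation farthest from each
    pixel; dividing lines at angles jπ/n, ties broken toward j = 0."""
    ny, nx = shape
    y = np.arange(ny) - ny // 2
    x = np.arange(nx) - nx // 2
    yy, xx = np.meshgrid(y.astype(float), x.astype(float), indexing="ij")
    theta = np.arctan2(yy, xx)
    alphas = np.pi * np.arange(n_sectors) / n_sectors
    t = np.mod(theta[None] - alphas[:, None, None], np.pi)
    dist = np.minimum(t, np.pi - t)
    j_best = np.argmax(dist, axis=0)  # first max → ties toward j = 0
    alpha_best = alphas[j_best]
    side = np.where(np.sin(theta - alpha_best) >= 0, 1, -1)
    return side.astype(np.int8)


def _soft_circular_mask(box: int, pixel_size: float, mask_diameter: float,
                        edge_px: float = 6.0) -> np.ndarray:
    if mask_diameter > box * pixel_size:
        raise ValueError(
            f"mask diameter {mask_diameter} Å exceeds the box "
            f"({box * pixel_size} Å)"
        )
    u = (np.arange(box) - box // 2) * pixel_size
    yy, xx = np.meshgrid(u, u, indexing="ij")
    r = np.sqrt(xx**2 + yy**2)
    r0 = mask_diameter / 2.0
    edge = edge_px * pixel_size
    mask = np.zeros((box, box))
    mask[r <= r0] = 1.0
    ramp = (r > r0) & (r < r0 + edge)
    mask[ramp] = 0.5 * (1.0 + np.cos(np.pi * (r[ramp] - r0) / edge))
    return mask


def split_sideband(image_ft: FourierGrid, ctf: CtfParams, n_sectors: int = 2,
                   curvature: int = +1, mask_diameter: float | None = None,
                   apply_mask: bool = True) -> SidebandPair:
    """Split a particle transform into its P/Q side-band pair.

    Per pixel, the sector rotation whose dividing line is farthest away is
    chosen; on its positive half ``p_ft`` gets the CTF_P product and
    ``q_ft`` the CTF_Q product (and vice versa on the negative half).
    The unit-modulus multiplications leave the amplitudes intact but break
    Friedel symmetry.  With ``apply_mask`` each side-band is
    back-transformed, multiplied by a soft circular real-space mask
    (raised-cosine edge of 6 px outside ``mask_diameter``/2; default
    diameter 0.9 × box) and transformed back.
    """
    if n_sectors < 1:
        raise ValueError(f"n_sectors must be >= 1, got {n_sectors}")
    box = image_ft.shape[0]
    pix = image_ft.pixel_size
    if mask_diameter is None:
        mask_diameter = 0.9 * box * pix
    ky, kx = freq_grids_2d(image_ft.shape, pix)
    psi = lens_phase(ctf, kx, ky)
    ctf_p, ctf_q = ssb_ctfs(psi)
    side = _sector_sides(image_ft.shape, n_sectors)
    pos = side > 0
    p_vals = np.where(pos, image_ft.values * ctf_p, image_ft.values * ctf_q)
    q_vals = np.where(pos, image_ft.values * ctf_q, image_ft.values * ctf_p)
    if apply_mask:
        mask = _soft_circular_mask(box, pix, mask_diameter)
        p_vals = fft_centered(ifft_centered(p_vals) * mask)
        q_vals = fft_centered(ifft_centered(q_vals) * mask)
    return SidebandPair(FourierGrid(p_vals, pix), FourierGrid(q_vals, pix),
                        side, n_sectors, int(np.sign(curvature) or 1))


def reconstruct(images: np.ndarray, table: pd.DataFrame, pixel_size: float,
                mode: str = "plain", curvature: str = "normal",
                n_sectors: int = 2, mask_diameter: float | None = None,
                pad_factor: int = 2) -> VolumeGrid:
    """Reconstruct a 3D map from a particle stack and its metadata table.

    ``mode="plain"``: ordinary CTF-weighted central-section insertion
    (data += CTF·X, weights += CTF² per pixel).  ``mode="ewald"``: each
    particle is split into its side-band pair; every pixel is inserted off
    the central section at its signed displacement side·Δz*·curvature
    with unit weight, so each side-band lands on the Ewald hemisphere it
    coherently samples.  ``curvature="reverse"`` flips all displacement
    signs; flipping twice reproduces the original reconstruction exactly.
    """
    if mode not in ("plain", "ewald"):
        raise ValueError(f"unknown mode {mode!r}; expected 'plain' or 'ewald'")
    if curvature not in ("normal", "reverse"):
        raise ValueError(f"unknown curvature {curvature!r}")
    if len(table) != len(images):
        raise ValueError(f"{len(images)} images but {len(table)} table rows")
    box = images.shape[-1]
    curv = +1 if curvature == "normal" else -1
    acc = ReconstructionAccumulator(box, pixel_size, pad_factor)
    ky, kx = freq_grids_2d((box, box), pixel_size)
    k_mag = np.sqrt(kx**2 + ky**2)
    ones = np.ones((box, box))
    for i, (_, row) in enumerate(table.iterrows()):
        params = pt.ctf_from_row(row)
        ori = pt.orientation_from_row(row)
        x_ft = FourierGrid(fft_centered(images[i]), pixel_size)
        if mode == "plain":
            ctf = -np.sin(lens_phase(params, kx, ky))
            # signed CTF weighting via phase-flipped values and |CTF| weights:
            # data += |CTF|·sign(CTF)·X = CTF·X, weights += CTF²
            insert_slice(acc, x_ft.values * np.sign(ctf), ori, np.abs(ctf))
        else:
            pair = split_sideband(x_ft, params, n_sectors=n_sectors,
                                  curvature=curv, mask_diameter=mask_diameter)
            dz = delta_z(k_mag, params.lam) * pair.side * curv
            insert_slice(acc, pair.p_ft.values, ori, ones, z_offsets=dz)
            insert_slice(acc, pair.q_ft.values, ori, ones, z_offsets=-dz)
    return finalize(acc)
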