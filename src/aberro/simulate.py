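"""Synthetic cryo-EM data with known ground truth.

Everything the rest of the package consumes can be fabricated here:
soft-blob phantom volumes, particle stacks with injected defocus /
astigmatism / beam tilt / Ewald curvature, tilted-stage defocus geometry,
and micrographs with planted blobs for picker tests.

The noise model is additive white Gaussian noise in real space, with the
per-particle standard deviation set from a target signal-to-noise power
ratio (SNR = mean signal power / noise variance).  All randomness flows
from the single mandatory ``seed`` through one `numpy` Generator, so
every simulation is exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import particles as pt
from .ctf import (BeamTilt, CtfParams, chi_from_amplitude_contrast, lens_phase,
                  ssb_ctfs, tilt_phase, wavelength_from_voltage)
from .fourier_core import Orientation, project_volume, volume_to_fourier
from .grids import ImageGrid, VolumeGrid, freq_grids_2d, ifft_centered

__all__ = ["SimulationConfig", "make_phantom", "simulate_stack", "simulate_micrograph"]

TRUE_DEFOCUS = "_abTrueDefocus"


@dataclass
class SimulationConfig:
    """Ground-truth study conditions for one simulated particle stack.

    Defaults describe a desk-scale stand-in for a routine 300 kV data
    set: 64-px boxes at 1.5 Å/px, ~3000 Å underfocus with a ±1500 Å
    per-particle spread.  ``stage_tilt_deg`` switches the defocus model to
    a planar gradient across a ``field_width`` Å field of view (particle
    height = x·tan(tilt)), emulating data collected at a tilted stage.
    """

    seed: int
    box: int = 64
    pixel_size: float = 1.5  # Å/px
    n_particles: int = 32
    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.1
    defocus_base: float = 3000.0  # Å
    defocus_spread: float = 1500.0  # uniform ± spread, Å
    stage_tilt_deg: float | None = None
    field_width: float = 4800.0  # Å
    astigmatism: tuple = (0.0, 0.0)  # (δA Å, φA deg), common to all particles
    beam_tilt: tuple = (0.0, 0.0)  # mrad
    ewald: bool = False
    curvature: int = +1
    snr: float | None = None  # signal-to-noise power ratio; None = noiseless
    pad_factor: int = 2
    n_tilt_groups: int = 1

    def __post_init__(self) -> None:
        for name in ("box", "pixel_size", "n_particles", "voltage_kv"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.cs_mm < 0:
            raise ValueError("cs_mm must be non-negative")
        if self.snr is not None and not self.snr > 0:
            raise ValueError("snr must be positive when given")

    @property
    def lam(self) -> float:
        return wavelength_from_voltage(self.voltage_kv)


def make_phantom(box: int, pixel_size: float, n_blobs: int = 12, seed: int = 0,
                 diameter_fraction: float = 0.6,
                 granularity: float = 2.0) -> VolumeGrid:
    """Random soft-sphere / Gaussian-cluster phantom volume.

    Blob centres are confined to a sphere of diameter
    ``diameter_fraction × box`` so the particle support is known.  A
    granular texture (lightly smoothed white noise confined to the same
    support, RMS = ``granularity`` × the blob RMS) emulates the atomic
    detail of a real macromolecule and gives the phantom power out to
    high frequency — without it, CTF oscillations beyond the first zero
    would carry no signal.  Deterministic per seed; ``n_blobs = 0``
    yields a zero volume.
    """
    rng = np.random.default_rng(seed)
    vol = np.zeros((box,) * 3)
    if n_blobs == 0:
        return VolumeGrid(vol, pixel_size)
    ctr = box // 2
    max_r = 0.5 * diameter_fraction * box
    z, y, x = np.mgrid[0:box, 0:box, 0:box].astype(float)
    for _ in range(n_blobs):
        sigma = rng.uniform(1.0, 3.0)  # px
        # keep the blob (centre + 3σ) inside the stated support
        r_max = max(max_r - 3.0 * sigma, 0.0)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        radius = r_max * rng.uniform() ** (1 / 3)
        cz, cy, cx = ctr + u * radius
        amp = rng.uniform(0.5, 1.5)
        vol += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
                            / (2 * sigma**2))
    if granularity > 0:
        from scipy.ndimage import gaussian_filter

        r2 = (x - ctr) ** 2 + (y - ctr) ** 2 + (z - ctr) ** 2
        support = np.clip((max_r - np.sqrt(r2)) / 2.0, 0.0, 1.0)  # soft edge
        texture = gaussian_filter(rng.normal(size=vol.shape), 0.5) * support
        rms = texture[support > 0].std()
        if rms > 0:
            texture *= granularity * vol[support > 0].std() / rms
        vol += texture
    return VolumeGrid(vol, pixel_size)


def _random_orientation(rng) -> Orientation:
    return Orientation(
        rot=rng.uniform(0.0, 360.0),
        tilt=np.degrees(np.arccos(rng.uniform(-1.0, 1.0))),
        psi=rng.uniform(0.0, 360.0),
    )


def simulate_stack(phantom: VolumeGrid, config: SimulationConfig):
    """Project a phantom into a particle stack with injected aberrations.

    Per particle: random orientation, central-slice (or Ewald
    two-side-band) projection, CTF multiplication, optional beam-tilt
    phase, additive white Gaussian noise at the configured SNR.  Returns
    ``(stack, table)`` where the table records the injected ground truth
    (defocus columns hold the true per-particle values; ``_abTrueDefocus``
    duplicates δ0 for convenience).
    """
    rng = np.random.default_rng(config.seed)
    box = config.box
    vol_ft = volume_to_fourier(phantom, config.pad_factor)
    lam = config.lam
    chi = chi_from_amplitude_contrast(config.amplitude_contrast)
    delta_a, phi_a_deg = config.astigmatism
    tilt = BeamTilt(*config.beam_tilt)
    ky, kx = freq_grids_2d((box, box), config.pixel_size)
    k_mag = np.sqrt(kx**2 + ky**2)
    tilt_factor = None
    if tilt.bx or tilt.by:
        tilt_factor = np.exp(1j * tilt_phase(tilt, kx, ky, config.cs_mm, lam))

    stack = np.zeros((config.n_particles, box, box), dtype=np.float64)
    rows = []
    for i in range(config.n_particles):
        ori = _random_orientation(rng)
        if config.stage_tilt_deg is not None:
            x_pos = rng.uniform(-0.5, 0.5) * config.field_width
            y_pos = rng.uniform(-0.5, 0.5) * config.field_width
            delta0 = config.defocus_base + x_pos * np.tan(np.radians(config.stage_tilt_deg))
        else:
            x_pos = y_pos = 0.0
            delta0 = config.defocus_base + rng.uniform(-1.0, 1.0) * config.defocus_spread
        params = CtfParams(delta0=delta0, delta_a=delta_a,
                           phi_a=np.radians(phi_a_deg), cs_mm=config.cs_mm,
                           chi=chi, lam=lam)
        psi = lens_phase(params, kx, ky)
        if config.ewald:
            dz = 0.5 * lam * k_mag**2 * config.curvature
            v_plus = project_volume(vol_ft, ori, box, z_offsets=dz).values
            v_minus = project_volume(vol_ft, ori, box, z_offsets=-dz).values
            ctf_p, ctf_q = ssb_ctfs(psi)
            x_ft = 0.5 * (ctf_q * v_plus + ctf_p * v_minus)
        else:
            v = project_volume(vol_ft, ori, box).values
            x_ft = -np.sin(psi) * v
        if tilt_factor is not None:
            x_ft = x_ft * tilt_factor
        img = ifft_centered(x_ft).real
        if config.snr is not None:
            sigma = np.sqrt(np.mean(img**2) / config.snr)
            img = img + rng.normal(0.0, sigma, size=img.shape)
        stack[i] = img
        rows.append({
            pt.MICROGRAPH: "synthetic_001.mrc",
            pt.COORD_X: x_pos / config.pixel_size,
            pt.COORD_Y: y_pos / config.pixel_size,
            pt.ANGLE_ROT: ori.rot,
            pt.ANGLE_TILT: ori.tilt,
            pt.ANGLE_PSI: ori.psi,
            pt.SHIFT_X: 0.0,
            pt.SHIFT_Y: 0.0,
            pt.DEFOCUS_U: params.defocus_u,
            pt.DEFOCUS_V: params.defocus_v,
            pt.DEFOCUS_ANGLE: params.astigmatism_angle_deg,
            pt.VOLTAGE: config.voltage_kv,
            pt.CS: config.cs_mm,
            pt.AMPLITUDE_CONTRAST: config.amplitude_contrast,
            pt.PHASE_SHIFT: 0.0,
            pt.HALF_SET: 1 + i % 2,
            pt.TILT_GROUP: 1 + i % max(config.n_tilt_groups, 1),
            TRUE_DEFOCUS: delta0,
        })
    return stack, pd.DataFrame(rows)


def simulate_micrograph(size: int, pixel_size: float, n_particles: int,
                        blob_diameter: float, seed: int,
                        snr: float | None = 0.5, amplitude: float = 1.0,
                        min_separation: float | None = None,
                        positions: np.ndarray | None = None):
    """A micrograph with planted Gaussian blobs at known coordinates.

    Blobs are dark on a bright background (amplitude subtracted), with
    real-space width σ = diameter/2 (the scale-normalised LoG bank gives
    its best response to such a blob at the filter of the same nominal
    diameter).  ``snr`` is the field-wide signal
    power over noise variance; ``None`` plants the blobs without noise.
    Returns ``(ImageGrid, positions table)`` with 0-based pixel centres.
    """
    rng = np.random.default_rng(seed)
    if positions is None:
        if min_separation is None:
            min_separation = 1.5 * blob_diameter
        sep_px = min_separation / pixel_size
        margin = 0.75 * blob_diameter / pixel_size
        pos = []
        attempts = 0
        while len(pos) < n_particles and attempts < 20000:
            cand = rng.uniform(margin, size - margin, size=2)  # (y, x)
            if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= sep_px**2
                   for p in pos):
                pos.append(cand)
            attempts += 1
        if len(pos) < n_particles:
            raise ValueError(
                f"could not place {n_particles} blobs with separation "
                f"{min_separation} Å in a {size}-px field"
            )
        positions = np.array(pos) if pos else np.zeros((0, 2))
    else:
        positions = np.asarray(positions, dtype=float)

    signal = np.zeros((size, size))
    sigma_px = blob_diameter / (2.0 * pixel_size)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    for cy, cx in positions:
        signal -= amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2)
                                     / (2 * sigma_px**2))
    image = signal.copy()
    if snr is not None and len(positions):
        noise_sigma = np.sqrt(np.mean(signal**2) / snr)
        image = image + rng.normal(0.0, noise_sigma, size=image.shape)
    elif snr is not None:
        image = image + rng.normal(0.0, 1.0, size=image.shape)
    table = pd.DataFrame({
        pt.COORD_X: positions[:, 1] if len(positions) else [],
        pt.COORD_Y: positions[:, 0] if len(positions) else [],
        "_abDiameter": [blob_diameter] * len(positions),
    })
    return ImageGrid(image, pixel_size), table
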