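"""Contrast transfer function parameterisation and closed-form lens optics.

The CTF of a defocused objective lens at 2D spatial frequency k (Å⁻¹) is

    CTF(k) = -sin( π λ (δ0 + δA cos 2(φk - φA)) |k|²
                   + (π/2) Cs λ³ |k|⁴ - χ )

with δ0 the average defocus (positive = underfocus), δA half the
difference between the two effective defoci from astigmatism, φA the
astigmatism azimuth, Cs the spherical aberration and χ the total phase
shift from amplitude contrast (and a phase plate, if present).

A tilted illuminating beam b (mrad) adds axial coma, an antisymmetric
per-frequency phase error

    φ(b, k) = 2π Cs λ² ⟨k, b⟩ |k|²  .

Single-side-band CTFs for Ewald-sphere work are the unit-modulus pair

    CTF_P = e^{+i(ψ+π/2)},  CTF_Q = e^{-i(ψ+π/2)}

whose real average reproduces the ordinary CTF: (CTF_P + CTF_Q)/2 = -sin ψ.

Unit conventions: Cs is accepted in mm on every interface and converted
to Å (×1e7) internally; beam tilt is accepted in mrad and converted to
radians internally; defocus, wavelength and frequencies are in Å and Å⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import constants

from .grids import FourierGrid, freq_grids_2d

__all__ = [
    "CtfParams",
    "BeamTilt",
    "wavelength_from_voltage",
    "chi_from_amplitude_contrast",
    "lens_phase",
    "ctf_value",
    "ctf_grid",
    "ssb_ctfs",
    "tilt_phase",
    "apply_tilt",
]

MM_TO_A = 1.0e7
MRAD_TO_RAD = 1.0e-3


def wavelength_from_voltage(kv: float) -> float:
    """Relativistic de Broglie wavelength (Å) of electrons at ``kv`` kV.

    λ = h / sqrt(2 m0 e U (1 + e U / (2 m0 c²)));  300 kV → 0.019687 Å.
    """
    if not kv > 0:
        raise ValueError(f"accelerating voltage must be > 0 kV, got {kv}")
    u = kv * 1e3
    h, m0, e, c = constants.h, constants.m_e, constants.e, constants.c
    lam_m = h / np.sqrt(2.0 * m0 * e * u * (1.0 + e * u / (2.0 * m0 * c**2)))
    return float(lam_m * 1e10)


def chi_from_amplitude_contrast(amplitude_contrast: float = 0.1,
                                phase_shift: float = 0.0) -> float:
    """Total phase shift χ (rad) from an amplitude-contrast fraction A
    plus an optional phase-plate shift: χ = atan(A/√(1-A²)) + shift."""
    a = float(amplitude_contrast)
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"amplitude contrast must be in [0, 1], got {a}")
    return float(np.arctan2(a, np.sqrt(max(1.0 - a * a, 0.0))) + phase_shift)


@dataclass
class CtfParams:
    """CTF parameter set θ = {δ0, δA, φA, Cs, χ} plus the wavelength λ.

    The astigmatism pair is canonicalised so δA ≥ 0 and φA ∈ [0, π):
    (δA, φA) and (-δA, φA+π/2) describe the same lens.
    """

    delta0: float  # average defocus, Å; positive = underfocus
    delta_a: float = 0.0  # astigmatism half-difference, Å
    phi_a: float = 0.0  # astigmatism azimuth, rad
    cs_mm: float = 2.7  # spherical aberration, mm
    chi: float = chi_from_amplitude_contrast(0.1)  # total phase shift, rad
    lam: float = wavelength_from_voltage(300.0)  # electron wavelength, Å

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError(f"wavelength must be > 0, got {self.lam}")
        if self.delta_a < 0:
            self.delta_a = -self.delta_a
            self.phi_a = self.phi_a + np.pi / 2
        self.phi_a = float(np.mod(self.phi_a, np.pi))
        if self.phi_a >= np.pi:  # float wrap of a tiny negative angle
            self.phi_a = 0.0

    @property
    def cs_angstrom(self) -> float:
        return self.cs_mm * MM_TO_A

    @property
    def defocus_u(self) -> float:
        """STAR-convention defocusU = δ0 + δA (Å)."""
        return self.delta0 + self.delta_a

    @property
    def defocus_v(self) -> float:
        """STAR-convention defocusV = δ0 - δA (Å)."""
        return self.delta0 - self.delta_a

    @property
    def astigmatism_angle_deg(self) -> float:
        return float(np.degrees(self.phi_a))

    @classmethod
    def from_defocus_uv(cls, defocus_u, defocus_v, angle_deg=0.0, **kw) -> "CtfParams":
        delta0 = 0.5 * (defocus_u + defocus_v)
        delta_a = 0.5 * (defocus_u - defocus_v)
        return cls(delta0=delta0, delta_a=delta_a, phi_a=np.radians(angle_deg), **kw)

    def with_defocus(self, delta0: float) -> "CtfParams":
        return replace(self, delta0=delta0)


@dataclass
class BeamTilt:
    """Beam-tilt vector b = (bx, by) in mrad."""

    bx: float = 0.0
    by: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.bx) and np.isfinite(self.by)):
            raise ValueError(f"beam tilt must be finite, got {(self.bx, self.by)}")

    @property
    def mrad(self) -> np.ndarray:
        return np.array([self.bx, self.by], dtype=float)


def lens_phase(params: CtfParams, kx, ky):
    """Lens phase ψ(k) — the argument of the CTF's sine (rad)."""
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k2 = kx * kx + ky * ky
    phi_k = np.arctan2(ky, kx)
    defocus_term = params.delta0 + params.delta_a * np.cos(2.0 * (phi_k - params.phi_a))
    return (np.pi * params.lam * defocus_term * k2
            + 0.5 * np.pi * params.cs_angstrom * params.lam**3 * k2 * k2
            - params.chi)


def ctf_value(params: CtfParams, kx, ky):
    """CTF(k) = -sin ψ(k); vectorised over frequency arrays (Å⁻¹)."""
    return -np.sin(lens_phase(params, kx, ky))


def ctf_grid(params: CtfParams, shape: tuple, pixel_size: float) -> np.ndarray:
    """CTF evaluated on a full centred 2D Fourier grid."""
    ky, kx = freq_grids_2d(shape, pixel_size)
    return ctf_value(params, kx, ky)


def ssb_ctfs(psi):
    """Single-side-band CTF pair for lens phase ψ.

    Returns (CTF_P, CTF_Q) = (e^{+i(ψ+π/2)}, e^{-i(ψ+π/2)}); the π/2 is
    the phase shift upon scattering by the specimen.  Both have unit
    modulus, CTF_P·CTF_Q = 1 and (CTF_P+CTF_Q)/2 = -sin ψ.
    """
    psi = np.asarray(psi, dtype=float)
    ctf_p = np.exp(1j * (psi + np.pi / 2))
    ctf_q = np.exp(-1j * (psi + np.pi / 2))
    return ctf_p, ctf_q


def tilt_phase(tilt: BeamTilt, kx, ky, cs_mm: float, lam: float):
    """Axial-coma phase φ = 2π Cs λ² ⟨k, b⟩ |k|² (rad); b given in mrad."""
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    bx = tilt.bx * MRAD_TO_RAD
    by = tilt.by * MRAD_TO_RAD
    k2 = kx * kx + ky * ky
    return 2.0 * np.pi * cs_mm * MM_TO_A * lam**2 * (kx * bx + ky * by) * k2


def _tilt_factor(shape, pixel_size, tilt, cs_mm, lam):
    ky, kx = freq_grids_2d(shape, pixel_size)
    phase = tilt_phase(tilt, kx, ky, cs_mm, lam)
    factor = np.exp(1j * phase)
    # unpaired Nyquist rows/columns of even-sized grids have no Friedel
    # mate; leave them untouched so real images stay real
    for ax, n in enumerate(shape):
        if n % 2 == 0:
            sl = [slice(None)] * len(shape)
            sl[ax] = 0
            factor[tuple(sl)] = 1.0
    return factor


def apply_tilt(image_ft: FourierGrid, tilt: BeamTilt, cs_mm: float, lam: float) -> FourierGrid:
    """Multiply each frequency by e^{iφ(b,k)} (beam-tilt phase model).

    Amplitudes are unchanged; the antisymmetry φ(-k) = -φ(k) preserves
    Friedel symmetry, so real images map to real images.
    """
    factor = _tilt_factor(image_ft.shape, image_ft.pixel_size, tilt, cs_mm, lam)
    return FourierGrid(image_ft.values * factor, image_ft.pixel_size)
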