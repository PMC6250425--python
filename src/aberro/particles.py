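"""Particle metadata schema: the STAR column labels this package reads/writes.

One row of a particles table describes one particle: its micrograph,
centre coordinates (0-based pixels of the particle centre), Euler angles
(degrees, ZYZ), in-plane shifts (Å), CTF parameters (defocusU/V/angle
convention: defocusU = δ0+δA, defocusV = δ0-δA, angle = φA in degrees),
microscope constants, half-set id and beam-tilt group id.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ctf import CtfParams, chi_from_amplitude_contrast, wavelength_from_voltage
from .fourier_core import Orientation

MICROGRAPH = "_rlnMicrographName"
COORD_X = "_rlnCoordinateX"
COORD_Y = "_rlnCoordinateY"
ANGLE_ROT = "_rlnAngleRot"
ANGLE_TILT = "_rlnAngleTilt"
ANGLE_PSI = "_rlnAnglePsi"
SHIFT_X = "_rlnOriginXAngst"
SHIFT_Y = "_rlnOriginYAngst"
DEFOCUS_U = "_rlnDefocusU"
DEFOCUS_V = "_rlnDefocusV"
DEFOCUS_ANGLE = "_rlnDefocusAngle"
VOLTAGE = "_rlnVoltage"
CS = "_rlnSphericalAberration"
AMPLITUDE_CONTRAST = "_rlnAmplitudeContrast"
PHASE_SHIFT = "_rlnPhaseShift"
HALF_SET = "_rlnRandomSubset"
TILT_GROUP = "_rlnBeamTiltClass"

__all__ = [
    "MICROGRAPH", "COORD_X", "COORD_Y", "ANGLE_ROT", "ANGLE_TILT", "ANGLE_PSI",
    "SHIFT_X", "SHIFT_Y", "DEFOCUS_U", "DEFOCUS_V", "DEFOCUS_ANGLE",
    "VOLTAGE", "CS", "AMPLITUDE_CONTRAST", "PHASE_SHIFT", "HALF_SET",
    "TILT_GROUP", "ctf_from_row", "orientation_from_row", "set_defocus",
]


def ctf_from_row(row) -> CtfParams:
    """Build :class:`~aberro.ctf.CtfParams` from one particles-table row."""
    chi = chi_from_amplitude_contrast(
        float(row.get(AMPLITUDE_CONTRAST, 0.1)),
        np.radians(float(row.get(PHASE_SHIFT, 0.0))),
    )
    return CtfParams.from_defocus_uv(
        float(row[DEFOCUS_U]),
        float(row[DEFOCUS_V]),
        float(row.get(DEFOCUS_ANGLE, 0.0)),
        cs_mm=float(row.get(CS, 2.7)),
        chi=chi,
        lam=wavelength_from_voltage(float(row.get(VOLTAGE, 300.0))),
    )


def orientation_from_row(row) -> Orientation:
    return Orientation(
        rot=float(row.get(ANGLE_ROT, 0.0)),
        tilt=float(row.get(ANGLE_TILT, 0.0)),
        psi=float(row.get(ANGLE_PSI, 0.0)),
        shift_x=float(row.get(SHIFT_X, 0.0)),
        shift_y=float(row.get(SHIFT_Y, 0.0)),
    )


def set_defocus(table: pd.DataFrame, index, params: CtfParams) -> None:
    """Write a CTF parameter set back into the defocusU/V/angle columns."""
    for col in (DEFOCUS_U, DEFOCUS_V, DEFOCUS_ANGLE):
        if col in table.columns and table[col].dtype != np.float64:
            table[col] = table[col].astype(float)
    table.loc[index, DEFOCUS_U] = params.defocus_u
    table.loc[index, DEFOCUS_V] = params.defocus_v
    table.loc[index, DEFOCUS_ANGLE] = params.astigmatism_angle_deg
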