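"""Beam-tilt estimation from accumulated per-pixel phase differences.

A tilted illuminating beam induces axial coma: an antisymmetric phase
error φ(b, k) = 2π Cs λ² ⟨k, b⟩ |k|² in every image.  Fitting b directly
to the phase *angles* would fail because phases are cyclic, so instead a
per-pixel complex average of the phase differences between experimental
images X_j and CTF-modulated reference projections V_j is formed in a
single pass over the data:

    q_k = Σ_j X_{j,k} V*_{j,k} / Σ_j |V_{j,k}|²,   w_k = Σ_j |V_{j,k}|²

and the tilt is then the minimiser of the weighted circular residual

    b = argmin_β Σ_k w_k |z_k(β) - q_k|²,   z_k(β) = e^{iφ(β,k)} ,

found by Nelder-Mead simplex started from β = 0 and from the best point
of a coarse 2D grid (the phase wrapping makes the surface multimodal for
large tilts).  Inspecting the phases of q_k before trusting the fit
guards against fitting b to noise or to other antisymmetric aberrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import particles as pt
from .ctf import BeamTilt, ctf_grid, tilt_phase
from .ctf_refine import _prepare_references
from .fourier_core import project_volume
from .grids import FourierGrid, ImageGrid, fft_centered, freq_grids_2d, shell_radius_grid

logger = logging.getLogger(__name__)

__all__ = ["PhaseAggregate", "accumulate", "fit_tilt", "phase_plot", "group_fit",
           "estimate_tilt"]


@dataclass
class PhaseAggregate:
    """Running sums behind the per-pixel optima q_k and weights w_k."""

    shape: tuple
    pixel_size: float
    numerator: np.ndarray = field(init=False)  # Σ_j X_j V*_j
    w: np.ndarray = field(init=False)  # Σ_j |V_j|²
    n_images: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        self.numerator = np.zeros(self.shape, dtype=np.complex128)
        self.w = np.zeros(self.shape, dtype=float)

    @property
    def q(self) -> np.ndarray:
        """Per-pixel optima q_k = Σ X V* / Σ |V|²; zero where w = 0."""
        out = np.zeros(self.shape, dtype=np.complex128)
        ok = self.w > 0
        out[ok] = self.numerator[ok] / self.w[ok]
        return out


def accumulate(agg: PhaseAggregate, x_ft: FourierGrid, v_ft: FourierGrid) -> PhaseAggregate:
    """Add one particle's contribution; V must include the CTF.

    Maintains the running sums so the whole data set is visited once;
    accumulating the same image twice doubles w and leaves q unchanged.
    """
    if x_ft.shape != agg.shape or v_ft.shape != agg.shape:
        raise ValueError(
            f"image/reference dims {x_ft.shape}/{v_ft.shape} do not match "
            f"aggregate {agg.shape}"
        )
    agg.numerator += x_ft.values * np.conj(v_ft.values)
    agg.w += np.abs(v_ft.values) ** 2
    agg.n_images += 1
    return agg


def _residual(agg: PhaseAggregate, kx, ky, cs_mm, lam, beta_mrad) -> float:
    phase = tilt_phase(BeamTilt(*beta_mrad), kx, ky, cs_mm, lam)
    z = np.exp(1j * phase)
    q = agg.q
    return float(np.sum(agg.w * np.abs(z - q) ** 2))


def fit_tilt(agg: PhaseAggregate, cs_mm: float, lam: float,
             max_shell: int | None = None, grid_mrad: float = 1.0,
             grid_points: int = 11):
    """Fit the beam-tilt vector to an aggregate.

    Runs Nelder-Mead from β = 0 and from the best point of a
    ``grid_points × grid_points`` coarse grid spanning ±``grid_mrad``;
    convergence when the simplex diameter falls below 1e-4 mrad.
    ``max_shell`` limits the fit to shells below a resolution cutoff
    (beyond the half-map FSC resolution the reference is noise).
    Returns ``(BeamTilt, residual)``.
    """
    if not np.any(agg.w > 0):
        raise ValueError("aggregate has all-zero weights; accumulate images first")
    ky, kx = freq_grids_2d(agg.shape, agg.pixel_size)
    work = agg
    if max_shell is not None:
        radius = shell_radius_grid(agg.shape)
        keep = radius <= max_shell
        work = PhaseAggregate(agg.shape, agg.pixel_size)
        work.numerator = np.where(keep, agg.numerator, 0.0)
        work.w = np.where(keep, agg.w, 0.0)
        work.n_images = agg.n_images

    def objective(beta):
        return _residual(work, kx, ky, cs_mm, lam, beta)

    starts = [np.zeros(2)]
    axis = np.linspace(-grid_mrad, grid_mrad, grid_points)
    gx, gy = np.meshgrid(axis, axis)
    grid = np.stack([gx.ravel(), gy.ravel()], axis=1)
    grid_scores = [objective(b) for b in grid]
    starts.append(grid[int(np.argmin(grid_scores))])

    best_x, best_f = None, np.inf
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-12,
                                         "maxiter": 2000})
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    return BeamTilt(float(best_x[0]), float(best_x[1])), float(best_f)


def phase_plot(agg: PhaseAggregate) -> ImageGrid:
    """Per-pixel phase of q_k in [-π, π], zeroed where w = 0.

    The coma signature of a genuinely tilted beam is an antisymmetric
    phase map (φ(-k) = -φ(k)); inspecting it before trusting the fitted
    vector guards against fitting noise.
    """
    phases = np.where(agg.w > 0, np.angle(agg.q), 0.0)
    return ImageGrid(phases, agg.pixel_size)


def estimate_tilt(images: np.ndarray, table: pd.DataFrame, halfmaps: dict,
                  cs_mm: float | None = None, lam: float | None = None,
                  pixel_size: float | None = None, pad_factor: int = 2,
                  max_shell: int | None = None):
    """Accumulate one aggregate over a particle set and fit its tilt.

    The reference projection of each particle comes from the half-map of
    its own half-set and includes the particle's CTF.  Returns
    ``(BeamTilt, residual, PhaseAggregate)``.
    """
    if len(table) == 0:
        raise ValueError("need at least one particle")
    if pixel_size is None:
        pixel_size = next(iter(halfmaps.values())).pixel_size
    first = table.iloc[0]
    params0 = pt.ctf_from_row(first)
    if cs_mm is None:
        cs_mm = params0.cs_mm
    if lam is None:
        lam = params0.lam
    refs = _prepare_references(halfmaps, pad_factor)
    box = images.shape[-1]
    agg = PhaseAggregate((box, box), pixel_size)
    for i, (_, row) in enumerate(table.iterrows()):
        half = int(row.get(pt.HALF_SET, 1))
        v = project_volume(refs[half], pt.orientation_from_row(row), box)
        ctf = ctf_grid(pt.ctf_from_row(row), (box, box), pixel_size)
        v_ctf = FourierGrid(v.values * ctf, pixel_size)
        accumulate(agg, FourierGrid(fft_centered(images[i]), pixel_size), v_ctf)
    tilt, residual = fit_tilt(agg, cs_mm, lam, max_shell=max_shell)
    return tilt, residual, agg


def group_fit(images: np.ndarray, table: pd.DataFrame, halfmaps: dict,
              group_column: str = pt.TILT_GROUP, **kwargs) -> pd.DataFrame:
    """One independent tilt estimate per tilt group.

    Returns a table with group id, fitted (bx, by) in mrad, final
    residual and the number of images accumulated.  Empty groups are
    skipped with a logged warning.
    """
    rows = []
    for gid, sub in table.groupby(group_column, sort=True, observed=False):
        if len(sub) == 0:
            logger.warning("tilt group %r is empty; skipped", gid)
            continue
        idx = table.index.get_indexer(sub.index)
        tilt, residual, agg = estimate_tilt(images[idx], sub, halfmaps, **kwargs)
        rows.append({group_column: gid, "bx_mrad": tilt.bx, "by_mrad": tilt.by,
                     "residual": residual, "n_images": agg.n_images})
    return pd.DataFrame(rows)
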