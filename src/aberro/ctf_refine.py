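"""Reference-based CTF refinement.

Given a 3D reference and known viewing geometry, the CTF parameters of a
particle (or of all particles in a micrograph) are re-estimated by
maximising the FSC-weighted correlation between the experimental image X
and the CTF-modulated reference projection V:

    θ = argmax_θ' Σ_k g_k · CTF(θ', k) · Σ_p Re(V*_{p,k} X_{p,k})

This is equivalent, for noiseless data, to minimising the squared
difference Σ g_k (X - CTF·V)², but needs only the cross term, which under
pure noise is centred around zero — no background model is required, in
contrast to Thon-ring fitting on power spectra.

The per-shell weights g_k come from the FSC between the two independently
refined half-maps, clamped to [0, 1] and zeroed beyond the first crossing
of 0.143; frequencies below 1/40 Å⁻¹ are excluded because the half-maps
share information there.  Half-set hygiene is strict: the reference
projection for particle p always comes from the half-map of p's own
half-set, so the fitted parameters cannot feed noise from one half-set
into the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import particles as pt
from .ctf import CtfParams, ctf_grid, lens_phase
from .fourier_core import project_volume, volume_to_fourier
from .grids import FourierGrid, fft_centered, freq_grids_2d, shell_radius_grid

__all__ = [
    "RefinementScope",
    "FrequencyWeights",
    "correlation_objective",
    "refine_particle_defocus",
    "refine_micrograph_params",
    "diagnostic_spectra",
]

SCORE_CHANGE = "_abScoreChange"
LOW_RES_CUTOFF_A = 40.0  # half-maps share information below this resolution


@dataclass
class RefinementScope:
    """Which CTF parameters float, and at what granularity."""

    delta0: str = "per_particle"  # per_particle | per_micrograph | fixed
    astigmatism: str = "fixed"  # fixed | per_micrograph | per_particle
    cs: str = "fixed"  # fixed | per_micrograph
    chi: str = "fixed"  # fixed | per_micrograph

    def __post_init__(self) -> None:
        allowed = {
            "delta0": {"per_particle", "per_micrograph", "fixed"},
            "astigmatism": {"fixed", "per_micrograph", "per_particle"},
            "cs": {"fixed", "per_micrograph"},
            "chi": {"fixed", "per_micrograph"},
        }
        for name, ok in allowed.items():
            if getattr(self, name) not in ok:
                raise ValueError(f"scope.{name} must be one of {sorted(ok)}")
        if all(getattr(self, n) == "fixed" for n in allowed):
            raise ValueError("at least one CTF parameter must not be fixed")


class FrequencyWeights:
    """Per-shell weights g_k ∈ [0, 1] derived from a half-map FSC curve.

    g is clamped to [0, 1] and zeroed from the first shell where the FSC
    drops below 0.143 onwards (the reference carries no usable signal
    there).
    """

    def __init__(self, g: np.ndarray):
        g = np.asarray(g, dtype=float)
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("shell weights must lie in [0, 1]")
        self.g = g

    @classmethod
    def from_fsc(cls, fsc_table: pd.DataFrame, threshold: float = 0.143) -> "FrequencyWeights":
        vals = np.clip(fsc_table["fsc"].to_numpy(dtype=float), 0.0, 1.0)
        below = np.nonzero(fsc_table["fsc"].to_numpy() < threshold)[0]
        below = below[below > 0]
        if len(below):
            vals[below[0]:] = 0.0
        return cls(vals)

    @classmethod
    def flat(cls, n_shells: int) -> "FrequencyWeights":
        return cls(np.ones(n_shells))

    def pixel_weights(self, shape: tuple, pixel_size: float,
                      low_res_cutoff: float = LOW_RES_CUTOFF_A) -> np.ndarray:
        """Per-pixel weights on a centred 2D grid; shells beyond the table
        and frequencies below 1/``low_res_cutoff`` Å⁻¹ get weight 0."""
        radius = shell_radius_grid(shape)
        shells = np.floor(radius).astype(int)
        g = np.zeros(shape)
        valid = shells < len(self.g)
        g[valid] = self.g[shells[valid]]
        n = shape[0]
        g[shells > n // 2] = 0.0
        if low_res_cutoff and low_res_cutoff > 0:
            freq = radius / (n * pixel_size)
            g[freq < 1.0 / low_res_cutoff] = 0.0
        return g


def correlation_objective(theta: CtfParams, x_ft: FourierGrid, v_ft: FourierGrid,
                          weights: FrequencyWeights) -> float:
    """Σ_k g_k · CTF(θ, k) · Re(V*_k X_k) for a single particle."""
    if x_ft.shape != v_ft.shape:
        raise ValueError(f"image/reference dims differ: {x_ft.shape} vs {v_ft.shape}")
    g = weights.pixel_weights(x_ft.shape, x_ft.pixel_size)
    cross = (np.conj(v_ft.values) * x_ft.values).real
    ctf = ctf_grid(theta, x_ft.shape, x_ft.pixel_size)
    return float(np.sum(g * ctf * cross))


# ---------------------------------------------------------------------------
# internal fast path
# ---------------------------------------------------------------------------


class _ParticleTerms:
    """Pixel-wise pieces of the objective for one particle, flattened to the
    pixels with non-zero weight."""

    def __init__(self, image: np.ndarray, v_vals: np.ndarray, params: CtfParams,
                 g: np.ndarray, kx: np.ndarray, ky: np.ndarray):
        mask = g > 0
        x_vals = fft_centered(image)
        self.g = g[mask]
        self.cross = (np.conj(v_vals[mask]) * x_vals[mask]).real
        self.kx = kx[mask]
        self.ky = ky[mask]
        self.k2 = self.kx**2 + self.ky**2
        self.phi_k = np.arctan2(self.ky, self.kx)
        self.params = params
        # ψ(δ0) = base + δ0 · mult, holding the other parameters fixed
        self.mult = np.pi * params.lam * self.k2
        self.base = (np.pi * params.lam * params.delta_a
                     * np.cos(2.0 * (self.phi_k - params.phi_a)) * self.k2
                     + 0.5 * np.pi * params.cs_angstrom * params.lam**3 * self.k2**2
                     - params.chi)

    def score_defocus(self, delta0) -> np.ndarray:
        """Objective at one or many trial δ0 (vectorised)."""
        d = np.atleast_1d(np.asarray(delta0, dtype=float))
        psi = self.base[None, :] + d[:, None] * self.mult[None, :]
        vals = (self.g * self.cross)[None, :] * (-np.sin(psi))
        out = vals.sum(axis=1)
        return out if np.ndim(delta0) else float(out[0])

    def score_params(self, params: CtfParams) -> float:
        psi = lens_phase(params, self.kx, self.ky)
        return float(np.sum(self.g * self.cross * (-np.sin(psi))))


def _prepare_references(halfmaps: dict, pad_factor: int) -> dict:
    return {key: volume_to_fourier(vol, pad_factor) for key, vol in halfmaps.items()}


def _particle_terms(images, table, refs, weights, pixel_size):
    box = images.shape[-1]
    g = weights.pixel_weights((box, box), pixel_size)
    ky, kx = freq_grids_2d((box, box), pixel_size)
    terms = []
    for i, (_, row) in enumerate(table.iterrows()):
        half = int(row.get(pt.HALF_SET, 1))
        if half not in refs:
            raise ValueError(f"particle {i} references missing half-map {half}")
        v = project_volume(refs[half], pt.orientation_from_row(row), box)
        terms.append(_ParticleTerms(images[i], v.values, pt.ctf_from_row(row), g, kx, ky))
    return terms


def refine_particle_defocus(images: np.ndarray, table: pd.DataFrame, halfmaps: dict,
                            weights: FrequencyWeights, search_range: float = 2500.0,
                            pixel_size: float | None = None,
                            pad_factor: int = 2) -> pd.DataFrame:
    """Re-estimate the average defocus δ0 of every particle independently.

    For each particle the objective is scanned on a coarse grid of 201
    points across ±``search_range`` Å around the current δ0 and the best
    point polished by bounded scalar minimisation; astigmatism and all
    other parameters are untouched.  A ``_abScoreChange`` column records
    the objective improvement per particle.  ``halfmaps`` maps half-set id
    → reference VolumeGrid; each particle only ever reads the half-map of
    its own half-set.
    """
    if pixel_size is None:
        pixel_size = next(iter(halfmaps.values())).pixel_size
    out = table.copy()
    out[SCORE_CHANGE] = 0.0
    if search_range <= 0:
        return out
    refs = _prepare_references(halfmaps, pad_factor)
    terms = _particle_terms(images, table, refs, weights, pixel_size)
    grid_offsets = np.linspace(-search_range, search_range, 201)
    step = grid_offsets[1] - grid_offsets[0]
    for i, (idx, row) in enumerate(table.iterrows()):
        term = terms[i]
        d0 = term.params.delta0
        cand = d0 + grid_offsets
        scores = term.score_defocus(cand)
        best = cand[int(np.argmax(scores))]
        res = optimize.minimize_scalar(
            lambda d: -term.score_defocus(d),
            bounds=(max(best - step, d0 - search_range),
                    min(best + step, d0 + search_range)),
            method="bounded", options={"xatol": 0.5},
        )
        new_d0 = float(res.x) if -res.fun >= scores.max() else best
        pt.set_defocus(out, idx, term.params.with_defocus(new_d0))
        out.loc[idx, SCORE_CHANGE] = term.score_defocus(new_d0) - term.score_defocus(d0)
    return out


def _joint_refine(terms, params0: CtfParams, scope: RefinementScope,
                  defocus_range: float) -> CtfParams:
    """Joint coarse-grid + Nelder-Mead fit of the scoped parameters for one
    group of particles (astigmatism parameterised as a1 = δA cos 2φA,
    a2 = δA sin 2φA so the search space is smooth and unique)."""
    fit_d0 = scope.delta0 != "fixed"
    fit_astig = scope.astigmatism != "fixed"
    fit_chi = scope.chi != "fixed"
    fit_cs = scope.cs != "fixed"

    def build(vec) -> CtfParams:
        j = 0
        d0 = params0.delta0
        a1 = params0.delta_a * np.cos(2 * params0.phi_a)
        a2 = params0.delta_a * np.sin(2 * params0.phi_a)
        chi = params0.chi
        cs = params0.cs_mm
        if fit_d0:
            d0 = vec[j]; j += 1
        if fit_astig:
            a1, a2 = vec[j], vec[j + 1]; j += 2
        if fit_chi:
            chi = vec[j]; j += 1
        if fit_cs:
            cs = vec[j]; j += 1
        delta_a = float(np.hypot(a1, a2))
        phi_a = 0.5 * np.arctan2(a2, a1)
        return CtfParams(delta0=d0, delta_a=delta_a, phi_a=phi_a,
                         cs_mm=cs, chi=chi, lam=params0.lam)

    def objective(vec) -> float:
        p = build(vec)
        return -sum(t.score_params(p) for t in terms)

    x0 = []
    if fit_d0:
        x0.append(params0.delta0)
    if fit_astig:
        x0 += [params0.delta_a * np.cos(2 * params0.phi_a),
               params0.delta_a * np.sin(2 * params0.phi_a)]
    if fit_chi:
        x0.append(params0.chi)
    if fit_cs:
        x0.append(params0.cs_mm)
    x0 = np.array(x0, dtype=float)

    # coarse grid over δ0 (the most oscillatory direction), then simplex
    starts = [x0]
    if fit_d0:
        for off in np.linspace(-defocus_range, defocus_range, 21):
            s = x0.copy()
            s[0] = params0.delta0 + off
            starts.append(s)
    best_x, best_f = x0, objective(x0)
    for s in starts:
        f = objective(s)
        if f < best_f:
            best_x, best_f = s, f
    res = optimize.minimize(objective, best_x, method="Nelder-Mead",
                            options={"xatol": 0.05, "fatol": 1e-12, "maxiter": 4000})
    x_final = res.x if res.fun <= best_f else best_x
    return build(x_final)


def refine_micrograph_params(images: np.ndarray, table: pd.DataFrame, halfmaps: dict,
                             weights: FrequencyWeights, scope: RefinementScope,
                             defocus_range: float = 2000.0,
                             pixel_size: float | None = None,
                             pad_factor: int = 2):
    """Jointly re-estimate the scoped CTF parameters of one micrograph.

    Per-micrograph parameters maximise the objective summed over all the
    micrograph's particles; per-particle parameters are fitted from each
    particle's own single term, making the estimate independent of how
    many particles the micrograph holds.  Returns ``(table, params)``
    where ``params`` is the fitted per-micrograph parameter set (taken
    from the first particle when everything is per-particle).
    """
    if len(table) == 0:
        raise ValueError("micrograph has no particles")
    if pixel_size is None:
        pixel_size = next(iter(halfmaps.values())).pixel_size
    refs = _prepare_references(halfmaps, pad_factor)
    terms = _particle_terms(images, table, refs, weights, pixel_size)
    out = table.copy()
    per_particle = (scope.delta0 == "per_particle"
                    or scope.astigmatism == "per_particle")
    fitted = None
    if per_particle:
        for i, (idx, _) in enumerate(table.iterrows()):
            p = _joint_refine([terms[i]], terms[i].params, scope, defocus_range)
            pt.set_defocus(out, idx, p)
            if fitted is None:
                fitted = p
    else:
        fitted = _joint_refine(terms, terms[0].params, scope, defocus_range)
        for idx in table.index:
            pt.set_defocus(out, idx, fitted)
    return out, fitted


def diagnostic_spectra(images: np.ndarray, table: pd.DataFrame, halfmaps: dict,
                       pixel_size: float | None = None,
                       pad_factor: int = 2) -> pd.DataFrame:
    """Ring statistics of the cross term Σ_p Re(V*_k X_k) and of the power
    spectrum Σ_p |X_k|².

    The cross term is centred around zero under pure noise, so no
    background intensity needs to be modelled — unlike the power spectrum,
    whose Thon rings sit on an unknown rising background.  Returns a table
    with per-shell mean and standard deviation of both quantities.
    """
    if len(table) == 0:
        raise ValueError("need at least one particle")
    if pixel_size is None:
        pixel_size = next(iter(halfmaps.values())).pixel_size
    refs = _prepare_references(halfmaps, pad_factor)
    box = images.shape[-1]
    cross_sum = np.zeros((box, box))
    power_sum = np.zeros((box, box))
    for i, (_, row) in enumerate(table.iterrows()):
        half = int(row.get(pt.HALF_SET, 1))
        v = project_volume(refs[half], pt.orientation_from_row(row), box)
        x_vals = fft_centered(images[i])
        cross_sum += (np.conj(v.values) * x_vals).real
        power_sum += np.abs(x_vals) ** 2
    shells = np.floor(shell_radius_grid((box, box))).astype(int)
    smax = box // 2
    rows = []
    for s in range(smax + 1):
        ring = shells == s
        n_pix = int(ring.sum())
        rows.append({
            "shell": s,
            "freq": s / (box * pixel_size),
            "n_pixels": n_pix,
            "cross_mean": float(cross_sum[ring].mean()) if n_pix else np.nan,
            "cross_std": float(cross_sum[ring].std()) if n_pix else np.nan,
            "power_mean": float(power_sum[ring].mean()) if n_pix else np.nan,
            "power_std": float(power_sum[ring].std()) if n_pix else np.nan,
        })
    return pd.DataFrame(rows)
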