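"""Reference-based CTF refinement: objective, recovery, scopes, hygiene."""

import numpy as np
import pandas as pd
import pytest

import aberro.ctf_refine as cr
from aberro import particles as pt
from aberro.ctf import CtfParams, lens_phase
from aberro.ctf_refine import (FrequencyWeights, RefinementScope,
                               correlation_objective, diagnostic_spectra,
                               refine_micrograph_params, refine_particle_defocus)
from aberro.fourier_core import Orientation, project_volume, volume_to_fourier
from aberro.grids import FourierGrid, fft_centered, freq_grids_2d, shell_radius_grid
from aberro.simulate import TRUE_DEFOCUS, SimulationConfig, simulate_stack

BOX, PIX = 64, 1.5


def _start_table(table, base=3000.0):
    start = table.copy()
    start[pt.DEFOCUS_U] = base
    start[pt.DEFOCUS_V] = base
    start[pt.DEFOCUS_ANGLE] = 0.0
    return start


@pytest.fixture(scope="module")
def weights():
    return FrequencyWeights.flat(BOX // 2 + 1)


@pytest.fixture(scope="module")
def noiseless(phantom64):
    cfg = SimulationConfig(seed=11, box=BOX, pixel_size=PIX, n_particles=8,
                           defocus_base=3000.0, defocus_spread=1500.0, snr=None)
    return simulate_stack(phantom64, cfg)


@pytest.fixture(scope="module")
def noisy(phantom64):
    cfg = SimulationConfig(seed=11, box=BOX, pixel_size=PIX, n_particles=24,
                           defocus_base=3000.0, defocus_spread=1500.0, snr=0.1)
    return simulate_stack(phantom64, cfg)


class TestObjective:
    def test_noiseless_brute_force_scan_peaks_near_true_defocus(self, phantom64):
        """X = CTF(θ⁰)·V: the objective over a δ0 grid peaks at δ0⁰."""
        vft = volume_to_fourier(phantom64, 2)
        ori = Orientation(rot=70, tilt=55, psi=10)
        v = project_volume(vft, ori, BOX)
        true = 3200.0
        ky, kx = freq_grids_2d((BOX, BOX), PIX)
        ctf_true = -np.sin(lens_phase(CtfParams(delta0=true), kx, ky))
        x = FourierGrid(ctf_true * v.values, PIX)
        g = FrequencyWeights.flat(BOX // 2 + 1)
        grid = np.arange(true - 2500.0, true + 2500.0 + 1, 10.0)
        scores = [correlation_objective(CtfParams(delta0=d), x, v, g) for d in grid]
        assert abs(grid[int(np.argmax(scores))] - true) <= 30.0

    def test_zero_weights_give_zero_score(self, phantom64, rng):
        vft = volume_to_fourier(phantom64, 2)
        v = project_volume(vft, Orientation(), BOX)
        x = FourierGrid(rng.normal(size=(BOX, BOX)) + 0j, PIX)
        g = FrequencyWeights(np.zeros(BOX // 2 + 1))
        assert correlation_objective(CtfParams(delta0=3000.0), x, v, g) == 0.0

    def test_linear_in_image(self, phantom64, rng):
        vft = volume_to_fourier(phantom64, 2)
        v = project_volume(vft, Orientation(rot=30), BOX)
        x = FourierGrid(fft_centered(rng.normal(size=(BOX, BOX))), PIX)
        x2 = FourierGrid(2.0 * x.values, PIX)
        g = FrequencyWeights.flat(BOX // 2 + 1)
        theta = CtfParams(delta0=2500.0)
        assert correlation_objective(theta, x2, v, g) == pytest.approx(
            2.0 * correlation_objective(theta, x, v, g), rel=1e-9)


class TestFrequencyWeights:
    def test_from_fsc_clamps_and_zeros_beyond_crossing(self):
        fsc_table = pd.DataFrame({
            "shell": range(8),
            "fsc": [1.0, 0.9, 1.1, 0.5, 0.3, 0.1, 0.4, -0.2],
        })
        g = FrequencyWeights.from_fsc(fsc_table).g
        np.testing.assert_allclose(g, [1.0, 0.9, 1.0, 0.5, 0.3, 0, 0, 0])

    def test_low_resolution_cutoff_excluded(self):
        g = FrequencyWeights.flat(17).pixel_weights((32, 32), 1.5)
        radius = shell_radius_grid((32, 32))
        freq = radius / (32 * 1.5)
        assert np.all(g[freq < 1.0 / 40.0] == 0.0)
        assert np.all(g[(freq >= 1.0 / 40.0) & (radius <= 16)] == 1.0)


class TestDefocusRefinement:
    def test_noiseless_recovery_within_one_coarse_step(self, phantom64, noiseless,
                                                       weights):
        stack, table = noiseless
        refined = refine_particle_defocus(stack, _start_table(table),
                                          {1: phantom64, 2: phantom64}, weights)
        rec = 0.5 * (refined[pt.DEFOCUS_U] + refined[pt.DEFOCUS_V]).to_numpy()
        err = np.abs(rec - table[TRUE_DEFOCUS].to_numpy())
        assert err.max() < 25.0  # one coarse grid step

    def test_noisy_recovery_median_error(self, phantom64, noisy, weights):
        """Injected uniform ±1500 Å offsets at SNR 0.1, ±2500 Å search:
        median recovery error well under 60 Å."""
        stack, table = noisy
        refined = refine_particle_defocus(stack, _start_table(table),
                                          {1: phantom64, 2: phantom64}, weights,
                                          search_range=2500.0)
        rec = 0.5 * (refined[pt.DEFOCUS_U] + refined[pt.DEFOCUS_V]).to_numpy()
        err = np.abs(rec - table[TRUE_DEFOCUS].to_numpy())
        assert np.median(err) < 60.0

    def test_zero_search_range_returns_table_unchanged(self, phantom64, noiseless,
                                                       weights):
        stack, table = noiseless
        start = _start_table(table)
        out = refine_particle_defocus(stack, start, {1: phantom64, 2: phantom64},
                                      weights, search_range=0.0)
        np.testing.assert_allclose(out[pt.DEFOCUS_U], start[pt.DEFOCUS_U])

    def test_objective_never_decreases(self, phantom64, noisy, weights):
        stack, table = noisy
        refined = refine_particle_defocus(stack, _start_table(table),
                                          {1: phantom64, 2: phantom64}, weights)
        assert np.all(refined[cr.SCORE_CHANGE].to_numpy() >= -1e-9)

    def test_missing_halfmap_rejected(self, phantom64, noiseless, weights):
        stack, table = noiseless
        with pytest.raises(ValueError, match="half-map"):
            refine_particle_defocus(stack, _start_table(table), {1: phantom64},
                                    weights)

    def test_half_set_hygiene(self, phantom64, noisy, weights, monkeypatch):
        """Refining particle p only ever reads the half-map of p's own
        half-set (instrumented reference lookup)."""
        stack, table = noisy

        class Recorder(dict):
            accesses: list = []

            def __getitem__(self, key):
                Recorder.accesses.append(key)
                return super().__getitem__(key)

        original = cr._prepare_references

        def patched(halfmaps, pad_factor):
            return Recorder(original(halfmaps, pad_factor))

        monkeypatch.setattr(cr, "_prepare_references", patched)
        Recorder.accesses = []
        refine_particle_defocus(stack, _start_table(table),
                                {1: phantom64, 2: phantom64}, weights)
        assert Recorder.accesses == [int(h) for h in table[pt.HALF_SET]]

    def test_no_systematic_defocus_drift(self, phantom64, weights):
        """Signed recovery errors average out: |bias| < 10 Å on the
        seeded SNR-0.1 simulation."""
        cfg = SimulationConfig(seed=11, box=BOX, pixel_size=PIX, n_particles=48,
                               defocus_base=3000.0, defocus_spread=1500.0,
                               snr=0.1)
        stack, table = simulate_stack(phantom64, cfg)
        refined = refine_particle_defocus(stack, _start_table(table),
                                          {1: phantom64, 2: phantom64}, weights,
                                          search_range=2500.0)
        rec = 0.5 * (refined[pt.DEFOCUS_U] + refined[pt.DEFOCUS_V]).to_numpy()
        bias = np.mean(rec - table[TRUE_DEFOCUS].to_numpy())
        assert abs(bias) < 10.0

    def test_rmse_decreases_with_snr(self, phantom64, weights):
        rmses = []
        for snr in (0.05, 0.1, 0.5):
            cfg = SimulationConfig(seed=11, box=BOX, pixel_size=PIX,
                                   n_particles=24, defocus_base=3000.0,
                                   defocus_spread=1500.0, snr=snr)
            stack, table = simulate_stack(phantom64, cfg)
            refined = refine_particle_defocus(stack, _start_table(table),
                                              {1: phantom64, 2: phantom64}, weights)
            rec = 0.5 * (refined[pt.DEFOCUS_U] + refined[pt.DEFOCUS_V]).to_numpy()
            err = rec - table[TRUE_DEFOCUS].to_numpy()
            rmses.append(np.sqrt(np.mean(err**2)))
        assert rmses[0] > rmses[1] > rmses[2]


class TestMicrographRefinement:
    def test_common_astigmatism_recovered(self, phantom64, weights):
        cfg = SimulationConfig(seed=21, box=BOX, pixel_size=PIX, n_particles=10,
                               defocus_base=3000.0, defocus_spread=300.0,
                               astigmatism=(300.0, 30.0), snr=None)
        stack, table = simulate_stack(phantom64, cfg)
        scope = RefinementScope(delta0="per_micrograph",
                                astigmatism="per_micrograph")
        _, fitted = refine_micrograph_params(stack, _start_table(table),
                                             {1: phantom64, 2: phantom64},
                                             weights, scope, defocus_range=1000.0)
        assert fitted.delta_a == pytest.approx(300.0, abs=10.0)
        assert np.degrees(fitted.phi_a) == pytest.approx(30.0, abs=2.0)

    def test_all_fixed_scope_rejected(self):
        with pytest.raises(ValueError, match="fixed"):
            RefinementScope(delta0="fixed", astigmatism="fixed",
                            cs="fixed", chi="fixed")

    def test_per_particle_estimate_independent_of_other_particles(
            self, phantom64, noiseless, weights):
        """Per-particle scope sums a single term, so the estimate cannot
        depend on how many particles share the micrograph."""
        stack, table = noiseless
        scope = RefinementScope(delta0="per_particle")
        few, _ = refine_micrograph_params(stack[:1], _start_table(table.iloc[:1]),
                                          {1: phantom64, 2: phantom64}, weights,
                                          scope, defocus_range=500.0)
        many, _ = refine_micrograph_params(stack[:4], _start_table(table.iloc[:4]),
                                           {1: phantom64, 2: phantom64}, weights,
                                           scope, defocus_range=500.0)
        assert few[pt.DEFOCUS_U].iloc[0] == pytest.approx(
            many[pt.DEFOCUS_U].iloc[0], abs=1.0)

    def test_empty_micrograph_rejected(self, phantom64, weights):
        scope = RefinementScope(delta0="per_micrograph")
        with pytest.raises(ValueError, match="no particles"):
            refine_micrograph_params(np.zeros((0, BOX, BOX)),
                                     pd.DataFrame(), {1: phantom64}, weights, scope)


class TestOracleEquivalence:
    def test_correlation_maximiser_close_to_squared_difference_minimiser(
            self, phantom64, noiseless, weights):
        """The squared-difference objective is exactly unbiased on
        noiseless data; the correlation objective omits its norm term and
        may differ by a few tens of Å when the reference spectrum is not
        flat.  Both brute-force scans must agree closely."""
        stack, table = noiseless
        vft = volume_to_fourier(phantom64, 2)
        g = weights.pixel_weights((BOX, BOX), PIX)
        ky, kx = freq_grids_2d((BOX, BOX), PIX)
        mask = g > 0
        for i in (0, 3, 5):
            row = table.iloc[i]
            v = project_volume(vft, pt.orientation_from_row(row), BOX).values
            x = fft_centered(stack[i])
            true = row[TRUE_DEFOCUS]
            grid = np.arange(true - 500.0, true + 500.0 + 1, 10.0)
            e2, e3 = [], []
            for d in grid:
                ctf = -np.sin(lens_phase(CtfParams(delta0=d), kx, ky))
                e2.append(np.sum(g[mask] * np.abs(x[mask] - ctf[mask] * v[mask]) ** 2))
                e3.append(np.sum(g[mask] * ctf[mask] * (np.conj(v[mask]) * x[mask]).real))
            d2 = grid[int(np.argmin(e2))]
            d3 = grid[int(np.argmax(e3))]
            assert abs(d2 - true) <= 10.0  # squared difference: exact oracle
            assert abs(d3 - d2) <= 50.0


class TestDiagnosticSpectra:
    def test_pure_noise_cross_term_centred_on_zero(self, phantom64, rng):
        """Under pure noise the cross term needs no background model: its
        ring means sit around zero."""
        stack = rng.normal(size=(12, BOX, BOX))
        cfg = SimulationConfig(seed=33, box=BOX, pixel_size=PIX, n_particles=12)
        _, table = simulate_stack(phantom64, cfg)
        diag = diagnostic_spectra(stack, table, {1: phantom64, 2: phantom64})
        sub = diag[(diag["shell"] > 1) & (diag["n_pixels"] > 8)]
        z = np.abs(sub["cross_mean"]) / (sub["cross_std"] / np.sqrt(sub["n_pixels"]))
        assert np.mean(z < 3.0) >= 0.9

    def test_noiseless_cross_term_matches_ctf_weighted_power(self, phantom64,
                                                             noiseless):
        """X = CTF·V: cross-term rings equal ring averages of CTF·|V|²,
        oscillating with the CTF sign."""
        stack, table = noiseless
        diag = diagnostic_spectra(stack[:1], table.iloc[:1],
                                  {1: phantom64, 2: phantom64})
        vft = volume_to_fourier(phantom64, 2)
        row = table.iloc[0]
        v = project_volume(vft, pt.orientation_from_row(row), BOX).values
        ky, kx = freq_grids_2d((BOX, BOX), PIX)
        ctf = -np.sin(lens_phase(pt.ctf_from_row(row), kx, ky))
        oracle = ctf * np.abs(v) ** 2
        shells = np.floor(shell_radius_grid((BOX, BOX))).astype(int)
        for s in range(2, BOX // 2, 5):
            expected = oracle[shells == s].mean()
            got = diag.loc[diag["shell"] == s, "cross_mean"].iloc[0]
            assert got == pytest.approx(expected, rel=2e-2, abs=1e-3 * np.abs(oracle).max())

    def test_power_spectrum_non_negative(self, phantom64, noisy):
        stack, table = noisy
        diag = diagnostic_spectra(stack, table, {1: phantom64, 2: phantom64})
        assert np.all(diag["power_mean"].dropna() >= 0.0)
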