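# aberro

Aberration refinement and preprocessing for cryo-EM single-particle
analysis: reference-based **per-particle CTF refinement**, **beam-tilt
(axial coma) estimation and correction**, **single-side-band Ewald
sphere correction**, and **Laplacian-of-Gaussian autopicking** — built
as a self-contained library plus CLI and validated end-to-end on
synthetic data with known ground truth.

## Who this is for

Cryo-EM method developers and practitioners who want the
aberration-correction stages of a single-particle pipeline as small,
inspectable, testable Python — each algorithm exposed as a plain
function over numpy arrays and pandas tables, with MRC2014 and STAR
files at the boundaries and a generator that fabricates every input
(phantom volumes, aberrated particle stacks, blob-planted micrographs)
so that each stage can be checked against the value that was injected.

## The models

**CTF refinement.** With the viewing geometry known, the reference
projection V_p of particle p is compared against its image X_p, and the
CTF parameters θ = {δ0, δA, φA, Cs, χ} are re-estimated by maximising
the FSC-weighted correlation

    θ = argmax_θ' Σ_k g_k · CTF(θ',k) · Σ_p Re(V*_{p,k} X_{p,k}),

where CTF(k) = −sin(πλ(δ0 + δA cos 2(φk−φA))|k|² + (π/2)Csλ³|k|⁴ − χ)
and g_k come from the gold-standard half-map FSC.  Defocus δ0 can float
per particle — the cross term is evaluated against the half-map of the
particle's own half-set, so the gold-standard split stays intact.

**Beam tilt.** A tilt b (mrad) adds the antisymmetric coma phase
φ(b,k) = 2π Cs λ² ⟨k,b⟩ |k|².  Per-pixel complex phase averages
q_k = Σ_j X_{j,k}V*_{j,k} / Σ_j|V_{j,k}|² are accumulated in one pass,
then b = argmin_β Σ_k w_k |e^{iφ(β,k)} − q_k|² by Nelder–Mead with a
coarse-grid start; `phase_plot` exposes arg(q_k) so the coma signature
can be inspected before the fit is trusted.

**Ewald correction.** Each particle transform is split into side-bands
with CTF_P = e^{+i(ψ+π/2)}, CTF_Q = e^{−i(ψ+π/2)} (sector-rotated
dividing line, real-space masking) and every pixel is inserted off the
central section at Δz* = (λ/2)|k|², with a `--reverse_curvature` option
because mirroring during acquisition makes the true direction unknown.
Curvature limits resolution at k* = √(1.4/(d·λ)) for particle
diameter d.

**LoG picking.** Eleven scale-normalised band-pass filters
R(ω) = (ω²/σ²)e^{−ω²/2σ²}, σ = 2/d span a particle-diameter range
(four below, four above, three in-range); candidates are picked greedily
at the best remaining response, deleting a circle of the best-responding
diameter around each pick, with the threshold normalised by the mean and
standard deviation of the in-range responses.

## Worked example

Simulate a stack with per-particle defocus spread and a known beam tilt,
then recover both and reconstruct:

```python
import numpy as np
from aberro import (SimulationConfig, make_phantom, simulate_stack,
                    FrequencyWeights, refine_particle_defocus, estimate_tilt,
                    reconstruct, fsc, resolution_at, ewald_limit,
                    wavelength_from_voltage)
from aberro import particles as pt
from aberro.simulate import TRUE_DEFOCUS

phantom = make_phantom(box=64, pixel_size=1.5, n_blobs=14, seed=7)
config = SimulationConfig(seed=11, box=64, pixel_size=1.5, n_particles=120,
                          defocus_base=3000.0, defocus_spread=1500.0,
                          beam_tilt=(0.3, -0.1), snr=0.1)
stack, truth = simulate_stack(phantom, config)

start = truth.copy()
start[pt.DEFOCUS_U] = config.defocus_base   # forget the per-particle truth
start[pt.DEFOCUS_V] = config.defocus_base
weights = FrequencyWeights.flat(33)
refined = refine_particle_defocus(stack, start, {1: phantom, 2: phantom},
                                  weights, search_range=2500.0)
err = np.abs(0.5 * (refined[pt.DEFOCUS_U] + refined[pt.DEFOCUS_V])
             - truth[TRUE_DEFOCUS])
print(f"median defocus error: {np.median(err):.1f} A")

tilt, residual, _ = estimate_tilt(stack, refined, {1: phantom, 2: phantom})
print(f"beam tilt: ({tilt.bx:+.3f}, {tilt.by:+.3f}) mrad")

volume = reconstruct(stack, refined, pixel_size=1.5, mode="plain")
half1 = (refined[pt.HALF_SET] == 1).to_numpy()
v1 = reconstruct(stack[half1], refined[refined[pt.HALF_SET] == 1], 1.5)
v2 = reconstruct(stack[~half1], refined[refined[pt.HALF_SET] == 2], 1.5)
res = resolution_at(fsc(v1, v2))
print(f"half-map resolution (FSC 0.143): {res.resolution:.1f} A")

print(f"Ewald limit, 700 A particle at 300 kV: "
      f"{ewald_limit(700.0, wavelength_from_voltage(300.0)):.1f} A")
```

prints

```
median defocus error: 14.8 A
beam tilt: (+0.293, -0.105) mrad
half-map resolution (FSC 0.143): 9.6 A
Ewald limit, 700 A particle at 300 kV: 3.1 A
```

The refinement was started from the micrograph-average defocus, 1500 Å
wrong for the extreme particles, and recovers the injected per-particle
values to ~15 Å median at a signal-to-noise power ratio of 0.1; the
injected (0.3, −0.1) mrad tilt comes back to ~0.01 mrad; the gold-standard
half-map FSC of the 120-particle reconstruction crosses 0.143 at 9.6 Å
(a desk-scale stack — resolution here is particle-number limited); and
the closed-form Ewald curvature limit for a 700 Å particle at 300 kV is
3.1 Å.

The same steps are available from the shell:

```sh
aberro simulate --seed 11 --o run/
aberro pick --i run/micrographs.star --d-min 120 --d-max 180 --o run/coords/
aberro ctf-refine --i run/truth.star --images run/images.mrcs \
    --ref-half1 run/phantom.mrc --ref-half2 run/phantom.mrc --o run/refined.star
aberro fit-tilt --i run/refined.star --images run/images.mrcs \
    --ref-half1 run/phantom.mrc --ref-half2 run/phantom.mrc --o run/tilt.star
aberro reconstruct --i run/refined.star --images run/images.mrcs --o run/map.mrc
```

plus `fsc`, `bfactor-fit` (Rosenthal–Henderson 1/d² vs ln N fitting,
B = 2/slope) and `dedupe` (drop particles translated within 30 Å of a
retained neighbour, protecting the gold-standard split).

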