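# Methods

`aberro` implements four post-picking/pre-sharpening steps of a cryo-EM
single-particle pipeline — reference-based CTF refinement, beam-tilt
estimation and correction, single-side-band Ewald sphere correction, and
Laplacian-of-Gaussian (LoG) autopicking — together with the Fourier-slice
projection/reconstruction machinery, file I/O and the synthetic-data
generator used to validate them against known ground truth.  This note
records the models, the conventions, the parameters that matter, and the
limits of what the synthetic validation shows.

## Conventions

* **Units.** Lengths in Å, frequencies in Å⁻¹, angles in degrees at API
  boundaries (radians internally), spherical aberration Cs in mm on all
  interfaces (Å internally), beam tilt in mrad (radians internally).
* **Transforms.** Real and Fourier grids are both centred: the origin sits
  at index `n//2` of every axis (`ifftshift` → FFT → `fftshift`).  The
  forward transform is un-normalised and the inverse divides by N; a
  round trip is the identity and Parseval holds with a 1/N factor.
* **Geometry.** Euler angles (rot, tilt, psi) in ZYZ convention;
  A = Rz(psi)·Ry(tilt)·Rz(rot) maps reference-frame to projection-frame
  coordinates, and a slice pixel (kx, ky, 0) sits at Aᵀ·(kx, ky, 0) in the
  reference transform.  In-plane shifts are Fourier phase ramps with the
  sign convention that a particle displaced by +s carries e^{-2πi k·s}.
* **STAR dialect.** Coordinates are 0-based pixel positions of the
  particle centre.  Defocus is stored as defocusU = δ0+δA,
  defocusV = δ0−δA, angle = φA in degrees; the astigmatism pair is
  canonicalised to δA ≥ 0, φA ∈ [0, π), exploiting the degeneracy
  (δA, φA) ≡ (−δA, φA+π/2).
* **MRC.** MRC2014, mode 2 (float32) written; modes 0/1/2/6 read; pixel
  size = cell/sampling.

## CTF model

CTF(k) = −sin(πλ(δ0 + δA cos 2(φk − φA))|k|² + (π/2)Cs λ³|k|⁴ − χ), with
positive δ0 = underfocus (the first zero moves to lower |k| as δ0 grows —
asserted in tests).  χ combines the amplitude-contrast fraction A as
χ = atan(A/√(1−A²)) plus any phase-plate shift; default A = 0.1.  The sine
is a pure phase-shift reading — no √(1−A²) amplitude renormalisation, no
envelope or B-factor attenuation inside the CTF.  The electron wavelength
is the relativistic de Broglie formula (300 kV → 0.019687 Å).

## Reference-based CTF refinement

With known viewing geometry, the reference projection V_p of particle p is
compared with its image X_p and the CTF parameters are re-estimated by
maximising the FSC-weighted correlation

θ = argmax_θ' Σ_k g_k · CTF(θ', k) · Σ_p Re(V*_{p,k} X_{p,k}).

The per-shell weights g_k come from the gold-standard half-map FSC,
clamped to [0, 1] and zeroed beyond the first 0.143 crossing; frequencies
below 1/40 Å⁻¹ are excluded (the two half-maps share their lowest
frequencies).  Half-set hygiene is strict: V_p always comes from the
half-map of p's own half-set, so per-particle parameters cannot launder
noise across the gold-standard split.

**Optimisation.** Per-particle defocus: a 201-point coarse grid over
±search_range (default ±2500 Å) followed by bounded scalar polish
(absolute tolerance 0.5 Å).  Joint scopes (per-micrograph defocus,
astigmatism, χ, Cs): astigmatism is reparameterised as
(a1, a2) = δA(cos 2φA, sin 2φA), which makes the search space smooth and
removes the representation degeneracy; a coarse defocus grid seeds a
Nelder–Mead simplex.

**A property worth knowing.** The correlation objective omits the
trial-dependent norm Σ g CTF(θ')²|V|² that the squared-difference
objective Σ g (X − CTF·V)² carries.  The two therefore agree exactly only
when that norm is independent of θ' — in practice, when the reference
spectrum is roughly flat across the fitted band and several CTF cycles
fall inside it.  On references with steeply decaying spectra the
correlation maximiser acquires a systematic offset of a few tens of Å.
The synthetic phantom is therefore texture-dominated (below), matching the
regime in which real macromolecular references put the objective; under
those conditions the measured defocus bias is under 10 Å and the median
per-particle error at SNR 0.1 is ~13 Å against the 60 Å validation bound.

**Diagnostics.** The per-shell statistics of Σ_p Re(V*_k X_k) are exposed
alongside the plain power spectrum: the cross term is centred on zero
under pure noise, so CTF oscillations are visible without modelling a
background — the motivation for fitting images against a reference rather
than fitting Thon rings in power spectra.

## Beam-tilt estimation

A tilted beam induces axial coma, the antisymmetric per-frequency phase
error φ(b, k) = 2π Cs λ² ⟨k, b⟩ |k|².  Because phases are cyclic, the
per-pixel phase difference between images and CTF-modulated reference
projections is averaged as a complex quantity in one pass over the data:

q_k = Σ_j X_{j,k} V*_{j,k} / Σ_j |V_{j,k}|²,  w_k = Σ_j |V_{j,k}|²,

and b minimises Σ_k w_k |e^{iφ(b,k)} − q_k|².  The fit runs Nelder–Mead
from β = 0 and from the best point of an 11×11 coarse grid (±1 mrad by
default), converging at a 1e−4 mrad simplex tolerance — the coarse start
guards against the multimodality that phase wrapping causes for large
tilts (the complex formulation recovers tilts whose coma phase exceeds π,
where naive angle averaging fails; tested).  The phase map arg(q_k) is
exposed for visual inspection: genuine beam tilt shows an antisymmetric
signature, and fitting without looking risks fitting noise or higher-order
antisymmetric aberrations (trefoil is out of scope).  Per-tilt-group
estimation simply repeats accumulate+fit per group.  Half-set separation
is not required for this stage, but each particle is still referenced
against its own half-map.

## Ewald sphere correction

At high resolution or large particle diameter, the scattered wave samples
the 3D transform on a sphere, not a plane.  The single-side-band scheme
multiplies each particle transform by the unit-modulus pair
CTF_P = e^{+i(ψ+π/2)}, CTF_Q = e^{−i(ψ+π/2)} (ψ the lens phase; π/2 the
scattering phase), whose real average reproduces the ordinary CTF.  The
multiplication is applied per half-plane and assembled over `n_sectors`
rotations of the dividing line (default 2), choosing per pixel the
rotation whose edge is farthest away; each assembled side-band is
back-transformed, masked with a soft circular real-space mask
(raised-cosine edge of 6 px beyond mask_diameter/2, default diameter
0.9 × box) and transformed back.

**Insertion.** Each Fourier pixel is inserted off the central section at
Δz* = (λ/2)|k|² along the beam axis with unit weight.  Because the
assembled side-band transform carries the CTF_P product on one side of
the dividing line and the CTF_Q product on the other, the displacement is
applied with a per-pixel sign (side × curvature): that places every pixel
on the Ewald hemisphere it coherently samples, and is the full-plane
equivalent of inserting a Hermitian half-stored transform at a single
signed displacement.  `--reverse_curvature` flips all signs; flipping
twice is exactly the identity.  The curvature limit for a particle of
diameter d is k* = sqrt(1.4/(d·λ)) — 3.1 Å for a 700 Å particle at
300 kV.

## LoG autopicking

Micrographs are mean-subtracted, contrast-inverted (particles dark by
convention; `--no-invert` for the opposite), and filtered with the
scale-normalised band-pass R(ω) = (ω²/σ²)·exp(−ω²/(2σ²)), σ = 2/d, where
ω = 2π|k| is angular frequency — the pairing under which the filter
peaks for real-space structure of extent ~d and its peak response is
independent of d (the normalisation that makes one threshold meaningful
across scales).  Eleven filters cover a particle-diameter range
[d_min, d_max]: {d_min/n} and {n·d_max} for n = 2..5 absorb too-small and
too-large contamination, plus the three in-range scales d_min, midpoint,
d_max.  Per pixel the best response and its scale are kept; candidates
must have an in-range best scale and a response above threshold; picking
is greedy at the highest remaining response, deleting a circle of
diameter d_best (boundary inclusive) around each pick.  The default
threshold is the mean of the in-range best responses and user offsets are
in units of their standard deviation.  Ties in the global maximum break
in row-major order, so output is deterministic.  Filtering runs at native
sampling (no internal down-sampling).

## Reconstruction and FSC

Slice insertion spreads weight·value into `data` and weight² into
`weights` trilinearly on a pad_factor-oversampled grid (default 2;
pad_factor 1 is exposed for skipped-padding workflows); plain
reconstruction uses signed-CTF weighting (data += CTF·X, weights += CTF²),
Ewald mode unit weights.  Finalisation divides by max(weights, ε) with
ε = 1e−3 × the mean positive weight — a floor that bounds voxels the
sampling barely touched — then inverse-transforms and crops.  There are
no gridding-kernel corrections beyond the weights division; the
projection/back-projection consistency this buys is ~0.97–0.99 per ring
at pad 2, which the tests assert explicitly.  FSC uses integer-radius
shells ([s, s+1) grid units); resolution is the linearly interpolated
first crossing below the threshold (default 0.143), with a
Nyquist-limited flag when no crossing exists.

## Synthetic data: what it emulates, what it does not

`make_phantom` builds a particle as a handful of soft Gaussian blobs
confined to a known support diameter plus a granular texture —
near-white noise (0.5 px smoothing against interpolation aliasing)
masked to the same support, with RMS twice the blob RMS.  The texture is
the point: real protein density at 2–4 Å is dominated by atomic-scale
contrast, and without high-frequency power the CTF band beyond the first
zero carries no signal and reference-based refinement has nothing to fit.

`simulate_stack` draws uniform orientations, applies the forward CTF (or
the two-side-band Ewald forward model, whose flat-sphere limit reduces
exactly to CTF multiplication), the coma phase for an injected beam
tilt, and white Gaussian real-space noise scaled to a target
signal-to-noise power ratio.  The tilted-stage geometry assigns each
particle an x-position across a configurable field of view and a defocus
base + x·tan(stage tilt) — a 40° tilt across a 4800 Å field spans ~4000 Å
of height, the regime where per-particle defocus refinement matters.
`simulate_micrograph` plants dark Gaussian blobs (σ = d/2, the width the
LoG bank matches at nominal scale d) at known, separation-constrained
coordinates.

Default study conditions: 64-px boxes at 1.5 Å/px, 300 kV, Cs 2.7 mm,
amplitude contrast 0.1, defocus 3000 ± 1500 Å (kept below the CTF
aliasing limit of the 64-px box), SNR 0.1 for recovery tests.  The
curvature-discrimination benchmark instead uses an exaggerated wavelength
(1.25 kV → λ ≈ 0.35 Å, with Cs 0 and ~50 Å defocus to keep the CTF
sampled) so that the curvature limit of a 45 Å phantom falls at shell ~19
of a 64-px box — a desk-scale analogue of a 700 Å capsid at 1.54 Å/px,
where the correct curvature direction holds FSC ≈ 0.85 beyond the limit
shell while the reverse direction collapses to noise.

What passing these tests does **not** show about real data: the noise is
white and Gaussian (no structured solvent/ice background, no detector
DQE, no dose-dependent damage), orientations and shifts are known exactly
(no alignment error feeding into the aberration fits), magnification is
exact, and micrographs contain only particles and noise (no carbon edges
or contamination, which the out-of-range LoG scales can only partially
absorb).  Recovery bounds measured here are therefore best-case floors,
not field performance.

## Numerical choices and degenerate inputs

* Defocus scan step = search_range/100; polish tolerance 0.5 Å; simplex
  tolerances 0.05 (CTF joint fit) and 1e−4 mrad (tilt fit).
* The unpaired Nyquist row/column of even-sized grids is left untouched
  by the beam-tilt phase factor so that real images stay exactly real.
* Empty accumulators, all-zero tilt weights, all-fixed refinement scopes,
  empty micrograph tables, non-cubic references, inverted diameter
  ranges, non-positive physical quantities: validation errors.  Empty
  tilt groups are skipped with a logged warning.  A constant micrograph
  yields zero LoG response and no candidates.
* Duplicate removal is a greedy pass in table order (earlier record
  wins), per micrograph, on shift-updated centres; default threshold
  30 Å.
* B-factor fitting is unweighted least squares of 1/d² on ln N;
  B = 2/slope, the convention under which 1/d² gains 2/B per e-fold of
  particles.  Predictions at 2×/4×/8× the largest subset extrapolate the
  fitted line.

## Known limitations

Trilinear gridding without kernel correction slightly attenuates high
shells; no per-shell noise regularisation or phase-randomised mask
correction in FSC; no magnification refinement; no higher-order
antisymmetric aberrations (trefoil); the picker has no neural or
template mode; reconstruction offers no symmetry expansion.  The CLI
holds no logic of its own — every command is a thin shell over the
functions documented above.
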