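"""Reference-free particle picking with a multi-scale Laplacian-of-Gaussian bank.

A micrograph is filtered with a scale-normalised LoG band-pass

    R(|k|) = (|k|²/σ²) · exp(-|k|²/(2σ²)),   σ = 2/d,

which gives its optimum response for blobs of diameter d (Å).  The
division by σ² outside the exponential normalises the peak response so
that filters for different d are comparable.

Eleven filters span the user's particle diameter range [d_min, d_max]:
four below it (d_min/n, n = 2..5), four above it (n·d_max, n = 2..5), and
three in range (d_min, the midpoint, d_max).  Per pixel, the strongest
response over the bank (LoG_best) and its scale (d_best) are kept; pixels
whose d_best falls outside [d_min, d_max] are rejected — the out-of-range
filters exist to absorb contamination that is too small or too large to
be a particle.

Candidates are then picked greedily at the highest remaining LoG_best,
deleting all pixels within a circle of diameter d_best around each pick.
The default threshold is the mean of the in-range LoG_best values, and a
user offset is expressed in standard deviations of those same values, so
the threshold scale transfers across data sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import ImageGrid, fft_centered, freq_grids_2d, ifft_centered

__all__ = ["PickCandidate", "FilterScale", "log_filter", "build_filter_bank", "pick"]


@dataclass
class PickCandidate:
    """One picked blob: centre (px, 0-based), response and best scale (Å)."""

    x: float
    y: float
    log_best: float
    d_best: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log_best):
            raise ValueError("log_best must be finite")
        if not self.d_best > 0:
            raise ValueError("d_best must be > 0")


@dataclass(frozen=True)
class FilterScale:
    d: float  # blob diameter, Å
    in_range: bool  # within [d_min, d_max]?


def log_filter(micrograph: ImageGrid, d: float) -> ImageGrid:
    """Scale-normalised LoG response map for blob diameter ``d`` (Å).

    The response is real and mean-free (R(0) = 0 removes the DC term).
    Raises a validation error if ``d`` is below the 2-pixel sampling
    limit.
    """
    if not d > 2.0 * micrograph.pixel_size:
        raise ValueError(
            f"blob diameter {d} Å is too small for pixel size "
            f"{micrograph.pixel_size} Å/px (needs d > 2·pixel_size)"
        )
    ky, kx = freq_grids_2d(micrograph.shape, micrograph.pixel_size)
    # σ = 2/d pairs with angular frequency ω = 2π|k| (rad/Å): the band
    # then peaks for real-space structure of extent ~d, as intended
    w2 = (2.0 * np.pi) ** 2 * (kx * kx + ky * ky)
    sigma = 2.0 / d
    response = (w2 / sigma**2) * np.exp(-w2 / (2.0 * sigma**2))
    ft = fft_centered(micrograph.data)
    filtered = ifft_centered(ft * response).real
    return ImageGrid(filtered, micrograph.pixel_size)


def build_filter_bank(d_min: float, d_max: float) -> list:
    """The eleven LoG scales for a particle diameter range (Å).

    {d_min/n : n = 2..5} ∪ {n·d_max : n = 2..5} ∪
    {d_min, (d_min+d_max)/2, d_max}; only the last three are flagged
    in-range.
    """
    if not 0 < d_min <= d_max:
        raise ValueError(f"need 0 < d_min <= d_max, got ({d_min}, {d_max})")
    scales = [FilterScale(d_min / n, False) for n in (2, 3, 4, 5)]
    scales += [FilterScale(n * d_max, False) for n in (2, 3, 4, 5)]
    scales += [
        FilterScale(d_min, True),
        FilterScale(0.5 * (d_min + d_max), True),
        FilterScale(d_max, True),
    ]
    return scales


def pick(micrograph: ImageGrid, d_min: float, d_max: float,
         threshold_sd: float = 0.0, invert_contrast: bool = True) -> list:
    """Pick blob candidates from one micrograph.

    The micrograph is mean-subtracted and (by default) contrast-inverted,
    so that the conventional dark-on-bright particles give positive
    responses; pass ``invert_contrast=False`` for negative-stain-like
    contrast.  ``threshold_sd`` offsets the default threshold in units of
    the standard deviation of the in-range LoG_best values; lowering it
    never decreases the number of candidates.
    """
    if micrograph.data.size == 0:
        return []
    data = micrograph.data.astype(float)
    data = data - data.mean()
    if invert_contrast:
        data = -data
    work = ImageGrid(data, micrograph.pixel_size)

    scales = build_filter_bank(d_min, d_max)
    log_best = np.full(micrograph.shape, -np.inf)
    d_best = np.zeros(micrograph.shape)
    in_range_best = np.zeros(micrograph.shape, dtype=bool)
    for scale in scales:
        if not scale.in_range and scale.d <= 2.0 * micrograph.pixel_size:
            # sub-Nyquist junk-absorber scale: nothing to detect at this
            # sampling, skip it rather than reject the whole micrograph
            continue
        resp = log_filter(work, scale.d).data
        better = resp > log_best
        log_best[better] = resp[better]
        d_best[better] = scale.d
        in_range_best[better] = scale.in_range

    if not in_range_best.any():
        return []
    vals = log_best[in_range_best]
    threshold = vals.mean() + threshold_sd * vals.std()

    candidates_mask = in_range_best & (log_best > threshold)
    picks: list[PickCandidate] = []
    ny, nx = micrograph.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    # greedy: global max, delete a circle of diameter d_best, repeat
    masked = np.where(candidates_mask, log_best, -np.inf)
    while True:
        flat = np.argmax(masked)  # row-major order breaks ties deterministically
        iy, ix = np.unravel_index(flat, masked.shape)
        if not np.isfinite(masked[iy, ix]):
            break
        d = d_best[iy, ix]
        picks.append(PickCandidate(float(ix), float(iy), float(log_best[iy, ix]), float(d)))
        radius_px = 0.5 * d / micrograph.pixel_size
        circle = (yy - iy) ** 2 + (xx - ix) ** 2 <= radius_px**2
        masked[circle] = -np.inf
        masked[iy, ix] = -np.inf
    return picks
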