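"""Small numerical utilities around refinement: Rosenthal-Henderson
B-factor fitting and duplicate-particle removal.

The B-factor plot relates achievable resolution d to particle number N:
1/d² grows linearly with ln N, with slope 2/B.  Fitting a line to
(ln N, 1/d²) points from refinements of nested random subsets therefore
estimates the overall B-factor of a data set and extrapolates how many
more particles a target resolution would need.

Duplicate removal guards gold-standard separation: two records of the
same physical particle (for example after refined shifts pulled picks
onto one another) can end up in different half-sets and inflate the FSC,
so particles translated within a minimum distance of a retained
neighbour are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import particles as pt

__all__ = ["BfactorFit", "bfactor_fit", "remove_duplicates"]


@dataclass
class BfactorFit:
    b_factor: float  # Å²
    slope: float  # d⁻² gain per ln N
    intercept: float
    predictions: dict  # {multiple of n_max: predicted resolution Å}


def bfactor_fit(points) -> BfactorFit:
    """Least-squares line through (ln N, 1/d²) points.

    ``points`` is a sequence of (n_particles, resolution_Å) pairs with at
    least two distinct N.  B = 2/slope (a B-factor of B Å² halves 1/d²
    gains per e-fold of particles); resolutions at 2×/4×/8× the largest N
    are predicted by extrapolating the fitted line.
    """
    pts = [(float(n), float(d)) for n, d in points]
    if len(pts) < 2:
        raise ValueError("need at least two (n, resolution) points")
    ns = np.array([p[0] for p in pts])
    ds = np.array([p[1] for p in pts])
    if np.unique(ns).size < 2:
        raise ValueError("all particle counts are equal; the slope is undefined")
    if np.any(ns <= 0) or np.any(ds <= 0):
        raise ValueError("particle counts and resolutions must be positive")
    x = np.log(ns)
    y = 1.0 / ds**2
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError(
            "fitted slope is non-positive; resolution does not improve with N"
        )
    b = 2.0 / slope
    n_max = ns.max()
    predictions = {}
    for mult in (2, 4, 8):
        y_pred = intercept + slope * np.log(mult * n_max)
        predictions[mult] = float(1.0 / np.sqrt(y_pred))
    return BfactorFit(float(b), float(slope), float(intercept), predictions)


def remove_duplicates(table: pd.DataFrame, min_distance: float = 30.0,
                      pixel_size: float = 1.0, use_shifts: bool = True):
    """Drop particles whose (shift-updated) centre lies within
    ``min_distance`` Å of a retained particle's centre.

    A single greedy pass in table order keeps the earlier record, so the
    result is deterministic.  Particles on different micrographs never
    suppress each other.  Returns ``(filtered table, n_removed)``.
    """
    if min_distance < 0:
        raise ValueError(f"min_distance must be >= 0, got {min_distance}")
    x = table[pt.COORD_X].to_numpy(dtype=float) * pixel_size
    y = table[pt.COORD_Y].to_numpy(dtype=float) * pixel_size
    if use_shifts and pt.SHIFT_X in table.columns:
        x = x + table[pt.SHIFT_X].to_numpy(dtype=float)
        y = y + table[pt.SHIFT_Y].to_numpy(dtype=float)
    if pt.MICROGRAPH in table.columns:
        mics = table[pt.MICROGRAPH].to_numpy()
    else:
        mics = np.zeros(len(table))
    keep = []
    kept_by_mic: dict = {}
    for i in range(len(table)):
        retained = kept_by_mic.setdefault(mics[i], [])
        ok = True
        for j in retained:
            if (x[i] - x[j]) ** 2 + (y[i] - y[j]) ** 2 < min_distance**2:
                ok = False
                break
        if ok:
            retained.append(i)
            keep.append(i)
    filtered = table.iloc[keep].copy()
    return filtered, len(table) - len(filtered)
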