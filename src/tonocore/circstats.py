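"""Circular statistics for gradient directions and ROI orientations.

Directional data (gradient directions) live on (-180, 180]; axial data
(long-axis orientations) live on [0, 180) and are processed by angle
doubling.  Confidence intervals for the mean direction use the
Upton/Zar construction (the one implemented by the CircStat toolbox):
with mean resultant length r and R = n r,

    t = sqrt(2 n (2 R^2 - n chi2) / (4 n - chi2))        (r < 0.9)
    t = sqrt(n^2 - (n^2 - R^2) exp(chi2 / n))            (r >= 0.9)

with chi2 the (level) quantile of chi-square(1); the half-width is
arccos(t / R), undefined (flagged NaN) when the sample is too diffuse
(r below sqrt(chi2 / 2n)).

Across-hemisphere consistency of 2D gradient vectors is tested
pixelwise with a one-sample Hotelling T^2 test against zero,
FDR-adjusted over the responsive mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fdr import fdr_reject
from .gradients import VectorField, smooth_map_or_field

__all__ = [
    "circ_mean_ci",
    "axial_mean_ci",
    "hotelling_t2",
    "consistency_map",
    "ConsistencyResult",
]


def _resultant(rad: np.ndarray, weights=None):
    w = np.ones_like(rad) if weights is None else np.asarray(weights, float)
    C = np.sum(w * np.cos(rad)) / w.sum()
    S = np.sum(w * np.sin(rad)) / w.sum()
    return np.hypot(C, S), np.arctan2(S, C)


def circ_mean_ci(angles_deg, level: float = 0.95, weights=None):
    """Circular mean and CI half-width (deg) of directional angles.

    Returns (mean_deg in (-180, 180], halfwidth_deg); the half-width is
    NaN (flagged undefined) when the sample is too dispersed for the
    large-sample construction (argument of asin outside [0, 1]).
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 angles")
    rad = np.deg2rad(a)
    r, mu = _resultant(rad, weights)
    n = a.size
    R = n * r
    chi2 = stats.chi2.ppf(level, 1)
    if r >= 0.9:
        t2 = n * n - (n * n - R * R) * np.exp(chi2 / n)
    elif r > np.sqrt(chi2 / (2.0 * n)):
        t2 = 2.0 * n * (2.0 * R * R - n * chi2) / (4.0 * n - chi2)
    else:
        t2 = -1.0     # too diffuse: CI undefined
    if t2 >= 0 and np.sqrt(t2) / R <= 1.0:
        half = float(np.rad2deg(np.arccos(np.sqrt(t2) / R)))
    else:
        half = float("nan")
    mean = np.rad2deg(mu)
    if mean <= -180.0:
        mean += 360.0
    return float(mean), half


def axial_mean_ci(orientations_deg, level: float = 0.95, weights=None):
    """Axial mean and CI half-width (deg in [0, 180)) via angle doubling."""
    a = np.asarray(orientations_deg, dtype=float)
    mean2, half2 = circ_mean_ci(2.0 * a, level, weights)
    mean = (mean2 / 2.0) % 180.0
    return float(mean), float(half2 / 2.0)


def hotelling_t2(vectors: np.ndarray):
    """One-sample Hotelling T^2 test of n 2D vectors against zero.

    T^2 = n * xbar' S^-1 xbar with S the sample covariance;
    p from F = ((n - 2) / (2 (n - 1))) * T^2 on (2, n - 2) dof.
    """
    x = np.asarray(vectors, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("expected an (n, 2) array")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 vectors")
    xbar = x.mean(axis=0)
    S = np.cov(x, rowvar=False)
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    if not np.isfinite(det) or abs(det) < 1e-300:
        raise ValueError("singular sample covariance (degenerate sample)")
    Sinv = np.array([[S[1, 1], -S[0, 1]], [-S[1, 0], S[0, 0]]]) / det
    t2 = float(n * xbar @ Sinv @ xbar)
    F = (n - 2) / (2.0 * (n - 1)) * t2
    p = float(stats.f.sf(F, 2, n - 2))
    return t2, p


@dataclass
class ConsistencyResult:
    t2: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    n_valid: np.ndarray


def consistency_map(
    fields: list,
    responsive_mask: np.ndarray,
    smoothing_fwhm_mm: float = 3.0,
    q: float = 0.05,
    adaptive: bool = True,
) -> ConsistencyResult:
    """Pixelwise Hotelling consistency test over a cohort of HG-frame-
    aligned vector fields sharing one grid.

    Each field is smoothed along the surface first (smoothing raises
    power; the test without smoothing is available with fwhm 0), then
    each pixel's n vectors are tested against zero and the p-values are
    FDR-adjusted over the responsive mask.  Pixels with fewer than 3
    valid hemispheres are excluded.
    """
    if len(fields) < 3:
        raise ValueError("need at least 3 hemispheres")
    sm = [smooth_map_or_field(f, smoothing_fwhm_mm, f.pixel_mm) for f in fields]
    vx = np.stack([f.vx for f in sm])
    vy = np.stack([f.vy for f in sm])
    ok = np.stack([f.mask for f in sm])
    n_valid = ok.sum(axis=0)
    shape = responsive_mask.shape
    t2 = np.full(shape, np.nan)
    p = np.full(shape, np.nan)
    test_px = responsive_mask & (n_valid >= 3)
    rr, cc = np.nonzero(test_px)
    for r, c in zip(rr, cc):
        sel = ok[:, r, c]
        vecs = np.column_stack([vx[sel, r, c], vy[sel, r, c]])
        try:
            t2[r, c], p[r, c] = hotelling_t2(vecs)
        except ValueError:
            continue
    significant = np.zeros(shape, dtype=bool)
    significant[test_px] = fdr_reject(p[test_px], q=q, adaptive=adaptive)
    return ConsistencyResult(t2=t2, p=p, significant=significant, n_valid=n_valid)
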