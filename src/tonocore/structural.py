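"""Structural (myelin-sensitive) map processing.

MTR is computed voxelwise as (M0 - MSAT) / M0.  Myelin-sensitive maps
(PSIR, MTR) correlate with cortical curvature and thickness and, absent
a direct B1-error measurement, with a proton-density proxy; these
nuisance covariates are regressed out per cortical depth by OLS, with
the fitted intercept added back so maps keep their interpretable mean
level for thresholding.  Depth handling follows the 11-depth sampling
convention (0 = gray/white border, 1 = pial): group maps average the
middle 5 depths (0.3-0.7) and are minimally smoothed (2-mm FWHM).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gradients import smooth_map_or_field
from .synth import DEPTHS

__all__ = ["mtr", "residualize", "depth_average", "depth_profile"]


def mtr(m0_map: np.ndarray, msat_map: np.ndarray) -> np.ndarray:
    """Magnetization transfer ratio (M0 - MSAT) / M0; NaN where M0 <= 0."""
    m0 = np.asarray(m0_map, dtype=float)
    msat = np.asarray(msat_map, dtype=float)
    out = np.full(m0.shape, np.nan)
    ok = m0 > 0
    out[ok] = (m0[ok] - msat[ok]) / m0[ok]
    return out


def residualize(stack: np.ndarray, covariates: dict, mask: np.ndarray):
    """Regress nuisance covariates out of each depth's map over the mask.

    ``stack`` is (n_depths, rows, cols); ``covariates`` maps names to
    per-pixel 2D arrays (PD proxy, curvature, thickness, ...).  Per
    depth, the map is fitted by OLS on the covariates plus an intercept;
    the output is residual + fitted intercept (the mask mean level is
    preserved).  Returns (residualized stack, per-depth R^2 array).

    Collinear covariates raise an error naming the offending pair.
    """
    stack = np.asarray(stack, dtype=float)
    names = list(covariates)
    if len(names) < 1:
        raise ValueError("need at least one covariate")
    cols = [np.asarray(covariates[k], dtype=float)[mask] for k in names]
    X = np.column_stack(cols)
    # collinearity check on the centred, scaled covariates
    Xc = X - X.mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    if np.any(norms == 0):
        k = names[int(np.argmin(norms))]
        raise ValueError(f"covariate {k!r} is constant over the mask")
    corr = (Xc / norms).T @ (Xc / norms)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1.0 - 1e-10:
                raise ValueError(
                    f"collinear covariates: {names[i]!r} and {names[j]!r}")
    # centred covariates: the fitted intercept is then the mask mean, so
    # adding it back preserves the map's mean level
    A = np.column_stack([Xc, np.ones(X.shape[0])])

    out = stack.copy()
    r2 = np.zeros(stack.shape[0])
    for d in range(stack.shape[0]):
        y = stack[d][mask]
        ok = np.isfinite(y)
        coef, *_ = np.linalg.lstsq(A[ok], y[ok], rcond=None)
        fitted = A @ coef
        resid = y - fitted
        tot = np.sum((y[ok] - y[ok].mean()) ** 2)
        r2[d] = 0.0 if tot == 0 else 1.0 - np.sum(resid[ok] ** 2) / tot
        plane = np.full(stack.shape[1:], np.nan)
        plane[mask] = resid + coef[-1]
        out[d] = np.where(mask, plane, stack[d])
    return out, r2


def depth_average(stack: np.ndarray, depth_range=(0.3, 0.7),
                  smoothing_fwhm_mm: float = 0.0, pixel_mm: float = 0.33,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean over the depths within ``depth_range`` (inclusive),
    optionally followed by minimal (default 2-mm when requested) surface
    smoothing."""
    stack = np.asarray(stack, dtype=float)
    sel = (DEPTHS >= depth_range[0] - 1e-9) & (DEPTHS <= depth_range[1] + 1e-9)
    if not sel.any():
        raise ValueError("no depths inside the requested range")
    out = stack[sel].mean(axis=0)
    if smoothing_fwhm_mm > 0:
        out = smooth_map_or_field(out, smoothing_fwhm_mm, pixel_mm, mask)
    return out


def depth_profile(stacks, roi: np.ndarray) -> pd.DataFrame:
    """ROI-mean value at each cortical depth.

    ``stacks`` is one (n_depths, rows, cols) array or a cohort list of
    them; the cohort version reports the across-hemisphere mean and SE.
    """
    if not roi.any():
        raise ValueError("empty ROI")
    if isinstance(stacks, np.ndarray) and stacks.ndim == 3:
        stacks = [stacks]
    per_hemi = np.array([[np.nanmean(s[d][roi]) for d in range(len(DEPTHS))]
                         for s in stacks])
    mean = per_hemi.mean(axis=0)
    se = (per_hemi.std(axis=0, ddof=1) / np.sqrt(len(stacks))
          if len(stacks) > 1 else np.full(len(DEPTHS), np.nan))
    return pd.DataFrame({"depth": DEPTHS, "mean": mean, "se": se})
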