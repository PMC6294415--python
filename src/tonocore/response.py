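"""Per-voxel response estimation from sparse-fMRI trial series.

Each acquisition in the sparse protocol (TR = 7.5 s) follows one trial:
one of 7 narrowband-noise frequencies or silence.  Runs are high-pass
filtered (discrete-cosine drift basis, 0.01 Hz cutoff, mean preserved),
converted to percent signal change about the run average, concatenated,
and fitted with an ordinary-least-squares GLM with one indicator
regressor per stimulus frequency plus per-run intercepts (silence is
the baseline, so each beta is a sound-versus-silence contrast in a
balanced design).  Auditory-responsive voxels are selected by an F-test
of all 7 contrasts jointly, FDR-corrected with the shared adaptive
step-up routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fdr import fdr_reject

__all__ = [
    "TrialTable",
    "BetaSet",
    "preprocess",
    "fit_glm",
    "sound_f_test",
    "select_responsive",
]

N_FREQS = 7
HIGHPASS_HZ = 0.01


@dataclass(frozen=True)
class TrialTable:
    """Trial conditions: -1 = silence, 0..6 = stimulus frequency index."""

    condition: np.ndarray
    run: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.condition)
        r = np.asarray(self.run)
        if c.shape != r.shape:
            raise ValueError("condition and run must have the same length")
        if not np.any(c == -1):
            raise ValueError("silence trials are required")

    def __len__(self):
        return len(self.condition)

    def design(self) -> np.ndarray:
        """Indicator design: 7 frequency columns then one intercept per run."""
        c = np.asarray(self.condition)
        runs = np.unique(self.run)
        X = np.zeros((len(c), N_FREQS + len(runs)))
        for i in range(N_FREQS):
            X[:, i] = c == i
        for j, r in enumerate(runs):
            X[:, N_FREQS + j] = np.asarray(self.run) == r
        return X


@dataclass
class BetaSet:
    """GLM results: per-voxel betas, residual variance and dof, and the
    unscaled covariance of the 7 frequency betas (identity for emulated
    single-beta noise)."""

    beta: np.ndarray          # (..., 7)
    sigma2: np.ndarray        # (...,)
    dof: int
    cov_unscaled: np.ndarray | None = None   # (7, 7); None means identity


def _dct_drift_basis(n: int, tr_s: float, cutoff_hz: float = HIGHPASS_HZ) -> np.ndarray:
    """Discrete-cosine drift regressors below the cutoff (constant excluded)."""
    order = int(np.floor(2.0 * n * tr_s * cutoff_hz))
    t = np.arange(n)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2.0 * n)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n, 0))


def preprocess(series: np.ndarray, run: np.ndarray, tr_s: float = 7.5):
    """High-pass filter, percent-signal-change conversion, concatenation.

    ``series`` is (n_voxels, n_timepoints) (a single voxel may be passed
    as 1D); ``run`` labels each timepoint.  Per run, slow drifts below
    0.01 Hz are projected out on a discrete-cosine basis (mean
    retained), then the series is expressed as percent change relative
    to its run average.  Voxels whose run average is not positive are
    flagged invalid (NaN output).

    Returns (processed, valid) where valid marks voxels with defined
    percent change in every run.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    run = np.asarray(run)
    out = np.empty_like(series)
    valid = np.ones(series.shape[0], dtype=bool)
    for r in np.unique(run):
        sel = run == r
        x = series[:, sel]
        drift = _dct_drift_basis(sel.sum(), tr_s)
        if drift.shape[1]:
            coef, *_ = np.linalg.lstsq(drift, x.T, rcond=None)
            x = x - (drift @ coef).T
        mean = x.mean(axis=1, keepdims=True)
        ok = mean[:, 0] > 0
        valid &= ok
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, sel] = 100.0 * (x - mean) / mean
    out[~valid] = np.nan
    return out, valid


def fit_glm(series: np.ndarray, trials: TrialTable) -> BetaSet:
    """Voxelwise OLS fit of the 7-regressor indicator GLM."""
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[1] != len(trials):
        raise ValueError("series length must equal the number of trials")
    X = trials.design()
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        present = set(np.unique(trials.condition))
        missing = [f"freq_{i + 1}" for i in range(N_FREQS) if i not in present]
        raise ValueError("rank-deficient design; missing conditions: "
                         + (", ".join(missing) or "<collinear intercepts>"))
    coef, _, _, _ = np.linalg.lstsq(X, series.T, rcond=None)
    fitted = X @ coef
    resid = series.T - fitted
    dof = series.shape[1] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    return BetaSet(beta=coef.T[:, :N_FREQS], sigma2=sigma2, dof=dof,
                   cov_unscaled=xtx_inv[:N_FREQS, :N_FREQS])


def sound_f_test(betas: BetaSet):
    """F-test of the joint null beta_1 = ... = beta_7 = 0.

    Returns (F, p) with reference distribution F(7, dof).
    """
    if betas.dof <= 0:
        raise ValueError("residual dof must be positive")
    b = np.asarray(betas.beta, dtype=float)
    if betas.cov_unscaled is None:
        quad = (b ** 2).sum(axis=-1)
    else:
        m = np.linalg.inv(betas.cov_unscaled)
        quad = np.einsum("...i,ij,...j->...", b, m, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = quad / (N_FREQS * betas.sigma2)
    p = stats.f.sf(F, N_FREQS, betas.dof)
    return F, p


def select_responsive(p_map: np.ndarray, q: float = 0.05,
                      candidate_mask: np.ndarray | None = None,
                      adaptive: bool = True) -> np.ndarray:
    """FDR voxel selection over the candidate mask (default: finite p)."""
    p_map = np.asarray(p_map, dtype=float)
    if candidate_mask is None:
        candidate_mask = np.isfinite(p_map)
    out = np.zeros(p_map.shape, dtype=bool)
    if not candidate_mask.any():
        import warnings

        warnings.warn("empty candidate mask: nothing selected")
        return out
    p = np.where(candidate_mask, p_map, np.nan)
    out[candidate_mask] = fdr_reject(p[candidate_mask], q=q, adaptive=adaptive)
    return out
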