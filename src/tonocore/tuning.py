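"""Voxelwise frequency tuning: centroids, spreads, debiased preferred
frequencies, and tuning-width fitting.

Tuning curves are 7 response amplitudes at the 7 stimulus frequencies,
with frequency expressed on the ERB-number (Cam) scale throughout.

The raw centroid (positive-weighted mean stimulus position) is a biased
preferred-frequency estimator: values at the edges of the stimulus
range can only occur when all other responses are zero, so estimates
are pulled towards the middle of the range.  The debiasing procedure
corrects this by matching each measured curve's (centroid, spread) pair
against a bank of hypothetical Gaussian tuning curves -- modes spanning
the audible range (0 to 16.2 kHz), widths 0.4 to 20 ERB_N -- sampled at
the same 7 stimulus positions; the mode of the best-matching bank entry
(minimum sum of squared differences in centroid and spread, both in
Cam) is the unbiased estimate.  Monotone curves are matched by bank
entries with modes outside the stimulus range, extending the estimate
range beyond the stimuli.

Tuning widths are instead estimated by fitting a 4-parameter Gaussian
(mode, width, height, non-positive baseline offset) to depth-averaged,
spatially smoothed, centroid-recentred curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .scale import DEFAULT_SCALE, STIMULUS_FREQS_HZ
from .gradients import smooth_map_or_field

__all__ = [
    "centroid",
    "spread",
    "GaussianBank",
    "debias",
    "debias_map",
    "preferred_frequency_map",
    "tuning_width",
    "split_half",
    "STIM_CAM",
]

STIM_CAM = DEFAULT_SCALE.hz_to_cam(STIMULUS_FREQS_HZ)

WIDTH_BOUNDS = (0.4, 20.0)


def centroid(beta, freq_cam=STIM_CAM):
    """Positive-weighted tuning-curve centroid C (Cam).

    C = sum(max(beta_i, 0) * F_i) / sum(max(beta_i, 0)); NaN when no
    weight is positive (the voxel is then excluded downstream).
    Broadcasts over leading axes; the last axis indexes the stimuli.
    """
    beta = np.asarray(beta, dtype=float)
    w = np.clip(beta, 0.0, None)
    tot = w.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (w * freq_cam).sum(axis=-1) / tot
    c = np.where(tot > 0, c, np.nan)
    return float(c) if np.ndim(c) == 0 else c


def spread(beta, freq_cam=STIM_CAM, literal: bool = False):
    """Tuning-curve spread S (Cam) about the centroid.

    Default: the positive-weighted standard deviation
    sqrt(sum w_i (F_i - C)^2 / sum w_i) with w_i = max(beta_i, 0).
    ``literal=True`` selects instead the unweighted-numerator form
    S = sum_i (F_i - C)^2 / sum_i w_i, retained as a configurable
    alternative reading.
    """
    beta = np.asarray(beta, dtype=float)
    w = np.clip(beta, 0.0, None)
    tot = w.sum(axis=-1)
    c = centroid(beta, freq_cam)
    dev2 = (freq_cam - np.expand_dims(np.asarray(c), -1)) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        if literal:
            s = dev2.sum(axis=-1) / tot
        else:
            s = np.sqrt((w * dev2).sum(axis=-1) / tot)
    s = np.where(tot > 0, s, np.nan)
    return float(s) if np.ndim(s) == 0 else s


@dataclass
class GaussianBank:
    """Bank of hypothetical Gaussian tuning curves sampled at the stimuli.

    Modes every ``mode_step`` Cam over [0, hz_to_cam(f_max_hz)]; widths
    geometric over WIDTH_BOUNDS.  Each entry stores its (C, S) pair for
    nearest-neighbour matching.
    """

    freq_cam: np.ndarray = None
    mode_step: float = 0.1
    f_max_hz: float = 16200.0
    n_widths: int = 60
    literal_spread: bool = False

    def __post_init__(self):
        if self.freq_cam is None:
            self.freq_cam = STIM_CAM
        cam_max = DEFAULT_SCALE.hz_to_cam(self.f_max_hz)
        n_modes = int(np.floor(cam_max / self.mode_step)) + 1
        modes = np.arange(n_modes) * self.mode_step
        widths = np.geomspace(WIDTH_BOUNDS[0], WIDTH_BOUNDS[1], self.n_widths)
        M, W = np.meshgrid(modes, widths, indexing="ij")
        self.modes = M.ravel()
        self.widths = W.ravel()
        g = np.exp(-((self.freq_cam[None, :] - self.modes[:, None]) ** 2)
                   / (2.0 * self.widths[:, None] ** 2))
        self.curves = g
        self.C = centroid(g, self.freq_cam)
        self.S = spread(g, self.freq_cam, literal=self.literal_spread)
        ok = np.isfinite(self.C) & np.isfinite(self.S)
        if not ok.all():  # pragma: no cover - bank entries are all positive
            self.modes, self.widths = self.modes[ok], self.widths[ok]
            self.curves, self.C, self.S = self.curves[ok], self.C[ok], self.S[ok]
        if self.modes.size == 0:
            raise ValueError("empty bank")
        self._tree = cKDTree(np.column_stack([self.C, self.S]))

    def match(self, C, S):
        """Indices of the bank entries nearest to (C, S) in squared error.

        Vectorised nearest-neighbour lookup; NaN inputs return -1.
        """
        C = np.atleast_1d(np.asarray(C, dtype=float))
        S = np.atleast_1d(np.asarray(S, dtype=float))
        idx = np.full(C.shape, -1, dtype=np.int64)
        ok = np.isfinite(C) & np.isfinite(S)
        if ok.any():
            _, ii = self._tree.query(np.column_stack([C[ok], S[ok]]))
            idx[ok] = ii
        return idx


def debias(beta, bank: GaussianBank) -> float:
    """Unbiased preferred-frequency estimate (Cam) for one tuning curve.

    Returns the mode of the bank entry minimising
    (C - C_b)^2 + (S - S_b)^2; exact ties are broken toward the smaller
    mode, then the smaller width.
    """
    if bank is None or bank.modes.size == 0:
        raise ValueError("empty bank")
    c = centroid(beta, bank.freq_cam)
    s = spread(beta, bank.freq_cam, literal=bank.literal_spread)
    if not (np.isfinite(c) and np.isfinite(s)):
        return float("nan")
    d2 = (bank.C - c) ** 2 + (bank.S - s) ** 2
    best = np.min(d2)
    ties = np.nonzero(d2 <= best)[0]
    order = np.lexsort((bank.widths[ties], bank.modes[ties]))
    return float(bank.modes[ties[order[0]]])


def debias_map(betas: np.ndarray, bank: GaussianBank, mask: np.ndarray) -> np.ndarray:
    """Debiased preferred-frequency maps for a stack of curves.

    ``betas`` has shape (..., 7, rows, cols); returns (..., rows, cols)
    with NaN outside the mask or where the centroid is undefined.
    """
    betas = np.asarray(betas, dtype=float)
    curves = np.moveaxis(betas, -3, -1)           # (..., rows, cols, 7)
    C = centroid(curves, bank.freq_cam)
    S = spread(curves, bank.freq_cam, literal=bank.literal_spread)
    idx = bank.match(C.ravel(), S.ravel()).reshape(C.shape)
    out = np.where(idx >= 0, bank.modes[np.clip(idx, 0, None)], np.nan)
    out = np.where(mask, out, np.nan)
    return out


def preferred_frequency_map(
    betas: np.ndarray,
    bank: GaussianBank,
    mask: np.ndarray,
    depth_range: tuple = (3, 8),
) -> np.ndarray:
    """Debias per depth and average over the middle depths (default
    indices 3..7, i.e. depth fractions 0.3-0.7), with no surface
    smoothing so spatial detail is retained."""
    per_depth = debias_map(betas, bank, mask)
    mid = per_depth[depth_range[0]:depth_range[1]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mid, axis=0)


def _recenter(betas: np.ndarray, freq_cam: np.ndarray) -> np.ndarray:
    """Shift each curve by an integer index so its centroid lands on the
    nearest stimulus position at the centre index; vacated samples are NaN.
    """
    nd, nf = betas.shape[:2]
    curves = np.moveaxis(betas, 1, -1)            # (nd, R, C, 7)
    cen = centroid(curves, freq_cam)
    k = np.argmin(np.abs(freq_cam[None, None, None, :]
                         - cen[..., None]), axis=-1)
    k = np.where(np.isfinite(cen), k, nf // 2)
    shift = (nf // 2) - k                          # move centroid bin to centre
    out = np.full_like(betas, np.nan)
    for s in np.unique(shift):
        sel = shift == s                           # (nd, R, C)
        if s >= 0:
            out[:, s:, :, :][np.broadcast_to(sel[:, None, :, :],
                                             out[:, s:, :, :].shape)] = \
                betas[:, :nf - s, :, :][np.broadcast_to(sel[:, None, :, :],
                                                        out[:, s:, :, :].shape)]
        else:
            out[:, :nf + s, :, :][np.broadcast_to(sel[:, None, :, :],
                                                  out[:, :nf + s, :, :].shape)] = \
                betas[:, -s:, :, :][np.broadcast_to(sel[:, None, :, :],
                                                    out[:, :nf + s, :, :].shape)]
    return out


def _gauss_lls(y, wts, g):
    """Constrained least-squares height/offset for fixed Gaussian shape.

    Minimises sum w (y - h g - b)^2 subject to h >= 0, b <= 0.
    All arrays broadcast with the sample axis last; returns (h, b, sse).
    """
    sw = wts.sum(axis=-1)
    swg = (wts * g).sum(axis=-1)
    swgg = (wts * g * g).sum(axis=-1)
    swy = (wts * y).sum(axis=-1)
    swgy = (wts * g * y).sum(axis=-1)
    det = swgg * sw - swg ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (swgy * sw - swg * swy) / det
        b = (swgg * swy - swg * swgy) / det
        h0 = np.where(swgg > 0, swgy / np.where(swgg > 0, swgg, 1.0), 0.0)
    bad = ~np.isfinite(h) | ~np.isfinite(b) | (b > 0)
    h = np.where(bad, h0, h)
    b = np.where(bad, 0.0, b)
    h = np.clip(h, 0.0, None)
    r = y - h[..., None] * g - b[..., None]
    sse = (wts * r * r).sum(axis=-1)
    return h, b, sse


def tuning_width(
    betas: np.ndarray,
    mask: np.ndarray,
    pixel_mm: float = 0.33,
    smoothing_fwhm_mm: float = 3.0,
    freq_cam: np.ndarray = STIM_CAM,
    return_fit: bool = False,
):
    """Tuning-width map (ERB_N) from per-depth tuning curves.

    Pipeline per pixel: recentre each depth's curve to its centroid
    (integer shift on the stimulus grid; vacated samples missing),
    average over all depths, smooth each aligned sample map with an
    isotropic 2D Gaussian kernel, then fit the 4-parameter Gaussian
    (mode, width, height, offset <= 0) by least squares: a coarse
    (mode, width) grid with closed-form height/offset, polished by
    damped Gauss-Newton.  Degenerate or non-convergent pixels are NaN.
    """
    nd, nf = betas.shape[:2]
    rec = _recenter(betas, freq_cam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        avg = np.nanmean(rec, axis=0)              # (7, R, C)
    smoothed = np.stack([
        smooth_map_or_field(avg[i], smoothing_fwhm_mm, pixel_mm, mask)
        for i in range(nf)
    ])
    y = np.moveaxis(smoothed, 0, -1)               # (R, C, 7)
    wts = np.isfinite(y).astype(float)
    y = np.nan_to_num(y)
    enough = (wts.sum(axis=-1) >= 4) & mask

    x = freq_cam
    grid_m = np.arange(x[0] - 6.0, x[-1] + 6.0 + 1e-9, 1.0)
    grid_s = np.geomspace(WIDTH_BOUNDS[0], WIDTH_BOUNDS[1], 24)
    best_sse = np.full(mask.shape, np.inf)
    # widths initialised to 1 so untouched (off-mask) pixels never divide by 0
    best = [np.zeros(mask.shape), np.ones(mask.shape),
            np.zeros(mask.shape), np.zeros(mask.shape)]  # m, s, h, b
    for m in grid_m:
        for s in grid_s:
            g = np.exp(-((x - m) ** 2) / (2.0 * s * s))
            h, b, sse = _gauss_lls(y, wts, g)
            better = sse < best_sse
            best_sse = np.where(better, sse, best_sse)
            best[0] = np.where(better, m, best[0])
            best[1] = np.where(better, s, best[1])
            best[2] = np.where(better, h, best[2])
            best[3] = np.where(better, b, best[3])
    m_, s_ = best[0], best[1]

    # Levenberg-damped Gauss-Newton polish on (mode, width), with the
    # height/offset pair re-solved in closed form at every step
    lam = np.full(mask.shape, 1e-3)
    for _ in range(400):
        g = np.exp(-((x - m_[..., None]) ** 2) / (2.0 * s_[..., None] ** 2))
        h, b, sse0 = _gauss_lls(y, wts, g)
        r = y - h[..., None] * g - b[..., None]
        dgm = g * (x - m_[..., None]) / s_[..., None] ** 2
        dgs = g * (x - m_[..., None]) ** 2 / s_[..., None] ** 3
        j1 = h[..., None] * dgm
        j2 = h[..., None] * dgs
        a11 = (wts * j1 * j1).sum(axis=-1) + 1e-12
        a12 = (wts * j1 * j2).sum(axis=-1)
        a22 = (wts * j2 * j2).sum(axis=-1) + 1e-12
        g1 = (wts * j1 * r).sum(axis=-1)
        g2 = (wts * j2 * r).sum(axis=-1)
        d11 = a11 * (1.0 + lam)
        d22 = a22 * (1.0 + lam)
        det = d11 * d22 - a12 * a12
        with np.errstate(invalid="ignore", divide="ignore"):
            dm = (d22 * g1 - a12 * g2) / det
            ds = (d11 * g2 - a12 * g1) / det
        dm = np.clip(np.nan_to_num(dm), -3.0, 3.0)
        ds = np.clip(np.nan_to_num(ds), -3.0, 3.0)
        m_try = m_ + dm
        s_try = np.clip(s_ + ds, WIDTH_BOUNDS[0], WIDTH_BOUNDS[1])
        g_try = np.exp(-((x - m_try[..., None]) ** 2) / (2.0 * s_try[..., None] ** 2))
        _, _, sse_try = _gauss_lls(y, wts, g_try)
        accept = sse_try <= sse0
        m_ = np.where(accept, m_try, m_)
        s_ = np.where(accept, s_try, s_)
        lam = np.where(accept, np.maximum(lam / 3.0, 1e-9), lam * 10.0)
        lam = np.minimum(lam, 1e8)
        moved = np.where(accept, np.abs(dm) + np.abs(ds), 0.0)
        if moved.max() < 1e-8:
            break

    g = np.exp(-((x - m_[..., None]) ** 2) / (2.0 * s_[..., None] ** 2))
    h, b, sse = _gauss_lls(y, wts, g)

    # degenerate fits: no usable samples, or essentially flat curves
    ptp = y.max(axis=-1) - y.min(axis=-1)
    scale = np.maximum(np.abs(y).max(axis=-1), 1e-12)
    flat = (h <= 1e-8 * scale) | (ptp <= 1e-10 * scale)
    width = np.where(enough & ~flat, s_, np.nan)
    if return_fit:
        mode = np.where(enough & ~flat, m_, np.nan)
        return width, {"mode": mode, "height": h, "offset": b, "sse": sse}
    return width


def split_half(betas_a, betas_b, bank: GaussianBank, mask: np.ndarray,
               depth_range: tuple = (3, 8)) -> float:
    """Pearson correlation between debiased preferred-frequency maps
    computed from two independent halves of a dataset."""
    pa = preferred_frequency_map(betas_a, bank, mask, depth_range)
    pb = preferred_frequency_map(betas_b, bank, mask, depth_range)
    ok = np.isfinite(pa) & np.isfinite(pb)
    if ok.sum() < 3:
        raise ValueError("fewer than 3 pixels defined in both halves")
    return float(np.corrcoef(pa[ok], pb[ok])[0, 1])
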