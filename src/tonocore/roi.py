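"""HG coordinate frame, core and gradient ROI delineation, and ROI
geometry statistics.

All angles are reported relative to the long axis of Heschl's gyrus
(HG): the HG frame is defined by the HG ROI's pixel centroid (origin)
and the second right-singular vector of the cortical-curvature
gradients within the ROI (curvature gradients point across the gyral
ridge, so the second singular direction runs along it).  Frame
coordinates are (u, v) in mm, u along the axis, v across it; the +v
side is called anterior.  Axial quantities (long axes, reversal
orientations) are handled with angle doubling to avoid the 0/180
wrap-around.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import axial_mean_ci
from .gradients import (ReversalCluster, VectorField, axial_angle_diff,
                        sobel_field)

__all__ = [
    "Frame",
    "RoiStats",
    "OverlapStats",
    "hg_frame",
    "roi_stats",
    "core_roi",
    "gradient_rois",
    "overlap_stats",
    "reversal_orientation",
    "curvature_by_frequency",
]


@dataclass
class Frame:
    origin_rc: tuple            # (row, col), grid coordinates
    axis_deg: float             # axial, [0, 180), CCW from the column axis
    pixel_mm: float = 0.33
    degenerate: bool = False    # near-isotropic curvature gradients

    def to_frame(self, rows, cols):
        """Grid indices -> (u, v) HG-frame coordinates in mm."""
        y = (np.asarray(rows, dtype=float) - self.origin_rc[0]) * self.pixel_mm
        x = (np.asarray(cols, dtype=float) - self.origin_rc[1]) * self.pixel_mm
        th = np.deg2rad(self.axis_deg)
        u = np.cos(th) * x + np.sin(th) * y
        v = -np.sin(th) * x + np.cos(th) * y
        return u, v

    def frame_coords(self, shape):
        rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]),
                             indexing="ij")
        return self.to_frame(rr, cc)

    def rel_direction(self, angle_deg):
        """Directional angle relative to the HG axis, in (-180, 180]."""
        d = (np.asarray(angle_deg, dtype=float) - self.axis_deg) % 360.0
        return np.where(d > 180.0, d - 360.0, d)

    def rel_axial(self, angle_deg):
        """Axial angle relative to the HG axis, in [0, 180)."""
        return (np.asarray(angle_deg, dtype=float) - self.axis_deg) % 180.0


@dataclass
class RoiStats:
    long_axis_deg: float        # axial, relative to HG axis
    centroid_u_mm: float
    centroid_v_mm: float
    area_mm2: float
    mean_gradient_deg: float    # directional, relative to HG axis (NaN if no field)
    axis_stable: bool           # singular values well separated


@dataclass
class OverlapStats:
    overlap_anterior: float
    overlap_posterior: float

    @property
    def overlap_ratio(self) -> float:
        if self.overlap_anterior == 0 and self.overlap_posterior == 0:
            return float("nan")
        if self.overlap_posterior == 0:
            return float("inf")
        return self.overlap_anterior / self.overlap_posterior


def _svd_axis(xy: np.ndarray):
    """First right-singular axis (deg in [0,180)) of centered coordinates
    plus the singular-value ratio s1/s2 (inf for collinear sets)."""
    if len(xy) < 2:
        return 0.0, 1.0
    centered = xy - xy.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    ax = np.rad2deg(np.arctan2(vt[0, 1], vt[0, 0])) % 180.0
    ratio = np.inf if s[1] == 0 else s[0] / s[1]
    return float(ax), float(ratio)


def hg_frame(curvature_map: np.ndarray, hg_roi: np.ndarray,
             pixel_mm: float = 0.33) -> Frame:
    """HG frame from the curvature gradients within the HG ROI.

    The curvature map is differentiated with the Sobel operator; the
    n x 2 matrix of in-ROI gradient vectors is decomposed by SVD and the
    *second* right-singular vector gives the long-axis orientation.
    Near-isotropic gradient distributions (singular-value ratio < 1.05)
    raise a warning and flag the frame degenerate.
    """
    if not hg_roi.any():
        raise ValueError("empty HG ROI")
    fld = sobel_field(curvature_map, np.ones_like(hg_roi, dtype=bool), pixel_mm)
    sel = hg_roi & fld.mask
    g = np.column_stack([fld.vx[sel], fld.vy[sel]])
    _, s, vt = np.linalg.svd(g, full_matrices=False)
    axis = np.rad2deg(np.arctan2(vt[1, 1], vt[1, 0])) % 180.0
    degenerate = bool(s[1] > 0 and s[0] / s[1] < 1.05)
    if degenerate:
        warnings.warn("near-isotropic curvature gradients; HG axis ill-defined")
    rr, cc = np.nonzero(hg_roi)
    return Frame(origin_rc=(rr.mean(), cc.mean()), axis_deg=float(axis),
                 pixel_mm=pixel_mm, degenerate=degenerate)


def roi_stats(roi: np.ndarray, frame: Frame,
              field: VectorField | None = None) -> RoiStats:
    """Long axis, centroid (HG frame), area, and mean gradient direction."""
    if not roi.any():
        raise ValueError("empty ROI")
    rr, cc = np.nonzero(roi)
    xy = np.column_stack([cc, rr]).astype(float) * frame.pixel_mm
    ax, ratio = _svd_axis(xy)
    stable = ratio >= 1.05
    if not stable:
        warnings.warn("ROI nearly isotropic; long-axis orientation unstable")
    u, v = frame.to_frame(rr.mean(), cc.mean())
    area = roi.sum() * frame.pixel_mm ** 2
    mean_dir = float("nan")
    if field is not None:
        sel = roi & field.mask
        sx, sy = field.vx[sel].sum(), field.vy[sel].sum()
        mean_dir = float(frame.rel_direction(np.rad2deg(np.arctan2(sy, sx))))
    return RoiStats(long_axis_deg=float(frame.rel_axial(ax)),
                    centroid_u_mm=float(u), centroid_v_mm=float(v),
                    area_mm2=float(area), mean_gradient_deg=mean_dir,
                    axis_stable=stable)


def core_roi(map2d: np.ndarray, labels: dict, polarity: str,
             responsive_mask: np.ndarray, alternative: bool = False,
             largest_component_only: bool = False) -> np.ndarray:
    """Core delineation by individualized thresholding.

    The criterion is set midway between the map average within the
    TE1.0 ROI and within the union of the anterior and posterior
    non-core ROIs (``alternative=True`` uses the union of all three TE1
    areas instead).  ``polarity`` is "below" for tuning width (narrow
    tuning = core) and "above" for myelin.
    """
    for key in ("te10", "anterior", "posterior"):
        if key not in labels or not np.asarray(labels[key]).any():
            raise ValueError(f"empty or missing label mask: {key}")
    if alternative:
        inside = labels["te10"] | labels.get("te11", False) | labels.get("te12", False)
    else:
        inside = labels["te10"]
    outside = labels["anterior"] | labels["posterior"]
    finite = np.isfinite(map2d)
    m_in = map2d[inside & finite].mean()
    m_out = map2d[outside & finite].mean()
    crit = 0.5 * (m_in + m_out)
    if polarity == "below":
        roi = map2d < crit
    elif polarity == "above":
        roi = map2d > crit
    else:
        raise ValueError("polarity must be 'below' or 'above'")
    roi = roi & responsive_mask & finite
    if largest_component_only and roi.any():
        from skimage import measure

        lab = measure.label(roi, connectivity=2)
        sizes = np.bincount(lab.ravel())[1:]
        roi = lab == (np.argmax(sizes) + 1)
    return roi


def _border_curve(clusters, frame, u_grid):
    """Across-axis position v(u) of a joined reversal border, by median-v
    binning along the axis and nearest-edge extension across gaps."""
    us, vs = [], []
    for cl in clusters:
        u, v = frame.to_frame(cl.pixels[:, 0], cl.pixels[:, 1])
        us.append(u)
        vs.append(v)
    u = np.concatenate(us)
    v = np.concatenate(vs)
    order = np.argsort(u)
    u, v = u[order], v[order]
    bins = np.arange(u.min(), u.max() + 1.0, 1.0)
    idx = np.digitize(u, bins) - 1
    bu, bv = [], []
    for i in range(len(bins)):
        sel = idx == i
        if sel.any():
            bu.append(u[sel].mean())
            bv.append(np.median(v[sel]))
    return np.interp(u_grid, bu, bv)


def gradient_rois(clusters: list, frame: Frame, responsive_mask: np.ndarray):
    """Anterior and posterior gradient ROIs bounded by reversals.

    The anterior ROI lies between the low-frequency reversal on HG and
    the high-frequency reversal anterior to it (+v side); the posterior
    ROI between the low reversal and the posterior high reversal.
    Collinear reversal segments are expected to be merged already
    (cluster_reversals); remaining gaps are bridged by interpolating
    each border's across-axis position along the HG axis.  ROIs are
    clipped to the responsive mask.
    """
    lows = [c for c in clusters if c.denomination == "low"]
    highs = [c for c in clusters if c.denomination == "high"]

    def v_centroid(cl):
        _, v = frame.to_frame(cl.pixels[:, 0], cl.pixels[:, 1])
        return float(np.mean(v))

    if not lows:
        raise ValueError("no low-frequency reversal found near the HG axis")
    low_main = [min(lows, key=lambda c: abs(v_centroid(c)))]
    # pull in further low clusters collinear and close to the main one
    v0 = v_centroid(low_main[0])
    for c in lows:
        if c is not low_main[0] and abs(v_centroid(c) - v0) < 3.0:
            low_main.append(c)
    ant_high = [c for c in highs if v_centroid(c) > v0]
    post_high = [c for c in highs if v_centroid(c) < v0]
    if not ant_high:
        raise ValueError("missing high-frequency reversal on the anterior side")
    if not post_high:
        raise ValueError("missing high-frequency reversal on the posterior side")

    rr, cc = np.meshgrid(np.arange(responsive_mask.shape[0]),
                         np.arange(responsive_mask.shape[1]), indexing="ij")
    U, V = frame.to_frame(rr, cc)
    u_flat = U.ravel()
    v_low = _border_curve(low_main, frame, u_flat).reshape(U.shape)
    v_ant = _border_curve(ant_high, frame, u_flat).reshape(U.shape)
    v_post = _border_curve(post_high, frame, u_flat).reshape(U.shape)

    anterior = (V > v_low) & (V < v_ant) & responsive_mask
    posterior = (V < v_low) & (V > v_post) & responsive_mask
    if not anterior.any():
        warnings.warn("anterior gradient ROI is empty (zero-width band)")
    if not posterior.any():
        warnings.warn("posterior gradient ROI is empty (zero-width band)")
    return anterior, posterior


def overlap_stats(core: np.ndarray, anterior: np.ndarray,
                  posterior: np.ndarray) -> OverlapStats:
    """Overlap of a core ROI with the two gradient ROIs.

    overlap(A, B) = |A & B| / min(|A|, |B|); the overlap ratio
    anterior/posterior runs from 0 to infinity, 1 meaning equal overlap.
    """

    def ov(a, b):
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 or nb == 0:
            return float("nan")
        return float((a & b).sum() / min(na, nb))

    return OverlapStats(overlap_anterior=ov(core, anterior),
                        overlap_posterior=ov(core, posterior))


def reversal_orientation(clusters: list, frame: Frame,
                         hg_roi: np.ndarray | None = None) -> float:
    """Pixel-count-weighted axial mean orientation (deg, relative to the
    HG axis) of the low-frequency reversal clusters, optionally
    restricted to clusters intersecting the HG ROI."""
    lows = [c for c in clusters if c.denomination == "low"]
    if hg_roi is not None:
        lows = [c for c in lows
                if hg_roi[c.pixels[:, 0], c.pixels[:, 1]].any()]
    if not lows:
        raise ValueError("no low-frequency reversal clusters")
    angles = np.array([frame.rel_axial(c.orientation_deg) for c in lows])
    weights = np.array([c.size for c in lows], dtype=float)
    if len(angles) == 1:
        mean = float(angles[0])
    else:
        mean, _ = axial_mean_ci(angles, weights=weights)
    # report in (-90, 90] about the HG axis
    return mean - 180.0 if mean > 90.0 else mean


def curvature_by_frequency(roi: np.ndarray, preferred_map: np.ndarray,
                           curvature_map: np.ndarray, n_bins: int = 8,
                           equal_count: bool = True) -> pd.DataFrame:
    """Mean cortical curvature in preferred-frequency bins within a ROI."""
    if not roi.any():
        raise ValueError("empty ROI")
    sel = roi & np.isfinite(preferred_map) & np.isfinite(curvature_map)
    pf = preferred_map[sel]
    cv = curvature_map[sel]
    if equal_count:
        edges = np.quantile(pf, np.linspace(0, 1, n_bins + 1))
        edges[-1] += 1e-9
    else:
        edges = np.linspace(pf.min(), pf.max() + 1e-9, n_bins + 1)
    rows = []
    for i in range(n_bins):
        m = (pf >= edges[i]) & (pf < edges[i + 1])
        if m.sum() == 0:
            rows.append({"bin_center_cam": 0.5 * (edges[i] + edges[i + 1]),
                         "mean_curvature": np.nan, "se": np.nan, "n": 0})
            continue
        c = cv[m]
        rows.append({"bin_center_cam": float(pf[m].mean()),
                     "mean_curvature": float(c.mean()),
                     "se": float(c.std(ddof=1) / np.sqrt(m.sum())) if m.sum() > 1 else np.nan,
                     "n": int(m.sum())})
    return pd.DataFrame(rows)
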