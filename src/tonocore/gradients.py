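"""Tonotopic gradient fields, sign maps, and gradient-reversal detection.

Local gradients are computed with the standard 3x3 Sobel operator on
masked flat maps.  Reversals are located with the orientation-counting
procedure: for each pixel and each of 180 equidistant orientations
theta in {0, ..., 179} deg, the gradient vectors of the two neighbours
straddling the pixel along theta (nearest-pixel sampling at +/- one
pixel step) are projected onto theta; a strict sign change counts as a
reversal along that orientation.  Pixels whose count reaches a
criterion (default 10 orientations) form the reversal mask.  Each
reversal pixel is denominated "low" or "high" according to whether the
preferred frequency is a local minimum or maximum along the mean
detected orientation.

Grid conventions: x = column index, y = row index, angles CCW from the
column axis in degrees; vector components are stored as (vx, vy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "VectorField",
    "ReversalMap",
    "ReversalCluster",
    "sobel_field",
    "smooth_map_or_field",
    "sign_map",
    "detect_reversals",
    "cluster_reversals",
    "axial_angle_diff",
]

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])
SOBEL_Y = SOBEL_X.T


@dataclass
class VectorField:
    """Per-pixel 2D vectors (Cam per pixel) with a validity mask."""

    vx: np.ndarray
    vy: np.ndarray
    mask: np.ndarray
    pixel_mm: float = 0.33

    @property
    def shape(self):
        return self.vx.shape

    def angle_deg(self) -> np.ndarray:
        """Vector direction, deg CCW from the x (column) axis; NaN off-mask."""
        out = np.rad2deg(np.arctan2(self.vy, self.vx))
        out[~self.mask] = np.nan
        return out

    def magnitude(self) -> np.ndarray:
        out = np.hypot(self.vx, self.vy)
        out[~self.mask] = np.nan
        return out

    def rotated(self, deg: float) -> "VectorField":
        """Rotate every vector by ``deg`` CCW (e.g. into an HG frame)."""
        th = np.deg2rad(deg)
        vx = np.cos(th) * self.vx - np.sin(th) * self.vy
        vy = np.sin(th) * self.vx + np.cos(th) * self.vy
        return VectorField(vx, vy, self.mask.copy(), self.pixel_mm)


@dataclass
class ReversalCluster:
    pixels: np.ndarray            # (n, 2) array of (row, col)
    orientation_deg: float        # axial, [0, 180)
    denomination: str             # "low" | "high"
    pixel_mm: float = 0.33

    @property
    def size(self) -> int:
        return len(self.pixels)

    def centroid_xy_mm(self):
        r, c = self.pixels.mean(axis=0)
        return c * self.pixel_mm, r * self.pixel_mm


@dataclass
class ReversalMap:
    count: np.ndarray             # orientations with a sign change, 0..180
    mask: np.ndarray              # count >= criterion
    denomination: np.ndarray      # 0 none, 1 low, 2 high
    criterion: int
    pixel_mm: float = 0.33


def _valid_interior(mask: np.ndarray) -> np.ndarray:
    """Pixels whose full 3x3 neighbourhood lies inside the mask."""
    return ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)


def sobel_field(map2d: np.ndarray, mask: np.ndarray, pixel_mm: float = 0.33) -> VectorField:
    """Local gradient vectors from the 2D Sobel operator.

    Pixels whose 3x3 neighbourhood leaves the mask are marked invalid.
    """
    data = np.where(mask, map2d, 0.0)
    gx = ndimage.correlate(data, SOBEL_X, mode="nearest")
    gy = ndimage.correlate(data, SOBEL_Y, mode="nearest")
    valid = _valid_interior(mask) & np.isfinite(map2d)
    gx[~valid] = 0.0
    gy[~valid] = 0.0
    return VectorField(gx, gy, valid, pixel_mm)


def smooth_map_or_field(data, fwhm_mm: float, pixel_mm: float = 0.33, mask=None):
    """Mask-aware normalised Gaussian smoothing of a map or vector field.

    The kernel is renormalised over the in-mask support, so constants
    are preserved under any mask; ``fwhm_mm = 0`` is the identity.
    Vector fields are smoothed componentwise over their validity mask.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if isinstance(data, VectorField):
        if fwhm_mm == 0:
            return VectorField(data.vx.copy(), data.vy.copy(), data.mask.copy(),
                               data.pixel_mm)
        vx = smooth_map_or_field(data.vx, fwhm_mm, data.pixel_mm, data.mask)
        vy = smooth_map_or_field(data.vy, fwhm_mm, data.pixel_mm, data.mask)
        vx, vy = np.nan_to_num(vx), np.nan_to_num(vy)
        return VectorField(vx, vy, data.mask.copy(), data.pixel_mm)

    data = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return data.copy()
    if mask is None:
        mask = np.isfinite(data)
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pixel_mm
    m = mask.astype(float)
    num = ndimage.gaussian_filter(np.where(mask, data, 0.0), sigma, mode="constant")
    den = ndimage.gaussian_filter(m, sigma, mode="constant")
    out = np.full(data.shape, np.nan)
    ok = mask & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def sign_map(fld: VectorField, direction_deg: float) -> np.ndarray:
    """Sign of the projection of each vector onto a direction (-1, 0, +1)."""
    th = np.deg2rad(direction_deg)
    proj = fld.vx * np.cos(th) + fld.vy * np.sin(th)
    out = np.sign(proj)
    # orthogonal within floating tolerance counts as zero
    out[np.abs(proj) <= 1e-12 * np.hypot(fld.vx, fld.vy)] = 0
    out[~fld.mask] = 0
    return out


def _shift(arr: np.ndarray, dy: int, dx: int, fill=0.0) -> np.ndarray:
    """arr sampled at (row + dy, col + dx); out-of-grid entries -> fill."""
    out = np.full_like(np.asarray(arr, dtype=float), fill)
    rows, cols = arr.shape
    dst_r = slice(max(0, -dy), min(rows, rows - dy))
    dst_c = slice(max(0, -dx), min(cols, cols - dx))
    src_r = slice(max(0, dy), min(rows, rows + dy))
    src_c = slice(max(0, dx), min(cols, cols + dx))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def neighbor_offset(theta_deg: float):
    """Nearest-pixel unit-step offset (dx, dy) along orientation theta."""
    th = np.deg2rad(theta_deg)
    return int(np.rint(np.cos(th))), int(np.rint(np.sin(th)))


def detect_reversals(
    fld: VectorField,
    preferred_map: np.ndarray,
    criterion: int = 10,
    orientations: int = 180,
) -> ReversalMap:
    """Orientation-counting gradient-reversal detection (vectorised)."""
    if not (1 <= criterion <= 180):
        raise ValueError("criterion must lie in [1, 180]")
    count = np.zeros(fld.shape, dtype=np.int16)
    c2 = np.zeros(fld.shape)
    s2 = np.zeros(fld.shape)
    valid = fld.mask
    validf = valid.astype(float)

    # cache shifted arrays per unique offset
    cache = {}

    def shifted(dy, dx):
        key = (dy, dx)
        if key not in cache:
            cache[key] = (
                _shift(fld.vx, dy, dx),
                _shift(fld.vy, dy, dx),
                _shift(validf, dy, dx) > 0.5,
            )
        return cache[key]

    thetas = np.arange(orientations) * (180.0 / orientations)
    for theta in thetas:
        dx, dy = neighbor_offset(theta)
        ux, uy = np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))
        vxp, vyp, okp = shifted(dy, dx)
        vxm, vym, okm = shifted(-dy, -dx)
        pp = vxp * ux + vyp * uy
        pm = vxm * ux + vym * uy
        rev = (pp * pm < 0) & okp & okm & valid
        count += rev
        th2 = np.deg2rad(2.0 * theta)
        c2 += rev * np.cos(th2)
        s2 += rev * np.sin(th2)

    rmask = count >= criterion
    denom = np.zeros(fld.shape, dtype=np.int8)
    if rmask.any():
        mean_axial = 0.5 * np.arctan2(s2, c2)  # radians, axial
        rr, cc = np.nonzero(rmask)
        rows, cols = fld.shape
        for r, c in zip(rr, cc):
            th = np.rad2deg(mean_axial[r, c]) % 180.0
            dx, dy = neighbor_offset(th)
            r1, c1, r2, c2_ = r + dy, c + dx, r - dy, c - dx
            if not (0 <= r1 < rows and 0 <= c1 < cols and 0 <= r2 < rows and 0 <= c2_ < cols):
                continue
            p0, p1, p2 = preferred_map[r, c], preferred_map[r1, c1], preferred_map[r2, c2_]
            if np.isnan(p1) or np.isnan(p2):
                continue
            if p1 > p0 and p2 > p0:
                denom[r, c] = 1  # low-frequency reversal (local minimum)
            elif p1 < p0 and p2 < p0:
                denom[r, c] = 2  # high-frequency reversal
    return ReversalMap(count=count, mask=rmask, denomination=denom,
                       criterion=criterion, pixel_mm=fld.pixel_mm)


def axial_angle_diff(a: float, b: float) -> float:
    """Smallest difference between two axial angles (deg, mod 180)."""
    d = abs((a - b) % 180.0)
    return min(d, 180.0 - d)


def _axis_of(coords_xy: np.ndarray) -> float:
    """Axial orientation (deg in [0, 180)) of a point set via SVD."""
    centered = coords_xy - coords_xy.mean(axis=0)
    if len(centered) < 2:
        return 0.0
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    ax = vt[0]
    return float(np.rad2deg(np.arctan2(ax[1], ax[0])) % 180.0)


def cluster_reversals(
    rmap: ReversalMap,
    collinearity_tol_deg: float = 20.0,
    gap_tol_mm: float = 3.0,
    min_size: int = 3,
) -> list:
    """8-connected reversal clusters per denomination, with merging of
    disconnected but collinear segments (axis agreement within
    ``collinearity_tol_deg`` and endpoint gap within ``gap_tol_mm``).
    """
    pix = rmap.pixel_mm
    clusters = []
    for code, name in ((1, "low"), (2, "high")):
        lab = measure.label(rmap.denomination == code, connectivity=2)
        comps = []
        for i in range(1, lab.max() + 1):
            rc = np.argwhere(lab == i)
            if len(rc) < min_size:
                continue
            comps.append(rc)
        if not comps:
            continue
        # union-find merge of collinear, nearby components
        parent = list(range(len(comps)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        info = []
        for rc in comps:
            xy = rc[:, ::-1].astype(float) * pix  # (x, y) mm
            ax = _axis_of(xy)
            u = np.array([np.cos(np.deg2rad(ax)), np.sin(np.deg2rad(ax))])
            proj = (xy - xy.mean(axis=0)) @ u
            ends = np.array([xy[np.argmin(proj)], xy[np.argmax(proj)]])
            info.append((ax, ends))
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                ai, ei = info[i]
                aj, ej = info[j]
                if axial_angle_diff(ai, aj) > collinearity_tol_deg:
                    continue
                gap = min(np.linalg.norm(p - q) for p in ei for q in ej)
                if gap <= gap_tol_mm:
                    parent[find(i)] = find(j)
        groups = {}
        for i in range(len(comps)):
            groups.setdefault(find(i), []).append(i)
        for members in groups.values():
            rc = np.vstack([comps[i] for i in members])
            xy = rc[:, ::-1].astype(float) * pix
            clusters.append(ReversalCluster(pixels=rc, orientation_deg=_axis_of(xy),
                                            denomination=name, pixel_mm=pix))
    return clusters
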