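"""Synthetic cortical flat patches with known tonotopy and core geometry.

The generator emulates a cohort of hemispheres, each a 120 x 120 grid of
0.33-mm pixels carrying the quantities the analysis consumes: a V-shaped
mirror-symmetric preferred-frequency field (two tonotopic gradients at
roughly +/-70 deg from the long axis of Heschl's gyrus, separated by a
low-frequency reversal line parallel to that axis), a curvature ridge
marking the gyrus, elongated high-myelin and high-selectivity (narrow
tuning width) ellipses, cytoarchitectonic-style label masks, and noisy
per-depth response amplitudes sampled from Gaussian tuning curves.

Geometry is constructed analytically in a gyrus-aligned frame (u along
the HG long axis, v across it, anterior = +v) and rotated into the grid,
so every truth quantity (realized gradient angles, reversal lines,
ellipse orientations) is known exactly and recovery can be tested.

Preferred frequency across the patch follows

    pf(u, v) = cam_min + m_v(side) * fold(|v - v0|) + m_u * (u - u_c)

where ``fold`` reflects at the band width L (creating the high-frequency
reversals at |v - v0| = L and low-frequency flanks beyond, so the
reversal detector sees true sign changes of both denominations), m_v is
the across-band slope on each side and m_u the common along-axis tilt.
The realized gradient direction on each side is atan2(+/-m_v, m_u),
exactly the configured angle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .scale import DEFAULT_SCALE, STIMULUS_FREQS_HZ

__all__ = [
    "Ellipse",
    "PatchConfig",
    "TonotopyTruth",
    "CoreTruth",
    "NoiseModel",
    "GroundTruth",
    "Hemisphere",
    "generate_truth",
    "simulate_betas",
    "simulate_structurals",
    "simulate_cohort",
    "write_hemisphere",
    "write_cohort",
    "DEPTHS",
]

#: The 11 cortical depth fractions (0 = gray/white border, 1 = pial).
DEPTHS = np.round(np.linspace(0.0, 1.0, 11), 1)


@dataclass(frozen=True)
class Ellipse:
    """Ellipse in the HG frame: centre (mm), semi-axes (mm), orientation
    (deg CCW from the HG long axis, axial)."""

    center_u: float
    center_v: float
    semi_major: float
    semi_minor: float
    orientation_deg: float = 0.0

    def contains(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        th = np.deg2rad(self.orientation_deg)
        du, dv = u - self.center_u, v - self.center_v
        a = np.cos(th) * du + np.sin(th) * dv
        b = -np.sin(th) * du + np.cos(th) * dv
        return (a / self.semi_major) ** 2 + (b / self.semi_minor) ** 2 <= 1.0


@dataclass(frozen=True)
class PatchConfig:
    grid_shape: tuple = (120, 120)
    pixel_mm: float = 0.33
    hg_axis_deg: float = 25.0          # grid frame, CCW from the column axis
    ridge_center_mm: float = 0.0       # across-axis offset of the HG crest
    ridge_width_mm: float = 3.0
    ridge_amplitude: float = 0.15      # curvature units (1/mm), positive = gyrus
    mask_semi_u_mm: float = 15.0       # responsive-region ellipse, HG frame
    mask_semi_v_mm: float = 15.0

    def __post_init__(self):
        if min(self.grid_shape) <= 0 or self.pixel_mm <= 0:
            raise ValueError("grid_shape and pixel_mm must be positive")
        if not (0 <= self.hg_axis_deg < 180):
            raise ValueError("hg_axis_deg must lie in [0, 180)")


@dataclass(frozen=True)
class TonotopyTruth:
    low_reversal_offset_mm: float = 0.0
    anterior_angle_deg: float = 70.0    # gradient direction, rel. HG axis
    posterior_angle_deg: float = -70.0
    # across-band preferred-frequency span (Cam).  Kept narrower than the
    # stimulus range so that, with the along-axis tilt implied by the
    # +/-70 deg gradient angles, the field stays within the audible
    # range everywhere on the patch (about 385 Hz to 3.8 kHz).
    cam_range: tuple = (9.0, 23.0)
    band_width_mm: float = 9.0          # low reversal -> high reversal distance

    def __post_init__(self):
        span = self.cam_range[1] - self.cam_range[0]
        if span > 0 and self.anterior_angle_deg * self.posterior_angle_deg >= 0:
            raise ValueError("gradient angles must lie on opposite sides of the HG axis")


@dataclass(frozen=True)
class CoreTruth:
    myelin_ellipse: Ellipse = Ellipse(-2.0, 0.0, 10.0, 3.5, 0.0)
    selectivity_ellipse: Ellipse = Ellipse(2.0, 0.0, 11.0, 4.0, 0.0)
    myelin_baseline: float = 0.70
    myelin_effect: float = 0.05
    width_outside_erb: float = 9.0
    width_inside_erb: float = 4.0
    response_height: float = 1.0        # percent signal change at the mode
    te10: Ellipse = Ellipse(0.0, 0.0, 4.0, 3.0, 0.0)
    te11: Ellipse = Ellipse(-7.0, 0.0, 3.5, 3.0, 0.0)
    te12: Ellipse = Ellipse(7.0, 0.0, 3.5, 3.0, 0.0)

    def __post_init__(self):
        if self.myelin_effect <= 0:
            raise ValueError("effect sizes must be positive")


@dataclass(frozen=True)
class NoiseModel:
    beta_noise_sd: float = 0.3          # additive, percent-signal-change units
    structural_noise_sd: float = 0.0125
    curvature_nuisance: float = 0.02    # myelin units per curvature unit
    angle_jitter_sd: float = 8.0        # deg, per hemisphere, per side
    offset_jitter_sd: float = 1.0       # mm, low-reversal line
    effect_jitter_frac: float = 0.1     # multiplicative SD on effect sizes
    hg_axis_jitter_sd: float = 5.0      # deg, per hemisphere
    residual_dof: int = 44              # GLM residual dof emulated for F-tests

    def __post_init__(self):
        for name in ("beta_noise_sd", "structural_noise_sd", "angle_jitter_sd",
                     "offset_jitter_sd", "effect_jitter_frac", "hg_axis_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Realized per-hemisphere maps and parameters."""

    patch: PatchConfig
    pf_cam: np.ndarray                 # preferred frequency (Cam)
    width_erb: np.ndarray              # tuning width (ERB_N = Cam)
    myelin: np.ndarray
    curvature: np.ndarray
    thickness: np.ndarray
    mask: np.ndarray                   # auditory-responsive region
    labels: dict                       # hg, te10, te11, te12, anterior, posterior
    hg_axis_deg: float                 # realized
    anterior_angle_deg: float          # realized, rel. HG axis
    posterior_angle_deg: float
    low_reversal_offset_mm: float
    band_width_mm: float
    tonotopy_frame_deg: float          # frame the tonotopy was generated in
    u: np.ndarray = field(repr=False, default=None)  # HG-frame coords (mm)
    v: np.ndarray = field(repr=False, default=None)

    @property
    def grid_shape(self):
        return self.pf_cam.shape


@dataclass
class Hemisphere:
    """One synthetic hemisphere: truth plus simulated measurements."""

    index: int
    truth: GroundTruth
    betas: np.ndarray                  # (n_depths, 7, rows, cols)
    beta_var: np.ndarray               # (n_depths, rows, cols) residual var
    residual_dof: int
    structurals: dict                  # psir/m0/msat depth stacks + covariates


def _frame_coords(patch: PatchConfig, axis_deg: float):
    """Physical HG-frame coordinates (u along axis, v across) per pixel."""
    rows, cols = patch.grid_shape
    y = (np.arange(rows) - (rows - 1) / 2.0) * patch.pixel_mm
    x = (np.arange(cols) - (cols - 1) / 2.0) * patch.pixel_mm
    X, Y = np.meshgrid(x, y)
    th = np.deg2rad(axis_deg)
    u = np.cos(th) * X + np.sin(th) * Y
    v = -np.sin(th) * X + np.cos(th) * Y
    return u, v


def generate_truth(
    patch: PatchConfig = PatchConfig(),
    tono: TonotopyTruth = TonotopyTruth(),
    core: CoreTruth = CoreTruth(),
    hg_axis_deg: float | None = None,
    tonotopy_frame_deg: float | None = None,
) -> GroundTruth:
    """Build the noiseless truth maps for one hemisphere.

    ``hg_axis_deg`` overrides the patch's nominal axis (used for
    per-hemisphere jitter); ``tonotopy_frame_deg`` decouples the frame
    the tonotopy is generated in from the HG axis (used for null
    cohorts), default equal to the HG axis.
    """
    axis = patch.hg_axis_deg if hg_axis_deg is None else hg_axis_deg % 180.0
    tono_frame = axis if tonotopy_frame_deg is None else tonotopy_frame_deg
    u, v = _frame_coords(patch, axis)
    ut, vt = _frame_coords(patch, tono_frame)

    mask = (u / patch.mask_semi_u_mm) ** 2 + (v / patch.mask_semi_v_mm) ** 2 <= 1.0

    cam_min, cam_max = tono.cam_range
    span = cam_max - cam_min
    L = tono.band_width_mm
    d = vt - tono.low_reversal_offset_mm
    # fold |d| at the band width: 0 on the low line, L on the high lines
    t = np.mod(np.abs(d), 2 * L)
    folded = np.minimum(t, 2 * L - t)
    if span > 0:
        ang_a = np.deg2rad(abs(tono.anterior_angle_deg))
        ang_p = np.deg2rad(abs(tono.posterior_angle_deg))
        m_v_nom = span / L
        mean_ang = 0.5 * (ang_a + ang_p)
        m_u = m_v_nom / np.tan(mean_ang)
        m_v_a = m_u * np.tan(ang_a)
        m_v_p = m_u * np.tan(ang_p)
        m_v = np.where(d >= 0, m_v_a, m_v_p)
        pf = cam_min + m_v * folded + m_u * ut
        realized_a = np.rad2deg(np.arctan2(m_v_a, m_u))
        realized_p = -np.rad2deg(np.arctan2(m_v_p, m_u))
    else:  # degenerate: flat map, no gradients, no reversals
        pf = np.full(patch.grid_shape, cam_min)
        realized_a = realized_p = 0.0

    sel = core.selectivity_ellipse
    mye = core.myelin_ellipse
    for name, e in (("selectivity", sel), ("myelin", mye)):
        eu = np.array([e.center_u + s * e.semi_major * np.cos(np.deg2rad(e.orientation_deg))
                       for s in (-1, 1)])
        ev = np.array([e.center_v + s * e.semi_major * np.sin(np.deg2rad(e.orientation_deg))
                       for s in (-1, 1)])
        if np.any((eu / patch.mask_semi_u_mm) ** 2 + (ev / patch.mask_semi_v_mm) ** 2 > 1.0):
            raise ValueError(f"{name} ellipse does not fit inside the responsive mask")

    width = np.where(sel.contains(u, v), core.width_inside_erb, core.width_outside_erb)
    myelin = core.myelin_baseline + core.myelin_effect * mye.contains(u, v)

    dv = v - patch.ridge_center_mm
    w = patch.ridge_width_mm
    z2 = (dv / w) ** 2
    curvature = patch.ridge_amplitude * (1.0 - z2) * np.exp(-z2 / 2.0)
    thickness = 2.5 + 0.3 * np.exp(-z2 / 2.0)

    labels = {
        "hg": (np.abs(dv) <= w) & mask,
        "te10": core.te10.contains(u, v) & mask,
        "te11": core.te11.contains(u, v) & mask,
        "te12": core.te12.contains(u, v) & mask,
        "anterior": (d > L + 1.0) & mask,
        "posterior": (d < -(L + 1.0)) & mask,
    }

    return GroundTruth(
        patch=patch, pf_cam=pf, width_erb=width, myelin=myelin,
        curvature=curvature, thickness=thickness, mask=mask, labels=labels,
        hg_axis_deg=axis, anterior_angle_deg=realized_a,
        posterior_angle_deg=realized_p,
        low_reversal_offset_mm=tono.low_reversal_offset_mm,
        band_width_mm=L, tonotopy_frame_deg=tono_frame, u=u, v=v,
    )


def simulate_betas(
    truth: GroundTruth,
    stim_freqs_hz: np.ndarray = STIMULUS_FREQS_HZ,
    noise: NoiseModel = NoiseModel(),
    n_depths: int = 11,
    rng: np.random.Generator | None = None,
    height: float = 1.0,
):
    """Sample noisy per-depth response amplitudes from Gaussian tuning curves.

    Each pixel's noiseless 7-point curve is a Gaussian in Cam with mode
    equal to the truth preferred frequency and SD equal to the truth
    tuning width; depths receive independent additive noise around the
    same mean.  Also returns emulated GLM residual-variance estimates
    (scaled chi-square draws) so downstream F-tests behave as they would
    on real single-voxel fits.
    """
    rng = rng or np.random.default_rng(0)
    f_cam = DEFAULT_SCALE.hz_to_cam(np.asarray(stim_freqs_hz, dtype=float))
    pf = truth.pf_cam[None, :, :]
    sig = truth.width_erb[None, :, :]
    clean = height * np.exp(-((f_cam[:, None, None] - pf) ** 2) / (2.0 * sig ** 2))
    shape = (n_depths,) + clean.shape
    betas = clean[None] + noise.beta_noise_sd * rng.standard_normal(shape)
    nu = noise.residual_dof
    if noise.beta_noise_sd > 0:
        var = noise.beta_noise_sd ** 2 * rng.chisquare(nu, (n_depths,) + truth.grid_shape) / nu
    else:
        var = np.zeros((n_depths,) + truth.grid_shape)
    return betas, var


def simulate_structurals(
    truth: GroundTruth,
    noise: NoiseModel = NoiseModel(),
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-depth structural stacks: PSIR-like myelin, M0/MSAT, covariates.

    Myelin follows a depth profile that decreases towards the pial
    surface with a plateau at mid depths, plus a curvature-correlated
    nuisance (so residualisation has something to remove) and i.i.d.
    noise.  MTR truth is tied to the same myelin ellipse.
    """
    rng = rng or np.random.default_rng(0)
    nd = len(DEPTHS)
    prof = 1.0 - 0.12 * np.clip((DEPTHS - 0.7) / 0.3, 0.0, None) \
               - 0.04 * np.clip((0.3 - DEPTHS) / 0.3, 0.0, None)
    base = truth.myelin[None] * prof[:, None, None]
    nuis = noise.curvature_nuisance * truth.curvature[None]
    eps = noise.structural_noise_sd * rng.standard_normal((nd,) + truth.grid_shape)
    psir = base + nuis + eps

    mtr_truth = 0.25 + 0.05 * (truth.myelin > truth.myelin.mean())
    m0 = 100.0 * np.ones((nd,) + truth.grid_shape) \
        + rng.standard_normal((nd,) + truth.grid_shape)
    msat = m0 * (1.0 - mtr_truth[None]
                 - 0.02 * truth.curvature[None] * noise.curvature_nuisance / 0.02) \
        + noise.structural_noise_sd * 100.0 * rng.standard_normal((nd,) + truth.grid_shape)
    return {
        "psir": psir,
        "m0": m0,
        "msat": msat,
        "curvature": truth.curvature,
        "thickness": truth.thickness,
    }


def simulate_cohort(
    n: int = 24,
    patch: PatchConfig = PatchConfig(),
    tono: TonotopyTruth = TonotopyTruth(),
    core: CoreTruth = CoreTruth(),
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    null_cohort: bool = False,
    with_structurals: bool = True,
    with_betas: bool = True,
) -> list:
    """Simulate a cohort of hemispheres with per-hemisphere jitter.

    Jitter (drawn once per hemisphere): gradient angles (per side),
    low-reversal offset, effect sizes, and HG axis orientation.  In
    ``null_cohort`` mode the tonotopy pattern of each hemisphere is
    rotated by an independent uniform angle, so gradient directions are
    uniformly distributed across the cohort (type-I-error testing).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = []
    for h in range(n):
        rng = np.random.default_rng([int(seed) % (2 ** 31), h])
        ant = tono.anterior_angle_deg + noise.angle_jitter_sd * rng.standard_normal()
        post = tono.posterior_angle_deg + noise.angle_jitter_sd * rng.standard_normal()
        ant = float(np.clip(ant, 5.0, 89.0))
        post = float(np.clip(post, -89.0, -5.0))
        off = tono.low_reversal_offset_mm + noise.offset_jitter_sd * rng.standard_normal()
        axis = (patch.hg_axis_deg + noise.hg_axis_jitter_sd * rng.standard_normal()) % 180.0
        escale = max(0.1, 1.0 + noise.effect_jitter_frac * rng.standard_normal())
        core_h = replace(core, myelin_effect=core.myelin_effect * escale)
        tono_h = replace(tono, anterior_angle_deg=ant, posterior_angle_deg=post,
                         low_reversal_offset_mm=float(off))
        frame = None
        if null_cohort:
            # null mode: a planar tonotopic gradient pointing in a uniform
            # random direction per hemisphere (one very wide band whose
            # reversal lines lie outside the patch), so per-pixel gradient
            # directions are i.i.d. uniform across the cohort
            frame = float(rng.uniform(0.0, 360.0))
            tono_h = replace(tono_h, band_width_mm=60.0,
                             low_reversal_offset_mm=-20.0)
        truth = generate_truth(patch, tono_h, core_h, hg_axis_deg=axis,
                               tonotopy_frame_deg=frame)
        if with_betas:
            betas, bvar = simulate_betas(truth, noise=noise, rng=rng,
                                         height=core.response_height)
        else:
            betas = np.empty((0, 7) + truth.grid_shape)
            bvar = np.empty((0,) + truth.grid_shape)
        structurals = simulate_structurals(truth, noise, rng) if with_structurals else {}
        out.append(Hemisphere(index=h, truth=truth, betas=betas, beta_var=bvar,
                              residual_dof=noise.residual_dof,
                              structurals=structurals))
    return out


# ---------------------------------------------------------------------------
# on-disk writer: one directory per hemisphere, plain matrix text + JSON
# sidecar (NIfTI via tonocore.mapio if preferred), cohort manifest CSV

def write_hemisphere(out_dir, hemi: Hemisphere, fmt: str = "text") -> None:
    from . import mapio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = hemi.truth
    sidecar = {
        "grid_shape": list(t.grid_shape),
        "pixel_mm": t.patch.pixel_mm,
        "hg_axis_deg": t.hg_axis_deg,
        "anterior_angle_deg": t.anterior_angle_deg,
        "posterior_angle_deg": t.posterior_angle_deg,
        "low_reversal_offset_mm": t.low_reversal_offset_mm,
        "band_width_mm": t.band_width_mm,
        "tonotopy_frame_deg": t.tonotopy_frame_deg,
        "residual_dof": hemi.residual_dof,
    }
    (out_dir / "truth.json").write_text(json.dumps(sidecar, indent=1))
    mapio.write_map(out_dir / "pf_truth", t.pf_cam, t.patch.pixel_mm, fmt)
    mapio.write_map(out_dir / "width_truth", t.width_erb, t.patch.pixel_mm, fmt)
    mapio.write_map(out_dir / "curvature", t.curvature, t.patch.pixel_mm, fmt)
    mapio.write_map(out_dir / "thickness", t.thickness, t.patch.pixel_mm, fmt)
    mapio.write_map(out_dir / "mask", t.mask.astype(float), t.patch.pixel_mm, fmt)
    for name, lab in t.labels.items():
        mapio.write_map(out_dir / f"label_{name}", lab.astype(float), t.patch.pixel_mm, fmt)
    mapio.write_stack(out_dir / "betas", hemi.betas, t.patch.pixel_mm, fmt)
    mapio.write_stack(out_dir / "beta_var", hemi.beta_var, t.patch.pixel_mm, fmt)
    for name, arr in hemi.structurals.items():
        if arr.ndim == 3:
            mapio.write_stack(out_dir / name, arr, t.patch.pixel_mm, fmt)
        else:
            mapio.write_map(out_dir / name, arr, t.patch.pixel_mm, fmt)


def write_cohort(out_dir, cohort: list, fmt: str = "text") -> None:
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for hemi in cohort:
        name = f"hemi_{hemi.index:02d}"
        write_hemisphere(out_dir / name, hemi, fmt)
        rows.append({
            "hemisphere": name,
            "hg_axis_deg": hemi.truth.hg_axis_deg,
            "anterior_angle_deg": hemi.truth.anterior_angle_deg,
            "posterior_angle_deg": hemi.truth.posterior_angle_deg,
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
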