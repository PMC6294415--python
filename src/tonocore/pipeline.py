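"""End-to-end orchestration: simulate -> per-hemisphere analysis -> cohort
statistics.

Per hemisphere the stages mirror the measurement analysis: select
auditory-responsive pixels (sound-versus-silence F-test, adaptive FDR),
estimate debiased preferred frequencies (middle 5 depths, unsmoothed)
and tuning widths (all 11 depths, 3-mm smoothing), derive tonotopic
gradient fields (Sobel per depth, vectors averaged across depths,
unsmoothed for direction statistics; 6-mm smoothed for reversal
detection), locate and cluster gradient reversals, build the HG frame
from curvature gradients, delineate the core by tuning-width and myelin
criteria and the gradient ROIs from the reversals, and compute the ROI
geometry statistics.  The cohort stage aggregates circular statistics
across hemispheres and runs the pixelwise Hotelling consistency test.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circstats import axial_mean_ci, circ_mean_ci, consistency_map
from .gradients import (VectorField, cluster_reversals, detect_reversals,
                        smooth_map_or_field, sobel_field)
from .response import BetaSet, select_responsive, sound_f_test
from .roi import (Frame, core_roi, gradient_rois, hg_frame, overlap_stats,
                  reversal_orientation, roi_stats)
from .structural import depth_average, residualize
from .synth import (CoreTruth, Hemisphere, NoiseModel, PatchConfig,
                    TonotopyTruth, simulate_cohort, write_cohort)
from .tuning import (GaussianBank, debias_map, preferred_frequency_map,
                     split_half, tuning_width)

__all__ = [
    "PipelineConfig",
    "HemisphereResult",
    "CohortReport",
    "analyze_hemisphere",
    "group_analysis",
    "run_simulate",
    "run_analyze",
    "run_group",
]


@dataclass(frozen=True)
class PipelineConfig:
    n_hemispheres: int = 24
    seed: int = 0
    null_cohort: bool = False
    fdr_q: float = 0.05
    adaptive_fdr: bool = True
    reversal_criterion: int = 10
    field_smoothing_fwhm_mm: float = 6.0    # individual reversal maps
    group_smoothing_fwhm_mm: float = 3.0    # consistency testing
    width_smoothing_fwhm_mm: float = 3.0
    structural_smoothing_fwhm_mm: float = 2.0
    alternative_core_criterion: bool = False

    def to_dict(self):
        return dataclasses.asdict(self)


@dataclass
class HemisphereResult:
    index: int
    responsive: np.ndarray
    pf_map: np.ndarray                 # Cam, middle 5 depths
    width_map: np.ndarray              # ERB_N
    myelin_map: np.ndarray
    direction_field: VectorField       # depth-averaged, unsmoothed
    frame: Frame
    clusters: list
    selectivity_core: np.ndarray
    myelin_core: np.ndarray
    anterior_roi: np.ndarray
    posterior_roi: np.ndarray
    stats: dict                        # per-ROI RoiStats
    overlap: dict                      # core name -> OverlapStats
    reversal_orientation_deg: float
    split_half_r: float
    truth_anterior_deg: float
    truth_posterior_deg: float


def analyze_hemisphere(hemi: Hemisphere, bank: GaussianBank,
                       cfg: PipelineConfig = PipelineConfig()) -> HemisphereResult:
    truth = hemi.truth
    pix = truth.patch.pixel_mm
    nd = hemi.betas.shape[0]

    # --- responsive-voxel selection (depth-pooled F statistics) ---------
    beta_mean = np.moveaxis(hemi.betas.mean(axis=0), 0, -1)   # (R, C, 7)
    sigma2 = hemi.beta_var.mean(axis=0) / nd
    bs = BetaSet(beta=beta_mean, sigma2=sigma2, dof=hemi.residual_dof * nd)
    if np.all(sigma2 > 0):
        _, p = sound_f_test(bs)
        responsive = select_responsive(p, q=cfg.fdr_q, candidate_mask=truth.mask,
                                       adaptive=cfg.adaptive_fdr)
    else:  # noiseless simulation: every in-mask pixel responds
        responsive = truth.mask.copy()

    # --- preferred frequency and tuning width ---------------------------
    pf_map = preferred_frequency_map(hemi.betas, bank, responsive)
    width_map = tuning_width(hemi.betas, responsive, pix,
                             cfg.width_smoothing_fwhm_mm)

    # --- gradient fields -------------------------------------------------
    per_depth_pf = debias_map(hemi.betas, bank, responsive)
    vx = np.zeros(truth.grid_shape)
    vy = np.zeros(truth.grid_shape)
    vmask = None
    for d in range(nd):
        fld = sobel_field(per_depth_pf[d], responsive & np.isfinite(per_depth_pf[d]), pix)
        vx += fld.vx
        vy += fld.vy
        vmask = fld.mask if vmask is None else (vmask & fld.mask)
    direction_field = VectorField(vx / nd, vy / nd, vmask, pix)

    smoothed = smooth_map_or_field(direction_field, cfg.field_smoothing_fwhm_mm, pix)
    rmap = detect_reversals(smoothed, pf_map, cfg.reversal_criterion)
    clusters = cluster_reversals(rmap)

    # --- structural myelin map -------------------------------------------
    if hemi.structurals:
        psir = hemi.structurals["psir"]
        covs = {"curvature": hemi.structurals["curvature"],
                "thickness": hemi.structurals["thickness"]}
        resid, _ = residualize(psir, covs, truth.mask)
        myelin_map = depth_average(resid, (0.3, 0.7),
                                   cfg.structural_smoothing_fwhm_mm, pix,
                                   truth.mask)
    else:
        myelin_map = truth.myelin

    # --- ROIs -------------------------------------------------------------
    frame = hg_frame(truth.curvature, truth.labels["hg"], pix)
    sel_core = core_roi(width_map, truth.labels, "below", responsive,
                        cfg.alternative_core_criterion)
    mye_core = core_roi(myelin_map, truth.labels, "above", responsive,
                        cfg.alternative_core_criterion)
    anterior, posterior = gradient_rois(clusters, frame, responsive)

    stats = {
        "selectivity_core": roi_stats(sel_core, frame, direction_field),
        "myelin_core": roi_stats(mye_core, frame, direction_field),
        "anterior_gradient": roi_stats(anterior, frame, direction_field),
        "posterior_gradient": roi_stats(posterior, frame, direction_field),
    }
    overlap = {
        "selectivity_core": overlap_stats(sel_core, anterior, posterior),
        "myelin_core": overlap_stats(mye_core, anterior, posterior),
    }
    rev_deg = reversal_orientation(clusters, frame, truth.labels["hg"])

    # split-half reliability from two disjoint depth subsets (independent
    # noise realisations of the same underlying maps)
    try:
        r = split_half(hemi.betas[0::2], hemi.betas[1::2], bank, responsive,
                       depth_range=(0, nd // 2))
    except ValueError:
        r = float("nan")

    return HemisphereResult(
        index=hemi.index, responsive=responsive, pf_map=pf_map,
        width_map=width_map, myelin_map=myelin_map,
        direction_field=direction_field, frame=frame, clusters=clusters,
        selectivity_core=sel_core, myelin_core=mye_core,
        anterior_roi=anterior, posterior_roi=posterior, stats=stats,
        overlap=overlap, reversal_orientation_deg=rev_deg, split_half_r=r,
        truth_anterior_deg=truth.anterior_angle_deg,
        truth_posterior_deg=truth.posterior_angle_deg,
    )


@dataclass
class CohortReport:
    circular: pd.DataFrame             # per-quantity circular mean + CI
    per_hemisphere: pd.DataFrame       # RoiStats/OverlapStats rows
    consistency: object                # ConsistencyResult
    group_field: VectorField           # pixelwise mean HG-frame field
    group_maps: dict
    inter_gradient_angle_deg: float


def group_analysis(results: list, cfg: PipelineConfig = PipelineConfig(),
                   responsive_union: np.ndarray | None = None) -> CohortReport:
    if len(results) < 3:
        raise ValueError("need at least 3 analyzed hemispheres")

    rows = []
    for res in results:
        for roi_name, st in res.stats.items():
            rows.append({
                "hemisphere": res.index, "roi": roi_name,
                "long_axis_deg": st.long_axis_deg,
                "centroid_u_mm": st.centroid_u_mm,
                "centroid_v_mm": st.centroid_v_mm,
                "area_mm2": st.area_mm2,
                "mean_gradient_deg": st.mean_gradient_deg,
                "angle_kind": "axial",
            })
        for core_name, ov in res.overlap.items():
            rows.append({
                "hemisphere": res.index, "roi": core_name + "_overlap",
                "overlap_anterior": ov.overlap_anterior,
                "overlap_posterior": ov.overlap_posterior,
                "overlap_ratio": ov.overlap_ratio,
            })
        rows.append({"hemisphere": res.index, "roi": "low_reversal",
                     "long_axis_deg": res.reversal_orientation_deg,
                     "angle_kind": "axial"})
        rows.append({"hemisphere": res.index, "roi": "split_half",
                     "split_half_r": res.split_half_r})
    per_hemi = pd.DataFrame(rows)

    def directional(key):
        return np.array([r.stats[key].mean_gradient_deg for r in results])

    circ_rows = []
    ant = directional("anterior_gradient")
    post = directional("posterior_gradient")
    for name, vals, kind in (
        ("anterior_gradient_direction", ant, "directional"),
        ("posterior_gradient_direction", post, "directional"),
        ("selectivity_core_long_axis",
         np.array([r.stats["selectivity_core"].long_axis_deg for r in results]),
         "axial"),
        ("myelin_core_long_axis",
         np.array([r.stats["myelin_core"].long_axis_deg for r in results]),
         "axial"),
        ("low_reversal_orientation",
         np.array([r.reversal_orientation_deg for r in results]), "axial"),
    ):
        vals = vals[np.isfinite(vals)]
        if kind == "directional":
            mean, half = circ_mean_ci(vals)
        else:
            mean, half = axial_mean_ci(vals)
            if mean > 90.0:
                mean -= 180.0
        circ_rows.append({"quantity": name, "mean_deg": mean,
                          "ci_halfwidth_deg": half, "n": len(vals),
                          "angle_kind": kind})
    circular = pd.DataFrame(circ_rows)

    mean_ant = circular.loc[circular.quantity == "anterior_gradient_direction",
                            "mean_deg"].item()
    mean_post = circular.loc[circular.quantity == "posterior_gradient_direction",
                             "mean_deg"].item()
    inter = abs(((mean_ant - mean_post) + 180.0) % 360.0 - 180.0)

    # pixelwise consistency of HG-frame-aligned gradient fields
    aligned = [r.direction_field.rotated(-r.frame.axis_deg) for r in results]
    if responsive_union is None:
        responsive_union = np.zeros(results[0].responsive.shape, dtype=bool)
        for r in results:
            responsive_union |= r.responsive
    cons = consistency_map(aligned, responsive_union,
                           cfg.group_smoothing_fwhm_mm, cfg.fdr_q,
                           cfg.adaptive_fdr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vx = np.nanmean(np.stack([np.where(f.mask, f.vx, np.nan) for f in aligned]), axis=0)
        vy = np.nanmean(np.stack([np.where(f.mask, f.vy, np.nan) for f in aligned]), axis=0)
    gmask = np.isfinite(vx) & np.isfinite(vy)
    group_field = VectorField(np.nan_to_num(vx), np.nan_to_num(vy), gmask,
                              results[0].direction_field.pixel_mm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        group_maps = {
            "pf": np.nanmean(np.stack([r.pf_map for r in results]), axis=0),
            "width": np.nanmean(np.stack([r.width_map for r in results]), axis=0),
            "myelin": np.nanmean(np.stack([r.myelin_map for r in results]), axis=0),
        }
    return CohortReport(circular=circular, per_hemisphere=per_hemi,
                        consistency=cons, group_field=group_field,
                        group_maps=group_maps,
                        inter_gradient_angle_deg=float(inter))


# ---------------------------------------------------------------------------
# disk-based runners (the CLI surface)

def _write_config(out_dir: Path, cfg: PipelineConfig):
    payload = {"config": cfg.to_dict(), "version": __version__}
    (out_dir / "config.json").write_text(json.dumps(payload, indent=1))


def run_simulate(cfg: PipelineConfig, out_dir, fmt: str = "text",
                 force: bool = False) -> Path:
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(cfg.n_hemispheres, seed=cfg.seed,
                             null_cohort=cfg.null_cohort)
    write_cohort(out_dir, cohort, fmt)
    _write_config(out_dir, cfg)
    return out_dir


def _load_hemisphere(hemi_dir: Path) -> Hemisphere:
    from . import mapio

    meta = json.loads((hemi_dir / "truth.json").read_text())
    pf, pix = mapio.read_map(hemi_dir / "pf_truth")
    width, _ = mapio.read_map(hemi_dir / "width_truth")
    curv, _ = mapio.read_map(hemi_dir / "curvature")
    thick, _ = mapio.read_map(hemi_dir / "thickness")
    mask, _ = mapio.read_map(hemi_dir / "mask")
    labels = {}
    for f in hemi_dir.glob("label_*.txt"):
        labels[f.stem[len("label_"):]] = mapio.read_map(f)[0] > 0.5
    for f in hemi_dir.glob("label_*.nii"):
        labels[f.stem[len("label_"):]] = mapio.read_map(f)[0] > 0.5
    betas, _ = mapio.read_stack(hemi_dir / "betas")
    bvar, _ = mapio.read_stack(hemi_dir / "beta_var")
    structurals = {}
    for name in ("psir", "m0", "msat"):
        p = hemi_dir / name
        if p.with_suffix(".txt").exists() or p.with_suffix(".nii").exists():
            structurals[name] = mapio.read_stack(p)[0]
    if structurals:
        structurals["curvature"] = curv
        structurals["thickness"] = thick
    patch = PatchConfig(grid_shape=tuple(meta["grid_shape"]),
                        pixel_mm=meta["pixel_mm"],
                        hg_axis_deg=meta["hg_axis_deg"])
    from .synth import GroundTruth, _frame_coords

    u, v = _frame_coords(patch, meta["hg_axis_deg"])
    truth = GroundTruth(
        patch=patch, pf_cam=pf, width_erb=width, myelin=np.full_like(pf, np.nan),
        curvature=curv, thickness=thick, mask=mask > 0.5, labels=labels,
        hg_axis_deg=meta["hg_axis_deg"],
        anterior_angle_deg=meta["anterior_angle_deg"],
        posterior_angle_deg=meta["posterior_angle_deg"],
        low_reversal_offset_mm=meta["low_reversal_offset_mm"],
        band_width_mm=meta["band_width_mm"],
        tonotopy_frame_deg=meta["tonotopy_frame_deg"], u=u, v=v,
    )
    index = int(hemi_dir.name.split("_")[-1])
    return Hemisphere(index=index, truth=truth, betas=betas, beta_var=bvar,
                      residual_dof=int(meta["residual_dof"]),
                      structurals=structurals)


def run_analyze(dataset_dir, out_dir, cfg: PipelineConfig = PipelineConfig(),
                force: bool = False):
    """Analyze every hemisphere in a simulated dataset directory.

    Failures are logged per hemisphere and do not stop the others;
    returns (results, failed_names).
    """
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} is not empty; pass force=True to overwrite")
    out_dir.mkdir(parents=True, exist_ok=True)
    bank = GaussianBank()
    results, failed = [], []
    for hemi_dir in sorted(dataset_dir.glob("hemi_*")):
        try:
            hemi = _load_hemisphere(hemi_dir)
            res = analyze_hemisphere(hemi, bank, cfg)
            results.append(res)
        except Exception as exc:   # noqa: BLE001 - stage isolation by design
            warnings.warn(f"{hemi_dir.name} failed: {exc}")
            failed.append(hemi_dir.name)
            continue
        from . import mapio

        hdir = out_dir / hemi_dir.name
        hdir.mkdir(exist_ok=True)
        pix = hemi.truth.patch.pixel_mm
        mapio.write_map(hdir / "pf_map", res.pf_map, pix)
        mapio.write_map(hdir / "width_map", res.width_map, pix)
        mapio.write_map(hdir / "myelin_map", res.myelin_map, pix)
        rois = (res.responsive.astype(int) + 2 * res.selectivity_core
                + 4 * res.myelin_core + 8 * res.anterior_roi
                + 16 * res.posterior_roi)
        mapio.write_map(hdir / "roi_labels", rois.astype(float), pix)
    _write_config(out_dir, cfg)
    return results, failed


def run_group(results: list, out_dir, cfg: PipelineConfig = PipelineConfig()):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = group_analysis(results, cfg)
    report.circular.to_csv(out_dir / "cohort_circular_stats.csv", index=False)
    report.per_hemisphere.to_csv(out_dir / "per_hemisphere_stats.csv", index=False)
    np.savetxt(out_dir / "consistency_mask.txt",
               report.consistency.significant.astype(int), fmt="%d")
    _write_config(out_dir, cfg)
    return report
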