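"""Reading and writing flat-map grids.

Two interchangeable on-disk formats:

* ``text`` — plain matrix text (``numpy.savetxt``) plus a JSON sidecar
  carrying the grid shape and pixel size; stacks are stored flattened
  with their full shape in the sidecar.
* ``nifti`` — 2D (or N-D) NIfTI via nibabel, pixel size in the affine.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_map", "read_map", "write_stack", "read_stack"]


def _affine(pixel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_mm
    return aff


def write_map(path, arr: np.ndarray, pixel_mm: float, fmt: str = "text") -> Path:
    path = Path(path)
    arr = np.asarray(arr, dtype=float)
    if fmt == "text":
        out = path.with_suffix(".txt")
        np.savetxt(out, arr, fmt="%.8g")
        sidecar = {"shape": list(arr.shape), "pixel_mm": pixel_mm}
        path.with_suffix(".json").write_text(json.dumps(sidecar))
    elif fmt == "nifti":
        import nibabel as nib

        out = path.with_suffix(".nii")
        nib.save(nib.Nifti1Image(arr, _affine(pixel_mm)), out)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return out


def read_map(path):
    """Return (array, pixel_mm). Accepts the basename or either file."""
    path = Path(path)
    if path.suffix == "" and path.with_suffix(".txt").exists():
        path = path.with_suffix(".txt")
    elif path.suffix == "" and path.with_suffix(".nii").exists():
        path = path.with_suffix(".nii")
    if path.suffix == ".txt":
        arr = np.loadtxt(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return arr.reshape(meta["shape"]), float(meta["pixel_mm"])
    if path.suffix == ".nii":
        import nibabel as nib

        img = nib.load(path)
        return np.asarray(img.dataobj, dtype=float), float(img.affine[0, 0])
    raise FileNotFoundError(path)


def write_stack(path, arr: np.ndarray, pixel_mm: float, fmt: str = "text") -> Path:
    path = Path(path)
    arr = np.asarray(arr, dtype=float)
    if fmt == "text":
        out = path.with_suffix(".txt")
        np.savetxt(out, arr.reshape(-1, arr.shape[-1]), fmt="%.8g")
        sidecar = {"shape": list(arr.shape), "pixel_mm": pixel_mm}
        path.with_suffix(".json").write_text(json.dumps(sidecar))
        return out
    if fmt == "nifti":
        import nibabel as nib

        out = path.with_suffix(".nii")
        nib.save(nib.Nifti1Image(arr, _affine(pixel_mm)), out)
        return out
    raise ValueError(f"unknown format {fmt!r}")


def read_stack(path):
    path = Path(path)
    if path.suffix == "" and path.with_suffix(".txt").exists():
        path = path.with_suffix(".txt")
    elif path.suffix == "" and path.with_suffix(".nii").exists():
        path = path.with_suffix(".nii")
    if path.suffix == ".txt":
        meta = json.loads(path.with_suffix(".json").read_text())
        arr = np.loadtxt(path).reshape(meta["shape"])
        return arr, float(meta["pixel_mm"])
    if path.suffix == ".nii":
        import nibabel as nib

        img = nib.load(path)
        return np.asarray(img.dataobj, dtype=float), float(img.affine[0, 0])
    raise FileNotFoundError(path)
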