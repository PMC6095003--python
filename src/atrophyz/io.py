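"""Cohort-table and image I/O.

Cohort tables are CSV with the documented column dictionary (see
``synthetic.COHORT_COLUMNS``); extra columns round-trip as opaque
passthrough. Images and masks are NIfTI-1; the voxel size is read from the
header zooms. Truth parameters travel as a JSON sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .synthetic import COHORT_COLUMNS, PhantomResult
from .volumetry import LesionMap, TissueMaps

__all__ = [
    "read_cohort_csv", "write_cohort_csv",
    "save_image", "load_image", "save_phantom", "load_tissue_maps",
]

REQUIRED_COLUMNS = ("id", "cohort", "scanner", "age", "tiv")


def write_cohort_csv(table: pd.DataFrame, path, truth_sidecar: bool = True) -> None:
    """Write a cohort table; ground-truth attrs go to ``<path>.truth.json``."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table lacks required columns: {missing}")
    path = Path(path)
    # shortest round-trip float text so read-back is value-exact
    table.to_csv(path, index=False,
                 float_format=lambda v: repr(float(v)))
    if truth_sidecar and table.attrs.get("truth"):
        with open(path.with_suffix(path.suffix + ".truth.json"), "w") as fh:
            json.dump(table.attrs["truth"], fh, indent=1)


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table, validating the documented schema.

    Unknown columns are preserved; EDSS values off the 0-10 half-step grid
    trigger a validation warning. A truth sidecar, if present, is restored
    into ``DataFrame.attrs['truth']``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name} lacks required columns: {missing}")
    if "edss" in df.columns:
        edss = df["edss"].dropna().to_numpy(float)
        off_grid = edss[(edss < 0) | (edss > 10) |
                        (np.abs(edss * 2 - np.round(edss * 2)) > 1e-9)]
        if off_grid.size:
            warnings.warn(
                f"{off_grid.size} EDSS value(s) off the 0-10 half-step grid",
                UserWarning, stacklevel=2)
    sidecar = path.with_suffix(path.suffix + ".truth.json")
    if sidecar.exists():
        with open(sidecar) as fh:
            df.attrs["truth"] = json.load(fh)
    return df


def save_image(array: np.ndarray, voxel_size, path) -> None:
    """Write a 3D array as NIfTI-1 with the voxel size in the header."""
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine)
    img.header.set_zooms(tuple(float(v) for v in voxel_size))
    nib.save(img, str(path))


def load_image(path):
    """Read a NIfTI image; returns (array, voxel_size)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), \
        tuple(float(z) for z in img.header.get_zooms()[:3])


def save_phantom(phantom: PhantomResult, outdir) -> dict:
    """Write one NIfTI per tissue class/mask plus a truth JSON; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    vs = phantom.voxel_size
    for name, arr in (("gm", phantom.gm), ("wm", phantom.wm),
                      ("csf", phantom.csf), ("lesions", phantom.lesions),
                      ("t1", phantom.t1)):
        p = outdir / f"{name}.nii.gz"
        save_image(arr, vs, p)
        paths[name] = str(p)
    for name, mask in phantom.masks.items():
        p = outdir / f"mask_{name}.nii.gz"
        save_image(mask, vs, p)
        paths[f"mask_{name}"] = str(p)
    truth_path = outdir / "truth.json"
    with open(truth_path, "w") as fh:
        json.dump({k: float(v) for k, v in phantom.truth.items()}, fh, indent=1)
    paths["truth"] = str(truth_path)
    return paths


def load_tissue_maps(gm_path, wm_path, csf_path) -> TissueMaps:
    gm, vs = load_image(gm_path)
    wm, _ = load_image(wm_path)
    csf, _ = load_image(csf_path)
    return TissueMaps(gm=gm, wm=wm, csf=csf, voxel_size=vs)


def load_lesion_map(path) -> LesionMap:
    arr, vs = load_image(path)
    return LesionMap(mask=np.round(arr).astype(np.uint8), voxel_size=vs)
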