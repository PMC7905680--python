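"""Readers and writers for on-disk artifacts.

Two bundle layouts per subject:

* one HDF5 file with ``/velocity`` [t, 3, x, y, z] (cm/s), ``/mask``
  (uint8), ``/volume_series`` (mL) and metadata attributes;
* a directory of NIfTI-1 files (``vel_x.nii``, ``vel_y.nii``,
  ``vel_z.nii`` as 4-D x,y,z,t volumes in cm/s, ``mask.nii`` uint8) plus a
  ``meta.json`` sidecar.  NIfTI affines carry the spacing in millimetres
  (the scanner convention); spacings are converted to the internal
  centimetre convention on read and never defaulted silently.

Tables (flow curves, biomarkers, cohorts, stats) are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .core import AlignmentError, GridSpec, VelocityField4D, VentricleMask


def save_bundle_hdf5(
    path,
    field: VelocityField4D,
    mask: VentricleMask,
    volume_series: np.ndarray,
    meta: Optional[dict] = None,
) -> None:
    if mask.voxels.shape != field.grid.shape:
        raise AlignmentError(
            f"mask shape {mask.voxels.shape} vs grid {field.grid.shape}"
        )
    with h5py.File(path, "w") as f:
        f.create_dataset("velocity", data=field.values, compression="gzip", compression_opts=1)
        f.create_dataset("mask", data=mask.voxels.astype(np.uint8))
        f.create_dataset("volume_series", data=np.asarray(volume_series, dtype=float))
        f.attrs["spacing_mm"] = field.grid.spacing_mm
        f.attrs["n_frames"] = field.grid.n_frames
        f.attrs["rr_interval_s"] = field.grid.rr_interval
        f.attrs["venc_cm_s"] = field.venc
        f.attrs["aliased"] = field.aliased
        f.attrs["chamber"] = mask.chamber
        f.attrs["meta_json"] = json.dumps(meta or {})


def load_bundle_hdf5(path) -> Tuple[VelocityField4D, VentricleMask, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        if "mask" not in f:
            raise KeyError(f"{path}: bundle has no /mask dataset")
        if "spacing_mm" not in f.attrs:
            raise KeyError(f"{path}: bundle lacks spacing_mm; refusing to guess")
        values = f["velocity"][...]
        grid = GridSpec(
            shape=values.shape[2:],
            spacing_mm=tuple(float(s) for s in f.attrs["spacing_mm"]),
            n_frames=int(f.attrs["n_frames"]),
            rr_interval=float(f.attrs["rr_interval_s"]),
        )
        if values.shape != (grid.n_frames, 3, *grid.shape):
            raise AlignmentError(
                f"velocity shape {values.shape} inconsistent with header frames/grid"
            )
        mask_arr = f["mask"][...].astype(bool)
        if mask_arr.shape != grid.shape:
            raise AlignmentError(
                f"mask shape {mask_arr.shape} does not match grid {grid.shape}"
            )
        field = VelocityField4D(
            values, grid, venc=float(f.attrs["venc_cm_s"]), aliased=bool(f.attrs["aliased"])
        )
        mask = VentricleMask(mask_arr, str(f.attrs["chamber"]))
        series = f["volume_series"][...]
        meta = json.loads(f.attrs["meta_json"])
    return field, mask, series, meta


def save_bundle_nifti(
    dirpath,
    field: VelocityField4D,
    mask: VentricleMask,
    volume_series: np.ndarray,
    meta: Optional[dict] = None,
) -> None:
    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*field.grid.spacing_mm, 1.0])
    for c, name in enumerate("xyz"):
        # [t, c, x, y, z] -> [x, y, z, t]
        vol = np.moveaxis(field.values[:, c], 0, -1)
        img = nib.Nifti1Image(vol, affine)
        img.header.set_xyzt_units("mm", "sec")
        nib.save(img, dirpath / f"vel_{name}.nii")
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), dirpath / "mask.nii")
    sidecar = {
        "spacing_mm": list(field.grid.spacing_mm),
        "n_frames": field.grid.n_frames,
        "rr_interval_s": field.grid.rr_interval,
        "venc_cm_s": field.venc,
        "aliased": field.aliased,
        "chamber": mask.chamber,
        "volume_series_ml": np.asarray(volume_series, dtype=float).tolist(),
        "meta": meta or {},
    }
    (dirpath / "meta.json").write_text(json.dumps(sidecar, indent=1))


def load_bundle_nifti(dirpath) -> Tuple[VelocityField4D, VentricleMask, np.ndarray, dict]:
    dirpath = Path(dirpath)
    sidecar_path = dirpath / "meta.json"
    if not sidecar_path.exists():
        raise FileNotFoundError(f"{dirpath}: missing meta.json sidecar (spacing/timing)")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("spacing_mm", "n_frames", "rr_interval_s"):
        if key not in sidecar:
            raise KeyError(f"{dirpath}: sidecar lacks {key!r}; refusing to guess")
    mask_path = dirpath / "mask.nii"
    if not mask_path.exists():
        raise FileNotFoundError(f"{dirpath}: missing mask.nii")
    comps = []
    for name in "xyz":
        img = nib.load(dirpath / f"vel_{name}.nii")
        comps.append(np.moveaxis(np.asarray(img.dataobj, dtype=float), -1, 0))
        zooms = img.header.get_zooms()[:3]
    values = np.stack(comps, axis=1)
    spacing = tuple(float(s) for s in sidecar["spacing_mm"])
    if not np.allclose(zooms, spacing, rtol=1e-4):
        raise AlignmentError(f"NIfTI zooms {zooms} disagree with sidecar spacing {spacing}")
    grid = GridSpec(
        shape=values.shape[2:],
        spacing_mm=spacing,
        n_frames=int(sidecar["n_frames"]),
        rr_interval=float(sidecar["rr_interval_s"]),
    )
    if values.shape[0] != grid.n_frames:
        raise AlignmentError(
            f"velocity has {values.shape[0]} frames but sidecar declares {grid.n_frames}"
        )
    mask_arr = np.asarray(nib.load(mask_path).dataobj).astype(bool)
    if mask_arr.shape != grid.shape:
        raise AlignmentError(
            f"mask shape {mask_arr.shape} does not match velocity grid {grid.shape}"
        )
    field = VelocityField4D(
        values, grid, venc=float(sidecar.get("venc_cm_s", 150.0)),
        aliased=bool(sidecar.get("aliased", False)),
    )
    mask = VentricleMask(mask_arr, str(sidecar.get("chamber", "LV")))
    series = np.asarray(sidecar["volume_series_ml"], dtype=float)
    return field, mask, series, sidecar.get("meta", {})


def save_bundle(path, field, mask, volume_series, meta=None, format: str = "hdf5") -> None:
    if format == "hdf5":
        save_bundle_hdf5(path, field, mask, volume_series, meta)
    elif format == "nifti":
        save_bundle_nifti(path, field, mask, volume_series, meta)
    else:
        raise ValueError(f"unknown bundle format {format!r}; use 'hdf5' or 'nifti'")


def load_bundle(path, format: Optional[str] = None):
    path = Path(path)
    if format is None:
        format = "nifti" if path.is_dir() else "hdf5"
    if format == "hdf5":
        return load_bundle_hdf5(path)
    if format == "nifti":
        return load_bundle_nifti(path)
    raise ValueError(f"unknown bundle format {format!r}; use 'hdf5' or 'nifti'")


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
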