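"""Disk formats: NIfTI volumes, YAML sidecars, CSV tables, TIFF histology.

NIfTI is the universal volume container here. Voxel spacing is recorded in
the affine (mm); multi-volume stacks use the 4th/5th dimensions. The wave
acquisition travels as a 5-D NIfTI (x, y, z, encoding direction, wave
phase) with a YAML sidecar holding frequency, phase-to-displacement scale,
wave-phase offsets and spacing. DWI gradient tables use the plain-text
FSL-style bval/bvec dialect.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .phantom import DWISet, EchoTrain, PropertyPhantom
from .recon import Elastogram
from .wavesim import WaveAcquisition

__all__ = [
    "save_volume",
    "load_volume",
    "save_acquisition",
    "load_acquisition",
    "save_elastogram",
    "save_echo_train",
    "load_echo_train",
    "save_dwi",
    "load_dwi",
    "save_phantom",
    "save_table",
    "load_table",
    "save_yaml",
    "load_yaml",
    "save_histology_tiff",
    "load_histology_tiff",
]


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(path: str | Path, data: np.ndarray, spacing_mm) -> None:
    img = nib.Nifti1Image(np.asarray(data), _affine(spacing_mm))
    img.header.set_zooms(tuple(spacing_mm) + (1.0,) * (data.ndim - 3))
    nib.save(img, str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), spacing


def save_acquisition(prefix: str | Path, acq: WaveAcquisition) -> None:
    """Write <prefix>.nii.gz (5-D phases) and <prefix>.yaml (geometry)."""
    prefix = Path(prefix)
    save_volume(prefix.with_suffix(".nii.gz"), acq.phase_images, acq.spacing_mm)
    meta = dict(
        frequency_hz=float(acq.frequency),
        scale_rad_per_m=float(acq.scale),
        phase_offsets_rad=[float(t) for t in acq.phase_offsets],
        spacing_mm=[float(s) for s in acq.spacing_mm],
        wrap_applied=bool(acq.wrap_applied),
    )
    save_yaml(prefix.with_suffix(".yaml"), meta)


def load_acquisition(prefix: str | Path) -> WaveAcquisition:
    prefix = Path(prefix)
    data, _ = load_volume(prefix.with_suffix(".nii.gz"))
    meta = load_yaml(prefix.with_suffix(".yaml"))
    return WaveAcquisition(
        phase_images=np.asarray(data, float),
        scale=meta["scale_rad_per_m"],
        frequency=meta["frequency_hz"],
        spacing_mm=tuple(meta["spacing_mm"]),
        wrap_applied=meta["wrap_applied"],
        phase_offsets=np.asarray(meta["phase_offsets_rad"]),
    )


def save_elastogram(outdir: str | Path, elast: Elastogram, spacing_mm) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(outdir / "gd.nii.gz", elast.gd, spacing_mm)
    save_volume(outdir / "gl.nii.gz", elast.gl, spacing_mm)
    save_volume(outdir / "gstar.nii.gz", elast.g_magnitude, spacing_mm)
    save_volume(outdir / "y.nii.gz", elast.y, spacing_mm)
    save_volume(outdir / "validity.nii.gz", elast.validity.astype(np.uint8), spacing_mm)


def save_echo_train(prefix: str | Path, train: EchoTrain, spacing_mm) -> None:
    prefix = Path(prefix)
    save_volume(prefix.with_suffix(".nii.gz"), train.signal, spacing_mm)
    save_yaml(prefix.with_suffix(".yaml"), dict(
        te_ms=[float(t) for t in train.te_list], noise_sd=float(train.noise_sd)
    ))


def load_echo_train(prefix: str | Path) -> tuple[EchoTrain, tuple[float, float, float]]:
    prefix = Path(prefix)
    data, spacing = load_volume(prefix.with_suffix(".nii.gz"))
    meta = load_yaml(prefix.with_suffix(".yaml"))
    train = EchoTrain(te_list=np.asarray(meta["te_ms"]), signal=np.asarray(data, float),
                      noise_sd=meta["noise_sd"])
    return train, spacing


def save_dwi(prefix: str | Path, dwi: DWISet, spacing_mm) -> None:
    """4-D NIfTI plus FSL-style .bval (one row) and .bvec (three rows)."""
    prefix = Path(prefix)
    save_volume(prefix.with_suffix(".nii.gz"), dwi.signal, spacing_mm)
    np.savetxt(str(prefix) + ".bval", dwi.bvalues[None, :], fmt="%.17g")
    np.savetxt(str(prefix) + ".bvec", dwi.directions.T, fmt="%.17g")


def load_dwi(prefix: str | Path) -> tuple[DWISet, tuple[float, float, float]]:
    prefix = Path(prefix)
    data, spacing = load_volume(prefix.with_suffix(".nii.gz"))
    bvals = np.loadtxt(str(prefix) + ".bval").ravel()
    bvecs = np.loadtxt(str(prefix) + ".bvec").T
    return DWISet(bvalues=bvals, directions=bvecs, signal=np.asarray(data, float)), spacing


def save_phantom(outdir: str | Path, phantom: PropertyPhantom) -> None:
    """One NIfTI per truth quantity plus an integer label volume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = phantom.spacing_mm
    save_volume(outdir / "gd_truth.nii.gz", phantom.storage_modulus, sp)
    save_volume(outdir / "gl_truth.nii.gz", phantom.loss_modulus, sp)
    save_volume(outdir / "density.nii.gz", phantom.density, sp)
    save_volume(outdir / "t2_truth.nii.gz", phantom.t2, sp)
    save_volume(outdir / "tensors_truth.nii.gz", phantom.tensors, sp)
    save_volume(outdir / "labels.nii.gz", phantom.labels.astype(np.int16), sp)
    from .phantom import REGION_IDS

    save_yaml(outdir / "labels.yaml", dict(REGION_IDS))


def save_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_yaml(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_histology_tiff(path: str | Path, pixels: np.ndarray) -> None:
    tifffile.imwrite(str(path), pixels, photometric="rgb")


def load_histology_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))
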