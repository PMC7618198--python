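"""File interfaces: NIfTI images, HDF5 k-space containers, configs.

Conventions
-----------
* images and field maps are written as NIfTI (.nii.gz); field maps in
  Hz carry their space tag ("distorted" / "undistorted") in the header
  description field;
* k-space goes into an HDF5 container with datasets ``kspace``
  (complex, n_lines x n_coils x n_readout), ``sensitivities`` (complex)
  and ``noise_sigma``, plus the trajectory sidecar as a JSON string
  attribute;
* run configurations are YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .fieldmap import FieldMap
from .simulate import KspaceData, SensitivityMaps
from .trajectory import Trajectory

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_fieldmap",
    "load_fieldmap",
    "save_kspace",
    "load_kspace",
    "load_config",
    "save_config",
]


def save_nifti(path, array: np.ndarray, description: str = "") -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), affine=np.eye(4))
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def save_fieldmap(path, fm: FieldMap) -> None:
    img = nib.Nifti1Image(fm.b0_hz.astype(np.float64), affine=np.eye(4))
    img.header["descrip"] = f"dB0 Hz; space={fm.space_tag}".encode()[:79]
    nib.save(img, str(path))
    mask_path = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    nib.save(
        nib.Nifti1Image(fm.mask.astype(np.uint8), affine=np.eye(4)),
        str(mask_path) + "_mask.nii.gz",
    )


def load_fieldmap(path) -> FieldMap:
    img = nib.load(str(path))
    desc = img.header["descrip"].tobytes().decode(errors="ignore")
    space = "distorted" if "distorted" in desc and "undistorted" not in desc else (
        "undistorted" if "undistorted" in desc else "distorted"
    )
    b0 = np.asarray(img.dataobj, dtype=np.float64)
    mask_path = str(Path(str(path)).with_suffix("").with_suffix("")) + "_mask.nii.gz"
    if Path(mask_path).exists():
        mask = np.asarray(nib.load(mask_path).dataobj) > 0
    else:
        mask = np.ones(b0.shape, dtype=bool)
    return FieldMap(b0_hz=b0, mask=mask, space_tag=space)


def save_kspace(path, kspace: KspaceData, sens: SensitivityMaps | None = None) -> None:
    with h5py.File(str(path), "w") as fh:
        fh.create_dataset("kspace", data=kspace.samples)
        fh.create_dataset("noise_sigma", data=kspace.noise_sigma)
        if sens is not None:
            fh.create_dataset("sensitivities", data=sens.maps)
        fh.attrs["trajectory"] = json.dumps(kspace.traj.to_dict())


def load_kspace(path) -> tuple[KspaceData, SensitivityMaps | None]:
    with h5py.File(str(path), "r") as fh:
        samples = fh["kspace"][()]
        noise_sigma = float(fh["noise_sigma"][()])
        sens = (
            SensitivityMaps(maps=fh["sensitivities"][()])
            if "sensitivities" in fh
            else None
        )
        traj = Trajectory.from_dict(json.loads(fh.attrs["trajectory"]))
    return KspaceData(samples=samples, traj=traj, noise_sigma=noise_sigma), sens


def load_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(path, cfg: dict) -> None:
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(cfg, indent=1))
    else:
        Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
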