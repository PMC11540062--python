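"""File I/O: NIfTI volumes, FSL-style gradient tables, CSV tables, JSON truth."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .dti import DWIVolume
from .freewater import FWMaps
from .protocol import AcquisitionProtocol

__all__ = [
    "read_bvals_bvecs", "write_bvals_bvecs",
    "read_dwi", "write_dwi",
    "write_nifti", "read_nifti",
    "write_fw_maps",
]


def read_bvals_bvecs(bval_path, bvec_path) -> AcquisitionProtocol:
    """Read FSL-style plain-text b-value and gradient files.

    bvals: one row of values; bvecs: three rows (x, y, z components).
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return AcquisitionProtocol(bvals=bvals, bvecs=bvecs)


def write_bvals_bvecs(protocol: AcquisitionProtocol, bval_path, bvec_path) -> None:
    np.savetxt(bval_path, protocol.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, protocol.bvecs.T, fmt="%.6f")


def write_nifti(data: np.ndarray, path, affine=None) -> None:
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(data), affine)
    nib.save(img, str(path))


def read_nifti(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def write_dwi(dwi: DWIVolume, prefix) -> dict:
    """Write signal, mask and gradient table; returns the paths used."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "dwi": f"{prefix}.nii.gz",
        "mask": f"{prefix}_mask.nii.gz",
        "bval": f"{prefix}.bval",
        "bvec": f"{prefix}.bvec",
    }
    write_nifti(dwi.signal, paths["dwi"], dwi.affine)
    write_nifti(dwi.mask.astype(np.uint8), paths["mask"], dwi.affine)
    write_bvals_bvecs(dwi.protocol, paths["bval"], paths["bvec"])
    return paths


def read_dwi(dwi_path, bval_path, bvec_path, mask_path=None) -> DWIVolume:
    signal, affine = read_nifti(dwi_path)
    protocol = read_bvals_bvecs(bval_path, bvec_path)
    if mask_path is not None:
        mask, _ = read_nifti(mask_path)
        mask = mask.astype(bool)
    else:
        mask = np.ones(signal.shape[:3], dtype=bool)
    vox = tuple(float(v) for v in np.abs(np.diag(affine))[:3])
    return DWIVolume(signal=np.asarray(signal, dtype=float), protocol=protocol,
                     mask=mask, voxel_size=vox, affine=affine)


def write_fw_maps(maps: FWMaps, out_dir, prefix: str = "fw") -> dict:
    """Write fw / fa maps and flags as NIfTI plus a JSON diagnostics sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (("fw", maps.fw), ("fa_fwcorr", maps.fa_fwcorr),
                      ("fa_conv", maps.fa_conv), ("s0", maps.s0)):
        p = out_dir / f"{prefix}_{name}.nii.gz"
        write_nifti(arr, p, maps.affine)
        paths[name] = str(p)
    for name, arr in maps.flags.items():
        p = out_dir / f"{prefix}_flag_{name}.nii.gz"
        write_nifti(arr.astype(np.uint8), p, maps.affine)
        paths[f"flag_{name}"] = str(p)
    n_mask = int(maps.mask.sum())
    diag = {
        "n_mask_voxels": n_mask,
        "n_degenerate": int(maps.flags["degenerate_isotropic"].sum()),
        "n_clipped": int(maps.flags["clipped"].sum()),
        "n_converged": int(maps.flags["converged"].sum()),
        "fw_mean_in_mask": float(maps.fw[maps.mask].mean()) if n_mask else None,
    }
    p = out_dir / f"{prefix}_diagnostics.json"
    p.write_text(json.dumps(diag, indent=2))
    paths["diagnostics"] = str(p)
    return paths
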