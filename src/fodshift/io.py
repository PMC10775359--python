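"""Reading and writing the standard on-disk formats.

Volumes are NIfTI (via nibabel) on a nominal 1.5 mm isotropic grid;
gradient tables are FSL-style ``bvals``/``bvecs`` text files; SH
coefficient volumes are 4D NIfTI (x, y, z, coeff) whose header carries the
basis convention and lmax in the ``descrip`` field, checked on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .sh_core import BASIS_CONVENTION, SHCoefficientField, lmax_for_n_coeffs
from .synthetic_cohort import FiberConfig, GradientScheme, SubjectPhantom

__all__ = [
    "save_nifti",
    "load_nifti",
    "write_bvals_bvecs",
    "read_bvals_bvecs",
    "save_sh_field",
    "load_sh_field",
    "save_subject",
    "load_subject",
]

VOXEL_SIZE_MM = 1.5


def _affine() -> np.ndarray:
    return np.diag([VOXEL_SIZE_MM, VOXEL_SIZE_MM, VOXEL_SIZE_MM, 1.0])


def save_nifti(path, data: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), _affine()), str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_bvals_bvecs(prefix, scheme: GradientScheme) -> None:
    """Write ``<prefix>.bval`` / ``<prefix>.bvec`` (FSL row convention)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(prefix.with_suffix(".bvec"), scheme.bvecs.T, fmt="%.8f")


def read_bvals_bvecs(prefix) -> GradientScheme:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).reshape(-1)
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).reshape(3, -1).T
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def save_sh_field(path, field: SHCoefficientField) -> None:
    img = nib.Nifti1Image(np.asarray(field.coefficients), _affine())
    img.header["descrip"] = f"sh:{field.basis_convention};lmax={field.lmax}".encode()
    nib.save(img, str(path))


def load_sh_field(path) -> SHCoefficientField:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    descrip = bytes(img.header["descrip"]).decode(errors="ignore").rstrip("\x00")
    lmax = lmax_for_n_coeffs(data.shape[-1])
    if descrip.startswith("sh:"):
        convention = descrip[3:].split(";")[0]
        if convention != BASIS_CONVENTION:
            raise ValueError(f"SH basis convention mismatch: {convention!r}")
        if f"lmax={lmax}" not in descrip:
            raise ValueError("header lmax does not match coefficient count")
    return SHCoefficientField(lmax=lmax, coefficients=data)


def save_subject(directory, subject: SubjectPhantom) -> None:
    """Write one phantom: dwi.nii.gz, bvals/bvecs, wm_mask.nii.gz,
    gt_fod.nii.gz and subject.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_nifti(d / "dwi.nii.gz", subject.dwi.astype(np.float32))
    write_bvals_bvecs(d / "dwi", subject.scheme)
    save_nifti(d / "wm_mask.nii.gz", subject.wm_mask.astype(np.uint8))
    save_sh_field(d / "gt_fod.nii.gz", subject.gt_fod)
    meta = {
        "subject_id": subject.subject_id,
        "age_months": subject.age,
        "site": subject.site,
        "seed": subject.seed,
    }
    (d / "subject.json").write_text(json.dumps(meta, indent=2))


def load_subject(directory) -> SubjectPhantom:
    d = Path(directory)
    meta = json.loads((d / "subject.json").read_text())
    dwi = load_nifti(d / "dwi.nii.gz").astype(np.float32)
    scheme = read_bvals_bvecs(d / "dwi")
    wm = load_nifti(d / "wm_mask.nii.gz").astype(bool)
    gt = load_sh_field(d / "gt_fod.nii.gz")
    # fiber configuration is not serialized; peaks of the GT FOD carry it
    empty = FiberConfig(
        directions=np.zeros(wm.shape + (3, 3)),
        fractions=np.zeros(wm.shape + (3,)),
        counts=np.zeros(wm.shape, dtype=int),
    )
    return SubjectPhantom(
        subject_id=meta["subject_id"],
        dwi=dwi,
        scheme=scheme,
        gt_fod=gt,
        fiber_config=empty,
        wm_mask=wm,
        age=meta["age_months"],
        site=meta["site"],
        seed=meta["seed"],
    )
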