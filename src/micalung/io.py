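"""NIfTI import/export for volumes, label maps and displacement fields.

Each volume is written as a NIfTI-1 file with the voxel spacing in the
affine, plus a YAML sidecar carrying the lobe-label integer coding.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .voxel_metrics import LOBES, AirFractionVolume, DisplacementField, PRMMap

_LOBE_CODES = {name: i + 1 for i, name in enumerate(LOBES)}  # 0 = outside


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def save_volume(vol: AirFractionVolume, prefix: str | Path) -> None:
    """Write ``<prefix>.nii`` (air fraction), ``<prefix>_lobes.nii`` and a
    ``<prefix>.yaml`` sidecar."""
    prefix = Path(prefix)
    aff = _affine(vol.spacing)
    nib.save(nib.Nifti1Image(vol.values.astype(np.float32), aff), f"{prefix}.nii")
    lobes = np.zeros(vol.values.shape, dtype=np.int16)
    for name, mask in vol.lobe_labels.items():
        lobes[mask] = _LOBE_CODES[name]
    nib.save(nib.Nifti1Image(lobes, aff), f"{prefix}_lobes.nii")
    sidecar = {"spacing_mm": [float(s) for s in vol.spacing], "lobe_codes": _LOBE_CODES}
    Path(f"{prefix}.yaml").write_text(yaml.safe_dump(sidecar))


def load_volume(prefix: str | Path) -> AirFractionVolume:
    prefix = Path(prefix)
    img = nib.load(f"{prefix}.nii")
    meta = yaml.safe_load(Path(f"{prefix}.yaml").read_text())
    values = np.asarray(img.dataobj, dtype=float)
    lobes_img = np.asarray(nib.load(f"{prefix}_lobes.nii").dataobj)
    codes = meta["lobe_codes"]
    lobe_labels = {name: lobes_img == code for name, code in codes.items()}
    mask = lobes_img > 0
    return AirFractionVolume(values, tuple(meta["spacing_mm"]), mask, lobe_labels)


def save_displacement(disp: DisplacementField, prefix: str | Path) -> None:
    prefix = Path(prefix)
    aff = _affine(disp.spacing)
    nib.save(nib.Nifti1Image(disp.vectors.astype(np.float32), aff), f"{prefix}_disp.nii")
    nib.save(nib.Nifti1Image(disp.mask.astype(np.int16), aff), f"{prefix}_dispmask.nii")
    Path(f"{prefix}_disp.yaml").write_text(
        yaml.safe_dump({"spacing_mm": [float(s) for s in disp.spacing]})
    )


def load_displacement(prefix: str | Path) -> DisplacementField:
    prefix = Path(prefix)
    meta = yaml.safe_load(Path(f"{prefix}_disp.yaml").read_text())
    vectors = np.asarray(nib.load(f"{prefix}_disp.nii").dataobj, dtype=float)
    mask = np.asarray(nib.load(f"{prefix}_dispmask.nii").dataobj) > 0
    return DisplacementField(vectors, tuple(meta["spacing_mm"]), mask)


def save_prm(prm: PRMMap, spacing, path: str | Path) -> None:
    """PRM labels as an integer-coded NIfTI (0 outside, 1 Normal, 2 fSAD, 3 Emph)."""
    nib.save(nib.Nifti1Image(prm.labels.astype(np.int16), _affine(spacing)), str(path))
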