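"""NIfTI and sidecar I/O for dynamic volumes, label maps and parametric maps."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .fitting import ParametricMaps
from .phantom import DynamicImage, PhantomSpec
from .schedule import FrameSchedule


def _affine(voxel_size_mm: Tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(voxel_size_mm) + [1.0])
    return aff


def write_dynamic_nifti(path, dyn: DynamicImage) -> None:
    img = nib.Nifti1Image(dyn.data.astype(np.float32), _affine(dyn.voxel_size))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def read_dynamic_nifti(path, schedule_path) -> DynamicImage:
    """Load a 4-D volume and its frame schedule, validating the frame axis."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path} is {data.ndim}-D; a 4-D dynamic volume is required")
    schedule = FrameSchedule.from_text(schedule_path)
    if data.shape[3] != schedule.n_frames:
        raise ValueError(
            f"volume has {data.shape[3]} frames but the schedule lists "
            f"{schedule.n_frames}")
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    return DynamicImage(np.asarray(data, dtype=float), schedule, voxel_size)


def write_label_nifti(path, phantom: PhantomSpec) -> None:
    img = nib.Nifti1Image(phantom.label_grid.astype(np.int16),
                          _affine(phantom.voxel_size))
    nib.save(img, str(path))


def read_mask_nifti(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj) > 0


def read_label_nifti(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj).astype(np.int16)


def write_parametric_maps(out_dir, maps: ParametricMaps,
                          voxel_size_mm: Tuple[float, float, float],
                          prefix: Optional[str] = None) -> dict:
    """One 3-D NIfTI per parameter, a status volume and a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prefix = prefix or maps.model
    written = {}
    for name, vol in maps.params.items():
        p = out / f"{prefix}_{name}.nii"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), _affine(voxel_size_mm)),
                 str(p))
        written[name] = str(p)
    sp = out / f"{prefix}_status.nii"
    nib.save(nib.Nifti1Image(maps.status.astype(np.int8), _affine(voxel_size_mm)),
             str(sp))
    written["status"] = str(sp)
    sidecar = {
        "model": maps.model, "units": "kBq/mL inputs; rate constants 1/min",
        "provenance": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in maps.provenance.items()},
        "files": {k: Path(v).name for k, v in written.items()},
        "n_failed": int((maps.status == 1).sum()),
        "n_masked": int((maps.status == 2).sum()),
    }
    with open(out / f"{prefix}_maps.json", "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return written
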