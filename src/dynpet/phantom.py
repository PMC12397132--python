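"""Geometric thorax phantom and noise-free 4D ground truth.

A stylized, deterministic stand-in for an anthropomorphic labeled thorax:
body outline with a fat rim and muscle interior, two lungs, heart, liver,
spleen, spine and sternum (bone), a descending-aorta cylinder (arterial
blood pool), a vena-cava cylinder (venous blood pool) and two lung tumors,
each with a center core and a border shell.  All structures except the
tumors are extruded along z so every axial slice carries the full tissue
inventory; tumor cores span a narrower z range than their border shells so
the core is strictly contained in the shell in 3-D.

Every label carries the reference kinetic parameters packaged with the
library (estimated from one-hour thoracic FDG acquisitions); blood-pool
labels carry the input function directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .kinetics import InputFunction, KineticParams, tissue_tac
from .schedule import FrameSchedule

# label ids (0 = air)
FAT, MUSCLE, LUNGS, BONE, HEART, LIVER, SPLEEN = 1, 2, 3, 4, 5, 6, 7
TUMOR_R_BORDER, TUMOR_R_CENTER, TUMOR_L_BORDER, TUMOR_L_CENTER = 8, 9, 10, 11
AORTA, CAVA = 12, 13

LABEL_NAMES = {
    FAT: "fat", MUSCLE: "muscle", LUNGS: "lungs", BONE: "bone",
    HEART: "heart", LIVER: "liver", SPLEEN: "spleen",
    TUMOR_R_BORDER: "tumor_r_border", TUMOR_R_CENTER: "tumor_r_center",
    TUMOR_L_BORDER: "tumor_l_border", TUMOR_L_CENTER: "tumor_l_center",
    AORTA: "aorta", CAVA: "cava",
}

#: the 11 tissue structures evaluated in bias/CNR tables (blood pools excluded)
TISSUE_STRUCTURES = [
    "tumor_r_border", "tumor_r_center", "tumor_l_border", "tumor_l_center",
    "liver", "lungs", "bone", "heart", "spleen", "muscle", "fat",
]

#: 511 keV linear attenuation coefficients by tissue class (1/cm)
MU_BY_CLASS = {"air": 0.0, "lung": 0.03, "soft": 0.096, "bone": 0.17}


@dataclass(frozen=True)
class StructureDef:
    name: str
    tissue_class: str          # "tissue" | "arterial" | "venous"
    params: Optional[KineticParams]  # None for blood pools
    attenuation_class: str     # key into MU_BY_CLASS


@dataclass
class PhantomSpec:
    """Labeled voxel grid plus the per-label structure table."""

    label_grid: np.ndarray          # int16, 0 = air
    label_table: Dict[int, StructureDef]
    voxel_size: Tuple[float, float, float]  # mm

    def __post_init__(self) -> None:
        classes = [d.tissue_class for d in self.label_table.values()]
        if classes.count("arterial") != 1 or classes.count("venous") != 1:
            raise ValueError("exactly one arterial and one venous blood label required")
        present = set(np.unique(self.label_grid)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels without parameters: {sorted(missing)}")

    @property
    def arterial_label(self) -> int:
        return next(l for l, d in self.label_table.items() if d.tissue_class == "arterial")

    @property
    def venous_label(self) -> int:
        return next(l for l, d in self.label_table.items() if d.tissue_class == "venous")

    def voxel_counts(self) -> Dict[str, int]:
        labels, counts = np.unique(self.label_grid, return_counts=True)
        return {self.label_table[l].name: int(c)
                for l, c in zip(labels, counts) if l != 0}

    def mask(self, label: int) -> np.ndarray:
        return self.label_grid == label

    def mu_map(self) -> np.ndarray:
        """Piecewise-constant 511 keV attenuation map (1/cm)."""
        mu = np.zeros(self.label_grid.shape, dtype=float)
        for label, d in self.label_table.items():
            mu[self.label_grid == label] = MU_BY_CLASS[d.attenuation_class]
        return mu


def load_reference_kinetic_params() -> pd.DataFrame:
    """Packaged per-tissue reference values (2TCM K1,k2,k3,vb,Ki + Patlak Ki,vb)."""
    from .evaluation import _read_packaged_csv
    return _read_packaged_csv("reference_kinetic_params.csv").set_index("structure")


def _default_label_table(params: Optional[pd.DataFrame] = None) -> Dict[int, StructureDef]:
    tab = load_reference_kinetic_params() if params is None else params

    def kp(row: str) -> KineticParams:
        r = tab.loc[row]
        return KineticParams(r["K1"], r["k2"], r["k3"], r["vb"])

    return {
        FAT: StructureDef("fat", "tissue", kp("fat"), "soft"),
        MUSCLE: StructureDef("muscle", "tissue", kp("muscle"), "soft"),
        LUNGS: StructureDef("lungs", "tissue", kp("lungs"), "lung"),
        BONE: StructureDef("bone", "tissue", kp("bone"), "bone"),
        HEART: StructureDef("heart", "tissue", kp("heart"), "soft"),
        LIVER: StructureDef("liver", "tissue", kp("liver"), "soft"),
        SPLEEN: StructureDef("spleen", "tissue", kp("spleen"), "soft"),
        TUMOR_R_BORDER: StructureDef("tumor_r_border", "tissue", kp("tumor_border"), "soft"),
        TUMOR_R_CENTER: StructureDef("tumor_r_center", "tissue", kp("tumor_center"), "soft"),
        TUMOR_L_BORDER: StructureDef("tumor_l_border", "tissue", kp("tumor_border"), "soft"),
        TUMOR_L_CENTER: StructureDef("tumor_l_center", "tissue", kp("tumor_center"), "soft"),
        AORTA: StructureDef("aorta", "arterial", None, "soft"),
        CAVA: StructureDef("cava", "venous", None, "soft"),
    }


def build_thorax_phantom(grid_shape: Tuple[int, int, int] = (128, 128, 16),
                         voxel_size: Tuple[float, float, float] = (3.0, 3.0, 6.0),
                         params_table: Optional[pd.DataFrame] = None) -> PhantomSpec:
    """Deterministic geometric thorax with 13 labels (11 tissues + 2 blood pools).

    Structure placement scales with the grid, so voxel counts grow ~linearly
    with in-plane area x slices.  Grids smaller than 48x48x4 cannot hold all
    structures without overlap and are rejected.
    """
    nx, ny, nz = grid_shape
    if nx < 48 or ny < 48 or nz < 4:
        raise ValueError(f"grid {grid_shape} too small; need >= 48x48x4")

    xi, yi = np.meshgrid(np.arange(nx) + 0.5, np.arange(ny) + 0.5, indexing="ij")

    def ellipse(cx, cy, rx, ry):
        return ((xi - cx * nx) / (rx * nx)) ** 2 + ((yi - cy * ny) / (ry * ny)) ** 2 <= 1.0

    lab2d = np.zeros((nx, ny), dtype=np.int16)

    def paint(mask, label):
        lab2d[mask] = label

    paint(ellipse(0.50, 0.50, 0.45, 0.38), FAT)          # body outline
    paint(ellipse(0.50, 0.50, 0.41, 0.34), MUSCLE)       # interior
    lung_l = ellipse(0.31, 0.42, 0.135, 0.20)
    lung_r = ellipse(0.69, 0.42, 0.135, 0.20)
    paint(lung_l | lung_r, LUNGS)
    paint(ellipse(0.50, 0.45, 0.085, 0.105), HEART)      # mediastinum
    paint(ellipse(0.63, 0.66, 0.15, 0.105), LIVER)
    paint(ellipse(0.32, 0.68, 0.075, 0.055), SPLEEN)
    paint(ellipse(0.50, 0.82, 0.055, 0.055), BONE)       # spine
    paint(ellipse(0.50, 0.145, 0.045, 0.028), BONE)      # sternum
    # blood-pool diameters match clinical vessel calibres in pixel units
    # (aorta ~8 px, cava ~7 px on the default 48-px thorax) so the pools
    # survive the reconstruction point spread as they do clinically
    paint(ellipse(0.60, 0.72, 0.075, 0.075), AORTA)      # descending aorta
    paint(ellipse(0.40, 0.70, 0.070, 0.070), CAVA)       # vena cava

    grid = np.repeat(lab2d[:, :, None], nz, axis=2)

    # tumors: border shell spans a wider z range than the center core so the
    # core is strictly inside the shell in all three directions
    z_all = np.arange(nz)
    z_shell = (z_all >= max(0, nz // 2 - max(1, nz // 4) - 1)) & \
              (z_all <= min(nz - 1, nz // 2 + max(1, nz // 4)))
    z_core = (z_all >= max(1, nz // 2 - max(1, nz // 4))) & \
             (z_all <= min(nz - 2, nz // 2 + max(1, nz // 4) - 1))

    def add_tumor(cx, cy, r_out, r_in, lab_border, lab_center):
        outer = ellipse(cx, cy, r_out, r_out)
        inner = ellipse(cx, cy, r_in, r_in)
        if not inner.any() or not (outer & ~inner).any():
            raise ValueError("grid too small to resolve tumor core and shell")
        grid[:, :, z_shell] = np.where(outer[:, :, None], lab_border,
                                       grid[:, :, z_shell])
        grid[:, :, z_core] = np.where(inner[:, :, None], lab_center,
                                      grid[:, :, z_core])

    add_tumor(0.70, 0.36, 0.055, 0.030, TUMOR_R_BORDER, TUMOR_R_CENTER)
    add_tumor(0.29, 0.33, 0.070, 0.040, TUMOR_L_BORDER, TUMOR_L_CENTER)

    spec = PhantomSpec(grid, _default_label_table(params_table), tuple(voxel_size))
    counts = spec.voxel_counts()
    empty = [n for n in LABEL_NAMES.values() if counts.get(n, 0) == 0]
    if empty:
        raise ValueError(f"grid {grid_shape} leaves structures empty: {empty}")
    return spec


@dataclass
class DynamicImage:
    """4D activity-concentration volume (kBq/mL) on a frame schedule."""

    data: np.ndarray                       # (x, y, z, frame)
    schedule: FrameSchedule
    voxel_size: Tuple[float, float, float]  # mm
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DynamicImage data must be 4-D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"frame axis has {self.data.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}")

    @property
    def shape3(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]


def label_tacs(phantom: PhantomSpec, schedule: FrameSchedule,
               inp: InputFunction, dt_s: float = 1.0) -> Dict[int, np.ndarray]:
    """Noise-free frame-averaged TAC per label (blood pools carry Cb)."""
    t_s = np.arange(0.0, schedule.end_s[-1] + 0.5 * dt_s, dt_s)
    from .kinetics import frame_average
    blood = frame_average(t_s, inp.cb_at(t_s / 60.0), schedule).frame_values
    out: Dict[int, np.ndarray] = {}
    for label, d in phantom.label_table.items():
        if d.tissue_class in ("arterial", "venous"):
            out[label] = blood
        else:
            try:
                out[label] = tissue_tac(d.params, inp, schedule, dt_s).frame_values
            except Exception as exc:
                raise type(exc)(f"label '{d.name}': {exc}") from exc
    return out


def synthesize_ground_truth(phantom: PhantomSpec, schedule: FrameSchedule,
                            inp: InputFunction, dt_s: float = 1.0) -> DynamicImage:
    """Noise-free, decay-corrected 4D volume from per-label kinetics."""
    tacs = label_tacs(phantom, schedule, inp, dt_s)
    lut = np.zeros((max(phantom.label_table, default=0) + 1, schedule.n_frames))
    for label, tac in tacs.items():
        lut[label] = tac
    data = lut[phantom.label_grid]          # (x, y, z, frame)
    return DynamicImage(data, schedule, phantom.voxel_size, decay_corrected=True)
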