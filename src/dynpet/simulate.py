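"""End-to-end simulation of noisy dynamic PET studies.

For each scanner configuration the noise-free decay-corrected ground truth
is forward-projected per frame and slice, scaled to expected counts (frame
duration x physical decay x scanner sensitivity, plus uniform randoms),
Poisson-sampled per replicate, and reconstructed with OSEM back into
decay-corrected activity concentration (kBq/mL).

Two configurations mirror a short- and a long-axial-FOV system: identical
geometry, but the long-FOV system collects 3.5x the true and random
coincidences and uses 19 OSEM subsets instead of 28.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from .kinetics import InputFunction, decay_factor
from .phantom import DynamicImage, PhantomSpec, synthesize_ground_truth
from .projection import (ProjectionGeometry, add_poisson_noise,
                         attenuation_factors, frame_count_scale, replicate_rng,
                         system_matrix)
from .recon import osem_reconstruct
from .schedule import FrameSchedule

#: sensitivity advantage of the long-axial-FOV configuration
LAFOV_SENSITIVITY_FACTOR = 3.5


@dataclass(frozen=True)
class ScannerConfig:
    """Scanner-and-reconstruction configuration for one simulated system."""

    name: str
    osem_subsets: int
    trues_scale: Optional[float] = None   # counts per (kBq/mL * pixel * s); None = calibrate
    randoms_fraction: float = 0.3
    n_angles: int = 48
    attenuation_on: bool = True
    tof_sensitivity: float = 1.0  # effective extra sensitivity multiplier (stand-in)

    def with_scale(self, scale: float) -> "ScannerConfig":
        return dataclasses.replace(self, trues_scale=scale)


def safov_config(**kw) -> ScannerConfig:
    """Short-axial-FOV-like system: 28 OSEM subsets, baseline sensitivity."""
    return ScannerConfig(name="safov", osem_subsets=28, **kw)


def lafov_config(safov_scale: Optional[float] = None, **kw) -> ScannerConfig:
    """Long-axial-FOV-like system: 19 OSEM subsets, trues/randoms x 3.5."""
    scale = None if safov_scale is None else LAFOV_SENSITIVITY_FACTOR * safov_scale
    return ScannerConfig(name="lafov", osem_subsets=19, trues_scale=scale, **kw)


def calibrate_trues_scale(phantom: PhantomSpec, schedule: FrameSchedule,
                          inp: InputFunction, config: ScannerConfig,
                          target_mean_trues: float = 20.0) -> float:
    """Sensitivity so the central slice of the last frame averages the target
    expected trues per sinogram bin (the absolute count level is otherwise a
    free parameter of the study)."""
    truth = synthesize_ground_truth(phantom, schedule, inp)
    proj = _LabelProjector(phantom, config)
    frame = schedule.n_frames - 1
    zc = phantom.label_grid.shape[2] // 2
    li = proj.line_integrals(truth.data[:, :, zc, frame], zc)
    mean_li = float(li.mean()) * frame_count_scale(frame, schedule, 1.0)
    if mean_li <= 0:
        raise ValueError("phantom produces no counts; cannot calibrate")
    return target_mean_trues / mean_li


class _LabelProjector:
    """Cached attenuated projection machinery for one phantom/config pair."""

    def __init__(self, phantom: PhantomSpec, config: ScannerConfig):
        n = phantom.label_grid.shape[0]
        if phantom.label_grid.shape[1] != n:
            raise ValueError("phantom slices must be square")
        self.geometry = ProjectionGeometry(n, config.n_angles)
        self.A = system_matrix(n, config.n_angles)
        self.pixel_cm = phantom.voxel_size[0] / 10.0
        mu = phantom.mu_map() if config.attenuation_on else None
        self.att = {}
        for z in range(phantom.label_grid.shape[2]):
            if mu is None:
                self.att[z] = np.ones(self.geometry.sino_shape)
            else:
                self.att[z] = attenuation_factors(mu[:, :, z], self.geometry,
                                                  self.pixel_cm)
        self.mu = mu

    def line_integrals(self, image_slice: np.ndarray, z: int) -> np.ndarray:
        sino = (self.A @ image_slice.ravel()).reshape(self.geometry.sino_shape)
        return sino * self.att[z]


@dataclass
class SimulationResult:
    """In-memory result of one (config, iterations) simulation arm."""

    config: ScannerConfig
    iterations: int
    ground_truth: DynamicImage          # unreconstructed model image
    noise_free_recon: DynamicImage      # OSEM of the noise-free sinograms
    replicates: List[DynamicImage]
    master_seed: int
    replicate_seeds: List[int] = field(default_factory=list)


def simulate_arm(phantom: PhantomSpec, schedule: FrameSchedule, inp: InputFunction,
                 config: ScannerConfig, iterations: int, n_replicates: int,
                 master_seed: int, frames: Optional[Sequence[int]] = None,
                 target_mean_trues: float = 20.0,
                 reconstruct_noise_free: bool = True) -> SimulationResult:
    """Simulate and reconstruct one configuration arm.

    ``frames`` restricts simulation/reconstruction to a frame subset (e.g.
    only the last frame for SUV-only studies); omitted frames are zero in
    the returned 4-D volumes.
    """
    if config.trues_scale is None:
        scale = calibrate_trues_scale(phantom, schedule, inp, config,
                                      target_mean_trues)
        config = config.with_scale(scale)
    scale = config.trues_scale * config.tof_sensitivity

    truth = synthesize_ground_truth(phantom, schedule, inp)
    proj = _LabelProjector(phantom, config)
    nx, ny, nz = phantom.label_grid.shape
    frames = list(range(schedule.n_frames)) if frames is None else list(frames)

    def recon_stack(counts_fn) -> np.ndarray:
        """counts_fn(frame, z, expected_trues, expected_randoms) -> observed."""
        out = np.zeros((nx, ny, nz, schedule.n_frames))
        for f in frames:
            fscale = frame_count_scale(f, schedule, scale)
            for z in range(nz):
                li = proj.line_integrals(truth.data[:, :, z, f], z)
                trues = li * fscale
                randoms = np.full_like(trues, config.randoms_fraction * trues.mean())
                y = counts_fn(f, z, trues, randoms)
                img = osem_reconstruct(
                    y, proj.geometry, iterations, config.osem_subsets,
                    expected_randoms=randoms,
                    mu_slice=None if proj.mu is None else proj.mu[:, :, z],
                    pixel_size_cm=proj.pixel_cm)
                # counts-domain image -> decay-corrected kBq/mL
                out[:, :, z, f] = img / fscale if fscale > 0 else 0.0
        return out

    result = SimulationResult(config, iterations, truth, None, [], master_seed)

    if reconstruct_noise_free:
        nf = recon_stack(lambda f, z, t, r: t + r)
        result.noise_free_recon = DynamicImage(nf, schedule, phantom.voxel_size)

    for rep in range(n_replicates):
        arr = recon_stack(
            lambda f, z, t, r: add_poisson_noise(
                t + r, replicate_rng(master_seed, rep, f, z)).astype(float))
        result.replicates.append(DynamicImage(arr, schedule, phantom.voxel_size))
        result.replicate_seeds.append(rep)
    return result


def simulate_counts(phantom: PhantomSpec, schedule: FrameSchedule,
                    inp: InputFunction, config: ScannerConfig,
                    replicate: int, frame: int, slice_idx: int,
                    master_seed: int) -> np.ndarray:
    """Observed counts for one (replicate, frame, slice); deterministic in
    the seeding rule, used by determinism checks and external tooling."""
    if config.trues_scale is None:
        raise ValueError("config must carry an explicit trues_scale")
    truth = synthesize_ground_truth(phantom, schedule, inp)
    proj = _LabelProjector(phantom, config)
    fscale = frame_count_scale(frame, schedule,
                               config.trues_scale * config.tof_sensitivity)
    li = proj.line_integrals(truth.data[:, :, slice_idx, frame], slice_idx)
    trues = li * fscale
    randoms = np.full_like(trues, config.randoms_fraction * trues.mean())
    rng = replicate_rng(master_seed, replicate, frame, slice_idx)
    return add_poisson_noise(trues + randoms, rng)


# ---------------------------------------------------------------------------
# On-disk studies
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def simulate_study(phantom: PhantomSpec, schedule: FrameSchedule,
                   inp: InputFunction, configs: Sequence[ScannerConfig],
                   iteration_counts: Sequence[int], n_replicates: int,
                   master_seed: int, out_dir, overwrite: bool = False,
                   target_mean_trues: float = 20.0) -> dict:
    """Run the full experiment matrix and write it to disk.

    Writes the unreconstructed ground truth, the label map, the schedule,
    one 4-D NIfTI per (config, iterations, replicate) plus the noise-free
    reconstruction of each arm, and a manifest with per-replicate seeds and
    file checksums.
    """
    from . import io as dio

    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)

    truth = synthesize_ground_truth(phantom, schedule, inp)
    dio.write_dynamic_nifti(out / "ground_truth.nii", truth)
    dio.write_label_nifti(out / "labels.nii", phantom)
    schedule.to_text(out / "schedule.txt")
    inp.to_csv(out / "input_function.csv")

    files: Dict[str, str] = {}
    arms = []
    for config in configs:
        if config.trues_scale is None:
            config = config.with_scale(calibrate_trues_scale(
                phantom, schedule, inp, config, target_mean_trues))
        for iters in iteration_counts:
            res = simulate_arm(phantom, schedule, inp, config, iters,
                               n_replicates, master_seed)
            arm_dir = out / f"{config.name}_{iters}it"
            arm_dir.mkdir(exist_ok=True)
            dio.write_dynamic_nifti(arm_dir / "noise_free.nii", res.noise_free_recon)
            rep_files = []
            for i, rep in enumerate(res.replicates):
                p = arm_dir / f"replicate_{i:03d}.nii"
                dio.write_dynamic_nifti(p, rep)
                rep_files.append(str(p.relative_to(out)))
            arms.append({
                "config": dataclasses.asdict(config), "iterations": iters,
                "noise_free": str((arm_dir / "noise_free.nii").relative_to(out)),
                "replicates": rep_files,
                "replicate_seeds": [[master_seed, r] for r in range(n_replicates)],
            })

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(out))] = _sha256(p)
    manifest = {
        "master_seed": master_seed, "n_replicates": n_replicates,
        "grid_shape": list(phantom.label_grid.shape),
        "voxel_size_mm": list(phantom.voxel_size),
        "schedule_n_frames": schedule.n_frames,
        "units": "kBq/mL (decay corrected)",
        "arms": arms, "files": files,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
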