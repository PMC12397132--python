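"""Parallel-beam forward projection and projection-domain count modeling.

The scanner is modeled slice-by-slice as a 2-D parallel-beam system.  The
projector is an explicit sparse matrix: for each view angle the image is
resampled onto the rotated grid with bilinear interpolation and summed along
detector columns.  Reconstruction uses the exact transpose, so forward and
back projection form an adjoint pair.

Counts model per frame: expected trues are the attenuated line integrals of
the activity image scaled by frame duration, physical decay at the frame
mid-time and a scanner sensitivity factor; expected randoms are a spatially
uniform fraction of the mean trues.  Observed counts are independent Poisson
draws with a reproducible per-(replicate, frame, slice) seeding rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple

import numpy as np
from scipy import sparse

from .kinetics import decay_factor
from .schedule import FrameSchedule


@dataclass(frozen=True)
class ProjectionGeometry:
    """2-D parallel-beam geometry: n_radial detector bins x n_angles views."""

    n_pixels: int              # square image side; also number of radial bins
    n_angles: int = 48

    @property
    def angles(self) -> np.ndarray:
        """View angles in [0, pi)."""
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def n_bins(self) -> int:
        return self.n_pixels * self.n_angles

    @property
    def sino_shape(self) -> Tuple[int, int]:
        return (self.n_angles, self.n_pixels)


@lru_cache(maxsize=8)
def system_matrix(n_pixels: int, n_angles: int) -> sparse.csr_matrix:
    """Sparse projector A: image (n^2,) -> sinogram (n_angles*n,).

    Row block for angle theta is "rotate the image by theta about its center
    with bilinear interpolation, then sum along axis 0"; bin k of a view is
    the line integral (in pixel-length units) along the ray at signed radial
    offset (k - n/2 + 0.5) from the center.
    """
    n = n_pixels
    c = (n - 1) / 2.0
    pp, qq = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    # rotated-frame pixel centers relative to the image center
    u = pp.ravel() - c   # along-ray axis (summed)
    v = qq.ravel() - c   # detector axis
    blocks = []
    for theta in np.arange(n_angles) * np.pi / n_angles:
        ct, st = np.cos(theta), np.sin(theta)
        xs = c + u * ct - v * st
        ys = c + u * st + v * ct
        x0 = np.floor(xs).astype(np.int64)
        y0 = np.floor(ys).astype(np.int64)
        fx = xs - x0
        fy = ys - y0
        rows_out = qq.ravel()  # detector bin index of each rotated pixel
        data, rows, cols = [], [], []
        for dx, dy, w in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                          (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
            xi = x0 + dx
            yi = y0 + dy
            ok = (xi >= 0) & (xi < n) & (yi >= 0) & (yi < n) & (w > 0)
            data.append(w[ok])
            rows.append(rows_out[ok])
            cols.append(xi[ok] * n + yi[ok])
        blocks.append(sparse.csr_matrix(
            (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n * n)))
    return sparse.vstack(blocks).tocsr()


def forward_project(image_slice: np.ndarray, geometry: ProjectionGeometry,
                    mu_slice: Optional[np.ndarray] = None,
                    pixel_size_cm: float = 0.3) -> np.ndarray:
    """Line integrals of a square slice, optionally attenuated.

    Returns a (n_angles, n_radial) sinogram in (image-unit x pixel) units;
    with ``mu_slice`` (1/cm) each line integral is multiplied by
    ``exp(-int mu dl)`` along the same ray.
    """
    img = np.asarray(image_slice, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image slice must be square")
    A = system_matrix(img.shape[0], geometry.n_angles)
    sino = (A @ img.ravel()).reshape(geometry.sino_shape)
    if mu_slice is not None:
        sino = sino * attenuation_factors(mu_slice, geometry, pixel_size_cm)
    return sino


def attenuation_factors(mu_slice: np.ndarray, geometry: ProjectionGeometry,
                        pixel_size_cm: float) -> np.ndarray:
    """Per-bin survival probabilities ``exp(-int mu dl)``."""
    mu = np.asarray(mu_slice, dtype=float)
    A = system_matrix(mu.shape[0], geometry.n_angles)
    return np.exp(-(A @ mu.ravel()).reshape(geometry.sino_shape) * pixel_size_cm)


def frame_count_scale(frame: int, schedule: FrameSchedule, trues_scale: float) -> float:
    """Counts per unit line integral for one frame: duration x decay x sensitivity."""
    if trues_scale <= 0:
        raise ValueError("trues_scale must be positive")
    dur = schedule.dur_s[frame]
    dec = float(decay_factor(schedule.mid_min[frame]))
    return trues_scale * dur * dec


def frame_counts(trues_line_integrals: np.ndarray, frame: int,
                 schedule: FrameSchedule, trues_scale: float,
                 randoms_fraction: float = 0.3):
    """Expected (trues, randoms) sinograms for one frame.

    ``trues_line_integrals`` are attenuated line integrals of the
    decay-corrected activity image; the physical decay at the frame mid-time
    is applied here.  Expected randoms are uniform at ``randoms_fraction`` of
    the mean expected trues.
    """
    scale = frame_count_scale(frame, schedule, trues_scale)
    trues = np.asarray(trues_line_integrals, dtype=float) * scale
    randoms = np.full_like(trues, randoms_fraction * float(trues.mean()))
    return trues, randoms


def replicate_rng(master_seed: int, replicate: int, frame: int,
                  slice_idx: int) -> np.random.Generator:
    """Reproducible, order-insensitive generator per (replicate, frame, slice).

    Seeding rule: ``SeedSequence(master_seed, spawn_key=(replicate, frame,
    slice))`` -- streams are independent and identical regardless of the
    order replicates are generated in.
    """
    ss = np.random.SeedSequence(master_seed, spawn_key=(replicate, frame, slice_idx))
    return np.random.default_rng(ss)


def add_poisson_noise(expected: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson draw per bin with the given mean (integer counts)."""
    expected = np.asarray(expected, dtype=float)
    if np.any(expected < 0):
        raise ValueError("expected counts must be non-negative")
    return rng.poisson(expected)
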