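"""OSEM / MLEM reconstruction for the 2-D parallel-beam model.

Standard ordered-subsets expectation maximization with the randoms estimate
as an additive background in the forward model and attenuation in the system
model.  Angles are assigned to subsets by stride (angle i -> subset i mod N)
and subsets are processed in index order, so the algorithm is fully
deterministic.  The multiplicative update preserves non-negativity; voxels
with zero sensitivity are set to zero and reported.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .projection import ProjectionGeometry, attenuation_factors, system_matrix

_EPS = 1e-12


def subset_angle_indices(n_angles: int, n_subsets: int):
    """Stride partition of view angles: angle i belongs to subset i mod N."""
    if not (1 <= n_subsets <= n_angles):
        raise ValueError("need 1 <= n_subsets <= n_angles")
    return [np.arange(s, n_angles, n_subsets) for s in range(n_subsets)]


def osem_reconstruct(observed: np.ndarray, geometry: ProjectionGeometry,
                     n_iterations: int, n_subsets: int,
                     expected_randoms: Optional[np.ndarray] = None,
                     mu_slice: Optional[np.ndarray] = None,
                     pixel_size_cm: float = 0.3,
                     return_mask: bool = False):
    """Reconstruct one sinogram into a square image (line-integral units).

    ``observed`` and ``expected_randoms`` are (n_angles, n_radial) arrays.
    The output image is in the same units as the line integrals divided by
    pixel length, i.e. the units of the image the sinogram was projected
    from; count-to-concentration calibration is applied by the caller.
    """
    y = np.asarray(observed, dtype=float)
    if y.shape != geometry.sino_shape:
        raise ValueError(f"sinogram shape {y.shape} != {geometry.sino_shape}")
    n = geometry.n_pixels
    r = (np.zeros_like(y) if expected_randoms is None
         else np.asarray(expected_randoms, dtype=float))
    att = (np.ones_like(y) if mu_slice is None
           else attenuation_factors(mu_slice, geometry, pixel_size_cm))
    A = system_matrix(n, geometry.n_angles)

    subsets = subset_angle_indices(geometry.n_angles, n_subsets)
    rows = [np.concatenate([s * n + np.arange(n) for s in sub]) for sub in subsets]
    A_subs = [A[rr] for rr in rows]
    sens = [Ak.T @ att.ravel()[rr] for Ak, rr in zip(A_subs, rows)]

    total_sens = A.T @ att.ravel()
    dead = total_sens <= _EPS

    x = np.ones(n * n)
    x[dead] = 0.0
    for _ in range(n_iterations):
        for Ak, rr, sk in zip(A_subs, rows, sens):
            ak = att.ravel()[rr]
            fwd = ak * (Ak @ x) + r.ravel()[rr]
            ratio = np.where(fwd > _EPS, y.ravel()[rr] / np.maximum(fwd, _EPS), 0.0)
            back = Ak.T @ (ak * ratio)
            ok = sk > _EPS
            x[ok] *= back[ok] / sk[ok]
    img = x.reshape(n, n)
    if return_mask:
        return img, dead.reshape(n, n)
    return img


def kl_divergence(observed: np.ndarray, expected: np.ndarray) -> float:
    """Poisson KL divergence of data from a model (lower = better fit)."""
    y = np.asarray(observed, dtype=float).ravel()
    m = np.maximum(np.asarray(expected, dtype=float).ravel(), _EPS)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / m), 0.0)
    return float(np.sum(term - y + m))
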