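"""Whole-volume parametric imaging: IDIF extraction, Patlak and 2TCM fits.

This is the computation the package exists for: given any reconstructed 4-D
dynamic PET volume, a frame schedule and a blood-pool mask, produce
voxel-wise parametric maps with an indirect method:

* an image-derived input function (IDIF) from the eroded arterial mask,
* Patlak ``Ki``/``vb`` maps by closed-form weighted linear regression of the
  graphical transform beyond ``t*``,
* irreversible 2TCM ``K1, k2, k3, vb`` maps by bounded nonlinear least
  squares of the frame-averaged compartment model, with ``Ki`` derived as
  ``K1*k3/(k2+k3)``,
* SUV maps from the last frame.

Fits never abort the volume: per-voxel failures are recorded in a status
volume (0 ok, 1 failed, 2 masked) with NaN parameter sentinels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares

from .kinetics import InputFunction, exp_convolve, suv
from .phantom import DynamicImage
from .schedule import FrameSchedule

STATUS_OK, STATUS_FAILED, STATUS_MASKED = 0, 1, 2


@dataclass
class FitSettings:
    """Tunable settings of the voxel-wise fits.

    ``t_star_min``: first Patlak frame mid-time (minutes); 20 min leaves
    > 5 equilibration time constants for every packaged tissue
    (k2+k3 >= 0.25 /min).  ``fg_fraction``: voxels whose time-integrated
    activity is below this fraction of the volume maximum are masked.
    """

    t_star_min: float = 20.0
    weighting: str = "uniform"            # "uniform" | "duration"
    fg_fraction: float = 0.01
    bounds_lo: Tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    bounds_hi: Tuple[float, float, float, float] = (2.0, 5.0, 5.0, 1.0)
    x0: Tuple[float, float, float, float] = (0.05, 0.2, 0.03, 0.05)
    x0_fallback: Tuple[float, float, float, float] = (0.2, 0.5, 0.1, 0.2)
    max_nfev: int = 200
    ftol: float = 1e-8
    xtol: float = 1e-8
    model_dt_s: float = 1.0
    blood_plasma_ratio: float = 1.0

    def __post_init__(self) -> None:
        for lo, x, hi in zip(self.bounds_lo, self.x0, self.bounds_hi):
            if not (lo <= x <= hi):
                raise ValueError("initial values must lie within bounds")

    def frame_weights(self, schedule: FrameSchedule) -> np.ndarray:
        if self.weighting == "uniform":
            return np.ones(schedule.n_frames)
        if self.weighting == "duration":
            return schedule.dur_s / schedule.dur_s.mean()
        raise ValueError(f"unknown weighting '{self.weighting}'")


@dataclass
class ParametricMaps:
    """Per-voxel kinetic parameter volumes plus fit diagnostics."""

    model: str                              # "patlak" | "2tcm" | "suv"
    params: Dict[str, np.ndarray]           # name -> 3-D volume
    status: np.ndarray                      # int8: ok/failed/masked
    provenance: Dict = field(default_factory=dict)
    diagnostics: Dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.params[name]

    @property
    def param_names(self) -> List[str]:
        return list(self.params)


def foreground_mask(dyn: DynamicImage, fg_fraction: float) -> np.ndarray:
    """Voxels with time-integrated activity above a fraction of the maximum."""
    auc = np.tensordot(dyn.data, dyn.schedule.dur_s, axes=([3], [0]))
    if fg_fraction <= 0:
        return np.ones(dyn.shape3, dtype=bool)
    return auc > fg_fraction * auc.max()


# ---------------------------------------------------------------------------
# Image-derived input function
# ---------------------------------------------------------------------------

def extract_idif(dyn: DynamicImage, blood_mask: np.ndarray,
                 erosion_radius: int = 1,
                 blood_plasma_ratio: float = 1.0):
    """Image-derived input function from a blood-pool mask.

    The mask is eroded by ``erosion_radius`` voxels to limit partial-volume
    contamination; if erosion empties it the full mask is used and a warning
    is recorded.  Cp is the per-frame mean over the mask, tabulated at frame
    mid-times (Cb = Cp by default; a whole-blood/plasma ratio can be applied).

    Returns ``(InputFunction, info)`` where ``info`` carries the mask size
    and any warnings.
    """
    mask = np.asarray(blood_mask, dtype=bool)
    if mask.shape != dyn.shape3:
        raise ValueError("blood mask grid does not match the dynamic image")
    if not mask.any():
        raise ValueError("blood mask is empty")
    info = {"warnings": [], "erosion_radius": erosion_radius,
            "n_voxels_input": int(mask.sum())}
    eroded = mask
    if erosion_radius > 0:
        eroded = ndimage.binary_erosion(mask, iterations=erosion_radius)
        if not eroded.any():
            info["warnings"].append(
                f"erosion by {erosion_radius} emptied the mask; using uneroded mask")
            eroded = mask
    info["n_voxels_used"] = int(eroded.sum())
    cb = dyn.data[eroded].mean(axis=0)          # (n_frames,)
    cp = cb / blood_plasma_ratio
    t = dyn.schedule.mid_min
    # prepend the injection origin so the Patlak integral starts at zero
    inp = InputFunction(np.concatenate([[0.0], t]),
                        np.concatenate([[0.0], cp]),
                        cb=np.concatenate([[0.0], cb]))
    return inp, info


# ---------------------------------------------------------------------------
# Patlak
# ---------------------------------------------------------------------------

def fit_patlak_voxelwise(dyn: DynamicImage, inp: InputFunction,
                         settings: Optional[FitSettings] = None) -> ParametricMaps:
    """Closed-form voxel-wise Patlak fit (Ki slope, vb intercept).

    Frames with mid-time >= ``t*`` and Cp > 0 enter a weighted least-squares
    line through the graphical coordinates; the whole volume is solved with
    vectorized normal equations.
    """
    s = settings or FitSettings()
    t = dyn.schedule.mid_min
    cp = inp.cp_at(t)
    sel = (t >= s.t_star_min) & (cp > 0)
    n_excluded_cp = int(((t >= s.t_star_min) & (cp <= 0)).sum())

    shape3 = dyn.shape3
    status = np.full(shape3, STATUS_OK, dtype=np.int8)
    fg = foreground_mask(dyn, s.fg_fraction)
    status[~fg] = STATUS_MASKED

    ki = np.full(shape3, np.nan)
    vb = np.full(shape3, np.nan)
    if sel.sum() < 3:
        status[fg] = STATUS_FAILED
    else:
        x = inp.cumint_cp_at(t[sel]) / cp[sel]
        w = s.frame_weights(dyn.schedule)[sel]
        Y = dyn.data[..., sel][fg] / cp[sel]          # (n_fg, n_sel)
        sw = w.sum()
        swx = (w * x).sum()
        swxx = (w * x * x).sum()
        swy = Y @ w
        swxy = Y @ (w * x)
        det = sw * swxx - swx * swx
        slope = (sw * swxy - swx * swy) / det
        inter = (swxx * swy - swx * swxy) / det
        ki[fg] = slope
        vb[fg] = inter
    return ParametricMaps(
        "patlak", {"Ki": ki, "vb": vb}, status,
        provenance={"t_star_min": s.t_star_min, "weighting": s.weighting,
                    "n_frames_used": int(sel.sum()),
                    "n_frames_excluded_cp": n_excluded_cp})


# ---------------------------------------------------------------------------
# 2TCM
# ---------------------------------------------------------------------------

class _Tcm2Model:
    """Frame-averaged irreversible 2TCM evaluator on a uniform fine grid."""

    def __init__(self, schedule: FrameSchedule, inp: InputFunction, dt_s: float):
        self.schedule = schedule
        t_s = np.arange(0.0, schedule.end_s[-1] + 0.5 * dt_s, dt_s)
        self.t_min = t_s / 60.0
        self.h = dt_s / 60.0
        self.cp = inp.cp_at(self.t_min)
        self.cb = inp.cb_at(self.t_min)
        self.cumint = inp.cumint_cp_at(self.t_min)
        # frame-edge indices on the fine grid for fast duration averaging
        self.lo = np.rint(schedule.start_s / dt_s).astype(int)
        self.hi = np.rint(schedule.end_s / dt_s).astype(int)
        self.fcb = self.frame_avg(self.cb)

    def frame_avg(self, curves: np.ndarray) -> np.ndarray:
        """Duration-average one curve or a stack of curves (last axis = time)."""
        c = np.asarray(curves)
        cum = np.zeros(c.shape)
        cum[..., 1:] = np.cumsum(0.5 * (c[..., 1:] + c[..., :-1]), axis=-1)
        return (cum[..., self.hi] - cum[..., self.lo]) / (self.hi - self.lo)

    def _mix(self, alpha: float, k2: float, k3: float):
        """Frame-averaged mixing curve A = (k3 I + k2 E(alpha))/alpha and its
        k2/k3 partials; uses dE/dalpha = -exp_convolve(E, alpha)."""
        E = exp_convolve(self.t_min, self.cp, alpha)
        dE = -exp_convolve(self.t_min, E, alpha)
        num = k3 * self.cumint + k2 * E
        A = num / alpha
        dA_dk2 = (E * alpha - num) / alpha ** 2 + (k2 / alpha) * dE
        dA_dk3 = (self.cumint * alpha - num) / alpha ** 2 + (k2 / alpha) * dE
        return self.frame_avg(np.stack([A, dA_dk2, dA_dk3]))

    def _eval(self, theta) -> Tuple[np.ndarray, np.ndarray]:
        """Frame-averaged model and analytic (n_frames, 4) Jacobian."""
        K1, k2, k3, vb = theta
        alpha = k2 + k3
        nf = self.lo.size
        if alpha < 1e-9:
            fA = self.frame_avg(self.cumint)   # pure-trapping limit
            dk2 = dk3 = np.zeros(nf)
        else:
            fA, dk2, dk3 = self._mix(alpha, k2, k3)
        fcb = self.fcb
        model = (1.0 - vb) * K1 * fA + vb * fcb
        jac = np.empty((nf, 4))
        jac[:, 0] = (1.0 - vb) * fA
        jac[:, 1] = (1.0 - vb) * K1 * dk2
        jac[:, 2] = (1.0 - vb) * K1 * dk3
        jac[:, 3] = fcb - K1 * fA
        return model, jac

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        return self._eval(theta)[0]


def fit_2tcm_voxelwise(dyn: DynamicImage, inp: InputFunction,
                       settings: Optional[FitSettings] = None,
                       voxel_mask: Optional[np.ndarray] = None) -> ParametricMaps:
    """Bounded per-voxel nonlinear least squares of the irreversible 2TCM.

    Each foreground voxel's frame series is fitted for (K1, k2, k3, vb) with
    a deterministic initial point and one fallback restart; ``Ki`` is derived
    voxel-wise as ``K1*k3/(k2+k3)``.  Residual norm, evaluation count and
    convergence flag are kept per voxel; failures are marked, never raised.
    """
    s = settings or FitSettings()
    model = _Tcm2Model(dyn.schedule, inp, s.model_dt_s)
    w = np.sqrt(s.frame_weights(dyn.schedule))

    shape3 = dyn.shape3
    status = np.full(shape3, STATUS_OK, dtype=np.int8)
    fg = foreground_mask(dyn, s.fg_fraction)
    if voxel_mask is not None:
        fg &= voxel_mask
    status[~fg] = STATUS_MASKED

    out = {p: np.full(shape3, np.nan) for p in ("K1", "k2", "k3", "vb")}
    resnorm = np.full(shape3, np.nan)
    nfev = np.zeros(shape3, dtype=np.int32)

    idx = np.argwhere(fg)
    lo = np.asarray(s.bounds_lo)
    hi = np.asarray(s.bounds_hi)
    for ix, iy, iz in idx:
        y = dyn.data[ix, iy, iz]
        if not y.any():
            for p, v in zip(("K1", "k2", "k3", "vb"), (0.0, 0.0, 0.0, 0.0)):
                out[p][ix, iy, iz] = v
            resnorm[ix, iy, iz] = 0.0
            continue
        res = None
        cache: Dict = {}

        def fun(th):
            m, j = model._eval(th)
            cache["th"], cache["jac"] = tuple(th), j
            return w * (m - y)

        def jac(th):
            if cache.get("th") != tuple(th):
                fun(th)
            return w[:, None] * cache["jac"]

        for x0 in (s.x0, s.x0_fallback):
            try:
                res = least_squares(
                    fun, x0, jac=jac, bounds=(lo, hi), method="trf",
                    max_nfev=s.max_nfev, ftol=s.ftol, xtol=s.xtol,
                    x_scale=[0.1, 0.5, 0.1, 0.1])
            except Exception:
                res = None
            if res is not None and res.status > 0:
                break
        if res is None or res.status <= 0:
            status[ix, iy, iz] = STATUS_FAILED
            continue
        for p, v in zip(("K1", "k2", "k3", "vb"), res.x):
            out[p][ix, iy, iz] = v
        resnorm[ix, iy, iz] = float(np.sqrt(2.0 * res.cost))
        nfev[ix, iy, iz] = res.nfev

    # derived macro influx map: exact voxel-wise identity with K1*k3/(k2+k3)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = out["k2"] + out["k3"]
        ki = np.where(denom > 0, out["K1"] * out["k3"] / denom, 0.0)
        ki[np.isnan(out["K1"])] = np.nan
    out["Ki"] = ki
    return ParametricMaps(
        "2tcm", out, status,
        provenance={"weighting": s.weighting, "x0": s.x0,
                    "bounds": [s.bounds_lo, s.bounds_hi]},
        diagnostics={"resnorm": resnorm, "nfev": nfev})


# ---------------------------------------------------------------------------
# SUV
# ---------------------------------------------------------------------------

def compute_suv_map(dyn: DynamicImage, injected_dose_mbq: float = 240.0,
                    weight_kg: float = 60.0,
                    frame: int = -1) -> ParametricMaps:
    """SUV volume from one frame (default: last) at its mid-time.

    Defaults follow the standardized study conditions: 60 kg body weight and
    4 MBq/kg injected dose.
    """
    f = range(dyn.schedule.n_frames)[frame]
    vol = suv(dyn.data[..., f], injected_dose_mbq, weight_kg,
              t_min=float(dyn.schedule.mid_min[f]))
    status = np.full(dyn.shape3, STATUS_OK, dtype=np.int8)
    return ParametricMaps("suv", {"SUV": vol}, status,
                          provenance={"frame": f,
                                      "dose_mbq": injected_dose_mbq,
                                      "weight_kg": weight_kg})
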