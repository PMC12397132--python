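"""Kinetic mathematics for irreversible FDG-type tracers.

This module holds the ground-truth model layer everything else builds on:

* a tri-exponential bolus plasma input function,
* the irreversible two-tissue compartment model (2TCM, ``k4 = 0``),
* the Patlak graphical linearization,
* the macro influx constant ``Ki = K1*k3/(k2+k3)``,
* SUV and decay arithmetic,
* frame-duration averaging of continuous curves.

Units: rate constants are per minute (``K1`` in mL/min/cm^3), concentrations
in kBq/mL, schedule times in seconds, kinetic time bases in minutes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .schedule import FrameSchedule

FDG_HALF_LIFE_MIN = 110.0


class DegenerateKineticsError(ValueError):
    """Raised for parameter combinations outside the model's domain."""


class DegenerateKineticsWarning(UserWarning):
    """Signalled when a limiting form of the model is substituted."""


@dataclass(frozen=True)
class KineticParams:
    """Irreversible 2TCM parameters for one tissue.

    K1 [mL/min/cm^3], k2, k3 [1/min], vb dimensionless blood volume fraction.
    """

    K1: float
    k2: float
    k3: float
    vb: float

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be non-negative")
        if not (0.0 <= self.vb <= 1.0):
            raise ValueError("vb must lie in [0, 1]")

    @property
    def ki(self) -> float:
        """Macro influx constant K1*k3/(k2+k3)."""
        return macro_ki(self.K1, self.k2, self.k3)


@dataclass(frozen=True)
class PatlakParams:
    """Patlak slope (influx rate) and intercept (apparent blood volume)."""

    Ki_slope: float
    v_intercept: float


@dataclass
class TissueTAC:
    """Frame-averaged tissue time-activity curve on a schedule."""

    frame_values: np.ndarray  # kBq/mL
    schedule: FrameSchedule

    def __post_init__(self) -> None:
        self.frame_values = np.asarray(self.frame_values, dtype=float)
        if self.frame_values.size != self.schedule.n_frames:
            raise ValueError("frame_values length must equal schedule n_frames")
        if not np.all(np.isfinite(self.frame_values)):
            raise ValueError("frame_values must be finite")

    @property
    def frame_mid_min(self) -> np.ndarray:
        return self.schedule.mid_min


# ---------------------------------------------------------------------------
# Input function
# ---------------------------------------------------------------------------

#: Tri-exponential bolus defaults: peak ~40 kBq/mL (a 4 MBq/kg injection in a
#: 60 kg body), 60-min tail ~12% of peak, and an intermediate clearance rate
#: fast enough that graphical-analysis equilibration completes before the
#: default Patlak window (t* = 20 min) for all packaged tissue parameters.
FENG_DEFAULTS = dict(A1=329.0, A2=8.0, A3=8.6, l1=4.1339, l2=0.25, l3=0.01043)


def feng_input_function(t_min, A1=None, A2=None, A3=None, l1=None, l2=None, l3=None):
    """Tri-exponential bolus plasma curve, ``Cp(0) = 0``, clipped at zero.

    ``Cp(t) = (A1*t - A2 - A3) e^(-l1 t) + A2 e^(-l2 t) + A3 e^(-l3 t)``
    with decay rates ``l1 > l2 > l3 >= 0`` (1/min) and t in minutes.
    """
    p = {k: (v if v is not None else FENG_DEFAULTS[k])
         for k, v in zip("A1 A2 A3 l1 l2 l3".split(), (A1, A2, A3, l1, l2, l3))}
    if not (p["l1"] > p["l2"] > p["l3"] >= 0):
        raise ValueError("rate constants must satisfy l1 > l2 > l3 >= 0")
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    cp = ((p["A1"] * t - p["A2"] - p["A3"]) * np.exp(-p["l1"] * t)
          + p["A2"] * np.exp(-p["l2"] * t) + p["A3"] * np.exp(-p["l3"] * t))
    return np.clip(cp, 0.0, None)


class InputFunction:
    """Plasma (Cp) and whole-blood (Cb) input curves on a common time base.

    Stored as dense samples in minutes; values are linearly interpolated and
    the running integral of Cp is the sample-wise trapezoid rule, so the same
    object serves both analytic curves sampled finely and tabulated
    image-derived curves sampled at frame mid-times.
    """

    def __init__(self, t_min, cp, cb=None):
        t = np.asarray(t_min, dtype=float)
        cp = np.asarray(cp, dtype=float)
        if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time base must be 1-D, increasing, length >= 2")
        if cp.shape != t.shape:
            raise ValueError("cp must match the time base")
        if np.any(cp < -1e-12):
            raise ValueError("Cp must be non-negative")
        self.t_min = t
        self.cp = np.clip(cp, 0.0, None)
        self.cb = self.cp if cb is None else np.asarray(cb, dtype=float)
        if self.cb.shape != t.shape:
            raise ValueError("cb must match the time base")
        # running integral of Cp from the start of the time base
        self._cumint = np.concatenate(
            [[0.0], np.cumsum(0.5 * (self.cp[1:] + self.cp[:-1]) * np.diff(t))])
        if t[0] > 0:
            # extend integration down to t=0 assuming Cp(0)=0 (bolus start)
            self._cumint = self._cumint + 0.5 * self.cp[0] * t[0]

    @classmethod
    def from_feng(cls, t_end_min: float = 60.0, dt_s: float = 1.0,
                  blood_plasma_ratio: float = 1.0, **feng_params) -> "InputFunction":
        t = np.arange(0.0, t_end_min * 60.0 + 0.5 * dt_s, dt_s) / 60.0
        cp = feng_input_function(t, **feng_params)
        return cls(t, cp, cb=blood_plasma_ratio * cp)

    def cp_at(self, t_min):
        t = np.asarray(t_min, dtype=float)
        return np.interp(t, self.t_min, self.cp, left=0.0 if self.t_min[0] > 0 else self.cp[0])

    def cb_at(self, t_min):
        t = np.asarray(t_min, dtype=float)
        return np.interp(t, self.t_min, self.cb, left=0.0 if self.t_min[0] > 0 else self.cb[0])

    def cumint_cp_at(self, t_min):
        """Trapezoid running integral of Cp from 0 to t (kBq/mL * min)."""
        t = np.asarray(t_min, dtype=float)
        return np.interp(t, self.t_min, self._cumint)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.t_min, self.cp, self.cb]),
                   delimiter=",", header="t_min,cp_kbq_ml,cb_kbq_ml", comments="")

    @classmethod
    def from_csv(cls, path) -> "InputFunction":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        cb = arr[:, 2] if arr.shape[1] > 2 else None
        return cls(arr[:, 0], arr[:, 1], cb)


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def exp_convolve(t_min: np.ndarray, curve: np.ndarray, alpha: float) -> np.ndarray:
    """``y(t) = int_0^t e^{-alpha (t-s)} curve(s) ds`` for piecewise-linear input.

    Uses the exact exponential-integrator update per step (no discretization
    bias beyond the linear-interpolation of the input); uniform grids run
    through a single IIR filter, non-uniform grids step by step.
    """
    t = np.asarray(t_min, dtype=float)
    c = np.asarray(curve, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    dt = np.diff(t)
    if alpha == 0.0:
        return np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * dt)])
    if dt.size and np.allclose(dt, dt[0], rtol=1e-9, atol=0):
        h = dt[0]
        E = np.exp(-alpha * h)
        g = (1.0 - (1.0 + alpha * h) * E) / (alpha * alpha * h)  # coeff of c[n-1]
        b0 = (1.0 - E) / alpha - g
        y = lfilter([b0, g], [1.0, -E], c)
        # lfilter assumes zero history; remove the spurious response to c[0]
        y = y - b0 * c[0] * E ** np.arange(c.size)
        return y
    y = np.zeros_like(c)
    for n in range(1, c.size):
        h = dt[n - 1]
        E = np.exp(-alpha * h)
        g = (1.0 - (1.0 + alpha * h) * E) / (alpha * alpha * h)
        y[n] = y[n - 1] * E + ((1.0 - E) / alpha - g) * c[n] + g * c[n - 1]
    return y


def tcm2_tissue_concentration(params: KineticParams, inp: InputFunction,
                              t_grid_min) -> np.ndarray:
    """Measured voxel concentration of the irreversible 2TCM.

    Solves ``C1' = K1 Cp - (k2+k3) C1``, ``C2' = k3 C1`` and returns
    ``C = (1-vb) (C1+C2) + vb Cb``, equivalently the convolution form
    ``C_T = [K1/(k2+k3)] (k3 + k2 e^{-(k2+k3) t}) (x) Cp``.
    """
    t = np.asarray(t_grid_min, dtype=float)
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing and start at 0")
    cp = inp.cp_at(t)
    cb = inp.cb_at(t)
    alpha = params.k2 + params.k3
    if params.K1 == 0.0:
        ct = np.zeros_like(t)
    elif alpha == 0.0:
        warnings.warn("k2 + k3 = 0 with K1 > 0: using the pure-trapping limit "
                      "C_T = K1 * int Cp", DegenerateKineticsWarning)
        ct = params.K1 * inp.cumint_cp_at(t)
    else:
        trap = params.k3 / alpha * inp.cumint_cp_at(t)
        rev = params.k2 / alpha * exp_convolve(t, cp, alpha)
        ct = params.K1 * (trap + rev)
    return (1.0 - params.vb) * ct + params.vb * cb


def macro_ki(K1: float, k2: float, k3: float) -> float:
    """Net influx constant ``Ki = K1 * k3 / (k2 + k3)`` (mL/min/cm^3)."""
    if k2 + k3 <= 0:
        raise DegenerateKineticsError("k2 + k3 must be positive")
    return K1 * k3 / (k2 + k3)


def frame_average(t_fine_s, curve, schedule: FrameSchedule) -> TissueTAC:
    """Average a finely sampled curve over each frame of a schedule.

    ``t_fine_s`` is in seconds, must cover the full schedule with step <= 1 s;
    each frame value is the duration-average of the curve over
    [start, start + dur).
    """
    t = np.asarray(t_fine_s, dtype=float)
    c = np.asarray(curve, dtype=float)
    if t[0] > schedule.start_s[0] or t[-1] < schedule.end_s[-1]:
        raise ValueError("fine grid must cover the schedule time range")
    if np.max(np.diff(t)) > 1.0 + 1e-9:
        raise ValueError("fine grid step must be <= 1 s")
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))])
    lo = np.interp(schedule.start_s, t, cum)
    hi = np.interp(schedule.end_s, t, cum)
    return TissueTAC((hi - lo) / schedule.dur_s, schedule)


def tissue_tac(params: KineticParams, inp: InputFunction,
               schedule: FrameSchedule, dt_s: float = 1.0) -> TissueTAC:
    """Frame-averaged noise-free tissue TAC for one parameter set."""
    t_s = np.arange(0.0, schedule.end_s[-1] + 0.5 * dt_s, dt_s)
    curve = tcm2_tissue_concentration(params, inp, t_s / 60.0)
    return frame_average(t_s, curve, schedule)


# ---------------------------------------------------------------------------
# Patlak transform
# ---------------------------------------------------------------------------

def patlak_transform(tac: TissueTAC, inp: InputFunction):
    """Patlak coordinates at the TAC's frame mid-times.

    Returns ``(x, y, used)`` where ``x = int_0^t Cp / Cp(t)`` (normalized
    time, minutes), ``y = C(t)/Cp(t)`` and ``used`` flags frames with
    ``Cp > 0``; excluded frames are reported through the mask.
    """
    t = tac.frame_mid_min
    cp = inp.cp_at(t)
    used = cp > 0
    x = np.full(t.shape, np.nan)
    y = np.full(t.shape, np.nan)
    x[used] = inp.cumint_cp_at(t[used]) / cp[used]
    y[used] = tac.frame_values[used] / cp[used]
    return x, y, used


def fit_patlak_line(x, y, weights=None) -> PatlakParams:
    """Closed-form weighted least-squares line through Patlak points."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx * swx
    if det <= 0:
        raise ValueError("degenerate Patlak design (need >= 2 distinct x)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return PatlakParams(slope, intercept)


# ---------------------------------------------------------------------------
# SUV and decay
# ---------------------------------------------------------------------------

def decay_factor(t_min, half_life_min: float = FDG_HALF_LIFE_MIN):
    """Physical decay factor ``2^(-t/T)`` at time t post injection."""
    return 2.0 ** (-np.asarray(t_min, dtype=float) / half_life_min)


def suv(activity_kbq_ml, injected_dose_mbq: float, weight_kg: float,
        t_min: float = 0.0, half_life_min: float = FDG_HALF_LIFE_MIN):
    """Standardized uptake value (1 g/mL tissue density).

    ``SUV = C / (D * 2^{-t/T} / W)`` with C in kBq/mL, the injected dose D
    decay-corrected to acquisition time t (minutes), and weight W in kg.
    The standardized defaults of the simulation study are W = 60 kg and
    D = 4 MBq/kg x W = 240 MBq.
    """
    if injected_dose_mbq <= 0 or weight_kg <= 0:
        raise ValueError("dose and weight must be positive")
    dose_kbq = injected_dose_mbq * 1000.0 * decay_factor(t_min, half_life_min)
    weight_g = weight_kg * 1000.0
    return np.asarray(activity_kbq_ml, dtype=float) * weight_g / dose_kbq
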