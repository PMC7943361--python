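"""Modified Mitchell-Schaeffer (mMS) cell model and parameter mappings.

The mMS model is a two-variable excitable-cell model with a nondimensional
transmembrane variable ``v`` and a recovery gate ``h``:

    dv/dt = h * v * (v - v_gate) * (1 - v) / tau_in  -  v / tau_out
    dh/dt = (1 - h) / tau_open   if v <  v_gate
          = -h / tau_close       if v >= v_gate

The cubic source term vanishes at rest (v = 0), so rest is a genuine fixed
point and the model is robust to slow drift, unlike the original
Mitchell-Schaeffer formulation.  The excitation threshold ``v_gate`` plays
the role usually written h_min.

This module also owns the two calibration mappings used to personalize
tissue: conductivity from the maximum conduction velocity CV_max (via a 1-D
cable and the diffusive CV proportional to sqrt(D) law) and tau_close from the
maximum action potential duration APD_max (via monotone root finding
against the single-cell integrator).  Both are defined by a round-trip
contract: simulating with the mapped parameter must reproduce the target
within 5 %.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as dataclass_fields

import numpy as np
from scipy.optimize import brentq

try:  # compiled single-cell stepper; the python loop below is the reference
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class MMSParameters:
    """mMS cell parameters plus tissue conductivity.

    Times in ms, ``diffusivity`` in mm**2/ms, ``v_gate`` dimensionless.
    """

    tau_in: float = 0.3
    tau_out: float = 6.0
    tau_open: float = 120.0
    tau_close: float = 80.0
    v_gate: float = 0.1
    diffusivity: float = 0.1

    def __post_init__(self):
        for f in dataclass_fields(self):
            val = getattr(self, f.name)
            if not np.isfinite(val) or val <= 0:
                raise ValueError(f"{f.name} must be strictly positive, got {val}")
        if not 0 < self.v_gate < 1:
            raise ValueError(f"v_gate must lie in (0, 1), got {self.v_gate}")
        if not self.tau_in < self.tau_out:
            raise ValueError(
                f"excitability requires tau_in < tau_out "
                f"(got {self.tau_in} >= {self.tau_out})"
            )


@dataclass
class CellState:
    v: float = 0.0
    h: float = 1.0


#: threshold used everywhere for activation and APD measurement
V_THR = 0.1

#: a captured action potential must exceed this level: the tangency point
#: of the cubic nullcline at the minimal firing h, plus margin.  The default
#: stimulus (0.25 /ms for 2 ms) can push v at most ~0.5 directly, so graded
#: sub-threshold responses stay below it
def capture_level(v_gate: float) -> float:
    return 0.5 * (1.0 + v_gate) + 0.05


def mms_rates(v, h, p: MMSParameters):
    """Right-hand side of the mMS ODEs; works on scalars or arrays."""
    dv = h * v * (v - p.v_gate) * (1.0 - v) / p.tau_in - v / p.tau_out
    dh = np.where(v < p.v_gate, (1.0 - h) / p.tau_open, -h / p.tau_close)
    return dv, dh


# ---------------------------------------------------------------------------
# single-cell integration
# ---------------------------------------------------------------------------

def _check_dt(dt: float, tau_in: float) -> None:
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if dt > 0.1 * tau_in + 1e-12:
        raise ValueError(
            f"dt = {dt} is unstable for tau_in = {tau_in}; require dt <= 0.1*tau_in"
        )


def _cell_loop_python(v, h, dt, tin, tout, topen, tclose, vg, starts, ends, amp):
    n_steps = v.shape[0] - 1
    for i in range(n_steps):
        ti = i * dt
        stim = 0.0
        for k in range(starts.shape[0]):
            if starts[k] <= ti < ends[k]:
                stim = amp
        vi, hi = v[i], h[i]
        v[i + 1] = vi + dt * (hi * vi * (vi - vg) * (1.0 - vi) / tin
                              - vi / tout + stim)
        if vi < vg:
            h[i + 1] = hi + dt * (1.0 - hi) / topen
        else:
            h[i + 1] = hi - dt * hi / tclose


if _HAVE_NUMBA:
    _cell_loop = _njit(cache=True)(_cell_loop_python)
else:  # pragma: no cover
    _cell_loop = _cell_loop_python


def simulate_single_cell(
    p: MMSParameters,
    stim_times,
    dt: float = 0.02,
    duration: float = 500.0,
    stim_amplitude: float = 0.25,
    stim_duration: float = 2.0,
    v_thr: float = V_THR,
    initial: CellState | None = None,
):
    """Integrate one mMS cell with brief additive stimuli on dv/dt.

    Returns a dict with the full (t, v, h) trace, the APD of every beat
    (time v stayed >= ``v_thr``, upstroke and downstroke linearly
    interpolated), and a capture flag per stimulus.
    """
    _check_dt(dt, p.tau_in)
    stim_times = np.sort(np.asarray(stim_times, dtype=float))
    n_steps = int(round(duration / dt))
    t = np.arange(n_steps + 1) * dt
    v = np.empty(n_steps + 1)
    h = np.empty(n_steps + 1)
    v[0] = initial.v if initial is not None else 0.0
    h[0] = initial.h if initial is not None else 1.0

    starts = stim_times
    ends = stim_times + stim_duration
    _cell_loop(v, h, dt, p.tau_in, p.tau_out, p.tau_open, p.tau_close,
               p.v_gate, starts, ends, stim_amplitude)

    apds, beat_starts = _apds_from_trace(t, v, v_thr)
    # a stimulus captured iff it produced a *new* upstroke whose beat reaches
    # the capture level (graded sub-threshold responses cross v_thr but stay
    # low; the S1 plateau itself is not a new upstroke)
    lvl = capture_level(p.v_gate)
    beat_peaks = []
    for t_up, apd in zip(beat_starts, apds):
        seg = (t >= t_up) & (t <= t_up + apd)
        beat_peaks.append(v[seg].max() if np.any(seg) else 0.0)
    captured = []
    bounds = np.append(stim_times, duration + dt)
    for k in range(len(stim_times)):
        ok = any(
            bounds[k] <= t_up < bounds[k + 1] + stim_duration and peak > lvl
            for t_up, peak in zip(beat_starts, beat_peaks)
        )
        captured.append(bool(ok))
    return {
        "t": t,
        "v": v,
        "h": h,
        "apds": np.asarray(apds),
        "beat_starts": np.asarray(beat_starts),
        "captured": captured,
    }


def _apds_from_trace(t, v, v_thr):
    """(APD, upstroke time) per beat from a single-cell trace."""
    above = v >= v_thr
    up = np.flatnonzero(~above[:-1] & above[1:])
    down = np.flatnonzero(above[:-1] & ~above[1:])
    apds, starts = [], []
    for iu in up:
        later = down[down >= iu]
        if later.size == 0:
            break
        idn = later[0]
        t_up = _interp_cross(t, v, iu, v_thr)
        t_dn = _interp_cross(t, v, idn, v_thr)
        apds.append(t_dn - t_up)
        starts.append(t_up)
    return apds, starts


def _interp_cross(t, v, i, v_thr):
    dv = v[i + 1] - v[i]
    frac = 0.0 if dv == 0 else (v_thr - v[i]) / dv
    return t[i] + frac * (t[i + 1] - t[i])


def plateau_apd(p: MMSParameters, dt: float = 0.02) -> float:
    """APD_max: the APD of a single beat elicited from the fully rested state."""
    g = math.log(p.tau_out / (4.0 * p.tau_in)) if p.tau_out > 4.0 * p.tau_in else 1.0
    duration = 20.0 + 3.0 * p.tau_close * max(g, 1.0) + 10.0 * p.tau_out
    out = simulate_single_cell(p, [5.0], dt=dt, duration=duration)
    if len(out["apds"]) == 0:
        raise RuntimeError("cell failed to fire from rest; parameters not excitable")
    return float(out["apds"][0])


# ---------------------------------------------------------------------------
# restitution and refractoriness
# ---------------------------------------------------------------------------

#: marker returned for a diastolic interval that fails to capture
NON_CAPTURED = np.nan


def restitution_curve(p: MMSParameters, diastolic_intervals, dt: float = 0.02):
    """APD restitution by S1-S2 runs: one conditioning beat from rest, then a
    premature beat a given diastolic interval after repolarization.

    Returns an APD array aligned with ``diastolic_intervals``; non-captured
    intervals are marked ``NON_CAPTURED`` (NaN), never zero.
    """
    dis = np.asarray(diastolic_intervals, dtype=float)
    if np.any(dis <= 0):
        raise ValueError("diastolic intervals must be positive")
    if np.any(np.diff(dis) < 0):
        raise ValueError("diastolic intervals must be sorted ascending")

    s1 = 5.0
    base = simulate_single_cell(p, [s1], dt=dt, duration=s1 + 6.0 * p.tau_close + 100.0)
    if len(base["apds"]) == 0:
        raise RuntimeError("S1 failed to capture from rest")
    t_rep = base["beat_starts"][0] + base["apds"][0]  # end of S1 plateau

    apds = np.empty_like(dis)
    for k, di in enumerate(dis):
        s2 = t_rep + di
        out = simulate_single_cell(
            p, [s1, s2], dt=dt, duration=s2 + 6.0 * p.tau_close + 100.0
        )
        if out["captured"][1] and len(out["apds"]) >= 2:
            apds[k] = out["apds"][1]
        else:
            apds[k] = NON_CAPTURED
    return apds


def erp_single_cell(
    p: MMSParameters, dt: float = 0.02, resolution: float = 1.0
) -> float:
    """Effective refractory period of an isolated cell: the longest S1-S2
    coupling interval that fails to elicit a full action potential,
    located by bisection to ``resolution`` ms."""
    s1 = 5.0
    apd1 = plateau_apd(p, dt=dt)

    def captures(ci: float) -> bool:
        out = simulate_single_cell(
            p, [s1, s1 + ci], dt=dt, duration=s1 + ci + 4.0 * p.tau_close + 100.0
        )
        return out["captured"][1]

    lo = 0.2 * apd1          # deep in the plateau: must fail
    hi = apd1 + 5.0 * p.tau_open  # fully recovered: must capture
    if captures(lo):
        return lo  # below-grid: refractoriness shorter than probed
    while not captures(hi):
        hi *= 1.5
        if hi > 1e5:
            raise RuntimeError("cell never recovers excitability")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if captures(mid):
            hi = mid
        else:
            lo = mid
    return float(lo)


# ---------------------------------------------------------------------------
# tau_close <-> APD_max mapping
# ---------------------------------------------------------------------------

def tau_close_from_apdmax(
    apd_max: float, p_other: MMSParameters, dt: float = 0.02
) -> float:
    """Invert the monotone tau_close -> APD_max relation by root finding
    against the single-cell integrator.

    Raises if ``apd_max`` is below the minimum APD attainable with the other
    parameters held fixed.
    """
    if not np.isfinite(apd_max) or apd_max <= 0:
        raise ValueError(f"apd_max must be > 0, got {apd_max}")

    def apd_of(tc: float) -> float:
        return plateau_apd(replace(p_other, tau_close=tc), dt=dt)

    lo, hi = 1.0, max(4.0 * apd_max, 50.0)
    apd_lo = apd_of(lo)
    if apd_lo >= apd_max:
        raise ValueError(
            f"apd_max = {apd_max} ms is below the minimum APD "
            f"({apd_lo:.1f} ms) attainable with these parameters"
        )
    while apd_of(hi) < apd_max:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError(f"apd_max = {apd_max} ms unattainable")
    return float(brentq(lambda tc: apd_of(tc) - apd_max, lo, hi, xtol=1e-3))


def calibrate_apd_map(p_other: MMSParameters, dt: float = 0.02):
    """Linear calibration APD_max = a*tau_close + b for vectorized mapping of
    whole APD fields; the relation is affine to high accuracy."""
    tcs = np.array([0.5, 1.0, 2.0]) * p_other.tau_close
    apds = np.array([plateau_apd(replace(p_other, tau_close=tc), dt=dt) for tc in tcs])
    a, b = np.polyfit(tcs, apds, 1)
    return float(a), float(b)


# ---------------------------------------------------------------------------
# conductivity <-> CV_max mapping via a 1-D cable
# ---------------------------------------------------------------------------

class PropagationError(RuntimeError):
    """Raised when a planar wave fails to propagate along the cable."""


def cable_cv(
    p: MMSParameters,
    dx: float = 0.25,
    length: float = 60.0,
    dt: float = 0.02,
    v_thr: float = V_THR,
) -> float:
    """Planar-wave conduction velocity (cm/s) in a 1-D cable at spacing dx.

    A stimulus at one end launches a wave; CV is measured between 40 % and
    80 % of the cable from interpolated threshold-crossing times.  The time
    step is reduced automatically to satisfy the explicit diffusion bound.
    """
    D = p.diffusivity
    dt_stab = 0.5 * dx * dx / (2.0 * D)
    dt_eff = min(dt, dt_stab, 0.1 * p.tau_in)
    n = int(round(length / dx)) + 1
    v = np.zeros(n)
    h = np.ones(n)
    iA, iB = int(0.4 * n), int(0.8 * n)
    # generous horizon: CV is never below ~0.15*sqrt(D/tau_in) mm/ms
    cv_floor = 0.15 * math.sqrt(D / p.tau_in)
    t_max = 20.0 + length / cv_floor
    coef = D / (dx * dx)
    n_steps = int(t_max / dt_eff)
    tA = tB = None
    prevA = prevB = 0.0
    for i in range(n_steps):
        t = i * dt_eff
        lap = np.empty(n)
        lap[1:-1] = v[:-2] - 2.0 * v[1:-1] + v[2:]
        lap[0] = v[1] - v[0]
        lap[-1] = v[-2] - v[-1]
        dv = coef * lap + h * v * (v - p.v_gate) * (1.0 - v) / p.tau_in - v / p.tau_out
        if t < 2.0:
            dv[:3] += 1.0
        h = h + dt_eff * np.where(v < p.v_gate, (1.0 - h) / p.tau_open, -h / p.tau_close)
        v = v + dt_eff * dv
        if tA is None and v[iA] >= v_thr:
            tA = t + dt_eff * (v_thr - prevA) / (v[iA] - prevA)
        if v[iB] >= v_thr:
            tB = t + dt_eff * (v_thr - prevB) / (v[iB] - prevB)
            break
        prevA, prevB = v[iA], v[iB]
    if tA is None or tB is None:
        raise PropagationError(
            f"wave failed to propagate (D = {D:g} mm^2/ms at dx = {dx} mm)"
        )
    cv_mm_ms = (iB - iA) * dx / (tB - tA)
    return 100.0 * cv_mm_ms  # mm/ms -> cm/s


_CV_SLOPE_CACHE: dict = {}


def cv_slope(p_other: MMSParameters, dx: float = 0.25, dt: float = 0.02) -> float:
    """Calibrated slope s of CV = s * sqrt(D) (cm/s per sqrt(mm^2/ms)) for
    the given cell parameters at spacing dx.  Cached."""
    key = (round(p_other.tau_in, 9), round(p_other.tau_out, 9),
           round(p_other.v_gate, 9), round(dx, 9), round(dt, 9))
    if key not in _CV_SLOPE_CACHE:
        # reference conductivities must propagate at this spacing; the
        # lattice propagation threshold scales like dx^2
        refs = np.array([0.1, 0.4, 1.6]) * max(1.0, (dx / 0.25) ** 2)
        cvs = np.array([cable_cv(replace(p_other, diffusivity=d), dx=dx, dt=dt)
                        for d in refs])
        s = float(np.sum(cvs * np.sqrt(refs)) / np.sum(refs))
        _CV_SLOPE_CACHE[key] = s
    return _CV_SLOPE_CACHE[key]


def conductivity_from_cvmax(
    cv_max: float,
    p_other: MMSParameters,
    dx: float = 0.25,
    dt: float = 0.02,
    refine: bool = True,
    tol: float = 0.05,
) -> float:
    """Conductivity D (mm**2/ms) whose cable CV matches ``cv_max`` (cm/s).

    Uses the calibrated CV = s*sqrt(D) law, then (optionally) one fixed-point
    correction from a direct cable measurement.  Raises a diagnostic error if
    the requested speed cannot be represented at this discretization.
    """
    if not np.isfinite(cv_max) or cv_max <= 0:
        raise ValueError(f"cv_max must be > 0, got {cv_max}")
    s = cv_slope(p_other, dx=dx, dt=dt)
    D = (cv_max / s) ** 2
    if refine:
        try:
            meas = cable_cv(replace(p_other, diffusivity=D), dx=dx, dt=dt)
        except PropagationError as e:
            raise ValueError(
                f"cv_max = {cv_max} cm/s is below the propagation limit at dx = {dx} mm"
            ) from e
        D *= (cv_max / meas) ** 2
        check = cable_cv(replace(p_other, diffusivity=D), dx=dx, dt=dt)
        if abs(check - cv_max) / cv_max > tol:
            raise ValueError(
                f"mapping failed: requested {cv_max} cm/s, cable gives {check:.1f} "
                f"cm/s at dx = {dx} mm (sub-discretization wavelength?)"
            )
    return float(D)


# ---------------------------------------------------------------------------
# per-node parameter fields
# ---------------------------------------------------------------------------

@dataclass
class ParameterFieldSet:
    """Per-node restitution targets (CV_max, APD_max) and the mMS parameter
    fields derived from them.  All arrays are (n_nodes,)."""

    cv_max: np.ndarray      # cm/s
    apd_max: np.ndarray     # ms
    tau_in: np.ndarray
    tau_out: np.ndarray
    tau_open: np.ndarray
    tau_close: np.ndarray
    v_gate: np.ndarray
    diffusivity: np.ndarray  # mm^2/ms

    @property
    def n_nodes(self) -> int:
        return self.cv_max.shape[0]

    @classmethod
    def uniform(cls, n: int, p: MMSParameters,
                cv_max: float = np.nan, apd_max: float = np.nan):
        full = lambda x: np.full(n, float(x))
        return cls(full(cv_max), full(apd_max), full(p.tau_in), full(p.tau_out),
                   full(p.tau_open), full(p.tau_close), full(p.v_gate),
                   full(p.diffusivity))

    @classmethod
    def from_targets(cls, cv_max, apd_max, base: MMSParameters, dx: float,
                     dt: float = 0.02):
        """Map per-node (CV_max, APD_max) to (diffusivity, tau_close) fields
        using the calibrated analytic laws; other parameters are global."""
        cv_max = np.asarray(cv_max, dtype=float)
        apd_max = np.asarray(apd_max, dtype=float)
        if np.any(cv_max <= 0):
            raise ValueError("cv_max field must be strictly positive")
        if np.any(apd_max <= 0):
            raise ValueError("apd_max field must be strictly positive")
        s = cv_slope(base, dx=dx, dt=dt)
        D = (cv_max / s) ** 2
        a, b = calibrate_apd_map(base, dt=dt)
        tau_close = (apd_max - b) / a
        if np.any(tau_close <= 0):
            raise ValueError("apd_max field below the attainable minimum APD")
        n = cv_max.shape[0]
        full = lambda x: np.full(n, float(x))
        return cls(cv_max, apd_max, full(base.tau_in), full(base.tau_out),
                   full(base.tau_open), tau_close, full(base.v_gate), D)

    def local_parameters(self, node: int) -> MMSParameters:
        return MMSParameters(
            tau_in=float(self.tau_in[node]), tau_out=float(self.tau_out[node]),
            tau_open=float(self.tau_open[node]), tau_close=float(self.tau_close[node]),
            v_gate=float(self.v_gate[node]), diffusivity=float(self.diffusivity[node]),
        )
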