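"""Measurement protocols: AP detection, stimulus thresholds, conduction
velocity, space constant, and action-potential duration.

Conventions (documented here once, used by every protocol):

* An action potential is *detected* when the membrane potential exceeds
  0 mV within a fixed window after the pulse (50 ms for isolated cells;
  250 ms for fiber propagation, long enough for slow waves at weak
  coupling to reach the probe cell).  A pulse only counts as eliciting a
  *new* AP if the cell had repolarised below -40 mV at pulse onset.
* Threshold searches work on the 0.5 nA amplitude grid of the pacing
  protocol: pulses at 1 Hz, 0.2 ms duration, threshold = the
  smallest-magnitude grid amplitude for which two consecutive pulses both
  elicit APs (for fibers: both propagate to the probe cell, by default
  the cell at 3/4 of the chain).  The default search brackets and bisects
  on the first-pulse response and then verifies the two-pulse criterion,
  which is equivalent to — and tested against — the literal incremental
  scan.
* A fiber is declared inexcitable when the amplitude cap is reached
  (about 100x the default-parameter threshold magnitude).
* Activation time = instant of maximum dV/dt during the upstroke,
  earliest time on ties; conduction velocity uses the activation-time
  difference between the 25th and 75th cells over 50 cell lengths.
* The space constant is fitted as dV_i = A exp(-i/lambda) (least squares)
  to the end-of-pulse depolarisations of a 100 ms pulse at 95% of the
  separately measured long-pulse threshold, excluding the stimulated
  cells and the last five cells (sealed-end distortion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .cell_model import CellParameters, resting_state
from .engine import SimulationTrace, StimulusProtocol, simulate
from .fiber_model import FiberConfig, System

__all__ = [
    "ThresholdResult", "SpaceConstantFit", "CVResult",
    "detect_ap", "find_cell_threshold", "find_fiber_threshold",
    "measure_cv", "measure_space_constant", "measure_apd",
]

AP_PEAK_MV = 0.0          # detection level for a full AP
REARM_MV = -40.0          # cell must repolarise below this to re-fire
CELL_AP_WINDOW = 50.0     # ms after pulse onset, isolated cell
FIBER_AP_WINDOW = 250.0   # ms after pulse onset, propagation to probe cell
DEFAULT_RESOLUTION = 0.5  # nA search grid
CELL_AMPLITUDE_CAP = -2000.0   # ~100x the default-parameter cell threshold
FIBER_AMPLITUDE_CAP = -6500.0  # ~100x the default-parameter fiber threshold

_REST_CACHE: dict = {}


def _rest_vector(params: CellParameters) -> np.ndarray:
    if params not in _REST_CACHE:
        _REST_CACHE[params] = resting_state(params).vector
    return _REST_CACHE[params].copy()


def detect_ap(v: np.ndarray, t: np.ndarray, window: tuple[float, float]) -> bool:
    """True iff the voltage series peaks above 0 mV inside ``window``."""
    t = np.asarray(t, float)
    v = np.asarray(v, float)
    m = (t >= window[0]) & (t <= window[1])
    if not np.any(m):
        raise ValueError(f"empty detection window {window}")
    return bool(np.max(v[m]) > AP_PEAK_MV)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of a stimulus-threshold search.

    ``amplitude`` is the threshold on the search grid (nA, negative), or
    None with ``inexcitable`` set when no amplitude up to the cap
    elicited the required response.
    """

    amplitude: float | None
    inexcitable: bool
    resolution: float
    n_simulations: int
    cap: float

    @property
    def magnitude(self) -> float:
        if self.inexcitable:
            return math.inf
        return abs(self.amplitude)


@dataclass(frozen=True)
class CVResult:
    cv_cm_s: float
    t_activation: dict          # cell index -> ms
    amplitude: float
    threshold: ThresholdResult | None


@dataclass(frozen=True)
class SpaceConstantFit:
    lam_cells: float            # space constant, multiples of L_c
    amplitude_mV: float         # fitted exponential amplitude at cell i0
    residual_norm: float        # rms residual of the fit, mV
    cells: tuple                # 1-based cell indices included
    stim_amplitude: float       # nA used for the measurement
    deltaV: np.ndarray = field(repr=False, default=None)


# ----------------------------------------------------------------------
# threshold searches
# ----------------------------------------------------------------------

def _pulse_elicits(trace: SimulationTrace, cell: int, onset: float,
                   window: float) -> bool:
    t, v = trace.t, trace.cell(cell)
    i0 = int(np.searchsorted(t, onset))
    armed = v[max(i0 - 1, 0)] < REARM_MV
    return armed and detect_ap(v, t, (onset, onset + window))


def _two_pulse_ok(system: System, protocol: StimulusProtocol, amp: float,
                  cell: int, window: float, y0: np.ndarray, rtol, atol) -> bool:
    pr = protocol.replace(amplitude=amp, n_pulses=2)
    t_end = pr.onset + pr.period + window + pr.duration
    tr = simulate(system, pr, (0.0, t_end), y0=y0.copy(),
                  upstroke_window=min(window, 60.0), rtol=rtol, atol=atol)
    return (_pulse_elicits(tr, cell, pr.onset, window)
            and _pulse_elicits(tr, cell, pr.onset + pr.period, window))


def _first_pulse_ok(system: System, protocol: StimulusProtocol, amp: float,
                    cell: int, window: float, y0: np.ndarray, rtol, atol) -> bool:
    pr = protocol.replace(amplitude=amp, n_pulses=1)
    t_end = pr.onset + pr.duration + window
    tr = simulate(system, pr, (0.0, t_end), y0=y0.copy(),
                  upstroke_window=min(window, 60.0), rtol=rtol, atol=atol)
    return _pulse_elicits(tr, cell, pr.onset, window)


def _threshold_search(system: System, protocol: StimulusProtocol, *,
                      probe_cell: int, window: float, resolution: float,
                      cap: float, method: str, y0: np.ndarray,
                      rtol: float, atol: float) -> ThresholdResult:
    n_sim = 0

    def probe(k: int) -> bool:   # first-pulse response at grid index k
        nonlocal n_sim
        n_sim += 1
        return _first_pulse_ok(system, protocol, -k * resolution,
                               probe_cell, window, y0, rtol, atol)

    def full(k: int) -> bool:    # two consecutive pulses
        nonlocal n_sim
        n_sim += 1
        return _two_pulse_ok(system, protocol, -k * resolution,
                             probe_cell, window, y0, rtol, atol)

    k_cap = int(abs(cap) / resolution)

    if method == "incremental":
        # the literal protocol: raise the magnitude in grid steps until
        # two consecutive pulses both elicit APs (a failing first pulse
        # decides the pair, so the cheap probe short-circuits it)
        for k in range(1, k_cap + 1):
            if probe(k) and full(k):
                return ThresholdResult(-k * resolution, False, resolution,
                                       n_sim, cap)
        return ThresholdResult(None, True, resolution, n_sim, cap)

    if method != "bracket":
        raise ValueError(f"unknown search method {method!r}")

    # exponential bracketing on the first-pulse response ...
    k_lo, k_hi = 0, 4            # k_lo always fails, k_hi candidate
    while not probe(k_hi):
        k_lo = k_hi
        k_hi *= 2
        if k_hi > k_cap:
            if k_lo < k_cap and probe(k_cap):
                k_hi = k_cap
                break
            return ThresholdResult(None, True, resolution, n_sim, cap)
    # ... bisection down to the grid
    while k_hi - k_lo > 1:
        k_mid = (k_lo + k_hi) // 2
        if probe(k_mid):
            k_hi = k_mid
        else:
            k_lo = k_mid
    # verify the two-pulse criterion, walking up the grid if needed
    k = k_hi
    while k <= k_cap:
        if full(k):
            return ThresholdResult(-k * resolution, False, resolution,
                                   n_sim, cap)
        k += 1
    return ThresholdResult(None, True, resolution, n_sim, cap)


def find_cell_threshold(params: CellParameters, *,
                        protocol: StimulusProtocol | None = None,
                        resolution: float = DEFAULT_RESOLUTION,
                        cap: float = CELL_AMPLITUDE_CAP,
                        window: float = CELL_AP_WINDOW,
                        method: str = "bracket",
                        rtol: float = 1e-6, atol: float = 1e-6) -> ThresholdResult:
    """Stimulus-current threshold of an isolated cell.

    0.2 ms square pulses at 1 Hz; the threshold is the smallest-magnitude
    amplitude on the ``resolution`` grid for which two consecutive pulses
    each elicit an AP.
    """
    protocol = protocol or StimulusProtocol(amplitude=-resolution,
                                            target_cells=(1,))
    system = System.from_cell(params)
    y0 = _rest_vector(params)
    return _threshold_search(system, protocol, probe_cell=1, window=window,
                             resolution=resolution, cap=cap, method=method,
                             y0=y0, rtol=rtol, atol=atol)


def find_fiber_threshold(config: FiberConfig, *,
                         protocol: StimulusProtocol | None = None,
                         probe_cell: int | None = None,
                         resolution: float = DEFAULT_RESOLUTION,
                         cap: float = FIBER_AMPLITUDE_CAP,
                         window: float = FIBER_AP_WINDOW,
                         method: str = "bracket",
                         rtol: float = 1e-6, atol: float = 1e-6) -> ThresholdResult:
    """Propagation threshold of a fiber stimulated at its first four cells.

    Success requires the AP to be detected at ``probe_cell`` (defaults to
    the cell at 3/4 of the chain, i.e. cell 75 of 100 — far from both the
    stimulated end and the sealed distal end) for two consecutive pulses.
    """
    protocol = protocol or StimulusProtocol(amplitude=-resolution,
                                            target_cells=(1, 2, 3, 4))
    if probe_cell is None:
        probe_cell = max(2, int(round(0.75 * config.n_cells)))
    system = System.from_fiber(config)
    y0 = np.tile(_rest_vector(config.cell_params), config.n_cells)
    return _threshold_search(system, protocol, probe_cell=probe_cell,
                             window=window, resolution=resolution, cap=cap,
                             method=method, y0=y0, rtol=rtol, atol=atol)


# ----------------------------------------------------------------------
# conduction velocity
# ----------------------------------------------------------------------

def activation_time(t: np.ndarray, v: np.ndarray,
                    after: float = 0.0) -> float:
    """Instant of maximum dV/dt (earliest on ties), restricted to t >= after."""
    m = t >= after
    tt, vv = t[m], v[m]
    dv = np.gradient(vv, tt)
    return float(tt[int(np.argmax(dv))])


def measure_cv(config: FiberConfig, *, amplitude: float | None = None,
               threshold: ThresholdResult | None = None,
               cells: tuple[int, int] = (25, 75), max_time: float = 400.0,
               protocol: StimulusProtocol | None = None,
               rtol: float = 1e-6, atol: float = 1e-6) -> CVResult:
    """Conduction velocity in cm/s from the activation times of two cells.

    The stimulus is, by convention, 1.5x the fiber threshold (measured
    here unless ``threshold`` or an explicit ``amplitude`` is supplied),
    applied to the first four cells; CV = (distance between the two
    cells) x L_c / (activation-time difference).
    """
    if amplitude is None:
        if threshold is None:
            threshold = find_fiber_threshold(config, rtol=rtol, atol=atol)
        if threshold.inexcitable:
            raise RuntimeError("fiber is inexcitable; no CV measurable")
        amplitude = 1.5 * threshold.amplitude
    protocol = (protocol or StimulusProtocol(amplitude=amplitude,
                                             target_cells=(1, 2, 3, 4))
                ).replace(amplitude=amplitude, n_pulses=1)
    system = System.from_fiber(config)
    y0 = np.tile(_rest_vector(config.cell_params), config.n_cells)
    tr = simulate(system, protocol, (0.0, protocol.onset + max_time),
                  y0=y0, upstroke_window=max_time, dense_dt=0.02,
                  rtol=rtol, atol=atol)
    c_near, c_far = cells
    if tr.cell(c_far).max() <= AP_PEAK_MV:
        raise RuntimeError(
            f"no activation at cell {c_far} at 1.5x threshold "
            f"(amplitude {amplitude} nA) — protocol inconsistency")
    t_act = {c: activation_time(tr.t, tr.cell(c), after=protocol.onset)
             for c in cells}
    dt_ms = t_act[c_far] - t_act[c_near]
    dist_cm = abs(c_far - c_near) * config.L_c * 1e-4
    return CVResult(cv_cm_s=dist_cm / (dt_ms * 1e-3),
                    t_activation=t_act, amplitude=amplitude,
                    threshold=threshold)


# ----------------------------------------------------------------------
# space constant
# ----------------------------------------------------------------------

def find_long_pulse_threshold(config: FiberConfig, *, duration: float = 100.0,
                              resolution: float = DEFAULT_RESOLUTION,
                              cap: float = FIBER_AMPLITUDE_CAP,
                              rtol: float = 1e-6, atol: float = 1e-6,
                              system: System | None = None,
                              y0: np.ndarray | None = None) -> ThresholdResult:
    """Smallest-magnitude long-pulse amplitude that fires any cell.

    Single pulse of ``duration`` ms to the first four cells; an AP
    anywhere in the fiber (within the pulse or 50 ms after it) counts.
    Used to scale the subthreshold space-constant stimulus.
    """
    system = system or System.from_fiber(config)
    if y0 is None:
        y0 = np.tile(_rest_vector(config.cell_params), config.n_cells)
    n_sim = 0

    def fires(k: int) -> bool:
        nonlocal n_sim
        n_sim += 1
        pr = StimulusProtocol(amplitude=-k * resolution, duration=duration,
                              n_pulses=1, onset=5.0, target_cells=(1, 2, 3, 4))
        tr = simulate(system, pr, (0.0, pr.onset + duration + 50.0),
                      y0=y0.copy(), upstroke_window=20.0, dense_dt=0.1,
                      coarse_dt=0.5, pulse_dt=0.1, rtol=rtol, atol=atol)
        return float(tr.V.max()) > AP_PEAK_MV

    k_cap = int(abs(cap) / resolution)
    k_lo, k_hi = 0, 4
    while not fires(k_hi):
        k_lo = k_hi
        k_hi *= 2
        if k_hi > k_cap:
            return ThresholdResult(None, True, resolution, n_sim, cap)
    while k_hi - k_lo > 1:
        k_mid = (k_lo + k_hi) // 2
        if fires(k_mid):
            k_hi = k_mid
        else:
            k_lo = k_mid
    return ThresholdResult(-k_hi * resolution, False, resolution, n_sim, cap)


def measure_space_constant(config, *, amplitude: float | None = None,
                           duration: float = 100.0, safety: float = 0.95,
                           exclude_last: int = 5,
                           target_cells: tuple = (1, 2, 3, 4),
                           rtol: float = 1e-6, atol: float = 1e-6
                           ) -> SpaceConstantFit:
    """Fiber space constant from a long subthreshold pulse.

    A 100 ms pulse (at ``safety`` x the long-pulse threshold unless an
    explicit subthreshold ``amplitude`` is given) lets the fiber reach
    steady state; the end-of-pulse depolarisations dV_i of the
    non-stimulated cells (omitting the last ``exclude_last`` cells, where
    the sealed end distorts the profile) are fitted to
    A exp(-(i - i0)/lambda) by least squares, with lambda in cell lengths.

    ``config`` may be a FiberConfig or a ready-made System (the passive
    fixture uses the latter).
    """
    if isinstance(config, System):
        system = config
        y0 = system.resting_vector()
        n = system.n_cells
    else:
        system = System.from_fiber(config)
        y0 = np.tile(_rest_vector(config.cell_params), config.n_cells)
        n = config.n_cells
    auto_amplitude = amplitude is None
    if auto_amplitude:
        thr = find_long_pulse_threshold(config, duration=duration,
                                        rtol=rtol, atol=atol,
                                        system=system, y0=y0)
        if thr.inexcitable:
            raise RuntimeError("no long-pulse threshold found; cannot scale "
                               "the space-constant stimulus")
        amplitude = safety * thr.amplitude

    # the 0.5 nA threshold grid can leave safety x threshold still (just)
    # suprathreshold; when the amplitude was chosen automatically, back it
    # off in 5% steps rather than fail
    for attempt in range(5):
        pr = StimulusProtocol(amplitude=amplitude, duration=duration,
                              n_pulses=1, onset=5.0, target_cells=target_cells)
        tr = simulate(system, pr, (0.0, pr.onset + duration), y0=y0.copy(),
                      upstroke_window=0.0, dense_dt=0.5, coarse_dt=0.5,
                      pulse_dt=0.5, rtol=rtol, atol=atol)
        if float(tr.V.max()) <= AP_PEAK_MV:
            break
        if not auto_amplitude:
            raise RuntimeError(
                f"amplitude {amplitude} nA triggered an AP during the "
                "space-constant pulse; reduce the amplitude")
        amplitude *= 0.95
    else:
        raise RuntimeError("could not find a subthreshold long-pulse "
                           "amplitude; parameter regime pathological")
    dV = tr.V[-1] - tr.V[0]
    first_fit = max(target_cells) + 1
    cells = np.arange(first_fit, n - exclude_last + 1)  # 1-based indices
    y = dV[cells - 1]
    # short space constants decay below float resolution within a few
    # cells; keep only the leading cells above a relative floor
    floor = max(1e-9, 1e-6 * float(np.max(np.abs(dV))))
    above = np.nonzero(y > floor)[0]
    keep = above[-1] + 1 if above.size else 0
    if keep < 5:
        raise RuntimeError("non-positive steady-state depolarisation in the "
                           "fit range; stimulus too weak or fiber too short")
    cells, y = cells[:keep], y[:keep]
    x = cells - float(first_fit)

    # log-linear start, then true least squares on the exponential
    slope, intercept = np.polyfit(x, np.log(y), 1)
    lam0 = -1.0 / slope if slope < 0 else float(n)
    popt, _ = curve_fit(lambda xx, A, lam: A * np.exp(-xx / lam), x, y,
                        p0=(math.exp(intercept), lam0), maxfev=10000)
    A_fit, lam = float(popt[0]), float(popt[1])
    resid = float(np.sqrt(np.mean((A_fit * np.exp(-x / lam) - y) ** 2)))
    if not (lam > 0 and np.isfinite(lam)):
        raise RuntimeError(f"space-constant fit did not converge (lam={lam}, "
                           f"residual={resid})")
    return SpaceConstantFit(lam_cells=lam, amplitude_mV=A_fit,
                            residual_norm=resid, cells=tuple(cells),
                            stim_amplitude=amplitude, deltaV=dV)


# ----------------------------------------------------------------------
# action-potential duration
# ----------------------------------------------------------------------

def measure_apd(trace: SimulationTrace, *, level: float = 0.90,
                cell: int = 1, v_rest: float | None = None) -> float:
    """AP duration at ``level`` repolarisation (APD90 by default), ms.

    Measured from the maximum-upstroke instant to the time the voltage
    falls below peak - level x (peak - rest).  Returns ``inf`` when the
    AP has not repolarised to that level by the end of the trace (the
    trace then only bounds the APD from below).  Raises if the trace
    contains no AP.
    """
    t, v = trace.t, trace.cell(cell)
    if v.max() <= AP_PEAK_MV:
        raise ValueError("trace contains no action potential")
    if v_rest is None:
        v_rest = float(v[0])
    t_up = activation_time(t, v)
    i_up = int(np.searchsorted(t, t_up))
    i_peak = i_up + int(np.argmax(v[i_up:]))
    v_level = v[i_peak] - level * (v[i_peak] - v_rest)
    below = np.nonzero(v[i_peak:] <= v_level)[0]
    if below.size == 0:
        return math.inf
    i_cross = i_peak + below[0]
    # linear interpolation of the crossing instant
    if i_cross > i_peak:
        t0, t1 = t[i_cross - 1], t[i_cross]
        v0, v1 = v[i_cross - 1], v[i_cross]
        t_cross = t0 + (v_level - v0) / (v1 - v0) * (t1 - t0) if v1 != v0 else t1
    else:
        t_cross = t[i_cross]
    return float(t_cross - t_up)
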