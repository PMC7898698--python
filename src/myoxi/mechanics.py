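"""Contractile-mechanics metrics from force and length traces.

Covers the full in-vitro / in-situ analysis chain: twitch kinetics,
specific force (stress), force–frequency curves, shortening velocity
from after-loaded transients, hyperbolic-linear force–velocity fitting
(Vmax, peak power, power ratio), work-loop net power, linear
preparation-decline correction, and the fatigue index of sustained
stimulation runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .traces import G_TO_N, ForceTrace, LengthTrace, WorkLoopTrace

MUSCLE_DENSITY = 1.06  # g/cm³


class MechanicsError(ValueError):
    pass


# ----------------------------------------------------------------------
# Twitch kinetics
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TwitchMetrics:
    peak: float      # above baseline, trace units
    ttp_ms: float    # stimulus onset -> peak
    hrt_ms: float    # peak -> decay to half amplitude
    baseline: float


def twitch_metrics(trace: ForceTrace) -> TwitchMetrics:
    """Peak force, time-to-peak tension and half-relaxation time.

    Baseline is the pre-stimulus mean; HRT is measured from the peak to
    the time force decays to baseline + half the peak amplitude
    (linear interpolation between samples).
    """
    if len(trace.stimulus_onsets) != 1:
        raise MechanicsError("twitch_metrics expects exactly one stimulus onset")
    onset = trace.stimulus_onsets[0]
    t, f = trace.time, np.asarray(trace.force, dtype=float)
    # light Savitzky-Golay smoothing (~3 ms) stabilises the peak and the
    # half-relaxation crossing against sampling noise at 10 kHz
    win = int(round(0.003 * trace.sampling_rate))
    win = max(win + (win + 1) % 2, 5)
    if len(f) > win:
        from scipy.signal import savgol_filter

        f = savgol_filter(f, win, 2)
    raw = np.asarray(trace.force, dtype=float)
    pre = t < onset
    baseline = float(f[pre].mean()) if pre.any() else float(f[0])
    post = t >= onset
    if not post.any():
        raise MechanicsError("no samples after the stimulus onset")
    i_rel = np.argmax(f[post])
    i_peak = np.nonzero(post)[0][i_rel]
    # peak location from the smoothed trace, amplitude from the raw one
    # (smoothing flattens sharp apices; the raw sample at an independently
    # chosen index carries no max-selection bias)
    peak = raw[i_peak] - baseline
    ttp_ms = (t[i_peak] - onset) * 1e3
    half = baseline + 0.5 * peak
    below = np.nonzero(f[i_peak:] <= half)[0]
    if len(below) == 0:
        raise MechanicsError("force never decays to half amplitude")
    j = i_peak + below[0]
    if j == i_peak:
        t_half = t[i_peak]
    else:
        # interpolate the crossing between samples j-1 and j
        f0, f1 = f[j - 1], f[j]
        t_half = t[j - 1] + (t[j] - t[j - 1]) * (f0 - half) / (f0 - f1)
    return TwitchMetrics(peak=float(peak), ttp_ms=float(ttp_ms),
                         hrt_ms=float((t_half - t[i_peak]) * 1e3),
                         baseline=baseline)


# ----------------------------------------------------------------------
# Specific force
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MuscleGeometry:
    """Wet mass (g), optimal length L0 (cm) and density (g/cm³)."""

    wet_mass: float
    l0: float
    density: float = MUSCLE_DENSITY

    def __post_init__(self) -> None:
        if self.wet_mass <= 0 or self.l0 <= 0 or self.density <= 0:
            raise MechanicsError("mass, L0 and density must all be positive")

    @property
    def csa_cm2(self) -> float:
        """Physiological cross-section: mass / (L0 · density)."""
        return self.wet_mass / (self.l0 * self.density)


def specific_force(force: float, geom: MuscleGeometry, unit: str = "N") -> float:
    """Stress in N/cm² from a force in newtons (or gram-force)."""
    if unit == "g":
        force = force * G_TO_N
    elif unit != "N":
        raise MechanicsError(f"unknown force unit {unit!r}")
    return force / geom.csa_cm2


# ----------------------------------------------------------------------
# Force–frequency
# ----------------------------------------------------------------------

def force_frequency(traces: dict) -> tuple[pd.DataFrame, float]:
    """Per-frequency peak force (above baseline), sorted by frequency.

    Returns the curve and the peak tetanic force (maximum across
    frequencies).  Units are those of the input traces (mixed units are
    rejected)."""
    if len(traces) < 2:
        raise MechanicsError("need at least two stimulation frequencies")
    units = {tr.unit for tr in traces.values()}
    if len(units) > 1:
        raise MechanicsError("traces have mixed force units")
    rows = []
    for freq in sorted(traces):
        tr = traces[freq]
        onset = tr.stimulus_onsets[0] if tr.stimulus_onsets else tr.time[0]
        pre = tr.time < onset
        baseline = tr.force[pre].mean() if pre.any() else tr.force[0]
        rows.append((freq, float(tr.force.max() - baseline)))
    curve = pd.DataFrame(rows, columns=["freq_hz", "peak_force"])
    return curve, float(curve["peak_force"].max())


def twitch_tetanus_ratio(curve: pd.DataFrame) -> float:
    """Peak twitch (lowest frequency) over peak tetanic force."""
    twitch = curve.loc[curve["freq_hz"].idxmin(), "peak_force"]
    return float(twitch / curve["peak_force"].max())


# ----------------------------------------------------------------------
# Shortening velocity
# ----------------------------------------------------------------------

def shortening_velocity(trace: LengthTrace, release_time: Optional[float] = None,
                        offset_ms: float = 10.0, slope_tol: float = 0.05,
                        min_window_ms: float = 5.0) -> float:
    """Shortening velocity (L0/s, shortening positive) from a transient.

    The slope is a least-squares fit over the linear section: starting
    ``offset_ms`` after the first length change, extended for as long
    as the local slope stays within ``slope_tol`` of the initial one.
    """
    if trace.l0_cm is None:
        raise MechanicsError("length trace has no L0; set l0_cm")
    t, L = trace.time, trace.length_mm
    fs = 1.0 / np.median(np.diff(t))
    if fs < 1000.0:
        raise MechanicsError("length must be sampled at >= 1 kHz")
    if release_time is None:
        release_time = trace.release_time
    if release_time is None:
        dL = np.abs(np.diff(L))
        moved = np.nonzero(dL > 1e-12)[0]
        if len(moved) == 0:
            return 0.0
        release_time = t[moved[0]]
    start = release_time + offset_ms * 1e-3
    i0 = np.searchsorted(t, start)
    if i0 >= len(t) - 3:
        raise MechanicsError("no samples in the analysis window")
    # local slopes over short sub-windows (~2 ms)
    w = max(int(round(0.002 * fs)), 2)
    s0 = np.polyfit(t[i0:i0 + w], L[i0:i0 + w], 1)[0]
    if abs(s0) < 1e-9 * max(np.max(np.abs(L)), 1.0):
        return 0.0
    i1 = i0 + w
    while i1 + w <= len(t):
        s = np.polyfit(t[i1:i1 + w], L[i1:i1 + w], 1)[0]
        if abs(s - s0) > slope_tol * abs(s0):
            break
        i1 += w
    if (t[min(i1, len(t) - 1)] - t[i0]) < min_window_ms * 1e-3:
        raise MechanicsError("no linear section of at least "
                             f"{min_window_ms} ms after the release")
    slope_mm_s = np.polyfit(t[i0:i1], L[i0:i1], 1)[0]
    return float(-slope_mm_s / (trace.l0_cm * 10.0))


# ----------------------------------------------------------------------
# Force–velocity fitting (hyperbolic-linear)
# ----------------------------------------------------------------------

def _hyplin(f, a, b, c):
    """V(f) = b·(1−f)/(f+a) + c·(1−f), f = F/P0."""
    return b * (1.0 - f) / (f + a) + c * (1.0 - f)


def _hill(f, a, vmax):
    return vmax * a * (1.0 - f) / (f + a)


class ForceVelocityModel:
    """Hyperbolic-linear force–velocity model for after-loaded data.

    Parameters
    ----------
    force_frac : array-like
        Loads as fractions of the maximal tetanic force P0.
    velocity : array-like
        Shortening velocities, L0/s.
    p0_force_n, l0_cm, mass_g : optional absolute scale
        Needed only to express peak power in W/kg.
    """

    def __init__(self, force_frac: Sequence[float], velocity: Sequence[float],
                 p0_force_n: Optional[float] = None, l0_cm: Optional[float] = None,
                 mass_g: Optional[float] = None):
        self.f = np.asarray(force_frac, dtype=float)
        self.v = np.asarray(velocity, dtype=float)
        if len(self.f) < 5:
            raise MechanicsError("need at least 5 load levels for the fit")
        if self.f.min() <= 0 or self.f.max() >= 1:
            raise MechanicsError("load fractions must lie strictly in (0, 1)")
        self.p0_force_n = p0_force_n
        self.l0_cm = l0_cm
        self.mass_g = mass_g

    def fit(self, form: str = "hyperbolic-linear") -> "ForceVelocityResults":
        f, v = self.f, self.v
        # Hill prefit provides the starting point
        try:
            hill_p, _ = curve_fit(_hill, f, v, p0=[0.25, max(v.max(), 1e-3)],
                                  bounds=([1e-4, 1e-6], [1e3, 1e3]), maxfev=20000)
        except RuntimeError:
            hill_p = np.array([0.25, v.max()])
        if form == "hill":
            a, vmax0 = hill_p
            params = np.array([a, vmax0 * a, 0.0])
        elif form == "hyperbolic-linear":
            p0 = [hill_p[0], hill_p[0] * hill_p[1], 0.0]
            try:
                params, _ = curve_fit(
                    _hyplin, f, v, p0=p0,
                    bounds=([1e-6, 0.0, -np.inf], [1e4, np.inf, np.inf]),
                    maxfev=50000)
            except RuntimeError as exc:
                raise MechanicsError(f"force–velocity fit did not converge: {exc}")
        else:
            raise MechanicsError(f"unknown form {form!r}")
        vmax = float(_hyplin(0.0, *params))
        if vmax <= 0:
            raise MechanicsError(
                f"fitted Vmax = {vmax:.3g} L0/s is not positive "
                f"(params a={params[0]:.3g}, b={params[1]:.3g}, c={params[2]:.3g})")
        # peak power on the fitted curve, by dense grid + parabolic refinement
        fg = np.linspace(0.0, 1.0, 20001)
        pw = fg * _hyplin(fg, *params)
        i = int(np.argmax(pw))
        if 0 < i < len(fg) - 1:
            y0, y1, y2 = pw[i - 1], pw[i], pw[i + 2 - 1]
            denom = (y0 - 2 * y1 + y2)
            df = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            f_opt = fg[i] + np.clip(df, -1, 1) * (fg[1] - fg[0])
        else:
            f_opt = fg[i]
        wmax_norm = float(f_opt * _hyplin(f_opt, *params))
        return ForceVelocityResults(model=self, form=form, params=params,
                                    vmax=vmax, f_opt=float(f_opt),
                                    wmax_norm=wmax_norm,
                                    power_ratio=wmax_norm / vmax)


@dataclass
class ForceVelocityResults:
    """Fitted force–velocity curve and its derived quantities.

    ``wmax_norm`` is peak power in P0·Vmax-free units (P0·L0/s);
    ``power_ratio`` = Ẇmax/(P0·Vmax), the curvature index.
    """

    model: ForceVelocityModel
    form: str
    params: np.ndarray              # (a, b, c) of V = b(1−f)/(f+a) + c(1−f)
    vmax: float                     # L0/s
    f_opt: float                    # load fraction at peak power
    wmax_norm: float                # in P0·L0/s
    power_ratio: float

    def predict(self, f) -> np.ndarray:
        return _hyplin(np.asarray(f, dtype=float), *self.params)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.v - self.predict(self.model.f)

    @property
    def wmax_w_per_kg(self) -> Optional[float]:
        m = self.model
        if None in (m.p0_force_n, m.l0_cm, m.mass_g):
            return None
        return self.wmax_norm * m.p0_force_n * (m.l0_cm * 1e-2) / (m.mass_g * 1e-3)

    def summary(self) -> str:
        a, b, c = self.params
        lines = [
            "Force-velocity fit (%s)" % self.form,
            "  V(f) = b(1-f)/(f+a) + c(1-f),  f = F/P0",
            f"  a = {a:.4g}   b = {b:.4g} L0/s   c = {c:.4g} L0/s",
            f"  Vmax        = {self.vmax:.4g} L0/s",
            f"  Wmax        = {self.wmax_norm:.4g} P0*L0/s at f = {self.f_opt:.3f}",
            f"  power ratio = {self.power_ratio:.4f}",
            f"  RMS residual = {np.sqrt(np.mean(self.residuals ** 2)):.3g} L0/s "
            f"over n = {len(self.model.f)} loads",
        ]
        if self.wmax_w_per_kg is not None:
            lines.insert(5, f"  Wmax        = {self.wmax_w_per_kg:.4g} W/kg")
        return "\n".join(lines)


def fit_force_velocity(points: Sequence[tuple], p0: float = 1.0,
                       **scale) -> ForceVelocityResults:
    """Functional wrapper: ``points`` are (force, velocity) pairs with
    force in the same units as ``p0``; forces are normalised by p0."""
    pts = np.asarray(points, dtype=float)
    return ForceVelocityModel(pts[:, 0] / p0, pts[:, 1], **scale).fit()


# ----------------------------------------------------------------------
# Work loops
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class WorkLoopResult:
    net_work_j: float      # per cycle
    net_power_w_per_kg: float
    cycle_freq: float
    n_cycles_used: int


def workloop_power(trace: WorkLoopTrace, mass_g: float,
                   discard_first: bool = True) -> WorkLoopResult:
    """Net work per cycle (∮F dL, shortening work positive) and net power.

    The trace must hold an integer number of cycles; the first cycle is
    discarded as a transient when more than one is present.
    """
    if mass_g <= 0:
        raise MechanicsError("mass must be positive")
    t = trace.time
    dt = np.median(np.diff(t))
    duration = t[-1] - t[0] + dt
    n_cyc = duration * trace.cycle_freq
    if abs(n_cyc - round(n_cyc)) > 1e-2:
        raise MechanicsError(f"trace holds {n_cyc:.3f} cycles; an integer "
                             "number is required")
    n_cyc = int(round(n_cyc))
    per_cycle = int(round(len(t) / n_cyc))
    works = []
    for k in range(n_cyc):
        lo = k * per_cycle
        hi = min((k + 1) * per_cycle, len(t))
        idx = list(range(lo, hi))
        # close the loop: next cycle's first sample, or wrap periodically
        idx.append(hi if hi < len(t) else lo)
        F = trace.force_n[idx]
        L = trace.length_mm[idx] * 1e-3  # m
        works.append(-np.trapezoid(F, L))  # muscle work positive during shortening
    if discard_first and n_cyc > 1:
        works = works[1:]
    net_work = float(np.mean(works))
    power = net_work * trace.cycle_freq / (mass_g * 1e-3)
    return WorkLoopResult(net_work_j=net_work, net_power_w_per_kg=power,
                          cycle_freq=trace.cycle_freq,
                          n_cycles_used=len(works))


# ----------------------------------------------------------------------
# Preparation decline and fatigue
# ----------------------------------------------------------------------

def decline_correction(trial_values: Sequence[tuple],
                       reference_values: Sequence[tuple]) -> list:
    """Correct trial values for linear preparation decline.

    ``reference_values`` are (time, value) monitoring contractions; the
    fractional decline at any trial time is interpolated linearly
    between them (relative to the first reference) and each trial value
    is divided by it.  ``trial_values`` are (time, value) pairs.
    """
    refs = sorted(reference_values)
    if len(refs) < 2:
        raise MechanicsError("need at least two bracketing references")
    rt = np.array([r[0] for r in refs], dtype=float)
    rv = np.array([r[1] for r in refs], dtype=float)
    if np.any(rv <= 0):
        raise MechanicsError("reference values must be positive")
    frac = rv / rv[0]
    out = []
    for t, v in trial_values:
        g = np.interp(t, rt, frac)
        out.append((t, v / g))
    return out


def fatigue_index(trace: ForceTrace, n_avg: int = 5,
                  refractory_ms: float = 5.0) -> float:
    """Fatigue index: end-stimulation twitch tension as % of peak tension.

    Twitch peaks are local maxima exceeding 5× the baseline noise SD,
    with a refractory window between peaks; the index is
    100 × mean(last ``n_avg`` peaks) / mean(``n_avg`` peaks around the
    maximum).
    """
    t, f = trace.time, trace.force
    fs = trace.sampling_rate
    onset = trace.stimulus_onsets[0] if trace.stimulus_onsets else t[0]
    pre = t < onset
    baseline = f[pre].mean() if pre.any() else np.percentile(f, 5)
    noise_sd = f[pre].std() if pre.any() and f[pre].std() > 0 else 0.0
    amp = f.max() - baseline
    height = baseline + max(5.0 * noise_sd, 0.05 * amp)
    distance = max(int(round(refractory_ms * 1e-3 * fs)), 1)
    peaks, _ = find_peaks(f, height=height, distance=distance,
                          prominence=0.25 * amp)
    if len(peaks) < 2 * n_avg:
        raise MechanicsError(f"found only {len(peaks)} twitches; "
                             f"need at least {2 * n_avg}")
    heights = f[peaks] - baseline
    i_max = int(np.argmax(heights))
    lo = max(0, min(i_max - n_avg // 2, len(heights) - n_avg))
    peak_mean = heights[lo: lo + n_avg].mean()
    end_mean = heights[-n_avg:].mean()
    return float(100.0 * end_mean / peak_mean)
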