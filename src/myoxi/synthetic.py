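"""Seeded synthetic muscle sections, contraction traces and helix profiles.

The generators emulate the statistical structure of the study inputs so
that every downstream analysis stage (morphometry, PO₂ modelling,
contractile mechanics, haemodynamics, disarray) can be exercised and
validated without any imaging data:

* ``generate_section`` builds a fibre tessellation (Poisson seeds +
  Lloyd relaxation) over a square ROI, scales fibres to per-type mean
  cross-sectional-area targets, and places capillaries at fibre-boundary
  junctions until a target capillary-to-fibre ratio is met.
* ``generate_twitch`` produces a difference-of-exponentials twitch whose
  time-to-peak and half-relaxation time are analytically controlled.
* ``generate_isotonic_transients`` produces after-loaded shortening
  transients whose post-release slopes follow a Hill force–velocity
  relation.
* ``generate_workloop`` produces sinusoidal length cycles with a
  first-order activation force model gated by a stimulation window.
* ``generate_flow_recording`` produces an exponential-rise hyperaemic
  flow response at constant arterial pressure.
* ``generate_helix_profile`` produces 5th-order polynomial helix-angle
  profiles with Gaussian noise.

All generators take explicit integer seeds and never touch global
random state; the same seed and profile give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import brentq, root
from shapely import affinity, voronoi_polygons
from shapely.geometry import MultiPoint, Point, Polygon, box

from .section import FIBRE_TYPES, Fibre, MuscleSection
from .traces import (FlowRecording, ForceTrace, HelixProfile, LengthTrace,
                     WorkLoopTrace)


class ProfileError(ValueError):
    pass


class SizingError(ValueError):
    """Requested fibre areas cannot fit inside the ROI."""


# ----------------------------------------------------------------------
# Profiles
# ----------------------------------------------------------------------

@dataclass
class SectionProfile:
    """Targets for one synthetic muscle section."""

    group_label: str
    muscle: str  # "soleus" | "diaphragm"
    n_fibres: int
    type_fractions: dict  # fibre type -> fraction, sums to 1
    mean_fcsa: dict       # fibre type -> µm²
    fcsa_cv: float        # coefficient of variation of fibre areas
    target_cf_ratio: float
    roi_side: float       # µm
    seed: int

    def validate(self) -> None:
        if self.muscle not in ("soleus", "diaphragm"):
            raise ProfileError(f"unknown muscle {self.muscle!r}")
        if self.n_fibres < 1:
            raise ProfileError("n_fibres must be >= 1")
        total = sum(self.type_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ProfileError(f"type fractions sum to {total}, not 1")
        for t in self.type_fractions:
            if t not in FIBRE_TYPES:
                raise ProfileError(f"unknown fibre type {t!r}")
        for t, a in self.mean_fcsa.items():
            if a <= 0:
                raise ProfileError(f"mean FCSA for type {t} must be positive")
        if self.target_cf_ratio < 0:
            raise ProfileError("target_cf_ratio must be >= 0")
        if self.fcsa_cv < 0:
            raise ProfileError("fcsa_cv must be >= 0")
        if self.roi_side <= 0:
            raise ProfileError("roi_side must be positive")


@dataclass
class MechanicsProfile:
    """Contractile parameters for one synthetic preparation.

    ``p0_stress`` is the maximal tetanic stress (N/cm²), ``vmax`` the
    unloaded shortening velocity (L0/s), ``curvature`` the Hill a/P0
    analogue (smaller = more curved force–velocity relation), ``ttp``
    and ``hrt`` the twitch time-to-peak and half-relaxation time (ms).
    """

    p0_stress: float          # N/cm²
    vmax: float               # L0/s
    curvature: float          # dimensionless a/P0
    ttp: float                # ms
    hrt: float                # ms
    l0: float                 # cm
    mass: float               # g
    sampling_rate: float = 10_000.0  # Hz
    noise_sd: float = 0.0     # fraction of peak
    twitch_tetanus_ratio: float = 0.16
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ProfileError("sampling_rate must be positive")
        if self.vmax <= 0:
            raise ProfileError("vmax must be positive")
        if self.curvature <= 0:
            raise ProfileError("curvature must be positive")
        for name in ("p0_stress", "ttp", "hrt", "l0", "mass"):
            if getattr(self, name) <= 0:
                raise ProfileError(f"{name} must be positive")

    @property
    def csa_cm2(self) -> float:
        return self.mass / (self.l0 * 1.06)

    @property
    def tetanic_force_n(self) -> float:
        return self.p0_stress * self.csa_cm2


@dataclass
class FlowProfile:
    """Synthetic femoral-flow recording parameters."""

    resting_flow: float       # ml/min
    plateau_flow: float       # ml/min
    map_pressure: float       # mmHg
    rise_tau: float           # s
    stim_window: tuple        # (start_s, end_s)
    muscle_mass: float        # g (EDL wet mass)
    noise_sd: float = 0.0     # ml/min
    seed: int = 0

    def validate(self) -> None:
        if self.resting_flow < 0:
            raise ProfileError("resting_flow must be >= 0")
        t0, t1 = self.stim_window
        if not t0 < t1:
            raise ProfileError("stim_window start must precede end")
        if self.map_pressure <= 0:
            raise ProfileError("map_pressure must be positive")


# ----------------------------------------------------------------------
# Section generation
# ----------------------------------------------------------------------

def _round_pt(x: float, y: float, ndigits: int = 6) -> tuple:
    return (round(x, ndigits), round(y, ndigits))


def _lloyd_cells(roi: Polygon, seeds: np.ndarray, n_iter: int = 5) -> list:
    """Lloyd-relaxed Voronoi tessellation of `roi` from initial seeds."""
    minx, miny, maxx, maxy = roi.bounds
    envelope = box(minx - (maxx - minx), miny - (maxy - miny),
                   maxx + (maxx - minx), maxy + (maxy - miny))
    pts = seeds.copy()
    cells = None
    for _ in range(n_iter + 1):
        if len(pts) == 1:
            cells = [roi]
            break
        vor = voronoi_polygons(MultiPoint(pts), extend_to=envelope, ordered=True)
        cells = [g.intersection(roi) for g in vor.geoms]
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    return cells


def _type_counts(n: int, profile: SectionProfile) -> dict:
    """Per-type fibre counts matching the fractions (largest remainder)."""
    types = [t for t in FIBRE_TYPES if profile.type_fractions.get(t, 0) > 0]
    raw = {t: profile.type_fractions[t] * n for t in types}
    counts = {t: int(np.floor(raw[t])) for t in types}
    rem = n - sum(counts.values())
    for t in sorted(types, key=lambda t: raw[t] - np.floor(raw[t]),
                    reverse=True)[:rem]:
        counts[t] += 1
    return counts


def generate_section(profile: SectionProfile, scale_to_fcsa: bool = True,
                     lloyd_iters: int = 5) -> MuscleSection:
    """Generate a synthetic muscle section meeting the profile targets.

    With ``scale_to_fcsa=True`` each fibre polygon is shrunk toward its
    centroid so the realised per-type mean cross-sectional area matches
    ``profile.mean_fcsa`` (leaving interstitial space, as in real
    sections).  With ``scale_to_fcsa=False`` the raw Lloyd cells are
    kept: the fibres tile the ROI gap-free, which the conservation
    properties of the morphometry module rely on.

    Raises :class:`SizingError` when the requested areas cannot fit.
    """
    profile.validate()
    roi = box(0.0, 0.0, profile.roi_side, profile.roi_side)
    overall_target = sum(profile.type_fractions.get(t, 0.0) * profile.mean_fcsa.get(t, 0.0)
                         for t in profile.type_fractions)
    if scale_to_fcsa and overall_target * profile.n_fibres > roi.area * (1 + 1e-12):
        raise SizingError(
            f"target fibre area {overall_target * profile.n_fibres:.0f} µm² exceeds "
            f"ROI area {roi.area:.0f} µm²; enlarge roi_side or shrink mean_fcsa")

    rng = np.random.default_rng(profile.seed)
    seeds = rng.uniform(0, profile.roi_side, size=(profile.n_fibres, 2))
    cells = _lloyd_cells(roi, seeds, lloyd_iters)
    counts = _type_counts(len(cells), profile)

    # draw per-fibre target areas (lognormal around the per-type mean,
    # renormalised so each type's mean is exact), then match the sorted
    # targets to the sorted cell areas — the largest requested fibre gets
    # the largest available cell, which minimises shrink-only clipping
    sigma = np.sqrt(np.log(1 + profile.fcsa_cv ** 2))
    draw_t, draw_a = [], []
    for t in sorted(counts):
        a = profile.mean_fcsa[t] * np.exp(rng.normal(0.0, sigma, counts[t]))
        a *= profile.mean_fcsa[t] / a.mean()
        draw_t += [t] * counts[t]
        draw_a += list(a)
    draw_t = np.array(draw_t, dtype=object)
    draw_a = np.array(draw_a)
    cell_areas = np.array([c.area for c in cells])
    cell_order = np.argsort(-cell_areas)
    draw_order = np.argsort(-draw_a)
    labels = [None] * len(cells)
    target = np.empty(len(cells))
    for cell_i, draw_i in zip(cell_order, draw_order):
        labels[cell_i] = draw_t[draw_i]
        target[cell_i] = draw_a[draw_i]

    if scale_to_fcsa:
        target = np.minimum(target, cell_areas)  # shrink-only
        # one renormalisation pass per type among unclipped fibres
        for t in counts:
            idx = np.array([i for i, lab in enumerate(labels) if lab == t])
            clipped = target[idx] >= cell_areas[idx] - 1e-9
            deficit = profile.mean_fcsa[t] * len(idx) - target[idx].sum()
            if deficit > 0 and (~clipped).any():
                head = cell_areas[idx][~clipped] - target[idx][~clipped]
                boost = min(1.0, deficit / head.sum()) if head.sum() > 0 \
                    else 0.0
                target[idx[~clipped]] += boost * head
        fibres = []
        for c, t, a in zip(cells, labels, target):
            s = np.sqrt(min(1.0, a / c.area))
            fibres.append(Fibre(affinity.scale(c, xfact=s, yfact=s,
                                               origin=c.centroid), t))
    else:
        fibres = [Fibre(c, t) for c, t in zip(cells, labels)]

    capillaries = _place_capillaries(roi, cells, profile, rng)
    meta = {"group": profile.group_label, "muscle": profile.muscle,
            "seed": profile.seed}
    return MuscleSection(roi=roi, fibres=fibres, capillaries=capillaries, meta=meta)


def _place_capillaries(roi: Polygon, cells: list, profile: SectionProfile,
                       rng: np.random.Generator) -> np.ndarray:
    """Capillary points at tessellation junctions (3-way vertices first,
    then shared-edge midpoints), subsampled uniformly by the seeded rng."""
    n_cap = int(round(profile.target_cf_ratio * profile.n_fibres))
    if n_cap == 0:
        return np.empty((0, 2))

    vertex_count: dict = {}
    edge_mid_count: dict = {}
    boundary = roi.exterior
    for c in cells:
        coords = list(c.exterior.coords)[:-1]
        for i, (x, y) in enumerate(coords):
            vertex_count[_round_pt(x, y)] = vertex_count.get(_round_pt(x, y), 0) + 1
            x2, y2 = coords[(i + 1) % len(coords)]
            mid = _round_pt(0.5 * (x + x2), 0.5 * (y + y2))
            edge_mid_count[mid] = edge_mid_count.get(mid, 0) + 1

    junctions = [p for p, k in vertex_count.items()
                 if k >= 3 or (k >= 1 and boundary.distance(Point(p)) < 1e-6)]
    midpoints = [p for p, k in edge_mid_count.items()
                 if k >= 2 and p not in vertex_count]
    junctions.sort()
    midpoints.sort()

    chosen: list = []
    if n_cap <= len(junctions):
        idx = rng.choice(len(junctions), size=n_cap, replace=False)
        chosen = [junctions[i] for i in sorted(idx)]
    else:
        chosen = list(junctions)
        extra = n_cap - len(junctions)
        if extra > len(midpoints):
            raise SizingError(
                f"cannot place {n_cap} capillaries: only "
                f"{len(junctions) + len(midpoints)} boundary sites available")
        idx = rng.choice(len(midpoints), size=extra, replace=False)
        chosen += [midpoints[i] for i in sorted(idx)]
    return np.array(chosen, dtype=float)


# ----------------------------------------------------------------------
# Twitch
# ----------------------------------------------------------------------

def _biexp_peak_time(tau_r: float, tau_d: float) -> float:
    return np.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)


def _biexp_hrt(tau_r: float, tau_d: float) -> float:
    """Half-relaxation time of f(t)=exp(-t/tau_d)-exp(-t/tau_r)."""
    tp = _biexp_peak_time(tau_r, tau_d)
    fp = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)

    def g(dt):
        t = tp + dt
        return (np.exp(-t / tau_d) - np.exp(-t / tau_r)) - 0.5 * fp

    hi = tau_d
    while g(hi) > 0:
        hi *= 2
    return brentq(g, 1e-12, hi, xtol=1e-12)


def _solve_twitch_taus(ttp_s: float, hrt_s: float) -> tuple:
    """Invert (time-to-peak, half-relaxation) -> (tau_rise, tau_decay)."""
    def resid(logp):
        tau_r, tau_d = np.exp(logp)
        if tau_d <= tau_r:
            return [1e3, 1e3]
        return [_biexp_peak_time(tau_r, tau_d) - ttp_s,
                _biexp_hrt(tau_r, tau_d) - hrt_s]

    x0 = np.log([ttp_s / 3.0, max(hrt_s / np.log(2.0), ttp_s)])
    sol = root(resid, x0, method="hybr", tol=1e-12)
    if not sol.success:
        raise ProfileError(f"cannot realise ttp={ttp_s * 1e3:.2f} ms with "
                           f"hrt={hrt_s * 1e3:.2f} ms as a biexponential twitch")
    tau_r, tau_d = np.exp(sol.x)
    return tau_r, tau_d


def generate_twitch(profile: MechanicsProfile, amplitude_n: Optional[float] = None,
                    pre_s: float = 0.05) -> ForceTrace:
    """Difference-of-exponentials twitch with stimulus onset at t = 0.

    Peak amplitude defaults to ``twitch_tetanus_ratio`` times the
    profile's tetanic force.  A zero amplitude yields a flat trace.
    """
    profile.validate()
    if amplitude_n is None:
        amplitude_n = profile.twitch_tetanus_ratio * profile.tetanic_force_n
    dt = 1.0 / profile.sampling_rate
    ttp_s, hrt_s = profile.ttp * 1e-3, profile.hrt * 1e-3
    dur = max(8.0 * (ttp_s + hrt_s), 0.2)
    time = np.arange(-round(pre_s / dt), round(dur / dt) + 1) * dt
    force = np.zeros_like(time)
    if amplitude_n != 0.0:
        tau_r, tau_d = _solve_twitch_taus(ttp_s, hrt_s)
        tp = _biexp_peak_time(tau_r, tau_d)
        fp = np.exp(-tp / tau_d) - np.exp(-tp / tau_r)
        post = time >= 0
        force[post] = amplitude_n / fp * (np.exp(-time[post] / tau_d)
                                          - np.exp(-time[post] / tau_r))
    if profile.noise_sd > 0:
        rng = np.random.default_rng(profile.seed)
        force = force + rng.normal(0.0, profile.noise_sd * abs(amplitude_n),
                                   size=force.shape)
    return ForceTrace(time, force, "N", stimulus_onsets=[0.0],
                      sampling_rate=profile.sampling_rate)


def generate_tetanus(profile: MechanicsProfile, duration_s: float = 0.3,
                     tau_rise_s: float = 0.02, tau_fall_s: float = 0.04,
                     pre_s: float = 0.05) -> ForceTrace:
    """Fused tetanic contraction: first-order rise to P0, then decay."""
    profile.validate()
    dt = 1.0 / profile.sampling_rate
    f0 = profile.tetanic_force_n
    total = pre_s + duration_s + 8 * tau_fall_s
    time = np.arange(-round(pre_s / dt), round((total - pre_s) / dt) + 1) * dt
    force = np.zeros_like(time)
    on = (time >= 0) & (time <= duration_s)
    force[on] = f0 * (1 - np.exp(-time[on] / tau_rise_s))
    f_end = f0 * (1 - np.exp(-duration_s / tau_rise_s))
    after = time > duration_s
    force[after] = f_end * np.exp(-(time[after] - duration_s) / tau_fall_s)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(profile.seed + 1)
        force = force + rng.normal(0.0, profile.noise_sd * f0, size=force.shape)
    return ForceTrace(time, force, "N", stimulus_onsets=[0.0],
                      sampling_rate=profile.sampling_rate)


def generate_force_frequency(profile: MechanicsProfile,
                             freqs: Sequence[float] = (1, 15, 30, 50, 80, 120, 150),
                             f50: float = 40.0, hill_n: float = 2.5) -> dict:
    """Per-frequency traces whose peaks follow a sigmoid recruitment curve.

    Peak force rises from the twitch level to the tetanic level with a
    Hill sigmoid of half-maximal frequency ``f50``.
    """
    profile.validate()
    f_tw = profile.twitch_tetanus_ratio * profile.tetanic_force_n
    f_tet = profile.tetanic_force_n
    out = {}
    for fq in freqs:
        frac = fq ** hill_n / (fq ** hill_n + f50 ** hill_n)
        peak = f_tw + (f_tet - f_tw) * frac
        if fq <= 2:  # single twitch
            out[fq] = generate_twitch(profile, amplitude_n=peak)
        else:
            out[fq] = generate_tetanus(profile)
            out[fq].force *= peak / max(out[fq].force.max(), 1e-30)
    return out


# ----------------------------------------------------------------------
# Isotonic transients
# ----------------------------------------------------------------------

def hill_velocity(load_frac: float, vmax: float, curvature: float) -> float:
    """Hill force–velocity: V(F) = vmax·c·(1−f)/(f+c) with f = F/P0, c = a/P0."""
    return vmax * curvature * (1.0 - load_frac) / (load_frac + curvature)


def generate_isotonic_transients(profile: MechanicsProfile,
                                 loads: Sequence[float],
                                 release_time_s: float = 0.05,
                                 settle_ms: float = 8.0) -> list:
    """After-loaded shortening transients, one per load fraction of P0.

    Each trace holds length (mm) vs time: constant at L0 until the
    release, a short quadratic velocity ramp over ``settle_ms``, then a
    linear shortening whose slope is exactly the Hill velocity for that
    load.  Loads at or above P0 cannot shorten and raise ProfileError.
    """
    profile.validate()
    out = []
    dt = 1.0 / profile.sampling_rate
    l0_mm = profile.l0 * 10.0
    for load in loads:
        if not 0.0 < load < 1.0:
            raise ProfileError(f"load fraction {load} outside (0, 1): no shortening")
        v = hill_velocity(load, profile.vmax, profile.curvature)  # L0/s
        t_settle = settle_ms * 1e-3
        dur_short = min(0.25, 0.18 / max(v, 1e-9))
        total = release_time_s + t_settle + dur_short
        time = np.arange(0.0, total, dt)
        length = np.full_like(time, l0_mm)
        tr = time - release_time_s
        ramp = (tr > 0) & (tr <= t_settle)
        length[ramp] = l0_mm * (1.0 - v * tr[ramp] ** 2 / (2 * t_settle))
        lin = tr > t_settle
        l_at = 1.0 - v * t_settle / 2
        length[lin] = l0_mm * (l_at - v * (tr[lin] - t_settle))
        if profile.noise_sd > 0:
            rng = np.random.default_rng(profile.seed + int(load * 1e6))
            length = length + rng.normal(0.0, profile.noise_sd * l0_mm * 0.01,
                                         size=length.shape)
        out.append((load, LengthTrace(time, length, l0_cm=profile.l0,
                                      release_time=release_time_s)))
    return out


# ----------------------------------------------------------------------
# Work loops
# ----------------------------------------------------------------------

def generate_workloop(profile: MechanicsProfile, cycle_freq: float,
                      strain_amp: float = 0.065, phase_ms: float = -20.0,
                      stim_dur_ms: float = 210.0, n_cycles: int = 4,
                      force_model: str | Callable = "activation",
                      tau_act_ms: float = 25.0, tau_deact_ms: float = 35.0
                      ) -> WorkLoopTrace:
    """Sinusoidal length cycles with phasic stimulation.

    Length: L(t) = L0·(1 + ε·sin(2π·f·t)), peak length at T/4 of each
    cycle.  Stimulation starts ``phase_ms`` relative to peak length and
    lasts ``stim_dur_ms``.  Force models:

    * ``"activation"`` — first-order activation gated by the stimulus
      window, times a Hill force–velocity factor (default; produces an
      intermediate optimum cycle frequency for net power);
    * ``"elastic"`` — F = k·(L − L0), a conservative law netting zero
      work per cycle;
    * ``"shortening_step"`` — constant tetanic force during the
      shortening half-cycle only (net work = F0·2εL0 exactly);
    * a callable ``f(t, L_mm, dLdt_mm_s) -> force_N``.
    """
    profile.validate()
    if cycle_freq <= 0 or strain_amp <= 0:
        raise ProfileError("cycle_freq and strain_amp must be positive")
    period = 1.0 / cycle_freq
    if stim_dur_ms * 1e-3 >= period:
        raise ProfileError(
            f"stimulation duration {stim_dur_ms} ms covers an entire "
            f"{period * 1e3:.0f} ms cycle")
    fs = 1000.0 * cycle_freq  # per protocol: sampling at 1000 × cycle frequency
    dt = 1.0 / fs
    n = int(round(n_cycles * period / dt))
    time = np.arange(n) * dt
    l0_mm = profile.l0 * 10.0
    length = l0_mm * (1.0 + strain_amp * np.sin(2 * np.pi * cycle_freq * time))
    dldt = l0_mm * strain_amp * 2 * np.pi * cycle_freq \
        * np.cos(2 * np.pi * cycle_freq * time)

    stim_windows = []
    stim = np.zeros(n, dtype=bool)
    for k in range(n_cycles):
        t_on = k * period + period / 4.0 + phase_ms * 1e-3
        t_off = t_on + stim_dur_ms * 1e-3
        stim |= (time >= t_on) & (time < t_off)
        stim_windows.append((t_on, t_off))

    f0 = profile.tetanic_force_n
    if force_model == "elastic":
        k_el = f0 / (strain_amp * l0_mm)
        force = k_el * (length - l0_mm)
    elif force_model == "shortening_step":
        force = np.where(dldt < 0, f0, 0.0)
    elif callable(force_model):
        force = np.array([force_model(t, L, dL) for t, L, dL in
                          zip(time, length, dldt)])
    elif force_model == "activation":
        a = np.zeros(n)
        ta, td = tau_act_ms * 1e-3, tau_deact_ms * 1e-3
        for i in range(1, n):
            tau = ta if stim[i] else td
            u = 1.0 if stim[i] else 0.0
            a[i] = a[i - 1] + dt * (u - a[i - 1]) / tau
        v_norm = -dldt / (l0_mm * profile.vmax)  # shortening positive, in Vmax units
        fv = np.where(v_norm >= 0,
                      np.clip((1 - np.clip(v_norm, 0, 0.999))
                              / (1 + np.clip(v_norm, 0, 0.999) / profile.curvature),
                              0, None),
                      1.2)
        force = f0 * a * fv
    else:
        raise ProfileError(f"unknown force model {force_model!r}")

    if profile.noise_sd > 0:
        rng = np.random.default_rng(profile.seed + int(cycle_freq * 1000))
        force = force + rng.normal(0.0, profile.noise_sd * f0, size=n)
    return WorkLoopTrace(time, force, length, cycle_freq, profile.l0,
                         stim_windows)


# ----------------------------------------------------------------------
# Flow recordings
# ----------------------------------------------------------------------

def generate_flow_recording(profile: FlowProfile, duration_s: Optional[float] = None,
                            sampling_rate: float = 100.0) -> FlowRecording:
    """Exponential rise from resting to plateau flow during stimulation.

    ``rise_tau <= 0`` gives an ideal step.  Pressure is constant at the
    profile's mean arterial pressure plus optional noise.
    """
    profile.validate()
    t0, t1 = profile.stim_window
    if duration_s is None:
        duration_s = t1 + 30.0
    time = np.arange(0.0, duration_s, 1.0 / sampling_rate)
    flow = np.full_like(time, profile.resting_flow)
    delta = profile.plateau_flow - profile.resting_flow
    during = (time >= t0) & (time <= t1)
    after = time > t1
    if profile.rise_tau > 0:
        flow[during] += delta * (1 - np.exp(-(time[during] - t0) / profile.rise_tau))
        level_end = delta * (1 - np.exp(-(t1 - t0) / profile.rise_tau))
        flow[after] += level_end * np.exp(-(time[after] - t1) / profile.rise_tau)
    else:
        flow[during] += delta
    pressure = np.full_like(time, profile.map_pressure)
    if profile.noise_sd > 0:
        rng = np.random.default_rng(profile.seed)
        flow = flow + rng.normal(0.0, profile.noise_sd, size=flow.shape)
        pressure = pressure + rng.normal(0.0, profile.noise_sd, size=pressure.shape)
    return FlowRecording(time, flow, pressure, (t0, t1), profile.muscle_mass)


# ----------------------------------------------------------------------
# Helix-angle profiles
# ----------------------------------------------------------------------

def generate_helix_profile(coeffs: Sequence[float], n_points: int,
                           noise_sd: float, seed: int) -> HelixProfile:
    """Helix angles from a 5th-order polynomial of transmural distance.

    ``coeffs`` are the six polynomial coefficients in increasing order
    (numpy.polynomial convention); noise is Gaussian in degrees.
    """
    if len(coeffs) != 6:
        raise ProfileError("exactly 6 polynomial coefficients required")
    if n_points < 7:
        raise ProfileError("n_points must be >= 7 (5th-order fit is "
                           "underdetermined below 7 points)")
    x = np.linspace(0.0, 1.0, n_points)
    y = np.polynomial.polynomial.polyval(x, np.asarray(coeffs, dtype=float))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=n_points)
    return HelixProfile(x, y)


# ----------------------------------------------------------------------
# Study-condition profiles (group means from the source study)
# ----------------------------------------------------------------------

def study_section_profiles(seed: int = 0) -> dict:
    """Per-group section profiles matching the study's printed targets.

    Soleus regions contained ~155 fibres, diaphragm regions ~70.  ROI
    sides give ~35% interstitial headroom over the summed fibre-area
    targets.  Fractions are normalised to sum exactly to 1.
    """
    def _norm(d):
        s = sum(d.values())
        return {k: v / s for k, v in d.items()}

    def _side(n, fracs, fcsa, headroom=1.35):
        mean = sum(fracs[t] * fcsa[t] for t in fracs)
        return float(np.sqrt(headroom * n * mean))

    specs = {
        "control_soleus": dict(
            muscle="soleus", n_fibres=155,
            type_fractions=_norm({"I": 95.49, "IIa": 4.51}),
            mean_fcsa={"I": 3921.88, "IIa": 3351.43},
            target_cf_ratio=2.37),
        "hfpef_soleus": dict(
            muscle="soleus", n_fibres=155,
            type_fractions=_norm({"I": 87.84, "IIa": 12.16}),
            mean_fcsa={"I": 3009.75, "IIa": 2575.69},
            target_cf_ratio=1.96),
        "control_diaphragm": dict(
            muscle="diaphragm", n_fibres=70,
            type_fractions=_norm({"I": 32.93, "IIa": 34.41, "IIbx": 32.63}),
            mean_fcsa={"I": 1130.67, "IIa": 1352.19, "IIbx": 3109.90},
            target_cf_ratio=1.96),
        "hfpef_diaphragm": dict(
            muscle="diaphragm", n_fibres=70,
            type_fractions=_norm({"I": 38.38, "IIa": 30.65, "IIbx": 31.00}),
            mean_fcsa={"I": 1647.83, "IIa": 1709.33, "IIbx": 2418.50},
            target_cf_ratio=2.26),
    }
    out = {}
    for name, kw in specs.items():
        out[name] = SectionProfile(
            group_label=name.split("_")[0], roi_side=_side(
                kw["n_fibres"], kw["type_fractions"], kw["mean_fcsa"]),
            fcsa_cv=0.25, seed=seed, **kw)
    return out


def study_mechanics_profiles(seed: int = 0) -> dict:
    """Soleus / diaphragm contractile profiles from the printed group means."""
    return {
        "control_soleus": MechanicsProfile(
            p0_stress=20.72, vmax=1.16, curvature=0.15, ttp=23.10, hrt=41.68,
            l0=2.0, mass=0.20654, twitch_tetanus_ratio=0.16, seed=seed),
        "hfpef_soleus": MechanicsProfile(
            p0_stress=19.98, vmax=0.88, curvature=0.10, ttp=22.18, hrt=46.08,
            l0=2.0, mass=0.15250, twitch_tetanus_ratio=0.14, seed=seed),
        "control_diaphragm": MechanicsProfile(
            p0_stress=23.09, vmax=9.10, curvature=0.35, ttp=16.48, hrt=19.30,
            l0=1.5, mass=0.10, twitch_tetanus_ratio=0.31, seed=seed),
        "hfpef_diaphragm": MechanicsProfile(
            p0_stress=27.46, vmax=8.32, curvature=0.35, ttp=18.50, hrt=21.45,
            l0=1.5, mass=0.10, twitch_tetanus_ratio=0.32, seed=seed),
    }


def study_flow_profiles(seed: int = 0) -> dict:
    """Flow profiles: resting flows and muscle-specific hyperaemic deltas
    follow the printed group means; plateau = resting + delta·mass."""
    return {
        "control": FlowProfile(
            resting_flow=1.71, plateau_flow=1.71 + 2.59 * 0.26288,
            map_pressure=154.26, rise_tau=5.0, stim_window=(60.0, 240.0),
            muscle_mass=0.26288, seed=seed),
        "hfpef": FlowProfile(
            resting_flow=2.66, plateau_flow=2.66 + 0.69 * 0.19473,
            map_pressure=172.03, rise_tau=5.0, stim_window=(60.0, 240.0),
            muscle_mass=0.19473, seed=seed),
    }
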