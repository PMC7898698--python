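"""Sampled physiological time-series containers with CSV round trips.

All traces carry a `time` vector in seconds.  Force traces are
unit-tagged ("N" or "g"); 1 g-force = 9.80665e-3 N.  CSV layouts follow
the convention `time_s,<signal>` with one row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

G_TO_N = 9.80665e-3  # newtons per gram-force


class TraceError(ValueError):
    pass


def _check_time(time: np.ndarray) -> None:
    if time.ndim != 1 or len(time) < 2:
        raise TraceError("time vector must be 1-D with at least 2 samples")
    if np.any(np.diff(time) <= 0):
        raise TraceError("time must be strictly increasing")


@dataclass
class ForceTrace:
    """Force vs time with stimulus-onset markers.

    `unit` is "N" or "g"; use :meth:`in_newtons` before any computation
    that mixes units.
    """

    time: np.ndarray
    force: np.ndarray
    unit: str = "N"
    stimulus_onsets: list = field(default_factory=list)
    sampling_rate: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        _check_time(self.time)
        if self.force.shape != self.time.shape:
            raise TraceError("force and time must have equal length")
        if self.unit not in ("N", "g"):
            raise TraceError(f"unknown force unit {self.unit!r}")
        if self.sampling_rate is None:
            self.sampling_rate = 1.0 / float(np.median(np.diff(self.time)))

    def in_newtons(self) -> "ForceTrace":
        if self.unit == "N":
            return self
        return ForceTrace(self.time, self.force * G_TO_N, "N",
                          list(self.stimulus_onsets), self.sampling_rate)

    def to_csv(self, path) -> None:
        col = "force_n" if self.unit == "N" else "force_g"
        pd.DataFrame({"time_s": self.time, col: self.force}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stimulus_onsets=()) -> "ForceTrace":
        df = pd.read_csv(path)
        if "force_n" in df.columns:
            unit, col = "N", "force_n"
        elif "force_g" in df.columns:
            unit, col = "g", "force_g"
        else:
            raise TraceError("CSV must have a force_n or force_g column")
        return cls(df["time_s"].to_numpy(), df[col].to_numpy(), unit,
                   list(stimulus_onsets))


@dataclass
class LengthTrace:
    """Muscle length vs time (mm), with optional optimal length l0 (cm)."""

    time: np.ndarray
    length_mm: np.ndarray
    l0_cm: Optional[float] = None
    release_time: Optional[float] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        _check_time(self.time)
        if self.length_mm.shape != self.time.shape:
            raise TraceError("length and time must have equal length")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "length_mm": self.length_mm}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, l0_cm=None, release_time=None) -> "LengthTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["length_mm"].to_numpy(),
                   l0_cm, release_time)


@dataclass
class WorkLoopTrace:
    """Simultaneous force (N) and length (mm) during cyclical contractions."""

    time: np.ndarray
    force_n: np.ndarray
    length_mm: np.ndarray
    cycle_freq: float
    l0_cm: float
    stim_windows: list = field(default_factory=list)  # (start_s, end_s) per cycle

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force_n = np.asarray(self.force_n, dtype=float)
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        _check_time(self.time)
        if not (self.force_n.shape == self.length_mm.shape == self.time.shape):
            raise TraceError("force, length and time must have equal length")
        if self.cycle_freq <= 0:
            raise TraceError("cycle_freq must be positive")

    @property
    def n_cycles(self) -> float:
        return (self.time[-1] - self.time[0] + np.median(np.diff(self.time))) \
            * self.cycle_freq

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "force_n": self.force_n,
                      "length_mm": self.length_mm}).to_csv(path, index=False)


@dataclass
class FlowRecording:
    """Femoral-artery flow (ml/min) and arterial pressure (mmHg) vs time."""

    time: np.ndarray
    flow: np.ndarray
    pressure: np.ndarray
    stim_window: tuple
    muscle_mass: Optional[float] = None  # g, EDL wet mass

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        _check_time(self.time)
        t0, t1 = self.stim_window
        if not (t0 < t1):
            raise TraceError("stim_window start must precede end")
        if t0 < self.time[0] or t1 > self.time[-1]:
            raise TraceError("stim_window must lie within the recording")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "flow_ml_min": self.flow,
                      "pressure_mmHg": self.pressure}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, stim_window, muscle_mass=None) -> "FlowRecording":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["flow_ml_min"].to_numpy(),
                   df["pressure_mmHg"].to_numpy(), tuple(stim_window), muscle_mass)


@dataclass
class HelixProfile:
    """Myocyte helix angle (degrees) vs fractional transmural distance.

    Distance runs 0 (endocardium) to 1 (epicardium).
    """

    frac_distance: np.ndarray
    helix_deg: np.ndarray

    def __post_init__(self) -> None:
        self.frac_distance = np.asarray(self.frac_distance, dtype=float)
        self.helix_deg = np.asarray(self.helix_deg, dtype=float)
        if len(self.frac_distance) < 7:
            raise TraceError("helix profile needs at least 7 points")
        if self.frac_distance.min() < 0 or self.frac_distance.max() > 1:
            raise TraceError("fractional distances must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame({"frac_distance": self.frac_distance,
                      "helix_deg": self.helix_deg}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "HelixProfile":
        df = pd.read_csv(path)
        return cls(df["frac_distance"].to_numpy(), df["helix_deg"].to_numpy())
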