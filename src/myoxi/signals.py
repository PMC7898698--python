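"""Haemodynamic metrics from flow/pressure recordings and the cardiac
disarray index from helix-angle profiles.

Functional hyperaemia is the rise in arterial blood flow from rest to
muscle stimulation; vascular conductance normalises flow by arterial
pressure.  Myocyte disarray is quantified as the R² of a 5th-order
polynomial fit of helix angle against fractional transmural distance —
well-organised myocardium follows a smooth transmural rotation, so a
low R² indicates disarray.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .traces import FlowRecording, HelixProfile


class SignalError(ValueError):
    pass


@dataclass(frozen=True)
class HyperaemiaSummary:
    resting_flow: float            # ml/min
    end_stim_flow: float           # ml/min
    delta_flow: float              # ml/min
    delta_flow_specific: Optional[float]  # ml·min⁻¹·g⁻¹
    resting_cond: float            # ml·min⁻¹·mmHg⁻¹
    end_cond: float                # ml·min⁻¹·mmHg⁻¹
    scope: float                   # end_cond / resting_cond


def hyperaemia_metrics(rec: FlowRecording, rest_window_s: float = 30.0,
                       end_window_s: float = 30.0) -> HyperaemiaSummary:
    """Resting and end-stimulation flow, conductance and hyperaemic scope.

    Resting flow is the mean over ``rest_window_s`` immediately before
    stimulation onset; end-stimulation flow the mean over the final
    ``end_window_s`` of the stimulation period.  Conductance divides
    each window's mean flow by its mean arterial pressure; scope is the
    end/rest conductance ratio.  The specific flow delta divides by the
    muscle wet mass when the recording carries one.
    """
    t0, t1 = rec.stim_window
    if rest_window_s <= 0 or end_window_s <= 0:
        raise SignalError("window lengths must be positive")
    if t0 - rest_window_s < rec.time[0] - 1e-9:
        raise SignalError("rest window extends before the recording start")
    if end_window_s > (t1 - t0) + 1e-9:
        raise SignalError("end-stimulation window overlaps stimulation onset")
    rest = (rec.time >= t0 - rest_window_s) & (rec.time < t0)
    end = (rec.time >= t1 - end_window_s) & (rec.time <= t1)
    if not rest.any() or not end.any():
        raise SignalError("analysis windows contain no samples")
    q_rest = float(rec.flow[rest].mean())
    q_end = float(rec.flow[end].mean())
    p_rest = float(rec.pressure[rest].mean())
    p_end = float(rec.pressure[end].mean())
    if p_rest <= 0 or p_end <= 0:
        raise SignalError("mean arterial pressure must be positive")
    delta = q_end - q_rest
    g_rest, g_end = q_rest / p_rest, q_end / p_end
    return HyperaemiaSummary(
        resting_flow=q_rest, end_stim_flow=q_end, delta_flow=delta,
        delta_flow_specific=(delta / rec.muscle_mass
                             if rec.muscle_mass else None),
        resting_cond=g_rest, end_cond=g_end,
        scope=g_end / g_rest if g_rest != 0 else float("inf"))


@dataclass(frozen=True)
class DisarrayFit:
    """5th-order polynomial fit of helix angle vs transmural distance."""

    r_squared: float
    coeffs: np.ndarray             # increasing powers

    def predict(self, x) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(x, dtype=float),
                                                self.coeffs)

    def summary(self) -> str:
        c = ", ".join(f"{v:.4g}" for v in self.coeffs)
        return (f"Helix-angle polynomial fit (order 5)\n"
                f"  coefficients (increasing powers): {c}\n"
                f"  R² (organisation index) = {self.r_squared:.6f}")


def fit_disarray(profile: HelixProfile) -> DisarrayFit:
    """Ordinary least-squares 5th-order polynomial fit with its R²."""
    x, y = profile.frac_distance, profile.helix_deg
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        raise SignalError("all helix angles identical: R² is undefined")
    coeffs = np.polynomial.polynomial.polyfit(x, y, 5)
    resid = y - np.polynomial.polynomial.polyval(x, coeffs)
    ssr = float(np.sum(resid ** 2))
    return DisarrayFit(r_squared=1.0 - ssr / sst, coeffs=coeffs)


def disarray_index(profile: HelixProfile) -> float:
    """R² of the 5th-order polynomial fit (1 = perfectly organised)."""
    return fit_disarray(profile).r_squared
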