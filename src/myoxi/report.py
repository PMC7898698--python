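"""Cohort-level orchestration and group-comparison arithmetic.

``run_pipeline`` drives the whole chain on synthetic cohorts — section
generation, morphometry, PO₂ modelling, contractile mechanics, flow and
disarray analysis — and ``group_compare`` reproduces the summary
arithmetic used to report group differences: means ± SD, signed percent
differences relative to the control group, ratios, and unpaired Welch
t-tests.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import mechanics, morphometry, signals, synthetic
from .oxygen import OxygenTransportModel, TransportParams, summarize_po2
from .synthetic import (FlowProfile, MechanicsProfile, SectionProfile,
                        study_flow_profiles, study_mechanics_profiles,
                        study_section_profiles)


class ReportError(ValueError):
    pass


# ----------------------------------------------------------------------
# Group summaries and comparison
# ----------------------------------------------------------------------

@dataclass
class GroupSummary:
    """Per-group metric summaries: name -> (mean, sd, n)."""

    group_label: str
    metrics: dict = field(default_factory=dict)

    @classmethod
    def from_samples(cls, group_label: str, samples: dict) -> "GroupSummary":
        out = {}
        for name, vals in samples.items():
            v = np.asarray(vals, dtype=float)
            out[name] = (float(v.mean()), float(v.std(ddof=1)) if len(v) > 1
                         else 0.0, len(v))
        return cls(group_label, out)

    def add(self, name: str, mean: float, sd: float = 0.0, n: int = 1) -> None:
        if n < 1 or sd < 0:
            raise ReportError("n must be >= 1 and sd >= 0")
        self.metrics[name] = (float(mean), float(sd), int(n))


def percent_difference(control_mean: float, other_mean: float) -> float:
    """Signed percent difference of ``other`` relative to ``control``."""
    return 100.0 * (other_mean - control_mean) / control_mean


def group_compare(a: GroupSummary, b: GroupSummary,
                  equal_var: bool = False) -> pd.DataFrame:
    """Compare group b against control group a, metric by metric.

    Returns a DataFrame with control/comparison means and SDs, the
    signed percent difference relative to the control, the ratio, and
    an unpaired two-tailed t-test (Welch by default; ``equal_var=True``
    for the pooled-variance Student form).  Stored values are full
    precision — rounding belongs to rendering only.
    """
    missing = set(a.metrics) ^ set(b.metrics)
    if missing:
        raise ReportError("metrics missing in one group: "
                          + ", ".join(sorted(missing)))
    rows = []
    for name in a.metrics:
        ma, sa, na = a.metrics[name]
        mb, sb, nb = b.metrics[name]
        if na >= 2 and nb >= 2:
            t, p = stats.ttest_ind_from_stats(ma, sa, na, mb, sb, nb,
                                              equal_var=equal_var)
        else:
            t, p = float("nan"), float("nan")
        rows.append({
            "metric": name,
            f"{a.group_label}_mean": ma, f"{a.group_label}_sd": sa,
            f"{b.group_label}_mean": mb, f"{b.group_label}_sd": sb,
            "percent_difference": percent_difference(ma, mb) if ma != 0
            else float("nan"),
            "ratio": mb / ma if ma != 0 else float("nan"),
            "t_statistic": float(t), "p_value": float(p),
        })
    return pd.DataFrame(rows).set_index("metric")


def render_report(comparison: pd.DataFrame, a_label: str, b_label: str) -> str:
    """Markdown rendering with the conventional precision: percent
    differences to the nearest integer, ratios to 2 decimals."""
    lines = [f"# Group comparison: {b_label} vs {a_label}", "",
             "| metric | " + a_label + " (mean ± SD) | " + b_label +
             " (mean ± SD) | % diff | ratio | p |",
             "|---|---|---|---|---|---|"]
    for name, r in comparison.iterrows():
        lines.append(
            f"| {name} | {r[a_label + '_mean']:.4g} ± {r[a_label + '_sd']:.3g} "
            f"| {r[b_label + '_mean']:.4g} ± {r[b_label + '_sd']:.3g} "
            f"| {r['percent_difference']:+.0f}% | {r['ratio']:.2f} "
            f"| {r['p_value']:.3g} |")
    return "\n".join(lines) + "\n"


# ----------------------------------------------------------------------
# Pipeline
# ----------------------------------------------------------------------

_ALLOWED_TOP = {"seed", "cohorts", "stages", "po2", "workloop", "fatigue"}
_ALLOWED_COHORT = {"name", "section_profile", "mechanics_profile",
                   "flow_profile", "helix", "n_replicates"}


def _profile_from(spec, registry, cls, seed):
    """Resolve a profile spec: a registry name or an inline field dict."""
    if isinstance(spec, str):
        prof = registry(seed)[spec]
        return prof
    if isinstance(spec, dict):
        names = {f.name for f in dc_fields(cls)}
        bad = set(spec) - names
        if bad:
            raise ReportError(f"unknown {cls.__name__} keys: {sorted(bad)}")
        return cls(**{**spec, "seed": seed})
    raise ReportError(f"profile spec must be a name or mapping, got {spec!r}")


def _log(msg: str) -> None:
    print(msg, file=sys.stderr)


def run_pipeline(config: dict, out_dir) -> Path:
    """Run the full analysis over the configured synthetic cohorts.

    The config maps cohort names to section/mechanics/flow profiles
    (registry names such as ``control_soleus`` or inline parameter
    mappings), plus optional stage blocks (``po2``, ``workloop``,
    ``fatigue``).  Replicates re-seed every generator deterministically
    from the top-level seed, so the report directory is byte-identical
    across runs.  Invalid config keys fail before any computation.
    """
    bad = set(config) - _ALLOWED_TOP
    if bad:
        raise ReportError(f"unknown config keys: {sorted(bad)}")
    cohorts = config.get("cohorts", [])
    for c in cohorts:
        extra = set(c) - _ALLOWED_COHORT
        if extra:
            raise ReportError(f"unknown cohort keys: {sorted(extra)}")
        if "name" not in c:
            raise ReportError("every cohort needs a name")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base_seed = int(config.get("seed", 0))
    po2_cfg = config.get("po2") or {}
    summaries = []

    for ci, cohort in enumerate(cohorts):
        name = cohort["name"]
        _log(f"[myoxi] cohort {name}")
        n_rep = int(cohort.get("n_replicates", 3))
        samples: dict = {}

        def put(metric, value):
            samples.setdefault(metric, []).append(value)

        for rep in range(n_rep):
            seed = base_seed + 1000 * ci + rep
            # --- morphometry ------------------------------------------
            if "section_profile" in cohort:
                prof = _profile_from(cohort["section_profile"],
                                     study_section_profiles, SectionProfile, seed)
                section = synthetic.generate_section(prof)
                frame = morphometry.CountingFrame.from_roi(section.roi)
                framed = morphometry.apply_counting_frame(section, frame)
                doms = morphometry.capillary_domains(framed)
                summ = morphometry.summarize_capillarity(framed, doms)
                put("cf_ratio", summ.cf_ratio)
                put("cd_mm2", summ.cd)
                put("cda_um2", summ.cda_mean)
                for t in summ.fcsa:
                    put(f"fcsa_{t}_um2", summ.fcsa[t][0])
                    put(f"lcfr_{t}", summ.lcfr[t])
                    put(f"lcd_{t}_mm2", summ.lcd[t])
                # --- PO₂ ---------------------------------------------
                if po2_cfg.get("enabled", False):
                    params = TransportParams(
                        grid_h=float(po2_cfg.get("grid_h", 2.0)))
                    model = OxygenTransportModel(section, params)
                    for demand in po2_cfg.get("demands", ["rest", "max"]):
                        ps = summarize_po2(model.solve(demand=demand))
                        put(f"po2_{demand}_all_mmhg", ps.mean_po2["all"])
                        put(f"hypoxic_fraction_{demand}", ps.hypoxic_fraction)
            # --- mechanics --------------------------------------------
            if "mechanics_profile" in cohort:
                mp = _profile_from(cohort["mechanics_profile"],
                                   study_mechanics_profiles, MechanicsProfile,
                                   seed)
                geom = mechanics.MuscleGeometry(mp.mass, mp.l0)
                tw = mechanics.twitch_metrics(synthetic.generate_twitch(mp))
                put("twitch_force_n", tw.peak)
                put("ttp_ms", tw.ttp_ms)
                put("hrt_ms", tw.hrt_ms)
                ff_traces = synthetic.generate_force_frequency(mp)
                curve, p0_n = mechanics.force_frequency(ff_traces)
                put("p0_specific_n_cm2", mechanics.specific_force(p0_n, geom))
                put("twitch_tetanus_ratio",
                    mechanics.twitch_tetanus_ratio(curve))
                loads = [0.8, 0.65, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
                trans = synthetic.generate_isotonic_transients(mp, loads)
                vels = [mechanics.shortening_velocity(tr) for _, tr in trans]
                fv = mechanics.ForceVelocityModel(
                    loads, vels, p0_force_n=mp.tetanic_force_n,
                    l0_cm=mp.l0, mass_g=mp.mass).fit()
                put("vmax_l0_s", fv.vmax)
                put("power_ratio", fv.power_ratio)
                if fv.wmax_w_per_kg is not None:
                    put("wmax_w_kg", fv.wmax_w_per_kg)
                wl_cfg = config.get("workloop") or {}
                if wl_cfg.get("enabled", False):
                    freq = float(wl_cfg.get("cycle_freq", 5.0))
                    wl = synthetic.generate_workloop(mp, cycle_freq=freq)
                    res = mechanics.workloop_power(wl, mp.mass)
                    put(f"workloop_power_{freq:g}hz_w_kg",
                        res.net_power_w_per_kg)
            # --- flow --------------------------------------------------
            if "flow_profile" in cohort:
                fp = _profile_from(cohort["flow_profile"], study_flow_profiles,
                                   FlowProfile, seed)
                rec = synthetic.generate_flow_recording(fp)
                hyp = signals.hyperaemia_metrics(rec)
                put("resting_flow_ml_min", hyp.resting_flow)
                put("delta_flow_ml_min", hyp.delta_flow)
                if hyp.delta_flow_specific is not None:
                    put("delta_flow_specific_ml_min_g", hyp.delta_flow_specific)
                put("hyperaemic_scope", hyp.scope)
            # --- disarray ----------------------------------------------
            if "helix" in cohort:
                h = cohort["helix"]
                profile = synthetic.generate_helix_profile(
                    h.get("coeffs", [-60, 240, -240, 120, -30, 30]),
                    int(h.get("n_points", 50)),
                    float(h.get("noise_sd", 5.0)), seed)
                put("disarray_r2", signals.disarray_index(profile))

        gs = GroupSummary.from_samples(name, samples)
        summaries.append(gs)
        df = pd.DataFrame(
            [(m, *v) for m, v in gs.metrics.items()],
            columns=["metric", "mean", "sd", "n"])
        df.to_csv(out / f"summary_{name}.csv", index=False)

    result = {"cohorts": [s.group_label for s in summaries]}
    if len(summaries) >= 2:
        comp = group_compare(summaries[0], summaries[1])
        comp.to_csv(out / "comparison.csv")
        (out / "comparison.md").write_text(
            render_report(comp, summaries[0].group_label,
                          summaries[1].group_label))
        result["n_metrics"] = int(len(comp))
    (out / "report.json").write_text(
        json.dumps(result, indent=2, sort_keys=True) + "\n")
    _log(f"[myoxi] report written to {out}")
    return out
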