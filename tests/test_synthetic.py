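"""Generator correctness: determinism, target fidelity, recoverability."""

import json

import numpy as np
import pytest

from myoxi import (FlowProfile, SectionProfile,
                   generate_flow_recording, generate_helix_profile,
                   generate_isotonic_transients, generate_section,
                   generate_twitch, generate_workloop,
                   study_section_profiles)
from myoxi import mechanics, morphometry, signals
from myoxi.synthetic import (ProfileError, SizingError, hill_velocity,
                             generate_force_frequency)


# ----------------------------------------------------------------------
# Sections
# ----------------------------------------------------------------------

class TestGenerateSection:
    def test_seed_determinism_bytes(self, small_profile):
        a = generate_section(small_profile).to_geojson()
        b = generate_section(small_profile).to_geojson()
        assert json.dumps(a, sort_keys=True) == json.dumps(b, sort_keys=True)

    def test_realised_counts_and_validity(self, small_profile):
        s = generate_section(small_profile)
        s.validate()
        assert s.n_fibres == small_profile.n_fibres
        n_cap_target = round(small_profile.target_cf_ratio
                             * small_profile.n_fibres)
        assert s.n_capillaries == n_cap_target

    def test_cf_ratio_by_direct_recount(self, small_profile):
        # the oracle is a plain count of point features / polygon features
        s = generate_section(small_profile)
        gj = s.to_geojson()
        n_fib = sum(1 for f in gj["features"]
                    if f["properties"].get("role") == "fibre")
        n_cap = sum(1 for f in gj["features"]
                    if f["properties"].get("role") == "capillary")
        realised = n_cap / n_fib
        assert abs(realised - small_profile.target_cf_ratio) \
            <= 0.05 * small_profile.target_cf_ratio

    @pytest.mark.parametrize("seed", range(5))
    def test_target_fidelity_study_profile(self, seed):
        # per-type mean FCSA, composition and C:F within 5% of the
        # requested targets for the control-soleus conditions
        prof = study_section_profiles(seed)["control_soleus"]
        s = generate_section(prof)
        _, comp = morphometry.fibre_metrics(s)
        for t, target in prof.mean_fcsa.items():
            realised = comp.loc[t, "mean_csa_um2"]
            assert abs(realised - target) <= 0.05 * target, (t, realised)
        frac_I = comp.loc["I", "numerical_pct"] / 100.0
        assert abs(frac_I - prof.type_fractions["I"]) <= 0.05
        cf = s.n_capillaries / s.n_fibres
        assert abs(cf - prof.target_cf_ratio) <= 0.05 * prof.target_cf_ratio

    def test_single_fibre_covers_roi(self):
        prof = SectionProfile(group_label="x", muscle="soleus", n_fibres=1,
                              type_fractions={"I": 1.0},
                              mean_fcsa={"I": 10000.0}, fcsa_cv=0.0,
                              target_cf_ratio=4.0, roi_side=100.0, seed=0)
        s = generate_section(prof, scale_to_fcsa=False)
        assert s.n_fibres == 1
        assert s.fibres[0].polygon.equals(s.roi)
        # capillaries sit on the single fibre's boundary
        from shapely.geometry import Point

        for x, y in s.capillaries:
            assert s.roi.exterior.distance(Point(x, y)) < 1e-6

    def test_infeasible_sizing_raises(self):
        prof = SectionProfile(group_label="x", muscle="soleus", n_fibres=100,
                              type_fractions={"I": 1.0},
                              mean_fcsa={"I": 5000.0}, fcsa_cv=0.1,
                              target_cf_ratio=1.0, roi_side=100.0, seed=0)
        with pytest.raises(SizingError):
            generate_section(prof)

    def test_invalid_fractions_rejected(self, small_profile):
        small_profile.type_fractions = {"I": 0.7, "IIa": 0.2}
        with pytest.raises(ProfileError):
            generate_section(small_profile)


# ----------------------------------------------------------------------
# Twitches
# ----------------------------------------------------------------------

class TestGenerateTwitch:
    def test_metrics_recovered_noiseless(self, soleus_mechanics):
        tr = generate_twitch(soleus_mechanics)
        m = mechanics.twitch_metrics(tr)
        assert m.ttp_ms == pytest.approx(soleus_mechanics.ttp, rel=0.01)
        assert m.hrt_ms == pytest.approx(soleus_mechanics.hrt, rel=0.01)

    def test_zero_amplitude_flat(self, soleus_mechanics):
        tr = generate_twitch(soleus_mechanics, amplitude_n=0.0)
        assert np.all(tr.force == 0.0)

    def test_noise_bias_small(self, soleus_mechanics):
        # Monte-Carlo: 2% noise must not bias TTP/HRT by more than 2%
        import dataclasses

        ttps, hrts = [], []
        for seed in range(100):
            prof = dataclasses.replace(soleus_mechanics, noise_sd=0.02,
                                       seed=seed)
            m = mechanics.twitch_metrics(generate_twitch(prof))
            ttps.append(m.ttp_ms)
            hrts.append(m.hrt_ms)
        assert abs(np.mean(ttps) - soleus_mechanics.ttp) \
            <= 0.02 * soleus_mechanics.ttp
        assert abs(np.mean(hrts) - soleus_mechanics.hrt) \
            <= 0.02 * soleus_mechanics.hrt


# ----------------------------------------------------------------------
# Isotonic transients
# ----------------------------------------------------------------------

class TestIsotonicTransients:
    def test_slope_equals_hill_velocity(self, soleus_mechanics):
        loads = [0.8, 0.5, 0.2, 0.05]
        for load, tr in generate_isotonic_transients(soleus_mechanics, loads):
            v = mechanics.shortening_velocity(tr)
            expected = hill_velocity(load, soleus_mechanics.vmax,
                                     soleus_mechanics.curvature)
            assert v == pytest.approx(expected, rel=1e-6)

    def test_low_load_limit_is_vmax(self, soleus_mechanics):
        v = hill_velocity(1e-12, soleus_mechanics.vmax,
                          soleus_mechanics.curvature)
        assert v == pytest.approx(soleus_mechanics.vmax, rel=1e-9)

    def test_high_curvature_limit_is_linear(self):
        # as a/P0 -> infinity the Hill relation degenerates to the line
        # V = Vmax (1 - F/P0); oracle is the closed-form limit
        vmax = 2.0
        for load in (0.8, 0.5, 0.3, 0.05):
            v = hill_velocity(load, vmax, 1e9)
            assert v == pytest.approx(vmax * (1 - load), rel=1e-6)

    def test_monotone_in_load(self, soleus_mechanics):
        loads = [0.8, 0.65, 0.5, 0.4, 0.3, 0.2, 0.1, 0.05]
        vels = [mechanics.shortening_velocity(tr)
                for _, tr in generate_isotonic_transients(soleus_mechanics,
                                                          loads)]
        assert np.all(np.diff(vels) > 0)  # lighter load, faster shortening

    def test_load_of_one_rejected(self, soleus_mechanics):
        with pytest.raises(ProfileError):
            generate_isotonic_transients(soleus_mechanics, [1.0])


# ----------------------------------------------------------------------
# Work loops
# ----------------------------------------------------------------------

class TestGenerateWorkloop:
    def test_elastic_force_nets_zero(self, soleus_mechanics):
        wl = generate_workloop(soleus_mechanics, cycle_freq=2.0,
                               force_model="elastic")
        res = mechanics.workloop_power(wl, soleus_mechanics.mass)
        scale = soleus_mechanics.tetanic_force_n * 0.13 \
            * soleus_mechanics.l0 * 1e-2
        assert abs(res.net_work_j) < 1e-4 * scale

    def test_shortening_step_work_integral(self, soleus_mechanics):
        # constant F0 during shortening only: net work = F0 * 2 eps L0
        eps = 0.065
        wl = generate_workloop(soleus_mechanics, cycle_freq=2.0,
                               strain_amp=eps,
                               force_model="shortening_step")
        res = mechanics.workloop_power(wl, soleus_mechanics.mass)
        expected = soleus_mechanics.tetanic_force_n * 2 * eps \
            * soleus_mechanics.l0 * 1e-2
        assert res.net_work_j == pytest.approx(expected, rel=1e-4)

    def test_fatigue_protocol_shape(self, soleus_mechanics):
        # 2 Hz cycles, 0.065 L0 strain, -20 ms phase, 210 ms stimulation
        wl = generate_workloop(soleus_mechanics, cycle_freq=2.0,
                               strain_amp=0.065, phase_ms=-20.0,
                               stim_dur_ms=210.0)
        assert wl.n_cycles == pytest.approx(4, abs=0.01)
        assert len(wl.stim_windows) == 4
        res = mechanics.workloop_power(wl, soleus_mechanics.mass)
        assert res.net_work_j > 0  # properly phased stimulation yields work

    def test_stimulation_longer_than_cycle_rejected(self, soleus_mechanics):
        with pytest.raises(ProfileError):
            generate_workloop(soleus_mechanics, cycle_freq=10.0,
                              stim_dur_ms=150.0)


# ----------------------------------------------------------------------
# Flow recordings
# ----------------------------------------------------------------------

class TestGenerateFlow:
    def _profile(self, **kw):
        base = dict(resting_flow=1.71, plateau_flow=2.39, map_pressure=154.0,
                    rise_tau=5.0, stim_window=(60.0, 240.0), muscle_mass=0.26,
                    seed=0)
        base.update(kw)
        return FlowProfile(**base)

    def test_no_response_when_plateau_equals_resting(self):
        rec = generate_flow_recording(self._profile(plateau_flow=1.71))
        h = signals.hyperaemia_metrics(rec)
        assert h.delta_flow == pytest.approx(0.0, abs=1e-12)
        assert h.scope == pytest.approx(1.0, abs=1e-12)

    def test_step_response_reaches_plateau_exactly(self):
        # rise_tau -> 0 gives a step; the end-stimulation mean is the plateau
        rec = generate_flow_recording(self._profile(rise_tau=0.0))
        h = signals.hyperaemia_metrics(rec)
        assert h.end_stim_flow == pytest.approx(2.39, abs=1e-12)
        assert h.resting_flow == pytest.approx(1.71, abs=1e-12)

    def test_downstream_metrics_recover_profile(self):
        rec = generate_flow_recording(self._profile())
        h = signals.hyperaemia_metrics(rec)
        assert h.resting_flow == pytest.approx(1.71, rel=0.05)
        assert h.end_stim_flow == pytest.approx(2.39, rel=0.05)


# ----------------------------------------------------------------------
# Helix profiles
# ----------------------------------------------------------------------

class TestGenerateHelix:
    def test_noiseless_polynomial_r2_is_one(self):
        p = generate_helix_profile([-60, 240, -240, 120, -30, 30], 50, 0.0, 0)
        assert signals.disarray_index(p) == pytest.approx(1.0, abs=1e-12)

    def test_linear_profile_nested_r2_one(self):
        p = generate_helix_profile([-60, 120, 0, 0, 0, 0], 25, 0.0, 0)
        assert signals.disarray_index(p) == pytest.approx(1.0, abs=1e-12)

    def test_underdetermined_rejected(self):
        with pytest.raises(ProfileError):
            generate_helix_profile([0, 1, 0, 0, 0, 0], 6, 0.0, 0)


# ----------------------------------------------------------------------
# Cross-generator determinism
# ----------------------------------------------------------------------

def test_all_trace_generators_deterministic(soleus_mechanics):
    import dataclasses

    prof = dataclasses.replace(soleus_mechanics, noise_sd=0.02, seed=42)
    t1, t2 = generate_twitch(prof), generate_twitch(prof)
    assert np.array_equal(t1.force, t2.force)
    w1 = generate_workloop(prof, 3.0)
    w2 = generate_workloop(prof, 3.0)
    assert np.array_equal(w1.force_n, w2.force_n)
    fp = FlowProfile(resting_flow=2.0, plateau_flow=3.0, map_pressure=150.0,
                     rise_tau=4.0, stim_window=(30.0, 120.0),
                     muscle_mass=0.2, noise_sd=0.1, seed=9)
    r1, r2 = generate_flow_recording(fp), generate_flow_recording(fp)
    assert np.array_equal(r1.flow, r2.flow)
    h1 = generate_helix_profile([0, 60, 0, 0, 0, -20], 30, 5.0, 3)
    h2 = generate_helix_profile([0, 60, 0, 0, 0, -20], 30, 5.0, 3)
    assert np.array_equal(h1.helix_deg, h2.helix_deg)
    ff1 = generate_force_frequency(prof)
    ff2 = generate_force_frequency(prof)
    for k in ff1:
        assert np.array_equal(ff1[k].force, ff2[k].force)
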