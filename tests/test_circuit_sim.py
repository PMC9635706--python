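"""Unit tests for the closed-loop circuit simulator building blocks."""

import dataclasses
import math

import numpy as np
import pytest

from cardioloop import circuit_sim as cs
from cardioloop import units as U


# ---------------------------------------------------------------------------
# ladder construction
# ---------------------------------------------------------------------------

class TestLadder:
    def test_default_geometry_first_segment_matches_mold_table(self):
        geo = cs.default_aorta_geometry()
        asc = geo[0]
        assert asc.name == "ascending_aorta"
        assert asc.length_mm == 70
        assert asc.inlet_diameter_mm == 24.0

    def test_single_compartment_compliance_formula(self):
        # A = 1 m2, l = 1 m, rho = 1000 kg/m3, c = 10 m/s -> C = 1e-5 m3/Pa
        d_mm = 2000.0 * math.sqrt(1.0 / math.pi)  # area exactly 1 m2
        seg = cs.AortaSegmentSpec("tube", 1000.0, d_mm, n_compartments=1)
        fluid = cs.FluidProps(density=1000.0, viscosity=1e-3)
        ladder = cs.build_aorta_ladder([seg], target_pwv=10.0, fluid=fluid)
        assert ladder.comp_C[0] == pytest.approx(1e-5, rel=1e-9)
        assert ladder.comp_L[0] == pytest.approx(1000.0, rel=1e-9)

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            cs.build_aorta_ladder([], target_pwv=10.0)

    @pytest.mark.parametrize("bad", [
        dict(length_mm=0), dict(inlet_diameter_mm=-1), dict(n_compartments=0),
    ])
    def test_degenerate_dimensions_rejected(self, bad):
        kw = dict(name="x", length_mm=50, inlet_diameter_mm=10)
        kw.update(bad)
        with pytest.raises(ValueError):
            cs.AortaSegmentSpec(**kw)

    def test_ac_rescale_hits_target_and_reports_effective_speed(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(),
                                       target_pwv=12.6, target_ac=1.51)
        assert ladder.total_compliance_ml_per_mmhg() == pytest.approx(
            1.51, rel=1e-9)
        assert ladder.effective_pwv == pytest.approx(
            12.6 / math.sqrt(ladder.ac_scale), rel=1e-12)
        # the rig AC exceeds the thin-tube estimate, so waves slow down
        assert ladder.effective_pwv < 12.6

    def test_preserved_pwv_keeps_geometric_compliance(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(),
                                       target_pwv=12.6, target_ac=None)
        assert ladder.effective_pwv == 12.6
        assert ladder.ac_scale == 1.0

    def test_positions_strictly_increasing_along_trunk(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        trunk = [i for i, s in enumerate(ladder.comp_segment)
                 if s in ("ascending_aorta", "aortic_arch", "thoracic_aorta",
                          "abdominal_aorta", "iliac_artery")]
        pos = ladder.comp_position[trunk]
        assert np.all(np.diff(pos) > 0)

    def test_taps_at_specified_centerline_distances(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        i_asc = ladder.tap_map["ascending_aorta"]
        i_abd = ladder.tap_map["abdominal_aorta"]
        # 6 cm from root; 23 cm past the arch center (arch center at 10 cm)
        assert ladder.comp_position[i_asc] == pytest.approx(0.06, abs=0.011)
        assert ladder.comp_position[i_abd] == pytest.approx(0.33, abs=0.011)


class TestStaticInflation:
    def test_linear_law_unit_step(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        p = cs.static_inflation(ladder, [0.0, 1.51])
        assert p[1] - p[0] == pytest.approx(1.0, rel=1e-9)

    def test_zero_volume_zero_pressure(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        assert cs.static_inflation(ladder, [0.0])[0] == 0.0

    def test_strictly_increasing(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        p = cs.static_inflation(ladder, [0.0, 1.0, 2.0, 5.0])
        assert np.all(np.diff(p) > 0)

    def test_open_outlet_is_an_error(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        with pytest.raises(ValueError, match="sealed"):
            cs.static_inflation(ladder, [0.0, 1.0], outlet_open=True)

    def test_decreasing_steps_rejected(self):
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        with pytest.raises(ValueError, match="nondecreasing"):
            cs.static_inflation(ladder, [1.0, 0.5])


# ---------------------------------------------------------------------------
# elastance
# ---------------------------------------------------------------------------

class TestElastance:
    lv = cs.LVParams(e_max=2.5, e_min=0.06)

    def test_starts_at_e_min(self):
        assert cs.elastance_curve(0.0, self.lv, 75) == pytest.approx(0.06)

    def test_peak_value_scales_with_contractility(self):
        for scale in (0.5, 1.0, 1.7):
            lv = dataclasses.replace(self.lv, contractility_scale=scale)
            t_pk = cs.activation_peak_time(lv, 75)
            e_pk = cs.elastance_curve(t_pk, lv, 75)
            assert e_pk == pytest.approx(
                lv.e_min + scale * (lv.e_max - lv.e_min), rel=1e-9)

    def test_doubling_contractility_doubles_activation_pointwise(self):
        t = np.linspace(0, 60 / 75, 4001)
        lv1 = dataclasses.replace(self.lv, contractility_scale=0.8)
        lv2 = dataclasses.replace(self.lv, contractility_scale=1.6)
        e1 = cs.elastance_curve(t, lv1, 75) - lv1.e_min
        e2 = cs.elastance_curve(t, lv2, 75) - lv2.e_min
        assert np.allclose(e2, 2.0 * e1, atol=1e-12)

    def test_periodic(self):
        t = np.linspace(0, 60 / 75, 500)
        period = 60 / 75
        e0 = cs.elastance_curve(t, self.lv, 75)
        e1 = cs.elastance_curve(t + 3 * period, self.lv, 75)
        assert np.allclose(e0, e1, atol=1e-12)

    def test_first_derivative_continuous(self):
        # central-difference derivative has no jumps at the phase boundaries
        dt = 1e-5
        t = np.arange(0, 60 / 75, dt)
        e = cs.elastance_curve(t, self.lv, 75)
        d = np.gradient(e, dt)
        jumps = np.abs(np.diff(d))
        # a C1 curve sampled at dt has derivative increments O(E''*dt)
        assert jumps.max() < 50.0 * dt * (self.lv.e_max / 0.01)


# ---------------------------------------------------------------------------
# valves
# ---------------------------------------------------------------------------

class TestValve:
    valve = cs.ValveParams(open_resistance=0.02, transition_width=0.5)

    def test_closed_limit(self):
        g = cs.valve_conductance(-10 * self.valve.transition_width, self.valve)
        assert g < 1e-4 / self.valve.open_resistance

    def test_open_limit(self):
        g = cs.valve_conductance(+10 * self.valve.transition_width, self.valve)
        assert g == pytest.approx(1 / self.valve.open_resistance, rel=1e-3)

    def test_conductance_monotone_on_grid(self):
        dp = np.linspace(-20, 20, 4001)
        g = cs.valve_conductance(dp, self.valve)
        assert np.all(np.diff(g) >= 0)

    def test_flow_never_negative(self):
        dp = np.linspace(-200, 200, 20001)
        q = cs.valve_flow(dp, self.valve)
        assert q.min() >= 0.0

    def test_open_flow_matches_ohmic_law_past_cracking_pressure(self):
        q = cs.valve_flow(40.0, self.valve)
        expect = (40.0 - self.valve.opening_threshold) \
            / self.valve.open_resistance
        assert q == pytest.approx(expect, rel=1e-6)

    def test_backflow_flag_rejected(self):
        with pytest.raises(ValueError):
            cs.ValveParams(open_resistance=0.02, allows_backflow=True)


# ---------------------------------------------------------------------------
# closed-loop simulation
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_no_pump_no_flow(self):
        lv = cs.LVParams(e_max=2.5, contractility_scale=0.0)
        cfg = dataclasses.replace(
            cs.make_preset("baseline"), lv=lv,
            numerics=cs.Numerics(max_cycles=12))
        res = cs.simulate(cfg)
        assert res.co_measured < 0.05

    def test_determinism_bit_identical(self):
        cfg = dataclasses.replace(
            cs.make_preset("baseline"),
            numerics=cs.Numerics(max_cycles=4, min_cycles=2))
        with pytest.warns(RuntimeWarning):
            r1 = cs.simulate(cfg)
        with pytest.warns(RuntimeWarning):
            r2 = cs.simulate(cfg)
        for site in r1.records:
            assert np.array_equal(r1.records[site].pressure,
                                  r2.records[site].pressure)
        assert r1.co_measured == r2.co_measured

    def test_steady_state_pressure_flow_balance(self, sim):
        # MAP at the ascending tap = CO * R_total + venous head pressure
        res = sim("baseline")
        from conftest import map_of
        mp = map_of(res)
        co_mls = res.co_measured * 1000.0 / 60.0
        pred = (co_mls * cs.nominal_total_resistance(res.config)
                + res.config.venous_pressure_mmhg)
        assert mp == pytest.approx(pred, rel=0.05)

    def test_volume_conserved_over_final_cycle(self, sim):
        total = sim("baseline").volumes["total"]
        assert np.ptp(total) / total.mean() < 1e-3

    def test_valve_flows_unidirectional(self, sim):
        res = sim("baseline")
        assert res.valve_flows["aortic"].min() >= -1e-9
        assert res.valve_flows["mitral"].min() >= -1e-9

    def test_valve_events_alternate(self, sim):
        ev = sim("baseline").valve_events
        for valve in ("aortic", "mitral"):
            assert len(ev[valve]) >= 1
            o, c = ev[valve][0]
            assert c is None or c > o

    def test_convergence_flag_and_history(self, sim):
        res = sim("baseline")
        assert res.converged
        assert res.convergence_history[-1] <= res.config.numerics.convergence_tol

    def test_wave_foot_arrival_matches_configured_speed(self):
        """Impulse response of the bare ladder against a matched resistive
        termination: transit of the pressure foot between the taps must
        track distance / effective wave speed (independent mini-integrator,
        not the closed-loop solver)."""
        ladder = cs.build_aorta_ladder(cs.default_aorta_geometry(), 12.6, 1.51)
        n = ladder.n_compartments
        c = ladder.effective_pwv
        dt, T = 5e-5, 0.30
        steps = int(T / dt)
        P = np.zeros(n)
        Q = np.zeros(n - 1)
        r_term = {int(i): ladder.char_impedance(int(i))
                  for i in ladder.terminal_comps}

        def q_in(t):  # impulse-like inflow at the root, m3/s
            return 2e-4 * math.exp(-0.5 * ((t - 0.02) / 0.005) ** 2)

        i_asc = ladder.tap_map["ascending_aorta"]
        i_abd = ladder.tap_map["abdominal_aorta"]
        trace = np.empty((steps, 2))

        def rhs(t, P, Q):
            dP = np.zeros(n)
            dQ = (P[ladder.parent[1:]] - P[1:]
                  - ladder.comp_R[1:] * Q) / ladder.comp_L[1:]
            np.add.at(dP, np.arange(1, n), Q)
            np.add.at(dP, ladder.parent[1:], -Q)
            dP[0] += q_in(t)
            for i, r in r_term.items():
                dP[i] -= P[i] / r
            return dP / ladder.comp_C, dQ

        for k in range(steps):
            t = k * dt
            k1p, k1q = rhs(t, P, Q)
            k2p, k2q = rhs(t + dt / 2, P + dt / 2 * k1p, Q + dt / 2 * k1q)
            k3p, k3q = rhs(t + dt / 2, P + dt / 2 * k2p, Q + dt / 2 * k2q)
            k4p, k4q = rhs(t + dt, P + dt * k3p, Q + dt * k3q)
            P = P + dt / 6 * (k1p + 2 * k2p + 2 * k3p + k4p)
            Q = Q + dt / 6 * (k1q + 2 * k2q + 2 * k3q + k4q)
            trace[k] = P[i_asc], P[i_abd]

        def foot(x):
            thr = 0.05 * x.max()
            return np.argmax(x > thr) * dt

        transit = foot(trace[:, 1]) - foot(trace[:, 0])
        distance = ladder.comp_position[i_abd] - ladder.comp_position[i_asc]
        assert transit > 0
        assert distance / transit == pytest.approx(c, rel=0.10)


class TestPresets:
    def test_baseline_settings(self):
        cfg = cs.make_preset("baseline")
        assert cfg.hr == 75
        assert cfg.target_pwv == 12.6
        assert cfg.target_ac == 1.51

    def test_aorta_presets_use_fabricated_properties(self):
        cfg = cs.make_preset("aorta_3")
        assert (cfg.target_pwv, cfg.target_ac) == (12.6, 1.51)
        cfg1 = cs.make_preset("aorta_1")
        assert (cfg1.target_pwv, cfg1.target_ac) == (5.6, 2.28)

    def test_unknown_preset_lists_choices(self):
        with pytest.raises(ValueError) as exc:
            cs.make_preset("high_contrast")
        assert "baseline" in str(exc.value)

    def test_single_knob_presets(self):
        base = cs.make_preset("baseline")
        hp = cs.make_preset("high_preload")
        assert hp.venous_head != base.venous_head
        assert hp.lv == base.lv and hp.afterload == base.afterload
        hc = cs.make_preset("high_contractility")
        assert hc.lv.contractility_scale > 1
        assert hc.venous_head == base.venous_head
        ht = cs.make_preset("high_tpr")
        assert ht.afterload.outlet_resistance_scale > 1
        assert ht.lv == base.lv

    def test_preset_hr_range_is_physiological(self):
        for name in cs.PRESET_NAMES:
            assert 50 <= cs.make_preset(name).hr <= 125


class TestUnits:
    def test_round_trips(self):
        assert U.pa_to_mmhg(U.mmhg_to_pa(94.25)) == pytest.approx(94.25)
        assert U.r_from_si(U.r_to_si(18.85)) == pytest.approx(18.85)
        assert U.c_from_si(U.c_to_si(1.51)) == pytest.approx(1.51)

    def test_mmhg_constant(self):
        assert U.MMHG_PA == 133.322
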