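"""Nodal AC analysis, Bode/cut-off extraction, transient integration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from plasmoflow import (
    CircuitNetwork,
    PressureSource,
    Stage,
    WindkesselElement,
    ac_solve,
    bode,
    build_single_stage,
    build_y_cascade,
    cutoff_frequency,
    cutoff_from_bode,
    impedance,
    phase_between,
    to_electrical,
    transient_solve,
)

positive = st.floats(min_value=1e-2, max_value=1e2)


def quadrature_amplitude(x, omega, dt):
    """Amplitude of the omega-component over whole periods from the end."""
    period = 2 * math.pi / omega
    n_use = int(int(len(x) / (period / dt)) * period / dt)
    t = np.arange(n_use) * dt
    return 2.0 * abs(np.dot(x[-n_use:], np.exp(-1j * omega * t))) / n_use


class TestACSolve:
    def test_single_stage_against_closed_form(self, electrical_element):
        """The nodal solver must agree with the analytic divider."""
        net = build_single_stage(electrical_element)
        omega = 0.08
        sol = ac_solve(net, omega)
        r1, r2, c = 10.0, 500.0, 0.053
        zp = r2 / (1 + 1j * omega * r2 * c)
        h = zp / (r1 + zp)
        assert sol.node_voltage["n1"] == pytest.approx(h, rel=1e-12)
        # impedance seen by the source equals the closed-form element impedance
        z_seen = net.source.amplitude / sol.stage_current[0]
        assert abs(z_seen) == pytest.approx(
            impedance(electrical_element, omega).magnitude, rel=1e-12
        )

    def test_mid_node_lag_at_drive_frequency(self, electrical_element):
        """Along one segment the pressure wave is delayed by 2.4 deg."""
        sol = ac_solve(build_single_stage(electrical_element), 0.08)
        assert sol.phase_deg("n1") == pytest.approx(-2.4, abs=0.05)
        assert sol.gain("n1", 1.0) == pytest.approx(0.980, abs=5e-4)

    def test_dc_gives_resistive_divider(self, electrical_element):
        net = build_y_cascade(electrical_element)
        sol = ac_solve(net, 0.0)
        for v in sol.node_voltage.values():
            assert abs(v.imag) < 1e-15
        # hand-computed resistive ladder for the 2-stem/2-arm cascade:
        # fold the ladder from the arms back to the source
        r1, r2 = 10.0, 500.0
        z_arm = r1 + r2
        z_at_stem2 = 1 / (1 / r2 + 2 / z_arm)
        z_from_stem1 = 1 / (1 / r2 + 1 / (r1 + z_at_stem2))
        v1 = z_from_stem1 / (r1 + z_from_stem1)
        v2 = v1 * z_at_stem2 / (r1 + z_at_stem2)
        v_arm = v2 * r2 / (r1 + r2)
        assert sol.node_voltage["stem1"].real == pytest.approx(v1, rel=1e-12)
        assert sol.node_voltage["stem2"].real == pytest.approx(v2, rel=1e-12)
        assert sol.node_voltage["arm1"].real == pytest.approx(v_arm, rel=1e-12)

    def test_arm_symmetry(self, electrical_element):
        net = build_y_cascade(electrical_element, n_stem=2, n_arms=2)
        for f in (1e-3, 0.03, 0.3, 3.0):
            sol = ac_solve(net, 2 * math.pi * f)
            assert sol.node_voltage["arm1"] == pytest.approx(
                sol.node_voltage["arm2"], rel=1e-12
            )

    @settings(deadline=None, max_examples=50)
    @given(r1=positive, r2=positive, c=positive, omega=positive)
    def test_oracle_random_elements(self, r1, r2, c, omega):
        el = WindkesselElement(r1, r2, c, "electrical")
        net = build_single_stage(el, PressureSource(1.0, omega))
        sol = ac_solve(net, omega)
        zp = r2 / (1 + 1j * omega * r2 * c)
        assert sol.node_voltage["n1"] == pytest.approx(zp / (r1 + zp), rel=1e-10)
        assert sol.kcl_residual < 1e-9

    def test_kcl_residual_reported(self, electrical_element):
        sol = ac_solve(build_y_cascade(electrical_element), 0.08)
        assert sol.kcl_residual < 1e-9


class TestTopology:
    def test_degenerate_cascade_is_single_stage(self, electrical_element):
        net = build_y_cascade(electrical_element, n_stem=1, n_arms=0)
        assert len(net.stages) == 1
        assert net.probes == ["stem1"]

    def test_y_cascade_node_count(self, electrical_element):
        net = build_y_cascade(electrical_element, n_stem=2, n_arms=2)
        assert len(net.stages) == 4
        assert len(net.nodes) == 5  # source + 2 stem + 2 arm ends
        assert net.probes == ["stem1", "stem2", "arm1"]

    def test_invalid_counts_rejected(self, electrical_element):
        with pytest.raises(ValueError):
            build_y_cascade(electrical_element, n_stem=0)
        with pytest.raises(ValueError):
            build_y_cascade(electrical_element, n_arms=-1)

    def test_disconnected_network_rejected(self):
        with pytest.raises(ValueError, match="connected"):
            CircuitNetwork(
                stages=[
                    Stage("in", "a", 10, 500, 0.05),
                    Stage("b", "c", 10, 500, 0.05),
                ],
                source_node="in",
                source=PressureSource(1.0, 0.08),
            )

    def test_netlist_roundtrip(self, electrical_element, tmp_path):
        net = build_y_cascade(electrical_element)
        path = tmp_path / "net.json"
        net.to_json(path)
        loaded = CircuitNetwork.from_json(path)
        assert loaded.stages == net.stages
        assert loaded.probes == net.probes
        assert loaded.source == net.source


@pytest.fixture(scope="module")
def cascade_bode():
    el = WindkesselElement(10.0, 500.0, 0.053, "electrical")
    return bode(build_y_cascade(el), f_min=1e-3, f_max=2.0, n_points=60)


class TestBodeAndCutoff:

    def test_low_frequency_plateau(self, cascade_bode):
        """Gain at the lowest frequency sits on the DC divider value."""
        dc = ac_solve(cascade_bode.network, 0.0)
        for p in cascade_bode.network.probes:
            plateau_db = 20 * math.log10(abs(dc.node_voltage[p]))
            assert cascade_bode.gain_db[p][0] == pytest.approx(plateau_db, abs=0.5)

    def test_gain_ordering_along_cascade(self, cascade_bode):
        g1, g2, g3 = (cascade_bode.gain_db[p] for p in ("stem1", "stem2", "arm1"))
        assert np.all(g1 >= g2 - 1e-12)
        assert np.all(g2 >= g3 - 1e-12)

    def test_cascade_cutoffs(self, cascade_bode):
        """Cut-offs fall along the cascade: 0.058, 0.036, 0.033 Hz."""
        cut = {
            p: cutoff_from_bode(cascade_bode, p, "absolute")
            for p in ("stem1", "stem2", "arm1")
        }
        assert round(cut["stem1"], 3) == 0.058
        assert round(cut["stem2"], 3) == 0.036
        assert round(cut["arm1"], 3) == 0.033
        assert cut["stem1"] > cut["stem2"] > cut["arm1"]

    def test_single_stage_relative_convention_matches_formula(self, electrical_element):
        net = build_single_stage(electrical_element)
        result = bode(net, f_min=1e-3, f_max=5.0, n_points=40)
        fc = cutoff_from_bode(result, "n1", "relative")
        assert fc == pytest.approx(cutoff_frequency(electrical_element), rel=1e-4)

    def test_single_stage_gain_monotone(self, electrical_element):
        result = bode(build_single_stage(electrical_element), f_min=1e-3,
                      f_max=5.0, n_points=40)
        assert np.all(np.diff(result.gain_db["n1"]) < 0)

    def test_missing_crossing_raises(self, electrical_element):
        result = bode(build_single_stage(electrical_element), f_min=1e-4,
                      f_max=1e-3, n_points=10)
        with pytest.raises(ValueError, match="crossing"):
            cutoff_from_bode(result, "n1", "absolute")


class TestTransient:
    def test_zero_source_stays_zero(self, electrical_element):
        net = build_single_stage(electrical_element, PressureSource(0.0, 0.08))
        res = transient_solve(net, (0.0, 100.0), 0.5)
        assert np.all(res.node_voltage["n1"] == 0.0)

    def test_dc_source_converges_to_divider(self, electrical_element):
        net = build_single_stage(electrical_element, PressureSource(0.0, 0.0, dc_offset=1.0))
        res = transient_solve(net, (0.0, 60.0), 0.05)
        assert res.node_voltage["n1"][-1] == pytest.approx(500.0 / 510.0, rel=1e-3)

    def test_steady_state_matches_ac(self, electrical_element):
        """After the start-up transient the network sits on the AC solution."""
        omega = 0.08
        net = build_y_cascade(electrical_element, source=PressureSource(1.0, omega))
        period = 2 * math.pi / omega
        res = transient_solve(net, (0.0, 12 * period), period / 200)
        ac = ac_solve(net, omega)
        for node in ("stem1", "stem2", "arm1"):
            amp = quadrature_amplitude(res.node_voltage[node], omega, period / 200)
            assert amp == pytest.approx(abs(ac.node_voltage[node]), rel=0.01)
            ph = phase_between(res.node_voltage["in"], res.node_voltage[node],
                               omega, dt=period / 200)
            assert ph == pytest.approx(
                math.degrees(np.angle(ac.node_voltage[node])), abs=0.5
            )

    def test_coarse_step_refused(self, electrical_element):
        net = build_y_cascade(electrical_element, source=PressureSource(1.0, 0.08))
        with pytest.raises(ValueError, match="dt"):
            transient_solve(net, (0.0, 100.0), 10.0)


class TestPhaseBetween:
    def test_identical_traces(self):
        t = np.arange(0, 400, 0.5)
        x = np.cos(0.08 * t)
        assert phase_between(x, x, 0.08, dt=0.5) == pytest.approx(0.0, abs=1e-10)

    def test_quarter_period(self):
        omega = 2 * math.pi / 80.0  # whole number of samples per period
        t = np.arange(0, 400, 0.5)
        assert phase_between(np.cos(omega * t), np.sin(omega * t), omega, dt=0.5) == (
            pytest.approx(-90.0, abs=1e-8)
        )

    def test_short_record_rejected(self):
        t = np.arange(0, 100, 0.5)  # just over one period at 0.08 rad/s
        x = np.cos(0.08 * t)
        with pytest.raises(ValueError, match="period"):
            phase_between(x, x, 0.08, dt=0.5)

    def test_transient_mid_node_lag(self, electrical_element):
        omega = 0.08
        net = build_single_stage(electrical_element, PressureSource(1.0, omega))
        period = 2 * math.pi / omega
        res = transient_solve(net, (0.0, 10 * period), period / 200)
        ph = phase_between(res.node_voltage["in"], res.node_voltage["n1"],
                           omega, dt=period / 200)
        assert ph == pytest.approx(-2.4, abs=0.1)


def test_unit_system_invariance(fluidic_element):
    """Fluidic and electrically converted networks share gains and phases."""
    elec = to_electrical(fluidic_element, 10.0)
    for f in (0.01, 0.05, 0.31):
        omega = 2 * math.pi * f
        sol_f = ac_solve(build_y_cascade(fluidic_element), omega)
        sol_e = ac_solve(build_y_cascade(elec), omega)
        for node in ("stem1", "stem2", "arm1"):
            assert abs(sol_f.node_voltage[node]) == pytest.approx(
                abs(sol_e.node_voltage[node]), rel=1e-10
            )
            assert np.angle(sol_f.node_voltage[node]) == pytest.approx(
                np.angle(sol_e.node_voltage[node]), abs=1e-10
            )
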