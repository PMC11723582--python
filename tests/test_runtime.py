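"""Flattening, RHS evaluation, integration, events and recording."""

import math
import random

import pytest

from conftest import count_bursts, hr_reference_rhs
from lemslite.dimensions import parse_quantity
from lemslite.fixtures import (
    HR_PARAMS,
    linear_component,
    worked_example,
)
from lemslite.lems_model import Component
from lemslite.runtime import (
    BuildError,
    SimulationError,
    build,
    build_instance,
    eval_rhs,
    read_simulation,
    run,
    step,
    write_simulation,
)


def hr_component(**overrides):
    params = dict(HR_PARAMS)
    params.update({k: str(v) for k, v in overrides.items()})
    return Component(id="hr0", type="HindmarshRose1984Cell",
                     parameter_values=params)


def si_params():
    p = {k: float(v) for k, v in HR_PARAMS.items()
         if k not in ("v_scaling", "C")}
    p["v_scaling"] = parse_quantity(HR_PARAMS["v_scaling"]).si_value
    p["C"] = parse_quantity(HR_PARAMS["C"]).si_value
    return p


class TestBuild:
    def test_worked_example_structure(self, hr_network, stdlib):
        doc, _ = hr_network
        (inst,) = build(doc, stdlib)
        assert inst.state_names == ["v", "y", "z", "spiking"]
        assert [d.name for d in inst.derived] == \
            ["iSyn", "x", "phi", "chi", "rho", "iMemb"]
        assert [c.id for c in inst.attachments["synapses"]] == ["pg0"]

    def test_on_start_applied(self, hr_network, stdlib):
        doc, _ = hr_network
        (inst,) = build(doc, stdlib)
        v_scaling = parse_quantity(HR_PARAMS["v_scaling"]).si_value
        assert inst.scope["v"] == float(HR_PARAMS["x0"]) * v_scaling
        assert inst.scope["y"] == float(HR_PARAMS["y0"])
        assert inst.scope["z"] == float(HR_PARAMS["z0"])
        assert inst.scope["spiking"] == 0.0

    def test_missing_parameter_is_an_error(self, stdlib):
        params = {k: v for k, v in HR_PARAMS.items() if k != "s"}
        comp = Component(id="hr0", type="HindmarshRose1984Cell",
                         parameter_values=params)
        with pytest.raises(BuildError, match="'s'"):
            build_instance(comp, stdlib)

    def test_wrong_parameter_dimension_is_an_error(self, stdlib):
        with pytest.raises(BuildError, match="C"):
            build_instance(hr_component(C="0.5 s"), stdlib)

    def test_empty_attachment_reduces_to_zero(self, stdlib):
        inst = build_instance(hr_component(), stdlib)
        eval_rhs(inst, 0.0)
        assert inst.scope["iSyn"] == 0.0

    def test_attachment_base_type_mismatch(self, stdlib, hr_network):
        doc, _ = hr_network
        # replace the input with another HR cell: not a basePointCurrent
        net = doc.networks[0]
        ei = net.find("explicitInput")
        ei.attrs["input"] = "hr0"
        with pytest.raises(BuildError, match="extend"):
            build(doc, stdlib)


class TestRhsOracle:
    def test_zero_state_hand_values(self, stdlib):
        inst = build_instance(hr_component(x0="0", y0="0", z0="0"), stdlib)
        d = eval_rhs(inst, 0.0)
        p = si_params()
        msec = 1e-3
        assert d["v"] == 0.0
        assert d["y"] == pytest.approx(p["c"] / msec)
        assert d["z"] == pytest.approx(-p["r"] * p["s"] * p["x1"] / msec)
        assert d["spiking"] == 0.0

    def test_mid_pulse_input_contributes_exactly_amplitude(
            self, hr_network, stdlib):
        doc, _ = hr_network
        (inst,) = build(doc, stdlib)
        eval_rhs(inst, 0.5)  # mid-pulse (pulse covers [0, 1.4) s)
        assert inst.scope["iSyn"] == 5e-9
        eval_rhs(inst, 1.5)  # past the pulse window
        assert inst.scope["iSyn"] == 0.0

    def test_pulse_window_is_half_open(self, stdlib):
        comp = Component(id="pg", type="pulseGenerator", parameter_values={
            "delay": "50 ms", "duration": "200 ms", "amplitude": "5 nA"})
        pg = build_instance(comp, stdlib)
        for t, expected in [(0.049, 0.0), (0.050, 5e-9), (0.249, 5e-9),
                            (0.250, 0.0)]:
            eval_rhs(pg, t)
            assert pg.scope["i"] == expected, t

    def test_flattened_rhs_matches_hand_coded_oracle(self, stdlib):
        """<=1e-12 relative agreement on 100 random states/parameter sets."""
        rng = random.Random(2024)
        for _ in range(100):
            overrides = {
                k: float(HR_PARAMS[k]) * (1 + rng.uniform(-0.5, 0.5))
                for k in ("a", "b", "c", "d", "r", "s", "x1")
            }
            inst = build_instance(hr_component(**overrides), stdlib)
            state = (rng.uniform(-0.08, 0.04), rng.uniform(-12, 3),
                     rng.uniform(-2, 6))
            inst.scope["v"], inst.scope["y"], inst.scope["z"] = state
            got = eval_rhs(inst, 0.0)
            p = si_params()
            p.update(overrides)
            want = hr_reference_rhs(state, p, i_syn=0.0)
            for g, w in zip((got["v"], got["y"], got["z"]), want):
                assert abs(g - w) <= 1e-12 * max(1.0, abs(w))


class TestIntegration:
    def test_single_euler_step_closed_form(self):
        comp, reg = linear_component("10 ms", "1 mV")
        inst = build_instance(comp, reg)
        tau, dt = 0.01, 0.001
        step(inst, 0.0, dt, method="euler")
        # one-step closed form v1 = v0*(1 - dt/tau), up to summation order
        assert inst.scope["v"] == pytest.approx(1e-3 * (1.0 - dt / tau),
                                                rel=1e-15)

    @pytest.mark.parametrize("method,order", [("euler", 1), ("rk4", 4)])
    def test_global_error_order(self, method, order):
        comp, reg = linear_component("10 ms", "1 mV")
        tau, v0 = 0.01, 1e-3
        errs = []
        for frac in (0.1, 0.05, 0.025):
            inst = build_instance(comp, reg)
            dt = frac * tau
            n = round(5 * tau / dt)
            for k in range(n):
                step(inst, k * dt, dt, method=method)
            errs.append(abs(inst.scope["v"] - v0 * math.exp(-5.0)))
        for coarse, fine in zip(errs, errs[1:]):
            ratio = coarse / fine
            assert 0.6 * 2 ** order < ratio < 1.6 * 2 ** order

    def test_euler_under_decays_for_positive_initial_value(self):
        # 1 - h < e^-h, so each Euler step loses too much: v_euler < v_exact
        comp, reg = linear_component("10 ms", "1 mV")
        inst = build_instance(comp, reg)
        dt = 0.001
        for k in range(10):
            step(inst, k * dt, dt, method="euler")
        assert inst.scope["v"] < 1e-3 * math.exp(-10 * dt / 0.01)

    def test_non_finite_state_aborts_with_diagnostic(self, stdlib):
        inst = build_instance(hr_component(), stdlib)
        inst.scope["y"] = float("inf")
        with pytest.raises(SimulationError, match="non-finite"):
            step(inst, 0.0, 1e-5)


class TestEvents:
    def test_spike_emitted_once_per_upward_crossing(self, stdlib):
        inst = build_instance(hr_component(), stdlib)
        inst.scope["v"], inst.scope["spiking"] = -1e-3, 0.0
        # drive v across 0 by hand: hold the state, run the handlers
        inst.scope["v"] = 1e-3
        events = []
        for test, assigns, port in inst.on_conditions:
            if test(inst.scope) != 0.0:
                for var, fn in assigns:
                    inst.scope[var] = fn(inst.scope)
                if port:
                    events.append(port)
        assert events == ["spike"] and inst.scope["spiking"] == 1.0
        # still depolarised: the spiking guard suppresses a second event
        events2 = [port for test, _, port in inst.on_conditions
                   if test(inst.scope) != 0.0 and port]
        assert events2 == []

    def test_event_count_matches_spiking_transitions(self, hr_network, stdlib):
        doc, spec = hr_network
        spec.output_files[0][1].append(("spiking", "HRPop0[0]/spiking"))
        spec.length = "300 ms"
        res = run(spec, doc, stdlib)
        s = res.columns["HRPop0[0]/spiking"]
        transitions = sum(1 for a, b in zip(s, s[1:]) if a < 0.5 <= b)
        assert len(res.events) == transitions > 0


class TestRun:
    def test_worked_example_bursts(self, hr_network, stdlib):
        doc, spec = hr_network
        res = run(spec, doc, stdlib)
        assert len(res.times) == 56001
        spike_times = [t for t, _ in res.events]
        bursts, _ = count_bursts(spike_times)
        assert bursts >= 2

    def test_recording_path_out_of_range(self, hr_network, stdlib):
        doc, spec = hr_network
        spec.output_files = [("v.dat", [("v", "HRPop0[1]/v")])]
        with pytest.raises(SimulationError, match="resolve"):
            run(spec, doc, stdlib)

    def test_identical_seeds_give_byte_identical_outputs(
            self, hr_network, stdlib, tmp_path):
        doc, spec = hr_network
        spec.length = "50 ms"
        out1, out2 = tmp_path / "a", tmp_path / "b"
        run(spec, doc, stdlib, outdir=out1)
        run(spec, doc, stdlib, outdir=out2)
        for f1, f2 in zip(sorted(out1.iterdir()), sorted(out2.iterdir())):
            assert f1.read_bytes() == f2.read_bytes()

    def test_rows_are_time_first_tab_separated(self, hr_network, stdlib,
                                               tmp_path):
        doc, spec = hr_network
        spec.length = "1 ms"
        run(spec, doc, stdlib, outdir=tmp_path)
        lines = (tmp_path / "hr_v.dat").read_text().splitlines()
        assert len(lines) == 41  # 1 ms / 0.025 ms + inclusive endpoint
        t0, v0 = lines[0].split("\t")
        assert float(t0) == 0.0
        assert float(v0) == pytest.approx(-0.0385)

    def test_spec_invariants_enforced(self, hr_network, stdlib):
        doc, spec = hr_network
        spec.step = "2 s"  # step > length
        with pytest.raises(SimulationError):
            run(spec, doc, stdlib)


class TestSimulationXML:
    def test_spec_round_trips(self, hr_network):
        _, spec = hr_network
        spec.model_files = ["worked_example.nml"]
        back = read_simulation(write_simulation(spec))
        assert back.length == spec.length and back.step == spec.step
        assert back.seed == spec.seed
        assert back.output_files == spec.output_files
        assert back.event_files == spec.event_files
        assert back.model_files == spec.model_files

    def test_display_elements_are_ignored(self):
        xml = """<Lems><Simulation id='s' length='10 ms' step='1 ms'
                 target='net0' seed='1'>
                 <Display id='d' title='t' timeScale='1ms'>
                 <Line id='l' quantity='p[0]/v'/></Display>
                 </Simulation></Lems>"""
        spec = read_simulation(xml)
        assert spec.length == "10 ms" and spec.output_files == []
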