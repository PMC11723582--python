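"""ComponentType model, inheritance flattening, XML round trip, library."""

import random

import pytest

from lemslite.dimensions import DimensionError
from lemslite.expressions import parse_expr
from lemslite.lems_model import (
    Component,
    ComponentType,
    Constant,
    DerivedVariable,
    Dynamics,
    Exposure,
    LemsError,
    Parameter,
    StateAssignment,
    StateVariable,
    TimeDerivative,
    check_dynamics_dimensions,
    derived_variable_order,
    element_name_for_type,
    read_lems,
    resolve_type,
    standard_library,
    write_lems,
)


class TestStandardLibrary:
    def test_contains_the_expected_types(self, stdlib):
        assert {"baseCellMembPotCap", "basePointCurrent", "pulseGenerator",
                "HindmarshRose1984Cell"} <= set(stdlib)

    def test_hr_extends_base_cell(self, stdlib):
        assert stdlib["HindmarshRose1984Cell"].extends == "baseCellMembPotCap"

    def test_resolved_hr_inherits_capacitance_and_v(self, hr_type):
        assert "C" in {p.name for p in hr_type.parameters}
        assert {"v", "iMemb"} <= {e.name for e in hr_type.exposures}

    def test_hr_has_exactly_three_on_start_assignments(self, hr_type):
        assert [sa.variable for sa in hr_type.dynamics.on_start] == ["v", "y", "z"]

    def test_hr_exposes_states_and_inspectable_derived(self, hr_type):
        exposed = {e.name for e in hr_type.exposures}
        assert {"v", "y", "z", "x", "spiking", "iMemb", "phi", "chi",
                "rho"} <= exposed

    def test_isyn_is_a_reduce_add_over_the_synapse_attachment(self, hr_type):
        isyn = next(dv for dv in hr_type.dynamics.derived_variables
                    if dv.name == "iSyn")
        assert isyn.reduce == "add"
        collection = isyn.select.split("[*]/")[0]
        assert collection in {a.name for a in hr_type.attachments}
        assert isyn.select.endswith("/i")

    def test_msec_constant_is_one_millisecond(self, hr_type):
        msec = next(c for c in hr_type.constants if c.name == "MSEC")
        assert msec.si_value() == 1e-3

    def test_every_library_type_dimension_checks_clean(self, stdlib):
        for name in stdlib:
            check_dynamics_dimensions(resolve_type(name, stdlib))

    def test_pulse_generator_extends_base_point_current(self, stdlib):
        assert stdlib["pulseGenerator"].extends == "basePointCurrent"
        resolved = resolve_type("pulseGenerator", stdlib)
        assert {p.name for p in resolved.parameters} == {"delay", "duration",
                                                         "amplitude"}


class TestResolveType:
    def test_root_type_resolves_to_itself(self, stdlib):
        assert resolve_type("baseCellMembPotCap", stdlib) is \
            stdlib["baseCellMembPotCap"]

    def test_cycle_is_an_error(self):
        reg = {
            "A": ComponentType("A", extends="B"),
            "B": ComponentType("B", extends="A"),
        }
        with pytest.raises(LemsError, match="cycle"):
            resolve_type("A", reg)

    def test_unknown_extends_target(self):
        reg = {"A": ComponentType("A", extends="Ghost")}
        with pytest.raises(LemsError, match="Ghost"):
            resolve_type("A", reg)

    def test_name_collision_between_levels_is_an_error(self):
        reg = {
            "Base": ComponentType("Base",
                                  parameters=(Parameter("tau", "time"),)),
            "Derived": ComponentType("Derived", extends="Base",
                                     parameters=(Parameter("tau", "time"),)),
        }
        with pytest.raises(LemsError, match="duplicate"):
            resolve_type("Derived", reg)


class TestInvariants:
    def test_duplicate_state_names_rejected(self):
        with pytest.raises(LemsError, match="duplicate"):
            ComponentType("Bad", dynamics=Dynamics(
                state_variables=(StateVariable("v", "voltage"),
                                 StateVariable("v", "voltage"))))

    def test_derivative_of_undeclared_state_rejected(self):
        with pytest.raises(LemsError, match="undeclared"):
            ComponentType("Bad", dynamics=Dynamics(
                time_derivatives=(TimeDerivative("ghost", parse_expr("1")),)))

    def test_derived_variable_cycle_detected(self):
        ct = ComponentType("Loop", dynamics=Dynamics(
            derived_variables=(
                DerivedVariable("p", "none", value=parse_expr("q + 1")),
                DerivedVariable("q", "none", value=parse_expr("p - 1")),
            )))
        with pytest.raises(LemsError, match="cycle"):
            derived_variable_order(ct)

    def test_derived_variables_topologically_ordered(self, hr_type):
        order = [dv.name for dv in derived_variable_order(hr_type)]
        assert order.index("x") < order.index("phi")
        assert order.index("phi") < order.index("iMemb")
        assert order.index("iSyn") < order.index("iMemb")

    def test_unknown_dimension_rejected(self):
        with pytest.raises(LemsError, match="dimension"):
            ComponentType("Bad", parameters=(Parameter("p", "parsecs"),))


class TestDimensionValidation:
    def test_mismatched_derived_declaration_caught(self):
        ct = ComponentType("Bad",
                           parameters=(Parameter("C", "capacitance"),),
                           dynamics=Dynamics(
                               derived_variables=(
                                   DerivedVariable("q", "current",
                                                   value=parse_expr("C")),)))
        with pytest.raises(DimensionError):
            check_dynamics_dimensions(ct)

    def test_time_derivative_must_be_state_per_time(self):
        ct = ComponentType("Bad", dynamics=Dynamics(
            state_variables=(StateVariable("v", "voltage"),),
            time_derivatives=(TimeDerivative("v", parse_expr("v")),)))
        with pytest.raises(DimensionError, match="dv/dt|d"):
            check_dynamics_dimensions(ct)


def _random_type(seed: int) -> ComponentType:
    rng = random.Random(seed)
    n_params = rng.randint(1, 4)
    params = tuple(Parameter(f"p{i}", rng.choice(["none", "time", "voltage"]))
                   for i in range(n_params))
    states = tuple(StateVariable(f"s{i}", "none",
                                 exposure=f"s{i}" if rng.random() < 0.5 else None)
                   for i in range(rng.randint(1, 3)))
    exprs = ["s0 + 1", "s0 * 2", "3 - s0", "s0 ^ 2"]
    return ComponentType(
        name=f"RandomType{seed}",
        parameters=params,
        constants=(Constant("K", "2 ms", "time"),),
        exposures=tuple(Exposure(sv.exposure, "none")
                        for sv in states if sv.exposure),
        dynamics=Dynamics(
            state_variables=states,
            derived_variables=(DerivedVariable(
                "d0", "none", value=parse_expr(rng.choice(exprs))),),
            on_start=(StateAssignment("s0", parse_expr("1")),),
        ),
    )


class TestXMLRoundTrip:
    def test_standard_library_round_trips(self, stdlib):
        types = read_lems(write_lems(stdlib))
        assert {t.name: t for t in types} == stdlib

    @pytest.mark.parametrize("seed", range(10))
    def test_random_types_round_trip(self, seed):
        ct = _random_type(seed)
        (back,) = read_lems(write_lems([ct]))
        assert back == ct

    def test_duplicate_type_names_rejected_on_read(self):
        xml = "<Lems><ComponentType name='T'/><ComponentType name='T'/></Lems>"
        with pytest.raises(LemsError, match="duplicate"):
            read_lems(xml)

    def test_empty_document_reads_as_empty_list(self):
        assert read_lems("<Lems/>") == []

    def test_write_refuses_cyclic_extends(self):
        types = [ComponentType("A", extends="B"),
                 ComponentType("B", extends="A")]
        with pytest.raises(LemsError, match="cycl"):
            write_lems(types)

    def test_duplicate_state_variables_rejected_on_read(self):
        xml = """<Lems><ComponentType name='T'><Dynamics>
                 <StateVariable name='v' dimension='none'/>
                 <StateVariable name='v' dimension='none'/>
                 </Dynamics></ComponentType></Lems>"""
        with pytest.raises(LemsError, match="duplicate"):
            read_lems(xml)


def test_element_name_mapping():
    assert element_name_for_type("HindmarshRose1984Cell") == \
        "hindmarshRose1984Cell"
    assert element_name_for_type("pulseGenerator") == "pulseGenerator"
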