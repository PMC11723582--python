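"""Programmatic generators for every test input.

Nothing here is loaded from data files: the worked single-cell
Hindmarsh–Rose network, one minimal invalid document per validation
check, random valid networks, and an analytic linear-decay cell type
(the integrator oracle) are all constructed in code, deterministically
per seed.

The bundled Hindmarsh–Rose parameter set is a repository choice of the
classic regular-bursting configuration (a=1, b=3, c=-3, d=5, s=4,
r=0.002, x1=-1.3, started from x0=-1.1, y0=-9, z0=1); the membrane
scaling v_scaling = 35 mV and C = 28.57142857 pF map the 5 nA current
pulse onto a dimensionless drive of ~5, which yields regular bursts.
Only the 5 nA amplitude and the 1 ms time constant are fixed by the
model's published description; the rest are documented repository
constants, not published values.
"""

from __future__ import annotations

import random
from typing import Optional

from .expressions import parse_expr
from .lems_model import (
    Component,
    ComponentType,
    Dynamics,
    Parameter,
    StateAssignment,
    StateVariable,
    TimeDerivative,
)
from .nml_document import ModelDocument, XMLNode, node
from .runtime import SimulationSpec
from .validator import CHECK_IDS, UNBRANCHED_NEUROLEX_ID

__all__ = [
    "HR_PARAMS",
    "worked_example",
    "invalid",
    "random_network",
    "linear_test_type",
    "linear_component",
]

#: Regular-bursting Hindmarsh–Rose parameters (quantity strings as they
#: appear in the document).
HR_PARAMS: dict[str, str] = {
    "a": "1", "b": "3", "c": "-3", "d": "5",
    "r": "0.002", "s": "4", "x1": "-1.3",
    "x0": "-1.1", "y0": "-9", "z0": "1",
    "v_scaling": "35 mV",
    "C": "28.57142857 pF",
}


def _hr_cell(cell_id: str = "hr0", **overrides: str) -> XMLNode:
    params = dict(HR_PARAMS)
    params.update(overrides)
    return node("hindmarshRose1984Cell", id=cell_id, **params)


def worked_example(seed: int = 12345) -> tuple[ModelDocument, SimulationSpec]:
    """The single-cell network: one bursting HR cell driven by a
    sustained 5 nA current pulse, with its membrane potential and spike
    events recorded over 1400 ms at dt = 0.025 ms."""
    doc = ModelDocument(node(
        "neuroml",
        _hr_cell(),
        node("pulseGenerator", id="pg0", delay="0 ms", duration="1400 ms",
             amplitude="5 nA"),
        node("network",
             node("population", id="HRPop0", component="hr0", size=1),
             node("explicitInput", target="HRPop0[0]", input="pg0"),
             id="net0"),
        id="HRNet",
    ))
    spec = SimulationSpec(
        id="HRSim",
        length="1400 ms",
        step="0.025 ms",
        target="net0",
        seed=seed,
        output_files=[("hr_v.dat", [("v", "HRPop0[0]/v")])],
        event_files=[("hr_spikes.dat", [("0", "HRPop0[0]", "spike")])],
    )
    return doc, spec


# ---------------------------------------------------------------------------
# invalid documents, one per validation check

def _seg(seg_id: int, parent: Optional[int] = None, name: str = "seg") -> XMLNode:
    children = []
    if parent is not None:
        children.append(node("parent", segment=parent))
    children.append(node("distal", x=0, y=0, z=float(seg_id) * 10, diameter=2))
    return node("segment", *children, id=seg_id, name=f"{name}{seg_id}")


def _cell_with(morph_children: list[XMLNode], cell_id: str = "c0",
               extra: Optional[list[XMLNode]] = None) -> XMLNode:
    kids = [node("morphology", *morph_children, id="m0")]
    if extra:
        kids.extend(extra)
    return node("cell", *kids, id=cell_id)


def _doc(*children: XMLNode, doc_id: str = "invalidDoc") -> ModelDocument:
    return ModelDocument(node("neuroml", *children, id=doc_id))


def invalid(check_id: str) -> ModelDocument:
    """A minimal document violating exactly the named check."""
    builders = _INVALID_BUILDERS
    if check_id not in builders:
        raise KeyError(f"no invalid-document generator for {check_id!r}; "
                       f"known: {sorted(builders)}")
    return builders[check_id]()


def _inv_schema_names() -> ModelDocument:
    return _doc(node("bogusElement", id="b0"))


def _inv_schema_types() -> ModelDocument:
    return _doc(
        _hr_cell(),
        node("network", node("population", id="p0", component="hr0",
                             size="two"), id="net0"),
    )


def _inv_schema_values() -> ModelDocument:
    return _doc(_hr_cell(C="0.5 s"))


def _inv_schema_inclusion() -> ModelDocument:
    params = {k: v for k, v in HR_PARAMS.items() if k != "s"}
    return _doc(node("hindmarshRose1984Cell", id="hr0", **params))


def _inv_schema_cardinality() -> ModelDocument:
    return _doc(node("cell",
                     node("morphology", _seg(0), id="m0"),
                     node("morphology", _seg(0), id="m1"),
                     id="c0"))


def _inv_schema_hierarchy() -> ModelDocument:
    return _doc(_hr_cell(), node("population", id="p0", component="hr0", size=1))


def _inv_schema_sequence_order() -> ModelDocument:
    return _doc(node("network", id="net0"), _hr_cell())


def _inv_top_level_ids() -> ModelDocument:
    pg = lambda: node("pulseGenerator", id="pg0", delay="0 ms",
                      duration="100 ms", amplitude="1 nA")
    return _doc(pg(), pg())


def _inv_network_ids() -> ModelDocument:
    pop = lambda: node("population", id="p0", component="hr0", size=1)
    return _doc(_hr_cell(), node("network", pop(), pop(), id="net0"))


def _inv_segment_ids() -> ModelDocument:
    return _doc(_cell_with([_seg(0), _seg(0, parent=0)]))


def _inv_single_root_segment() -> ModelDocument:
    return _doc(_cell_with([_seg(0), _seg(1)]))


def _inv_segment_group_ids() -> ModelDocument:
    g = lambda: node("segmentGroup", id="g0")
    return _doc(_cell_with([_seg(0), g(), g()]))


def _inv_member_segments() -> ModelDocument:
    return _doc(_cell_with([
        _seg(0),
        node("segmentGroup", node("member", segment=5), id="g0"),
    ]))


def _inv_segment_group_defined() -> ModelDocument:
    return _doc(
        node("ionChannel", id="kChan"),
        _cell_with(
            [_seg(0), node("segmentGroup", id="g0")],
            extra=[node("biophysicalProperties",
                        node("membraneProperties",
                             node("channelDensity", id="cd0",
                                  ionChannel="kChan",
                                  segmentGroup="missingGroup")),
                        id="bp0")],
        ),
    )


def _inv_segment_group_order() -> ModelDocument:
    return _doc(_cell_with([
        _seg(0),
        node("segmentGroup", node("include", segmentGroup="gB"), id="gA"),
        node("segmentGroup", node("member", segment=0), id="gB"),
    ]))


def _inv_included_segment_groups() -> ModelDocument:
    return _doc(_cell_with([
        _seg(0),
        node("segmentGroup", node("include", segmentGroup="nope"), id="gA"),
    ]))


def _inv_number_internal_divisions() -> ModelDocument:
    return _doc(_cell_with([
        _seg(0),
        node("segmentGroup", node("member", segment=0), id="g0",
             neuroLexId=UNBRANCHED_NEUROLEX_ID),
    ]))


def _inv_included_files() -> ModelDocument:
    return _doc(node("include", href="no_such_model_file_xyz.nml"))


def _inv_population_component() -> ModelDocument:
    return _doc(node("network",
                     node("population", id="p0", component="ghost", size=1),
                     id="net0"))


def _inv_ion_channel_exists() -> ModelDocument:
    return _doc(_cell_with(
        [_seg(0)],
        extra=[node("biophysicalProperties",
                    node("membraneProperties",
                         node("channelDensity", id="cd0",
                              ionChannel="ghostChan")),
                    id="bp0")],
    ))


def _inv_concentration_model_species() -> ModelDocument:
    return _doc(_cell_with(
        [_seg(0)],
        extra=[node("biophysicalProperties",
                    node("intracellularProperties",
                         node("species", id="ca",
                              concentrationModel="ghostModel")),
                    id="bp0")],
    ))


def _inv_population_size() -> ModelDocument:
    return _doc(
        _hr_cell(),
        node("network",
             node("population",
                  node("instance", node("location", x=0, y=0, z=0), id=0),
                  node("instance", node("location", x=10, y=0, z=0), id=1),
                  id="p0", component="hr0", size=3, type="populationList"),
             id="net0"),
    )


def _two_pop_projection(connection: Optional[XMLNode] = None,
                        post_pop: str = "p1",
                        synapse: str = "syn0") -> ModelDocument:
    conns = [connection] if connection is not None else []
    return _doc(
        node("expOneSynapse", id="syn0", gbase="1 nS", erev="0 mV",
             tauDecay="5 ms"),
        _cell_with([_seg(0)]),
        node("network",
             node("population", id="p0", component="c0", size=1),
             node("population", id="p1", component="c0", size=1),
             node("projection", *conns, id="proj0",
                  presynapticPopulation="p0",
                  postsynapticPopulation=post_pop, synapse=synapse),
             id="net0"),
    )


def _inv_projection_populations() -> ModelDocument:
    return _two_pop_projection(post_pop="ghostPop")


def _inv_connection_segments() -> ModelDocument:
    return _two_pop_projection(node("connection", id=0, preCellId="p0[0]",
                                    postCellId="p1[0]", preSegmentId=7))


def _inv_connection_cells() -> ModelDocument:
    return _two_pop_projection(node("connection", id=0, preCellId="p0[5]",
                                    postCellId="p1[0]"))


def _inv_projection_synapse() -> ModelDocument:
    doc = _two_pop_projection(synapse="ghostSyn")
    # drop the real synapse so only the reference is dangling
    doc.root.children = [c for c in doc.root.children
                         if c.tag != "expOneSynapse"]
    return doc


def _inv_root_id_zero() -> ModelDocument:
    return _doc(_cell_with([_seg(7)]))


_INVALID_BUILDERS = {
    "schema.names": _inv_schema_names,
    "schema.types": _inv_schema_types,
    "schema.values": _inv_schema_values,
    "schema.inclusion": _inv_schema_inclusion,
    "schema.cardinality": _inv_schema_cardinality,
    "schema.hierarchy": _inv_schema_hierarchy,
    "schema.sequence_order": _inv_schema_sequence_order,
    "semantic.top_level_ids": _inv_top_level_ids,
    "semantic.network_ids": _inv_network_ids,
    "semantic.segment_ids": _inv_segment_ids,
    "semantic.single_root_segment": _inv_single_root_segment,
    "semantic.segment_group_ids": _inv_segment_group_ids,
    "semantic.member_segments": _inv_member_segments,
    "semantic.segment_group_defined": _inv_segment_group_defined,
    "semantic.segment_group_order": _inv_segment_group_order,
    "semantic.included_segment_groups": _inv_included_segment_groups,
    "semantic.number_internal_divisions": _inv_number_internal_divisions,
    "semantic.included_files": _inv_included_files,
    "semantic.population_component": _inv_population_component,
    "semantic.ion_channel_exists": _inv_ion_channel_exists,
    "semantic.concentration_model_species": _inv_concentration_model_species,
    "semantic.population_size": _inv_population_size,
    "semantic.projection_populations": _inv_projection_populations,
    "semantic.connection_segments": _inv_connection_segments,
    "semantic.connection_cells": _inv_connection_cells,
    "semantic.projection_synapse": _inv_projection_synapse,
    "semantic.root_id_zero": _inv_root_id_zero,
}

assert set(_INVALID_BUILDERS) == set(CHECK_IDS)


# ---------------------------------------------------------------------------
# random valid networks

def random_network(n: int, seed: int, with_input: bool = True) -> ModelDocument:
    """A valid network of ``n`` HR cells in one population.

    The shared cell component's dimensionless parameters are jittered
    ±10% around the bursting set, deterministically per seed; an
    optional pulse input is wired to every cell.
    """
    rng = random.Random(seed)
    params = dict(HR_PARAMS)
    for key in ("a", "b", "c", "d", "r", "s", "x1", "x0", "y0", "z0"):
        base = float(params[key])
        params[key] = repr(base * (1.0 + rng.uniform(-0.1, 0.1)))
    children = [
        _hr_cell("hr0", **params),
        node("pulseGenerator", id="pg0", delay="50 ms", duration="200 ms",
             amplitude="5 nA"),
    ]
    net_children = [node("population", id="HRPop0", component="hr0", size=n)]
    if with_input:
        for idx in range(n):
            net_children.append(node("explicitInput",
                                     target=f"HRPop0[{idx}]", input="pg0"))
    children.append(node("network", *net_children, id="net0"))
    return ModelDocument(node("neuroml", *children, id=f"randNet{seed}"))


# ---------------------------------------------------------------------------
# linear decay type: analytic integrator oracle

def linear_test_type() -> ComponentType:
    """Single-state exponential decay: dv/dt = -v/tau, v(0) = v0.

    The closed form v(t) = v0 * exp(-t/tau) makes this the oracle for
    integrator-order tests; the declared dimensions (v: voltage,
    tau: time) also exercise the dimension checker.
    """
    return ComponentType(
        name="LinearDecayCell",
        parameters=(Parameter("tau", "time"), Parameter("v0", "voltage")),
        dynamics=Dynamics(
            state_variables=(StateVariable("v", "voltage", exposure="v"),),
            time_derivatives=(TimeDerivative("v", parse_expr("-v / tau")),),
            on_start=(StateAssignment("v", parse_expr("v0")),),
        ),
    )


def linear_component(tau: str = "10 ms", v0: str = "1 mV",
                     comp_id: str = "lin0") -> tuple[Component, dict[str, ComponentType]]:
    ct = linear_test_type()
    comp = Component(id=comp_id, type=ct.name,
                     parameter_values={"tau": tau, "v0": v0})
    return comp, {ct.name: ct}
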