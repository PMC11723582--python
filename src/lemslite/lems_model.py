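"""LEMS ComponentType definitions: data model, XML I/O, standard library.

A ComponentType is a parameterized template for a model element — its
parameters and state variables carry declared dimensions, and a Dynamics
block gives the ODEs, derived variables, initialisation and threshold
rules.  A Component is an instance of a type with concrete parameter
value strings.  Types may extend other types; :func:`resolve_type`
flattens the inheritance chain into a single merged view.

The bundled standard library covers the abstract-cell subset used
throughout the package: ``baseCellMembPotCap`` (membrane potential ``v``
with capacitance ``C``), ``basePointCurrent`` (current exposure ``i``),
``pulseGenerator`` (square current pulse) and ``HindmarshRose1984Cell``
(three-variable bursting neuron with a synaptic-current attachment).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

from .dimensions import DIMENSIONS, Dimension, DimensionError, parse_quantity
from .expressions import (
    Expr,
    free_symbols,
    infer_dimension,
    parse_expr,
    serialize_expr,
)

__all__ = [
    "Parameter",
    "Constant",
    "Exposure",
    "Requirement",
    "Attachment",
    "StateVariable",
    "DerivedVariable",
    "TimeDerivative",
    "StateAssignment",
    "OnCondition",
    "Dynamics",
    "ComponentType",
    "Component",
    "LemsError",
    "read_lems",
    "write_lems",
    "resolve_type",
    "standard_library",
    "check_dynamics_dimensions",
    "derived_variable_order",
    "element_name_for_type",
    "type_name_for_element",
]


class LemsError(ValueError):
    """Structural error in a type definition (duplicates, cycles, collisions)."""


@dataclass(frozen=True)
class Parameter:
    name: str
    dimension: str


@dataclass(frozen=True)
class Constant:
    name: str
    value: str  # quantity string, e.g. "1 ms"
    dimension: str

    def si_value(self) -> float:
        return parse_quantity(self.value, self.dimension).si_value


@dataclass(frozen=True)
class Exposure:
    name: str
    dimension: str


@dataclass(frozen=True)
class Requirement:
    """A variable the type expects its context to supply (e.g. v for a synapse)."""

    name: str
    dimension: str


@dataclass(frozen=True)
class Attachment:
    name: str        # collection name, e.g. "synapses"
    type: str        # base ComponentType attached components must extend


@dataclass(frozen=True)
class StateVariable:
    name: str
    dimension: str
    exposure: Optional[str] = None


@dataclass(frozen=True)
class DerivedVariable:
    """Either an expression-valued variable or a select/reduce over an attachment."""

    name: str
    dimension: str
    exposure: Optional[str] = None
    value: Optional[Expr] = None
    select: Optional[str] = None   # path pattern, e.g. "synapses[*]/i"
    reduce: Optional[str] = None   # "add" | "multiply"

    def __post_init__(self) -> None:
        if (self.value is None) == (self.select is None):
            raise LemsError(
                f"derived variable {self.name!r} needs exactly one of value/select"
            )
        if self.select is not None and self.reduce not in ("add", "multiply"):
            raise LemsError(
                f"derived variable {self.name!r}: reduce must be add|multiply"
            )


@dataclass(frozen=True)
class TimeDerivative:
    variable: str
    value: Expr


@dataclass(frozen=True)
class StateAssignment:
    variable: str
    value: Expr


@dataclass(frozen=True)
class OnCondition:
    test: Expr
    assignments: tuple[StateAssignment, ...] = ()
    event_out: Optional[str] = None


@dataclass(frozen=True)
class Dynamics:
    state_variables: tuple[StateVariable, ...] = ()
    derived_variables: tuple[DerivedVariable, ...] = ()
    time_derivatives: tuple[TimeDerivative, ...] = ()
    on_start: tuple[StateAssignment, ...] = ()
    on_conditions: tuple[OnCondition, ...] = ()

    def is_empty(self) -> bool:
        return not (self.state_variables or self.derived_variables
                    or self.time_derivatives or self.on_start
                    or self.on_conditions)


@dataclass(frozen=True)
class ComponentType:
    name: str
    extends: Optional[str] = None
    parameters: tuple[Parameter, ...] = ()
    constants: tuple[Constant, ...] = ()
    exposures: tuple[Exposure, ...] = ()
    requirements: tuple[Requirement, ...] = ()
    attachments: tuple[Attachment, ...] = ()
    dynamics: Dynamics = field(default_factory=Dynamics)

    def __post_init__(self) -> None:
        _check_local_names(self)


@dataclass
class Component:
    id: str
    type: str
    parameter_values: dict[str, str] = field(default_factory=dict)
    children: list["Component"] = field(default_factory=list)


def _check_local_names(ct: ComponentType) -> None:
    seen: set[str] = set()
    for group in (ct.parameters, ct.constants, ct.dynamics.state_variables,
                  ct.dynamics.derived_variables):
        for item in group:
            if item.name in seen:
                raise LemsError(
                    f"type {ct.name!r}: duplicate name {item.name!r}"
                )
            seen.add(item.name)
    states = {sv.name for sv in ct.dynamics.state_variables}
    for td in ct.dynamics.time_derivatives:
        if td.variable not in states:
            raise LemsError(
                f"type {ct.name!r}: TimeDerivative targets undeclared "
                f"state {td.variable!r}"
            )
    for sa in ct.dynamics.on_start:
        if sa.variable not in states:
            raise LemsError(
                f"type {ct.name!r}: OnStart targets undeclared state "
                f"{sa.variable!r}"
            )
    for oc in ct.dynamics.on_conditions:
        for sa in oc.assignments:
            if sa.variable not in states:
                raise LemsError(
                    f"type {ct.name!r}: OnCondition targets undeclared "
                    f"state {sa.variable!r}"
                )
    for dim_owner in list(ct.parameters) + list(ct.constants) + \
            list(ct.exposures) + list(ct.requirements) + \
            list(ct.dynamics.state_variables) + list(ct.dynamics.derived_variables):
        if dim_owner.dimension not in DIMENSIONS:
            raise LemsError(
                f"type {ct.name!r}: unknown dimension {dim_owner.dimension!r} "
                f"on {dim_owner.name!r}"
            )


# ---------------------------------------------------------------------------
# inheritance

def resolve_type(name: str, registry: dict[str, ComponentType]) -> ComponentType:
    """Flatten the extends chain of ``name`` into one merged ComponentType.

    Inherited and local declarations are concatenated root-first; a name
    collision between them is an error (shadowing is not allowed), as is
    a cycle in the extends chain.
    """
    chain: list[ComponentType] = []
    seen: set[str] = set()
    cursor: Optional[str] = name
    while cursor is not None:
        if cursor in seen:
            raise LemsError(f"cycle in extends chain at {cursor!r}")
        seen.add(cursor)
        ct = registry.get(cursor)
        if ct is None:
            raise LemsError(f"unknown ComponentType {cursor!r}")
        chain.append(ct)
        cursor = ct.extends
    chain.reverse()  # root first
    if len(chain) == 1:
        return chain[0]
    merged = ComponentType(
        name=name,
        extends=None,
        parameters=tuple(p for ct in chain for p in ct.parameters),
        constants=tuple(c for ct in chain for c in ct.constants),
        exposures=_merge_exposures(chain),
        requirements=tuple(r for ct in chain for r in ct.requirements),
        attachments=tuple(a for ct in chain for a in ct.attachments),
        dynamics=Dynamics(
            state_variables=tuple(s for ct in chain for s in ct.dynamics.state_variables),
            derived_variables=tuple(d for ct in chain for d in ct.dynamics.derived_variables),
            time_derivatives=tuple(t for ct in chain for t in ct.dynamics.time_derivatives),
            on_start=tuple(s for ct in chain for s in ct.dynamics.on_start),
            on_conditions=tuple(o for ct in chain for o in ct.dynamics.on_conditions),
        ),
    )
    return merged


def _merge_exposures(chain: list[ComponentType]) -> tuple[Exposure, ...]:
    # an exposure declared on a base type may legitimately be *linked* by a
    # subtype's dynamics; only exposures (same namespace) may not repeat
    out: list[Exposure] = []
    seen: set[str] = set()
    for ct in chain:
        for e in ct.exposures:
            if e.name in seen:
                raise LemsError(f"exposure {e.name!r} declared twice in chain")
            seen.add(e.name)
            out.append(e)
    return tuple(out)


def derived_variable_order(ct: ComponentType) -> list[DerivedVariable]:
    """Topologically sort derived variables by their value-expression deps."""
    dvs = {dv.name: dv for dv in ct.dynamics.derived_variables}
    order: list[DerivedVariable] = []
    mark: dict[str, int] = {}  # 1 = in progress, 2 = done

    def visit(name: str) -> None:
        state = mark.get(name)
        if state == 2:
            return
        if state == 1:
            raise LemsError(
                f"type {ct.name!r}: cycle through derived variable {name!r}"
            )
        mark[name] = 1
        dv = dvs[name]
        if dv.value is not None:
            for sym in sorted(free_symbols(dv.value)):
                if sym in dvs:
                    visit(sym)
        mark[name] = 2
        order.append(dv)

    for name in dvs:
        visit(name)
    return order


def check_dynamics_dimensions(ct: ComponentType) -> None:
    """Dimension-check every dynamics expression of a resolved type.

    The scope maps parameters, constants, state variables and derived
    variables to their declared dimensions, plus the global simulation
    time ``t``.  Derived values must match their declaration; each time
    derivative must carry its state's dimension divided by time;
    condition tests must be dimensionless; assignments must match their
    target state.  Raises :class:`~.expressions.DimensionInconsistency`.
    """
    scope: dict[str, Dimension] = {"t": DIMENSIONS["time"]}
    for p in ct.parameters:
        scope[p.name] = DIMENSIONS[p.dimension]
    for c in ct.constants:
        scope[c.name] = DIMENSIONS[c.dimension]
    for sv in ct.dynamics.state_variables:
        scope[sv.name] = DIMENSIONS[sv.dimension]
    for dv in ct.dynamics.derived_variables:
        scope[dv.name] = DIMENSIONS[dv.dimension]
    for dv in ct.dynamics.derived_variables:
        if dv.value is None:
            continue
        got = infer_dimension(dv.value, scope)
        if got != DIMENSIONS[dv.dimension]:
            raise DimensionError(
                f"{ct.name}.{dv.name}: declared {dv.dimension!r} but "
                f"expression has dimension {got.name!r}"
            )
    state_dims = {sv.name: DIMENSIONS[sv.dimension]
                  for sv in ct.dynamics.state_variables}
    for td in ct.dynamics.time_derivatives:
        got = infer_dimension(td.value, scope)
        want = state_dims[td.variable] / DIMENSIONS["time"]
        if got != want:
            raise DimensionError(
                f"{ct.name}: d{td.variable}/dt has dimension {got.name!r}, "
                f"expected {want.name!r}"
            )
    for sa in ct.dynamics.on_start:
        got = infer_dimension(sa.value, scope)
        if got != state_dims[sa.variable]:
            raise DimensionError(
                f"{ct.name}: OnStart {sa.variable} assigned {got.name!r}"
            )
    for oc in ct.dynamics.on_conditions:
        got = infer_dimension(oc.test, scope)
        if not got.is_dimensionless:
            raise DimensionError(
                f"{ct.name}: condition test is not dimensionless"
            )
        for sa in oc.assignments:
            got = infer_dimension(sa.value, scope)
            if got != state_dims[sa.variable] and not _zero_expr(sa.value):
                raise DimensionError(
                    f"{ct.name}: OnCondition assigns {got.name!r} to "
                    f"{sa.variable!r}"
                )


def _zero_expr(e: Expr) -> bool:
    from .expressions import Lit
    return isinstance(e, Lit) and e.value == 0.0


# ---------------------------------------------------------------------------
# XML I/O

def _parse_source(source) -> etree._Element:
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
        tree = etree.parse(str(source))
        return tree.getroot()
    if isinstance(source, bytes):
        return etree.fromstring(source)
    if isinstance(source, str):
        return etree.fromstring(source.encode())
    return etree.parse(source).getroot()


def read_lems(source) -> list[ComponentType]:
    """Read ComponentType definitions from a LEMS XML document.

    ``source`` may be a path, XML text, or a file object.  Unresolved
    ``extends`` targets are allowed here and only fail at
    :func:`resolve_type` time.
    """
    root = _parse_source(source)
    types: list[ComponentType] = []
    names: set[str] = set()
    for el in root.iter("ComponentType"):
        ct = _read_component_type(el)
        if ct.name in names:
            raise LemsError(f"duplicate ComponentType name {ct.name!r}")
        names.add(ct.name)
        types.append(ct)
    return types


def _read_component_type(el: etree._Element) -> ComponentType:
    dyn = Dynamics()
    dyn_el = el.find("Dynamics")
    if dyn_el is not None:
        dyn = Dynamics(
            state_variables=tuple(
                StateVariable(s.get("name"), s.get("dimension", "none"),
                              s.get("exposure"))
                for s in dyn_el.findall("StateVariable")
            ),
            derived_variables=tuple(
                DerivedVariable(
                    d.get("name"), d.get("dimension", "none"),
                    d.get("exposure"),
                    value=parse_expr(d.get("value")) if d.get("value") else None,
                    select=d.get("select"),
                    reduce=d.get("reduce"),
                )
                for d in dyn_el.findall("DerivedVariable")
            ),
            time_derivatives=tuple(
                TimeDerivative(t.get("variable"), parse_expr(t.get("value")))
                for t in dyn_el.findall("TimeDerivative")
            ),
            on_start=tuple(
                StateAssignment(a.get("variable"), parse_expr(a.get("value")))
                for os_el in dyn_el.findall("OnStart")
                for a in os_el.findall("StateAssignment")
            ),
            on_conditions=tuple(
                OnCondition(
                    test=parse_expr(oc.get("test")),
                    assignments=tuple(
                        StateAssignment(a.get("variable"),
                                        parse_expr(a.get("value")))
                        for a in oc.findall("StateAssignment")
                    ),
                    event_out=(oc.find("EventOut").get("port")
                               if oc.find("EventOut") is not None else None),
                )
                for oc in dyn_el.findall("OnCondition")
            ),
        )
    return ComponentType(
        name=el.get("name"),
        extends=el.get("extends"),
        parameters=tuple(Parameter(p.get("name"), p.get("dimension", "none"))
                         for p in el.findall("Parameter")),
        constants=tuple(Constant(c.get("name"), c.get("value"),
                                 c.get("dimension", "none"))
                        for c in el.findall("Constant")),
        exposures=tuple(Exposure(x.get("name"), x.get("dimension", "none"))
                        for x in el.findall("Exposure")),
        requirements=tuple(Requirement(r.get("name"), r.get("dimension", "none"))
                           for r in el.findall("Requirement")),
        attachments=tuple(Attachment(a.get("name"), a.get("type"))
                          for a in el.findall("Attachments")),
        dynamics=dyn,
    )


def write_lems(types: list[ComponentType] | dict[str, ComponentType]) -> str:
    """Serialize ComponentTypes to LEMS XML; ``read_lems`` round-trips it.

    Refuses a type set whose extends graph contains a cycle.
    """
    if isinstance(types, dict):
        types = list(types.values())
    by_name = {ct.name: ct for ct in types}
    for ct in types:
        seen = {ct.name}
        cursor = ct.extends
        while cursor is not None and cursor in by_name:
            if cursor in seen:
                raise LemsError(f"refusing to write cyclic extends chain at {cursor!r}")
            seen.add(cursor)
            cursor = by_name[cursor].extends
    root = etree.Element("Lems")
    for ct in types:
        root.append(_write_component_type(ct))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


def _write_component_type(ct: ComponentType) -> etree._Element:
    el = etree.Element("ComponentType", name=ct.name)
    if ct.extends:
        el.set("extends", ct.extends)
    for p in ct.parameters:
        etree.SubElement(el, "Parameter", name=p.name, dimension=p.dimension)
    for c in ct.constants:
        etree.SubElement(el, "Constant", name=c.name, dimension=c.dimension,
                         value=c.value)
    for r in ct.requirements:
        etree.SubElement(el, "Requirement", name=r.name, dimension=r.dimension)
    for x in ct.exposures:
        etree.SubElement(el, "Exposure", name=x.name, dimension=x.dimension)
    for a in ct.attachments:
        etree.SubElement(el, "Attachments", name=a.name, type=a.type)
    if not ct.dynamics.is_empty():
        dyn = etree.SubElement(el, "Dynamics")
        for s in ct.dynamics.state_variables:
            sv = etree.SubElement(dyn, "StateVariable", name=s.name,
                                  dimension=s.dimension)
            if s.exposure:
                sv.set("exposure", s.exposure)
        for d in ct.dynamics.derived_variables:
            dv = etree.SubElement(dyn, "DerivedVariable", name=d.name,
                                  dimension=d.dimension)
            if d.exposure:
                dv.set("exposure", d.exposure)
            if d.value is not None:
                dv.set("value", serialize_expr(d.value))
            else:
                dv.set("select", d.select)
                dv.set("reduce", d.reduce)
        for t in ct.dynamics.time_derivatives:
            etree.SubElement(dyn, "TimeDerivative", variable=t.variable,
                             value=serialize_expr(t.value))
        if ct.dynamics.on_start:
            os_el = etree.SubElement(dyn, "OnStart")
            for a in ct.dynamics.on_start:
                etree.SubElement(os_el, "StateAssignment", variable=a.variable,
                                 value=serialize_expr(a.value))
        for oc in ct.dynamics.on_conditions:
            oc_el = etree.SubElement(dyn, "OnCondition",
                                     test=serialize_expr(oc.test))
            for a in oc.assignments:
                etree.SubElement(oc_el, "StateAssignment", variable=a.variable,
                                 value=serialize_expr(a.value))
            if oc.event_out:
                etree.SubElement(oc_el, "EventOut", port=oc.event_out)
    return el


# ---------------------------------------------------------------------------
# standard library

def _e(text: str) -> Expr:
    return parse_expr(text)


def standard_library() -> dict[str, ComponentType]:
    """Registry of the bundled abstract-cell ComponentTypes."""
    base_cell = ComponentType(
        name="baseCellMembPotCap",
        parameters=(Parameter("C", "capacitance"),),
        exposures=(Exposure("v", "voltage"), Exposure("iMemb", "current")),
    )
    base_point_current = ComponentType(
        name="basePointCurrent",
        exposures=(Exposure("i", "current"),),
    )
    pulse_generator = ComponentType(
        name="pulseGenerator",
        extends="basePointCurrent",
        parameters=(
            Parameter("delay", "time"),
            Parameter("duration", "time"),
            Parameter("amplitude", "current"),
        ),
        dynamics=Dynamics(
            derived_variables=(
                # square pulse: amplitude on [delay, delay+duration), else 0
                DerivedVariable(
                    "i", "current", exposure="i",
                    value=_e("amplitude * (t .geq. delay) * (t .lt. delay + duration)"),
                ),
            ),
        ),
    )
    hindmarsh_rose = ComponentType(
        name="HindmarshRose1984Cell",
        extends="baseCellMembPotCap",
        parameters=(
            Parameter("a", "none"), Parameter("b", "none"),
            Parameter("c", "none"), Parameter("d", "none"),
            Parameter("r", "none"), Parameter("s", "none"),
            Parameter("x1", "none"),
            Parameter("x0", "none"), Parameter("y0", "none"),
            Parameter("z0", "none"),
            Parameter("v_scaling", "voltage"),
        ),
        constants=(Constant("MSEC", "1 ms", "time"),),
        exposures=(
            Exposure("x", "none"), Exposure("y", "none"),
            Exposure("z", "none"), Exposure("spiking", "none"),
            Exposure("phi", "none"), Exposure("chi", "none"),
            Exposure("rho", "none"), Exposure("iSyn", "current"),
        ),
        attachments=(Attachment("synapses", "basePointCurrent"),),
        dynamics=Dynamics(
            state_variables=(
                StateVariable("v", "voltage", exposure="v"),
                StateVariable("y", "none", exposure="y"),
                StateVariable("z", "none", exposure="z"),
                StateVariable("spiking", "none", exposure="spiking"),
            ),
            derived_variables=(
                DerivedVariable("iSyn", "current", exposure="iSyn",
                                select="synapses[*]/i", reduce="add"),
                DerivedVariable("x", "none", exposure="x",
                                value=_e("v / v_scaling")),
                DerivedVariable("phi", "none", exposure="phi",
                                value=_e("y - a * x^3 + b * x^2")),
                DerivedVariable("chi", "none", exposure="chi",
                                value=_e("c - d * x^2 - y")),
                DerivedVariable("rho", "none", exposure="rho",
                                value=_e("s * (x - x1) - z")),
                DerivedVariable("iMemb", "current", exposure="iMemb",
                                value=_e("C * v_scaling * (phi - z) / MSEC + iSyn")),
            ),
            time_derivatives=(
                TimeDerivative("v", _e("iMemb / C")),
                TimeDerivative("y", _e("chi / MSEC")),
                TimeDerivative("z", _e("r * rho / MSEC")),
            ),
            on_start=(
                StateAssignment("v", _e("x0 * v_scaling")),
                StateAssignment("y", _e("y0")),
                StateAssignment("z", _e("z0")),
            ),
            on_conditions=(
                OnCondition(
                    test=_e("v .gt. 0 .and. spiking .lt. 0.5"),
                    assignments=(StateAssignment("spiking", _e("1")),),
                    event_out="spike",
                ),
                OnCondition(
                    test=_e("v .lt. 0"),
                    assignments=(StateAssignment("spiking", _e("0")),),
                ),
            ),
        ),
    )
    return {ct.name: ct for ct in
            (base_cell, base_point_current, pulse_generator, hindmarsh_rose)}


def element_name_for_type(type_name: str) -> str:
    """Capitalised type names serialize as lower-camel XML element names."""
    return type_name[0].lower() + type_name[1:]


def type_name_for_element(element_name: str,
                          registry: dict[str, ComponentType]) -> Optional[str]:
    if element_name in registry:
        return element_name
    cap = element_name[0].upper() + element_name[1:]
    if cap in registry:
        return cap
    return None
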