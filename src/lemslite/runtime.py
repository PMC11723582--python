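"""Flatten documents into runnable instances and integrate them.

A :class:`RunnableInstance` holds a cell's parameters and state in SI,
its derived variables compiled to fast evaluators and topologically
ordered, its threshold handlers, and any attached input components
(each itself a stateless instance).  Every dynamics expression is
dimension-checked before the first evaluation.

Integration is fixed-step (forward Euler by default, classic RK4
selectable).  After each step the on-condition tests are evaluated in
declaration order on the new state, assignments applied immediately and
events collected; the spiking-state guard in the bundled cell type
makes event emission edge-triggered.  Recording follows a LEMS
simulation specification: column files of SI values per step plus event
files of (time, selection id) rows; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from lxml import etree

from .dimensions import DimensionError, parse_quantity
from .expressions import compile_expr
from .lems_model import (
    Component,
    ComponentType,
    check_dynamics_dimensions,
    derived_variable_order,
    resolve_type,
    type_name_for_element,
)
from .nml_document import ModelDocument, XMLNode

__all__ = [
    "RunnableInstance",
    "SimulationSpec",
    "BuildError",
    "SimulationError",
    "build",
    "build_instance",
    "eval_rhs",
    "step",
    "run",
    "RunResult",
    "read_simulation",
    "write_simulation",
]


class BuildError(ValueError):
    """Missing parameter, unresolved reference or attachment mismatch."""


class SimulationError(RuntimeError):
    """Non-finite state, unresolvable recording path, or bad spec."""


@dataclass
class _Derived:
    name: str
    fn: Optional[Callable] = None            # expression-valued
    collection: Optional[str] = None         # select/reduce over attachment
    exposure: Optional[str] = None
    reduce: Optional[str] = None


@dataclass
class RunnableInstance:
    """One flattened cell or input component, ready to integrate."""

    id: str
    type: ComponentType                      # resolved (flattened) type
    scope: dict[str, float]                  # params, constants, states, derived, t
    state_names: list[str]
    derived: list[_Derived]                  # topological order
    time_derivs: list[tuple[str, Callable]]
    on_conditions: list[tuple[Callable, list[tuple[str, Callable]], Optional[str]]]
    attachments: dict[str, list["RunnableInstance"]] = field(default_factory=dict)
    exposures: dict[str, str] = field(default_factory=dict)  # exposure -> variable

    def exposure_value(self, name: str) -> float:
        return self.scope[self.exposures[name]]

    def state_vector(self) -> list[float]:
        return [self.scope[n] for n in self.state_names]

    def set_state(self, values) -> None:
        for n, v in zip(self.state_names, values):
            self.scope[n] = v


def build_instance(component: Component, registry: dict[str, ComponentType],
                   instance_id: Optional[str] = None) -> RunnableInstance:
    """Flatten one component into a runnable instance (SI-bound, initialised).

    Parameters are parsed with their declared dimensions; every dynamics
    expression is dimension-checked; OnStart assignments are applied.
    """
    rt = resolve_type(component.type, registry)
    check_dynamics_dimensions(rt)
    scope: dict[str, float] = {"t": 0.0}
    for p in rt.parameters:
        raw = component.parameter_values.get(p.name)
        if raw is None:
            raise BuildError(
                f"component {component.id!r} ({component.type}): missing "
                f"parameter {p.name!r}"
            )
        try:
            scope[p.name] = parse_quantity(raw, p.dimension).si_value
        except DimensionError as exc:
            raise BuildError(
                f"component {component.id!r}: parameter {p.name!r}: {exc}"
            ) from exc
    for c in rt.constants:
        scope[c.name] = c.si_value()
    for sv in rt.dynamics.state_variables:
        scope[sv.name] = 0.0
    derived = []
    for dv in derived_variable_order(rt):
        if dv.value is not None:
            derived.append(_Derived(dv.name, fn=compile_expr(dv.value)))
        else:
            collection, rest = dv.select.split("[*]/", 1)
            if collection not in {a.name for a in rt.attachments}:
                raise BuildError(
                    f"type {rt.name!r}: select references unknown "
                    f"attachment collection {collection!r}"
                )
            derived.append(_Derived(dv.name, collection=collection,
                                    exposure=rest, reduce=dv.reduce))
        scope[dv.name] = 0.0
    exposures: dict[str, str] = {}
    for sv in rt.dynamics.state_variables:
        if sv.exposure:
            exposures[sv.exposure] = sv.name
    for dv in rt.dynamics.derived_variables:
        if dv.exposure:
            exposures[dv.exposure] = dv.name
    inst = RunnableInstance(
        id=instance_id or component.id,
        type=rt,
        scope=scope,
        state_names=[sv.name for sv in rt.dynamics.state_variables],
        derived=derived,
        time_derivs=[(td.variable, compile_expr(td.value))
                     for td in rt.dynamics.time_derivatives],
        on_conditions=[
            (compile_expr(oc.test),
             [(sa.variable, compile_expr(sa.value)) for sa in oc.assignments],
             oc.event_out)
            for oc in rt.dynamics.on_conditions
        ],
        attachments={a.name: [] for a in rt.attachments},
        exposures=exposures,
    )
    for sa in rt.dynamics.on_start:
        inst.scope[sa.variable] = compile_expr(sa.value)(inst.scope)
    return inst


def attach(inst: RunnableInstance, child: RunnableInstance,
           registry: dict[str, ComponentType]) -> None:
    """Insert ``child`` into the first attachment collection whose base
    type appears in the child's extends chain."""
    for a in inst.type.attachments:
        chain: set[str] = set()
        cursor: Optional[str] = child.type.name
        # the resolved child type lost its extends link; re-walk via registry
        orig = registry.get(child.type.name)
        while orig is not None:
            chain.add(orig.name)
            orig = registry.get(orig.extends) if orig.extends else None
        if a.type in chain:
            inst.attachments[a.name].append(child)
            return
    raise BuildError(
        f"component {child.id!r} ({child.type.name}) does not extend any "
        f"attachment base type of {inst.type.name!r}"
    )


def _component_from_node(n: XMLNode, registry: dict[str, ComponentType]) -> Component:
    type_name = type_name_for_element(n.tag, registry)
    if type_name is None:
        raise BuildError(f"element <{n.tag}> has no registered ComponentType")
    params = {k: v for k, v in n.attrs.items() if k != "id"}
    return Component(id=n.get("id", n.tag), type=type_name,
                     parameter_values=params)


def build(doc: ModelDocument,
          registry: dict[str, ComponentType]) -> list[RunnableInstance]:
    """Build one runnable instance per cell instance in the document's
    networks, with explicit inputs instantiated and attached."""
    instances: list[RunnableInstance] = []
    for net in doc.networks:
        by_path: dict[str, RunnableInstance] = {}
        for pop in doc.populations(net):
            comp_node = doc.component(pop.get("component", ""))
            if comp_node is None:
                raise BuildError(
                    f"population {pop.get('id')!r}: component "
                    f"{pop.get('component')!r} not found"
                )
            component = _component_from_node(comp_node, registry)
            for idx in range(doc.population_size(pop)):
                path = f"{pop.get('id')}[{idx}]"
                inst = build_instance(component, registry, instance_id=path)
                by_path[path] = inst
                instances.append(inst)
        for ei in net.find_all("explicitInput"):
            target = ei.get("target", "")
            inst = by_path.get(target)
            if inst is None:
                raise BuildError(
                    f"explicitInput target {target!r} does not resolve"
                )
            input_node = doc.component(ei.get("input", ""))
            if input_node is None:
                raise BuildError(
                    f"explicitInput input {ei.get('input')!r} not found"
                )
            child = build_instance(_component_from_node(input_node, registry),
                                   registry)
            attach(inst, child, registry)
    return instances


# ---------------------------------------------------------------------------
# evaluation and stepping

def _refresh_derived(inst: RunnableInstance, t: float, rng=None) -> None:
    for coll in inst.attachments.values():
        for child in coll:
            _refresh_derived(child, t, rng)
    inst.scope["t"] = t
    for d in inst.derived:
        if d.fn is not None:
            inst.scope[d.name] = d.fn(inst.scope, rng)
        else:
            values = [c.exposure_value(d.exposure)
                      for c in inst.attachments[d.collection]]
            if d.reduce == "add":
                acc = 0.0
                for v in values:
                    acc += v
            else:
                acc = 1.0
                for v in values:
                    acc *= v
            inst.scope[d.name] = acc


def eval_rhs(inst: RunnableInstance, t: float, rng=None) -> dict[str, float]:
    """Refresh derived variables (attachments first, topological order)
    then evaluate all time derivatives at time ``t``, in SI."""
    _refresh_derived(inst, t, rng)
    out = {name: 0.0 for name in inst.state_names}
    for name, fn in inst.time_derivs:
        out[name] = fn(inst.scope, rng)
    return out


def step(inst: RunnableInstance, t: float, dt: float,
         method: str = "euler", rng=None) -> list[str]:
    """Advance one fixed step and run the condition handlers.

    Returns the event ports emitted at ``t + dt``.  Condition tests are
    level-checked on the post-step state in declaration order, with
    assignments applied immediately.
    """
    y0 = inst.state_vector()
    if method == "euler":
        d = eval_rhs(inst, t, rng)
        inst.set_state([y + dt * d[n] for n, y in zip(inst.state_names, y0)])
    elif method == "rk4":
        k1 = eval_rhs(inst, t, rng)
        inst.set_state([y + 0.5 * dt * k1[n] for n, y in zip(inst.state_names, y0)])
        k2 = eval_rhs(inst, t + 0.5 * dt, rng)
        inst.set_state([y + 0.5 * dt * k2[n] for n, y in zip(inst.state_names, y0)])
        k3 = eval_rhs(inst, t + 0.5 * dt, rng)
        inst.set_state([y + dt * k3[n] for n, y in zip(inst.state_names, y0)])
        k4 = eval_rhs(inst, t + dt, rng)
        inst.set_state([
            y + dt / 6.0 * (k1[n] + 2.0 * k2[n] + 2.0 * k3[n] + k4[n])
            for n, y in zip(inst.state_names, y0)
        ])
    else:
        raise ValueError(f"unknown method {method!r}")
    t_new = t + dt
    _refresh_derived(inst, t_new, rng)
    for v in inst.state_vector():
        if v != v or v in (float("inf"), float("-inf")):
            raise SimulationError(
                f"instance {inst.id!r}: non-finite state at t={t_new}"
            )
    events: list[str] = []
    for test, assignments, event_out in inst.on_conditions:
        if test(inst.scope, rng) != 0.0:
            for var, fn in assignments:
                inst.scope[var] = fn(inst.scope, rng)
            if event_out is not None:
                events.append(event_out)
    return events


# ---------------------------------------------------------------------------
# simulation specifications

@dataclass
class SimulationSpec:
    """LEMS simulation header: duration, step, seed, target, recordings."""

    id: str
    length: str                      # quantity strings, e.g. "1400 ms"
    step: str
    target: str
    seed: int = 12345
    model_files: list[str] = field(default_factory=list)
    output_files: list[tuple[str, list[tuple[str, str]]]] = field(default_factory=list)
    event_files: list[tuple[str, list[tuple[str, str, str]]]] = field(default_factory=list)

    def length_si(self) -> float:
        return parse_quantity(self.length, "time").si_value

    def step_si(self) -> float:
        return parse_quantity(self.step, "time").si_value

    def check(self) -> None:
        if self.length_si() <= 0 or self.step_si() <= 0:
            raise SimulationError("length and step must be positive")
        if self.step_si() > self.length_si():
            raise SimulationError("step must not exceed length")


def read_simulation(source) -> SimulationSpec:
    """Parse a LEMS simulation XML document into a :class:`SimulationSpec`.

    Display/Line elements are accepted and ignored (headless runs).
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source) and Path(str(source)).exists():
        root = etree.parse(str(source)).getroot()
    else:
        text = source if isinstance(source, bytes) else str(source).encode()
        root = etree.fromstring(text)
    sim = root.find("Simulation") if root.tag != "Simulation" else root
    if sim is None:
        raise SimulationError("no <Simulation> element found")
    spec = SimulationSpec(
        id=sim.get("id", "sim"),
        length=sim.get("length", ""),
        step=sim.get("step", ""),
        target=sim.get("target", ""),
        seed=int(sim.get("seed", "12345")),
        model_files=[i.get("file") for i in root.findall("Include")],
    )
    for of in sim.findall("OutputFile"):
        cols = [(c.get("id"), c.get("quantity"))
                for c in of.findall("OutputColumn")]
        spec.output_files.append((of.get("fileName"), cols))
    for ef in sim.findall("EventOutputFile"):
        sels = [(s.get("id"), s.get("select"), s.get("eventPort"))
                for s in ef.findall("EventSelection")]
        spec.event_files.append((ef.get("fileName"), sels))
    return spec


def write_simulation(spec: SimulationSpec) -> str:
    root = etree.Element("Lems")
    for f in spec.model_files:
        etree.SubElement(root, "Include", file=f)
    sim = etree.SubElement(root, "Simulation", id=spec.id, length=spec.length,
                           step=spec.step, target=spec.target,
                           seed=str(spec.seed))
    for path, cols in spec.output_files:
        of = etree.SubElement(sim, "OutputFile", id=Path(path).stem,
                              fileName=path)
        for cid, quantity in cols:
            etree.SubElement(of, "OutputColumn", id=cid, quantity=quantity)
    for path, sels in spec.event_files:
        ef = etree.SubElement(sim, "EventOutputFile", id=Path(path).stem,
                              fileName=path, format="TIME_ID")
        for sid, select, port in sels:
            etree.SubElement(ef, "EventSelection", id=sid, select=select,
                             eventPort=port)
    return etree.tostring(root, pretty_print=True, encoding="unicode")


@dataclass
class RunResult:
    times: list[float]
    columns: dict[str, list[float]]          # quantity path -> trace (SI)
    events: list[tuple[float, str]]          # (time, selection id)
    output_paths: list[Path] = field(default_factory=list)


def _fmt(x: float) -> str:
    s = repr(float(x))
    return s[:-2] if s.endswith(".0") else s


def _resolve_path(path: str,
                  by_path: dict[str, RunnableInstance]) -> tuple[RunnableInstance, str]:
    if "/" not in path:
        raise SimulationError(f"recording path {path!r} lacks a variable")
    target, var = path.rsplit("/", 1)
    inst = by_path.get(target)
    if inst is None:
        raise SimulationError(f"recording path {path!r} does not resolve")
    if var in inst.exposures:
        return inst, inst.exposures[var]
    if var in inst.scope:
        return inst, var
    raise SimulationError(f"no exposure or variable {var!r} on {target!r}")


def run(spec: SimulationSpec, doc: ModelDocument,
        registry: dict[str, ComponentType],
        outdir: str | Path | None = None,
        method: str = "euler") -> RunResult:
    """Integrate the document's network per ``spec`` and record outputs.

    The time loop covers t = 0, dt, ..., length inclusive; every output
    file receives one row per time point (time first, SI values,
    tab-separated).  Event files receive ``time<TAB>selection-id`` rows.
    Identical seeds give byte-identical outputs.
    """
    spec.check()
    rng = random.Random(spec.seed)
    instances = build(doc, registry)
    by_path = {inst.id: inst for inst in instances}

    columns: list[tuple[str, str, RunnableInstance, str]] = []
    for _, cols in spec.output_files:
        for cid, quantity in cols:
            inst, var = _resolve_path(quantity, by_path)
            columns.append((cid, quantity, inst, var))
    selections: list[tuple[str, RunnableInstance, str]] = []
    for _, sels in spec.event_files:
        for sid, select, port in sels:
            inst = by_path.get(select)
            if inst is None:
                raise SimulationError(f"event selection {select!r} does not resolve")
            selections.append((sid, inst, port))

    dt = spec.step_si()
    n_steps = round(spec.length_si() / dt)
    times: list[float] = []
    traces: dict[str, list[float]] = {q: [] for _, q, _, _ in columns}
    events: list[tuple[float, str]] = []

    for inst in instances:
        _refresh_derived(inst, 0.0, rng)

    for k in range(n_steps + 1):
        t = k * dt
        if k > 0:
            for inst in instances:
                emitted = step(inst, (k - 1) * dt, dt, method=method, rng=rng)
                for port in emitted:
                    for sid, sel_inst, sel_port in selections:
                        if sel_inst is inst and sel_port == port:
                            events.append((t, sid))
        times.append(t)
        for _, quantity, inst, var in columns:
            traces[quantity].append(inst.scope[var])

    out_paths: list[Path] = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        for fname, cols in spec.output_files:
            p = outdir / fname
            with open(p, "w") as fh:
                for i, t in enumerate(times):
                    row = [_fmt(t)] + [_fmt(traces[q][i]) for _, q in cols]
                    fh.write("\t".join(row) + "\n")
            out_paths.append(p)
        for fname, sels in spec.event_files:
            p = outdir / fname
            sel_ids = {sid for sid, _, _ in sels}
            with open(p, "w") as fh:
                for t, sid in events:
                    if sid in sel_ids:
                        fh.write(f"{_fmt(t)}\t{sid}\n")
            out_paths.append(p)
    return RunResult(times=times, columns=traces, events=events,
                     output_paths=out_paths)
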