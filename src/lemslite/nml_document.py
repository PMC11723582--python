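"""NeuroML-subset document model and XML serialization.

Documents are held as a generic element tree (:class:`XMLNode`) so that
reading is lossless: unknown elements and attributes are kept in place
for the validator to report rather than dropped.  An explicit grammar
table (:data:`GRAMMAR`) describes the supported subset — the allowed
attributes of each element (with the dimension of quantity-valued
attributes), required attributes and children, cardinality, and child
sequence order.  Component elements such as ``hindmarshRose1984Cell``
take their attribute lists directly from the bundled LEMS standard
library, so the schema and the dynamics definitions cannot drift apart.

Serialization is deterministic (grammar attribute order, canonical
child order), so identical documents produce byte-identical XML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

from lxml import etree

from .lems_model import element_name_for_type, resolve_type, standard_library

__all__ = [
    "XMLNode",
    "ModelDocument",
    "ElementSpec",
    "ChildSpec",
    "GRAMMAR",
    "CONTEXT_GRAMMAR",
    "element_spec",
    "DocumentError",
    "read_nml",
    "write_nml",
    "summarize",
    "node",
]


class DocumentError(ValueError):
    """Raised for write-time grammar violations and malformed XML."""


@dataclass
class XMLNode:
    """One document element: tag, attributes, children.

    ``line`` is the source line for diagnostics and does not take part
    in equality.
    """

    tag: str
    attrs: dict[str, str] = field(default_factory=dict)
    children: list["XMLNode"] = field(default_factory=list)
    line: Optional[int] = field(default=None, compare=False)

    def find_all(self, tag: str) -> list["XMLNode"]:
        return [c for c in self.children if c.tag == tag]

    def find(self, tag: str) -> Optional["XMLNode"]:
        for c in self.children:
            if c.tag == tag:
                return c
        return None

    def iter(self) -> Iterator["XMLNode"]:
        yield self
        for c in self.children:
            yield from c.iter()

    def get(self, attr: str, default: Optional[str] = None) -> Optional[str]:
        return self.attrs.get(attr, default)


def node(tag: str, *children: XMLNode, **attrs: object) -> XMLNode:
    """Convenience constructor used by the fixture generators."""
    return XMLNode(tag, {k: str(v) for k, v in attrs.items()}, list(children))


# ---------------------------------------------------------------------------
# subset grammar
#
# Attribute kinds: "id" and "ref" are identifier tokens, "int"/"float"
# primitive numerals, "path" a population path like "HRPop0[0]",
# "string" free text; any other kind names a dimension and the value is
# a quantity string checked with parse_quantity.

@dataclass(frozen=True)
class ChildSpec:
    tag: str
    min: int
    max: Optional[int]  # None = unbounded


@dataclass(frozen=True)
class ElementSpec:
    attrs: dict[str, str]
    required: frozenset[str]
    children: tuple[ChildSpec, ...] = ()

    def child_spec(self, tag: str) -> Optional[ChildSpec]:
        for cs in self.children:
            if cs.tag == tag:
                return cs
        return None

    def order_index(self, tag: str) -> Optional[int]:
        for i, cs in enumerate(self.children):
            if cs.tag == tag:
                return i
        return None


def _spec(attrs: dict[str, str], required: Optional[set[str]] = None,
          children: tuple[ChildSpec, ...] = ()) -> ElementSpec:
    return ElementSpec(attrs, frozenset(required if required is not None
                                        else attrs), children)


def _component_element_spec(type_name: str) -> ElementSpec:
    """Attribute spec of a component element from its resolved LEMS type."""
    resolved = resolve_type(type_name, _STDLIB)
    attrs = {"id": "id"}
    attrs.update({p.name: p.dimension for p in resolved.parameters})
    return _spec(attrs)


_STDLIB = standard_library()

_POINT = _spec({"x": "float", "y": "float", "z": "float",
                "diameter": "float"})

GRAMMAR: dict[str, ElementSpec] = {
    "neuroml": _spec(
        {"id": "id"},
        {"id"},
        (
            ChildSpec("include", 0, None),
            ChildSpec("ionChannel", 0, None),
            ChildSpec("decayingPoolConcentrationModel", 0, None),
            ChildSpec("expOneSynapse", 0, None),
            ChildSpec(element_name_for_type("HindmarshRose1984Cell"), 0, None),
            ChildSpec("pulseGenerator", 0, None),
            ChildSpec("cell", 0, None),
            ChildSpec("network", 0, None),
        ),
    ),
    "include": _spec({"href": "string"}),
    "ionChannel": _spec({"id": "id", "type": "string",
                         "conductance": "conductance"}, {"id"}),
    "decayingPoolConcentrationModel": _spec(
        {"id": "id", "ion": "string", "restingConc": "concentration",
         "decayConstant": "time", "shellThickness": "length"}, {"id"}),
    "expOneSynapse": _spec(
        {"id": "id", "gbase": "conductance", "erev": "voltage",
         "tauDecay": "time"}),
    "hindmarshRose1984Cell": _component_element_spec("HindmarshRose1984Cell"),
    "pulseGenerator": _component_element_spec("pulseGenerator"),
    "cell": _spec({"id": "id"}, {"id"},
                  (ChildSpec("morphology", 1, 1),
                   ChildSpec("biophysicalProperties", 0, 1))),
    "morphology": _spec({"id": "id"}, {"id"},
                        (ChildSpec("segment", 1, None),
                         ChildSpec("segmentGroup", 0, None))),
    "segment": _spec({"id": "int", "name": "string"}, {"id"},
                     (ChildSpec("parent", 0, 1),
                      ChildSpec("proximal", 0, 1),
                      ChildSpec("distal", 1, 1))),
    "parent": _spec({"segment": "int"}),
    "proximal": _POINT,
    "distal": _POINT,
    "segmentGroup": _spec({"id": "id", "neuroLexId": "string"}, {"id"},
                          (ChildSpec("member", 0, None),
                           ChildSpec("include", 0, None),
                           ChildSpec("property", 0, None))),
    "member": _spec({"segment": "int"}),
    "property": _spec({"tag": "string", "value": "string"}),
    "biophysicalProperties": _spec(
        {"id": "id"}, {"id"},
        (ChildSpec("membraneProperties", 0, 1),
         ChildSpec("intracellularProperties", 0, 1))),
    "membraneProperties": _spec({}, set(),
                                (ChildSpec("channelDensity", 0, None),)),
    "channelDensity": _spec(
        {"id": "id", "ionChannel": "ref", "segmentGroup": "ref",
         "condDensity": "conductanceDensity", "erev": "voltage"},
        {"id", "ionChannel"}),
    "intracellularProperties": _spec({}, set(),
                                     (ChildSpec("species", 0, None),)),
    "species": _spec(
        {"id": "id", "concentrationModel": "ref", "ion": "string",
         "initialConcentration": "concentration",
         "initialExtConcentration": "concentration"},
        {"id", "concentrationModel"}),
    "network": _spec({"id": "id"}, {"id"},
                     (ChildSpec("population", 0, None),
                      ChildSpec("projection", 0, None),
                      ChildSpec("explicitInput", 0, None))),
    "population": _spec(
        {"id": "id", "component": "ref", "size": "int", "type": "string"},
        {"id", "component"},
        (ChildSpec("instance", 0, None),)),
    "instance": _spec({"id": "int"}, {"id"},
                      (ChildSpec("location", 0, 1),)),
    "location": _spec({"x": "float", "y": "float", "z": "float"}),
    "projection": _spec(
        {"id": "id", "presynapticPopulation": "ref",
         "postsynapticPopulation": "ref", "synapse": "ref"},
        children=(ChildSpec("connection", 0, None),)),
    "connection": _spec(
        {"id": "int", "preCellId": "path", "postCellId": "path",
         "preSegmentId": "int", "postSegmentId": "int",
         "preFractionAlong": "float", "postFractionAlong": "float"},
        {"id", "preCellId", "postCellId"}),
    "explicitInput": _spec({"target": "path", "input": "ref"}),
}

#: Context-sensitive overrides keyed by (parent tag, tag): ``include``
#: inside a segmentGroup references another group rather than a file.
CONTEXT_GRAMMAR: dict[tuple[str, str], ElementSpec] = {
    ("segmentGroup", "include"): _spec({"segmentGroup": "ref"}),
}

#: Element names that are "component" elements instantiating a LEMS type.
COMPONENT_ELEMENTS: dict[str, str] = {
    element_name_for_type("HindmarshRose1984Cell"): "HindmarshRose1984Cell",
    "pulseGenerator": "pulseGenerator",
}


def element_spec(tag: str, parent_tag: Optional[str] = None) -> Optional[ElementSpec]:
    if parent_tag is not None and (parent_tag, tag) in CONTEXT_GRAMMAR:
        return CONTEXT_GRAMMAR[(parent_tag, tag)]
    return GRAMMAR.get(tag)


# ---------------------------------------------------------------------------
# document model

@dataclass
class ModelDocument:
    """A NeuroML-subset document: generic tree plus typed accessors."""

    root: XMLNode
    base_path: Optional[Path] = field(default=None, compare=False)

    @property
    def id(self) -> Optional[str]:
        return self.root.get("id")

    @property
    def includes(self) -> list[str]:
        return [c.get("href", "") for c in self.root.find_all("include")]

    @property
    def networks(self) -> list[XMLNode]:
        return self.root.find_all("network")

    @property
    def top_level(self) -> list[XMLNode]:
        """Top-level components: everything except includes and networks."""
        return [c for c in self.root.children
                if c.tag not in ("include", "network")]

    def component(self, component_id: str) -> Optional[XMLNode]:
        for c in self.top_level:
            if c.get("id") == component_id:
                return c
        return None

    def populations(self, network: XMLNode) -> list[XMLNode]:
        return network.find_all("population")

    def population_size(self, pop: XMLNode) -> int:
        instances = pop.find_all("instance")
        if instances:
            return len(instances)
        size = pop.get("size")
        return int(size) if size is not None and size.lstrip("-").isdigit() else 0


def _from_lxml(el: etree._Element) -> XMLNode:
    tag = etree.QName(el).localname if isinstance(el.tag, str) else ""
    n = XMLNode(tag, dict(el.attrib), [], getattr(el, "sourceline", None))
    for child in el:
        if isinstance(child.tag, str):  # skip comments / PIs
            n.children.append(_from_lxml(child))
    return n


def read_nml(source) -> ModelDocument:
    """Read a NeuroML document from a path, XML text, or file object.

    Only well-formedness errors raise; semantic problems (unknown
    elements, bad values, broken references) are preserved in the tree
    for the validator to report.
    """
    base: Optional[Path] = None
    try:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and "<" not in source
        ):
            path = Path(source)
            root_el = etree.parse(str(path)).getroot()
            base = path.resolve().parent
        elif isinstance(source, bytes):
            root_el = etree.fromstring(source)
        elif isinstance(source, str):
            root_el = etree.fromstring(source.encode())
        else:
            root_el = etree.parse(source).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise DocumentError(str(exc)) from exc
    return ModelDocument(_from_lxml(root_el), base_path=base)


def write_nml(doc: ModelDocument) -> str:
    """Serialize deterministically; raises on out-of-grammar content."""
    el = _to_lxml(doc.root, parent_tag=None)
    return etree.tostring(el, pretty_print=True, encoding="unicode",
                          xml_declaration=False)


def _to_lxml(n: XMLNode, parent_tag: Optional[str]) -> etree._Element:
    spec = element_spec(n.tag, parent_tag)
    if spec is None:
        raise DocumentError(f"unknown element {n.tag!r} (not in the supported subset)")
    el = etree.Element(n.tag)
    for name in spec.attrs:
        if name in n.attrs:
            el.set(name, n.attrs[name])
    extra = [a for a in n.attrs if a not in spec.attrs]
    if extra:
        raise DocumentError(f"element {n.tag!r}: unknown attribute(s) {extra}")
    ordered = sorted(
        n.children,
        key=lambda c: (spec.order_index(c.tag)
                       if spec.order_index(c.tag) is not None else -1),
    )
    for c in ordered:
        if spec.child_spec(c.tag) is None:
            raise DocumentError(
                f"element {c.tag!r} not allowed inside {n.tag!r}"
            )
        el.append(_to_lxml(c, n.tag))
    return el


def summarize(doc: ModelDocument) -> str:
    """Plain-text counts of cells, populations, projections and inputs."""
    lines = [f"document: {doc.id or '(no id)'}"]
    cells = [c for c in doc.top_level
             if c.tag in COMPONENT_ELEMENTS or c.tag == "cell"]
    inputs = [c for c in doc.top_level if c.tag == "pulseGenerator"]
    cells = [c for c in cells if c.tag != "pulseGenerator"]
    lines.append(f"cells: {len(cells)}")
    for c in cells:
        lines.append(f"  {c.tag} id={c.get('id')}")
    lines.append(f"input components: {len(inputs)}")
    lines.append(f"networks: {len(doc.networks)}")
    for net in doc.networks:
        pops = doc.populations(net)
        sizes = ", ".join(
            f"{p.get('id')} (size {doc.population_size(p)}, "
            f"component {p.get('component')})" for p in pops
        )
        lines.append(f"  network {net.get('id')}: populations: {len(pops)}"
                     + (f" [{sizes}]" if sizes else ""))
        projs = net.find_all("projection")
        lines.append(f"    projections: {len(projs)}")
        for p in projs:
            lines.append(
                f"      {p.get('id')}: {p.get('presynapticPopulation')} -> "
                f"{p.get('postsynapticPopulation')} "
                f"({len(p.find_all('connection'))} connections)"
            )
        lines.append(f"    inputs: {len(net.find_all('explicitInput'))}")
    return "\n".join(lines)
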