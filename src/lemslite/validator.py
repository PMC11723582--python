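"""Two-level pre-simulation validation of model documents.

Level 1 checks document structure against the subset grammar (names,
types, values, required inclusion, cardinality, hierarchy, sequence
order).  Level 2 runs semantic and logical checks: id uniqueness,
morphology integrity (segments, groups, root conventions), reference
resolution (populations, projections, synapses, ion channels,
concentration models, included files) and population-size consistency.

Problems are reported as ordered :class:`Finding` records keyed by a
stable, closed registry of check identifiers; nothing raises for a
merely invalid document.  A document is valid iff it produced no
error-severity finding.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .dimensions import DimensionError, parse_quantity
from .nml_document import (
    DocumentError,
    ModelDocument,
    XMLNode,
    element_spec,
    read_nml,
)

__all__ = [
    "Finding",
    "ValidationReport",
    "CHECKS",
    "validate_level1",
    "validate_level2",
    "validate",
]


@dataclass(frozen=True)
class Finding:
    check_id: str
    severity: str  # "error" | "warning" | "info"
    path: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def check_ids(self) -> list[str]:
        return [f.check_id for f in self.findings]

    def extend(self, other: "ValidationReport") -> None:
        self.findings.extend(other.findings)

    def to_json(self) -> dict:
        return {
            "valid": self.valid,
            "findings": [
                {"check_id": f.check_id, "severity": f.severity,
                 "path": f.path, "message": f.message}
                for f in self.findings
            ],
        }


#: Closed registry: (check_id, description).  The first seven are
#: structural (schema-level); the rest are semantic checks.
CHECKS: list[tuple[str, str]] = [
    ("schema.names", "element/attribute/parameter names match the subset grammar"),
    ("schema.types", "attribute values have the declared primitive type"),
    ("schema.values", "quantity values follow the declared restrictions"),
    ("schema.inclusion", "required elements and attributes are included"),
    ("schema.cardinality", "element counts respect cardinality limits"),
    ("schema.hierarchy", "children appear under the correct parent elements"),
    ("schema.sequence_order", "children appear in the correct order"),
    ("semantic.top_level_ids", "top-level elements have unique ids"),
    ("semantic.network_ids", "network children have unique ids"),
    ("semantic.segment_ids", "segments in a cell have unique ids"),
    ("semantic.single_root_segment", "exactly one segment is without a parent"),
    ("semantic.segment_group_ids", "segment groups in a cell have unique ids"),
    ("semantic.member_segments", "segments referred to in group members exist"),
    ("semantic.segment_group_defined", "referenced segment groups are defined"),
    ("semantic.segment_group_order", "segment groups are defined before being referenced"),
    ("semantic.included_segment_groups", "groups referenced by group includes exist"),
    ("semantic.number_internal_divisions", "unbranched groups declare a positive numberInternalDivisions"),
    ("semantic.included_files", "included model files exist"),
    ("semantic.population_component", "population component ids exist"),
    ("semantic.ion_channel_exists", "ion channels used by channel densities exist"),
    ("semantic.concentration_model_species", "species reference defined concentration models"),
    ("semantic.population_size", "population size attribute matches instance count"),
    ("semantic.projection_populations", "projection populations exist"),
    ("semantic.connection_segments", "segments used in connections exist"),
    ("semantic.connection_cells", "connection pre/post cells exist and are well formed"),
    ("semantic.projection_synapse", "projection synapse components exist"),
    ("semantic.root_id_zero", "the root segment of a morphology has id 0"),
]

CHECK_IDS = [cid for cid, _ in CHECKS]

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")
_INT_RE = re.compile(r"^[+-]?\d+$")
_PATH_RE = re.compile(r"^(\.\./)?[A-Za-z_][A-Za-z0-9_]*\[\d+\]$")

#: neuroLexId marking an unbranched segment group, which simulators
#: discretize and hence should declare numberInternalDivisions
UNBRANCHED_NEUROLEX_ID = "sao864921383"


def _node_path(ancestry: list[XMLNode]) -> str:
    parts = []
    for n in ancestry:
        ident = n.get("id") or n.get("name")
        parts.append(f"{n.tag}({ident})" if ident else n.tag)
    return "/" + "/".join(parts)


# ---------------------------------------------------------------------------
# level 1: structural checks against the grammar

def validate_level1(doc: ModelDocument, lenient: bool = False) -> ValidationReport:
    """Check the document tree against the subset grammar.

    In lenient mode unknown names are demoted to warnings; everything
    else stays an error.
    """
    report = ValidationReport()
    names_sev = "warning" if lenient else "error"

    def add(check_id: str, path: str, message: str, severity: str = "error") -> None:
        sev = names_sev if check_id == "schema.names" else severity
        report.findings.append(Finding(check_id, sev, path, message))

    def walk(n: XMLNode, parent_tag: Optional[str], ancestry: list[XMLNode]) -> None:
        spec = element_spec(n.tag, parent_tag)
        path = _node_path(ancestry)
        if spec is None:
            return  # unknown element; reported by the parent loop
        # --- attributes
        for attr, value in n.attrs.items():
            kind = spec.attrs.get(attr)
            if kind is None:
                add("schema.names", path,
                    f"unknown attribute {attr!r} on <{n.tag}>")
                continue
            if kind == "int":
                if not _INT_RE.match(value):
                    add("schema.types", path,
                        f"attribute {attr!r} must be an integer, got {value!r}")
            elif kind == "float":
                try:
                    float(value)
                except ValueError:
                    add("schema.types", path,
                        f"attribute {attr!r} must be a number, got {value!r}")
            elif kind in ("id", "ref"):
                if not _IDENT_RE.match(value):
                    add("schema.types", path,
                        f"attribute {attr!r} must be an identifier, got {value!r}")
            elif kind == "path":
                if not _PATH_RE.match(value):
                    add("schema.types", path,
                        f"attribute {attr!r} must be a path like 'pop[0]', got {value!r}")
            elif kind == "string":
                pass
            else:  # a dimension name: quantity string restriction
                try:
                    parse_quantity(value, kind)
                except DimensionError as exc:
                    add("schema.values", path,
                        f"attribute {attr!r}: {exc}")
        for attr in spec.required:
            if attr not in n.attrs:
                add("schema.inclusion", path,
                    f"<{n.tag}> is missing required attribute {attr!r}")
        # --- children
        counts: dict[str, int] = {}
        last_order = -1
        order_flagged = False
        for child in n.children:
            allowed = spec.child_spec(child.tag)
            if element_spec(child.tag, n.tag) is None:
                add("schema.names", path,
                    f"unknown element <{child.tag}> inside <{n.tag}>")
                continue
            if allowed is None:
                add("schema.hierarchy", path,
                    f"<{child.tag}> is not allowed inside <{n.tag}>")
            else:
                counts[child.tag] = counts.get(child.tag, 0) + 1
                idx = spec.order_index(child.tag)
                if idx is not None:
                    if idx < last_order and not order_flagged:
                        add("schema.sequence_order", path,
                            f"<{child.tag}> appears after later-ordered siblings "
                            f"inside <{n.tag}>")
                        order_flagged = True
                    last_order = max(last_order, idx)
            walk(child, n.tag, ancestry + [child])
        for cs in spec.children:
            have = counts.get(cs.tag, 0)
            if have < cs.min:
                add("schema.inclusion", path,
                    f"<{n.tag}> requires at least {cs.min} <{cs.tag}> "
                    f"child(ren), found {have}")
            if cs.max is not None and have > cs.max:
                add("schema.cardinality", path,
                    f"<{n.tag}> allows at most {cs.max} <{cs.tag}> "
                    f"child(ren), found {have}")

    root = doc.root
    if root.tag != "neuroml":
        report.findings.append(Finding(
            "schema.names", names_sev, "/",
            f"root element must be <neuroml>, got <{root.tag}>"))
    else:
        walk(root, None, [root])
    return report


# ---------------------------------------------------------------------------
# level 2: semantic checks

def _dup_finding(check_id: str, path: str, kind: str, ident: str) -> Finding:
    return Finding(check_id, "error", path, f"duplicate {kind} id {ident!r}")


def _morphologies(doc: ModelDocument):
    for cell in doc.root.find_all("cell"):
        morph = cell.find("morphology")
        if morph is not None:
            yield cell, morph


def _segment_ids(morph: XMLNode) -> list[str]:
    return [s.get("id", "") for s in morph.find_all("segment")]


def validate_level2(doc: ModelDocument) -> ValidationReport:
    """Run the semantic check suite; best-effort even on broken structure."""
    report = ValidationReport()
    add = report.findings.append
    root = doc.root

    # semantic.top_level_ids
    seen: set[str] = set()
    for c in root.children:
        ident = c.get("id")
        if ident is None:
            continue
        if ident in seen:
            add(_dup_finding("semantic.top_level_ids",
                             _node_path([root, c]), "top-level", ident))
        seen.add(ident)

    # semantic.network_ids
    for net in doc.networks:
        seen = set()
        for c in net.children:
            ident = c.get("id")
            if ident is None:
                continue
            if ident in seen:
                add(_dup_finding("semantic.network_ids",
                                 _node_path([root, net, c]), "network child",
                                 ident))
            seen.add(ident)

    # morphology checks
    for cell, morph in _morphologies(doc):
        mpath = _node_path([root, cell, morph])
        seg_ids = _segment_ids(morph)
        seen = set()
        for sid in seg_ids:
            if sid in seen:
                add(_dup_finding("semantic.segment_ids", mpath, "segment", sid))
            seen.add(sid)

        roots = [s for s in morph.find_all("segment") if s.find("parent") is None]
        if len(roots) != 1:
            add(Finding("semantic.single_root_segment", "error", mpath,
                        f"expected exactly one parentless segment, found "
                        f"{len(roots)}"))
        elif roots[0].get("id") != "0":
            add(Finding("semantic.root_id_zero", "error", mpath,
                        f"root segment has id {roots[0].get('id')!r}, "
                        f"expected 0"))

        groups = morph.find_all("segmentGroup")
        seen = set()
        for g in groups:
            gid = g.get("id", "")
            if gid in seen:
                add(_dup_finding("semantic.segment_group_ids", mpath,
                                 "segment group", gid))
            seen.add(gid)

        seg_id_set = set(seg_ids)
        group_ids = [g.get("id", "") for g in groups]
        group_order = {gid: i for i, gid in enumerate(group_ids)}
        for gi, g in enumerate(groups):
            gpath = _node_path([root, cell, morph, g])
            for m in g.find_all("member"):
                sid = m.get("segment", "")
                if sid not in seg_id_set:
                    add(Finding("semantic.member_segments", "error", gpath,
                                f"member references missing segment {sid!r}"))
            for inc in g.find_all("include"):
                ref = inc.get("segmentGroup", "")
                if ref not in group_order:
                    add(Finding("semantic.included_segment_groups", "error",
                                gpath,
                                f"include references missing group {ref!r}"))
                elif group_order[ref] > gi:
                    add(Finding("semantic.segment_group_order", "error", gpath,
                                f"group {ref!r} is referenced before its "
                                f"definition"))
            if g.get("neuroLexId") == UNBRANCHED_NEUROLEX_ID:
                props = [p for p in g.find_all("property")
                         if p.get("tag") == "numberInternalDivisions"]
                ok = False
                for p in props:
                    v = p.get("value", "")
                    ok = _INT_RE.match(v) is not None and int(v) > 0
                if not ok:
                    add(Finding("semantic.number_internal_divisions", "warning",
                                gpath,
                                "unbranched segment group lacks a positive "
                                "numberInternalDivisions property"))

        # segment groups referenced from biophysics
        biophys = cell.find("biophysicalProperties")
        if biophys is not None:
            membrane = biophys.find("membraneProperties")
            for cd in (membrane.find_all("channelDensity") if membrane is not None else []):
                ref = cd.get("segmentGroup")
                if ref is not None and ref not in group_order:
                    add(Finding("semantic.segment_group_defined", "error",
                                _node_path([root, cell, biophys, cd]),
                                f"channelDensity references undefined segment "
                                f"group {ref!r}"))

    # semantic.included_files
    base = doc.base_path or Path.cwd()
    for inc in root.find_all("include"):
        href = inc.get("href", "")
        if href and not (base / href).exists():
            add(Finding("semantic.included_files", "error",
                        _node_path([root, inc]),
                        f"included file {href!r} does not exist"))

    top_ids = {c.get("id") for c in root.children if c.get("id")}
    ion_channel_ids = {c.get("id") for c in root.find_all("ionChannel")}
    conc_model_ids = {c.get("id") for c in
                      root.find_all("decayingPoolConcentrationModel")}

    # semantic.ion_channel_exists / semantic.concentration_model_species
    for n in root.iter():
        if n.tag == "channelDensity":
            ref = n.get("ionChannel", "")
            if ref and ref not in ion_channel_ids:
                add(Finding("semantic.ion_channel_exists", "error",
                            f"/channelDensity({n.get('id')})",
                            f"ion channel {ref!r} does not exist"))
        elif n.tag == "species":
            ref = n.get("concentrationModel", "")
            if ref and ref not in conc_model_ids:
                add(Finding("semantic.concentration_model_species", "error",
                            f"/species({n.get('id')})",
                            f"concentration model {ref!r} is not defined"))

    # network-level reference checks
    for net in doc.networks:
        pops = {p.get("id"): p for p in doc.populations(net)}
        for pop in doc.populations(net):
            ppath = _node_path([root, net, pop])
            comp = pop.get("component")
            if comp is not None and comp not in top_ids:
                add(Finding("semantic.population_component", "error", ppath,
                            f"population component {comp!r} does not exist"))
            size = pop.get("size")
            instances = pop.find_all("instance")
            if size is not None and instances and _INT_RE.match(size):
                if int(size) != len(instances):
                    add(Finding("semantic.population_size", "error", ppath,
                                f"size attribute is {size} but "
                                f"{len(instances)} instance(s) are defined"))

        for proj in net.find_all("projection"):
            jpath = _node_path([root, net, proj])
            pre = proj.get("presynapticPopulation", "")
            post = proj.get("postsynapticPopulation", "")
            for ref in (pre, post):
                if ref and ref not in pops:
                    add(Finding("semantic.projection_populations", "error",
                                jpath,
                                f"population {ref!r} does not exist"))
            syn = proj.get("synapse", "")
            if syn and syn not in top_ids:
                add(Finding("semantic.projection_synapse", "error", jpath,
                            f"synapse component {syn!r} does not exist"))
            for conn in proj.find_all("connection"):
                cpath = _node_path([root, net, proj, conn])
                _check_connection(doc, pops, pre, post, conn, cpath, add)

    return report


def _check_connection(doc: ModelDocument, pops: dict[str, XMLNode],
                      pre: str, post: str, conn: XMLNode, cpath: str,
                      add: Callable[[Finding], None]) -> None:
    for attr, pop_id in (("preCellId", pre), ("postCellId", post)):
        raw = conn.get(attr)
        if raw is None:
            continue
        m = _PATH_RE.match(raw)
        if m is None:
            add(Finding("semantic.connection_cells", "error", cpath,
                        f"{attr} {raw!r} is not a well-formed cell path"))
            continue
        path_pop, idx = raw.lstrip("./").split("[")
        idx = int(idx.rstrip("]"))
        pop = pops.get(path_pop)
        if pop is None or path_pop != pop_id:
            add(Finding("semantic.connection_cells", "error", cpath,
                        f"{attr} {raw!r} does not reference population "
                        f"{pop_id!r}"))
            continue
        if idx >= doc.population_size(pop):
            add(Finding("semantic.connection_cells", "error", cpath,
                        f"{attr} {raw!r}: index out of range for population "
                        f"of size {doc.population_size(pop)}"))
            continue
        seg_attr = "preSegmentId" if attr == "preCellId" else "postSegmentId"
        seg = conn.get(seg_attr)
        if seg is not None and _INT_RE.match(seg):
            comp = doc.component(pop.get("component", ""))
            if comp is not None and comp.tag == "cell":
                morph = comp.find("morphology")
                if morph is not None and seg not in set(_segment_ids(morph)):
                    add(Finding("semantic.connection_segments", "error", cpath,
                                f"{seg_attr} {seg!r} does not exist in cell "
                                f"{comp.get('id')!r}"))


# ---------------------------------------------------------------------------
# multi-file entry point

def validate(files, level: str = "all",
             lenient: bool = False) -> tuple[ValidationReport, int]:
    """Validate one or more files; returns (report, exit_code).

    Exit codes: 0 valid, 1 findings with error severity, 2 unreadable or
    malformed input.  Files included by a document (that exist) are
    validated as well.
    """
    if isinstance(files, (str, Path)):
        files = [files]
    report = ValidationReport()
    queue = [Path(f) for f in files]
    seen: set[Path] = set()
    while queue:
        path = queue.pop(0)
        rp = path.resolve()
        if rp in seen:
            continue
        seen.add(rp)
        try:
            doc = read_nml(path)
        except DocumentError as exc:
            return report, 2
        if level in ("1", "all", 1):
            report.extend(validate_level1(doc, lenient=lenient))
        if level in ("2", "all", 2):
            report.extend(validate_level2(doc))
        base = doc.base_path or Path.cwd()
        for href in doc.includes:
            inc = base / href
            if inc.exists():
                queue.append(inc)
    return report, (0 if report.valid else 1)
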