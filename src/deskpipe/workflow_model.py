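"""Document model for the ``.pipe.xml`` workflow dialect.

A workflow is a directed graph of nodes — executable modules (referenced,
never embedded), data sources, study-design sources, conditionals, loop
groups and repeat-until wrappers — joined by typed connections from output
ports to input ports.  Connections may be flagged as *smartlines*, in which
case mismatched file formats/voxel dtypes are reconciled by automatically
inserted conversion jobs at expansion time.

The dialect is defined by this package (documented in ``docs/pipe-dialect.md``
with a schema in ``docs/pipe.xsd``); element and attribute spellings are our
own, the concepts (module-by-reference, parameter metadata, variables,
conditionals, loop groups) follow the workflow environment this engine
models.
"""

from __future__ import annotations

import shlex
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping

from .predicates import Predicate, PredicateError

__all__ = [
    "ParameterSpec",
    "ModuleSpec",
    "DataSourceSpec",
    "StudySourceSpec",
    "GraphSpec",
    "ConditionalSpec",
    "LoopGroupSpec",
    "RepeatUntilSpec",
    "Connection",
    "WorkflowSpec",
    "Finding",
    "ValidationReport",
    "WorkflowParseError",
    "SchemaError",
    "ExportError",
    "parse_workflow",
    "parse_workflow_file",
    "serialize_workflow",
    "validate_workflow",
    "export_script",
    "substitute_variables",
    "FORMAT_EXTENSIONS",
]


class WorkflowParseError(ValueError):
    """Malformed XML; carries the source line where available."""


class SchemaError(ValueError):
    """Well-formed XML that violates the dialect (unknown node kind,
    duplicate id, dangling connection reference...)."""


class ExportError(ValueError):
    """Raised when a workflow cannot be statically flattened to a script."""


FORMAT_EXTENSIONS = {
    "nifti-1": ".nii",
    "analyze-7.5": ".img",
    "raw-volume": ".raw",
    "csv": ".csv",
    "xml-metadata": ".xml",
    "any": ".out",
}

_PARAM_KINDS = {"file", "string", "number", "enumeration", "flag"}
_DTYPES = {"byte", "short", "float", "none"}


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    direction: str  # input | output
    kind: str  # file | string | number | enumeration | flag
    format_tag: str | None = None  # file-format identifier, None for non-files
    dtype_tag: str | None = None  # byte | short | float | None
    cardinality: str = "scalar"  # scalar | list
    required: bool = True
    default: str | None = None
    binding: str | None = None  # "pos:N" or "flag:--name" or "flag:-x"

    def __post_init__(self) -> None:
        if self.direction not in ("input", "output"):
            raise SchemaError(f"parameter {self.name!r}: bad direction {self.direction!r}")
        if self.kind not in _PARAM_KINDS:
            raise SchemaError(f"parameter {self.name!r}: bad kind {self.kind!r}")
        if self.direction == "output" and self.kind != "file":
            raise SchemaError(f"output parameter {self.name!r} must have kind=file")
        if self.cardinality == "list" and self.kind == "flag":
            raise SchemaError(f"parameter {self.name!r}: list cardinality not allowed on flags")
        if self.dtype_tag is not None and self.dtype_tag not in _DTYPES:
            raise SchemaError(f"parameter {self.name!r}: bad dtype {self.dtype_tag!r}")


@dataclass(frozen=True)
class ModuleSpec:
    id: str
    label: str
    executable: str
    parameters: tuple[ParameterSpec, ...] = ()
    metadata: Mapping[str, str] = field(default_factory=dict)
    environment: str = ""

    def __post_init__(self) -> None:
        if not self.executable:
            raise SchemaError(f"module {self.id!r}: executable must be non-empty")
        names = [p.name for p in self.parameters]
        if len(names) != len(set(names)):
            raise SchemaError(f"module {self.id!r}: duplicate parameter names")

    def param(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def inputs(self) -> tuple[ParameterSpec, ...]:
        return tuple(p for p in self.parameters if p.direction == "input")

    @property
    def outputs(self) -> tuple[ParameterSpec, ...]:
        return tuple(p for p in self.parameters if p.direction == "output")


@dataclass(frozen=True)
class DataSourceSpec:
    """A literal list of values feeding downstream inputs via port ``out``."""

    id: str
    items: tuple[str, ...] = ()
    format_tag: str | None = None
    dtype_tag: str | None = None


@dataclass(frozen=True)
class StudySourceSpec:
    """A study-design data source: per-subject image paths plus metadata.

    ``table`` names a CSV study table (header row mandatory); ``path_column``
    is the column holding the per-subject image path.  The source exposes the
    image path on port ``out`` and attaches the full metadata record to each
    instance for conditional predicates downstream.
    """

    id: str
    table: str
    path_column: str
    format_tag: str | None = None
    cohort: str | None = None  # optional predicate restricting the subjects


@dataclass(frozen=True)
class Connection:
    source: str
    source_port: str
    target: str
    target_port: str
    smartline: bool = False

    def sort_key(self) -> tuple:
        return (self.source, self.source_port, self.target, self.target_port)


@dataclass(frozen=True)
class GraphSpec:
    """A nested node graph (conditional branch or loop-group body).

    Connections inside the graph may reference the pseudo-node ``@`` whose
    ports are the enclosing node's input ports (or the loop iteration
    variable).  ``exports`` maps exported output-port names to
    ``(node id, parameter name)`` inside the graph.
    """

    nodes: tuple = ()
    connections: tuple[Connection, ...] = ()
    variables: Mapping[str, Any] = field(default_factory=dict)
    exports: Mapping[str, tuple[str, str]] = field(default_factory=dict)

    def node_map(self) -> dict[str, Any]:
        return {n.id: n for n in self.nodes}


@dataclass(frozen=True)
class ConditionalSpec:
    """If-else flow of control.  The predicate is evaluated per instance
    against metadata fields and workflow variables; both branches must export
    identically named output ports."""

    id: str
    predicate: str
    inputs: tuple[str, ...]
    true_branch: GraphSpec
    false_branch: GraphSpec

    def __post_init__(self) -> None:
        t = set(self.true_branch.exports)
        f = set(self.false_branch.exports)
        if t != f:
            raise SchemaError(
                f"conditional {self.id!r}: branches export different ports "
                f"({sorted(t)} vs {sorted(f)})"
            )

    @property
    def output_ports(self) -> tuple[str, ...]:
        return tuple(sorted(self.true_branch.exports))


@dataclass(frozen=True)
class LoopGroupSpec:
    """Loop group: the body is replicated once per iteration-source item
    before execution begins (iteration counts are static)."""

    id: str
    iteration_source: str  # node id of a data/study source, or list variable
    iteration_var: str
    body: GraphSpec

    @property
    def output_ports(self) -> tuple[str, ...]:
        return tuple(sorted(self.body.exports))


@dataclass(frozen=True)
class RepeatUntilSpec:
    """Dynamic repeat-until looping at the individual module level.

    The module is re-executed until ``condition`` (a predicate over values
    parsed from the module's outputs) is true or ``max_iter`` is reached.
    Dynamic by nature: cannot be exported to a static script.
    """

    id: str
    module: ModuleSpec
    condition: str
    max_iter: int = 10


@dataclass(frozen=True)
class WorkflowSpec:
    id: str
    nodes: tuple = ()
    connections: tuple[Connection, ...] = ()
    variables: Mapping[str, Any] = field(default_factory=dict)

    def node_map(self) -> dict[str, Any]:
        return {n.id: n for n in self.nodes}


@dataclass(frozen=True)
class Finding:
    code: str  # type-mismatch | unbound-input | cycle | cardinality-conflict |
    #            unresolved-variable | unsatisfiable-conversion
    message: str
    node: str | None = None
    port: str | None = None


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def add(self, code: str, message: str, node: str | None = None, port: str | None = None) -> None:
        self.findings.append(Finding(code, message, node, port))

    def __str__(self) -> str:
        if self.ok:
            return "valid: no findings"
        lines = []
        for f in self.findings:
            loc = f" [{f.node}{'.' + f.port if f.port else ''}]" if f.node else ""
            lines.append(f"{f.code}{loc}: {f.message}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# variable substitution
# ---------------------------------------------------------------------------

import re as _re

_VAR_RE = _re.compile(r"\$\{([A-Za-z_][A-Za-z0-9_]*)\}")


def variable_tokens(text: str) -> list[str]:
    return _VAR_RE.findall(text)


def substitute_variables(text: str, scopes: Iterable[Mapping[str, Any]]) -> str:
    """Replace ``${name}`` tokens; later scopes shadow earlier ones."""
    merged: dict[str, Any] = {}
    for scope in scopes:
        merged.update(scope)

    def repl(m: _re.Match) -> str:
        name = m.group(1)
        if name not in merged:
            raise KeyError(name)
        value = merged[name]
        if isinstance(value, (list, tuple)):
            raise KeyError(f"{name} is a list variable, not substitutable inline")
        return str(value)

    return _VAR_RE.sub(repl, text)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_workflow(document: str) -> WorkflowSpec:
    """Parse a ``.pipe.xml`` document into a :class:`WorkflowSpec`.

    Raises :class:`WorkflowParseError` for malformed XML (with the line
    number) and :class:`SchemaError` for dialect violations.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        line = exc.position[0] if exc.position else "?"
        raise WorkflowParseError(f"malformed XML at line {line}: {exc}") from exc
    if root.tag != "pipeline":
        raise SchemaError(f"root element must be <pipeline>, got <{root.tag}>")
    wf_id = root.get("id")
    if not wf_id:
        raise SchemaError("<pipeline> requires an id attribute")

    nodes: list[Any] = []
    connections: list[Connection] = []
    variables: dict[str, Any] = {}
    seen_ids: set[str] = set()

    for child in root:
        if child.tag == "variables":
            variables.update(_parse_variables(child))
        elif child.tag == "connection":
            connections.append(_parse_connection(child))
        else:
            node = _parse_node(child)
            if node.id in seen_ids:
                raise SchemaError(f"duplicate node id {node.id!r}")
            seen_ids.add(node.id)
            nodes.append(node)

    spec = WorkflowSpec(
        id=wf_id,
        nodes=tuple(nodes),
        connections=tuple(connections),
        variables=variables,
    )
    _check_connection_references(spec)
    return spec


def parse_workflow_file(path: str) -> WorkflowSpec:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_workflow(fh.read())


def _parse_variables(el: ET.Element) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for var in el:
        if var.tag != "variable":
            raise SchemaError(f"unexpected element <{var.tag}> inside <variables>")
        name = var.get("name")
        if not name:
            raise SchemaError("<variable> requires a name attribute")
        items = [i.text or "" for i in var.findall("item")]
        if items:
            out[name] = items
        else:
            out[name] = var.get("value", "")
    return out


def _parse_connection(el: ET.Element) -> Connection:
    for attr in ("source", "sourcePort", "target", "targetPort"):
        if el.get(attr) is None:
            raise SchemaError(f"<connection> missing attribute {attr!r}")
    return Connection(
        source=el.get("source"),
        source_port=el.get("sourcePort"),
        target=el.get("target"),
        target_port=el.get("targetPort"),
        smartline=el.get("smartline", "false").lower() == "true",
    )


def _parse_parameter(el: ET.Element, owner: str) -> ParameterSpec:
    name = el.get("name")
    if not name:
        raise SchemaError(f"module {owner!r}: <parameter> requires a name")
    return ParameterSpec(
        name=name,
        direction=el.get("direction", "input"),
        kind=el.get("kind", "string"),
        format_tag=el.get("format"),
        dtype_tag=el.get("dtype"),
        cardinality=el.get("cardinality", "scalar"),
        required=el.get("required", "true").lower() == "true",
        default=el.get("default"),
        binding=el.get("binding"),
    )


def _parse_module(el: ET.Element) -> ModuleSpec:
    mod_id = el.get("id")
    if not mod_id:
        raise SchemaError("<module> requires an id attribute")
    meta_el = el.find("metadata")
    metadata = dict(meta_el.attrib) if meta_el is not None else {}
    env_el = el.find("environment")
    return ModuleSpec(
        id=mod_id,
        label=el.get("label", mod_id),
        executable=el.get("executable", ""),
        parameters=tuple(
            _parse_parameter(p, mod_id) for p in el.findall("parameter")
        ),
        metadata=metadata,
        environment=(env_el.text or "") if env_el is not None else "",
    )


def _parse_graph(el: ET.Element) -> GraphSpec:
    nodes: list[Any] = []
    connections: list[Connection] = []
    variables: dict[str, Any] = {}
    exports: dict[str, tuple[str, str]] = {}
    for child in el:
        if child.tag == "variables":
            variables.update(_parse_variables(child))
        elif child.tag == "connection":
            connections.append(_parse_connection(child))
        elif child.tag == "export":
            port = child.get("port")
            node = child.get("node")
            param = child.get("parameter")
            if not (port and node and param):
                raise SchemaError("<export> requires port, node and parameter")
            exports[port] = (node, param)
        else:
            nodes.append(_parse_node(child))
    return GraphSpec(
        nodes=tuple(nodes),
        connections=tuple(connections),
        variables=variables,
        exports=exports,
    )


def _parse_node(el: ET.Element):
    if el.tag == "module":
        return _parse_module(el)
    if el.tag == "dataSource":
        if not el.get("id"):
            raise SchemaError("<dataSource> requires an id attribute")
        return DataSourceSpec(
            id=el.get("id"),
            items=tuple(i.text or "" for i in el.findall("item")),
            format_tag=el.get("format"),
            dtype_tag=el.get("dtype"),
        )
    if el.tag == "studySource":
        if not el.get("id"):
            raise SchemaError("<studySource> requires an id attribute")
        if not el.get("table") or not el.get("pathColumn"):
            raise SchemaError("<studySource> requires table and pathColumn")
        return StudySourceSpec(
            id=el.get("id"),
            table=el.get("table"),
            path_column=el.get("pathColumn"),
            format_tag=el.get("format"),
            cohort=el.get("cohort"),
        )
    if el.tag == "conditional":
        cond_id = el.get("id")
        if not cond_id or el.get("predicate") is None:
            raise SchemaError("<conditional> requires id and predicate")
        branches: dict[str, GraphSpec] = {}
        inputs: list[str] = []
        for child in el:
            if child.tag == "input":
                port = child.get("port")
                if not port:
                    raise SchemaError(f"conditional {cond_id!r}: <input> requires port")
                inputs.append(port)
            elif child.tag == "branch":
                which = child.get("which")
                if which not in ("true", "false"):
                    raise SchemaError(f"conditional {cond_id!r}: branch which must be true/false")
                branches[which] = _parse_graph(child)
            else:
                raise SchemaError(f"unexpected element <{child.tag}> in conditional")
        if set(branches) != {"true", "false"}:
            raise SchemaError(f"conditional {cond_id!r}: needs exactly one true and one false branch")
        return ConditionalSpec(
            id=cond_id,
            predicate=el.get("predicate"),
            inputs=tuple(inputs),
            true_branch=branches["true"],
            false_branch=branches["false"],
        )
    if el.tag == "loopGroup":
        lg_id = el.get("id")
        if not lg_id or not el.get("iterationSource") or not el.get("iterationVar"):
            raise SchemaError("<loopGroup> requires id, iterationSource and iterationVar")
        body_el = el.find("body")
        if body_el is None:
            raise SchemaError(f"loopGroup {lg_id!r}: missing <body>")
        body = _parse_graph(body_el)
        # exports may sit at group level for readability
        exports = dict(body.exports)
        for exp in el.findall("export"):
            exports[exp.get("port")] = (exp.get("node"), exp.get("parameter"))
        body = replace(body, exports=exports)
        return LoopGroupSpec(
            id=lg_id,
            iteration_source=el.get("iterationSource"),
            iteration_var=el.get("iterationVar"),
            body=body,
        )
    if el.tag == "repeatUntil":
        ru_id = el.get("id")
        if not ru_id or el.get("condition") is None:
            raise SchemaError("<repeatUntil> requires id and condition")
        mod_el = el.find("module")
        if mod_el is None:
            raise SchemaError(f"repeatUntil {ru_id!r}: missing <module>")
        return RepeatUntilSpec(
            id=ru_id,
            module=_parse_module(mod_el),
            condition=el.get("condition"),
            max_iter=int(el.get("maxIter", "10")),
        )
    raise SchemaError(f"unknown node kind <{el.tag}>")


def _node_ports(node: Any) -> tuple[set[str], set[str]]:
    """Return (input ports, output ports) of a top-level node."""
    if isinstance(node, ModuleSpec):
        return ({p.name for p in node.inputs}, {p.name for p in node.outputs})
    if isinstance(node, (DataSourceSpec, StudySourceSpec)):
        return (set(), {"out"})
    if isinstance(node, ConditionalSpec):
        return (set(node.inputs), set(node.output_ports))
    if isinstance(node, LoopGroupSpec):
        return (set(), set(node.output_ports))
    if isinstance(node, RepeatUntilSpec):
        return (
            {p.name for p in node.module.inputs},
            {p.name for p in node.module.outputs},
        )
    raise AssertionError(type(node))


def _check_connection_references(spec: WorkflowSpec | GraphSpec, context: str = "") -> None:
    nodes = spec.node_map()
    for conn in spec.connections:
        for end, port, is_source in (
            (conn.source, conn.source_port, True),
            (conn.target, conn.target_port, False),
        ):
            if end == "@":
                continue  # enclosing-node pseudo ports, resolved at expansion
            if end not in nodes:
                raise SchemaError(
                    f"connection references missing node id {end!r}{context}"
                )
            ins, outs = _node_ports(nodes[end])
            ports = outs if is_source else ins
            if port not in ports:
                raise SchemaError(
                    f"connection references missing port {end}.{port}{context}"
                )
    for node in spec.nodes:
        if isinstance(node, ConditionalSpec):
            _check_connection_references(node.true_branch, f" (in {node.id}/true)")
            _check_connection_references(node.false_branch, f" (in {node.id}/false)")
        elif isinstance(node, LoopGroupSpec):
            _check_connection_references(node.body, f" (in {node.id})")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def serialize_workflow(spec: WorkflowSpec) -> str:
    """Serialize to XML text.  Deterministic: nodes ordered by id,
    connections sorted, attributes in a fixed order."""
    root = ET.Element("pipeline", {"id": spec.id})
    _emit_variables(root, spec.variables)
    for node in sorted(spec.nodes, key=lambda n: n.id):
        _emit_node(root, node)
    for conn in sorted(spec.connections, key=Connection.sort_key):
        _emit_connection(root, conn)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode") + "\n"


def _emit_variables(parent: ET.Element, variables: Mapping[str, Any]) -> None:
    if not variables:
        return
    el = ET.SubElement(parent, "variables")
    for name in sorted(variables):
        value = variables[name]
        if isinstance(value, (list, tuple)):
            var = ET.SubElement(el, "variable", {"name": name})
            for item in value:
                ET.SubElement(var, "item").text = str(item)
        else:
            ET.SubElement(el, "variable", {"name": name, "value": str(value)})


def _emit_connection(parent: ET.Element, conn: Connection) -> None:
    attrs = {
        "source": conn.source,
        "sourcePort": conn.source_port,
        "target": conn.target,
        "targetPort": conn.target_port,
    }
    if conn.smartline:
        attrs["smartline"] = "true"
    ET.SubElement(parent, "connection", attrs)


def _emit_module(parent: ET.Element, node: ModuleSpec) -> None:
    el = ET.SubElement(
        parent,
        "module",
        {"id": node.id, "label": node.label, "executable": node.executable},
    )
    if node.metadata:
        ET.SubElement(el, "metadata", {k: str(v) for k, v in sorted(node.metadata.items())})
    if node.environment:
        ET.SubElement(el, "environment").text = node.environment
    for p in node.parameters:
        attrs = {"name": p.name, "direction": p.direction, "kind": p.kind}
        if p.format_tag is not None:
            attrs["format"] = p.format_tag
        if p.dtype_tag is not None:
            attrs["dtype"] = p.dtype_tag
        if p.cardinality != "scalar":
            attrs["cardinality"] = p.cardinality
        attrs["required"] = "true" if p.required else "false"
        if p.default is not None:
            attrs["default"] = p.default
        if p.binding is not None:
            attrs["binding"] = p.binding
        ET.SubElement(el, "parameter", attrs)


def _emit_graph_contents(el: ET.Element, graph: GraphSpec) -> None:
    _emit_variables(el, graph.variables)
    for node in sorted(graph.nodes, key=lambda n: n.id):
        _emit_node(el, node)
    for conn in sorted(graph.connections, key=Connection.sort_key):
        _emit_connection(el, conn)
    for port in sorted(graph.exports):
        node, param = graph.exports[port]
        ET.SubElement(el, "export", {"port": port, "node": node, "parameter": param})


def _emit_node(parent: ET.Element, node: Any) -> None:
    if isinstance(node, ModuleSpec):
        _emit_module(parent, node)
    elif isinstance(node, DataSourceSpec):
        attrs = {"id": node.id}
        if node.format_tag:
            attrs["format"] = node.format_tag
        if node.dtype_tag:
            attrs["dtype"] = node.dtype_tag
        el = ET.SubElement(parent, "dataSource", attrs)
        for item in node.items:
            ET.SubElement(el, "item").text = item
    elif isinstance(node, StudySourceSpec):
        attrs = {"id": node.id, "table": node.table, "pathColumn": node.path_column}
        if node.format_tag:
            attrs["format"] = node.format_tag
        if node.cohort:
            attrs["cohort"] = node.cohort
        ET.SubElement(parent, "studySource", attrs)
    elif isinstance(node, ConditionalSpec):
        el = ET.SubElement(parent, "conditional", {"id": node.id, "predicate": node.predicate})
        for port in node.inputs:
            ET.SubElement(el, "input", {"port": port})
        for which, branch in (("true", node.true_branch), ("false", node.false_branch)):
            bel = ET.SubElement(el, "branch", {"which": which})
            _emit_graph_contents(bel, branch)
    elif isinstance(node, LoopGroupSpec):
        el = ET.SubElement(
            parent,
            "loopGroup",
            {
                "id": node.id,
                "iterationSource": node.iteration_source,
                "iterationVar": node.iteration_var,
            },
        )
        body = ET.SubElement(el, "body")
        _emit_variables(body, node.body.variables)
        for inner in sorted(node.body.nodes, key=lambda n: n.id):
            _emit_node(body, inner)
        for conn in sorted(node.body.connections, key=Connection.sort_key):
            _emit_connection(body, conn)
        for port in sorted(node.body.exports):
            inner, param = node.body.exports[port]
            ET.SubElement(el, "export", {"port": port, "node": inner, "parameter": param})
    elif isinstance(node, RepeatUntilSpec):
        el = ET.SubElement(
            parent,
            "repeatUntil",
            {"id": node.id, "condition": node.condition, "maxIter": str(node.max_iter)},
        )
        _emit_module(el, node.module)
    else:
        raise AssertionError(f"cannot serialize node of type {type(node)}")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _port_format(node: Any, port: str, is_output: bool) -> tuple[str | None, str | None]:
    """(format_tag, dtype_tag) of a port, or (None, None) when untyped."""
    if isinstance(node, ModuleSpec):
        try:
            p = node.param(port)
        except KeyError:
            return (None, None)
        return (p.format_tag, p.dtype_tag)
    if isinstance(node, DataSourceSpec):
        return (node.format_tag, node.dtype_tag)
    if isinstance(node, StudySourceSpec):
        return (node.format_tag, None)
    if isinstance(node, RepeatUntilSpec):
        return _port_format(node.module, port, is_output)
    if isinstance(node, ConditionalSpec) and is_output:
        inner, param = node.true_branch.exports[port]
        return _port_format(node.true_branch.node_map()[inner], param, True)
    if isinstance(node, LoopGroupSpec) and is_output:
        inner, param = node.body.exports[port]
        return _port_format(node.body.node_map()[inner], param, True)
    return (None, None)


def _formats_conflict(src: str | None, dst: str | None) -> bool:
    if src is None or dst is None:
        return False
    if "any" in (src, dst):
        return False
    return src != dst


def validate_workflow(spec: WorkflowSpec) -> ValidationReport:
    """Static consistency check: data-type/parameter matches, binding
    completeness, acyclicity, cardinality, variable resolution.

    Findings are data; an empty report means the workflow is runnable.
    """
    import networkx as nx

    report = ValidationReport()
    _validate_graph(spec, report, scopes=({},), graph_name="")

    # cycle detection on the top-level node graph
    g = nx.DiGraph()
    for node in spec.nodes:
        g.add_node(node.id)
    for conn in spec.connections:
        if conn.source != "@" and conn.target != "@":
            g.add_edge(conn.source, conn.target)
    for cycle in nx.simple_cycles(g):
        report.add(
            "cycle",
            "cycle through nodes: " + " -> ".join(sorted(cycle)),
            node=sorted(cycle)[0],
        )

    # static cardinality conflicts: two list-valued inputs of known,
    # different lengths on the same module
    lengths = _static_lengths(spec)
    per_target: dict[str, dict[str, int]] = {}
    for conn in spec.connections:
        n = lengths.get(conn.source)
        if n is not None and n > 1:
            per_target.setdefault(conn.target, {})[conn.target_port] = n
    for target, ports in per_target.items():
        if len(set(ports.values())) > 1:
            detail = ", ".join(f"{p}={n}" for p, n in sorted(ports.items()))
            report.add(
                "cardinality-conflict",
                f"list inputs of different lengths on {target!r}: {detail}",
                node=target,
            )
    return report


def _static_lengths(spec: WorkflowSpec | GraphSpec) -> dict[str, int]:
    out: dict[str, int] = {}
    for node in spec.nodes:
        if isinstance(node, DataSourceSpec):
            out[node.id] = len(node.items)
    return out


def _validate_graph(
    spec: WorkflowSpec | GraphSpec,
    report: ValidationReport,
    scopes: tuple[Mapping[str, Any], ...],
    graph_name: str,
) -> None:
    nodes = spec.node_map()
    scopes = scopes + (spec.variables,)
    known_vars: set[str] = set()
    for scope in scopes:
        known_vars.update(scope)

    bound: dict[tuple[str, str], Connection] = {}
    for conn in spec.connections:
        bound[(conn.target, conn.target_port)] = conn

    for node in spec.nodes:
        loc = f"{graph_name}{node.id}"
        if isinstance(node, (ModuleSpec, RepeatUntilSpec)):
            mod = node.module if isinstance(node, RepeatUntilSpec) else node
            for p in mod.inputs:
                if p.required and p.default is None and (node.id, p.name) not in bound:
                    report.add(
                        "unbound-input",
                        f"required input {node.id}.{p.name} has no connection, "
                        "variable, default or literal binding",
                        node=loc,
                        port=p.name,
                    )
                if p.default is not None:
                    for tok in variable_tokens(p.default):
                        if tok not in known_vars:
                            report.add(
                                "unresolved-variable",
                                f"unresolved variable ${{{tok}}} in {node.id}.{p.name}",
                                node=loc,
                                port=p.name,
                            )
        elif isinstance(node, DataSourceSpec):
            for item in node.items:
                for tok in variable_tokens(item):
                    if tok not in known_vars:
                        report.add(
                            "unresolved-variable",
                            f"unresolved variable ${{{tok}}} in data source {node.id}",
                            node=loc,
                        )
        elif isinstance(node, ConditionalSpec):
            try:
                Predicate(node.predicate)
            except PredicateError as exc:
                report.add("predicate-error", str(exc), node=loc)
            inner_scopes = scopes
            _validate_graph(node.true_branch, report, inner_scopes, f"{loc}/true/")
            _validate_graph(node.false_branch, report, inner_scopes, f"{loc}/false/")
        elif isinstance(node, LoopGroupSpec):
            src = node.iteration_source
            if src not in nodes and src not in known_vars:
                report.add(
                    "unbound-input",
                    f"loop group {node.id}: iteration source {src!r} is neither "
                    "a node id nor a list variable",
                    node=loc,
                )
            body_scopes = scopes + ({node.iteration_var: ""},)
            _validate_graph(node.body, report, body_scopes, f"{loc}/")

    for conn in spec.connections:
        if conn.source == "@" or conn.target == "@":
            continue
        src_fmt, src_dtype = _port_format(nodes[conn.source], conn.source_port, True)
        dst_fmt, dst_dtype = _port_format(nodes[conn.target], conn.target_port, False)
        if not conn.smartline and (
            _formats_conflict(src_fmt, dst_fmt) or _formats_conflict(src_dtype, dst_dtype)
        ):
            report.add(
                "type-mismatch",
                f"connection {conn.source}.{conn.source_port} "
                f"({src_fmt}/{src_dtype}) -> {conn.target}.{conn.target_port} "
                f"({dst_fmt}/{dst_dtype}) without smartline",
                node=f"{graph_name}{conn.target}",
                port=conn.target_port,
            )


# ---------------------------------------------------------------------------
# command-line construction (shared by engine and script export)
# ---------------------------------------------------------------------------


def build_argv(module: ModuleSpec, values: Mapping[str, Any]) -> list[str]:
    """Assemble the command line for one module instance.

    ``values`` maps parameter names to bound values (file paths, literals).
    Token order: executable, then flag-bound parameters in declaration order,
    then positional parameters ordered by their ``pos:N`` index.  List-valued
    parameters contribute one token per element.
    """
    argv: list[str] = [module.executable]
    positionals: list[tuple[int, list[str]]] = []
    for p in module.parameters:
        if p.name not in values or values[p.name] is None:
            continue
        value = values[p.name]
        tokens = [str(v) for v in value] if isinstance(value, (list, tuple)) else [str(value)]
        binding = p.binding or f"pos:{len(positionals)}"
        if binding.startswith("flag:"):
            flag = binding[len("flag:"):]
            if p.kind == "flag":
                if _flag_set(value):
                    argv.append(flag)
            else:
                for tok in tokens:
                    argv.extend([flag, tok])
        elif binding.startswith("pos:"):
            positionals.append((int(binding[len("pos:"):]), tokens))
        else:
            raise SchemaError(f"module {module.id!r}: bad binding {binding!r}")
    for _, tokens in sorted(positionals, key=lambda t: t[0]):
        argv.extend(tokens)
    return argv


def _flag_set(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).lower() in ("1", "true", "yes", "on")


# ---------------------------------------------------------------------------
# script export
# ---------------------------------------------------------------------------


def export_script(spec: WorkflowSpec, dialect: str, workdir: str = "work") -> str:
    """Export a valid workflow to a POSIX shell script or makefile.

    The shell script runs commands in a topological order with parallel
    groups delimited by comments; executing it reproduces the engine's
    outputs (same generated paths under ``workdir``).  The make dialect
    emits one target per output file.

    Dynamic constructs (repeat-until) cannot be statically flattened and
    raise :class:`ExportError` naming the node.
    """
    from .engine import expand  # deferred: engine imports this module

    for node in spec.nodes:
        if isinstance(node, RepeatUntilSpec):
            raise ExportError(
                f"node {node.id!r} is a dynamic repeat-until construct and "
                "cannot be exported to a static script"
            )
    report = validate_workflow(spec)
    if not report.ok:
        raise ExportError(f"workflow is not valid: {report.findings[0].message}")

    dag = expand(spec, workdir=workdir)
    if dialect == "shell":
        return _export_shell(dag)
    if dialect == "make":
        return _export_make(dag)
    raise ValueError(f"unknown script dialect {dialect!r} (expected make|shell)")


def _topo_levels(dag) -> list[list[str]]:
    import networkx as nx

    return [sorted(level) for level in nx.topological_generations(dag.graph)]


def _export_shell(dag) -> str:
    lines = ["#!/bin/sh", "# generated by deskpipe export-script", "set -e", ""]
    dirs = sorted({_dirname(p) for job in dag.jobs.values() for p in job.output_paths})
    for d in dirs:
        lines.append(f"mkdir -p {shlex.quote(d)}")
    lines.append("")
    for i, level in enumerate(_topo_levels(dag), start=1):
        runnable = [jid for jid in level if not dag.jobs[jid].pre_skipped]
        if not runnable:
            continue
        lines.append(f"# --- parallel group {i} ---")
        for jid in runnable:
            job = dag.jobs[jid]
            lines.append(" ".join(shlex.quote(tok) for tok in job.argv))
        lines.append("")
    return "\n".join(lines) + "\n"


def _export_make(dag) -> str:
    lines = ["# generated by deskpipe export-script", ".POSIX:", ""]
    finals: list[str] = []
    consumed: set[str] = set()
    for job in dag.jobs.values():
        consumed.update(job.input_paths)
    for jid in sorted(dag.jobs):
        job = dag.jobs[jid]
        if job.pre_skipped or not job.output_paths:
            continue
        for p in job.output_paths:
            if p not in consumed:
                finals.append(p)
    lines.append("all: " + " ".join(sorted(finals)))
    lines.append("")
    for jid in sorted(dag.jobs):
        job = dag.jobs[jid]
        if job.pre_skipped or not job.output_paths:
            continue
        prereqs = " ".join(sorted(set(job.input_paths)))
        primary = job.output_paths[0]
        cmd = " ".join(shlex.quote(tok) for tok in job.argv)
        lines.append(f"{primary}: {prereqs}".rstrip())
        lines.append(f"\tmkdir -p {shlex.quote(_dirname(primary))}")
        lines.append(f"\t{cmd}")
        for secondary in job.output_paths[1:]:
            lines.append(f"{secondary}: {primary}")
        lines.append("")
    return "\n".join(lines) + "\n"


def _dirname(path: str) -> str:
    import os

    return os.path.dirname(path) or "."
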