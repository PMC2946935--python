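"""Workflow expansion and execution.

``expand`` flattens a validated workflow into a job DAG before anything
runs: list-valued inputs of length *n* on one module yield *n* instances
zipped by index, scalars broadcast, loop-group bodies are replicated once
per iteration (iteration counts are frozen at first expansion), conditional
instances resolve to exactly one branch, and smartline-flagged connections
with mismatched formats insert one conversion job per instance.

``Engine`` executes the DAG on a pluggable backend (serial or
local-parallel; the contract is submit/cancel/poll/capacity so grid
backends can slot in) with dependency-order safety, a bounded number of
concurrent jobs, pause/resume/restart semantics and an append-only event
log.  Run state is persisted to a single JSON store per run so a paused
workflow survives process death.
"""

from __future__ import annotations

import csv
import json
import os
import shutil
import subprocess
import sys
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Callable, Iterable, Mapping

import networkx as nx

from . import provenance as prov
from . import smartlines
from .predicates import Predicate, PredicateError
from .workflow_model import (
    Connection,
    ConditionalSpec,
    DataSourceSpec,
    FORMAT_EXTENSIONS,
    GraphSpec,
    LoopGroupSpec,
    ModuleSpec,
    RepeatUntilSpec,
    StudySourceSpec,
    WorkflowSpec,
    build_argv,
    substitute_variables,
    validate_workflow,
)

__all__ = [
    "JobInstance",
    "JobDAG",
    "RunState",
    "SerialBackend",
    "LocalBackend",
    "Engine",
    "CardinalityError",
    "PlanningError",
    "ExpansionError",
    "expand",
    "repeat_until",
    "RepeatTrace",
    "detect_processing_units",
]

PENDING = "pending"
RUNNING = "running"
COMPLETED = "completed"
FAILED = "failed"
INVALIDATED = "invalidated"
SKIPPED = "skipped"

_STATES = (PENDING, RUNNING, COMPLETED, FAILED, INVALIDATED, SKIPPED)


class ExpansionError(ValueError):
    pass


class CardinalityError(ExpansionError):
    """Two list inputs of different lengths were zipped on one module."""


class PlanningError(ExpansionError):
    """A smartline conversion has no path in the registry."""


def detect_processing_units() -> int:
    """Number of available processing units on this machine."""
    return os.cpu_count() or 1


def _now() -> str:
    return datetime.now(timezone.utc).isoformat()


@dataclass
class JobInstance:
    job_id: str  # "<node path>:<instance index>"
    module_id: str
    instance_index: int
    argv: list[str]
    state: str = PENDING
    output_paths: list[str] = field(default_factory=list)
    input_paths: list[str] = field(default_factory=list)
    depends_on: list[str] = field(default_factory=list)
    timestamps: dict[str, str] = field(default_factory=dict)
    exit_status: int | None = None
    tool_metadata: dict[str, str] = field(default_factory=dict)
    pre_skipped: bool = False  # untaken conditional branch, decided statically
    repeat: dict[str, Any] | None = None  # repeat-until: condition, max_iter
    diagnostic: str = ""

    def to_json(self) -> dict[str, Any]:
        return {
            "job_id": self.job_id,
            "module_id": self.module_id,
            "instance_index": self.instance_index,
            "argv": self.argv,
            "state": self.state,
            "output_paths": self.output_paths,
            "input_paths": self.input_paths,
            "depends_on": self.depends_on,
            "timestamps": self.timestamps,
            "exit_status": self.exit_status,
            "tool_metadata": self.tool_metadata,
            "pre_skipped": self.pre_skipped,
            "repeat": self.repeat,
            "diagnostic": self.diagnostic,
        }

    @staticmethod
    def from_json(data: Mapping[str, Any]) -> "JobInstance":
        return JobInstance(**dict(data))


@dataclass
class JobDAG:
    workflow_id: str
    jobs: dict[str, JobInstance]
    workdir: str

    def __post_init__(self) -> None:
        self.graph = nx.DiGraph()
        for jid in self.jobs:
            self.graph.add_node(jid)
        for job in self.jobs.values():
            for dep in job.depends_on:
                self.graph.add_edge(dep, job.job_id)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ExpansionError("job graph contains a cycle")

    def successors_transitive(self, job_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for jid in job_ids:
            out |= nx.descendants(self.graph, jid)
        return out

    def jobs_of_module(self, module_id: str) -> list[JobInstance]:
        return [j for j in self.jobs.values() if j.module_id == module_id]


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------


@dataclass
class _Item:
    value: str
    metadata: dict[str, Any] | None = None
    producer: str | None = None  # job id that creates the value
    format_tag: str | None = None
    dtype_tag: str | None = None


@dataclass
class _ExpandContext:
    dag_jobs: dict[str, JobInstance]
    workdir: str
    registry: smartlines.ConversionRegistry
    policies: Mapping[tuple, str]  # (source fmt/dtype key, target key) -> policy
    bindings: Mapping[str, list[str]]
    scopes: tuple[Mapping[str, Any], ...]
    prefix: str = ""
    pre_skipped: bool = False
    pseudo_ports: Mapping[str, list[_Item]] = field(default_factory=dict)


def expand(
    spec: WorkflowSpec,
    bindings: Mapping[str, list[str]] | None = None,
    workdir: str = "work",
    registry: smartlines.ConversionRegistry | None = None,
    policies: Mapping[tuple, str] | None = None,
    validate: bool = True,
) -> JobDAG:
    """Expand a workflow into an executable job DAG.

    ``bindings`` overrides data-source values by node id.  ``policies`` maps
    ``((src_format, src_dtype), (dst_format, dst_dtype))`` to a lossy policy
    name for narrowing smartline conversions (the non-interactive stand-in
    for a conversion prompt).
    """
    if validate:
        report = validate_workflow(spec)
        if not report.ok:
            raise ExpansionError(f"workflow invalid: {report.findings[0].message}")
    ctx = _ExpandContext(
        dag_jobs={},
        workdir=workdir,
        registry=registry if registry is not None else smartlines.default_registry(),
        policies=policies or {},
        bindings=bindings or {},
        scopes=(dict(spec.variables),),
    )
    _expand_graph(GraphSpec(nodes=spec.nodes, connections=spec.connections), ctx)
    return JobDAG(workflow_id=spec.id, jobs=ctx.dag_jobs, workdir=workdir)


def _graph_topo_order(graph: GraphSpec) -> list:
    g = nx.DiGraph()
    node_ids = [n.id for n in graph.nodes]
    g.add_nodes_from(node_ids)
    for conn in graph.connections:
        if conn.source != "@" and conn.target != "@":
            g.add_edge(conn.source, conn.target)
    for node in graph.nodes:
        if isinstance(node, LoopGroupSpec) and node.iteration_source in node_ids:
            g.add_edge(node.iteration_source, node.id)
    order = list(nx.topological_sort(g))
    by_id = graph.node_map()
    return [by_id[i] for i in order]


def _merged_scope(scopes: tuple[Mapping[str, Any], ...]) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for s in scopes:
        out.update(s)
    return out


def _expand_graph(graph: GraphSpec, ctx: _ExpandContext) -> dict[tuple[str, str], list[_Item]]:
    """Returns port streams keyed by (node id, output port)."""
    scopes = ctx.scopes + (dict(graph.variables),)
    streams: dict[tuple[str, str], list[_Item]] = {}
    for port, items in ctx.pseudo_ports.items():
        streams[("@", port)] = items

    incoming: dict[str, list[Connection]] = {}
    for conn in graph.connections:
        incoming.setdefault(conn.target, []).append(conn)

    for node in _graph_topo_order(graph):
        if isinstance(node, DataSourceSpec):
            values = ctx.bindings.get(node.id, list(node.items))
            items = [
                _Item(
                    value=substitute_variables(str(v), scopes),
                    format_tag=node.format_tag,
                    dtype_tag=node.dtype_tag,
                )
                for v in values
            ]
            streams[(node.id, "out")] = items
        elif isinstance(node, StudySourceSpec):
            streams[(node.id, "out")] = _study_items(node, scopes)
        elif isinstance(node, ModuleSpec):
            streams.update(
                _expand_module(node, incoming.get(node.id, []), streams, scopes, ctx)
            )
        elif isinstance(node, RepeatUntilSpec):
            streams.update(
                _expand_module(
                    node.module,
                    incoming.get(node.id, []),
                    streams,
                    scopes,
                    ctx,
                    node_id=node.id,
                    repeat={"condition": node.condition, "max_iter": node.max_iter},
                )
            )
        elif isinstance(node, ConditionalSpec):
            streams.update(
                _expand_conditional(node, incoming.get(node.id, []), streams, scopes, ctx)
            )
        elif isinstance(node, LoopGroupSpec):
            streams.update(_expand_loop_group(node, streams, scopes, ctx))
        else:  # pragma: no cover
            raise AssertionError(type(node))
    # exported ports become the graph's own streams under node id "@exports"
    for port, (inner, param) in graph.exports.items():
        streams[("@exports", port)] = streams.get((inner, param), [])
    return streams


def _study_items(node: StudySourceSpec, scopes) -> list[_Item]:
    table_path = substitute_variables(node.table, scopes)
    with open(table_path, "r", encoding="utf-8", newline="") as fh:
        rows = list(csv.DictReader(fh))
    from .study_design import infer_column_types, _typed

    columns: dict[str, list[str]] = {}
    for row in rows:
        for k, v in row.items():
            columns.setdefault(k, []).append(v if v is not None else "")
    types = infer_column_types(columns)
    items = []
    pred = Predicate(node.cohort) if node.cohort else None
    for row in rows:
        metadata = {k: _typed(v if v is not None else "", types[k]) for k, v in row.items()}
        if pred is not None and not pred.evaluate(metadata):
            continue
        items.append(
            _Item(
                value=row[node.path_column],
                metadata=metadata,
                format_tag=node.format_tag,
            )
        )
    return items


def _zip_instances(
    per_port: dict[str, list[_Item]], list_ports: set[str], node_id: str
) -> int:
    """Instance count after zip-by-index with scalar broadcast."""
    lengths = {
        port: len(items)
        for port, items in per_port.items()
        if port not in list_ports and len(items) != 1
    }
    distinct = sorted(set(lengths.values()))
    if not distinct:
        return 1
    if len(distinct) > 1:
        detail = ", ".join(f"{p}={n}" for p, n in sorted(lengths.items()))
        raise CardinalityError(
            f"module {node_id!r}: list inputs of different lengths cannot be "
            f"zipped ({detail})"
        )
    return distinct[0]


def _output_ext(param) -> str:
    return FORMAT_EXTENSIONS.get(param.format_tag or "any", ".out")


def _expand_module(
    module: ModuleSpec,
    conns: list[Connection],
    streams: dict[tuple[str, str], list[_Item]],
    scopes,
    ctx: _ExpandContext,
    node_id: str | None = None,
    repeat: dict[str, Any] | None = None,
) -> dict[tuple[str, str], list[_Item]]:
    node_id = node_id or module.id
    per_port: dict[str, list[_Item]] = {}
    conn_for_port: dict[str, Connection] = {}
    for conn in conns:
        key = (conn.source, conn.source_port)
        if key not in streams:
            raise ExpansionError(
                f"connection into {node_id}.{conn.target_port} references "
                f"unexpanded source {conn.source}.{conn.source_port}"
            )
        per_port[conn.target_port] = streams[key]
        conn_for_port[conn.target_port] = conn

    list_ports = {p.name for p in module.inputs if p.cardinality == "list"}
    n = _zip_instances(per_port, list_ports, node_id)

    # defaults / literals for unconnected inputs
    for p in module.inputs:
        if p.name not in per_port and p.default is not None:
            per_port[p.name] = [_Item(value=substitute_variables(p.default, scopes))]

    out_streams: dict[tuple[str, str], list[_Item]] = {
        (node_id, p.name): [] for p in module.outputs
    }
    for i in range(n):
        jid = f"{ctx.prefix}{node_id}:{i}"
        values: dict[str, Any] = {}
        depends: list[str] = []
        input_paths: list[str] = []
        metadata: dict[str, Any] | None = None
        for p in module.inputs:
            items = per_port.get(p.name)
            if items is None:
                continue
            if p.cardinality == "list":
                chosen = items
            else:
                chosen = [items[i % len(items)] if len(items) > 1 else items[0]]
            conn = conn_for_port.get(p.name)
            resolved: list[_Item] = []
            for k, item in enumerate(chosen):
                if conn is not None and conn.smartline:
                    item = _maybe_convert(item, p, module, i if p.cardinality != "list" else k,
                                          node_id, ctx, depends)
                resolved.append(item)
            vals = [it.value for it in resolved]
            values[p.name] = vals if p.cardinality == "list" else vals[0]
            for it in resolved:
                if it.producer is not None:
                    depends.append(it.producer)
                if p.kind == "file":
                    input_paths.append(it.value)
                if metadata is None and it.metadata is not None:
                    metadata = it.metadata
        # outputs get generated paths
        outputs: list[str] = []
        for p in module.outputs:
            path = os.path.join(
                ctx.workdir, "outputs", f"{ctx.prefix}{node_id}", str(i),
                p.name + _output_ext(p),
            )
            values[p.name] = path
            outputs.append(path)
        job = JobInstance(
            job_id=jid,
            module_id=f"{ctx.prefix}{node_id}",
            instance_index=i,
            argv=build_argv(module, {
                k: (substitute_variables(str(v), scopes) if isinstance(v, str) else v)
                for k, v in values.items()
            }),
            output_paths=outputs,
            input_paths=sorted(set(input_paths)),
            depends_on=sorted(set(depends)),
            tool_metadata=dict(module.metadata),
            pre_skipped=ctx.pre_skipped,
            repeat=dict(repeat) if repeat else None,
        )
        ctx.dag_jobs[jid] = job
        for p, path in zip(module.outputs, outputs):
            out_streams[(node_id, p.name)].append(
                _Item(
                    value=path,
                    metadata=metadata,
                    producer=jid,
                    format_tag=p.format_tag,
                    dtype_tag=p.dtype_tag,
                )
            )
    return out_streams


def _maybe_convert(
    item: _Item,
    param,
    module: ModuleSpec,
    index: int,
    node_id: str,
    ctx: _ExpandContext,
    depends: list[str],
) -> _Item:
    """Insert a conversion job when a smartline connection carries a
    format/dtype mismatch.  One job per instance; conversions are mutually
    independent and parallelizable."""
    src = (item.format_tag, item.dtype_tag)
    want_fmt = param.format_tag if param.format_tag not in (None, "any") else None
    want_dt = param.dtype_tag if param.dtype_tag not in (None, "any") else None
    if want_fmt is None and want_dt is None:
        return item
    if src[0] is None:
        return item  # untyped provider: nothing to reconcile statically
    src_key = (src[0], src[1] or "float")
    plan = smartlines.plan_conversion(src_key, want_fmt, want_dt, ctx.registry)
    if plan.empty:
        return item
    if not plan.satisfiable:
        raise PlanningError(
            f"smartline into {node_id}.{param.name}: no conversion path from "
            f"{src_key} to ({want_fmt}, {want_dt})"
        )
    final = plan.steps[-1].target
    ext = FORMAT_EXTENSIONS.get(final[0], ".out")
    jid = f"{ctx.prefix}{node_id}.{param.name}.smartline:{index}"
    out_path = os.path.join(
        ctx.workdir, "outputs", f"{ctx.prefix}{node_id}.{param.name}.smartline",
        str(index), "converted" + ext,
    )
    argv = [sys.executable, "-m", "deskpipe.smartlines", item.value, out_path,
            "--to-format", final[0], "--to-dtype", final[1]]
    policy = ctx.policies.get((src_key, final))
    if policy is None and plan.lossy:
        # fall back to a policy keyed by dtype pair only
        policy = ctx.policies.get((src_key[1], final[1]))
    if policy is not None:
        argv.extend(["--policy", policy])
    job = JobInstance(
        job_id=jid,
        module_id=f"{ctx.prefix}{node_id}.{param.name}.smartline",
        instance_index=index,
        argv=argv,
        output_paths=[out_path],
        input_paths=[item.value],
        depends_on=[item.producer] if item.producer else [],
        tool_metadata={"name": "smartline-convert", "version": "builtin"},
        pre_skipped=ctx.pre_skipped,
    )
    ctx.dag_jobs[jid] = job
    return _Item(
        value=out_path,
        metadata=item.metadata,
        producer=jid,
        format_tag=final[0],
        dtype_tag=final[1],
    )


def _expand_conditional(
    node: ConditionalSpec,
    conns: list[Connection],
    streams: dict[tuple[str, str], list[_Item]],
    scopes,
    ctx: _ExpandContext,
) -> dict[tuple[str, str], list[_Item]]:
    per_port: dict[str, list[_Item]] = {}
    for conn in conns:
        per_port[conn.target_port] = streams[(conn.source, conn.source_port)]
    n = _zip_instances(per_port, set(), node.id)
    pred = Predicate(node.predicate)
    merged_vars = _merged_scope(scopes)
    out: dict[tuple[str, str], list[_Item]] = {
        (node.id, port): [] for port in node.output_ports
    }
    for i in range(n):
        instance_items = {
            port: (items[i % len(items)] if len(items) > 1 else items[0])
            for port, items in per_port.items()
        }
        env = dict(merged_vars)
        for item in instance_items.values():
            if item.metadata:
                env.update(item.metadata)
        try:
            taken_true = pred.evaluate(env)
        except PredicateError as exc:
            raise ExpansionError(f"conditional {node.id!r}: {exc}") from exc
        for which, branch in (("true", node.true_branch), ("false", node.false_branch)):
            taken = which == ("true" if taken_true else "false")
            sub = _ExpandContext(
                dag_jobs=ctx.dag_jobs,
                workdir=ctx.workdir,
                registry=ctx.registry,
                policies=ctx.policies,
                bindings=ctx.bindings,
                scopes=scopes,
                prefix=f"{ctx.prefix}{node.id}/{i}/{which}/",
                pre_skipped=ctx.pre_skipped or not taken,
                pseudo_ports={port: [item] for port, item in instance_items.items()},
            )
            branch_streams = _expand_graph(branch, sub)
            if taken:
                for port in node.output_ports:
                    exported = branch_streams[("@exports", port)]
                    out[(node.id, port)].extend(exported)
    return out


def _expand_loop_group(
    node: LoopGroupSpec,
    streams: dict[tuple[str, str], list[_Item]],
    scopes,
    ctx: _ExpandContext,
) -> dict[tuple[str, str], list[_Item]]:
    merged = _merged_scope(scopes)
    if (node.iteration_source, "out") in streams:
        items = streams[(node.iteration_source, "out")]
    elif node.iteration_source in merged and isinstance(merged[node.iteration_source], (list, tuple)):
        items = [_Item(value=str(v)) for v in merged[node.iteration_source]]
    else:
        raise ExpansionError(
            f"loop group {node.id!r}: iteration source {node.iteration_source!r} "
            "is neither an expanded node nor a list variable"
        )
    out: dict[tuple[str, str], list[_Item]] = {
        (node.id, port): [] for port in node.output_ports
    }
    # iteration count frozen here, before execution begins
    for j, item in enumerate(items):
        sub = _ExpandContext(
            dag_jobs=ctx.dag_jobs,
            workdir=ctx.workdir,
            registry=ctx.registry,
            policies=ctx.policies,
            bindings=ctx.bindings,
            scopes=scopes + ({node.iteration_var: item.value, "__index__": j},),
            prefix=f"{ctx.prefix}{node.id}/{j}/",
            pre_skipped=ctx.pre_skipped,
            pseudo_ports={node.iteration_var: [item]},
        )
        body_streams = _expand_graph(node.body, sub)
        for port in node.output_ports:
            out[(node.id, port)].extend(body_streams[("@exports", port)])
    return out


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


@dataclass
class _Handle:
    job_id: str
    proc: subprocess.Popen | None = None
    exit_status: int | None = None
    diagnostic: str = ""


class SerialBackend:
    """Runs each job to completion at submit time; capacity 1."""

    capacity = 1

    def submit(self, job: JobInstance) -> _Handle:
        try:
            result = subprocess.run(
                job.argv, capture_output=True, text=True, check=False
            )
            diag = (result.stderr or "")[-2000:]
            return _Handle(job.job_id, exit_status=result.returncode, diagnostic=diag)
        except FileNotFoundError as exc:
            return _Handle(job.job_id, exit_status=127, diagnostic=str(exc))

    def poll(self, handle: _Handle) -> tuple[str, int | None]:
        return (COMPLETED if handle.exit_status == 0 else FAILED, handle.exit_status)

    def cancel(self, handle: _Handle) -> None:  # already finished
        pass


class LocalBackend:
    """Local parallel backend; capacity defaults to the detected number of
    processing units.  Cancellation is polite terminate, then forced kill
    after a grace period."""

    def __init__(self, capacity: int | None = None, grace_seconds: float = 2.0):
        self.capacity = capacity or detect_processing_units()
        self.grace_seconds = grace_seconds

    def submit(self, job: JobInstance) -> _Handle:
        try:
            proc = subprocess.Popen(
                job.argv,
                stdout=subprocess.DEVNULL,
                stderr=subprocess.PIPE,
                text=True,
            )
            return _Handle(job.job_id, proc=proc)
        except FileNotFoundError as exc:
            return _Handle(job.job_id, exit_status=127, diagnostic=str(exc))

    def poll(self, handle: _Handle) -> tuple[str, int | None]:
        if handle.proc is None:
            return (COMPLETED if handle.exit_status == 0 else FAILED, handle.exit_status)
        code = handle.proc.poll()
        if code is None:
            return (RUNNING, None)
        if handle.exit_status is None:
            handle.exit_status = code
            try:
                handle.diagnostic = (handle.proc.stderr.read() or "")[-2000:]
            except Exception:
                pass
        return (COMPLETED if code == 0 else FAILED, code)

    def cancel(self, handle: _Handle) -> None:
        if handle.proc is None or handle.proc.poll() is not None:
            return
        handle.proc.terminate()
        deadline = time.monotonic() + self.grace_seconds
        while time.monotonic() < deadline:
            if handle.proc.poll() is not None:
                return
            time.sleep(0.01)
        handle.proc.kill()
        handle.proc.wait()


# ---------------------------------------------------------------------------
# run state and engine
# ---------------------------------------------------------------------------


@dataclass
class RunState:
    workflow_id: str
    jobs: dict[str, JobInstance]
    event_log: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    store_path: str | None = None
    workdir: str = "work"

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in _STATES}
        for job in self.jobs.values():
            out[job.state] += 1
        return out

    def persist(self) -> None:
        if self.store_path is None:
            return
        os.makedirs(os.path.dirname(os.path.abspath(self.store_path)), exist_ok=True)
        payload = {
            "workflow_id": self.workflow_id,
            "workdir": self.workdir,
            "jobs": {jid: job.to_json() for jid, job in sorted(self.jobs.items())},
            "event_count": len(self.event_log),
        }
        tmp = self.store_path + ".tmp"
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")
        os.replace(tmp, self.store_path)

    @property
    def event_log_path(self) -> str | None:
        return self.store_path + ".events" if self.store_path else None

    @staticmethod
    def load(store_path: str) -> "RunState":
        try:
            with open(store_path, "r", encoding="utf-8") as fh:
                payload = json.load(fh)
            jobs = {jid: JobInstance.from_json(j) for jid, j in payload["jobs"].items()}
        except (OSError, ValueError, KeyError, TypeError) as exc:
            raise ValueError(f"corrupt or unreadable run store {store_path!r}: {exc}") from exc
        state = RunState(
            workflow_id=payload["workflow_id"],
            jobs=jobs,
            store_path=store_path,
            workdir=payload.get("workdir", "work"),
        )
        events_path = state.event_log_path
        if events_path and os.path.exists(events_path):
            with open(events_path, "r", encoding="utf-8") as fh:
                for line in fh:
                    parts = line.rstrip("\n").split("\t")
                    if len(parts) == 5:
                        ts, seq, jid, old, new = parts
                        state.event_log.append((ts, int(seq), jid, old, new))
        return state


def _delete_outputs(job: JobInstance) -> None:
    """Delete only files declared as this job's outputs (plus their derived
    siblings: .prov records, Analyze .hdr, raw sidecars) — never user files."""
    for path in job.output_paths:
        for candidate in (
            path,
            prov.prov_path_for(path),
            os.path.splitext(path)[0] + ".hdr",
            os.path.splitext(path)[0] + smartlines.RAW_SIDECAR_SUFFIX,
        ):
            if os.path.exists(candidate):
                os.remove(candidate)


class Engine:
    """Step-driven executor over a job DAG.

    ``step()`` performs one scheduling round (poll running jobs, submit
    ready ones); ``run()`` loops until no progress is possible.  All state
    transitions are appended to the event log and the persistent store.
    """

    def __init__(
        self,
        dag: JobDAG | None = None,
        backend=None,
        store_path: str | None = None,
        limit: int | None = None,
        provenance: bool = True,
        state: RunState | None = None,
    ):
        if dag is None and state is None:
            raise ValueError("need a dag or a loaded state")
        self.backend = backend if backend is not None else SerialBackend()
        if state is None:
            state = RunState(
                workflow_id=dag.workflow_id,
                jobs=dag.jobs,
                store_path=store_path,
                workdir=dag.workdir,
            )
        if store_path is not None:
            state.store_path = store_path
        self.state = state
        self.graph = nx.DiGraph()
        for jid in state.jobs:
            self.graph.add_node(jid)
        for job in state.jobs.values():
            for dep in job.depends_on:
                self.graph.add_edge(dep, job.job_id)
        cap = getattr(self.backend, "capacity", 1)
        self.limit = min(limit, cap) if limit is not None else cap
        self.provenance_enabled = provenance
        self.handles: dict[str, _Handle] = {}
        self._seq = max((e[1] for e in state.event_log), default=-1) + 1
        self._started = False

    # -- event bookkeeping ---------------------------------------------------

    def _transition(self, job: JobInstance, new_state: str) -> None:
        old = job.state
        if old == new_state:
            return
        job.state = new_state
        event = (_now(), self._seq, job.job_id, old, new_state)
        self._seq += 1
        self.state.event_log.append(event)
        path = self.state.event_log_path
        if path:
            os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
            with open(path, "a", encoding="utf-8") as fh:
                fh.write("\t".join(str(p) for p in event) + "\n")

    # -- scheduling ----------------------------------------------------------

    def _begin(self) -> None:
        if self._started:
            return
        self._started = True
        for job in self.state.jobs.values():
            if job.state == INVALIDATED:
                self._transition(job, PENDING)  # resubmission after restart
            if job.pre_skipped and job.state == PENDING:
                self._transition(job, SKIPPED)
                job.diagnostic = "untaken conditional branch"
        self.state.persist()

    def _ready(self, job: JobInstance) -> bool:
        return job.state == PENDING and all(
            self.state.jobs[d].state == COMPLETED for d in job.depends_on
        )

    def _deps_doomed(self, job: JobInstance) -> bool:
        return any(
            self.state.jobs[d].state in (FAILED, SKIPPED) for d in job.depends_on
        )

    def _skip_descendants(self, job_id: str) -> None:
        for jid in sorted(nx.descendants(self.graph, job_id)):
            dep = self.state.jobs[jid]
            if dep.state == PENDING:
                self._transition(dep, SKIPPED)
                dep.diagnostic = f"upstream {job_id} did not complete"

    def step(self) -> bool:
        """One scheduling round.  Returns True while unfinished work remains."""
        self._begin()
        progressed = False

        # poll running jobs
        for jid in sorted(list(self.handles)):
            handle = self.handles[jid]
            job = self.state.jobs[jid]
            result, code = self.backend.poll(handle)
            if result == RUNNING:
                continue
            del self.handles[jid]
            job.exit_status = code
            job.timestamps["ended"] = _now()
            job.diagnostic = handle.diagnostic
            if result == COMPLETED:
                self._transition(job, COMPLETED)
                if self.provenance_enabled:
                    try:
                        prov.update_for_job(job, job.tool_metadata)
                    except Exception as exc:  # provenance must not kill the run
                        job.diagnostic += f"\nprovenance update failed: {exc}"
            else:
                self._transition(job, FAILED)
                self._skip_descendants(jid)
            progressed = True

        # propagate skips and submit ready jobs
        for jid in sorted(self.state.jobs):
            job = self.state.jobs[jid]
            if job.state != PENDING:
                continue
            if self._deps_doomed(job):
                self._transition(job, SKIPPED)
                job.diagnostic = "upstream failure or skip"
                progressed = True
                continue
            if len(self.handles) >= self.limit:
                continue
            if not self._ready(job):
                continue
            for out in job.output_paths:
                os.makedirs(os.path.dirname(os.path.abspath(out)), exist_ok=True)
            job.timestamps["submitted"] = _now()
            if job.repeat is not None:
                self._run_repeat(job)  # dynamic node, executed inline
                progressed = True
                continue
            handle = self.backend.submit(job)
            job.timestamps["started"] = _now()
            self._transition(job, RUNNING)
            self.handles[jid] = handle
            # serial backend finishes at submit time; reflect that promptly
            progressed = True

        if progressed:
            self.state.persist()
        self._progressed = progressed
        unfinished = any(
            j.state in (PENDING, RUNNING) for j in self.state.jobs.values()
        )
        return unfinished

    def run(self, poll_interval: float = 0.01) -> RunState:
        """Execute until no pending or running jobs remain."""
        while True:
            busy = self.step()
            if not busy:
                break
            if self.handles and not getattr(self, "_progressed", False):
                time.sleep(poll_interval)
        self.state.persist()
        return self.state

    # -- repeat-until --------------------------------------------------------

    def _run_repeat(self, job: JobInstance) -> None:
        job.timestamps["started"] = _now()
        self._transition(job, RUNNING)
        try:
            trace = _iterate_repeat(job.argv, job.output_paths,
                                    job.repeat["condition"], job.repeat["max_iter"])
            job.repeat["trace"] = trace.to_json()
            job.exit_status = 0 if trace.ok else 1
            job.timestamps["ended"] = _now()
            if trace.ok:
                self._transition(job, COMPLETED)
                if self.provenance_enabled:
                    prov.update_for_job(job, job.tool_metadata)
            else:
                job.diagnostic = trace.diagnostic
                self._transition(job, FAILED)
                self._skip_descendants(job.job_id)
        except Exception as exc:
            job.diagnostic = str(exc)
            job.timestamps["ended"] = _now()
            self._transition(job, FAILED)
            self._skip_descendants(job.job_id)

    # -- lifecycle operations -------------------------------------------------

    def pause(self) -> str:
        """Stop running jobs, delete their output files, reset them to
        pending; completed outputs are preserved.  Returns a notice."""
        counts = self.state.counts()
        if counts[RUNNING] == 0 and counts[PENDING] == 0:
            return "nothing to pause: workflow has no running or pending jobs"
        for jid in sorted(list(self.handles)):
            handle = self.handles.pop(jid)
            self.backend.cancel(handle)
            job = self.state.jobs[jid]
            _delete_outputs(job)
            job.timestamps.pop("started", None)
            job.exit_status = None
            self._transition(job, PENDING)
        self.state.persist()
        return "paused"

    @classmethod
    def resume(cls, store_path: str, backend=None, limit: int | None = None,
               provenance: bool = True) -> "Engine":
        """Rebuild an engine from a persisted store.  Completed work is never
        re-executed; jobs recorded as running (a crashed run) are reset to
        pending with their partial outputs removed."""
        state = RunState.load(store_path)
        engine = cls(backend=backend, state=state, limit=limit, provenance=provenance)
        for job in state.jobs.values():
            if job.state == RUNNING:
                _delete_outputs(job)
                job.timestamps.pop("started", None)
                engine._transition(job, PENDING)
        state.persist()
        return engine

    def restart_module(self, module_id: str) -> list[str]:
        """Invalidate all instances of a module and its transitive
        successors, deleting their outputs; ancestors and independent
        branches keep their state.  Returns the invalidated job ids."""
        targets = [j.job_id for j in self.state.jobs.values() if j.module_id == module_id]
        if not targets:
            raise KeyError(f"unknown module {module_id!r}")
        affected = set(targets) | {
            jid for t in targets for jid in nx.descendants(self.graph, t)
        }
        invalidated = []
        for jid in sorted(affected):
            job = self.state.jobs[jid]
            if job.state == PENDING and jid not in targets:
                continue
            _delete_outputs(job)
            job.exit_status = None
            job.timestamps.clear()
            self._transition(job, INVALIDATED)
            invalidated.append(jid)
        self._started = False  # next run() resubmits invalidated jobs
        self.state.persist()
        return invalidated

    def status(self) -> dict[str, Any]:
        counts = self.state.counts()
        per_module: dict[str, dict[str, int]] = {}
        for job in self.state.jobs.values():
            slot = per_module.setdefault(job.module_id, {"total": 0, "completed": 0})
            slot["total"] += 1
            if job.state == COMPLETED:
                slot["completed"] += 1
        modules = {
            mid: {"total": v["total"], "completed": v["completed"],
                  "fraction": v["completed"] / v["total"]}
            for mid, v in sorted(per_module.items())
        }
        capacity = getattr(self.backend, "capacity", 1)
        active = len(self.handles)
        return {
            "workflow_id": self.state.workflow_id,
            "counts": counts,
            "total": len(self.state.jobs),
            "modules": modules,
            "workers": {"active": active, "idle": max(capacity - active, 0),
                        "capacity": capacity},
        }


# ---------------------------------------------------------------------------
# repeat-until (also usable standalone on a single module)
# ---------------------------------------------------------------------------


@dataclass
class RepeatTrace:
    iterations: list[dict[str, Any]] = field(default_factory=list)
    condition_met: bool = False
    limit_reached: bool = False
    diagnostic: str = ""

    @property
    def ok(self) -> bool:
        return self.condition_met or self.limit_reached

    def to_json(self) -> dict[str, Any]:
        return {
            "iterations": self.iterations,
            "condition_met": self.condition_met,
            "limit_reached": self.limit_reached,
            "diagnostic": self.diagnostic,
        }


def _read_output_value(path: str) -> Any:
    try:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read().strip()
    except (OSError, UnicodeDecodeError):
        return None
    try:
        return float(text)
    except ValueError:
        return text


def _iterate_repeat(
    argv: list[str], output_paths: list[str], condition: str, max_iter: int
) -> RepeatTrace:
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    pred = Predicate(condition)
    trace = RepeatTrace()
    for iteration in range(1, max_iter + 1):
        result = subprocess.run(argv, capture_output=True, text=True, check=False)
        if result.returncode != 0:
            trace.diagnostic = (
                f"iteration {iteration}: exit {result.returncode}: "
                f"{(result.stderr or '')[-500:]}"
            )
            return trace
        outputs = {os.path.basename(p): _read_output_value(p) for p in output_paths}
        env: dict[str, Any] = {"iteration": iteration}
        env.update({k: v for k, v in outputs.items() if v is not None})
        if output_paths:
            env["value"] = _read_output_value(output_paths[0])
        trace.iterations.append({"iteration": iteration, "outputs": outputs})
        try:
            met = pred.evaluate(env)
        except PredicateError as exc:
            raise PredicateError(
                f"repeat-until condition unevaluable after iteration {iteration}: {exc}"
            ) from exc
        if met:
            trace.condition_met = True
            return trace
    trace.limit_reached = True
    return trace


def repeat_until(
    module: ModuleSpec,
    condition: str,
    max_iter: int,
    bindings: Mapping[str, Any] | None = None,
    workdir: str = "work",
) -> RepeatTrace:
    """Re-execute a single module until ``condition`` holds on its outputs
    or ``max_iter`` is reached.  The condition is a predicate over values
    parsed from the module's output files (``value`` names the first
    output's content; ``iteration`` is the 1-based count)."""
    values: dict[str, Any] = dict(bindings or {})
    output_paths = []
    for p in module.outputs:
        path = os.path.join(workdir, "outputs", module.id, "0", p.name + _output_ext(p))
        os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
        values[p.name] = path
        output_paths.append(path)
    for p in module.inputs:
        if p.name not in values and p.default is not None:
            values[p.name] = p.default
    argv = build_argv(module, values)
    return _iterate_repeat(argv, output_paths, condition, max_iter)
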