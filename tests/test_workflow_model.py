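"""Document model: parse/serialize round trips, validation findings, script
export contracts."""

import itertools

import pytest

from deskpipe import fixtures as fx
from deskpipe.workflow_model import (
    Connection,
    DataSourceSpec,
    ExportError,
    ModuleSpec,
    ParameterSpec,
    SchemaError,
    WorkflowParseError,
    WorkflowSpec,
    export_script,
    parse_workflow,
    parse_workflow_file,
    serialize_workflow,
    validate_workflow,
)

ALL_KINDS = ("chain", "diamond", "loop", "conditional", "repeat")


def _mod(mod_id: str, fmt: str = "any", executable: str = "/bin/true") -> ModuleSpec:
    return ModuleSpec(
        id=mod_id,
        label=mod_id,
        executable=executable,
        parameters=(
            ParameterSpec("in", "input", "file", format_tag=fmt, binding="pos:1"),
            ParameterSpec("out", "output", "file", format_tag=fmt, binding="pos:2"),
        ),
    )


def test_toy_chain_parses_to_two_modules_one_connection(chain_workflow):
    spec, _ = chain_workflow
    assert len(spec.nodes) == 2
    assert len(spec.connections) == 1


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_round_trip_identity_on_all_toy_workflows(kind, tmp_path):
    path = fx.make_toy_workflow(kind, str(tmp_path / kind))
    spec = parse_workflow_file(path)
    text = serialize_workflow(spec)
    assert parse_workflow(text) == spec
    # serialization is deterministic: byte-identical on repeat
    assert serialize_workflow(parse_workflow(text)) == text


def test_empty_workflow_serializes_to_minimal_document():
    text = serialize_workflow(WorkflowSpec(id="empty"))
    spec = parse_workflow(text)
    assert spec.id == "empty" and spec.nodes == () and spec.connections == ()


def test_malformed_xml_reports_line():
    with pytest.raises(WorkflowParseError, match="line"):
        parse_workflow("<pipeline id='x'>\n<module\n</pipeline>")


def test_unknown_node_kind_is_schema_error():
    with pytest.raises(SchemaError, match="unknown node kind"):
        parse_workflow("<pipeline id='x'><gadget id='g'/></pipeline>")


def test_duplicate_node_id_is_schema_error():
    doc = """<pipeline id='x'>
      <dataSource id='a'><item>1</item></dataSource>
      <dataSource id='a'><item>2</item></dataSource>
    </pipeline>"""
    with pytest.raises(SchemaError, match="duplicate node id 'a'"):
        parse_workflow(doc)


def test_connection_to_missing_node_names_the_id():
    doc = """<pipeline id='x'>
      <dataSource id='src'><item>1</item></dataSource>
      <connection source='src' sourcePort='out' target='ghost' targetPort='in'/>
    </pipeline>"""
    with pytest.raises(SchemaError, match="ghost"):
        parse_workflow(doc)


def test_output_parameter_must_be_file():
    with pytest.raises(SchemaError, match="kind=file"):
        ParameterSpec("out", "output", "string")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def test_format_mismatch_without_smartline_is_reported():
    spec = WorkflowSpec(
        id="x",
        nodes=(
            DataSourceSpec(id="src", items=("a.nii",), format_tag="nifti-1"),
            _mod("A", fmt="nifti-1"),
            _mod("B", fmt="csv"),
        ),
        connections=(
            Connection("src", "out", "A", "in"),
            Connection("A", "out", "B", "in", smartline=False),
        ),
    )
    report = validate_workflow(spec)
    codes = [f.code for f in report.findings]
    assert "type-mismatch" in codes
    finding = next(f for f in report.findings if f.code == "type-mismatch")
    assert finding.node == "B" and finding.port == "in"


def test_same_mismatch_with_smartline_is_not_a_finding():
    spec = WorkflowSpec(
        id="x",
        nodes=(
            DataSourceSpec(id="src", items=("a.nii",), format_tag="nifti-1"),
            _mod("A", fmt="nifti-1"),
            _mod("B", fmt="analyze-7.5"),
        ),
        connections=(
            Connection("src", "out", "A", "in"),
            Connection("A", "out", "B", "in", smartline=True),
        ),
    )
    assert validate_workflow(spec).ok


def test_unbound_required_input_is_reported():
    spec = WorkflowSpec(id="x", nodes=(_mod("A"),))
    report = validate_workflow(spec)
    assert [f.code for f in report.findings] == ["unbound-input"]
    assert report.findings[0].port == "in"


def test_cycle_finding_lists_members():
    spec = WorkflowSpec(
        id="x",
        nodes=(_mod("A"), _mod("B")),
        connections=(
            Connection("A", "out", "B", "in"),
            Connection("B", "out", "A", "in"),
        ),
    )
    report = validate_workflow(spec)
    cycle = next(f for f in report.findings if f.code == "cycle")
    # brute-force oracle on this 2-node graph: the only cycle is {A, B}
    assert "A" in cycle.message and "B" in cycle.message


def test_cardinality_conflict_between_sources_of_known_lengths():
    d = ModuleSpec(
        id="D",
        label="D",
        executable="/bin/true",
        parameters=(
            ParameterSpec("in1", "input", "file", format_tag="any", binding="pos:1"),
            ParameterSpec("in2", "input", "file", format_tag="any", binding="pos:2"),
            ParameterSpec("out", "output", "file", format_tag="any", binding="pos:3"),
        ),
    )
    spec = WorkflowSpec(
        id="x",
        nodes=(
            DataSourceSpec(id="s3", items=("a", "b", "c"), format_tag="any"),
            DataSourceSpec(id="s4", items=("a", "b", "c", "d"), format_tag="any"),
            d,
        ),
        connections=(
            Connection("s3", "out", "D", "in1"),
            Connection("s4", "out", "D", "in2"),
        ),
    )
    assert "cardinality-conflict" in [f.code for f in validate_workflow(spec).findings]


def test_unresolved_variable_is_reported():
    mod = ModuleSpec(
        id="A",
        label="A",
        executable="/bin/true",
        parameters=(
            ParameterSpec("in", "input", "string", default="${nope}", binding="pos:1"),
            ParameterSpec("out", "output", "file", format_tag="any", binding="pos:2"),
        ),
    )
    report = validate_workflow(WorkflowSpec(id="x", nodes=(mod,)))
    assert "unresolved-variable" in [f.code for f in report.findings]


@pytest.mark.parametrize("kind", ALL_KINDS)
def test_toy_workflows_validate_clean(kind, tmp_path):
    spec = parse_workflow_file(fx.make_toy_workflow(kind, str(tmp_path / kind)))
    assert validate_workflow(spec).ok


# ---------------------------------------------------------------------------
# script export
# ---------------------------------------------------------------------------


def _command_order(script: str, needles: list[str]) -> list[int]:
    lines = script.splitlines()
    out = []
    for needle in needles:
        idx = [i for i, l in enumerate(lines)
               if needle in l and not l.startswith(("#", "mkdir"))]
        assert idx, f"{needle} not found in script"
        out.append(idx[0])
    return out


def test_shell_export_respects_every_valid_topological_order(chain_workflow, tmp_path):
    """The chain A -> B admits exactly one topological order (brute-force
    enumeration over the 2-node graph); the script must use it."""
    spec, _ = chain_workflow
    script = export_script(spec, "shell", workdir=str(tmp_path / "w"))
    pos_a, pos_b = _command_order(script, ["/outputs/A/", "/outputs/B/"])
    # brute force: all permutations of (A, B) respecting the edge A->B
    valid = [p for p in itertools.permutations("AB") if p.index("A") < p.index("B")]
    assert valid == [("A", "B")]
    assert pos_a < pos_b


def test_make_export_diamond_prerequisites(diamond_workflow, tmp_path):
    spec, _ = diamond_workflow
    mk = export_script(spec, "make", workdir=str(tmp_path / "w"))
    d_rule = next(l for l in mk.splitlines() if "/outputs/D/0/out.out:" in l)
    assert "/outputs/B/0/out.out" in d_rule
    assert "/outputs/C/0/out.out" in d_rule


def test_repeat_until_cannot_be_exported(tmp_path):
    spec = parse_workflow_file(fx.make_toy_workflow("repeat", str(tmp_path / "r")))
    with pytest.raises(ExportError, match="count-up"):
        export_script(spec, "shell")


def test_export_refuses_invalid_workflow():
    spec = WorkflowSpec(id="x", nodes=(_mod("A"),))  # unbound input
    with pytest.raises(ExportError, match="unbound|binding"):
        export_script(spec, "shell")
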