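"""Build a toy diamond workflow, validate it, run it, then restart one
module and show that downstream work is redone while siblings are kept.

Run:  python examples/run_workflow.py
"""

import tempfile

from deskpipe import Engine, expand, parse_workflow_file, validate_workflow
from deskpipe.fixtures import make_toy_workflow

tmp = tempfile.mkdtemp(prefix="deskpipe-demo-")
path = make_toy_workflow("diamond", tmp)
spec = parse_workflow_file(path)

print(f"workflow: {spec.id} ({len(spec.nodes)} nodes, {len(spec.connections)} connections)")
print("validation:", validate_workflow(spec))

dag = expand(spec, workdir=f"{tmp}/work")
engine = Engine(dag, store_path=f"{tmp}/run.json")
state = engine.run()
print("after run:", state.counts())

invalidated = engine.restart_module("B")
print("restart B invalidates:", invalidated)  # B and its successor D, not A or C
state = engine.run()
print("after re-run:", state.counts())
print("event log has", len(state.event_log), "transitions; store at", state.store_path)

# The counts dict says how many job instances ended in each lifecycle state;
# a clean diamond run completes all 4 (A, B, C, D), and the restart re-runs
# exactly B and D.
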