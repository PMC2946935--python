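"""Run a two-step workflow and inspect the provenance record the engine
writes next to each output.

Run:  python examples/provenance_tour.py
"""

import tempfile

from deskpipe import Engine, expand, parse_workflow_file
from deskpipe.fixtures import make_toy_workflow
from deskpipe.provenance import prov_path_for, read_prov

tmp = tempfile.mkdtemp(prefix="deskpipe-prov-")
spec = parse_workflow_file(make_toy_workflow("chain", tmp))
dag = expand(spec, workdir=f"{tmp}/work")
state = Engine(dag, store_path=f"{tmp}/run.json").run()

final_output = state.jobs["B:0"].output_paths[0]
record = read_prov(prov_path_for(final_output))

print("dataset:", record.dataset)
for name, value in sorted(record.identity.items()):
    print(f"  identity.{name} = {value}")
print(f"{len(record.steps)} processing steps (full lineage of this file):")
for i, step in enumerate(record.steps):
    print(f"  step {i}: {step.tool_name} v{step.tool_version} [{step.job_id}]")
    print(f"    argv: {' '.join(step.arguments)}")
    print(f"    platform: {step.platform_os}/{step.platform_arch}")
    print(f"    executable checksum: {step.executable_checksum[:23]}...")

# B's output carries two steps — A's and B's — because its lineage includes
# everything that produced its inputs; A's own output carries only A's step.
# The argument lists reproduce the executed commands verbatim.
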