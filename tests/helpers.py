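"""Shared test utilities: randomized toy DAGs and brute-force event-log
checkers independent of the engine's own bookkeeping."""

from __future__ import annotations

import os

import numpy as np

from deskpipe.engine import JobDAG, JobInstance


def make_random_dag(
    rng: np.random.Generator,
    tools: dict[str, str],
    workdir: str,
    n_jobs: int | None = None,
    fail_job: str | None = None,
) -> JobDAG:
    """Random layered toy DAG of copy/merge jobs over real files.

    Each job concatenates the outputs of its dependencies (or a seed file
    for roots) into its own output, so final outputs are deterministic
    functions of the topology.
    """
    os.makedirs(workdir, exist_ok=True)
    seed_file = os.path.join(workdir, "seed.txt")
    with open(seed_file, "w", encoding="utf-8") as fh:
        fh.write("seed\n")
    n = int(n_jobs if n_jobs is not None else rng.integers(4, 9))
    jobs: dict[str, JobInstance] = {}
    for i in range(n):
        jid = f"J{i}:0"
        # depend on a random subset of earlier jobs (possible empty)
        n_deps = int(rng.integers(0, min(i, 3) + 1))
        deps = sorted(
            f"J{k}:0" for k in rng.choice(i, size=n_deps, replace=False)
        ) if n_deps else []
        out = os.path.join(workdir, f"out{i}.txt")
        if fail_job == f"J{i}":
            argv = [tools["fail.sh"]]
            deps = deps[:2]
        elif len(deps) >= 2:
            deps = deps[:2]  # dependencies are exactly the consumed inputs
            ins = [jobs[d].output_paths[0] for d in deps]
            argv = [tools["merge.sh"], ins[0], ins[1], out]
        elif len(deps) == 1:
            argv = [tools["copy.sh"], jobs[deps[0]].output_paths[0], out]
        else:
            argv = [tools["copy.sh"], seed_file, out]
        jobs[jid] = JobInstance(
            job_id=jid,
            module_id=f"J{i}",
            instance_index=0,
            argv=argv,
            output_paths=[out],
            input_paths=[a for a in argv[1:-1]],
            depends_on=deps,
        )
    return JobDAG(workflow_id="random", jobs=jobs, workdir=workdir)


def event_times(state) -> dict[tuple[str, str], int]:
    """(job, new state) -> sequence number of the transition (last wins)."""
    return {(jid, new): seq for (_, seq, jid, old, new) in state.event_log}


def check_dependency_order(state, dag: JobDAG) -> list[str]:
    """Brute-force constraint check: for every edge (u, v), u's completion
    precedes v's start.  Returns violation descriptions (empty = pass)."""
    times = event_times(state)
    violations = []
    for v in dag.jobs.values():
        start_v = times.get((v.job_id, "running"))
        if start_v is None:
            continue
        for u in v.depends_on:
            done_u = times.get((u, "completed"))
            if done_u is None or done_u > start_v:
                violations.append(f"{u} completed at {done_u}, {v.job_id} started at {start_v}")
    return violations


def max_concurrency(state) -> int:
    """Interval-overlap count over the event sequence: peak number of jobs
    simultaneously in the running state."""
    peak = 0
    running = 0
    for (_, _, _, old, new) in sorted(state.event_log, key=lambda e: e[1]):
        if new == "running":
            running += 1
            peak = max(peak, running)
        elif old == "running":
            running -= 1
    return peak


def checksum_tree(paths) -> dict[str, str]:
    import hashlib

    out = {}
    for p in paths:
        with open(p, "rb") as fh:
            out[os.path.basename(p)] = hashlib.sha256(fh.read()).hexdigest()
    return out
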