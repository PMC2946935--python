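"""Engine semantics: expansion, dependency-safe execution, failure
propagation, pause/resume/restart, repeat-until, status conservation."""

import os

import pytest

from deskpipe import fixtures as fx
from deskpipe.engine import (
    CardinalityError,
    Engine,
    LocalBackend,
    SerialBackend,
    expand,
    repeat_until,
)
from deskpipe.workflow_model import (
    Connection,
    DataSourceSpec,
    ModuleSpec,
    ParameterSpec,
    parse_workflow_file,
)

from helpers import check_dependency_order, checksum_tree, event_times, max_concurrency


def _step_until_running(engine, job_id, timeout=10.0):
    import time

    deadline = time.monotonic() + timeout
    while time.monotonic() < deadline:
        engine.step()
        if engine.state.jobs[job_id].state == "running":
            return
        time.sleep(0.005)
    pytest.fail(f"{job_id} never started")


def _list_module(mod_id, tool, n_in=1):
    params = [
        ParameterSpec(f"in{i + 1}" if n_in > 1 else "in", "input", "file",
                      format_tag="any", binding=f"pos:{i + 1}")
        for i in range(n_in)
    ]
    params.append(
        ParameterSpec("out", "output", "file", format_tag="any",
                      binding=f"pos:{n_in + 1}")
    )
    return ModuleSpec(id=mod_id, label=mod_id, executable=tool,
                      parameters=tuple(params))


class TestExpand:
    def test_list_input_of_length_three_yields_three_instances(self, toy_tools, tmp_path):
        items = []
        for k in range(3):
            p = tmp_path / f"i{k}.txt"
            p.write_text(str(k))
            items.append(str(p))
        spec_nodes = (
            DataSourceSpec(id="src", items=tuple(items), format_tag="any"),
            _list_module("A", toy_tools["copy.sh"]),
        )
        from deskpipe.workflow_model import WorkflowSpec

        spec = WorkflowSpec(id="x", nodes=spec_nodes,
                            connections=(Connection("src", "out", "A", "in"),))
        dag = expand(spec, workdir=str(tmp_path / "w"))
        assert sorted(dag.jobs) == ["A:0", "A:1", "A:2"]

    def test_irma_manifest_expands_to_186_instances(self):
        spec = fx.make_irma_workflow()
        dag = expand(spec, workdir="unused")
        assert len(dag.jobs) == fx.FixtureConfig().irma_total_runs == 186

    def test_mismatched_list_lengths_raise_cardinality_error(self, toy_tools, tmp_path):
        from deskpipe.workflow_model import WorkflowSpec

        files = []
        for k in range(4):
            p = tmp_path / f"f{k}.txt"
            p.write_text("x")
            files.append(str(p))
        spec = WorkflowSpec(
            id="x",
            nodes=(
                DataSourceSpec(id="s3", items=tuple(files[:3]), format_tag="any"),
                DataSourceSpec(id="s4", items=tuple(files), format_tag="any"),
                _list_module("M", toy_tools["merge.sh"], n_in=2),
            ),
            connections=(
                Connection("s3", "out", "M", "in1"),
                Connection("s4", "out", "M", "in2"),
            ),
        )
        with pytest.raises(CardinalityError, match="M"):
            expand(spec, workdir=str(tmp_path / "w"), validate=False)

    def test_scalar_broadcast_against_list(self, toy_tools, tmp_path):
        from deskpipe.workflow_model import WorkflowSpec

        files = []
        for k in range(3):
            p = tmp_path / f"f{k}.txt"
            p.write_text(str(k))
            files.append(str(p))
        scalar = tmp_path / "scalar.txt"
        scalar.write_text("s")
        spec = WorkflowSpec(
            id="x",
            nodes=(
                DataSourceSpec(id="many", items=tuple(files), format_tag="any"),
                DataSourceSpec(id="one", items=(str(scalar),), format_tag="any"),
                _list_module("M", toy_tools["merge.sh"], n_in=2),
            ),
            connections=(
                Connection("many", "out", "M", "in1"),
                Connection("one", "out", "M", "in2"),
            ),
        )
        dag = expand(spec, workdir=str(tmp_path / "w"))
        assert len(dag.jobs) == 3
        assert all(str(scalar) in j.argv for j in dag.jobs.values())


class TestRun:
    def test_chain_event_log_orders_completion_before_start(self, chain_workflow, tmp_path):
        spec, _ = chain_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        engine = Engine(dag, backend=SerialBackend())
        state = engine.run()
        assert state.counts()["completed"] == 2
        times = event_times(state)
        assert times[("A:0", "completed")] < times[("B:0", "running")]
        assert not check_dependency_order(state, dag)

    def test_failure_skips_dependents_but_not_siblings(self, diamond_workflow, toy_tools, tmp_path):
        spec, _ = diamond_workflow
        # seed a failure into B by swapping its executable
        nodes = []
        for node in spec.nodes:
            if node.id == "B":
                from dataclasses import replace

                node = replace(node, executable=toy_tools["fail.sh"])
            nodes.append(node)
        from dataclasses import replace

        spec = replace(spec, nodes=tuple(nodes))
        dag = expand(spec, workdir=str(tmp_path / "w"))
        state = Engine(dag).run()
        states = {jid: j.state for jid, j in state.jobs.items()}
        assert states["A:0"] == "completed"
        assert states["B:0"] == "failed"
        assert states["C:0"] == "completed"
        assert states["D:0"] == "skipped"

    def test_missing_executable_fails_with_diagnostic(self, tmp_path, toy_tools):
        from deskpipe.workflow_model import WorkflowSpec

        seed = tmp_path / "s.txt"
        seed.write_text("x")
        mod = ModuleSpec(
            id="A", label="A", executable=str(tmp_path / "ghost.sh"),
            parameters=(
                ParameterSpec("in", "input", "file", format_tag="any",
                              default=str(seed), binding="pos:1"),
                ParameterSpec("out", "output", "file", format_tag="any", binding="pos:2"),
            ),
        )
        dag = expand(WorkflowSpec(id="x", nodes=(mod,)), workdir=str(tmp_path / "w"))
        state = Engine(dag).run()
        job = state.jobs["A:0"]
        assert job.state == "failed" and job.diagnostic

    def test_concurrency_limit_respected_for_20_independent_jobs(self, toy_tools, tmp_path):
        from helpers import make_random_dag
        import numpy as np

        from deskpipe.engine import JobDAG, JobInstance

        jobs = {}
        seed = tmp_path / "seed.txt"
        seed.write_text("x")
        for i in range(20):
            out = str(tmp_path / f"o{i}.txt")
            jobs[f"J{i}:0"] = JobInstance(
                job_id=f"J{i}:0", module_id=f"J{i}", instance_index=0,
                argv=[toy_tools["slowcopy.sh"], "0.05", str(seed), out],
                output_paths=[out],
            )
        dag = JobDAG(workflow_id="par", jobs=jobs, workdir=str(tmp_path))
        state = Engine(dag, backend=LocalBackend(capacity=8), limit=4).run()
        assert state.counts()["completed"] == 20
        # oracle: interval-overlap count over the event log
        assert max_concurrency(state) <= 4

    def test_status_counts_are_conserved(self, diamond_workflow, tmp_path):
        spec, _ = diamond_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        engine = Engine(dag)
        st = engine.status()
        assert st["counts"]["pending"] == st["total"] == 4
        state = engine.run()
        st = engine.status()
        done = st["counts"]["completed"] + st["counts"]["failed"] + st["counts"]["skipped"]
        assert done == st["total"]
        assert st["modules"]["A"]["fraction"] == 1.0


class TestPauseResume:
    def _slow_chain(self, toy_tools, tmp_path, delay="0.5"):
        from deskpipe.workflow_model import WorkflowSpec

        seed = tmp_path / "seed.txt"
        seed.write_text("payload\n")
        a = ModuleSpec(
            id="A", label="A", executable=toy_tools["copy.sh"],
            parameters=(
                ParameterSpec("in", "input", "file", format_tag="any",
                              default=str(seed), binding="pos:1"),
                ParameterSpec("out", "output", "file", format_tag="any", binding="pos:2"),
            ),
        )
        b = ModuleSpec(
            id="B", label="B", executable=toy_tools["slowcopy.sh"],
            parameters=(
                ParameterSpec("delay", "input", "number", default=delay, binding="pos:1"),
                ParameterSpec("in", "input", "file", format_tag="any", binding="pos:2"),
                ParameterSpec("out", "output", "file", format_tag="any", binding="pos:3"),
            ),
        )
        return WorkflowSpec(id="slow", nodes=(a, b),
                            connections=(Connection("A", "out", "B", "in"),))

    def test_pause_deletes_partial_outputs_preserves_completed(self, toy_tools, tmp_path):
        spec = self._slow_chain(toy_tools, tmp_path)
        dag = expand(spec, workdir=str(tmp_path / "w"))
        store = str(tmp_path / "run.json")
        engine = Engine(dag, backend=LocalBackend(capacity=2), store_path=store)
        _step_until_running(engine, "B:0")
        notice = engine.pause()
        assert notice == "paused"
        a_out = engine.state.jobs["A:0"].output_paths[0]
        b_out = engine.state.jobs["B:0"].output_paths[0]
        assert os.path.exists(a_out)  # completed output preserved
        assert not os.path.exists(b_out)  # partial output deleted
        assert engine.state.jobs["B:0"].state == "pending"
        assert engine.state.jobs["A:0"].state == "completed"

    def test_pause_with_nothing_running_is_noop_with_notice(self, chain_workflow, tmp_path):
        spec, _ = chain_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        engine = Engine(dag)
        engine.run()
        notice = engine.pause()
        assert "nothing to pause" in notice

    def test_resume_after_pause_matches_uninterrupted_run(self, toy_tools, tmp_path):
        # uninterrupted reference run
        spec = self._slow_chain(toy_tools, tmp_path, delay="0.2")
        dag_ref = expand(spec, workdir=str(tmp_path / "ref"))
        Engine(dag_ref).run()
        ref_sums = checksum_tree(
            p for j in dag_ref.jobs.values() for p in j.output_paths
        )
        # interrupted run: pause mid-B, then resume from the persisted store
        dag = expand(spec, workdir=str(tmp_path / "int"))
        store = str(tmp_path / "run.json")
        engine = Engine(dag, backend=LocalBackend(capacity=2), store_path=store)
        _step_until_running(engine, "B:0")
        engine.pause()
        # simulate process death: rebuild everything from the store alone
        resumed = Engine.resume(store, backend=SerialBackend())
        state = resumed.run()
        assert state.counts()["completed"] == 2
        # completed work is never re-executed: exactly one completion of A
        a_completions = [e for e in state.event_log
                         if e[2] == "A:0" and e[4] == "completed"]
        assert len(a_completions) == 1
        int_sums = checksum_tree(
            p for j in state.jobs.values() for p in j.output_paths
        )
        assert {k: v for k, v in int_sums.items()} == ref_sums

    def test_resume_completed_run_is_noop(self, chain_workflow, tmp_path):
        spec, _ = chain_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        store = str(tmp_path / "run.json")
        Engine(dag, store_path=store).run()
        resumed = Engine.resume(store)
        before = len(resumed.state.event_log)
        state = resumed.run()
        new_submissions = [e for e in state.event_log[before:] if e[4] == "running"]
        assert not new_submissions

    def test_corrupt_store_errors_without_executing(self, tmp_path):
        store = tmp_path / "broken.json"
        store.write_text("{ not json")
        with pytest.raises(ValueError, match="corrupt"):
            Engine.resume(str(store))


class TestRestart:
    def test_diamond_restart_b_invalidates_b_and_d_only(self, diamond_workflow, tmp_path):
        spec, _ = diamond_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        store = str(tmp_path / "run.json")
        engine = Engine(dag, store_path=store)
        engine.run()
        a_out = dag.jobs["A:0"].output_paths[0]
        c_out = dag.jobs["C:0"].output_paths[0]
        invalidated = engine.restart_module("B")
        assert set(invalidated) == {"B:0", "D:0"}
        assert engine.state.jobs["A:0"].state == "completed"
        assert engine.state.jobs["C:0"].state == "completed"
        assert os.path.exists(a_out) and os.path.exists(c_out)
        assert not os.path.exists(dag.jobs["B:0"].output_paths[0])

    def test_restart_then_run_reproduces_fresh_outputs(self, diamond_workflow, tmp_path):
        spec, _ = diamond_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        engine = Engine(dag)
        engine.run()
        fresh = checksum_tree(p for j in dag.jobs.values() for p in j.output_paths)
        engine.restart_module("B")
        state = engine.run()
        assert state.counts()["completed"] == 4
        again = checksum_tree(p for j in state.jobs.values() for p in j.output_paths)
        assert again == fresh

    def test_restart_leaf_invalidates_only_itself(self, diamond_workflow, tmp_path):
        spec, _ = diamond_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        engine = Engine(dag)
        engine.run()
        assert engine.restart_module("D") == ["D:0"]

    def test_unknown_module_errors(self, chain_workflow, tmp_path):
        spec, _ = chain_workflow
        dag = expand(spec, workdir=str(tmp_path / "w"))
        engine = Engine(dag)
        with pytest.raises(KeyError):
            engine.restart_module("nope")


class TestRepeatUntil:
    def _counter(self, toy_tools, tmp_path):
        state = str(tmp_path / "state.txt")
        return ModuleSpec(
            id="counter", label="counter", executable=toy_tools["counter.sh"],
            parameters=(
                ParameterSpec("state", "input", "string", default=state, binding="pos:1"),
                ParameterSpec("increment", "input", "number", default="1", binding="pos:2"),
                ParameterSpec("out", "output", "file", format_tag="any", binding="pos:3"),
            ),
        )

    def test_counter_reaches_three_in_three_iterations(self, toy_tools, tmp_path):
        trace = repeat_until(self._counter(toy_tools, tmp_path), "value >= 3",
                             max_iter=10, workdir=str(tmp_path / "w"))
        assert trace.condition_met and len(trace.iterations) == 3

    def test_condition_true_initially_runs_once(self, toy_tools, tmp_path):
        trace = repeat_until(self._counter(toy_tools, tmp_path), "value >= 1",
                             max_iter=10, workdir=str(tmp_path / "w"))
        assert trace.condition_met and len(trace.iterations) == 1

    def test_never_true_condition_hits_limit_flag(self, toy_tools, tmp_path):
        trace = repeat_until(self._counter(toy_tools, tmp_path), "value < 0",
                             max_iter=5, workdir=str(tmp_path / "w"))
        assert trace.limit_reached and not trace.condition_met
        assert len(trace.iterations) == 5

    def test_unevaluable_condition_errors_after_first_iteration(self, toy_tools, tmp_path):
        from deskpipe.predicates import PredicateError

        with pytest.raises(PredicateError, match="iteration 1"):
            repeat_until(self._counter(toy_tools, tmp_path), "ghost_field > 3",
                         max_iter=5, workdir=str(tmp_path / "w"))

    def test_repeat_node_runs_inside_engine(self, tmp_path):
        path = fx.make_toy_workflow("repeat", str(tmp_path / "r"))
        spec = parse_workflow_file(path)
        dag = expand(spec, workdir=str(tmp_path / "w"))
        state = Engine(dag).run()
        job = state.jobs["count-up:0"]
        assert job.state == "completed"
        assert len(job.repeat["trace"]["iterations"]) == 3
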