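"""Deterministic synthetic-data generation: everything the engine and the
demo analyses need to run end-to-end without external data.

The defaults encode the study conditions the demos model: a 56-label atlas
(non-overlapping ellipsoids on a grid), an ADNI-like study table of 128
subjects whose MMSE-based stratification yields cohorts of 18 (AD), 49
(MCI) and 61 (NC) by construction, a 4-family/186-run registration
manifest, and tiny POSIX-shell toy executables for engine tests.  MMSE
cut-offs (AD 10-19, MCI 20-25, NC 26-30) are fixture constants — disjoint
integer ranges so that the documented cut-off predicates reproduce the
configured cohort sizes exactly.

Identical config + seed => byte-identical outputs.
"""

from __future__ import annotations

import os
import stat
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .shape import MEASURES, LabelVolume
from .smartlines import Volume, write_volume
from .study_design import CohortDefinition
from .workflow_model import (
    Connection,
    ConditionalSpec,
    DataSourceSpec,
    GraphSpec,
    ModuleSpec,
    ParameterSpec,
    RepeatUntilSpec,
    LoopGroupSpec,
    StudySourceSpec,
    WorkflowSpec,
    serialize_workflow,
)

__all__ = [
    "FixtureConfig",
    "MMSE_CUTOFFS",
    "COHORT_DEFINITIONS",
    "make_atlas",
    "make_study",
    "make_signatures",
    "make_irma_reference",
    "make_irma_manifest",
    "make_irma_workflow",
    "write_toy_tools",
    "make_toy_workflow",
]

# Fixture constants (not facts about any real study): disjoint MMSE ranges
# per diagnostic group.
MMSE_CUTOFFS = {"AD": (10, 19), "MCI": (20, 25), "NC": (26, 30)}

COHORT_DEFINITIONS = [
    CohortDefinition("AD", "mmse >= 10 and mmse <= 19"),
    CohortDefinition("MCI", "mmse >= 20 and mmse <= 25"),
    CohortDefinition("NC", "mmse >= 26 and mmse <= 30"),
]

# per-family distortion scales for synthetic "registrations": smaller =
# better aligned; flirt dominates by construction (the manifest split is a
# documented fixture choice, 40+50+48+48 = 186)
IRMA_FAMILY_RUNS = {"air-linear": 40, "air-warp": 50, "flirt": 48, "minc-tracc": 48}
IRMA_FAMILY_SCALE = {"flirt": 0.25, "air-warp": 0.6, "air-linear": 1.0, "minc-tracc": 1.4}


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_labels: int = 56
    cohort_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"AD": 18, "MCI": 49, "NC": 61}
    )
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # (cohort, label, measure, relative effect size) — applied in
    # make_signatures for any measure, and in make_study subject volumes for
    # the volume measure (radius rescaling)
    effects: tuple[tuple[str, int, str, float], ...] = ()
    mmse_ranges: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(MMSE_CUTOFFS)
    )
    irma_family_runs: Mapping[str, int] = field(
        default_factory=lambda: dict(IRMA_FAMILY_RUNS)
    )
    battery_size: int = 11
    signature_noise: float = 0.05  # per-subject coefficient of variation

    @property
    def total_subjects(self) -> int:
        return sum(self.cohort_sizes.values())

    @property
    def irma_total_runs(self) -> int:
        return sum(self.irma_family_runs.values())


def _rng(config: FixtureConfig, stream: str) -> np.random.Generator:
    # zlib.crc32 is stable across processes (str hash is not)
    import zlib

    return np.random.default_rng([config.seed, zlib.crc32(stream.encode()) % (2 ** 31)])


def _check_mmse_ranges(config: FixtureConfig) -> None:
    spans = sorted(config.mmse_ranges.items(), key=lambda kv: kv[1])
    for (name_a, (lo_a, hi_a)), (name_b, (lo_b, hi_b)) in zip(spans, spans[1:]):
        if hi_a >= lo_b:
            raise ValueError(
                f"MMSE ranges overlap: {name_a} {lo_a}-{hi_a} vs {name_b} {lo_b}-{hi_b}; "
                "stratification could not reproduce the configured cohort sizes"
            )


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------


def _ellipsoid_radii(config: FixtureConfig) -> np.ndarray:
    """Per-label base semi-axes, deterministic in the seed."""
    rng = np.random.default_rng(config.seed)
    base = np.array([3.2, 3.6, 2.8])
    jitter = rng.uniform(0.85, 1.15, size=(config.n_labels, 3))
    return base * jitter


def make_atlas(
    config: FixtureConfig | None = None,
    radius_scale: np.ndarray | None = None,
) -> LabelVolume:
    """Multi-label atlas: ``n_labels`` non-overlapping ellipsoids centered on
    a regular grid.  ``radius_scale`` (per-label factors) lets study
    generation deform individual ROIs.

    Raises if the labels cannot fit in ``volume_shape`` without overlap,
    suggesting a larger shape.
    """
    config = config or FixtureConfig()
    radii = _ellipsoid_radii(config)
    if radius_scale is not None:
        radii = radii * np.asarray(radius_scale).reshape(-1, 1)
    grid = int(np.ceil(config.n_labels ** (1.0 / 3.0)))
    cell = 12
    needed = grid * cell
    if any(s < needed for s in config.volume_shape):
        raise ValueError(
            f"{config.n_labels} labels need a volume of at least "
            f"{(needed,) * 3}; got {config.volume_shape} — use a larger shape"
        )
    if np.max(radii) * 2 + 2 > cell:
        raise ValueError("ellipsoid radii too large for the grid cell; use a larger shape")
    data = np.zeros(config.volume_shape, dtype=np.int16)
    zz, yy, xx = np.meshgrid(
        *[np.arange(s) for s in config.volume_shape], indexing="ij"
    )
    label = 0
    table: dict[int, str] = {}
    for gz in range(grid):
        for gy in range(grid):
            for gx in range(grid):
                if label >= config.n_labels:
                    break
                center = (np.array([gz, gy, gx]) * cell) + cell / 2.0
                rz, ry, rx = radii[label]
                inside = (
                    ((zz - center[0]) / rz) ** 2
                    + ((yy - center[1]) / ry) ** 2
                    + ((xx - center[2]) / rx) ** 2
                ) <= 1.0
                data[inside] = label + 1
                table[label + 1] = f"roi_{label + 1:03d}"
                label += 1
    return LabelVolume(data=data, voxel_size=config.voxel_size, label_table=table)


def write_atlas(config: FixtureConfig, path: str) -> str:
    atlas = make_atlas(config)
    write_volume(
        path,
        Volume(atlas.data, atlas.voxel_size, description="synthetic-atlas"),
        "nifti-1",
        "short",
    )
    return path


# ---------------------------------------------------------------------------
# study
# ---------------------------------------------------------------------------


def make_study(
    config: FixtureConfig | None = None,
    out_dir: str = "study",
    write_volumes: bool = True,
) -> str:
    """Generate the ADNI-like study: a CSV table (one row per subject: id,
    diagnosis, MMSE drawn uniformly from the cohort's range, age, sex, image
    path), per-subject metadata XML, and (optionally) per-subject label
    volumes — the atlas deformed by the configured cohort effects plus
    subject-level jitter.  Returns the CSV path.
    """
    from .study_design import write_subject_xml

    config = config or FixtureConfig()
    _check_mmse_ranges(config)
    os.makedirs(out_dir, exist_ok=True)
    vol_dir = os.path.join(out_dir, "volumes")
    meta_dir = os.path.join(out_dir, "metadata")
    os.makedirs(vol_dir, exist_ok=True)
    os.makedirs(meta_dir, exist_ok=True)

    rng = _rng(config, "study")
    rows = []
    subject_no = 0
    for cohort in sorted(config.cohort_sizes):
        lo, hi = config.mmse_ranges[cohort]
        n = config.cohort_sizes[cohort]
        mmse_values = rng.integers(lo, hi + 1, size=n)
        ages = np.clip(np.round(rng.normal(75, 6, size=n)), 55, 92).astype(int)
        sexes = rng.choice(["F", "M"], size=n)
        for k in range(n):
            subject_no += 1
            sid = f"sub-{subject_no:04d}"
            image_path = os.path.join(vol_dir, f"{sid}.nii")
            rows.append(
                {
                    "subject_id": sid,
                    "diagnosis": cohort,
                    "mmse": int(mmse_values[k]),
                    "age": int(ages[k]),
                    "sex": str(sexes[k]),
                    "image_path": image_path,
                }
            )

    df = pd.DataFrame(rows)
    csv_path = os.path.join(out_dir, "study.csv")
    df.to_csv(csv_path, index=False)

    for row in rows:
        write_subject_xml(
            os.path.join(meta_dir, row["subject_id"] + ".xml"),
            row["subject_id"],
            row,
        )

    if write_volumes:
        # volume-measure effects rescale ellipsoid radii: a relative volume
        # change of e maps to a radius factor (1 + e)^(1/3)
        effect_factor: dict[tuple[str, int], float] = {}
        for cohort, label, measure, rel in config.effects:
            if measure == "volume":
                effect_factor[(cohort, label)] = float((1.0 + rel) ** (1.0 / 3.0))
        for row in rows:
            srng = _rng(config, "subject-" + row["subject_id"])
            scale = srng.normal(1.0, 0.02, size=config.n_labels)
            for label in range(1, config.n_labels + 1):
                f = effect_factor.get((row["diagnosis"], label))
                if f is not None:
                    scale[label - 1] *= f
            atlas = make_atlas(config, radius_scale=np.clip(scale, 0.5, 1.45))
            write_volume(
                row["image_path"],
                Volume(atlas.data, atlas.voxel_size,
                       description=f"synthetic {row['subject_id']}"),
                "nifti-1",
                "short",
            )
    return csv_path


# ---------------------------------------------------------------------------
# signature tables (for the statistics demos: signatures drawn directly, so
# null simulations and power checks run in seconds)
# ---------------------------------------------------------------------------


def make_signatures(
    config: FixtureConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-subject per-label six-measure signature table with the configured
    effects planted, plus the cohort membership map.

    Baselines per (label, measure) are drawn once from the seed; subjects
    scatter around them with coefficient of variation ``signature_noise``.
    A configured effect (cohort, label, measure, rel) shifts that cohort's
    mean by ``rel`` times the baseline.
    """
    config = config or FixtureConfig()
    rng = _rng(config, "signatures")
    baseline_scale = {
        "volume": 130.0,
        "surface_area": 140.0,
        "mean_curvature": 0.30,
        "shape_index": 0.85,
        "curvedness": 0.32,
        "fractal_dimension": 2.0,
    }
    labels = list(range(1, config.n_labels + 1))
    baselines = {
        (label, m): baseline_scale[m] * rng.uniform(0.8, 1.2)
        for label in labels
        for m in MEASURES
    }
    effect_map = {
        (cohort, label, measure): rel
        for cohort, label, measure, rel in config.effects
    }
    cohorts: dict[str, list[str]] = {c: [] for c in sorted(config.cohort_sizes)}
    rows = []
    subject_no = 0
    for cohort in sorted(config.cohort_sizes):
        for _ in range(config.cohort_sizes[cohort]):
            subject_no += 1
            sid = f"sub-{subject_no:04d}"
            cohorts[cohort].append(sid)
            for label in labels:
                row = {"subject_id": sid, "label": label}
                for m in MEASURES:
                    mean = baselines[(label, m)]
                    shift = effect_map.get((cohort, label, m), 0.0)
                    sd = config.signature_noise * abs(baselines[(label, m)])
                    row[m] = rng.normal(mean * (1.0 + shift), sd)
                rows.append(row)
    return pd.DataFrame(rows), cohorts


# ---------------------------------------------------------------------------
# IRMA fixtures
# ---------------------------------------------------------------------------


def make_irma_reference(
    config: FixtureConfig | None = None, shape: tuple[int, int, int] = (24, 24, 24)
) -> np.ndarray:
    """Piecewise-constant reference phantom: concentric shells at <= 16
    distinct intensity levels (so Woods' per-class dispersion is exactly 0
    for an identical candidate)."""
    config = config or FixtureConfig()
    center = (np.asarray(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r = np.sqrt(
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    )
    shells = np.minimum((r / (max(shape) / 2.0) * 8).astype(int), 7)
    levels = np.linspace(0, 1000, 8)
    return levels[shells].astype(np.float32)


def make_irma_candidates(
    config: FixtureConfig | None = None, shape: tuple[int, int, int] = (24, 24, 24)
) -> list[tuple[str, str, np.ndarray]]:
    """(instance id, family, candidate volume) triples: the reference under
    a parameterized synthetic warp (subvoxel shift) plus noise, scaled per
    family so that family quality differs by construction."""
    from scipy import ndimage

    config = config or FixtureConfig()
    reference = make_irma_reference(config, shape)
    rng = _rng(config, "irma")
    out = []
    for family in sorted(config.irma_family_runs):
        scale = IRMA_FAMILY_SCALE.get(family, 1.0)
        for k in range(config.irma_family_runs[family]):
            shift = rng.normal(0.0, 0.4 * scale, size=3)
            noise = rng.normal(0.0, 12.0 * scale, size=shape)
            warped = ndimage.shift(reference, shift, order=1, mode="nearest")
            out.append((f"{family}-{k:03d}", family, (warped + noise).astype(np.float32)))
    return out


def make_irma_manifest(
    config: FixtureConfig | None = None, out_dir: str = "irma"
) -> str:
    """Write the reference, all candidate volumes and the manifest CSV
    (family, param_id, path).  Returns the manifest path."""
    config = config or FixtureConfig()
    os.makedirs(os.path.join(out_dir, "candidates"), exist_ok=True)
    reference = make_irma_reference(config)
    write_volume(
        os.path.join(out_dir, "reference.nii"),
        Volume(reference, description="synthetic irma reference"),
        "nifti-1",
        "float",
    )
    rows = []
    for iid, family, vol in make_irma_candidates(config):
        path = os.path.join(out_dir, "candidates", f"{iid}.nii")
        write_volume(path, Volume(vol), "nifti-1", "float")
        rows.append({"family": family, "param_id": iid, "path": path})
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def make_irma_workflow(config: FixtureConfig | None = None) -> WorkflowSpec:
    """The IRMA demo as a workflow: one module node per registration family,
    each fed its editable parameter list, so expansion yields one instance
    per configured run."""
    config = config or FixtureConfig()
    nodes = []
    connections = []
    for family in sorted(config.irma_family_runs):
        n = config.irma_family_runs[family]
        src = DataSourceSpec(
            id=f"{family}-params",
            items=tuple(f"{family}-{k:03d}" for k in range(n)),
        )
        mod = ModuleSpec(
            id=family,
            label=f"{family} registration",
            executable="/bin/echo",
            parameters=(
                ParameterSpec("params", "input", "string", binding="pos:1"),
                ParameterSpec("aligned", "output", "file", format_tag="any",
                              binding="pos:2"),
            ),
        )
        nodes.extend([src, mod])
        connections.append(Connection(src.id, "out", mod.id, "params"))
    return WorkflowSpec(id="irma-demo", nodes=tuple(nodes), connections=tuple(connections))


# ---------------------------------------------------------------------------
# toy executables and workflows for engine tests
# ---------------------------------------------------------------------------

_TOOLS = {
    # copy input to output
    "copy.sh": """#!/bin/sh
cp "$1" "$2"
""",
    # read integer from $1, add $2, write to $3
    "add.sh": """#!/bin/sh
v=$(cat "$1")
echo $((v + $2)) > "$3"
""",
    # concatenate two inputs
    "merge.sh": """#!/bin/sh
cat "$1" "$2" > "$3"
""",
    # copy with a delay (seconds in $1)
    "slowcopy.sh": """#!/bin/sh
sleep "$1"
cp "$2" "$3"
""",
    # deterministic failure after a beat
    "fail.sh": """#!/bin/sh
echo "forced failure" >&2
exit 1
""",
    # stateful counter: add $2 to the value in state file $1, write to $1 and $3
    "counter.sh": """#!/bin/sh
v=0
[ -f "$1" ] && v=$(cat "$1")
v=$((v + $2))
echo "$v" > "$1"
echo "$v" > "$3"
""",
}


def write_toy_tools(out_dir: str) -> dict[str, str]:
    """Write the tiny self-contained POSIX-shell tools and mark them
    executable.  Returns name -> path."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for name, body in _TOOLS.items():
        path = os.path.join(out_dir, name)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(body)
        os.chmod(path, os.stat(path).st_mode | stat.S_IXUSR | stat.S_IXGRP | stat.S_IXOTH)
        paths[name] = path
    return paths


def _copy_module(mod_id: str, tool: str, fmt: str = "any") -> ModuleSpec:
    return ModuleSpec(
        id=mod_id,
        label=mod_id,
        executable=tool,
        parameters=(
            ParameterSpec("in", "input", "file", format_tag=fmt, binding="pos:1"),
            ParameterSpec("out", "output", "file", format_tag=fmt, binding="pos:2"),
        ),
        metadata={"name": mod_id, "version": "1.0"},
    )


def make_toy_workflow(kind: str, out_dir: str) -> str:
    """Emit toy executables plus a ``.pipe.xml`` workflow referencing them.

    Kinds: ``chain`` (A -> B), ``diamond`` (A -> {B, C} -> D), ``loop``
    (loop group over a 3-item source), ``conditional`` (study subjects
    routed into AD / MCI / NC branches via nested if-else).  Returns the
    workflow path.
    """
    os.makedirs(out_dir, exist_ok=True)
    tools = write_toy_tools(os.path.join(out_dir, "tools"))
    seed_path = os.path.join(out_dir, "seed.txt")
    with open(seed_path, "w", encoding="utf-8") as fh:
        fh.write("1\n")

    if kind == "chain":
        a = _copy_module("A", tools["copy.sh"])
        a = replace(a, parameters=(
            ParameterSpec("in", "input", "file", format_tag="any",
                          default=seed_path, binding="pos:1"),
            ParameterSpec("out", "output", "file", format_tag="any", binding="pos:2"),
        ))
        b = _copy_module("B", tools["copy.sh"])
        spec = WorkflowSpec(
            id="toy-chain",
            nodes=(a, b),
            connections=(Connection("A", "out", "B", "in"),),
        )
    elif kind == "diamond":
        a = _copy_module("A", tools["copy.sh"])
        a = replace(a, parameters=(
            ParameterSpec("in", "input", "file", format_tag="any",
                          default=seed_path, binding="pos:1"),
            ParameterSpec("out", "output", "file", format_tag="any", binding="pos:2"),
        ))
        b = _copy_module("B", tools["copy.sh"])
        c = _copy_module("C", tools["copy.sh"])
        d = ModuleSpec(
            id="D",
            label="D",
            executable=tools["merge.sh"],
            parameters=(
                ParameterSpec("in1", "input", "file", format_tag="any", binding="pos:1"),
                ParameterSpec("in2", "input", "file", format_tag="any", binding="pos:2"),
                ParameterSpec("out", "output", "file", format_tag="any", binding="pos:3"),
            ),
            metadata={"name": "D", "version": "1.0"},
        )
        spec = WorkflowSpec(
            id="toy-diamond",
            nodes=(a, b, c, d),
            connections=(
                Connection("A", "out", "B", "in"),
                Connection("A", "out", "C", "in"),
                Connection("B", "out", "D", "in1"),
                Connection("C", "out", "D", "in2"),
            ),
        )
    elif kind == "loop":
        items = []
        for k in range(3):
            p = os.path.join(out_dir, f"item{k}.txt")
            with open(p, "w", encoding="utf-8") as fh:
                fh.write(f"{k}\n")
            items.append(p)
        src = DataSourceSpec(id="items", items=tuple(items), format_tag="any")
        inner = _copy_module("inner", tools["copy.sh"])
        body = GraphSpec(
            nodes=(inner,),
            connections=(Connection("@", "img", "inner", "in"),),
            exports={"out": ("inner", "out")},
        )
        loop = LoopGroupSpec(id="L", iteration_source="items",
                             iteration_var="img", body=body)
        sink = _copy_module("sink", tools["copy.sh"])
        spec = WorkflowSpec(
            id="toy-loop",
            nodes=(src, loop, sink),
            connections=(Connection("L", "out", "sink", "in"),),
        )
    elif kind == "conditional":
        study_csv = _toy_study_csv(out_dir)
        src = StudySourceSpec(id="study", table=study_csv, path_column="image_path",
                              format_tag="any")
        ad = _copy_module("ad-copy", tools["copy.sh"])
        mci = _copy_module("mci-copy", tools["copy.sh"])
        nc = _copy_module("nc-copy", tools["copy.sh"])
        inner_cond = ConditionalSpec(
            id="mci-or-nc",
            predicate="mmse <= 25",
            inputs=("subject",),
            true_branch=GraphSpec(
                nodes=(mci,),
                connections=(Connection("@", "subject", "mci-copy", "in"),),
                exports={"out": ("mci-copy", "out")},
            ),
            false_branch=GraphSpec(
                nodes=(nc,),
                connections=(Connection("@", "subject", "nc-copy", "in"),),
                exports={"out": ("nc-copy", "out")},
            ),
        )
        cond = ConditionalSpec(
            id="route",
            predicate="mmse <= 19",
            inputs=("subject",),
            true_branch=GraphSpec(
                nodes=(ad,),
                connections=(Connection("@", "subject", "ad-copy", "in"),),
                exports={"out": ("ad-copy", "out")},
            ),
            false_branch=GraphSpec(
                nodes=(inner_cond,),
                connections=(Connection("@", "subject", "mci-or-nc", "subject"),),
                exports={"out": ("mci-or-nc", "out")},
            ),
        )
        sink = _copy_module("sink", tools["copy.sh"])
        spec = WorkflowSpec(
            id="toy-conditional",
            nodes=(src, cond, sink),
            connections=(
                Connection("study", "out", "route", "subject"),
                Connection("route", "out", "sink", "in"),
            ),
        )
    elif kind == "repeat":
        state = os.path.join(out_dir, "counter-state.txt")
        counter = ModuleSpec(
            id="counter",
            label="counter",
            executable=tools["counter.sh"],
            parameters=(
                ParameterSpec("state", "input", "string", default=state, binding="pos:1"),
                ParameterSpec("increment", "input", "number", default="1", binding="pos:2"),
                ParameterSpec("out", "output", "file", format_tag="any", binding="pos:3"),
            ),
            metadata={"name": "counter", "version": "1.0"},
        )
        spec = WorkflowSpec(
            id="toy-repeat",
            nodes=(RepeatUntilSpec(id="count-up", module=counter,
                                   condition="value >= 3", max_iter=10),),
            connections=(),
        )
    else:
        raise ValueError(f"unknown toy workflow kind {kind!r}")

    path = os.path.join(out_dir, f"{spec.id}.pipe.xml")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_workflow(spec))
    return path


def _toy_study_csv(out_dir: str) -> str:
    """Six subjects, two per diagnostic group, with existing image files."""
    rows = []
    mmse_by_group = {"AD": (12, 18), "MCI": (21, 24), "NC": (27, 30)}
    i = 0
    for group in ("AD", "MCI", "NC"):
        for mmse in mmse_by_group[group]:
            i += 1
            img = os.path.join(out_dir, f"subj{i}.txt")
            with open(img, "w", encoding="utf-8") as fh:
                fh.write(f"subject {i} ({group})\n")
            rows.append({"subject_id": f"s{i:02d}", "diagnosis": group,
                         "mmse": mmse, "image_path": img})
    csv_path = os.path.join(out_dir, "toy-study.csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
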