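# deskpipe

A desk-scale scientific workflow engine for image-analysis studies, in the
mold of the graphical pipeline environments used by large neuroimaging
laboratories — but as an importable Python library plus a small CLI, sized
to run a whole study protocol on one machine in seconds.

It is aimed at researchers and tool builders who want the *semantics* of
those environments — declarative workflows over external executables,
study-design data sources, automatic format conversion, provenance capture,
robust pause/resume — in a form they can test, script and extend.

## What it does

* **Workflow model** (`deskpipe.workflow_model`): an XML dialect
  (`.pipe.xml`, documented in `docs/pipe-dialect.md` with a schema in
  `docs/pipe.xsd`) describing directed graphs of executable modules
  (referenced, never embedded), data sources, study sources, conditionals,
  loop groups and repeat-until nodes, with typed ports, `${variable}`
  scoping, a static validator, and export to POSIX shell scripts or
  makefiles.
* **Execution engine** (`deskpipe.engine`): expands a workflow into a job
  DAG — list inputs of length *n* become *n* instances zipped by index,
  scalars broadcast, loop bodies replicate per iteration, conditionals
  resolve per instance, smartline mismatches insert conversion jobs — and
  runs it on a pluggable backend (serial, or local-parallel with capacity =
  detected CPUs) with dependency-order safety, concurrency bounds,
  persistent run state, an append-only event log, and pause / resume /
  restart-module semantics.
* **Smartlines** (`deskpipe.smartlines`): content-based format sniffing
  (NIfTI-1, Analyze 7.5, raw + JSON sidecar), shortest-chain conversion
  planning over an extensible registry, voxel-exact widening, and
  policy-guarded lossy narrowing.
* **Provenance** (`deskpipe.provenance`): every engine output gets a
  sibling `.prov` XML record — header-derived identity metadata plus the
  file's full processing lineage (tool, version, checksums, verbatim argv,
  platform, timestamps), updated automatically and append-only.
* **Study design** (`deskpipe.study_design`): uniform subject tables from
  directory scans, per-subject XML metadata, or CSV spreadsheets (with a
  lossless spreadsheet → per-subject XML round trip); predicate-defined
  cohort stratification; contrast enumeration.
* **Demo analyses**: global shape analysis (`deskpipe.shape`) — per-ROI
  isosurface meshes and a six-measure signature (volume, surface area, mean
  curvature, shape index, curvedness, fractal dimension), Welch
  between-cohort tests, and significant-ROI scenes; and a rank-aggregation
  registration meta-algorithm (`deskpipe.irma`) — an 11-metric cost battery
  (including entropy-of-difference and Woods' coefficient), per-metric rank
  transform, and median-rank consensus selection.
* **Synthetic fixtures** (`deskpipe.fixtures`): a deterministic generator
  for everything above — a 56-label ellipsoid atlas, a 128-subject
  ADNI-like study table whose MMSE stratification yields cohorts of
  18/49/61, a 4-family/186-run registration manifest, and shell-script toy
  executables for engine tests.

## The statistics at the core

For cohorts A, B and a shape measure m, each ROI label ℓ is tested with
Welch's two-sample t-statistic

    t = (x̄_A − x̄_B) / sqrt(s²_A/n_A + s²_B/n_B)

two-sided, α = 0.05, with optional Benjamini–Hochberg adjustment; a *scene*
for the contrast (A, B) × m is the set of labels with an (adjusted) p below
α.  Three cohorts × six measures give 18 scenes.  Shape descriptors follow
Koenderink: with principal curvatures κ₁ ≥ κ₂ from a per-vertex quadric
fit, shape index S = (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂)) and curvedness
C = √((κ₁²+κ₂²)/2); fractal dimension is the box-counting slope over the
26-connected boundary voxels.  Registration selection ranks each candidate
within each cost metric (1 = best, average ties) and picks the minimal
median rank — invariant to any strictly monotone rescaling of the metrics.
Details and the reasoning behind every default are in `docs/methods.md`.

## Worked example

```sh
python examples/study_stratification.py
```

prints

```
128 subjects, schema fields: ['subject_id', 'diagnosis', 'mmse', 'age', 'sex', 'image_path', 'metadata_xml']
  AD: 18 subjects  (predicate: mmse >= 10 and mmse <= 19)
  MCI: 49 subjects  (predicate: mmse >= 20 and mmse <= 25)
  NC: 61 subjects  (predicate: mmse >= 26 and mmse <= 30)
unassigned: 0  multi-assigned: 0
18 contrasts = C(3,2) pairs x 6 shape measures
first: Contrast(cohort_a='AD', cohort_b='MCI', measure_id='curvedness')
```

— the synthetic study stratifies into the three diagnostic cohorts exactly
(the generator draws MMSE from disjoint per-cohort ranges), and the 3
cohort pairs × 6 measures yield the 18 contrast cells the shape-analysis
demo fills.  And

```sh
python examples/shape_measures.py
```

prints

```
digital ball r=10 (closed forms in parentheses):
  volume               4169.0 mm^3   (   4188.8)
  surface area         1227.0 mm^2   (   1256.6)
  mean curvature       0.0992 1/mm   (   0.1000)
  shape index           0.992        (   +1.000)
  curvedness           0.0993 1/mm   (   0.1000)
  fractal dimension     1.973        (    2.000)

planted +40% mean-curvature effect in label 7 (AD vs NC):
  scene AD-NC/mean_curvature lists labels [7]
```

— the six measures land on the sphere's closed forms (within the
discretization tolerances documented in `docs/methods.md`), and a planted
group effect surfaces as exactly one scene member.  The other examples tour
the engine (`run_workflow.py`), smartlines (`smartline_conversion.py`),
provenance (`provenance_tour.py`) and registration ranking
(`irma_ranking.py`).

The same functionality is scriptable from a shell:

```sh
deskpipe fixtures make --seed 0 --out demo --what study --no-volumes
deskpipe study stratify demo/study/study.csv
deskpipe validate workflow.pipe.xml
deskpipe run workflow.pipe.xml --workdir work --backend local
deskpipe status work/run.json
deskpipe export-script workflow.pipe.xml --dialect make
```

## Layout

```
src/deskpipe/      library (workflow model, engine, smartlines, provenance,
                   study design, shape analysis, registration ranking,
                   synthetic fixtures, CLI)
docs/              methods note, workflow/provenance dialect + XSD schemas
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance recomputation
```
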