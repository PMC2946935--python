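# Methods

deskpipe is a desk-scale re-creation of the workflow-engine paradigm used in
large neuroimaging laboratories: declarative XML workflows over referenced
external executables, study-design data sources, automatic format
reconciliation, and per-dataset provenance capture — plus two demonstration
analyses (global shape analysis of labelled volumes, and a rank-aggregation
registration meta-algorithm) that exercise the engine end to end on
synthetic data.  This note records the models, the parameters that matter,
and the numerical and design choices.

## Workflow model and execution semantics

**Expansion before execution.**  A workflow is statically flattened into a
job DAG before anything runs.  The rules:

* A data source with *n* items makes each consuming module expand to *n*
  instances, **zipped by index**; scalar inputs broadcast to all instances.
  Two list inputs of different lengths on one module are a cardinality
  error — cross products are expressed by nesting loop groups, never
  implicitly.  (The zip-with-broadcast rule is a design choice: indexed
  instance arrays need some multi-list combination rule, and zip is the
  least surprising.)
* Loop-group bodies are replicated once per iteration-source item, and the
  iteration count is frozen at expansion.  A paused-then-resumed run
  therefore never re-evaluates iteration counts; if the source list changed
  on disk meanwhile, the run still reflects the original expansion.
* Conditional predicates are evaluated per instance against the instance's
  metadata record and the variable scopes.  Both branches are instantiated;
  the untaken branch's jobs are marked `skipped` (not failed) so job
  accounting stays conservative.
* A smartline connection whose provider and receiver disagree on file
  format or voxel dtype inserts one conversion job per instance.  Conversion
  jobs are mutually independent and run in parallel like any other jobs.
* `repeatUntil` is the single dynamic construct: the wrapped module is
  re-executed (at run time, inside one job) until a predicate over its
  parsed outputs holds or `maxIter` is reached.  Scripts cannot express it,
  so script export refuses workflows containing one.

**Scheduling.**  The engine is step-driven: each round polls running jobs
and submits ready ones, bounded by `min(limit, backend capacity)`.  The
backend contract is `submit / cancel / poll / capacity`; shipped
implementations are a serial backend and a local-parallel backend whose
capacity defaults to the detected number of processing units.  Grid
backends are intentionally out of scope — the contract is the extension
point.  Cancellation is polite terminate followed by a forced kill after a
configurable grace period (default 2 s).

**Pause / resume / restart.**  Pause cancels running jobs, deletes *their
declared output files only* (never user files; the `.prov` sibling,
Analyze `.hdr` and raw sidecar files are treated as derived outputs), and
resets them to pending; completed jobs and their outputs are untouched.
State is persisted to a single JSON store per run plus an append-only
event-log file (timestamp, sequence number, job, transition), so resume
works from disk alone in a fresh process; jobs recorded as running in the
store (a crashed run) are reset to pending with partial outputs removed.
Restarting a module invalidates all of its instances and their transitive
successors and deletes their outputs; ancestors and independent branches
keep their state.  With deterministic tools, any interleaving of pause,
resume and restart yields final outputs byte-identical to an uninterrupted
run — this is asserted over randomized DAGs in the test suite.

**Script export.**  A valid, fully static workflow exports to a POSIX shell
script (commands in topological order, parallel groups delimited by
comments) or a makefile (one target per output file, prerequisites =
upstream outputs; secondary outputs of a multi-output job depend on the
primary).  The exported shell script uses the same generated output paths
as the engine, so its outputs are byte-identical.

## Smartlines

Formats implemented: NIfTI-1, Analyze 7.5, and raw volume with a JSON
sidecar (`.rvh`: shape, dtype, voxel size, endianness).  Sniffing reads
magic bytes — NIfTI `n+1`/`ni1` at offset 344, the Analyze `sizeof_hdr ==
348` signature — and content always overrides the extension.  MINC/MGZ are
out of scope; the conversion registry is the plugin point for adding them.

Planning is breadth-first over registry edges in (format, dtype) space:
the empty plan iff the source already satisfies the target, otherwise the
shortest chain, ties broken by edge registration order (deterministic).  An
unreachable target is reported as unsatisfiable, never guessed.

Widening dtype moves (byte → short → float) are voxel-exact.  Narrowing
requires an explicit lossy policy: `rescale` affinely maps the observed
min/max onto the full target range; `clip` rounds and saturates.  The
policy is supplied per conversion through a workflow-level table — the
non-interactive replacement for a GUI prompt.  Geometry metadata is copied
to the extent the target format can hold it: Analyze 7.5 has no full
affine, so orientation is lost there (voxel sizes survive); this loss is
accepted and documented rather than worked around.

## Provenance

Every output file gets a sibling `<file>.prov` XML record: identity
metadata extracted from the image header (dimensions, voxel sizes, dtype,
description; fields a format lacks are marked `unavailable`) plus ordered
processing steps.  A step stores the tool name and version, the executable
path with a SHA-256 content checksum (algorithm name stored beside the
value), the verbatim argument list, OS/architecture, start/end timestamps,
and input ids with checksums.  Compilation flags of external binaries are
unknowable at run time, so they are an optional free-text field the module
author supplies in module metadata.

A record carries only its dataset's own lineage: the steps of the producing
job and of the jobs that produced its inputs, recursively, ordered by
completion time, each ancestor exactly once.  History is append-only; the
single exception is restart-replacement (a re-run job's step is updated in
place, not duplicated).  DICOM extraction is out of scope; the header
handler table is the extension point.

## Study design

Subject tables are uniform by construction: every record carries exactly
the schema's fields.  Three construction routes: directory scans (subject
id = the match pattern's first capture group), per-subject XML metadata
files (leaf elements flattened to dotted field names; non-uniform field
sets are an error naming the offending file), and CSV spreadsheets (header
row mandatory; one hierarchical XML metadata file is emitted per subject,
so spreadsheet → XML → import is a lossless round trip).  Column types are
inferred: numeric if every non-empty value parses as a number, else string.

Cohorts are defined by predicates — comparisons on metadata fields joined
by `and`/`or`/`not`, no arbitrary code.  Stratification assigns each
subject to every cohort whose predicate it satisfies; unassigned and
multiply-assigned subjects are reported, not fatal, since study criteria
are not required to partition the population.  Contrasts enumerate all
unordered cohort pairs crossed with the requested measures, in
lexicographic order: C(n,2)·m contrasts.

## Global shape analysis

Each label's ROI is extracted as a binary mask and a closed triangular
mesh: the 0.5-level marching-cubes isosurface of the Gaussian-smoothed
(σ = 1 voxel) binary indicator.  Smoothing suppresses the voxel staircase
that would otherwise bias surface area (≈ +9 % on a radius-10 ball) and
curvature; labels too small to survive smoothing fall back to the raw
indicator, and labels under 8 voxels are skipped with a warning.  Faces are
oriented outward (positive signed volume).

The six-measure signature per ROI:

* **volume** = voxel count × voxel volume (mm³);
* **surface area** = Σ triangle areas (mm²);
* **mean curvature** (mm⁻¹): area-weighted vertex mean of H = (κ₁+κ₂)/2;
* **shape index** (dimensionless, [−1, 1]): area-weighted mean of
  Koenderink's S = (2/π)·arctan((κ₁+κ₂)/(κ₁−κ₂)), κ₁ ≥ κ₂, with S := ±1 at
  umbilic points by the sign of the curvature;
* **curvedness** (mm⁻¹): area-weighted mean of C = √((κ₁²+κ₂²)/2);
* **fractal dimension** (dimensionless): box counting over the 26-connected
  boundary voxel set at box sizes {1, 2, 4, 8, 16}, least-squares slope of
  log N vs log(1/s).

Principal curvatures come from a per-vertex quadric fit over the 2-ring
neighborhood: in the tangent frame (vertex normal = area-weighted face
normal average), fit h = a·u² + b·uv + c·v² + d·u + e·v and take the shape
operator W = I⁻¹II from the fitted fundamental forms, negated so convex
regions under outward normals have positive curvature (a ball gives
H = +1/r, S = +1).  Because S and C are strongly nonlinear near umbilic
points, the mean- and Gaussian-curvature fields are area-weighted-averaged
over the 2-ring for 3 passes before recovering κ = H ± √(max(H²−K, 0)); on
a radius-10 digital ball this estimator lands within 1 % of 1/r for H and
C and gives S ≈ 0.99.  Vertex integration weights are one third of the
incident triangle areas.

Between-cohort statistics use Welch's two-sample t-test, two-sided, per
label on one measure, with α = 0.05 and correction `none` by default and
Benjamini–Hochberg available as `bh-fdr` — the choice of test and
correction is this package's own, documented as a standard choice rather
than a reproduction of any external tool.  A cohort with fewer than two
subjects yields an unavailable marker, never a crash.  Scenes are one per
contrast × measure and contain exactly the flagged labels: 3 cohorts × 6
measures → 18 scenes.  Scenes serialize to XML with per-ROI meshes in
Wavefront OBJ and statistics tables in CSV.

## Registration meta-algorithm

Candidate alignments are scored with a battery of similarity costs (lower =
better), rank-transformed within each metric (ascending, average-rank
ties), and the consensus winner has the minimal median rank across metrics,
ties broken by mean rank, then row order; families are ordered by their
best member.  Rank aggregation makes the selection invariant to strictly
monotone per-metric rescaling (property-tested), which is the point of the
design: the metrics live on incomparable scales.  Median-rank consensus is
this package's documented selection rule; richer dimensionality-reduction
selections exist and the rank matrix is exposed for them.

The default battery has 11 metrics.  Two are specified exactly: **EDI**,
the Shannon entropy of the 64-bin histogram of voxelwise intensity
differences over the observed range (0 when the difference image is
constant), and **Woods' coefficient**, the mean over 16 equal-width
reference-intensity classes of the coefficient of variation (std/mean) of
candidate intensities per class.  Woods' documented optimum of 0 on
identical inputs holds when each reference class is internally constant —
true for the piecewise-constant phantom used here (≤ 16 distinct levels),
not for arbitrary continuous references.  The remaining nine are standard:
MSE, MAE, RMSE, median absolute difference, Chebyshev distance, SSD
normalized by reference variance, 1−|NCC|, gradient-magnitude MSE, and a
normalized-mutual-information cost (2 − NMI on a 32-bin joint histogram).

## The synthetic-data generator

The generator emulates the *structure* of a multi-cohort neuroimaging
study, not its physics.  Defaults (all in `FixtureConfig`):

* **Atlas**: 56 non-overlapping ellipsoids (semi-axes ≈ 2.4–4.1 voxels,
  jittered per label from the seed) on a 12-voxel grid in a 48³ volume,
  1 mm isotropic.
* **Study**: 128 subjects in cohorts AD = 18, MCI = 49, NC = 61.  MMSE
  scores are drawn uniformly from disjoint fixture ranges — AD 10–19,
  MCI 20–25, NC 26–30 — so stratification by the documented cut-offs
  reproduces the configured sizes exactly.  (These cut-offs are fixture
  constants, not clinical facts.)  Age ~ N(75, 6²) clipped to [55, 92];
  sex drawn uniformly.  Per-subject volumes are the atlas with per-label
  radius jitter (σ = 2 %) and configured cohort effects; a relative volume
  effect e rescales radii by (1+e)^(1/3).
* **Signature tables**: for statistics-level tests, six-measure signatures
  are drawn directly around per-(label, measure) baselines with a 5 %
  coefficient of variation, with configured effects shifting cohort means —
  this keeps null simulations (500 replicates) and permutation oracles
  (10,000 permutations) inside seconds instead of meshing thousands of
  volumes.
* **Registration manifest**: 186 runs split air-linear 40 / air-warp 50 /
  flirt 48 / minc-tracc 48 (the split is a generator choice; only the total
  and the four families are given conditions).  Candidates are the
  piecewise-constant phantom under a subvoxel shift plus Gaussian noise,
  with per-family distortion scales (flirt 0.25 … minc-tracc 1.4), so
  family quality differs by construction and the consensus ordering is
  known.
* **Toy executables**: six POSIX-shell tools (copy, add, merge, slow copy,
  forced failure, stateful counter) emitted at test time, honoring
  execution-by-reference.

Identical config + seed gives byte-identical outputs (RNG streams are
keyed by seed and a CRC of the stream name, so results are stable across
processes).  What passing tests on these fixtures shows: the engine's
scheduling, persistence and provenance semantics, the measures' numerics,
and the statistics' calibration.  What they do not show: behavior on real
MRI (anatomy, intensity inhomogeneity, registration error structure),
performance at cluster scale, or robustness to malformed third-party
headers.

**Recoverability check.**  The planted-effect power check runs
`group_compare` with BH at q = 0.001: at the documented effect size (+30 %
on a 5 %-CV measure, ≈ 22 standard errors for n = 18 vs 61) power is
saturated, and the stringent q keeps the no-false-positive requirement
satisfiable in ≥ 95 % of seeds.  The analysis default remains α = 0.05,
correction `none`.

## Problem sizes and tolerances

The test suite runs on one CPU in well under the minute-scale budgets per
area: 200 randomized DAGs for dependency-order safety, 8 interleaving
scenarios for pause/resume equivalence, 500-replicate null calibration
(flag rate within 4 binomial standard errors of α), digital balls of radius
10 and 20 (volume within 2 %, area 5 %, curvatures 10 %, shape index in
[0.9, 1], fractal dimension 2.0 ± 0.15), and ellipsoid scale laws at two
scales (ratios within 5–10 %).  These tolerances reflect the discretization
error of marching cubes plus the curvature estimator's bias at these radii;
they tighten as radius grows.

## Known limitations

* No grid/DRMAA backends, client–server protocol, authentication, or GUI;
  the backend contract and the registry/handler tables are the extension
  points.
* The makefile export re-lists multi-output recipes via a
  primary-target convention; `make -j` correctness relies on that
  convention.
* Analyze 7.5 orientation loss (above).
* The CLI `pause` on a store from another process resets running jobs
  without being able to signal them (no cross-process handles); in-process
  pause cancels properly.
* Shape-index averaging over a whole ROI can blur sign structure on
  surfaces mixing convex and concave sheets; the per-vertex fields are
  available for finer analyses.
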