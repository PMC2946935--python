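# The `.pipe.xml` workflow dialect

A workflow document is a single `<pipeline id="...">` element containing
variables, nodes and connections.  A formal schema ships as
[`pipe.xsd`](pipe.xsd); the provenance dialect is described at the end with
its schema in [`prov.xsd`](prov.xsd).

## Variables

```xml
<variables>
  <variable name="sigma" value="2.0"/>
  <variable name="images"><item>a.nii</item><item>b.nii</item></variable>
</variables>
```

Scalar variables substitute into parameter values and data-source items as
`${name}` tokens.  List variables can serve as loop-group iteration sources.
Scopes nest: a loop-group body's variables shadow the globals; an unresolved
token is a validation finding, not a crash.

## Nodes

### `<module>` — an external executable, referenced, never embedded

```xml
<module id="smooth" label="Smooth volume" executable="/opt/tools/smooth.sh">
  <metadata author="..." version="1.2" citation="..." license="..."
            compilation_flags="-O2"/>
  <environment>needs POSIX sh</environment>
  <parameter name="in"    direction="input"  kind="file" format="nifti-1"
             dtype="float" binding="pos:1"/>
  <parameter name="sigma" direction="input"  kind="number" required="false"
             default="${sigma}" binding="flag:-s"/>
  <parameter name="out"   direction="output" kind="file" format="nifti-1"
             binding="pos:2"/>
</module>
```

Parameter attributes:

| attribute     | values                                                 |
| ------------- | ------------------------------------------------------ |
| `direction`   | `input`, `output` (outputs must be `kind="file"`)      |
| `kind`        | `file`, `string`, `number`, `enumeration`, `flag`      |
| `format`      | `nifti-1`, `analyze-7.5`, `raw-volume`, `csv`, `xml-metadata`, `any` |
| `dtype`       | `byte`, `short`, `float` (voxel dtype of file params)  |
| `cardinality` | `scalar` (default) or `list` (not allowed on flags)    |
| `required`    | `true` (default) / `false`                             |
| `default`     | literal or `${variable}` binding                       |
| `binding`     | `pos:N` (0-based position) or `flag:<token>`           |

The command line is assembled as: executable, then flag-bound parameters in
declaration order, then positional parameters ordered by their `pos:N`
index.  Output parameters receive engine-generated paths under
`<workdir>/outputs/<node>/<instance>/<param><ext>`.

### `<dataSource>` — a literal value list (output port `out`)

```xml
<dataSource id="inputs" format="nifti-1" dtype="float">
  <item>subject1.nii</item>
  <item>subject2.nii</item>
</dataSource>
```

A source with *n* items makes every downstream module expand to *n*
instances (zip-by-index; scalar inputs broadcast; two list inputs of
different lengths are a cardinality error).

### `<studySource>` — a study-design data source (output port `out`)

```xml
<studySource id="study" table="study.csv" pathColumn="image_path"
             cohort="mmse &lt;= 19"/>
```

Emits one instance per CSV row (optionally restricted by the `cohort`
predicate); the instance value is the image path and the full metadata
record rides along for downstream conditionals.

### `<conditional>` — per-instance if-else

```xml
<conditional id="route" predicate="mmse &lt;= 19">
  <input port="subject"/>
  <branch which="true"> ...nodes, connections, exports... </branch>
  <branch which="false"> ... </branch>
</conditional>
```

The predicate (comparisons on metadata fields/variables joined by
`and`/`or`/`not`) is evaluated once per instance; the untaken branch's jobs
are created and marked `skipped`.  Inside a branch, connections may use the
pseudo-node `@` to reference the conditional's input ports.  Both branches
must export identically named output ports via
`<export port="out" node="inner" parameter="out"/>`.

### `<loopGroup>` — static iteration

```xml
<loopGroup id="per-image" iterationSource="inputs" iterationVar="img">
  <body>
    <module id="inner" ...> ... </module>
    <connection source="@" sourcePort="img" target="inner" targetPort="in"/>
  </body>
  <export port="out" node="inner" parameter="out"/>
</loopGroup>
```

`iterationSource` names a data/study source node or a list variable.  The
body is replicated once per item **before execution begins** (iteration
counts are frozen at expansion); `@.<iterationVar>` carries the current
item, and `${<iterationVar>}` / `${__index__}` substitute into values.

### `<repeatUntil>` — dynamic per-module looping

```xml
<repeatUntil id="converge" condition="value &gt;= 3" maxIter="10">
  <module id="step" ...> ... </module>
</repeatUntil>
```

The wrapped module is re-executed until the condition holds on its outputs
(`value` names the first output's parsed content, `iteration` the 1-based
count) or `maxIter` is reached.  Being dynamic, these nodes cannot be
exported to a static script.

## Connections

```xml
<connection source="smooth" sourcePort="out"
            target="stats" targetPort="in" smartline="true"/>
```

Connections join an output port to an input port.  With `smartline="true"`,
a format/dtype mismatch between provider and receiver inserts one
conversion job per instance (planned as the shortest chain through the
conversion registry); without it, a mismatch is a `type-mismatch`
validation finding.

## Determinism

Serialization orders nodes by id and connections lexicographically, so
`parse ∘ serialize` and `serialize ∘ parse` are identities and two
serializations of the same workflow are byte-identical.

## The `.prov` provenance dialect

Each dataset file written by the engine gets a sibling `<file>.prov`:

```xml
<provenance dataset="work/outputs/B/0/out.nii">
  <identity>
    <field name="dimensions">48x48x48</field>
    ...
  </identity>
  <steps>
    <step index="0" job="A:0">
      <tool name="A" version="1.0"/>
      <executable path="/opt/tools/a.sh" checksum="sha256:..."/>
      <arguments><arg>/opt/tools/a.sh</arg>...</arguments>
      <platform os="Linux" arch="x86_64"/>
      <started>2026-01-01T00:00:00+00:00</started>
      <ended>2026-01-01T00:00:01+00:00</ended>
      <inputs><file id="seed.txt" checksum="sha256:..."/></inputs>
      <outputs><file id="work/outputs/A/0/out.nii"/></outputs>
      <compilationFlags>-O2</compilationFlags>
    </step>
  </steps>
</provenance>
```

Steps are ordered by completion time and each record carries only its
dataset's own lineage.  History is append-only; the single exception is
restart-replacement, where a re-run job's step is updated in place.
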