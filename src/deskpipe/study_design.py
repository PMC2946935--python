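"""Study design: uniform per-subject tables, cohort stratification, contrasts.

A study table holds one record per subject — image paths plus a metadata map
whose field set is identical for every subject ("uniform" schema).  Tables
are built from directory scans, from per-subject XML metadata files, or from
a CSV spreadsheet (which also emits one hierarchical XML metadata file per
subject, so the spreadsheet and metadata routes round-trip).

Cohorts are predicate-defined subject subsets (see :mod:`deskpipe.predicates`
for the predicate language); stratification reports unassigned and
multiply-assigned subjects rather than failing, since study criteria are not
required to partition the population.
"""

from __future__ import annotations

import csv
import os
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from itertools import combinations
from typing import Any, Iterable, Mapping

import pandas as pd

from .predicates import Predicate, PredicateError

__all__ = [
    "SubjectRecord",
    "StudyTable",
    "CohortDefinition",
    "Cohort",
    "Contrast",
    "BuildReport",
    "StratificationReport",
    "UniformityError",
    "build_from_directory",
    "build_from_metadata_files",
    "build_from_spreadsheet",
    "write_subject_xml",
    "stratify",
    "enumerate_contrasts",
]


class UniformityError(ValueError):
    """Metadata field sets differ across subjects."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    image_paths: Mapping[str, str] = field(default_factory=dict)
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def env(self) -> dict[str, Any]:
        """Evaluation environment for predicates."""
        out = dict(self.metadata)
        out.setdefault("subject_id", self.subject_id)
        return out


@dataclass
class StudyTable:
    records: list[SubjectRecord]
    schema: list[tuple[str, str]]  # ordered (field name, type) pairs

    def __post_init__(self) -> None:
        ids = [r.subject_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dup}")
        fields = [name for name, _ in self.schema]
        for rec in self.records:
            if sorted(rec.metadata) != sorted(fields):
                raise UniformityError(
                    f"subject {rec.subject_id!r} has fields "
                    f"{sorted(rec.metadata)}, schema expects {sorted(fields)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def field_names(self) -> list[str]:
        return [name for name, _ in self.schema]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = {"subject_id": rec.subject_id}
            row.update(rec.metadata)
            for name, path in rec.image_paths.items():
                row[name] = path
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortDefinition:
    name: str
    predicate: str


@dataclass
class Cohort:
    name: str
    predicate: str
    members: list[SubjectRecord]

    def __len__(self) -> int:
        return len(self.members)

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.members]


@dataclass(frozen=True)
class Contrast:
    """Unordered cohort pair compared on one measure; stored sorted."""

    cohort_a: str
    cohort_b: str
    measure_id: str

    def __post_init__(self) -> None:
        if self.cohort_a == self.cohort_b:
            raise ValueError("contrast requires two distinct cohorts")
        lo, hi = sorted((self.cohort_a, self.cohort_b))
        object.__setattr__(self, "cohort_a", lo)
        object.__setattr__(self, "cohort_b", hi)

    @staticmethod
    def from_pair(a: str, b: str, measure_id: str) -> "Contrast":
        lo, hi = sorted((a, b))
        return Contrast(lo, hi, measure_id)

    @property
    def name(self) -> str:
        return f"{self.cohort_a}-{self.cohort_b}"


@dataclass
class BuildReport:
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (path, reason)
    missing_images: list[str] = field(default_factory=list)  # subject ids
    warnings: list[str] = field(default_factory=list)


@dataclass
class StratificationReport:
    unassigned: list[str] = field(default_factory=list)
    multi_assigned: list[tuple[str, list[str]]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# typed-value inference (documented rule: numeric if all values parse, else
# string; empty strings stay empty strings)
# ---------------------------------------------------------------------------


def _parse_number(text: str):
    try:
        f = float(text)
    except (TypeError, ValueError):
        return None
    return int(f) if f.is_integer() and "." not in text and "e" not in text.lower() else f


def infer_column_types(columns: Mapping[str, list[str]]) -> dict[str, str]:
    out: dict[str, str] = {}
    for name, values in columns.items():
        nonempty = [v for v in values if v != ""]
        if nonempty and all(_parse_number(v) is not None for v in nonempty):
            out[name] = "number"
        else:
            out[name] = "string"
    return out


def _typed(value: str, typ: str):
    if typ == "number" and value != "":
        return _parse_number(value)
    return value


# ---------------------------------------------------------------------------
# construction mode 1: filenames/directories
# ---------------------------------------------------------------------------


def build_from_directory(
    root: str,
    match_rule: str,
    recursive: bool = True,
    type_filter: str | None = None,
    filters: Iterable[str] = (),
) -> tuple[StudyTable, BuildReport]:
    """Scan ``root`` for files whose *filename* matches the regex
    ``match_rule``; the subject id is the pattern's first capture group.

    ``type_filter`` restricts matches to one sniffed format tag;
    ``filters`` are predicates evaluated over ``subject_id``/``filename``/
    ``path``.  Zero matches yield an empty table plus a warning, not an
    error.
    """
    from . import smartlines

    if not os.path.isdir(root):
        raise NotADirectoryError(f"study root {root!r} does not exist")
    pattern = re.compile(match_rule)
    if pattern.groups < 1:
        raise ValueError("match_rule must contain a capture group for the subject id")
    compiled_filters = [Predicate(f) for f in filters]

    report = BuildReport()
    records: list[SubjectRecord] = []
    if recursive:
        walker = (
            os.path.join(dirpath, fn)
            for dirpath, _, files in os.walk(root)
            for fn in sorted(files)
        )
    else:
        walker = (
            os.path.join(root, fn)
            for fn in sorted(os.listdir(root))
            if os.path.isfile(os.path.join(root, fn))
        )
    for path in sorted(walker):
        fn = os.path.basename(path)
        m = pattern.fullmatch(fn) or pattern.match(fn)
        if not m:
            continue
        if type_filter is not None:
            try:
                desc = smartlines.sniff_format(path)
            except (smartlines.UnknownFormatError, FileNotFoundError):
                report.skipped.append((path, "unrecognized format"))
                continue
            if desc.format_id != type_filter:
                report.skipped.append(
                    (path, f"format {desc.format_id} != filter {type_filter}")
                )
                continue
        subject_id = m.group(1)
        env = {"subject_id": subject_id, "filename": fn, "path": path}
        if compiled_filters and not all(p.evaluate(env) for p in compiled_filters):
            report.skipped.append((path, "excluded by filter"))
            continue
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                image_paths={"image": path},
                metadata={"image_path": path},
            )
        )
    if not records:
        report.warnings.append(f"no files under {root!r} matched {match_rule!r}")
    table = StudyTable(records=records, schema=[("image_path", "string")])
    return table, report


# ---------------------------------------------------------------------------
# construction mode 2: per-subject XML metadata files
# ---------------------------------------------------------------------------


def _flatten_xml(el: ET.Element, prefix: str = "") -> dict[str, str]:
    """Flatten leaf elements to dotted field names."""
    out: dict[str, str] = {}
    children = list(el)
    if not children:
        out[prefix.rstrip(".")] = (el.text or "").strip()
        return out
    for child in children:
        out.update(_flatten_xml(child, prefix + child.tag + "."))
    return out


def build_from_metadata_files(
    directory: str,
    data_path_element: str,
    match_rule: str = r".*\.xml$",
) -> tuple[StudyTable, BuildReport]:
    """One record per per-subject XML metadata file in ``directory``.

    The image path is read from ``data_path_element`` (dotted leaf name); all
    leaf elements become schema fields.  Non-uniform field sets across files
    raise :class:`UniformityError` naming the offending file and field;
    files lacking the data-path element are reported and excluded.
    """
    if not os.path.isdir(directory):
        raise NotADirectoryError(directory)
    pattern = re.compile(match_rule)
    report = BuildReport()
    parsed: list[tuple[str, str, dict[str, str]]] = []  # (file, subject_id, fields)
    for fn in sorted(os.listdir(directory)):
        if not pattern.match(fn):
            continue
        path = os.path.join(directory, fn)
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            report.skipped.append((path, f"malformed XML: {exc}"))
            continue
        fields = _flatten_xml(root)
        subject_id = root.get("id") or fields.get("subject_id") or os.path.splitext(fn)[0]
        if data_path_element not in fields:
            report.skipped.append(
                (path, f"missing data-path element {data_path_element!r}")
            )
            continue
        parsed.append((path, subject_id, fields))

    if parsed:
        reference_file, _, reference_fields = parsed[0]
        ref_set = set(reference_fields)
        for path, _, fields in parsed[1:]:
            diff = set(fields) ^ ref_set
            if diff:
                raise UniformityError(
                    f"metadata file {path!r} has inconsistent field(s) "
                    f"{sorted(diff)} relative to {reference_file!r}"
                )

    columns: dict[str, list[str]] = {}
    for _, _, fields in parsed:
        for k, v in fields.items():
            columns.setdefault(k, []).append(v)
    types = infer_column_types(columns)

    records = []
    for path, subject_id, fields in parsed:
        metadata = {k: _typed(v, types[k]) for k, v in fields.items()}
        image = str(fields[data_path_element])
        if not os.path.exists(image):
            report.missing_images.append(subject_id)
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                image_paths={"image": image},
                metadata=metadata,
            )
        )
    schema = [(name, types[name]) for name in sorted(columns)]
    if not records:
        report.warnings.append(f"no metadata files under {directory!r} matched")
    return StudyTable(records=records, schema=schema), report


# ---------------------------------------------------------------------------
# construction mode 3: CSV spreadsheet
# ---------------------------------------------------------------------------


def write_subject_xml(path: str, subject_id: str, fields: Mapping[str, Any]) -> None:
    """Per-subject metadata XML: one root, one element per column, nesting
    via dotted column names."""
    root = ET.Element("subject", {"id": subject_id})
    for name in fields:
        parts = name.split(".")
        el = root
        for part in parts[:-1]:
            nxt = el.find(part)
            if nxt is None:
                nxt = ET.SubElement(el, part)
            el = nxt
        leaf = ET.SubElement(el, parts[-1])
        leaf.text = str(fields[name])
    ET.indent(root)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ET.tostring(root, encoding="unicode") + "\n")


def build_from_spreadsheet(
    csv_path: str,
    path_column: str,
    metadata_dir: str | None = None,
    id_column: str | None = None,
) -> tuple[StudyTable, BuildReport]:
    """Build a table from a CSV spreadsheet (RFC 4180, header row mandatory)
    and write one hierarchical XML metadata file per subject.

    ``metadata_dir`` defaults to ``<csv dir>/metadata``.  Re-importing those
    XML files via :func:`build_from_metadata_files` reproduces the table.
    Ragged rows raise an error naming the 1-based row number.
    """
    with open(csv_path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        rows = list(reader)
    if not rows:
        raise ValueError(f"{csv_path}: empty file, header row is mandatory")
    header = rows[0]
    if path_column not in header:
        raise ValueError(f"{csv_path}: path column {path_column!r} not in header {header}")
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(
                f"{csv_path}: row {i} has {len(row)} fields, header has {len(header)}"
            )
    report = BuildReport()
    data_rows = rows[1:]
    if not data_rows:
        report.warnings.append(f"{csv_path}: no data rows")

    columns = {name: [row[j] for row in data_rows] for j, name in enumerate(header)}
    types = infer_column_types(columns)
    id_col = id_column or ("subject_id" if "subject_id" in header else header[0])

    if metadata_dir is None:
        metadata_dir = os.path.join(os.path.dirname(os.path.abspath(csv_path)), "metadata")
    os.makedirs(metadata_dir, exist_ok=True)

    records = []
    for row in data_rows:
        fields = dict(zip(header, row))
        subject_id = str(fields[id_col])
        xml_path = os.path.join(metadata_dir, f"{subject_id}.xml")
        write_subject_xml(xml_path, subject_id, fields)
        image = fields[path_column]
        if not os.path.exists(image):
            report.missing_images.append(subject_id)
        metadata = {k: _typed(v, types[k]) for k, v in fields.items()}
        metadata["metadata_xml"] = xml_path
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                image_paths={"image": image},
                metadata=metadata,
            )
        )
    schema = [(name, types[name]) for name in header]
    schema.append(("metadata_xml", "string"))
    return StudyTable(records=records, schema=schema), report


# ---------------------------------------------------------------------------
# stratification and contrasts
# ---------------------------------------------------------------------------


def stratify(
    table: StudyTable, definitions: Iterable[CohortDefinition]
) -> tuple[list[Cohort], StratificationReport]:
    """Assign each subject to every cohort whose predicate it satisfies.

    Predicates may reference only schema fields (plus ``subject_id``);
    unknown fields raise :class:`PredicateError` before any assignment.
    """
    definitions = list(definitions)
    known = set(table.field_names()) | {"subject_id"}
    compiled: list[tuple[CohortDefinition, Predicate]] = []
    for d in definitions:
        pred = Predicate(d.predicate)
        unknown = pred.fields() - known
        if unknown:
            raise PredicateError(
                f"cohort {d.name!r}: predicate references unknown field(s) {sorted(unknown)}"
            )
        compiled.append((d, pred))

    cohorts = [Cohort(d.name, d.predicate, []) for d, _ in compiled]
    report = StratificationReport()
    for rec in table.records:
        env = rec.env()
        hits = []
        for cohort, (_, pred) in zip(cohorts, compiled):
            if pred.evaluate(env):
                cohort.members.append(rec)
                hits.append(cohort.name)
        if not hits:
            report.unassigned.append(rec.subject_id)
        elif len(hits) > 1:
            report.multi_assigned.append((rec.subject_id, hits))
    return cohorts, report


def enumerate_contrasts(
    cohorts: Iterable[Cohort | str], measures: Iterable[str]
) -> list[Contrast]:
    """All unordered cohort pairs crossed with all measures, in
    lexicographic order.  Count = C(n, 2) * m."""
    names = sorted(c.name if isinstance(c, Cohort) else str(c) for c in cohorts)
    if len(names) < 2:
        raise ValueError("need at least 2 cohorts to enumerate contrasts")
    measures = sorted(str(m) for m in measures)
    return [
        Contrast.from_pair(a, b, m)
        for (a, b) in combinations(names, 2)
        for m in measures
    ]
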