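"""Per-dataset processing-history capture (``.prov`` documents).

Every dataset file produced by the engine gets a sibling ``<file>.prov`` XML
document: identity metadata extracted from the image header plus an ordered
list of processing steps.  A step records the tool name/version, the
executable reference and a content checksum, the verbatim argument list, the
platform, start/end timestamps, and input/output file ids with checksums.

Records are append-only; the single exception is restart-replacement — when
the engine re-runs an invalidated job, the step carrying that job's identity
is replaced in place rather than duplicated.  Compilation flags of external
binaries are unknowable at run time, so they are an optional free-text field
supplied by the module author via module metadata.
"""

from __future__ import annotations

import hashlib
import os
import platform
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from typing import Any, Mapping

__all__ = [
    "ProvenanceStep",
    "ProvenanceRecord",
    "ExtractionError",
    "ProvenanceParseError",
    "extract_header_metadata",
    "record_step",
    "step_from_job",
    "write_prov",
    "read_prov",
    "prov_path_for",
    "edit_field",
    "file_checksum",
    "CHECKSUM_ALGORITHM",
]

CHECKSUM_ALGORITHM = "sha256"


class ExtractionError(ValueError):
    """Header metadata extraction failed (unsupported format)."""


class ProvenanceParseError(ValueError):
    pass


def file_checksum(path: str) -> str:
    h = hashlib.new(CHECKSUM_ALGORITHM)
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return f"{CHECKSUM_ALGORITHM}:{h.hexdigest()}"


@dataclass(frozen=True)
class ProvenanceStep:
    job_id: str  # "module:instance" identity used for restart-replacement
    tool_name: str
    tool_version: str
    executable: str
    executable_checksum: str
    arguments: tuple[str, ...]  # reproduces the executed command verbatim
    platform_os: str
    platform_arch: str
    started: str  # ISO timestamps
    ended: str
    inputs: tuple[tuple[str, str], ...]  # (file id, checksum)
    outputs: tuple[str, ...]
    compilation_flags: str = ""


@dataclass
class ProvenanceRecord:
    dataset: str  # dataset file id (path)
    identity: dict[str, Any] = field(default_factory=dict)
    steps: list[ProvenanceStep] = field(default_factory=list)

    def step_job_ids(self) -> list[str]:
        return [s.job_id for s in self.steps]


# ---------------------------------------------------------------------------
# header metadata extraction
# ---------------------------------------------------------------------------


def extract_header_metadata(image_path: str) -> dict[str, Any]:
    """Identity metadata from a NIfTI-1 or Analyze 7.5 header.

    Returns dimensions, voxel sizes, dtype and description where the format
    provides them; fields a format cannot hold are reported as
    ``"unavailable"``.  The handler table is extensible: additional formats
    register via :data:`HEADER_HANDLERS`.
    """
    from . import smartlines

    try:
        desc = smartlines.sniff_format(image_path)
    except (smartlines.UnknownFormatError, FileNotFoundError) as exc:
        raise ExtractionError(f"cannot extract header metadata: {exc}") from exc
    handler = HEADER_HANDLERS.get(desc.format_id)
    if handler is None:
        raise ExtractionError(f"no header handler for format {desc.format_id!r}")
    return handler(image_path, desc)


def _nifti_handler(path: str, desc) -> dict[str, Any]:
    import nibabel as nib

    img = nib.load(path)
    hdr = img.header
    return {
        "format": "nifti-1",
        "dimensions": "x".join(str(int(s)) for s in img.shape),
        "voxel_sizes": " ".join(f"{float(z):g}" for z in hdr.get_zooms()[:3]),
        "dtype": desc.dtype,
        "description": hdr["descrip"].tobytes().split(b"\x00")[0].decode("ascii", "replace"),
    }


def _analyze_handler(path: str, desc) -> dict[str, Any]:
    import nibabel as nib

    img = nib.AnalyzeImage.from_filename(path)
    hdr = img.header
    return {
        "format": "analyze-7.5",
        "dimensions": "x".join(str(int(s)) for s in img.shape),
        "voxel_sizes": " ".join(f"{float(z):g}" for z in hdr.get_zooms()[:3]),
        "dtype": desc.dtype,
        "description": hdr["descrip"].tobytes().split(b"\x00")[0].decode("ascii", "replace"),
        "orientation": "unavailable",  # Analyze has no full affine
    }


def _raw_handler(path: str, desc) -> dict[str, Any]:
    return {
        "format": "raw-volume",
        "dimensions": "x".join(str(s) for s in desc.shape),
        "voxel_sizes": "unavailable",
        "dtype": desc.dtype,
        "description": "unavailable",
    }


HEADER_HANDLERS = {
    "nifti-1": _nifti_handler,
    "analyze-7.5": _analyze_handler,
    "raw-volume": _raw_handler,
}


# ---------------------------------------------------------------------------
# step recording
# ---------------------------------------------------------------------------


def step_from_job(job, tool_metadata: Mapping[str, str] | None = None) -> ProvenanceStep:
    """Build a provenance step from a completed engine job."""
    if job.state != "completed":
        raise ValueError(f"job {job.job_id} is {job.state}, not completed")
    meta = dict(tool_metadata or {})
    executable = job.argv[0] if job.argv else ""
    exe_checksum = ""
    if executable and os.path.exists(executable):
        exe_checksum = file_checksum(executable)
    inputs = tuple(
        (p, file_checksum(p) if os.path.exists(p) else "missing")
        for p in job.input_paths
    )
    return ProvenanceStep(
        job_id=job.job_id,
        tool_name=meta.get("name", job.module_id),
        tool_version=meta.get("version", "unknown"),
        executable=executable,
        executable_checksum=exe_checksum,
        arguments=tuple(job.argv),
        platform_os=platform.system(),
        platform_arch=platform.machine(),
        started=job.timestamps.get("started", ""),
        ended=job.timestamps.get("ended", ""),
        inputs=inputs,
        outputs=tuple(job.output_paths),
        compilation_flags=meta.get("compilation_flags", ""),
    )


def record_step(record: ProvenanceRecord, job, tool_metadata: Mapping[str, str] | None = None) -> ProvenanceRecord:
    """Append the step for ``job`` to ``record``; a pre-existing step with
    the same job identity (an invalidated-then-rerun job) is replaced in
    place, preserving history order."""
    step = step_from_job(job, tool_metadata)
    existing = [i for i, s in enumerate(record.steps) if s.job_id == step.job_id]
    if existing:
        record.steps[existing[0]] = step
    else:
        record.steps.append(step)
    return record


def edit_field(record: ProvenanceRecord, field_path: str, value: Any) -> ProvenanceRecord:
    """Edit one identity-metadata field.  Step history is append-only and
    refuses edits."""
    if field_path.startswith("steps") or field_path.startswith("step."):
        raise ValueError("processing history is append-only and cannot be edited")
    if field_path not in record.identity:
        raise KeyError(f"unknown identity field {field_path!r}")
    record.identity[field_path] = value
    return record


# ---------------------------------------------------------------------------
# .prov XML round trip
# ---------------------------------------------------------------------------


def prov_path_for(dataset_path: str) -> str:
    return dataset_path + ".prov"


def write_prov(record: ProvenanceRecord, path: str | None = None) -> str:
    """Serialize to the ``.prov`` XML dialect (deterministic)."""
    path = path or prov_path_for(record.dataset)
    root = ET.Element("provenance", {"dataset": record.dataset})
    identity = ET.SubElement(root, "identity")
    for name in sorted(record.identity):
        ET.SubElement(identity, "field", {"name": name}).text = str(record.identity[name])
    steps = ET.SubElement(root, "steps")
    for i, step in enumerate(record.steps):
        el = ET.SubElement(steps, "step", {"index": str(i), "job": step.job_id})
        ET.SubElement(el, "tool", {"name": step.tool_name, "version": step.tool_version})
        ET.SubElement(
            el, "executable", {"path": step.executable, "checksum": step.executable_checksum}
        )
        args = ET.SubElement(el, "arguments")
        for a in step.arguments:
            ET.SubElement(args, "arg").text = a
        ET.SubElement(el, "platform", {"os": step.platform_os, "arch": step.platform_arch})
        ET.SubElement(el, "started").text = step.started
        ET.SubElement(el, "ended").text = step.ended
        ins = ET.SubElement(el, "inputs")
        for fid, checksum in step.inputs:
            ET.SubElement(ins, "file", {"id": fid, "checksum": checksum})
        outs = ET.SubElement(el, "outputs")
        for fid in step.outputs:
            ET.SubElement(outs, "file", {"id": fid})
        if step.compilation_flags:
            ET.SubElement(el, "compilationFlags").text = step.compilation_flags
    ET.indent(root)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ET.tostring(root, encoding="unicode") + "\n")
    return path


def read_prov(path: str) -> ProvenanceRecord:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ProvenanceParseError(f"{path}: malformed provenance document: {exc}") from exc
    if root.tag != "provenance":
        raise ProvenanceParseError(f"{path}: root element is <{root.tag}>, expected <provenance>")
    record = ProvenanceRecord(dataset=root.get("dataset", ""))
    identity = root.find("identity")
    if identity is not None:
        for f in identity.findall("field"):
            record.identity[f.get("name")] = f.text or ""
    steps = root.find("steps")
    if steps is not None:
        for el in steps.findall("step"):
            tool = el.find("tool")
            exe = el.find("executable")
            plat = el.find("platform")
            flags = el.find("compilationFlags")
            record.steps.append(
                ProvenanceStep(
                    job_id=el.get("job", ""),
                    tool_name=tool.get("name", "") if tool is not None else "",
                    tool_version=tool.get("version", "") if tool is not None else "",
                    executable=exe.get("path", "") if exe is not None else "",
                    executable_checksum=exe.get("checksum", "") if exe is not None else "",
                    arguments=tuple(
                        a.text or "" for a in el.find("arguments").findall("arg")
                    )
                    if el.find("arguments") is not None
                    else (),
                    platform_os=plat.get("os", "") if plat is not None else "",
                    platform_arch=plat.get("arch", "") if plat is not None else "",
                    started=(el.findtext("started") or ""),
                    ended=(el.findtext("ended") or ""),
                    inputs=tuple(
                        (f.get("id", ""), f.get("checksum", ""))
                        for f in el.find("inputs").findall("file")
                    )
                    if el.find("inputs") is not None
                    else (),
                    outputs=tuple(
                        f.get("id", "") for f in el.find("outputs").findall("file")
                    )
                    if el.find("outputs") is not None
                    else (),
                    compilation_flags=(flags.text or "") if flags is not None else "",
                )
            )
    return record


# ---------------------------------------------------------------------------
# engine hook
# ---------------------------------------------------------------------------


def update_for_job(job, tool_metadata: Mapping[str, str] | None = None) -> list[str]:
    """Engine hook: after ``job`` completes, update the ``.prov`` record of
    each of its output files.

    Each output's record carries only its own lineage: the steps of this job
    and of the jobs that produced its inputs (recursively), in input-record
    order followed by the new step.  Returns the paths written.
    """
    written: list[str] = []
    for out_path in job.output_paths:
        record = ProvenanceRecord(dataset=out_path)
        try:
            record.identity = extract_header_metadata(out_path)
        except ExtractionError:
            record.identity = {"format": "non-image"}
        # merge lineage from input records; steps are ordered by execution
        # time (completion timestamp), each ancestor exactly once
        seen: set[str] = set()
        merged: list[ProvenanceStep] = []
        for in_path in job.input_paths:
            ppath = prov_path_for(in_path)
            if not os.path.exists(ppath):
                continue
            upstream = read_prov(ppath)
            for step in upstream.steps:
                if step.job_id not in seen:
                    merged.append(step)
                    seen.add(step.job_id)
        record.steps = sorted(merged, key=lambda s: (s.ended, s.job_id))
        record_step(record, job, tool_metadata)
        written.append(write_prov(record))
    return written
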