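"""Smartlines: automatic file-format/dtype detection and conversion.

When a connection joins a provider whose file format or voxel dtype differs
from what the receiver declares, the engine inserts conversion jobs (one per
instance, independently parallelizable) planned from a registry of converter
edges.  Implemented formats: NIfTI-1, Analyze 7.5, and raw volume with a
JSON sidecar header.  Content sniffing (magic bytes) overrides the file
extension.

Widening dtype conversions (byte -> short -> float) are voxel-exact.
Narrowing conversions require an explicit policy — ``rescale`` (affine map
of the observed min/max onto the target range) or ``clip`` (saturate, then
round) — otherwise a :class:`PolicyRequiredError` is raised; replacing an
interactive prompt with a non-interactive policy table is deliberate.
"""

from __future__ import annotations

import json
import os
import struct
import sys
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "FormatDescriptor",
    "ConversionStep",
    "ConversionRegistry",
    "UnknownFormatError",
    "PolicyRequiredError",
    "ConversionError",
    "sniff_format",
    "plan_conversion",
    "convert",
    "read_volume",
    "write_volume",
    "default_registry",
    "DTYPE_MAP",
    "RAW_SIDECAR_SUFFIX",
]

DTYPE_MAP = {"byte": np.uint8, "short": np.int16, "float": np.float32}
_DTYPE_NAMES = {np.dtype(v): k for k, v in DTYPE_MAP.items()}
# widening order: byte < short < float (value-preserving in that direction)
_DTYPE_RANK = {"byte": 0, "short": 1, "float": 2}

FORMATS = ("nifti-1", "analyze-7.5", "raw-volume")
RAW_SIDECAR_SUFFIX = ".rvh"  # raw-volume header sidecar (JSON)


class UnknownFormatError(ValueError):
    """File content matched no known volume format."""


class PolicyRequiredError(ValueError):
    """A narrowing dtype conversion was requested without a lossy policy."""


class ConversionError(RuntimeError):
    pass


@dataclass(frozen=True)
class FormatDescriptor:
    format_id: str  # nifti-1 | analyze-7.5 | raw-volume
    dtype: str  # byte | short | float
    shape: tuple[int, ...]
    evidence: str = ""  # what the sniffer saw (extension + magic)

    @property
    def key(self) -> tuple[str, str]:
        return (self.format_id, self.dtype)


# ---------------------------------------------------------------------------
# sniffing
# ---------------------------------------------------------------------------


def sniff_format(path: str) -> FormatDescriptor:
    """Identify the format, dtype and shape of a volume file.

    Magic bytes win over extension: a NIfTI file renamed ``.img`` is still
    reported as nifti-1.  Raw volumes require the JSON sidecar header.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    header_path = path
    with open(path, "rb") as fh:
        head = fh.read(352)

    # NIfTI-1 magic at offset 344: "n+1\0" (single file) or "ni1\0" (pair)
    if len(head) >= 348 and head[344:348] in (b"n+1\x00", b"ni1\x00"):
        return _describe_nifti(path, head[344:347].decode("ascii"))

    # Analyze 7.5: first int32 == 348 (either endianness), no NIfTI magic.
    # For .img files the header sits in the sibling .hdr.
    if len(head) >= 4:
        le, = struct.unpack("<i", head[:4])
        be, = struct.unpack(">i", head[:4])
        if 348 in (le, be):
            return _describe_analyze(header_path)
    base, ext = os.path.splitext(path)
    if ext in (".img", ".hdr"):
        sibling = base + ".hdr"
        if os.path.exists(sibling):
            with open(sibling, "rb") as fh:
                hh = fh.read(352)
            if len(hh) >= 348 and hh[344:348] in (b"n+1\x00", b"ni1\x00"):
                return _describe_nifti(sibling, "ni1")
            if len(hh) >= 4:
                le, = struct.unpack("<i", hh[:4])
                be, = struct.unpack(">i", hh[:4])
                if 348 in (le, be):
                    return _describe_analyze(sibling)

    sidecar = _raw_sidecar(path)
    if os.path.exists(sidecar):
        return _describe_raw(path, sidecar)

    raise UnknownFormatError(
        f"{path}: content matches no known volume format "
        "(nifti-1 / analyze-7.5 / raw-volume with sidecar)"
    )


def _raw_sidecar(path: str) -> str:
    return os.path.splitext(path)[0] + RAW_SIDECAR_SUFFIX


def _dtype_name(np_dtype) -> str:
    key = np.dtype(np_dtype)
    if key not in _DTYPE_NAMES:
        raise UnknownFormatError(f"unsupported voxel dtype {key}")
    return _DTYPE_NAMES[key]


def _load_nifti(path: str):
    """Extension-agnostic NIfTI-1 load (content sniffing wins, so the file
    may carry any extension)."""
    import nibabel as nib

    with open(path, "rb") as fh:
        head = fh.read(348)
    if head[344:348] == b"ni1\x00":  # detached header/data pair
        return nib.Nifti1Pair.from_filename(path)
    with open(path, "rb") as fh:
        return nib.Nifti1Image.from_bytes(fh.read())


def _describe_nifti(path: str, magic: str) -> FormatDescriptor:
    img = _load_nifti(path)
    return FormatDescriptor(
        format_id="nifti-1",
        dtype=_dtype_name(img.get_data_dtype()),
        shape=tuple(int(s) for s in img.shape),
        evidence=f"ext={os.path.splitext(path)[1]} magic={magic}",
    )


def _describe_analyze(path: str) -> FormatDescriptor:
    import nibabel as nib

    img = nib.AnalyzeImage.from_filename(path)
    return FormatDescriptor(
        format_id="analyze-7.5",
        dtype=_dtype_name(img.get_data_dtype()),
        shape=tuple(int(s) for s in img.shape),
        evidence=f"ext={os.path.splitext(path)[1]} magic=sizeof_hdr:348",
    )


def _describe_raw(path: str, sidecar: str) -> FormatDescriptor:
    with open(sidecar, "r", encoding="utf-8") as fh:
        hdr = json.load(fh)
    return FormatDescriptor(
        format_id="raw-volume",
        dtype=hdr["dtype"],
        shape=tuple(int(s) for s in hdr["shape"]),
        evidence=f"ext={os.path.splitext(path)[1]} sidecar={os.path.basename(sidecar)}",
    )


# ---------------------------------------------------------------------------
# volume I/O (nibabel behind the scenes)
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None
    description: str = ""


def read_volume(path: str) -> tuple[Volume, FormatDescriptor]:
    desc = sniff_format(path)
    import nibabel as nib

    if desc.format_id == "nifti-1":
        img = _load_nifti(path)
        data = np.asarray(img.dataobj, dtype=img.get_data_dtype())
        zooms = img.header.get_zooms()[:3]
        descr = img.header["descrip"].tobytes().split(b"\x00")[0].decode("ascii", "replace")
        return Volume(data, tuple(float(z) for z in zooms), img.affine, descr), desc
    if desc.format_id == "analyze-7.5":
        img = nib.AnalyzeImage.from_filename(path)
        data = np.asarray(img.dataobj, dtype=img.get_data_dtype())
        zooms = img.header.get_zooms()[:3]
        descr = img.header["descrip"].tobytes().split(b"\x00")[0].decode("ascii", "replace")
        return Volume(data, tuple(float(z) for z in zooms), img.affine, descr), desc
    # raw volume + sidecar
    with open(_raw_sidecar(path), "r", encoding="utf-8") as fh:
        hdr = json.load(fh)
    dtype = np.dtype(DTYPE_MAP[hdr["dtype"]]).newbyteorder(
        "<" if hdr.get("endianness", "little") == "little" else ">"
    )
    data = np.fromfile(path, dtype=dtype).reshape(hdr["shape"])
    vs = tuple(float(v) for v in hdr.get("voxel_size", (1.0, 1.0, 1.0)))
    return Volume(data.astype(DTYPE_MAP[hdr["dtype"]]), vs, None, hdr.get("description", "")), desc


def write_volume(path: str, volume: Volume, format_id: str, dtype: str | None = None) -> str:
    """Write ``volume`` as ``format_id``; returns the path written.

    Geometry metadata is preserved to the extent the target format can hold
    it (Analyze 7.5 has no full affine; voxel sizes survive, orientation does
    not — a documented loss).
    """
    import nibabel as nib

    data = volume.data
    if dtype is not None:
        data = data.astype(DTYPE_MAP[dtype])
    if format_id == "nifti-1":
        affine = volume.affine if volume.affine is not None else np.diag(
            list(volume.voxel_size) + [1.0]
        )
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(volume.voxel_size)
        img.header["descrip"] = volume.description.encode("ascii", "replace")[:79]
        img.to_filename(path)
        return path
    if format_id == "analyze-7.5":
        img = nib.AnalyzeImage(data, np.diag(list(volume.voxel_size) + [1.0]))
        img.header.set_zooms(volume.voxel_size)
        img.header["descrip"] = volume.description.encode("ascii", "replace")[:79]
        img.to_filename(path)
        return path
    if format_id == "raw-volume":
        data.astype(data.dtype.newbyteorder("<")).tofile(path)
        hdr = {
            "shape": list(data.shape),
            "dtype": _dtype_name(data.dtype),
            "voxel_size": list(volume.voxel_size),
            "endianness": "little",
            "description": volume.description,
        }
        with open(_raw_sidecar(path), "w", encoding="utf-8") as fh:
            json.dump(hdr, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path
    raise ValueError(f"unknown format {format_id!r}")


# ---------------------------------------------------------------------------
# conversion registry and planning
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConversionStep:
    source: tuple[str, str]  # (format, dtype)
    target: tuple[str, str]
    lossy: bool  # narrowing dtype step, needs a policy
    order: int  # registration order, used as deterministic tie-break


@dataclass
class ConversionRegistry:
    """Graph of converter edges over (format, dtype) states.

    Planning finds the shortest chain (breadth-first); among equal-length
    chains the one using earlier-registered edges wins.  A registry without
    a path reports the plan as unsatisfiable rather than guessing.
    Plugins extend the registry through :meth:`register`.
    """

    edges: list[ConversionStep] = field(default_factory=list)

    def register(
        self, source: tuple[str, str], target: tuple[str, str], lossy: bool = False
    ) -> ConversionStep:
        step = ConversionStep(tuple(source), tuple(target), lossy, order=len(self.edges))
        self.edges.append(step)
        return step

    def outgoing(self, state: tuple[str, str]) -> list[ConversionStep]:
        return [e for e in self.edges if e.source == state]


def default_registry() -> ConversionRegistry:
    """Format hops at constant dtype plus single-rank dtype moves at
    constant format.  Multi-step needs (e.g. analyze/short -> nifti/float)
    are reached by chaining."""
    reg = ConversionRegistry()
    dtypes = ("byte", "short", "float")
    hops = [
        ("nifti-1", "analyze-7.5"),
        ("analyze-7.5", "nifti-1"),
        ("nifti-1", "raw-volume"),
        ("raw-volume", "nifti-1"),
        ("analyze-7.5", "raw-volume"),
        ("raw-volume", "analyze-7.5"),
    ]
    for dt in dtypes:
        for a, b in hops:
            reg.register((a, dt), (b, dt))
    for fmt in FORMATS:
        reg.register((fmt, "byte"), (fmt, "short"))
        reg.register((fmt, "short"), (fmt, "float"))
        reg.register((fmt, "float"), (fmt, "short"), lossy=True)
        reg.register((fmt, "short"), (fmt, "byte"), lossy=True)
    return reg


@dataclass(frozen=True)
class ConversionPlan:
    steps: tuple[ConversionStep, ...]
    satisfiable: bool = True

    @property
    def empty(self) -> bool:
        return self.satisfiable and not self.steps

    @property
    def lossy(self) -> bool:
        return any(s.lossy for s in self.steps)


UNSATISFIABLE = ConversionPlan(steps=(), satisfiable=False)


def plan_conversion(
    source: FormatDescriptor | tuple[str, str],
    target_format: str | None,
    target_dtype: str | None = None,
    registry: ConversionRegistry | None = None,
) -> ConversionPlan:
    """Plan a converter chain from the source state to the target requirement.

    ``None`` (or ``"any"``) on either target axis means "no constraint".
    Empty plan iff the source already satisfies the target.  Deterministic:
    shortest chain, ties broken by edge registration order.
    """
    registry = registry if registry is not None else default_registry()
    state = source.key if isinstance(source, FormatDescriptor) else tuple(source)

    def satisfied(s: tuple[str, str]) -> bool:
        fmt_ok = target_format in (None, "any") or s[0] == target_format
        dt_ok = target_dtype in (None, "any") or s[1] == target_dtype
        return fmt_ok and dt_ok

    if satisfied(state):
        return ConversionPlan(steps=())

    # breadth-first search; expansion order = registration order, so the
    # first satisfying path found is the deterministic winner
    frontier: list[tuple[tuple[str, str], tuple[ConversionStep, ...]]] = [(state, ())]
    seen = {state}
    while frontier:
        nxt: list[tuple[tuple[str, str], tuple[ConversionStep, ...]]] = []
        for cur, path in frontier:
            for edge in registry.outgoing(cur):
                if edge.target in seen:
                    continue
                new_path = path + (edge,)
                if satisfied(edge.target):
                    return ConversionPlan(steps=new_path)
                seen.add(edge.target)
                nxt.append((edge.target, new_path))
        frontier = nxt
    return UNSATISFIABLE


# ---------------------------------------------------------------------------
# conversion execution
# ---------------------------------------------------------------------------


def _narrow(data: np.ndarray, target: np.dtype, policy: str | None) -> np.ndarray:
    info = np.iinfo(target)
    if policy is None:
        raise PolicyRequiredError(
            f"narrowing conversion to {_dtype_name(target)} requires an explicit "
            "lossy policy ('rescale' or 'clip')"
        )
    if policy == "clip":
        return np.clip(np.rint(data), info.min, info.max).astype(target)
    if policy == "rescale":
        lo, hi = float(data.min()), float(data.max())
        if hi == lo:
            return np.full(data.shape, info.min, dtype=target)
        scaled = (data.astype(np.float64) - lo) / (hi - lo)
        return np.rint(info.min + scaled * (info.max - info.min)).astype(target)
    raise ValueError(f"unknown lossy policy {policy!r}")


def convert(
    path: str,
    plan: ConversionPlan,
    out_path: str,
    policy: str | None = None,
) -> str:
    """Execute a conversion plan, writing the final state to ``out_path``.

    Widening steps are voxel-exact; narrowing steps apply ``policy``.  On
    failure no partial output is retained.
    """
    if not plan.satisfiable:
        raise ConversionError("plan is unsatisfiable")
    if plan.empty:
        raise ValueError("convert() requires a nonempty plan")
    volume, desc = read_volume(path)
    state = desc.key
    data = volume.data
    for step in plan.steps:
        if step.source != state:
            raise ConversionError(f"plan step {step} does not apply to state {state}")
        tgt_fmt, tgt_dt = step.target
        if tgt_dt != state[1]:
            np_target = np.dtype(DTYPE_MAP[tgt_dt])
            if _DTYPE_RANK[tgt_dt] > _DTYPE_RANK[state[1]]:
                data = data.astype(np_target)  # widening: exact
            else:
                data = _narrow(data, np_target, policy)
        state = (tgt_fmt, tgt_dt)
    # temp path keeps the extension (format writers key off it)
    tmp = os.path.join(os.path.dirname(out_path) or ".",
                       ".part-" + os.path.basename(out_path))
    try:
        write_volume(tmp, Volume(data, volume.voxel_size, volume.affine, volume.description),
                     state[0], state[1])
        _atomic_rename(tmp, out_path, state[0])
    except Exception:
        for leftover in (tmp, _raw_sidecar(tmp), os.path.splitext(tmp)[0] + ".hdr"):
            if os.path.exists(leftover):
                os.remove(leftover)
        raise
    return out_path


def _atomic_rename(tmp: str, out_path: str, format_id: str) -> None:
    os.replace(tmp, out_path)
    if format_id == "analyze-7.5":
        # nibabel writes <stem>.hdr next to <stem>.img
        tmp_hdr = os.path.splitext(tmp)[0] + ".hdr"
        out_hdr = os.path.splitext(out_path)[0] + ".hdr"
        if os.path.exists(tmp_hdr):
            os.replace(tmp_hdr, out_hdr)
    elif format_id == "raw-volume":
        if os.path.exists(_raw_sidecar(tmp)):
            os.replace(_raw_sidecar(tmp), _raw_sidecar(out_path))


def convert_to(
    path: str,
    out_path: str,
    target_format: str,
    target_dtype: str | None = None,
    policy: str | None = None,
    registry: ConversionRegistry | None = None,
) -> str:
    """Plan and execute in one call (used by engine-inserted conversion jobs)."""
    desc = sniff_format(path)
    plan = plan_conversion(desc, target_format, target_dtype, registry)
    if not plan.satisfiable:
        raise ConversionError(
            f"no conversion path from {desc.key} to ({target_format}, {target_dtype})"
        )
    if plan.empty:
        # already satisfies the target: copy through for a stable output path
        volume, _ = read_volume(path)
        write_volume(out_path, volume, desc.format_id, desc.dtype)
        return out_path
    return convert(path, plan, out_path, policy)


def main(argv: list[str] | None = None) -> int:
    """Entry point for engine-inserted conversion jobs:

    ``python -m deskpipe.smartlines SRC DST --to-format F [--to-dtype D]
    [--policy P]``
    """
    args = list(sys.argv[1:] if argv is None else argv)
    if len(args) < 2:
        print("usage: smartlines SRC DST --to-format F [--to-dtype D] [--policy P]",
              file=sys.stderr)
        return 2
    src, dst = args[0], args[1]
    opts = {"--to-format": None, "--to-dtype": None, "--policy": None}
    rest = args[2:]
    while rest:
        key = rest.pop(0)
        if key not in opts or not rest:
            print(f"unknown or valueless option {key!r}", file=sys.stderr)
            return 2
        opts[key] = rest.pop(0)
    if opts["--to-format"] is None:
        print("--to-format is required", file=sys.stderr)
        return 2
    try:
        convert_to(src, dst, opts["--to-format"], opts["--to-dtype"], opts["--policy"])
    except Exception as exc:
        print(f"smartline conversion failed: {exc}", file=sys.stderr)
        return 1
    return 0


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
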