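"""Smartline mechanics: sniff a volume's format by content, plan the
shortest conversion chain, execute it losslessly, and see the lossy-policy
guard.

Run:  python examples/smartline_conversion.py
"""

import tempfile

import numpy as np

from deskpipe.smartlines import (
    PolicyRequiredError,
    Volume,
    convert_to,
    plan_conversion,
    read_volume,
    sniff_format,
    write_volume,
)

tmp = tempfile.mkdtemp(prefix="deskpipe-smart-")
data = (np.arange(64, dtype=np.int16).reshape(4, 4, 4) - 8) * 3
src = write_volume(f"{tmp}/vol.img", Volume(data, (1.0, 1.0, 2.5)),
                   "analyze-7.5", "short")

desc = sniff_format(src)
print(f"sniffed: {desc.format_id}/{desc.dtype} shape={desc.shape} ({desc.evidence})")

plan = plan_conversion(desc, "nifti-1", "float")
print("plan:", " -> ".join([f"{s.source}" for s in plan.steps]
                           + [str(plan.steps[-1].target)]))

out = convert_to(src, f"{tmp}/vol.nii", "nifti-1", "float")
vol, out_desc = read_volume(out)
print(f"converted to {out_desc.format_id}/{out_desc.dtype}; "
      f"voxels exact: {np.array_equal(vol.data.astype(np.int16), data)}; "
      f"voxel size kept: {vol.voxel_size}")

try:
    convert_to(out, f"{tmp}/vol-byte.nii", "nifti-1", "byte")
except PolicyRequiredError as exc:
    print("narrowing without a policy is refused:", exc)

narrowed = convert_to(out, f"{tmp}/vol-byte.nii", "nifti-1", "byte", policy="rescale")
nv, _ = read_volume(narrowed)
print(f"with rescale policy: byte range [{nv.data.min()}, {nv.data.max()}]")

# Widening chains (analyze/short -> nifti/short -> nifti/float) are
# voxel-exact; narrowing is only performed under an explicit documented
# policy, mirroring how automatic conversion must defer to the user when
# information would be lost.
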