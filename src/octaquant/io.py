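"""Reading and writing the pipeline's on-disk formats.

* grayscale rasters (PNG/TIFF/JPEG) via imageio;
* acquisition sidecars: flat ``key: value`` text files with the schema
  subject_id, eye, plexus, scale_x_um, scale_y_um and optionally
  crop_x0/crop_y0/crop_x1/crop_y1 and field_label;
* thickness maps: TSV with three header lines (layer, spacing_x_mm,
  spacing_y_mm) followed by the thickness matrix;
* binary masks: 0/255 PNG plus a provenance text block.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InputError
from .types import AcquisitionMeta, ThicknessMap

__all__ = [
    "read_sidecar",
    "write_sidecar",
    "read_thickness_tsv",
    "write_thickness_tsv",
    "write_mask_png",
    "write_image_png",
]

_SIDECAR_REQUIRED = ("subject_id", "eye", "plexus", "scale_x_um", "scale_y_um")


def read_sidecar(path) -> AcquisitionMeta:
    """Parse a flat key:value sidecar into acquisition metadata."""
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise InputError(f"malformed sidecar line {line!r} in {path}")
        k, v = line.split(":", 1)
        kv[k.strip()] = v.strip()
    missing = [k for k in _SIDECAR_REQUIRED if k not in kv]
    if missing:
        raise InputError(f"sidecar {path} missing keys {missing}")
    crop = None
    if "crop_x0" in kv:
        try:
            crop = tuple(int(kv[f"crop_{k}"]) for k in ("x0", "y0", "x1", "y1"))
        except KeyError as exc:
            raise InputError(f"sidecar {path} has a partial crop box") from exc
    return AcquisitionMeta(
        subject_id=kv["subject_id"],
        eye=kv["eye"],
        plexus=kv["plexus"],
        scale_x_um=float(kv["scale_x_um"]),
        scale_y_um=float(kv["scale_y_um"]),
        crop_box=crop,
        field_label=kv.get("field_label", ""),
    )


def write_sidecar(path, meta: AcquisitionMeta) -> None:
    lines = [
        f"subject_id: {meta.subject_id}",
        f"eye: {meta.eye}",
        f"plexus: {meta.plexus}",
        f"scale_x_um: {meta.scale_x_um}",
        f"scale_y_um: {meta.scale_y_um}",
    ]
    if meta.crop_box is not None:
        x0, y0, x1, y1 = meta.crop_box
        lines += [f"crop_x0: {x0}", f"crop_y0: {y0}", f"crop_x1: {x1}", f"crop_y1: {y1}"]
    if meta.field_label:
        lines.append(f"field_label: {meta.field_label}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_thickness_tsv(path) -> ThicknessMap:
    """Read the documented gridded thickness TSV."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, str] = {}
    data_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#") or ":" in line.split("\t")[0]:
            k, v = line.lstrip("#").split(":", 1)
            header[k.strip()] = v.strip()
            data_start = i + 1
        else:
            break
    for key in ("layer", "spacing_x_mm", "spacing_y_mm"):
        if key not in header:
            raise InputError(f"thickness TSV {path} missing header {key!r}")
    values = np.loadtxt(lines[data_start:], delimiter="\t", ndmin=2)
    return ThicknessMap(
        layer=header["layer"],
        values=values,
        spacing_x_mm=float(header["spacing_x_mm"]),
        spacing_y_mm=float(header["spacing_y_mm"]),
    )


def write_thickness_tsv(path, m: ThicknessMap) -> None:
    with open(path, "w") as fh:
        fh.write(f"layer: {m.layer}\n")
        fh.write(f"spacing_x_mm: {m.spacing_x_mm}\n")
        fh.write(f"spacing_y_mm: {m.spacing_y_mm}\n")
        np.savetxt(fh, m.values, delimiter="\t", fmt="%.4f")


def write_image_png(path, pixels: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(pixels, dtype=np.uint8), extension=".png")


def write_mask_png(path, mask: np.ndarray, provenance: dict | None = None) -> None:
    """0/255 PNG plus a .provenance.json sibling recording the parameters."""
    path = Path(path)
    iio.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)), extension=".png")
    if provenance is not None:
        path.with_suffix(".provenance.json").write_text(
            json.dumps(provenance, indent=2, default=str)
        )
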