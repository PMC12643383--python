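"""Reading and writing volumes, masks, projections and metric reports.

Volumes and 3D masks travel as multi-page TIFF stacks (one page per depth
slice, page order = increasing z).  2D masks and projections are PNG or
single-page TIFF.  Volume metadata (stage, spacing, surface alignment) is
kept in a JSON sidecar next to the TIFF so the TIFF itself stays plain.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import REPORT_FIELDS, EnFaceProjection, MetricReport, OCTAVolume, VesselMask

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "write_projection", "write_report", "read_report",
]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff", ".bmp")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_volume(path, spacing_um=(15.0, 19.5, 19.5)) -> OCTAVolume:
    """Load a 3D volume from a multi-page TIFF or a directory of 2D images.

    Page (or sorted file) order maps to increasing depth z.  If a JSON
    sidecar written by :func:`write_volume` is present, its stage/spacing
    metadata overrides the ``spacing_um`` argument.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no image files in directory {path}")
        pages = [np.asarray(iio.imread(f)) for f in files]
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent page shapes in {path}: {sorted(shapes)}")
        data = np.stack(pages, axis=0)
        meta_path = _sidecar(path / "volume.tif")
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        meta_path = _sidecar(path)
    if not np.issubdtype(data.dtype, np.number):
        raise ValueError(f"non-numeric pixel data in {path} (dtype {data.dtype})")
    stage, surface_aligned = "original", False
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        stage = meta.get("stage", stage)
        spacing_um = tuple(meta.get("spacing_um", spacing_um))
        surface_aligned = bool(meta.get("surface_aligned", surface_aligned))
    return OCTAVolume(data=data.astype(np.float32), spacing_um=spacing_um,
                      stage=stage, surface_aligned=surface_aligned)


def write_volume(volume: OCTAVolume, path) -> None:
    """Write a volume as a float32 multi-page TIFF plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, volume.data.astype(np.float32),
                     photometric="minisblack")
    _sidecar(path).write_text(json.dumps({
        "stage": volume.stage,
        "spacing_um": list(volume.spacing_um),
        "surface_aligned": volume.surface_aligned,
    }, indent=1))


def read_mask(path, role: str = "pred") -> VesselMask:
    """Load a binary mask from PNG (2D) or TIFF (2D or 3D stack).

    Any nonzero pixel becomes vessel.  The connectivity convention follows
    from dimensionality (8-connected in 2D, 26-connected in 3D).  Inputs
    with more than two distinct values are binarized with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3 and data.shape[-1] in (3, 4):  # RGB(A) → grayscale
            data = data[..., 0]
    if len(np.unique(data)) > 2:
        warnings.warn(f"{path} has more than two distinct values; "
                      "binarizing nonzero -> 1", stacklevel=2)
    return VesselMask(data=data != 0, role=role)


def write_mask(mask: VesselMask, path) -> None:
    """Write a mask as 8-bit imagery (0/255); 3D masks as TIFF stacks."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = (mask.data.astype(np.uint8)) * 255
    if mask.ndim == 3 or path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data, photometric="minisblack")
    else:
        iio.imwrite(path, data)


def write_projection(projection: EnFaceProjection, path) -> None:
    """Write an 8-bit en-face projection (PNG or TIFF) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, projection.image)
    else:
        iio.imwrite(path, projection.image)
    _sidecar(path).write_text(json.dumps({
        "band": projection.band,
        "clip_value": float(projection.clip_value),
    }, indent=1))


def _jsonable(value):
    if isinstance(value, float) and math.isnan(value):
        return None
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def write_report(report: MetricReport, path, format: str | None = None) -> None:
    """Write a metric report as JSON (default) or a one-row CSV.

    NaN relative differences (undefined because the reference value was
    zero) serialize as JSON ``null`` / empty CSV cells.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "json")
    values = {k: _jsonable(v) for k, v in report.to_dict().items()}
    if fmt == "json":
        path.write_text(json.dumps(values, indent=1))
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=REPORT_FIELDS)
            writer.writeheader()
            writer.writerow({k: ("" if values[k] is None else values[k])
                             for k in REPORT_FIELDS})
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path) -> MetricReport:
    """Read back a JSON metric report written by :func:`write_report`."""
    values = json.loads(Path(path).read_text())
    clean = {k: (math.nan if v is None else v) for k, v in values.items()}
    return MetricReport(**clean)
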