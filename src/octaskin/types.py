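"""Core domain containers for skin OCTA analysis.

Conventions used throughout the package:

* Volumes are indexed ``(z, y, x)`` with ``z`` the depth below the skin
  surface (``z = 0`` is the surface after flattening), ``y`` the fast
  lateral axis within a B-scan and ``x`` the slow-scan axis.  A *B-scan*
  is therefore the ``(z, y)`` frame at a fixed slow-scan index ``x``.
* Binary masks carry the connectivity convention of their dimensionality:
  8-connected in 2D, 26-connected in 3D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "STAGES",
    "OCTAVolume",
    "VesselMask",
    "EnFaceProjection",
    "MetricReport",
    "REPORT_FIELDS",
]

#: Pipeline stages in processing order.
STAGES = ("original", "normalized", "pa_attenuated", "contrast_enhanced", "vesselness")

#: Depth bands an en-face projection can summarise.
BANDS = ("full", "superficial", "deep")


@dataclass
class OCTAVolume:
    """A 3D OCTA intensity volume with physical spacing and provenance.

    Parameters
    ----------
    data:
        Non-negative float32 array of shape ``(z, y, x)``.
    spacing_um:
        Physical voxel spacing ``(z, y, x)`` in micrometers.
    stage:
        Which preprocessing stage produced this volume (one of `STAGES`).
    surface_aligned:
        True once the skin surface has been flattened to ``z = 0``.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float] = (15.0, 19.5, 19.5)
    stage: str = "original"
    surface_aligned: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got shape {self.data.shape}")
        if self.data.shape[0] < 2:
            raise ValueError("volume needs at least 2 depth slices")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.data.min() < 0:
            raise ValueError("volume intensities must be non-negative")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)  # type: ignore[assignment]
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive values (z, y, x)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def depth(self) -> int:
        return self.data.shape[0]

    def with_data(self, data: np.ndarray, stage: str | None = None,
                  surface_aligned: bool | None = None) -> "OCTAVolume":
        """Copy metadata onto a new data array, optionally advancing the stage."""
        return OCTAVolume(
            data=data,
            spacing_um=self.spacing_um,
            stage=self.stage if stage is None else stage,
            surface_aligned=self.surface_aligned if surface_aligned is None
            else surface_aligned,
        )


@dataclass
class VesselMask:
    """A binary vessel segmentation, 2D or 3D.

    The connectivity convention is a pure function of dimensionality:
    8-connected for 2D masks, 26-connected for 3D masks.
    """

    data: np.ndarray
    role: str = "pred"  # "pred" (S) or "gt" (Sgt)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim not in (2, 3):
            raise ValueError(f"mask must be 2D or 3D, got {arr.ndim}D")
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be binary (0/1)")
            arr = arr.astype(bool)
        self.data = arr
        if self.role not in ("pred", "gt"):
            raise ValueError("role must be 'pred' or 'gt'")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def connectivity(self) -> int:
        """8 in 2D, 26 in 3D."""
        return 8 if self.data.ndim == 2 else 26

    @property
    def structure(self) -> np.ndarray:
        """The full (corner-touching) structuring element for labelling."""
        return np.ones((3,) * self.data.ndim, dtype=bool)

    @property
    def count(self) -> int:
        """Number of vessel pixels/voxels."""
        return int(self.data.sum())


@dataclass
class EnFaceProjection:
    """An 8-bit en-face image with its depth band and clip statistics."""

    image: np.ndarray
    band: str = "full"
    clip_value: float = 0.0

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 2:
            raise ValueError("en-face projection must be 2D")
        if img.dtype != np.uint8:
            if img.min() < 0 or img.max() > 255:
                raise ValueError("projection values must lie in [0, 255]")
            img = img.astype(np.uint8)
        self.image = img
        if self.band not in BANDS:
            raise ValueError(f"band must be one of {BANDS}")


# Stable column order for reports (CSV and JSON share it).
REPORT_FIELDS = (
    "dice", "precision", "recall", "balanced_accuracy",
    "cal_conn", "cal_area", "cal_length", "cal",
    "vd_pred", "vd_gt", "vf_pred", "vf_gt", "fd_pred", "fd_gt",
    "rpd_vd", "rpd_vf", "rpd_fd",
)


@dataclass
class MetricReport:
    """All eleven evaluation metrics for one (prediction, reference) pair.

    Bounded metrics (Dice, precision, recall, balanced accuracy, the three
    CAL components and their product) lie in [0, 1].  Vascular density is
    the vessel fraction of the field of view; fragmentation is a connected
    component count; fractal dimension is the box-counting slope.  The
    ``rpd_*`` fields are signed relative percentage differences of the
    prediction against the reference and are NaN when the reference value
    is zero.
    """

    dice: float
    precision: float
    recall: float
    balanced_accuracy: float
    cal_conn: float
    cal_area: float
    cal_length: float
    cal: float
    vd_pred: float
    vd_gt: float
    vf_pred: int
    vf_gt: int
    fd_pred: float
    fd_gt: float
    rpd_vd: float
    rpd_vf: float
    rpd_fd: float

    def __post_init__(self) -> None:
        for name in ("dice", "precision", "recall", "balanced_accuracy",
                     "cal_conn", "cal_area", "cal_length", "cal",
                     "vd_pred", "vd_gt"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 1]")
        prod = self.cal_conn * self.cal_area * self.cal_length
        if not math.isclose(self.cal, prod, rel_tol=1e-9, abs_tol=1e-12):
            raise ValueError("cal must equal cal_conn * cal_area * cal_length")

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
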