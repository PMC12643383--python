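"""Depth-band splitting, en-face projections and reference-mask generation.

The dermal vasculature is organised in a superficial plexus (roughly
100-400 um below the surface) and a deep plexus beneath it.  On a
flattened volume these become simple depth bands split at a configurable
boundary.  Average-intensity projections (AIP) are used for en-face
imagery because they are less sensitive to extreme values than maximum
projections.  Reference 3D masks are produced by global thresholding of a
normalized, projection-artifact-attenuated volume, morphological closing,
and removal of small isolated components; 2D reference masks are Otsu
binarizations of the band-wise mask projections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball, closing, disk

from .types import EnFaceProjection, OCTAVolume, VesselMask

__all__ = [
    "BandSpec", "MaskGenParams",
    "split_bands", "band_zrange", "average_intensity_projection",
    "make_reference_mask", "remove_small_components",
    "project_mask", "otsu_binarize",
]


@dataclass
class BandSpec:
    """Superficial/deep split depth below the (flattened) surface."""

    boundary_um: float = 400.0

    def boundary_index(self, spacing_z_um: float, depth: int) -> int:
        """Slice index of the band boundary for a given axial spacing."""
        idx = int(round(self.boundary_um / spacing_z_um))
        if not 0 < idx < depth:
            raise ValueError(
                f"band boundary index {idx} outside (0, {depth}) for "
                f"boundary {self.boundary_um} um at {spacing_z_um} um/slice")
        return idx


@dataclass
class MaskGenParams:
    """Reference-mask generation parameters.

    ``threshold`` of None selects Otsu's threshold on the 3D intensity
    histogram.  Components smaller than ``min_size`` voxels are removed.
    """

    threshold: float | None = None
    min_size: int = 100
    smooth_radius: int = 1

    def __post_init__(self) -> None:
        if self.min_size < 0:
            raise ValueError("min_size must be >= 0")
        if self.threshold is not None and not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        if self.smooth_radius < 0:
            raise ValueError("smooth_radius must be >= 0")


def band_zrange(volume_depth: int, band: str, boundary_index: int) -> tuple[int, int]:
    """The [start, stop) depth range of a named band."""
    if not 0 < boundary_index < volume_depth:
        raise ValueError(f"boundary_index {boundary_index} outside "
                         f"(0, {volume_depth})")
    if band == "full":
        return 0, volume_depth
    if band == "superficial":
        return 0, boundary_index
    if band == "deep":
        return boundary_index, volume_depth
    raise ValueError(f"unknown band {band!r}")


def split_bands(volume: OCTAVolume, band: BandSpec | int | None = None
                ) -> tuple[OCTAVolume, OCTAVolume]:
    """Partition a flattened volume into (superficial, deep) sub-volumes.

    ``band`` may be a `BandSpec` (boundary in micrometers, converted via
    the volume's axial spacing), an explicit slice index, or None for the
    default 400 um boundary.  Stacking the two outputs along z reproduces
    the input exactly.
    """
    if band is None:
        band = BandSpec()
    if isinstance(band, BandSpec):
        idx = band.boundary_index(volume.spacing_um[0], volume.depth)
    else:
        idx = int(band)
        if not 0 < idx < volume.depth:
            raise ValueError(f"boundary index {idx} outside (0, {volume.depth})")
    sup = volume.with_data(volume.data[:idx])
    deep = volume.with_data(volume.data[idx:])
    return sup, deep


def average_intensity_projection(volume: OCTAVolume, clip_percentile: float = 99.0,
                                 band: str = "full") -> EnFaceProjection:
    """Mean-over-depth en-face projection, clipped and converted to 8-bit.

    The per-(y, x) mean along z is clipped at its ``clip_percentile`` value
    p, then [0, p] is mapped linearly onto [0, 255] and rounded.  p is
    recorded on the projection.
    """
    if volume.depth == 0 or volume.data.size == 0:
        raise ValueError("cannot project an empty band")
    proj = volume.data.mean(axis=0)
    p = float(np.percentile(proj, clip_percentile))
    if p <= 0:
        img = np.zeros(proj.shape, dtype=np.uint8)
    else:
        img = np.rint(np.clip(proj, 0, p) / p * 255.0).astype(np.uint8)
    return EnFaceProjection(image=img, band=band, clip_value=p)


def remove_small_components(mask: VesselMask, min_size: int = 100) -> VesselMask:
    """Drop connected components strictly smaller than ``min_size``.

    Uses the mask's own connectivity convention (8 in 2D, 26 in 3D); a
    component of exactly ``min_size`` pixels/voxels is retained.
    """
    if min_size <= 1:
        return VesselMask(data=mask.data.copy(), role=mask.role)
    labels, n = ndi.label(mask.data, structure=mask.structure)
    if n == 0:
        return VesselMask(data=mask.data.copy(), role=mask.role)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return VesselMask(data=keep[labels], role=mask.role)


def make_reference_mask(volume: OCTAVolume, params: MaskGenParams | None = None
                        ) -> VesselMask:
    """Global threshold + 3D closing + small-component removal.

    Intended substrate is a B-scan-normalized, projection-artifact
    attenuated volume (the same preparation used when reference labels are
    drawn).  With ``params.threshold`` None the threshold is Otsu's on the
    3D histogram.
    """
    params = params or MaskGenParams()
    data = volume.data
    if params.threshold is None:
        if data.min() == data.max():
            warnings.warn("constant volume; reference mask is empty", stacklevel=2)
            return VesselMask(data=np.zeros(data.shape, bool), role="gt")
        thr = float(threshold_otsu(data, nbins=256))
    else:
        thr = params.threshold
    mask = data >= thr
    if params.smooth_radius > 0 and mask.any():
        footprint = ball(params.smooth_radius) if mask.ndim == 3 \
            else disk(params.smooth_radius)
        # skimage's closing pads so border-touching structures are preserved
        mask = closing(mask, footprint).astype(bool)
    return remove_small_components(VesselMask(data=mask, role="gt"),
                                   params.min_size)


def project_mask(mask3d: VesselMask, zrange: tuple[int, int] | None = None
                 ) -> np.ndarray:
    """Per-(y, x) vessel fraction of a 3D mask over a depth band.

    Returns a float image in [0, 1]: the mean of the binary values over the
    band's z range.
    """
    if mask3d.ndim != 3:
        raise ValueError("project_mask needs a 3D mask")
    z0, z1 = zrange if zrange is not None else (0, mask3d.data.shape[0])
    if not 0 <= z0 < z1 <= mask3d.data.shape[0]:
        raise ValueError(f"empty or out-of-range band ({z0}, {z1})")
    return mask3d.data[z0:z1].mean(axis=0)


def otsu_binarize(projection: np.ndarray, role: str = "gt") -> VesselMask:
    """Binarize a grayscale projection at the Otsu threshold.

    The threshold maximizes between-class variance over a 256-bin histogram
    of the projection's value range; pixels strictly above it are
    foreground.  A constant projection yields an empty mask with a warning.
    """
    proj = np.asarray(projection, dtype=float)
    if proj.ndim != 2:
        raise ValueError("projection must be 2D")
    if proj.min() == proj.max():
        warnings.warn("constant projection; Otsu mask is empty", stacklevel=2)
        return VesselMask(data=np.zeros(proj.shape, bool), role=role)
    thr = threshold_otsu(proj, nbins=256)
    return VesselMask(data=proj > thr, role=role)
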