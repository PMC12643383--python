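"""The five-stage OCTA enhancement pipeline.

Stages, in order: surface flattening happens first (outside the stage
chain), then *B-scan normalization* (unit mean per slow-scan frame, which
suppresses the vertical gain stripes seen in en-face projections),
*projection-artifact attenuation* (a step-down exponential filter that
subtracts a decaying accumulation of the overlying signal, removing the
false deep-flow tails cast by superficial vessels), *median filtering with
luminance contrast stretching*, and finally *multiscale Frangi vesselness*
enhancement of tubular structures.

Each stage is a pure ``OCTAVolume -> OCTAVolume`` transform; `run_pipeline`
chains them cumulatively and keeps every intermediate result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals

from .types import STAGES, OCTAVolume

__all__ = [
    "SurfaceMap", "PAFilterParams", "EnhanceParams", "FrangiParams",
    "NoSurfaceFound",
    "detect_surface", "flatten_volume", "normalize_bscans",
    "attenuate_projection_artifacts", "median_contrast_enhance",
    "frangi_vesselness", "run_pipeline",
]


class NoSurfaceFound(RuntimeError):
    """Raised when no A-line crosses the surface-detection threshold."""


@dataclass
class SurfaceMap:
    """Per-(y, x) integer depth index of the detected skin surface."""

    depth_index: np.ndarray

    def __post_init__(self) -> None:
        self.depth_index = np.asarray(self.depth_index, dtype=np.intp)
        if self.depth_index.ndim != 2:
            raise ValueError("surface map must be 2D (y, x)")


@dataclass
class PAFilterParams:
    """Step-down exponential filter parameters.

    ``weight`` is the fraction of the accumulated overlying signal
    subtracted at each voxel; ``decay`` is the per-slice exponential decay
    of that accumulator.
    """

    weight: float = 0.3
    decay: float = 0.85

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if not 0.0 <= self.decay <= 1.0:
            raise ValueError("decay must lie in [0, 1]")


@dataclass
class EnhanceParams:
    """3D median kernel size and contrast-stretch percentiles."""

    median_kernel: int = 3
    stretch_lo: float = 1.0
    stretch_hi: float = 99.0

    def __post_init__(self) -> None:
        if self.median_kernel < 1 or self.median_kernel % 2 == 0:
            raise ValueError("median_kernel must be odd and >= 1")
        if not 0.0 <= self.stretch_lo < self.stretch_hi <= 100.0:
            raise ValueError("need 0 <= stretch_lo < stretch_hi <= 100")


@dataclass
class FrangiParams:
    """Multiscale Frangi vesselness parameters.

    ``scales`` are the Gaussian scales in pixels; ``alpha`` controls
    sensitivity to plate-like structures, ``beta`` suppression of blob-like
    responses, and ``c`` the structure-contrast constant (None selects half
    the maximum Hessian Frobenius norm per scale).
    """

    scales: tuple[int, ...] = (4, 6, 8)
    alpha: float = 0.01
    beta: float = 1.0
    c: float | None = None

    def __post_init__(self) -> None:
        scales = tuple(self.scales)
        if not scales or any(s <= 0 for s in scales):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ValueError("scales must be strictly increasing")
        self.scales = scales
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be > 0")
        if self.c is not None and self.c <= 0:
            raise ValueError("c must be > 0")


def detect_surface(volume: OCTAVolume, threshold_frac: float = 0.5,
                   axial_sigma: float = 2.0, median_size: int = 5) -> SurfaceMap:
    """Locate the skin entry surface on every A-line.

    Each A-line is smoothed along depth; the surface is the first z where
    the smoothed intensity exceeds ``threshold_frac`` of that A-line's
    maximum.  The resulting index map is median-smoothed laterally to
    reject speckle-driven outliers.  A-lines with no signal at all borrow
    the smoothed value of their neighbours.
    """
    data = volume.data
    smoothed = ndi.gaussian_filter1d(data, sigma=axial_sigma, axis=0, mode="nearest")
    amax = smoothed.max(axis=0)
    valid = amax > 0
    if not valid.any():
        raise NoSurfaceFound("no A-line exceeds the surface threshold")
    above = smoothed >= threshold_frac * amax[None, :, :]
    idx = np.argmax(above, axis=0)
    idx[~valid] = int(np.median(idx[valid]))
    idx = ndi.median_filter(idx, size=median_size, mode="nearest")
    return SurfaceMap(depth_index=idx)


def flatten_volume(volume: OCTAVolume, surface: SurfaceMap,
                   discard_bscans: int = 30, out_depth: int = 90) -> OCTAVolume:
    """Shift every A-line so its surface sits at z = 0 and crop the volume.

    The first ``discard_bscans`` slow-scan frames (distorted by the
    acquisition pattern) are dropped, then the volume is cropped to
    ``out_depth`` depth slices.  Voxels shifted in from below the original
    acquisition depth are zero-filled.
    """
    depth, ny, nx = volume.shape
    if surface.depth_index.shape != (ny, nx):
        raise ValueError("surface map shape does not match volume")
    if out_depth > depth:
        raise ValueError(f"out_depth={out_depth} exceeds volume depth {depth}")
    if not 0 <= discard_bscans < nx:
        raise ValueError("discard_bscans outside the slow-scan range")
    data = volume.data[:, :, discard_bscans:]
    surf = surface.depth_index[:, discard_bscans:]
    nx_out = data.shape[2]
    z_src = surf[None, :, :] + np.arange(out_depth)[:, None, None]
    yy = np.arange(ny)[None, :, None]
    xx = np.arange(nx_out)[None, None, :]
    in_range = z_src < depth
    out = np.where(in_range, data[np.minimum(z_src, depth - 1), yy, xx], 0.0)
    return volume.with_data(out.astype(np.float32), surface_aligned=True)


def normalize_bscans(volume: OCTAVolume) -> OCTAVolume:
    """Divide each B-scan by its mean intensity so every frame has mean 1.

    Removes the inter-frame multiplicative bias that shows up as vertical
    bright/dark stripes in en-face projections, while leaving relative
    contrasts within each frame untouched.  All-zero frames pass through
    unchanged with a warning.
    """
    data = volume.data
    means = data.mean(axis=(0, 1))
    zero = means <= 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} all-zero B-scan(s) left unnormalized",
                      stacklevel=2)
    safe = np.where(zero, 1.0, means)
    out = data / safe[None, None, :]
    return volume.with_data(out, stage="normalized")


def attenuate_projection_artifacts(volume: OCTAVolume,
                                   params: PAFilterParams | None = None) -> OCTAVolume:
    """Step-down exponential suppression of projection (tail) artifacts.

    Per A-line, an accumulator of the overlying signal is carried down in
    depth with exponential forgetting and a fraction of it is subtracted::

        C(0) = 0
        C(z) = decay * C(z-1) + in(z-1)
        out(z) = max(0, in(z) - weight * C(z))

    The output never exceeds the input, the top slice is unchanged, and
    ``weight = 0`` is the identity.
    """
    params = params or PAFilterParams()
    data = volume.data
    out = np.empty_like(data)
    acc = np.zeros(data.shape[1:], dtype=np.float32)
    out[0] = data[0]
    for z in range(1, data.shape[0]):
        acc = params.decay * acc + data[z - 1]
        out[z] = np.maximum(0.0, data[z] - params.weight * acc)
    return volume.with_data(out, stage="pa_attenuated")


def median_contrast_enhance(volume: OCTAVolume,
                            params: EnhanceParams | None = None) -> OCTAVolume:
    """3D median filtering followed by luminance contrast stretching.

    The median window uses edge replication at the borders.  The stretch
    maps the volume-wide [stretch_lo, stretch_hi] percentile range linearly
    onto [0, 1] with clipping; a constant volume maps to 0.
    """
    params = params or EnhanceParams()
    filtered = ndi.median_filter(volume.data, size=params.median_kernel,
                                 mode="nearest")
    lo, hi = np.percentile(filtered, [params.stretch_lo, params.stretch_hi])
    if hi <= lo:
        out = np.zeros_like(filtered)
    else:
        out = np.clip((filtered - lo) / (hi - lo), 0.0, 1.0)
    return volume.with_data(out, stage="contrast_enhanced")


def frangi_vesselness(volume: OCTAVolume,
                      params: FrangiParams | None = None) -> OCTAVolume:
    """Multiscale Hessian vesselness enhancement of bright tubular structures.

    Per scale s the volume is differentiated with Gaussian derivatives at
    scale s, the Hessian eigenvalues are sorted by magnitude
    |l1| <= |l2| <= |l3|, and the tubular response is::

        Ra = |l2| / |l3|          (plate vs line,   weighted by alpha)
        Rb = |l1| / sqrt(|l2 l3|) (blob deviation,  weighted by beta)
        S  = sqrt(l1^2 + l2^2 + l3^2)  (structure,  weighted by c)
        v  = (1 - exp(-Ra^2/2a^2)) * exp(-Rb^2/2b^2) * (1 - exp(-S^2/2c^2))

    The response is set to zero wherever l2 > 0 or l3 > 0: bright tubes
    have negative principal curvatures, so this suppresses dark (inverted)
    structures explicitly rather than through the blobness term.  The
    output is the maximum response over scales, in [0, 1].
    """
    params = params or FrangiParams()
    if min(volume.shape) < 2 * max(params.scales):
        raise ValueError(
            f"volume shape {volume.shape} smaller than twice the largest "
            f"scale {max(params.scales)}")
    data = volume.data.astype(np.float64)
    response = np.zeros_like(data)
    for sigma in params.scales:
        eigvals = hessian_matrix_eigvals(hessian_matrix(
            data, sigma=sigma, use_gaussian_derivatives=True, mode="reflect"))
        eigvals = np.take_along_axis(eigvals, np.abs(eigvals).argsort(0), 0)
        l1, l2, l3 = eigvals
        wrong_sign = (l2 > 0) | (l3 > 0)
        a2 = np.maximum(np.abs(l2), 1e-30)
        a3 = np.maximum(np.abs(l3), 1e-30)
        ra2 = (a2 / a3) ** 2
        rb2 = l1 ** 2 / (a2 * a3)
        s2 = l1 ** 2 + l2 ** 2 + l3 ** 2
        c = params.c if params.c is not None else np.sqrt(s2.max()) / 2
        if c <= 0:
            continue  # flat volume at this scale: no structure anywhere
        v = ((1.0 - np.exp(-ra2 / (2 * params.alpha ** 2)))
             * np.exp(-rb2 / (2 * params.beta ** 2))
             * (1.0 - np.exp(-s2 / (2 * c ** 2))))
        v[wrong_sign] = 0.0
        response = np.maximum(response, v)
    return volume.with_data(np.clip(response, 0.0, 1.0), stage="vesselness")


_STAGE_INDEX = {name: i for i, name in enumerate(STAGES)}


@dataclass
class PipelineConfig:
    """Parameters of the four enhancement stages."""

    pa_filter: PAFilterParams = field(default_factory=PAFilterParams)
    enhance: EnhanceParams = field(default_factory=EnhanceParams)
    frangi: FrangiParams = field(default_factory=FrangiParams)


def run_pipeline(volume: OCTAVolume, upto_stage: str = "vesselness",
                 config: PipelineConfig | None = None) -> dict[str, OCTAVolume]:
    """Apply the enhancement stages cumulatively up to ``upto_stage``.

    Returns a dict mapping each stage name (in pipeline order, starting at
    ``original``) to its volume, so all intermediates are retained.
    """
    if upto_stage not in _STAGE_INDEX:
        raise ValueError(f"unknown stage {upto_stage!r}; expected one of {STAGES}")
    config = config or PipelineConfig()
    last = _STAGE_INDEX[upto_stage]
    results: dict[str, OCTAVolume] = {"original": volume}
    current = volume
    transforms = (
        ("normalized", lambda v: normalize_bscans(v)),
        ("pa_attenuated", lambda v: attenuate_projection_artifacts(v, config.pa_filter)),
        ("contrast_enhanced", lambda v: median_contrast_enhance(v, config.enhance)),
        ("vesselness", lambda v: frangi_vesselness(v, config.frangi)),
    )
    for name, fn in transforms:
        if _STAGE_INDEX[name] > last:
            break
        current = fn(current)
        results[name] = current
    return results
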