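"""Vessel-segmentation evaluation metrics for 2D and 3D binary masks.

Eleven quantities are reported for a (prediction S, reference Sgt) pair:

* four standard overlap metrics — Dice, precision, recall, balanced
  accuracy — from voxelwise TP/FP/FN/TN counts;
* vascular density VD = |S| / |domain|, vasculature fragmentation VF =
  number of connected components (8-connected in 2D, 26-connected in 3D),
  and box-counting fractal dimension FD, each computed on both masks and
  summarised as the signed relative percentage difference of the
  prediction against the reference;
* the connectivity-area-length index CAL: the product of a fragmentation
  agreement term, an overlap-after-small-dilation term (disc/ball radius
  alpha) and a skeleton-coincidence term (dilation radius beta), 1 for a
  perfect prediction and 0 for complete failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.morphology import ball, disk
from skimage.morphology import skeletonize as _skimage_skeletonize

from .types import MetricReport, VesselMask

__all__ = [
    "CALParams", "BoxCountParams",
    "overlap_metrics", "vascular_density", "count_components",
    "fractal_dimension", "skeletonize",
    "cal_connectivity", "cal_area", "cal_length", "cal_index",
    "relative_percent_difference", "evaluate",
]


@dataclass
class CALParams:
    """Dilation radii of the CAL area (alpha) and length (beta) terms.

    The structuring element is a disc in 2D and a ball in 3D.
    """

    alpha: int = 2
    beta: int = 3

    def __post_init__(self) -> None:
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("alpha and beta must be positive integers")


@dataclass
class BoxCountParams:
    """Box-counting configuration for the fractal dimension.

    ``n_scales`` box sizes are spaced geometrically between 2 and the
    largest power of 2 that fits in the smallest mask dimension; at each
    size, ``n_offsets`` grid offsets are tried and the smallest box count
    retained.
    """

    n_scales: int = 20
    n_offsets: int = 5

    def __post_init__(self) -> None:
        if self.n_scales < 2:
            raise ValueError("n_scales must be >= 2")
        if self.n_offsets < 1:
            raise ValueError("n_offsets must be >= 1")


def _check_pair(s: VesselMask, sgt: VesselMask) -> None:
    if s.data.shape != sgt.data.shape:
        raise ValueError(f"mask shapes differ: {s.data.shape} vs {sgt.data.shape}")


def _safe_ratio(num: float, den: float, both_empty: bool) -> float:
    if den == 0:
        return 1.0 if both_empty else 0.0
    return num / den


def overlap_metrics(s: VesselMask, sgt: VesselMask
                    ) -> tuple[float, float, float, float]:
    """Dice, precision, recall and balanced accuracy from voxel counts.

    Empty-denominator conventions: if both masks are empty all four
    metrics are 1; if only one side is empty the affected metric is 0.
    """
    _check_pair(s, sgt)
    a, b = s.data, sgt.data
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    tn = a.size - tp - fp - fn
    both_empty = (tp + fp + fn) == 0
    dice = _safe_ratio(2 * tp, 2 * tp + fp + fn, both_empty)
    precision = _safe_ratio(tp, tp + fp, both_empty)
    recall = _safe_ratio(tp, tp + fn, both_empty)
    # specificity's empty-denominator convention mirrors the others on the
    # complements: both complements empty -> 1, else 0
    specificity = _safe_ratio(tn, tn + fp, (fn + tn == 0) and (fp + tn == 0))
    return dice, precision, recall, (recall + specificity) / 2


def vascular_density(mask: VesselMask) -> float:
    """Fraction of the field of view occupied by vessels, |S| / |domain|."""
    if mask.data.size == 0:
        raise ValueError("empty domain")
    return mask.count / mask.data.size


def count_components(mask: VesselMask) -> int:
    """Connected-component count under the mask's connectivity convention."""
    _, n = ndi.label(mask.data, structure=mask.structure)
    return int(n)


def _box_sizes(shape: tuple[int, ...], n_scales: int) -> np.ndarray:
    max_box = 2 ** int(math.floor(math.log2(min(shape))))
    if max_box < 2:
        raise ValueError(f"mask shape {shape} too small for box counting")
    sizes = np.unique(np.rint(np.geomspace(2, max_box, n_scales)).astype(int))
    return sizes[::-1]  # largest first

def _min_box_count(coords: np.ndarray, size: int, n_offsets: int) -> int:
    # coords: (npix, ndim) vessel coordinates; diagonal offsets 0..size-1
    best = None
    for k in range(n_offsets):
        off = (k * size) // n_offsets
        boxes = (coords + off) // size
        # collapse box indices to single keys for uniqueness
        keys = boxes[:, 0]
        for d in range(1, boxes.shape[1]):
            keys = keys * (1 << 21) + boxes[:, d]
        count = np.unique(keys).size
        best = count if best is None else min(best, count)
    return int(best)


def fractal_dimension(mask: VesselMask, params: BoxCountParams | None = None
                      ) -> float:
    """Box-counting fractal dimension of a binary mask.

    For each box side D (geometrically spaced down from the largest power
    of 2 fitting the smallest dimension) the smallest number of grid-
    aligned boxes covering all vessel pixels is found over several grid
    offsets; FD is minus the slope of the least-squares fit of log N(D)
    against log D.  A space-filling 2D mask approaches 2, a thin curve 1.
    """
    params = params or BoxCountParams()
    if not mask.data.any():
        raise ValueError("fractal dimension undefined for an empty mask")
    sizes = _box_sizes(mask.data.shape, params.n_scales)
    if sizes.size < 2:
        raise ValueError("mask too small: fewer than 2 box scales available")
    coords = np.argwhere(mask.data)
    counts = np.array([_min_box_count(coords, int(d), params.n_offsets)
                       for d in sizes])
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def skeletonize(mask: VesselMask) -> VesselMask:
    """Morphological thinning to 1-pixel/voxel width."""
    return VesselMask(data=_skimage_skeletonize(mask.data), role=mask.role)


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    if not mask.any():
        return mask.copy()
    footprint = disk(radius) if mask.ndim == 2 else ball(radius)
    return ndi.binary_dilation(mask, structure=footprint)


def cal_connectivity(s: VesselMask, sgt: VesselMask) -> float:
    """Fragmentation agreement: 1 - min(1, |#c(Sgt) - #c(S)| / |Sgt|).

    The denominator is the reference vessel-pixel count; differences in
    component count larger than it clamp the term to 0.
    """
    _check_pair(s, sgt)
    n_gt = sgt.count
    if n_gt == 0:
        raise ValueError("cal_connectivity undefined for an empty reference")
    diff = abs(count_components(sgt) - count_components(s))
    return 1.0 - min(1.0, diff / n_gt)


def cal_area(s: VesselMask, sgt: VesselMask, params: CALParams | None = None
             ) -> float:
    """Overlap after small dilation (radius alpha), symmetric in S and Sgt.

    |(dil(S) & Sgt) | (S & dil(Sgt))| / |S | Sgt|; 1 when both are empty.
    """
    _check_pair(s, sgt)
    params = params or CALParams()
    a, b = s.data, sgt.data
    union = int((a | b).sum())
    if union == 0:
        return 1.0
    da = _dilate(a, params.alpha)
    db = _dilate(b, params.alpha)
    num = int(((da & b) | (a & db)).sum())
    return num / union


def cal_length(s: VesselMask, sgt: VesselMask, params: CALParams | None = None
               ) -> float:
    """Skeleton coincidence within dilation radius beta, symmetric.

    With skel() the thinning operator and dil() the radius-beta dilation:
    |(skel(S) & dil(Sgt)) | (dil(S) & skel(Sgt))| / |skel(S) | skel(Sgt)|;
    1 when both skeletons are empty.
    """
    _check_pair(s, sgt)
    params = params or CALParams()
    sk_s = skeletonize(s).data
    sk_gt = skeletonize(sgt).data
    den = int((sk_s | sk_gt).sum())
    if den == 0:
        return 1.0
    num = int(((sk_s & _dilate(sgt.data, params.beta))
               | (_dilate(s.data, params.beta) & sk_gt)).sum())
    return num / den


def cal_index(s: VesselMask, sgt: VesselMask, params: CALParams | None = None
              ) -> float:
    """The CAL index: product of connectivity, area and length terms."""
    params = params or CALParams()
    return (cal_connectivity(s, sgt)
            * cal_area(s, sgt, params)
            * cal_length(s, sgt, params))


def relative_percent_difference(value_pred: float, value_gt: float) -> float:
    """Signed relative difference, 100 * (pred - gt) / gt.

    NaN (with a warning) when the reference value is zero; the sign
    distinguishes over- from under-segmentation.
    """
    if value_gt == 0:
        warnings.warn("relative difference undefined for a zero reference",
                      stacklevel=2)
        return math.nan
    return 100.0 * (value_pred - value_gt) / value_gt


def evaluate(s: VesselMask, sgt: VesselMask,
             cal_params: CALParams | None = None,
             box_params: BoxCountParams | None = None) -> MetricReport:
    """Compute the full eleven-metric report for a (S, Sgt) pair.

    Works identically for 2D and 3D masks.  Fractal dimensions of empty
    masks are reported as NaN.
    """
    _check_pair(s, sgt)
    if s.ndim != sgt.ndim:
        raise ValueError("masks must share dimensionality")
    cal_params = cal_params or CALParams()
    box_params = box_params or BoxCountParams()
    dice, precision, recall, bal_acc = overlap_metrics(s, sgt)
    vd_pred = vascular_density(s)
    vd_gt = vascular_density(sgt)
    vf_pred = count_components(s)
    vf_gt = count_components(sgt)
    fd_pred = fractal_dimension(s, box_params) if s.data.any() else math.nan
    fd_gt = fractal_dimension(sgt, box_params) if sgt.data.any() else math.nan
    conn = cal_connectivity(s, sgt)
    area = cal_area(s, sgt, cal_params)
    length = cal_length(s, sgt, cal_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rpd_vd = relative_percent_difference(vd_pred, vd_gt)
        rpd_vf = relative_percent_difference(vf_pred, vf_gt)
        rpd_fd = (relative_percent_difference(fd_pred, fd_gt)
                  if not (math.isnan(fd_pred) or math.isnan(fd_gt)) else math.nan)
    return MetricReport(
        dice=dice, precision=precision, recall=recall,
        balanced_accuracy=bal_acc,
        cal_conn=conn, cal_area=area, cal_length=length,
        cal=conn * area * length,
        vd_pred=vd_pred, vd_gt=vd_gt,
        vf_pred=vf_pred, vf_gt=vf_gt,
        fd_pred=fd_pred, fd_gt=fd_gt,
        rpd_vd=rpd_vd, rpd_vf=rpd_vf, rpd_fd=rpd_fd,
    )
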