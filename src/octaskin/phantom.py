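"""Seeded synthetic OCTA phantoms: vessel trees, rendering, degradation.

The generator emulates the structure a skin OCTA volume presents to the
pipeline: branching tubular vessel networks in two depth bands (thin and
dense near the surface, thicker and sparser at depth), multiplicative
speckle, per-B-scan gain fluctuations (the vertical bright/dark stripes
of en-face projections), exponential depth attenuation, and projection
tails — decaying false flow signal replicated below superficial vessels.
It also provides controlled mask-degradation operators (dilate, erode,
fragment, add_spurious, shift) for exercising the evaluation metrics.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import scipy.ndimage as ndi

from .metrics import skeletonize
from .types import OCTAVolume, VesselMask

__all__ = [
    "PhantomSpec", "DegradeSpec", "Branch",
    "generate_vessel_trees", "rasterize_trees", "render_octa",
    "generate_phantom", "degrade_mask",
]


@dataclass
class PhantomSpec:
    """Parameters of the synthetic OCTA generator.

    Geometry: ``shape`` is (z, y, x); the superficial band occupies depths
    [0, boundary_index) and the deep band the rest.  Trees in the
    superficial band are thinner and denser; deep-band trees thicker and
    sparser.  Artifact amplitudes: ``speckle_contrast`` is the std/mean of
    the multiplicative noise, ``bscan_gain_sigma`` the log-std of the
    per-frame gain, ``tail_strength``/``tail_decay`` the amplitude and
    per-slice decay of the projection tails, ``attenuation`` the
    per-slice exponential signal loss.
    """

    shape: tuple[int, int, int] = (90, 128, 128)
    spacing_um: tuple[float, float, float] = (15.0, 19.5, 19.5)
    boundary_index: int = 27
    n_trees_superficial: int = 4
    n_trees_deep: int = 2
    radius_superficial: tuple[float, float] = (1.5, 2.5)
    radius_deep: tuple[float, float] = (3.0, 5.0)
    branch_prob: float = 0.12
    speckle_contrast: float = 0.3
    bscan_gain_sigma: float = 0.2
    tail_strength: float = 0.4
    # ~300 um 1/e tail length at 15 um/slice: tails reach the deep plexus
    tail_decay: float = 0.05
    attenuation: float = 0.01
    background: float = 0.1
    vessel_signal: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 4:
            raise ValueError(f"degenerate phantom shape {self.shape}")
        if not 0 < self.boundary_index < self.shape[0]:
            raise ValueError("boundary_index outside the depth range")
        for name in ("speckle_contrast", "bscan_gain_sigma", "tail_strength",
                     "tail_decay", "attenuation", "background", "vessel_signal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for rng in (self.radius_superficial, self.radius_deep):
            if rng[0] < 1 or rng[1] < rng[0]:
                raise ValueError("radius ranges must be >= 1 and ordered")


@dataclass
class DegradeSpec:
    """A controlled mask corruption for metric testing."""

    operation: str = "dilate"  # dilate | erode | fragment | add_spurious | shift
    magnitude: int = 1
    seed: int = 0

    _OPS = ("dilate", "erode", "fragment", "add_spurious", "shift")

    def __post_init__(self) -> None:
        if self.operation not in self._OPS:
            raise ValueError(f"unknown operation {self.operation!r}; "
                             f"expected one of {self._OPS}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")


@dataclass
class Branch:
    """A centerline polyline with per-node radii."""

    points: np.ndarray  # (n, 3) float, (z, y, x)
    radii: np.ndarray   # (n,) float


def _grow_branch(rng: np.random.Generator, start: np.ndarray, direction: np.ndarray,
                 radius: float, zlim: tuple[float, float],
                 shape: tuple[int, int, int], max_steps: int) -> Branch:
    """Random-walk a mostly-horizontal centerline inside its depth band."""
    step = 2.0
    pts = [start.copy()]
    radii = [radius]
    pos = start.copy()
    d = direction / np.linalg.norm(direction)
    for _ in range(max_steps):
        d = d + rng.normal(0.0, 0.15, size=3) * np.array([0.5, 1.0, 1.0])
        d[0] *= 0.7  # damp vertical drift: dermal plexus vessels run en face
        d /= np.linalg.norm(d)
        pos = pos + step * d
        # reflect at the band's depth limits
        if pos[0] < zlim[0]:
            pos[0] = 2 * zlim[0] - pos[0]
            d[0] = abs(d[0])
        elif pos[0] > zlim[1]:
            pos[0] = 2 * zlim[1] - pos[0]
            d[0] = -abs(d[0])
        if not (0 <= pos[1] < shape[1] and 0 <= pos[2] < shape[2]):
            break
        radius = max(1.0, radius * 0.995)  # gentle taper
        pts.append(pos.copy())
        radii.append(radius)
    return Branch(points=np.array(pts), radii=np.array(radii))


def generate_vessel_trees(spec: PhantomSpec) -> list[list[Branch]]:
    """Random branching vessel trees, one list of branches per tree.

    Superficial-band trees are thin and numerous, deep-band trees thick
    and sparse.  Bit-identical for a fixed spec (the seed drives a
    dedicated generator stream).
    """
    rng = np.random.default_rng([spec.seed, 0xA11])
    nz, ny, nx = spec.shape
    trees: list[list[Branch]] = []
    bands = [
        (spec.n_trees_superficial, spec.radius_superficial,
         (2.0, max(3.0, spec.boundary_index - 2.0))),
        (spec.n_trees_deep, spec.radius_deep,
         (spec.boundary_index + 2.0, max(spec.boundary_index + 3.0, nz - 3.0))),
    ]
    max_steps = int(1.2 * max(ny, nx))
    for n_trees, rad_range, zlim in bands:
        for _ in range(n_trees):
            branches: list[Branch] = []
            start = np.array([
                rng.uniform(*zlim),
                rng.uniform(0.1 * ny, 0.9 * ny),
                rng.uniform(0.1 * nx, 0.9 * nx),
            ])
            theta = rng.uniform(0, 2 * np.pi)
            direction = np.array([rng.normal(0, 0.1),
                                  np.sin(theta), np.cos(theta)])
            radius = rng.uniform(*rad_range)
            trunk = _grow_branch(rng, start, direction, radius, zlim,
                                 spec.shape, max_steps)
            branches.append(trunk)
            # side branches sprout from trunk nodes with reduced radius
            for i in range(2, len(trunk.points) - 2):
                if len(branches) >= 5 or rng.uniform() >= spec.branch_prob:
                    continue
                phi = rng.uniform(np.pi / 6, np.pi / 3) * rng.choice([-1, 1])
                base_d = trunk.points[i + 1] - trunk.points[i - 1]
                c, s = np.cos(phi), np.sin(phi)
                rot = np.array([base_d[0],
                                c * base_d[1] - s * base_d[2],
                                s * base_d[1] + c * base_d[2]])
                branches.append(_grow_branch(
                    rng, trunk.points[i].copy(), rot,
                    max(1.0, trunk.radii[i] * 0.7), zlim, spec.shape,
                    max_steps // 2))
            trees.append(branches)
    return trees


def rasterize_trees(trees: list[list[Branch]], shape: tuple[int, int, int]
                    ) -> VesselMask:
    """Stamp tubes (distance-to-centerline <= radius) into a 3D mask."""
    mask = np.zeros(shape, dtype=bool)
    for branches in trees:
        for br in branches:
            for i in range(len(br.points) - 1):
                p0, p1 = br.points[i], br.points[i + 1]
                seg = p1 - p0
                n_samples = max(2, int(np.ceil(np.linalg.norm(seg) / 0.5)) + 1)
                for t in np.linspace(0.0, 1.0, n_samples):
                    c = p0 + t * seg
                    r = br.radii[i] * (1 - t) + br.radii[i + 1] * t
                    _stamp_ball(mask, c, r)
    return VesselMask(data=mask, role="gt")


def _stamp_ball(mask: np.ndarray, center: np.ndarray, radius: float) -> None:
    lo = np.maximum(np.floor(center - radius).astype(int), 0)
    hi = np.minimum(np.ceil(center + radius).astype(int) + 1,
                    np.array(mask.shape))
    if np.any(lo >= hi):
        return
    grids = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= radius ** 2


def render_octa(gt_mask: VesselMask, spec: PhantomSpec) -> OCTAVolume:
    """Render a synthetic OCTA intensity volume from a ground-truth mask.

    Intensity model, applied in order: background plus vessel signal on
    the mask, plus projection tails (below each vessel voxel, a signal of
    ``tail_strength * exp(-tail_decay * dz)``); the sum is attenuated by
    ``exp(-attenuation * z)``, multiplied by per-B-scan lognormal gains
    (gain stripes) and by unit-mean speckle noise.
    """
    if gt_mask.data.shape != spec.shape:
        raise ValueError(f"mask shape {gt_mask.data.shape} does not match "
                         f"spec shape {spec.shape}")
    rng = np.random.default_rng([spec.seed, 0x0C7A])
    nz, ny, nx = spec.shape
    vessels = gt_mask.data.astype(np.float32) * spec.vessel_signal
    signal = spec.background + vessels
    if spec.tail_strength > 0:
        decay = np.exp(-spec.tail_decay)
        tail = np.zeros((ny, nx), dtype=np.float32)
        for z in range(1, nz):
            tail = decay * (tail + vessels[z - 1])
            signal[z] += spec.tail_strength * tail
    signal *= np.exp(-spec.attenuation * np.arange(nz, dtype=np.float32)
                     )[:, None, None]
    if spec.bscan_gain_sigma > 0:
        gains = rng.lognormal(mean=0.0, sigma=spec.bscan_gain_sigma, size=nx)
        signal *= gains[None, None, :].astype(np.float32)
    if spec.speckle_contrast > 0:
        # gamma speckle with unit mean and std/mean = speckle_contrast
        k = 1.0 / spec.speckle_contrast ** 2
        signal *= rng.gamma(shape=k, scale=1.0 / k,
                            size=spec.shape).astype(np.float32)
    return OCTAVolume(data=np.maximum(signal, 0.0), spacing_um=spec.spacing_um,
                      stage="original", surface_aligned=True)


def generate_phantom(spec: PhantomSpec) -> tuple[OCTAVolume, VesselMask]:
    """Convenience wrapper: trees -> ground-truth mask -> rendered volume."""
    trees = generate_vessel_trees(spec)
    gt = rasterize_trees(trees, spec.shape)
    return render_octa(gt, spec), gt


def degrade_mask(mask: VesselMask, spec: DegradeSpec) -> VesselMask:
    """Apply a controlled corruption to a binary mask.

    dilate/erode: morphological with a full-connectivity element repeated
    ``magnitude`` times; fragment: carve ``magnitude`` small gaps at random
    skeleton locations; add_spurious: insert ``magnitude`` small random
    blobs; shift: translate by ``magnitude`` voxels along the first
    lateral axis (zero fill).  Deterministic per seed; magnitude 0 is the
    identity for every operation.
    """
    data = mask.data.copy()
    if spec.magnitude == 0:
        return VesselMask(data=data, role=mask.role)
    rng = np.random.default_rng([spec.seed, 0xDE6])
    if spec.operation == "dilate":
        data = ndi.binary_dilation(data, structure=mask.structure,
                                   iterations=spec.magnitude)
    elif spec.operation == "erode":
        data = ndi.binary_erosion(data, structure=mask.structure,
                                  iterations=spec.magnitude)
    elif spec.operation == "fragment":
        skel = skeletonize(mask).data
        pts = np.argwhere(skel)
        if len(pts):
            picks = pts[rng.choice(len(pts), size=min(spec.magnitude, len(pts)),
                                   replace=False)]
            cut = np.zeros_like(data)
            for p in picks:
                # radius chosen to fully sever tubes up to the default
                # deep-band radius range
                _set_ball(cut, p, radius=4)
            data &= ~cut
    elif spec.operation == "add_spurious":
        for _ in range(spec.magnitude):
            center = np.array([rng.integers(0, s) for s in data.shape])
            _set_ball(data, center, radius=int(rng.integers(1, 3)))
    elif spec.operation == "shift":
        axis = 1 if data.ndim == 3 else 0
        shifted = np.zeros_like(data)
        m = spec.magnitude
        if m < data.shape[axis]:
            src = [slice(None)] * data.ndim
            dst = [slice(None)] * data.ndim
            src[axis] = slice(0, data.shape[axis] - m)
            dst[axis] = slice(m, None)
            shifted[tuple(dst)] = data[tuple(src)]
        data = shifted
    return VesselMask(data=data, role=mask.role)


def _set_ball(arr: np.ndarray, center: np.ndarray, radius: int) -> None:
    lo = np.maximum(center - radius, 0)
    hi = np.minimum(center + radius + 1, np.array(arr.shape))
    if np.any(lo >= hi):
        return
    grids = np.ogrid[tuple(slice(a, b) for a, b in zip(lo, hi))]
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    arr[tuple(slice(a, b) for a, b in zip(lo, hi))] |= dist2 <= radius ** 2


def spec_to_json(spec: PhantomSpec) -> str:
    """Serialize a phantom spec (for provenance sidecars)."""
    d = asdict(spec)
    d["shape"] = list(d["shape"])
    d["spacing_um"] = list(d["spacing_um"])
    return json.dumps(d, indent=1)
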