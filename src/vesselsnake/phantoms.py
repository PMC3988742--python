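"""Synthetic vessel phantoms with exact ground truth.

Every other module is exercised against these phantoms: bright tubes
(straight, Y-bifurcation, or fading contrast) on a darker background, an
optional tangent bright blob acting as a leak trap, additive Gaussian noise,
and an optional tri-modal global histogram emulating a contrast-enhanced CT
volume (air / soft tissue / blood-pool analog).

The ground-truth mask is computed from the clean analytic geometry
(distance-to-centerline <= vessel_radius) and is therefore independent of the
noise realization.  The blob is deliberately *excluded* from the mask: it is
the structure a leaking contour spills into, and counts as background in the
evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .grid import ImageGrid

GEOMETRIES = (
    "straight",
    "y_bifurcation",
    "straight_plus_blob",
    "y_plus_blob",
    "fading",
)

#: blood-pool-analog histogram defaults: (mean, sigma, weight) per mode,
#: ordered dark to bright (air / soft tissue / blood analog, HU-like units)
DEFAULT_MODES = (
    (-900.0, 40.0, 0.3),
    (50.0, 30.0, 0.6),
    (350.0, 25.0, 0.1),
)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic vessel image.

    ``contrast = intensity_vessel - intensity_background`` defaults to four
    noise standard deviations; the blob shares the vessel intensity so that
    intensity alone cannot separate the two (the leak scenario).
    """

    shape: tuple = (128, 128)
    vessel_radius: float = 4.0
    geometry: str = "straight"
    bifurcation_angle: float = 60.0
    blob_radius: float = None  # default: 3 x vessel_radius
    blob_gap: float = 0.0  # 0 = tangent to the vessel boundary
    intensity_background: float = 0.0
    intensity_vessel: float = 100.0
    intensity_blob: float = None  # default: intensity_vessel
    noise_sigma: float = 25.0
    fade_to: float = 0.1  # terminal contrast fraction for the fading tube
    n_modes: int = 1
    modes: tuple = DEFAULT_MODES  # (mean, sigma, weight) triples, n_modes of them
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        if len(self.shape) not in (2, 3) or any(n < 8 for n in self.shape):
            raise ValueError(f"shape must be 2D/3D with every axis >= 8, got {self.shape}")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unknown geometry {self.geometry!r}; choose from {GEOMETRIES}")
        if self.vessel_radius < 1:
            raise ValueError("vessel_radius must be >= 1 voxel")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.blob_gap < 0:
            raise ValueError(
                "blob_gap must be >= 0: a blob overlapping the vessel interior is "
                "rejected (the leak trap must be adjacent, gap 0 meaning tangent)"
            )
        for v in (
            self.intensity_background,
            self.intensity_vessel,
            self.noise_sigma,
        ):
            if not math.isfinite(v):
                raise ValueError("intensities and noise_sigma must be finite")
        if self.blob_radius is None:
            object.__setattr__(self, "blob_radius", 3.0 * self.vessel_radius)
        if self.intensity_blob is None:
            object.__setattr__(self, "intensity_blob", self.intensity_vessel)
        if not math.isfinite(self.intensity_blob):
            raise ValueError("intensity_blob must be finite")
        if self.n_modes < 1:
            raise ValueError("n_modes must be >= 1")
        for m in self.modes:
            if len(m) != 3 or not all(math.isfinite(x) for x in m):
                raise ValueError("each histogram mode is a finite (mean, sigma, weight) triple")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def contrast(self) -> float:
        return self.intensity_vessel - self.intensity_background


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def _voxel_coords(shape):
    axes = [np.arange(n, dtype=float) for n in shape]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _dist_to_segment(coords, p0, p1):
    """Euclidean distance from every voxel center to segment p0-p1."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L2 = float(d @ d)
    rel = coords - p0
    if L2 == 0.0:
        return np.linalg.norm(rel, axis=-1)
    t = np.clip((rel @ d) / L2, 0.0, 1.0)
    proj = p0 + t[..., None] * d
    return np.linalg.norm(coords - proj, axis=-1)


def centerline_segments(spec: PhantomSpec):
    """Centerline polyline of the vessel as a list of (p0, p1) voxel points.

    The tube runs along axis 0.  For the Y geometry the trunk spans the lower
    half and two branches leave the branch point at ±bifurcation_angle/2 from
    the axis, deflecting along the last axis.
    """
    shape = spec.shape
    n0 = shape[0]
    center = [(n - 1) / 2.0 for n in shape]
    bottom = [n0 - 1.0] + center[1:]
    top = [0.0] + center[1:]
    if spec.geometry in ("straight", "straight_plus_blob", "fading"):
        return [(np.array(bottom), np.array(top))]
    # Y: trunk to mid-plane, branches at +-angle/2 towards the top
    mid = [(n0 - 1) / 2.0] + center[1:]
    half = math.radians(spec.bifurcation_angle) / 2.0
    length = (n0 - 1) / 2.0 / math.cos(half) if math.cos(half) > 1e-9 else n0
    segs = [(np.array(bottom), np.array(mid))]
    for sgn in (+1.0, -1.0):
        direction = np.zeros(len(shape))
        direction[0] = -math.cos(half)
        direction[-1] = sgn * math.sin(half)
        segs.append((np.array(mid), np.array(mid) + length * direction))
    return segs


def centerline_distance(spec: PhantomSpec, coords=None):
    """Min distance of every voxel to the vessel centerline."""
    if coords is None:
        coords = _voxel_coords(spec.shape)
    dmin = None
    for p0, p1 in centerline_segments(spec):
        d = _dist_to_segment(coords, p0, p1)
        dmin = d if dmin is None else np.minimum(dmin, d)
    return dmin


def blob_center(spec: PhantomSpec):
    """Center of the leak-trap blob, offset along the last axis so that the
    blob boundary sits ``blob_gap`` voxels from the vessel boundary."""
    shape = spec.shape
    center = [(n - 1) / 2.0 for n in shape]
    if spec.geometry == "y_plus_blob":
        # beside the trunk, halfway between the bottom and the branch point
        c = [0.75 * (shape[0] - 1)] + center[1:]
    else:
        c = list(center)
    offset = spec.vessel_radius + spec.blob_gap + spec.blob_radius
    c[-1] += offset
    return np.array(c)


def _blob_mask(spec: PhantomSpec, coords):
    c = blob_center(spec)
    d = np.linalg.norm(coords - c, axis=-1)
    return d <= spec.blob_radius


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_phantom(spec: PhantomSpec):
    """Build a noisy phantom and its noise-free ground-truth vessel mask.

    Returns
    -------
    (ImageGrid, ndarray of bool)
        The image (clean geometry + i.i.d. N(0, noise_sigma^2) noise) and the
        analytic vessel mask.  The blob, when present, is *not* part of the
        mask.  Deterministic given ``spec.rng_seed``.
    """
    coords = _voxel_coords(spec.shape)
    dist = centerline_distance(spec, coords)
    mask = dist <= spec.vessel_radius
    if not mask.any():
        raise ValueError("phantom geometry produced an empty vessel mask")

    clean = np.full(spec.shape, spec.intensity_background, dtype=float)
    if spec.geometry == "fading":
        # contrast decays linearly along the tube: full at the bottom row,
        # fade_to fraction at the top row
        t = coords[..., 0] / max(spec.shape[0] - 1, 1)  # 0 at top, 1 at bottom
        frac = spec.fade_to + (1.0 - spec.fade_to) * t
        clean[mask] = (spec.intensity_background + frac * spec.contrast)[mask]
    else:
        clean[mask] = spec.intensity_vessel

    if spec.geometry in ("straight_plus_blob", "y_plus_blob"):
        blob = _blob_mask(spec, coords)
        if (blob & mask).any():
            raise ValueError(
                "blob overlaps the vessel interior; increase blob_gap "
                "(0 means tangent, never overlapping)"
            )
        clean[blob] = spec.intensity_blob

    rng = np.random.default_rng(spec.rng_seed)
    noisy = clean if spec.noise_sigma == 0 else clean + rng.normal(0.0, spec.noise_sigma, spec.shape)
    return ImageGrid(noisy), mask


def make_trimodal_volume(spec: PhantomSpec, return_labels: bool = False):
    """Phantom whose global histogram has three Gaussian modes.

    Background voxels are assigned to one of the ``spec.modes`` classes at
    random (per the mode weights); vessel and blob voxels are forced into the
    brightest mode, emulating the contrast-filled blood pool.  The brightest
    mode's mean replaces ``intensity_vessel``.

    With ``return_labels=True`` also returns the integer mode label of every
    voxel (the generator's own ground truth for mixture-recovery tests).
    """
    if spec.n_modes != 3 or len(spec.modes) != 3:
        raise ValueError("make_trimodal_volume requires n_modes=3 with three mode triples")
    means = np.array([m[0] for m in spec.modes])
    sigmas = np.array([m[1] for m in spec.modes])
    weights = np.array([m[2] for m in spec.modes])
    if (sigmas <= 0).any() or (weights <= 0).any():
        raise ValueError("mode sigmas and weights must be positive")
    weights = weights / weights.sum()
    bright = int(np.argmax(means))

    coords = _voxel_coords(spec.shape)
    dist = centerline_distance(spec, coords)
    vessel = dist <= spec.vessel_radius
    if spec.geometry in ("straight_plus_blob", "y_plus_blob"):
        vessel = vessel | _blob_mask(spec, coords)

    rng = np.random.default_rng(spec.rng_seed)
    labels = rng.choice(len(means), size=spec.shape, p=weights)
    labels[vessel] = bright
    image = rng.normal(means[labels], sigmas[labels])
    img = ImageGrid(image)
    return (img, labels) if return_labels else img


def default_seed_mask(spec: PhantomSpec, radius: float = None):
    """A ball seed on the vessel centerline, suitable for initializing the
    contour ("initialization shown as a circle" inside the vessel).

    Placed in the lower (high-contrast, trunk) part of the tube.
    """
    if radius is None:
        radius = max(spec.vessel_radius - 1.0, 2.0)
    shape = spec.shape
    center = [(n - 1) / 2.0 for n in shape]
    seed_pt = np.array([0.85 * (shape[0] - 1)] + center[1:])
    coords = _voxel_coords(shape)
    return np.linalg.norm(coords - seed_pt, axis=-1) <= radius


def with_seed(spec: PhantomSpec, seed: int) -> PhantomSpec:
    """Copy of ``spec`` with a different rng_seed."""
    return replace(spec, rng_seed=int(seed))
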