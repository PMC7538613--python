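"""Seeded synthetic TOF-MRA phantoms, lesion masks and cohort tables.

Stands in for the animal cohort: magnitude volumes are vessel cylinders with
configurable diameter and flow intensity on a dark background plus Rician
noise (two independent Gaussian quadrature channels), lesions are connected
blobs of a prescribed fractional volume inside one hemisphere, and cohorts are
(score, lesion %) pairs with a planted coefficient of determination and slope
sign.  Everything is deterministic given the seed in its config.
"""

from __future__ import annotations

import dataclasses
import heapq
from typing import Sequence

import numpy as np
import pandas as pd

from .angio import AngioVolume, RoiMask, SliceSlab

__all__ = [
    "VesselSpec",
    "PhantomConfig",
    "CohortConfig",
    "VesselTruth",
    "PhantomTruth",
    "make_angiophantom",
    "make_lesion_phantom",
    "make_cohort",
    "willis_vessels",
    "willis_phantom_config",
    "pcoma_corridor",
    "pcoma_slab",
]


@dataclasses.dataclass(frozen=True)
class VesselSpec:
    """One vessel as a polyline centerline with a diameter and flow signal.

    ``path`` is an (k, 3) array of points in mm (k >= 2); ``diameter`` is the
    lumen diameter in mm; ``flow_intensity`` is the noise-free magnitude
    signal (a.u.) of fully blood-filled voxels.
    """

    name: str
    path: np.ndarray
    diameter: float
    flow_intensity: float

    def __post_init__(self) -> None:
        path = np.asarray(self.path, dtype=float)
        if path.ndim != 2 or path.shape[1] != 3 or path.shape[0] < 2:
            raise ValueError(f"vessel {self.name!r}: path must be (k>=2, 3) points")
        if self.diameter < 0:
            raise ValueError(f"vessel {self.name!r}: diameter must be >= 0")
        if self.flow_intensity < 0:
            raise ValueError(f"vessel {self.name!r}: flow_intensity must be >= 0")
        object.__setattr__(self, "path", path)


@dataclasses.dataclass(frozen=True)
class PhantomConfig:
    """Geometry, vessel list and noise level of an angiography phantom."""

    grid_shape: tuple[int, int, int] = (80, 80, 48)
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    vessels: tuple[VesselSpec, ...] = ()
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be > 0")
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "vessels", tuple(self.vessels))

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(s * v for s, v in zip(self.grid_shape, self.voxel_size))


@dataclasses.dataclass(frozen=True)
class CohortConfig:
    """Data-generating process for a (score, lesion %) cohort.

    ``lesion = a + b * score + e`` with the slope ``b`` chosen so that the
    population squared correlation equals ``target_r2`` and its sign equals
    ``slope_sign``; clipping of lesion_percent to [0, 100] is applied last.
    Defaults mirror a pooled fMCAo cohort: 43 animals, r² = 0.34 with a
    negative slope (better collateral flow, smaller lesion).
    """

    n_animals: int = 43
    target_r2: float = 0.34
    slope_sign: str = "negative"
    score_mean: float = 8.0
    score_sd: float = 4.0
    lesion_mean: float = 20.0
    lesion_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_r2 <= 1.0):
            raise ValueError(f"target_r2 must be in [0, 1], got {self.target_r2}")
        if self.n_animals < 3:
            raise ValueError("n_animals must be >= 3")
        if self.slope_sign not in ("negative", "positive"):
            raise ValueError(f"slope_sign must be 'negative' or 'positive', got {self.slope_sign!r}")
        if self.score_sd <= 0 or self.lesion_sd < 0:
            raise ValueError("score_sd must be > 0 and lesion_sd >= 0")


@dataclasses.dataclass(frozen=True)
class VesselTruth:
    """Ground truth for one planted vessel."""

    diameter: float
    flow_intensity: float
    mask: np.ndarray  # voxels with any cylinder coverage


@dataclasses.dataclass(frozen=True)
class PhantomTruth:
    """Ground truth accompanying a generated phantom volume."""

    vessels: dict[str, VesselTruth]
    noise_sigma: float
    signal: np.ndarray  # noise-free signal volume


# ---------------------------------------------------------------------------
# angiography phantom


def _segment_distances(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance of each point (n, 3) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def _polyline_distances(points: np.ndarray, path: np.ndarray) -> np.ndarray:
    d = np.full(points.shape[0], np.inf)
    for a, b in zip(path[:-1], path[1:]):
        np.minimum(d, _segment_distances(points, a, b), out=d)
    return d


def _rasterize_vessel(
    grid_shape: Sequence[int],
    voxel_size: Sequence[float],
    vessel: VesselSpec,
    supersample: int = 3,
) -> np.ndarray:
    """Partial-volume coverage (0..1) of a vessel cylinder on the voxel grid.

    Each voxel is subdivided ``supersample`` times per axis and the coverage
    is the fraction of sub-voxel points within the cylinder radius of the
    centerline.  Sub-voxel diameters therefore produce graded intensities
    rather than all-or-nothing voxels, which matters for small PcomAs near
    the detection limit.
    """
    shape = np.asarray(grid_shape, int)
    vsize = np.asarray(voxel_size, float)
    extent = shape * vsize
    if np.any(vessel.path < 0) or np.any(vessel.path > extent):
        raise ValueError(
            f"vessel {vessel.name!r}: path leaves the grid extent {tuple(extent)} mm"
        )
    coverage = np.zeros(tuple(shape), dtype=float)
    if vessel.diameter == 0 or vessel.flow_intensity == 0:
        return coverage
    radius = vessel.diameter / 2.0

    lo_mm = vessel.path.min(axis=0) - radius - vsize
    hi_mm = vessel.path.max(axis=0) + radius + vsize
    lo = np.maximum(np.floor(lo_mm / vsize).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / vsize).astype(int), shape)
    if np.any(hi <= lo):
        return coverage

    axes = [np.arange(lo[i], hi[i]) for i in range(3)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    box_shape = ii.shape
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)

    s = supersample
    offs = (np.arange(s) + 0.5) / s  # sub-voxel positions in [0, 1)
    inside = np.zeros(idx.shape[0], dtype=float)
    for ox in offs:
        for oy in offs:
            for oz in offs:
                pts = (idx + np.array([ox, oy, oz])) * vsize
                inside += _polyline_distances(pts, vessel.path) <= radius
    coverage[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = (inside / s**3).reshape(box_shape)
    return coverage


def make_angiophantom(config: PhantomConfig) -> tuple[AngioVolume, PhantomTruth]:
    """Generate a magnitude TOF-like volume plus its ground truth.

    The noise-free signal of a voxel is the largest ``flow_intensity *
    coverage`` over all vessels; the magnitude image is the modulus of
    (signal + n1) + i*n2 with independent Gaussian channels of SD
    ``noise_sigma``, i.e. Rician-distributed with Rayleigh background.
    """
    signal = np.zeros(config.grid_shape, dtype=float)
    vessels: dict[str, VesselTruth] = {}
    for vessel in config.vessels:
        coverage = _rasterize_vessel(config.grid_shape, config.voxel_size, vessel)
        np.maximum(signal, vessel.flow_intensity * coverage, out=signal)
        vessels[vessel.name] = VesselTruth(
            diameter=vessel.diameter,
            flow_intensity=vessel.flow_intensity,
            mask=coverage > 0,
        )
    rng = np.random.default_rng(config.seed)
    n1 = rng.normal(0.0, config.noise_sigma, size=config.grid_shape)
    n2 = rng.normal(0.0, config.noise_sigma, size=config.grid_shape)
    magnitude = np.hypot(signal + n1, n2)
    volume = AngioVolume(magnitude, voxel_size=config.voxel_size, slice_axis=2)
    return volume, PhantomTruth(vessels=vessels, noise_sigma=config.noise_sigma, signal=signal)


# ---------------------------------------------------------------------------
# default circle-of-Willis geometry
#
# Coordinates in mm on the default 8.0 x 8.0 x 4.8 mm grid (0.1 mm voxels):
# axis 0 = left-right (left at low x), axis 1 = posterior at high y,
# axis 2 = axial slices (inferior at low z).  The basilar artery (BA) runs on
# the midline, splits into the superior cerebellar arteries (SCA); the
# posterior cerebral arteries (PCA) lie above; each PcomA bridges SCA to PCA.
# Diameters follow mouse anatomy: BA ~0.26 mm, recruited PcomA ~0.12 mm
# (up to ~60% of BA after stroke), i.e. near the 0.1 mm voxel size.

_WILLIS_EXTENT = (8.0, 8.0, 4.8)


def _mirror_x(path: Sequence[Sequence[float]]) -> np.ndarray:
    p = np.asarray(path, float).copy()
    p[:, 0] = _WILLIS_EXTENT[0] - p[:, 0]
    return p


def willis_vessels(
    pcoma_intensity: tuple[float, float] = (24.0, 24.0),
    pcoma_diameter: tuple[float, float] = (0.12, 0.12),
    trunk_intensity: float = 24.0,
) -> tuple[VesselSpec, ...]:
    """Default posterior circle-of-Willis vessel set (left, right order)."""
    ba = [(4.0, 7.0, 1.0), (4.0, 4.2, 1.4)]
    sca_l = [(4.0, 4.2, 1.4), (2.2, 3.6, 1.8)]
    pca_l = [(4.0, 3.4, 2.75), (1.8, 2.2, 2.75)]
    pcoma_l = [(2.4, 3.55, 1.8), (2.1, 2.4, 2.7)]
    return (
        VesselSpec("BA", np.asarray(ba, float), 0.26, trunk_intensity),
        VesselSpec("SCA_left", np.asarray(sca_l, float), 0.16, trunk_intensity),
        VesselSpec("SCA_right", _mirror_x(sca_l), 0.16, trunk_intensity),
        VesselSpec("PCA_left", np.asarray(pca_l, float), 0.18, trunk_intensity),
        VesselSpec("PCA_right", _mirror_x(pca_l), 0.18, trunk_intensity),
        VesselSpec("PcomA_left", np.asarray(pcoma_l, float), pcoma_diameter[0], pcoma_intensity[0]),
        VesselSpec("PcomA_right", _mirror_x(pcoma_l), pcoma_diameter[1], pcoma_intensity[1]),
    )


def willis_phantom_config(
    seed: int = 0,
    noise_sigma: float = 2.0,
    pcoma_snr: tuple[float, float] = (12.0, 12.0),
    pcoma_diameter: tuple[float, float] = (0.12, 0.12),
    trunk_snr: float = 12.0,
) -> PhantomConfig:
    """Convenience config: vessel intensities specified as target SNR."""
    vessels = willis_vessels(
        pcoma_intensity=(pcoma_snr[0] * noise_sigma, pcoma_snr[1] * noise_sigma),
        pcoma_diameter=pcoma_diameter,
        trunk_intensity=trunk_snr * noise_sigma,
    )
    return PhantomConfig(vessels=vessels, noise_sigma=noise_sigma, seed=seed)


_CORRIDOR_MM = {  # x, y, z bounds of the left SCA-PCA corridor
    "x": (1.95, 2.85),
    "y": (2.7, 3.4),
    "z": (1.75, 2.55),
}


def pcoma_corridor(
    grid_shape: Sequence[int] = (80, 80, 48),
    voxel_size: Sequence[float] = (0.1, 0.1, 0.1),
    side: str = "left",
) -> RoiMask:
    """Box ROI between SCA and PCA on one side of the default geometry."""
    shape = tuple(int(s) for s in grid_shape)
    vsize = np.asarray(voxel_size, float)
    xb, yb, zb = _CORRIDOR_MM["x"], _CORRIDOR_MM["y"], _CORRIDOR_MM["z"]
    if side == "right":
        xb = (_WILLIS_EXTENT[0] - _CORRIDOR_MM["x"][1], _WILLIS_EXTENT[0] - _CORRIDOR_MM["x"][0])
    elif side != "left":
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    mask = np.zeros(shape, dtype=bool)
    lo = [int(np.floor(b[0] / v)) for b, v in zip((xb, yb, zb), vsize)]
    hi = [min(int(np.ceil(b[1] / v)), s) for b, v, s in zip((xb, yb, zb), vsize, shape)]
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return RoiMask(mask=mask, side=side, label=f"SCA-PCA corridor ({side})")


def pcoma_slab(voxel_size: float = 0.1) -> SliceSlab:
    """Default 10-slice slab covering the posterior circle of Willis."""
    first = int(round(1.6 / voxel_size))
    return SliceSlab.of_length(first, 10)


# ---------------------------------------------------------------------------
# lesion phantom


def make_lesion_phantom(
    grid_shape: Sequence[int],
    lesion_fraction: float,
    seed: int = 0,
    axis: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Connected lesion blob inside one hemisphere of an ellipsoidal brain.

    Returns ``(lesion_mask, ipsi_hemisphere_mask, contra_hemisphere_mask)``.
    The brain is the ellipsoid inscribed (at 90% of each semi-axis) in the
    grid, split at the midsagittal plane along ``axis``; the ipsilateral
    (lesioned) hemisphere is the low-index half, matching a left-sided
    occlusion.  The lesion is grown voxel by voxel from a deep seed point in
    roughly concentric order with seeded jitter until it occupies
    ``lesion_fraction`` of the ipsilateral hemisphere (exact to the voxel).
    """
    if not (0.0 <= lesion_fraction <= 1.0):
        raise ValueError(f"lesion_fraction must be in [0, 1], got {lesion_fraction}")
    shape = tuple(int(s) for s in grid_shape)
    if len(shape) != 3 or any(s < 4 for s in shape):
        raise ValueError("grid_shape must be 3 axes of at least 4 voxels")

    center = (np.asarray(shape) - 1) / 2.0
    semi = 0.45 * np.asarray(shape)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    brain = r2 <= 1.0

    coords_axis = grids[axis]
    midline = shape[axis] // 2
    ipsi = brain & (coords_axis < midline)
    contra = brain & ~(coords_axis < midline)

    n_ipsi = int(ipsi.sum())
    target = int(round(lesion_fraction * n_ipsi))
    lesion = np.zeros(shape, dtype=bool)
    if target == 0:
        return lesion, ipsi, contra

    rng = np.random.default_rng(seed)
    # deep seed point: centre of the ipsilateral hemisphere, lateral third
    seed_pt = center.copy()
    seed_pt[axis] = midline / 2.0
    seed_idx = tuple(int(round(c)) for c in seed_pt)
    if not ipsi[seed_idx]:  # nudge onto the hemisphere if the ellipsoid misses
        cand = np.argwhere(ipsi)
        seed_idx = tuple(cand[np.argmin(((cand - seed_pt) ** 2).sum(axis=1))])

    visited = np.zeros(shape, dtype=bool)
    heap: list[tuple[float, tuple[int, int, int]]] = []

    def push(idx: tuple[int, int, int]) -> None:
        if visited[idx] or not ipsi[idx]:
            return
        visited[idx] = True
        dist = float(np.linalg.norm(np.asarray(idx) - np.asarray(seed_idx)))
        heapq.heappush(heap, (dist + rng.uniform(0.0, 1.5), idx))

    push(seed_idx)
    grown = 0
    neighbours = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while heap and grown < target:
        _, idx = heapq.heappop(heap)
        lesion[idx] = True
        grown += 1
        for d in neighbours:
            nb = (idx[0] + d[0], idx[1] + d[1], idx[2] + d[2])
            if all(0 <= nb[i] < shape[i] for i in range(3)):
                push(nb)
    return lesion, ipsi, contra


# ---------------------------------------------------------------------------
# cohort generator


def make_cohort(config: CohortConfig) -> pd.DataFrame:
    """Cohort table of (animal_id, score, lesion_percent) pairs.

    ``lesion = a + b*score + e`` with ``b = sign * sqrt(r2) * lesion_sd /
    score_sd`` and ``SD(e) = lesion_sd * sqrt(1 - r2)``, so the population
    squared correlation is exactly ``target_r2``.  Lesion percentages are
    clipped to [0, 100] after generation; the number of clipped rows is
    recorded in ``frame.attrs["n_clipped"]``.
    """
    rng = np.random.default_rng(config.seed)
    score = rng.normal(config.score_mean, config.score_sd, size=config.n_animals)
    sign = -1.0 if config.slope_sign == "negative" else 1.0
    b = sign * np.sqrt(config.target_r2) * config.lesion_sd / config.score_sd
    e_sd = config.lesion_sd * np.sqrt(1.0 - config.target_r2)
    a = config.lesion_mean - b * config.score_mean
    lesion = a + b * score + rng.normal(0.0, e_sd, size=config.n_animals)
    clipped = np.clip(lesion, 0.0, 100.0)
    frame = pd.DataFrame(
        {
            "animal_id": [f"animal_{i:03d}" for i in range(config.n_animals)],
            "score": score,
            "lesion_percent": clipped,
        }
    )
    frame.attrs["n_clipped"] = int(np.sum(clipped != lesion))
    frame.attrs["lesion_percent_unclipped"] = lesion
    return frame
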