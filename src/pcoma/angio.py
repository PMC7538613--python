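"""Semiquantitative PcomA patency scoring from TOF-MR angiograms.

The posterior communicating artery (PcomA) of C57BL/6 mice is the main
collateral that limits infarct growth after filament middle cerebral artery
occlusion.  On a time-of-flight (TOF) angiogram flowing blood is bright, so
the patency of the PcomA can be read out as the maximal flow-related
signal-to-noise ratio (SNR) inside a manually delineated corridor between the
superior cerebellar artery (SCA) and the posterior cerebral artery (PCA),
restricted to an atlas-defined slab of axial slices.

The scoring recipe implemented here:

1. estimate the Gaussian noise level ``sigma`` from a signal-free background
   region, correcting for the Rayleigh statistics of magnitude images;
2. convert the volume to a voxelwise SNR map (intensity / sigma);
3. discard everything below 1/10 of the dataset maximum (set to NaN);
4. report the maximum surviving SNR inside corridor ∩ slab as the score.

The score is dimensionless and, by construction, invariant under a global
rescaling of the image intensities.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "RAYLEIGH_MEAN_FACTOR",
    "RAYLEIGH_SD_FACTOR",
    "AngioVolume",
    "SnrMap",
    "SliceSlab",
    "RoiMask",
    "PatencyRecord",
    "PhenotypeSummary",
    "ScoreResult",
    "RatingSummary",
    "NoVesselError",
    "corner_background_mask",
    "estimate_noise",
    "snr_map",
    "threshold_map",
    "pcoma_score",
    "mip",
    "vessel_diameter",
    "diameter_percent_basilar",
    "classify_phenotype",
    "summarize_phenotypes",
    "aggregate_ratings",
]

#: Mean of a Rayleigh variate with channel sigma 1:  sqrt(pi/2).
RAYLEIGH_MEAN_FACTOR = math.sqrt(math.pi / 2.0)
#: SD of a Rayleigh variate with channel sigma 1:  sqrt(2 - pi/2) ~= 0.6551.
#: Background voxels of a magnitude MR image are Rayleigh distributed, so the
#: Gaussian channel noise is SD(background) / 0.6551.
RAYLEIGH_SD_FACTOR = math.sqrt(2.0 - math.pi / 2.0)


class NoVesselError(ValueError):
    """Raised when an intensity profile contains no vessel above background."""


@dataclasses.dataclass(frozen=True)
class AngioVolume:
    """A 3D magnitude TOF-MRA volume, assumed atlas-registered.

    Parameters
    ----------
    intensities:
        3D array of non-negative magnitude intensities (a.u.).
    voxel_size:
        Edge length of a voxel along each axis, in mm.
    slice_axis:
        Axis that indexes axial slices (the slab dimension).
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume intensities must be finite")
        if arr.min() < 0:
            raise ValueError("magnitude intensities must be >= 0")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")
        object.__setattr__(self, "intensities", arr)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def scaled(self, factor: float) -> "AngioVolume":
        """Return a copy with all intensities multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return AngioVolume(self.intensities * factor, self.voxel_size, self.slice_axis)


@dataclasses.dataclass(frozen=True)
class SnrMap:
    """Voxelwise SNR with NaN as the missing-value sentinel."""

    values: np.ndarray
    sigma: float
    threshold: float | None = None
    slice_axis: int = 2

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        finite = arr[np.isfinite(arr)]
        if finite.size and finite.min() < 0:
            raise ValueError("SNR values must be >= 0")
        if self.threshold is not None and finite.size and finite.min() < self.threshold - 1e-12:
            raise ValueError("thresholded map contains values below its threshold")
        object.__setattr__(self, "values", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclasses.dataclass(frozen=True)
class SliceSlab:
    """Inclusive range of slice indices along the slice axis.

    The atlas registration step of the upstream pipeline guarantees that the
    posterior circle of Willis falls into the same slices in every animal; the
    default slab length used throughout is 10 slices.
    """

    first_slice: int
    last_slice: int

    def __post_init__(self) -> None:
        if self.last_slice < self.first_slice:
            raise ValueError("last_slice must be >= first_slice")
        if self.first_slice < 0:
            raise ValueError("slice indices are 0-based and must be >= 0")

    @classmethod
    def of_length(cls, first_slice: int, length: int = 10) -> "SliceSlab":
        return cls(first_slice, first_slice + length - 1)

    def __len__(self) -> int:
        return self.last_slice - self.first_slice + 1

    def selector(self, shape: Sequence[int], slice_axis: int) -> np.ndarray:
        """Boolean mask of ``shape`` that is True inside the slab."""
        if self.last_slice >= shape[slice_axis]:
            raise ValueError(
                f"slab {self.first_slice}:{self.last_slice} exceeds "
                f"{shape[slice_axis]} slices along axis {slice_axis}"
            )
        mask = np.zeros(shape, dtype=bool)
        sl = [slice(None)] * len(shape)
        sl[slice_axis] = slice(self.first_slice, self.last_slice + 1)
        mask[tuple(sl)] = True
        return mask


@dataclasses.dataclass(frozen=True)
class RoiMask:
    """Binary region of interest (e.g. the SCA-PCA corridor on one side)."""

    mask: np.ndarray
    side: str = "left"
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask, dtype=bool)
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        object.__setattr__(self, "mask", arr)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.mask.shape


@dataclasses.dataclass
class ScoreResult:
    """Outcome of the semiquantitative patency measurement."""

    score: float
    no_signal: bool
    cutoff: float
    n_voxels: int

    def __float__(self) -> float:
        return float(self.score)


@dataclasses.dataclass
class PatencyRecord:
    """Per animal/side record of the score and optional manual assessments."""

    animal_id: str
    side: str
    score: float
    rating: int | None = None
    patent: bool | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("score must be >= 0")
        if self.rating is not None and self.rating not in (0, 1, 2, 3):
            raise ValueError(f"rating must be in 0..3, got {self.rating}")
        if self.patent is None:
            self.patent = self.score > 0


@dataclasses.dataclass(frozen=True)
class PhenotypeSummary:
    """Cohort-level distribution of circle-of-Willis phenotypes."""

    counts: dict[str, int]
    n: int
    fractions: dict[str, float]
    percentages: dict[str, int]

    @classmethod
    def from_counts(cls, complete: int, unilateral: int, absent: int) -> "PhenotypeSummary":
        counts = {"complete": int(complete), "unilateral": int(unilateral), "absent": int(absent)}
        n = sum(counts.values())
        if n == 0:
            raise ValueError("empty cohort")
        fractions = {k: v / n for k, v in counts.items()}
        percentages = {k: int(round(100.0 * v / n)) for k, v in counts.items()}
        return cls(counts=counts, n=n, fractions=fractions, percentages=percentages)


@dataclasses.dataclass(frozen=True)
class RatingSummary:
    """Per-subject mean of ordinal vessel-size ratings (0-3) across raters."""

    mean_ratings: pd.Series
    n_raters: int


# ---------------------------------------------------------------------------
# noise / SNR


def corner_background_mask(shape: Sequence[int], fraction: float = 0.125) -> RoiMask:
    """Fallback background mask: the 8 corner sub-cubes of the volume.

    In the TOF scout geometry used here the corners of the field of view
    contain air, so they are signal-free.  Each sub-cube spans ``fraction`` of
    the corresponding axis.
    """
    shape = tuple(int(s) for s in shape)
    sizes = [max(1, int(round(s * fraction))) for s in shape]
    mask = np.zeros(shape, dtype=bool)
    for ix in (slice(0, sizes[0]), slice(shape[0] - sizes[0], shape[0])):
        for iy in (slice(0, sizes[1]), slice(shape[1] - sizes[1], shape[1])):
            for iz in (slice(0, sizes[2]), slice(shape[2] - sizes[2], shape[2])):
                mask[ix, iy, iz] = True
    return RoiMask(mask=mask, side="left", label="corner background")


def estimate_noise(
    volume: AngioVolume,
    background_mask: RoiMask | np.ndarray | None = None,
    correction: float = RAYLEIGH_SD_FACTOR,
) -> float:
    """Estimate the Gaussian channel noise sigma from a background region.

    The background of a magnitude MR image follows a Rayleigh distribution
    whose SD is ``sigma * sqrt(2 - pi/2)``, so the returned noise level is
    ``SD(background) / correction`` with the Rayleigh factor 0.6551 as the
    default.  The ``correction`` is exposed for multi-channel coils whose
    background follows a higher-order chi distribution.
    """
    if background_mask is None:
        background_mask = corner_background_mask(volume.shape)
    mask = background_mask.mask if isinstance(background_mask, RoiMask) else np.asarray(background_mask, bool)
    if mask.shape != volume.shape:
        raise ValueError(f"background mask shape {mask.shape} != volume shape {volume.shape}")
    values = volume.intensities[mask]
    if values.size == 0:
        raise ValueError("background mask is empty")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("background has zero variance; cannot estimate noise")
    if correction <= 0:
        raise ValueError("correction factor must be positive")
    return sd / correction


def snr_map(volume: AngioVolume, sigma: float) -> SnrMap:
    """Voxelwise SNR map: intensity divided by the noise level ``sigma``."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return SnrMap(values=volume.intensities / sigma, sigma=float(sigma),
                  threshold=None, slice_axis=volume.slice_axis)


def threshold_map(snr: SnrMap, fraction: float = 0.1) -> SnrMap:
    """Suppress voxels below ``fraction`` of the dataset maximum.

    The cutoff is ``fraction * max(map)`` over the whole volume; voxels below
    it become NaN.  Applying the operation twice with the same fraction is a
    no-op because the retained maximum is unchanged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    finite = snr.values[np.isfinite(snr.values)]
    if finite.size == 0:
        raise ValueError("SNR map has no non-missing values")
    cutoff = fraction * float(finite.max())
    values = np.where(snr.values >= cutoff, snr.values, np.nan)
    return SnrMap(values=values, sigma=snr.sigma, threshold=cutoff, slice_axis=snr.slice_axis)


def pcoma_score(snr: SnrMap, roi: RoiMask, slab: SliceSlab) -> ScoreResult:
    """Maximum surviving SNR inside ``roi`` ∩ ``slab``: the patency score.

    If every corridor voxel fell below the threshold, the vessel produced no
    flow signal above noise and the score is 0, flagged ``no_signal``.  An
    empty corridor (before thresholding) is a geometry error, not a score.
    """
    if roi.shape != snr.shape:
        raise ValueError(f"ROI shape {roi.shape} != SNR map shape {snr.shape}")
    region = roi.mask & slab.selector(snr.shape, snr.slice_axis)
    n_voxels = int(region.sum())
    if n_voxels == 0:
        raise ValueError("ROI does not intersect the slab; check corridor and slab indices")
    values = snr.values[region]
    finite = values[np.isfinite(values)]
    cutoff = float(snr.threshold) if snr.threshold is not None else 0.0
    if finite.size == 0:
        return ScoreResult(score=0.0, no_signal=True, cutoff=cutoff, n_voxels=n_voxels)
    return ScoreResult(score=float(finite.max()), no_signal=False, cutoff=cutoff, n_voxels=n_voxels)


# ---------------------------------------------------------------------------
# MIP-based manual measurements


def mip(volume: AngioVolume, axis: int | None = None) -> np.ndarray:
    """Maximum intensity projection along ``axis`` (default: the slice axis)."""
    if axis is None:
        axis = volume.slice_axis
    return volume.intensities.max(axis=axis)


def vessel_diameter(
    image: np.ndarray,
    point: Sequence[float],
    direction: Sequence[float],
    pixel_size: float = 0.1,
    half_length: float = 15.0,
    step: float = 0.25,
    background_fraction: float = 0.25,
    noise_margin: float = 5.0,
) -> float:
    """Full-width-at-half-maximum vessel diameter on a 2D projection, in mm.

    An intensity profile is sampled (linear interpolation) along ``direction``
    through ``point`` (pixel coordinates), over ``±half_length`` pixels.  The
    local background is the median of the outer ``background_fraction`` of the
    profile at each end; the half-maximum level is background plus half of
    (peak − background).  The crossings on both sides of the peak are located
    by linear interpolation, giving sub-pixel width, converted to mm via
    ``pixel_size``.

    Raises
    ------
    NoVesselError
        If the peak does not exceed background by ``noise_margin`` times the
        background SD (a pure-noise profile), or never falls back to the
        half-maximum level within the profile.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("vessel_diameter expects a 2D projection image")
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("direction must be a nonzero 2D vector")
    d = d / norm
    ts = np.arange(-half_length, half_length + step / 2, step)
    coords = np.asarray(point, dtype=float)[:, None] + d[:, None] * ts[None, :]
    profile = ndimage.map_coordinates(image, coords, order=1, mode="nearest")

    n_outer = max(2, int(round(background_fraction * ts.size / 2)))
    outer = np.concatenate([profile[:n_outer], profile[-n_outer:]])
    background = float(np.median(outer))
    noise = float(np.std(outer, ddof=1))
    ipk = int(np.argmax(profile))
    peak = float(profile[ipk])
    if peak <= background or (noise > 0 and peak - background <= noise_margin * noise):
        raise NoVesselError(
            f"no vessel: peak {peak:.3g} does not exceed background "
            f"{background:.3g} by {noise_margin}x the background SD {noise:.3g}"
        )
    half = background + 0.5 * (peak - background)

    def _crossing(idx_range: Iterable[int]) -> float:
        prev = ipk
        for j in idx_range:
            if profile[j] < half:
                # linear interpolation between j and prev
                frac = (half - profile[j]) / (profile[prev] - profile[j])
                return ts[j] + frac * (ts[prev] - ts[j])
            prev = j
        raise NoVesselError("profile does not fall to half maximum within its length")

    t_left = _crossing(range(ipk - 1, -1, -1))
    t_right = _crossing(range(ipk + 1, ts.size))
    return float((t_right - t_left) * pixel_size)


def diameter_percent_basilar(d_pcoma: float, d_basilar: float) -> float:
    """PcomA diameter expressed as percent of the basilar artery diameter."""
    if d_basilar <= 0:
        raise ValueError(f"basilar diameter must be positive, got {d_basilar}")
    if d_pcoma < 0:
        raise ValueError(f"PcomA diameter must be >= 0, got {d_pcoma}")
    return 100.0 * d_pcoma / d_basilar


# ---------------------------------------------------------------------------
# phenotypes and manual ratings


def classify_phenotype(left_patent: bool | None, right_patent: bool | None) -> str:
    """Circle-of-Willis phenotype from per-side patency calls.

    Both PcomAs patent -> "complete"; exactly one -> "unilateral";
    neither -> "absent".
    """
    if left_patent is None or right_patent is None:
        raise ValueError("patency call missing for one side")
    if left_patent and right_patent:
        return "complete"
    if left_patent or right_patent:
        return "unilateral"
    return "absent"


def summarize_phenotypes(calls: Iterable[tuple[bool, bool]]) -> PhenotypeSummary:
    """Tabulate phenotypes for a cohort of (left_patent, right_patent) calls."""
    counts = {"complete": 0, "unilateral": 0, "absent": 0}
    for left, right in calls:
        counts[classify_phenotype(left, right)] += 1
    return PhenotypeSummary.from_counts(**counts)


def aggregate_ratings(ratings: pd.DataFrame | np.ndarray) -> RatingSummary:
    """Mean manual vessel-size rating (scale 0-3) per subject.

    ``ratings`` is raters x subjects (rows are raters).  Every entry must be
    an integer in {0, 1, 2, 3}; a violation is reported with the offending
    rater and subject.
    """
    if isinstance(ratings, pd.DataFrame):
        frame = ratings
    else:
        arr = np.asarray(ratings)
        frame = pd.DataFrame(arr,
                             index=[f"rater_{i}" for i in range(arr.shape[0])],
                             columns=[f"subject_{j}" for j in range(arr.shape[1])])
    values = frame.to_numpy()
    valid = np.isin(values, (0, 1, 2, 3))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"rating {values[i, j]!r} out of range 0..3 "
            f"(rater {frame.index[i]!r}, subject {frame.columns[j]!r})"
        )
    means = frame.astype(float).mean(axis=0)
    means.name = "mean_rating"
    return RatingSummary(mean_ratings=means, n_raters=frame.shape[0])
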