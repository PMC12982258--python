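"""Reference-ROI threshold segmentation of neuromelanin-rich brainstem nuclei.

The segmentation rule measured here is the classic automated NM-MRI volumetry
procedure: repeated 2-D gradient-echo measurements of the brainstem are
averaged voxelwise, the mean and standard deviation of signal intensity are
computed over a pair of reference regions placed in the cerebral peduncles,
and every voxel inside an anatomical target mask whose intensity exceeds

    mean_ref + k * sd_ref

is labelled as belonging to the target nucleus.  The multiplier ``k`` is
2.57 for the substantia nigra pars compacta (SNc) and 2.88 for the locus
coeruleus (LC).  The segmented volume is the suprathreshold voxel count times
the physical voxel volume (0.4563 mm^3 at the default 0.39 x 0.39 x 3 mm
geometry).

Inputs are assumed to be motion-corrected and spatially aligned already; this
module performs no registration.  Intensities are arbitrary scanner units and
are never normalised before thresholding: the rule is equivariant under
positive affine intensity transforms because the threshold transforms with
the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VolumetricImage",
    "RoiSet",
    "ThresholdConfig",
    "SegmentationResult",
    "average_measurements",
    "reference_statistics",
    "segment_target",
    "segment_subject",
]

Target = Literal["LC", "SNc"]

#: default in-plane x in-plane x slice voxel dimensions, mm
DEFAULT_VOXEL_DIMS: tuple[float, float, float] = (0.39, 0.39, 3.0)


@dataclass
class VolumetricImage:
    """A 3-D intensity grid with physical voxel dimensions.

    ``measurements`` holds one or more repeated acquisitions stacked on the
    leading axis, shape ``(m, nx, ny, nz)``.  A single-measurement image has
    ``m == 1``.
    """

    measurements: np.ndarray
    voxel_dims_mm: tuple[float, float, float] = DEFAULT_VOXEL_DIMS

    def __post_init__(self) -> None:
        arr = np.asarray(self.measurements, dtype=float)
        if arr.ndim == 3:
            arr = arr[np.newaxis]
        if arr.ndim != 4:
            raise ValueError(
                f"measurements must be a 3-D grid or a stack of them; got ndim={arr.ndim}"
            )
        if arr.shape[0] < 1:
            raise ValueError("at least one measurement is required")
        self.measurements = arr
        dims = tuple(float(d) for d in self.voxel_dims_mm)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise ValueError(f"voxel dimensions must be three positive reals; got {dims}")
        self.voxel_dims_mm = dims

    @property
    def n_measurements(self) -> int:
        return self.measurements.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.measurements.shape[1:]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims_mm
        return dx * dy * dz

    @property
    def grid(self) -> np.ndarray:
        """The single grid of a one-measurement image."""
        if self.n_measurements != 1:
            raise ValueError(
                "image carries multiple measurements; call average_measurements first"
            )
        return self.measurements[0]


@dataclass
class RoiSet:
    """Reference-region and probabilistic target masks on one image grid.

    The reference masks are binary; the LC and SNc masks may be fractional
    (atlas probabilities in [0, 1]) and are binarised at a configurable
    probability before restricting the thresholding.
    """

    reference_left: np.ndarray
    reference_right: np.ndarray
    lc_mask: np.ndarray
    snc_mask: np.ndarray

    def __post_init__(self) -> None:
        self.reference_left = np.asarray(self.reference_left, dtype=bool)
        self.reference_right = np.asarray(self.reference_right, dtype=bool)
        self.lc_mask = np.asarray(self.lc_mask, dtype=float)
        self.snc_mask = np.asarray(self.snc_mask, dtype=float)
        shape = self.reference_left.shape
        for name in ("reference_right", "lc_mask", "snc_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        if not self.reference_left.any() or not self.reference_right.any():
            raise ValueError("both reference masks must be non-empty")
        if (self.reference_left & self.reference_right).any():
            raise ValueError("reference masks must be disjoint")
        for name in ("lc_mask", "snc_mask"):
            m = getattr(self, name)
            if m.min() < 0.0 or m.max() > 1.0:
                raise ValueError(f"{name} values must lie in [0, 1]")

    def target_mask(self, target: Target) -> np.ndarray:
        if target == "LC":
            return self.lc_mask
        if target == "SNc":
            return self.snc_mask
        raise ValueError(f"unknown target {target!r}; expected 'LC' or 'SNc'")

    @property
    def reference_union(self) -> np.ndarray:
        return self.reference_left | self.reference_right


@dataclass(frozen=True)
class ThresholdConfig:
    """Tunable knobs of the thresholding rule.

    ``k_snc``/``k_lc`` are the SD multipliers; ``mask_binarize_p`` is the
    probability above which (inclusive) a fractional atlas voxel is eligible;
    ``sd_estimator`` chooses the n-1 (sample) or n (population) denominator.
    """

    k_snc: float = 2.57
    k_lc: float = 2.88
    mask_binarize_p: float = 0.5
    sd_estimator: Literal["sample", "population"] = "sample"

    def __post_init__(self) -> None:
        if self.k_snc <= 0 or self.k_lc <= 0:
            raise ValueError("SD multipliers must be positive")
        if not (0.0 < self.mask_binarize_p <= 1.0):
            raise ValueError("mask_binarize_p must be in (0, 1]")
        if self.sd_estimator not in ("sample", "population"):
            raise ValueError(f"unknown sd_estimator {self.sd_estimator!r}")

    def k_for(self, target: Target) -> float:
        return self.k_lc if target == "LC" else self.k_snc


@dataclass
class SegmentationResult:
    """Outcome of thresholding one target nucleus on one averaged image."""

    target: Target
    reference_mean: float
    reference_sd: float
    threshold_intensity: float
    voxel_count: int
    volume_mm3: float
    suprathreshold_mask: np.ndarray = field(repr=False)


def average_measurements(image: VolumetricImage) -> VolumetricImage:
    """Voxelwise arithmetic mean of the repeated measurements.

    A single-measurement image is returned with its grid unchanged.
    """
    if image.n_measurements == 1:
        return VolumetricImage(image.measurements[0].copy(), image.voxel_dims_mm)
    mean = image.measurements.mean(axis=0)
    return VolumetricImage(mean, image.voxel_dims_mm)


def reference_statistics(
    image: VolumetricImage,
    rois: RoiSet,
    sd_estimator: Literal["sample", "population"] = "sample",
) -> tuple[float, float, int]:
    """Mean and SD of signal intensity over the pooled reference ROIs.

    Both cerebral-peduncle masks are pooled into one voxel set; the SD uses
    the requested estimator (n-1 by default).
    """
    grid = image.grid
    union = rois.reference_union
    if union.shape != grid.shape:
        raise ValueError(
            f"reference mask shape {union.shape} does not match image {grid.shape}"
        )
    values = grid[union]
    n = values.size
    if n == 0:
        raise ValueError("reference ROI union is empty")
    if sd_estimator == "sample":
        if n < 2:
            raise ValueError("sample SD needs at least 2 reference voxels")
        sd = float(values.std(ddof=1))
    else:
        sd = float(values.std(ddof=0))
    return float(values.mean()), sd, int(n)


def segment_target(
    image: VolumetricImage,
    rois: RoiSet,
    config: ThresholdConfig,
    target: Target,
) -> SegmentationResult:
    """Threshold one target nucleus on a single-grid image.

    Voxels of the binarised target mask whose intensity is strictly greater
    than ``mean_ref + k * sd_ref`` are labelled; volume is count x voxel
    volume.
    """
    grid = image.grid
    mean, sd, _ = reference_statistics(image, rois, config.sd_estimator)
    prob_mask = rois.target_mask(target)
    if prob_mask.shape != grid.shape:
        raise ValueError(f"{target} mask shape {prob_mask.shape} != image {grid.shape}")
    eligible = prob_mask >= config.mask_binarize_p
    if not eligible.any():
        raise ValueError(
            f"{target} mask is empty after binarisation at p >= {config.mask_binarize_p}"
        )
    k = config.k_for(target)
    threshold = mean + k * sd
    supra = eligible & (grid > threshold)
    count = int(supra.sum())
    return SegmentationResult(
        target=target,
        reference_mean=mean,
        reference_sd=sd,
        threshold_intensity=float(threshold),
        voxel_count=count,
        volume_mm3=count * image.voxel_volume_mm3,
        suprathreshold_mask=supra,
    )


def segment_subject(
    image: VolumetricImage,
    rois: RoiSet,
    config: ThresholdConfig | None = None,
) -> tuple[SegmentationResult, SegmentationResult]:
    """Average the measurements and segment both LC and SNc.

    Returns ``(lc_result, snc_result)``.
    """
    config = config or ThresholdConfig()
    averaged = average_measurements(image)
    lc = segment_target(averaged, rois, config, "LC")
    snc = segment_target(averaged, rois, config, "SNc")
    return lc, snc
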