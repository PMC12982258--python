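"""Synthetic brainstem phantoms with known ground-truth blob volumes.

A phantom is a stack of noisy 3-D grids emulating repeated 2-D gradient-echo
measurements at NM-MRI geometry (default voxel 0.39 x 0.39 x 3 mm).  Each
measurement is an i.i.d. Gaussian noise field around ``background_mean`` with
``background_sd``; hyperintense ellipsoidal blobs stand in for the LC and SNc
nuclei, with intensity ``background_mean + contrast_in_sd_units *
background_sd`` plus the same noise.  Blob intensity is constant (no
partial-volume ramp) so the ground-truth voxel count of every blob is exact.

Alongside the image the generator emits an RoiSet: two rectangular reference
boxes (the cerebral-peduncle stand-ins) and per-target masks covering each
blob dilated by a configurable margin (binary-valued: probability 1 inside,
0 outside; the segmentation accepts fractional masks but the generator has
no atlas probabilities to draw on).  Optional explicit mask boxes allow
placing a target mask over pure noise, e.g. for false-positive calibration.

Noise is Gaussian, not Rician: at the signal levels of brainstem NM-MRI
tissue the Rician distribution is effectively Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import binary_dilation

from .segmentation import DEFAULT_VOXEL_DIMS, RoiSet, VolumetricImage

__all__ = ["BlobSpec", "Box", "PhantomSpec", "GroundTruth", "generate_phantom"]

Box = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]  # half-open per axis


@dataclass(frozen=True)
class BlobSpec:
    """One hyperintense ellipsoid.

    ``center`` is in voxel coordinates (may be fractional, which is how
    exact even-sized voxel counts are arranged); ``semi_axes`` are in voxels;
    ``contrast_in_sd_units`` is the intensity elevation in units of the
    background SD.
    """

    target: str  # "LC" | "SNc"
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    contrast_in_sd_units: float

    def __post_init__(self) -> None:
        if self.target not in ("LC", "SNc"):
            raise ValueError(f"blob target must be LC or SNc, got {self.target!r}")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi-axes must be positive")


@dataclass
class PhantomSpec:
    """Full description of one synthetic acquisition."""

    grid_shape: tuple[int, int, int]
    voxel_dims_mm: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    background_mean: float = 100.0
    background_sd: float = 10.0
    n_measurements: int = 1
    blobs: Sequence[BlobSpec] = field(default_factory=tuple)
    reference_boxes: tuple[Box, Box] = (
        ((0, 8), (0, 8), (0, 2)),
        ((0, 8), (8, 16), (0, 2)),
    )
    mask_dilation_voxels: int = 1
    mask_boxes: dict = field(default_factory=dict)  # target -> Box, optional
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be three positive ints: {self.grid_shape}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if int(self.n_measurements) < 1:
            raise ValueError("n_measurements must be >= 1")
        self.n_measurements = int(self.n_measurements)
        if self.mask_dilation_voxels < 0:
            raise ValueError("mask_dilation_voxels must be nonnegative")
        for box in self.reference_boxes:
            self._check_box(box, "reference box")
        for target, box in self.mask_boxes.items():
            if target not in ("LC", "SNc"):
                raise ValueError(f"mask_boxes key must be LC or SNc, got {target!r}")
            self._check_box(box, f"{target} mask box")

    def _check_box(self, box: Box, what: str) -> None:
        if len(box) != 3:
            raise ValueError(f"{what} must give (lo, hi) per axis: {box}")
        for (lo, hi), size in zip(box, self.grid_shape):
            if not (0 <= lo < hi <= size):
                raise ValueError(f"{what} {box} outside grid {self.grid_shape}")


@dataclass
class GroundTruth:
    """Exact blob voxel counts and volumes per target."""

    voxel_counts: dict[str, int]
    volumes_mm3: dict[str, float]


def _box_mask(shape: tuple[int, int, int], box: Box) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    (x0, x1), (y0, y1), (z0, z1) = box
    m[x0:x1, y0:y1, z0:z1] = True
    return m


def _ellipsoid_mask(shape: tuple[int, int, int], blob: BlobSpec) -> np.ndarray:
    cx, cy, cz = blob.center
    ax, ay, az = blob.semi_axes
    for c, a, size in zip(blob.center, blob.semi_axes, shape):
        if c - a < -0.5 or c + a > size - 0.5:
            raise ValueError(
                f"blob at {blob.center} with semi-axes {blob.semi_axes} "
                f"extends outside grid {shape}"
            )
    ix, iy, iz = np.ogrid[: shape[0], : shape[1], : shape[2]]
    q = ((ix - cx) / ax) ** 2 + ((iy - cy) / ay) ** 2 + ((iz - cz) / az) ** 2
    return q <= 1.0


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumetricImage, RoiSet, GroundTruth]:
    """Render a phantom: noisy measurements, ROI set, exact ground truth.

    Deterministic under ``spec.seed``: identical spec gives bit-identical
    output.  Rejects blobs that overlap a reference box or leave the grid.
    """
    shape = spec.grid_shape
    rng = np.random.default_rng(spec.seed)

    blob_masks = {"LC": np.zeros(shape, dtype=bool), "SNc": np.zeros(shape, dtype=bool)}
    for blob in spec.blobs:
        blob_masks[blob.target] |= _ellipsoid_mask(shape, blob)

    ref_left = _box_mask(shape, spec.reference_boxes[0])
    ref_right = _box_mask(shape, spec.reference_boxes[1])
    if (ref_left & ref_right).any():
        raise ValueError("reference boxes must be disjoint")
    ref_union = ref_left | ref_right
    any_blob = blob_masks["LC"] | blob_masks["SNc"]
    if (ref_union & any_blob).any():
        raise ValueError("reference boxes intersect a blob; move the boxes or the blob")

    # signal field: background plus per-blob contrast elevation
    signal = np.full(shape, spec.background_mean, dtype=float)
    for blob in spec.blobs:
        m = _ellipsoid_mask(shape, blob)
        signal[m] = spec.background_mean + blob.contrast_in_sd_units * spec.background_sd

    measurements = (
        signal[np.newaxis]
        + rng.standard_normal((spec.n_measurements, *shape)) * spec.background_sd
    )
    image = VolumetricImage(measurements, spec.voxel_dims_mm)

    target_masks = {}
    for target in ("LC", "SNc"):
        m = blob_masks[target]
        if spec.mask_dilation_voxels > 0 and m.any():
            m = binary_dilation(m, iterations=spec.mask_dilation_voxels)
        if target in spec.mask_boxes:
            m = m | _box_mask(shape, spec.mask_boxes[target])
        target_masks[target] = m.astype(float)

    rois = RoiSet(
        reference_left=ref_left,
        reference_right=ref_right,
        lc_mask=target_masks["LC"],
        snc_mask=target_masks["SNc"],
    )

    voxel_vol = float(np.prod(spec.voxel_dims_mm))
    counts = {t: int(blob_masks[t].sum()) for t in ("LC", "SNc")}
    truth = GroundTruth(
        voxel_counts=counts,
        volumes_mm3={t: c * voxel_vol for t, c in counts.items()},
    )
    return image, rois, truth
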