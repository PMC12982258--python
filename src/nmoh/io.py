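"""File formats: NIfTI images/masks and delimited-text cohort tables.

NIfTI I/O goes through nibabel; voxel dimensions are taken from (and written
to) the header zooms.  The cohort table is one row per subject with the
columns::

    subject_id, diagnosis, true_subgroup, age, disease_duration,
    rbdsq_group, lc_volume_mm3, snc_volume_mm3,
    supine_sbp, supine_dbp, supine_hr,
    sbp_1, sbp_3, sbp_5, dbp_1, dbp_3, dbp_5, hr_1, hr_3, hr_5

plus ``scanner_protocol`` and ``censor_flags`` (semicolon-joined tags).
Missing standing timepoints are empty cells.  The classifier appends
``oh_class, oh_subgroup_positive, neurogenic_ratio, supine_htn,
avg_delta_map, avg_delta_sbp, avg_delta_hr``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .autonomic import STANDING_MINUTES, OrthostaticPanel, Vitals
from .pipeline import SubjectRecord, ensure_labels
from .segmentation import RoiSet, SegmentationResult, VolumetricImage

__all__ = [
    "save_nifti",
    "load_image",
    "load_rois",
    "records_to_frame",
    "frame_to_records",
    "write_cohort",
    "read_cohort",
    "classified_frame",
    "segmentation_frame",
]

COHORT_COLUMNS = [
    "subject_id",
    "diagnosis",
    "true_subgroup",
    "age",
    "disease_duration",
    "rbdsq_group",
    "lc_volume_mm3",
    "snc_volume_mm3",
    "supine_sbp",
    "supine_dbp",
    "supine_hr",
    "sbp_1",
    "sbp_3",
    "sbp_5",
    "dbp_1",
    "dbp_3",
    "dbp_5",
    "hr_1",
    "hr_3",
    "hr_5",
    "scanner_protocol",
    "censor_flags",
]


# ---------------------------------------------------------------------------
# NIfTI


def save_nifti(
    grid: np.ndarray, voxel_dims_mm: Sequence[float], path: str | Path
) -> None:
    """Write one 3-D grid with the voxel dimensions on the affine/zooms."""
    affine = np.diag([*voxel_dims_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)
    img.header.set_zooms(tuple(float(d) for d in voxel_dims_mm))
    nib.save(img, str(path))


def _load_grid(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata(), dtype=float), zooms


def load_image(paths: Sequence[str | Path]) -> VolumetricImage:
    """Load one or more measurement files into a single VolumetricImage.

    All files must agree on grid shape and voxel dimensions.
    """
    if not paths:
        raise ValueError("at least one image path is required")
    grids, dims = [], None
    for p in paths:
        g, z = _load_grid(p)
        if dims is None:
            dims = z
        elif not np.allclose(z, dims):
            raise ValueError(f"voxel dimensions differ across measurements: {z} vs {dims}")
        if grids and g.shape != grids[0].shape:
            raise ValueError(
                f"grid shapes differ across measurements: {g.shape} vs {grids[0].shape}"
            )
        grids.append(g)
    return VolumetricImage(np.stack(grids), dims)  # type: ignore[arg-type]


def load_rois(
    ref_left: str | Path,
    ref_right: str | Path,
    lc_mask: str | Path,
    snc_mask: str | Path,
    grid_shape: Optional[tuple[int, int, int]] = None,
) -> RoiSet:
    """Load the four mask files; shape mismatches are hard errors."""
    arrays = {}
    for name, p in (
        ("reference_left", ref_left),
        ("reference_right", ref_right),
        ("lc_mask", lc_mask),
        ("snc_mask", snc_mask),
    ):
        g, _ = _load_grid(p)
        if grid_shape is not None and g.shape != tuple(grid_shape):
            raise ValueError(f"{name} shape {g.shape} does not match image {grid_shape}")
        arrays[name] = g
    return RoiSet(
        reference_left=arrays["reference_left"] > 0.5,
        reference_right=arrays["reference_right"] > 0.5,
        lc_mask=arrays["lc_mask"],
        snc_mask=arrays["snc_mask"],
    )


# ---------------------------------------------------------------------------
# Cohort tables


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "subject_id": r.subject_id,
            "diagnosis": r.diagnosis,
            "true_subgroup": r.true_subgroup,
            "age": r.age,
            "disease_duration": r.disease_duration,
            "rbdsq_group": r.rbdsq_group,
            "lc_volume_mm3": r.lc_volume_mm3,
            "snc_volume_mm3": r.snc_volume_mm3,
            "scanner_protocol": r.scanner_protocol,
            "censor_flags": ";".join(sorted(r.censor_flags)),
        }
        if r.panel is not None:
            row.update(
                supine_sbp=r.panel.supine.sbp,
                supine_dbp=r.panel.supine.dbp,
                supine_hr=r.panel.supine.hr,
            )
            for t in STANDING_MINUTES:
                v = r.panel.standing[t]
                row[f"sbp_{t}"] = v.sbp if v else np.nan
                row[f"dbp_{t}"] = v.dbp if v else np.nan
                row[f"hr_{t}"] = v.hr if v else np.nan
        return_cols = COHORT_COLUMNS
        rows.append({c: row.get(c, np.nan) for c in return_cols})
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def _cell(row: pd.Series, name: str) -> Optional[float]:
    if name not in row or row[name] is None:
        return None
    val = row[name]
    try:
        val = float(val)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(val) else val


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    records = []
    for _, row in frame.iterrows():
        sup = (_cell(row, "supine_sbp"), _cell(row, "supine_dbp"), _cell(row, "supine_hr"))
        panel = None
        if all(v is not None for v in sup):
            standing: dict[int, Optional[Vitals]] = {}
            for t in STANDING_MINUTES:
                vals = (_cell(row, f"sbp_{t}"), _cell(row, f"dbp_{t}"), _cell(row, f"hr_{t}"))
                standing[t] = Vitals(*vals) if all(v is not None for v in vals) else None
            panel = OrthostaticPanel(supine=Vitals(*sup), standing=standing)
        flags = row.get("censor_flags", "")
        flags = frozenset(str(flags).split(";")) - {"", "nan"} if pd.notna(flags) else frozenset()
        true_sub = row.get("true_subgroup")
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                diagnosis=str(row["diagnosis"]),
                # volume columns may be absent when segmentation runs later
                lc_volume_mm3=_cell(row, "lc_volume_mm3") or 0.0,
                snc_volume_mm3=_cell(row, "snc_volume_mm3") or 0.0,
                panel=panel,
                age=float(row.get("age", np.nan)),
                disease_duration=float(row.get("disease_duration", np.nan)),
                rbdsq_group=str(row.get("rbdsq_group", "low")),
                scanner_protocol=str(row.get("scanner_protocol", "A")),
                censor_flags=flags,
                true_subgroup=None if pd.isna(true_sub) else str(true_sub),
            )
        )
    return records


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    return frame_to_records(pd.read_csv(path))


def classified_frame(
    records: Sequence[SubjectRecord], require_minute3: bool = False
) -> pd.DataFrame:
    """Cohort table with the derived autonomic label columns appended."""
    ensure_labels(records, require_minute3=require_minute3)
    frame = records_to_frame(records)
    extra = []
    for r in records:
        if r.label is None:
            extra.append(dict.fromkeys(
                [
                    "oh_class",
                    "oh_subgroup_positive",
                    "neurogenic_ratio",
                    "supine_htn",
                    "avg_delta_map",
                    "avg_delta_sbp",
                    "avg_delta_hr",
                ],
                np.nan,
            ))
            continue
        lab = r.label
        extra.append(
            {
                "oh_class": lab.oh_class,
                "oh_subgroup_positive": lab.oh_subgroup_positive,
                "neurogenic_ratio": np.nan if lab.hr_sbp_ratio is None else lab.hr_sbp_ratio,
                "supine_htn": lab.supine_htn,
                "avg_delta_map": lab.avg_delta_map,
                "avg_delta_sbp": lab.avg_delta_sbp,
                "avg_delta_hr": lab.avg_delta_hr,
            }
        )
    return pd.concat([frame, pd.DataFrame(extra)], axis=1)


def segmentation_frame(
    subject_id: str, results: Sequence[SegmentationResult]
) -> pd.DataFrame:
    """Tabulate segmentation results for delimited-text output."""
    return pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "target": r.target,
                "reference_mean": r.reference_mean,
                "reference_sd": r.reference_sd,
                "threshold": r.threshold_intensity,
                "voxel_count": r.voxel_count,
                "volume_mm3": r.volume_mm3,
            }
            for r in results
        ]
    )
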