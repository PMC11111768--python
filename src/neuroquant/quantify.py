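"""Label maps to volumetric report, with head-size normalisation.

Raw region volume is voxel count times voxel volume (reported in mL).  The
head-size-normalised volume multiplies the raw volume by |det| of the
subject-to-template affine estimated during preprocessing: a subject whose
head is uniformly larger than the template has det < 1, so normalised
volumes are comparable across head sizes (invariant under global scaling).
The absolute value is used so that orientation flips cannot negate a volume.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import LabelMap
from .preprocess import AffineTransform

logger = logging.getLogger("neuroquant")


def region_volume(labels: LabelMap, code: int) -> float:
    """Volume in mL of all voxels carrying ``code`` (1 mL = 1000 mm^3)."""
    if code not in labels.schema.codes:
        raise KeyError(f"code {code} not in schema")
    n = int((labels.labels == code).sum())
    if n == 0:
        logger.warning("region %s (%d) empty", labels.schema.name_of(code), code)
    return n * labels.voxel_volume_mm3 / 1000.0


def head_size_normalize(raw_volume_ml: float, transform: AffineTransform) -> float:
    """raw * |det(subject -> template affine)|."""
    det = transform.determinant
    if det == 0:
        raise ValueError("zero determinant")
    if det < 0:
        logger.info("mirrored transform (det < 0): using |det|")
    return raw_volume_ml * abs(det)


def quantify_report(
    tissue: LabelMap,
    structural: LabelMap,
    transform: AffineTransform | None = None,
    subject_id: str = "subject",
) -> pd.DataFrame:
    """One row per schema region per task, in schema order.

    Columns: subject, task, region, code, voxels, raw_mL, normalized_mL, det.
    Deterministic: re-running on the same inputs yields identical bytes.
    """
    if tissue.shape != structural.shape or not np.allclose(
        tissue.affine, structural.affine, atol=1e-5
    ):
        raise ValueError("tissue and structural maps must share a grid")
    if transform is None:
        transform = AffineTransform(matrix=np.eye(4), provenance="given")
    det = transform.determinant
    rows = []
    for task, lm in (("tissue", tissue), ("structural", structural)):
        counts = np.bincount(lm.labels.ravel(), minlength=lm.schema.n_classes)
        for entry in lm.schema.entries:
            raw = counts[entry.code] * lm.voxel_volume_mm3 / 1000.0
            rows.append(
                {
                    "subject": subject_id,
                    "task": task,
                    "region": entry.name,
                    "code": entry.code,
                    "voxels": int(counts[entry.code]),
                    "raw_mL": round(raw, 3),
                    "normalized_mL": round(raw * abs(det), 3),
                    "det": det,
                }
            )
    return pd.DataFrame(rows)
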