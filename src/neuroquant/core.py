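"""Domain types and NIfTI-1 I/O shared by every pipeline stage.

The unit of image exchange is the :class:`Volume`: a 3-D scalar field plus a
4x4 voxel-to-world affine (RAS millimetres, 0-based voxel indices).  Integer
segmentations travel as :class:`LabelMap` objects that share a Volume's grid
and carry a :class:`LabelSchema` describing the label coding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

logger = logging.getLogger("neuroquant")

Laterality = Literal["left", "right", "midline", "n/a"]


@dataclass(frozen=True)
class SchemaEntry:
    code: int
    name: str
    laterality: Laterality = "n/a"


@dataclass(frozen=True)
class LabelSchema:
    """Ordered label coding for one segmentation task.

    Codes must be unique and contiguous from 0; background is always code 0.
    """

    task: Literal["tissue", "structural"]
    entries: tuple[SchemaEntry, ...]

    def __post_init__(self) -> None:
        codes = [e.code for e in self.entries]
        if codes != list(range(len(codes))):
            raise ValueError("schema codes must be contiguous from 0")
        if self.entries[0].name != "background":
            raise ValueError("code 0 must be background")

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    @property
    def codes(self) -> tuple[int, ...]:
        return tuple(e.code for e in self.entries)

    def name_of(self, code: int) -> str:
        return self.entries[code].name

    def code_of(self, name: str) -> int:
        for e in self.entries:
            if e.name == name:
                return e.code
        raise KeyError(name)


def tissue_schema() -> LabelSchema:
    """Four-class tissue coding: background, WM, GM, CSF."""
    return LabelSchema(
        task="tissue",
        entries=(
            SchemaEntry(0, "background"),
            SchemaEntry(1, "WM"),
            SchemaEntry(2, "GM"),
            SchemaEntry(3, "CSF"),
        ),
    )


_BILATERAL = (
    "white_matter",
    "cortical_gray_matter",
    "lateral_ventricle",
    "cerebellum_gray_matter",
    "cerebellum_white_matter",
    "caudate",
    "hippocampus",
    "globus_pallidus",
    "putamen",
)
_MIDLINE = ("brainstem_upper", "brainstem_lower", "corpus_callosum", "thalamus_midline")


def structural_schema() -> LabelSchema:
    """23-class structural coding: background + 22 structures.

    Nine bilateral pairs (18 codes) plus four midline structures.  The set is
    configurable elsewhere; this default matches the bilateral regions that a
    volumetric report typically carries (WM, cortical GM, lateral ventricles,
    cerebellar GM/WM, caudate, hippocampus, globus pallidus, putamen).
    """
    entries = [SchemaEntry(0, "background")]
    code = 1
    for name in _BILATERAL:
        for side in ("left", "right"):
            entries.append(SchemaEntry(code, f"{name}_{side[0].upper()}", side))
            code += 1
    for name in _MIDLINE:
        entries.append(SchemaEntry(code, name, "midline"))
        code += 1
    return LabelSchema(task="structural", entries=tuple(entries))


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("singular affine")
    return affine


@dataclass
class Volume:
    """3-D scalar field with voxel-to-world affine (RAS mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("expected 3-D volume")
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm along each axis, derived from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_grid(self, other: "Volume | LabelMap", atol: float = 1e-5) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


@dataclass
class LabelMap:
    """Integer-coded segmentation sharing a Volume's grid."""

    labels: np.ndarray
    schema: LabelSchema
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("expected 3-D label map")
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.allclose(self.labels, np.round(self.labels)):
                raise ValueError("label map must be integer valued")
            self.labels = np.round(self.labels).astype(np.int16)
        self.affine = _check_affine(self.affine)
        present = np.unique(self.labels)
        valid = set(self.schema.codes)
        bad = [int(c) for c in present if int(c) not in valid]
        if bad:
            raise ValueError(f"labels {bad} not in schema")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code


# ---------------------------------------------------------------------------
# NIfTI-1 I/O


def _affine_from_header(img: nib.Nifti1Image) -> np.ndarray:
    """qform preferred over sform when both are set (deterministic parsing)."""
    hdr = img.header
    qcode = int(hdr["qform_code"])
    scode = int(hdr["sform_code"])
    if qcode > 0 and scode > 0:
        q, s = img.get_qform(), img.get_sform()
        if not np.allclose(q, s, atol=1e-4):
            logger.warning("qform and sform disagree; using qform")
        return q
    if qcode > 0:
        return img.get_qform()
    if scode > 0:
        return img.get_sform()
    return img.affine


def load_volume(path: str | Path) -> Volume:
    """Read a 3-D NIfTI-1 file as a float Volume.

    The affine comes from the header with qform preferred over sform when the
    two disagree.  Raises on missing files, non-3-D images and singular
    affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D volume, got shape {img.shape}")
    affine = _check_affine(_affine_from_header(img))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    return Volume(data=data, affine=affine)


def load_labelmap(path: str | Path, schema: LabelSchema) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"expected 3-D label map, got shape {img.shape}")
    affine = _check_affine(_affine_from_header(img))
    labels = np.asanyarray(img.dataobj)
    return LabelMap(labels=labels, schema=schema, affine=affine)


def save_volume(vol: Volume | LabelMap, path: str | Path) -> None:
    """Write a Volume (float32) or LabelMap (smallest sufficient int) to NIfTI-1."""
    path = Path(path)
    if path.exists():
        logger.info("overwriting %s", path)
    if isinstance(vol, LabelMap):
        data = vol.labels.astype(np.min_scalar_type(max(1, int(vol.labels.max()))))
        if data.dtype == np.uint8 and vol.labels.max() > 255:  # pragma: no cover
            data = vol.labels.astype(np.int16)
        affine = vol.affine
    else:
        data = vol.data.astype(np.float32)
        affine = vol.affine
    img = nib.Nifti1Image(data, affine)
    img.set_qform(affine, code=1)
    img.set_sform(affine, code=1)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling


def resample_to_grid(
    vol: Volume | LabelMap,
    target_shape: Sequence[int],
    target_affine: np.ndarray,
    transform: np.ndarray | None = None,
    interpolation: Literal["linear", "nearest"] | None = None,
) -> Volume | LabelMap:
    """Resample onto a target grid through a world-to-world affine.

    ``transform`` maps moving-world coordinates to target-world coordinates
    (identity when omitted).  Intensity volumes use trilinear interpolation,
    label maps nearest-neighbour; passing ``interpolation='linear'`` for a
    LabelMap is rejected.
    """
    target_affine = _check_affine(target_affine)
    if transform is None:
        transform = np.eye(4)
    transform = np.asarray(transform, dtype=float)
    if abs(np.linalg.det(transform[:3, :3])) < 1e-12:
        raise ValueError("non-invertible transform")

    is_labels = isinstance(vol, LabelMap)
    if interpolation is None:
        interpolation = "nearest" if is_labels else "linear"
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if is_labels and interpolation == "linear":
        raise ValueError("label maps must use nearest interpolation")

    src_affine = vol.affine
    # output voxel j -> target world -> moving world -> moving voxel i
    M = np.linalg.inv(src_affine) @ np.linalg.inv(transform) @ target_affine
    data = vol.labels if is_labels else vol.data
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        data.astype(np.float32) if not is_labels else data,
        M[:3, :3],
        offset=M[:3, 3],
        output_shape=tuple(int(s) for s in target_shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if is_labels:
        return LabelMap(labels=out.astype(vol.labels.dtype), schema=vol.schema,
                        affine=target_affine.copy())
    return Volume(data=out, affine=target_affine.copy())


def default_template_grid(side: int = 96, spacing_mm: float = 1.0) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid of the bundled phantom template: ``side``^3 voxels, isotropic,
    centred on the world origin (stands in for an external atlas grid)."""
    shape = (side, side, side)
    affine = np.diag([spacing_mm, spacing_mm, spacing_mm, 1.0])
    affine[:3, 3] = -spacing_mm * (side - 1) / 2.0
    return shape, affine
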