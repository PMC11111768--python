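"""Synthetic T1-weighted head phantoms with ground-truth labels.

The generator renders nested ellipsoidal tissue shells (outer CSF, a gray
matter shell, a white matter core) plus a configurable set of ellipsoidal
substructures, each carrying its own structural code and the tissue class it
belongs to.  Intensities follow the adult T1 ordering (WM bright, GM
intermediate, CSF dark), modulated by a smooth multiplicative bias field and
additive Gaussian noise; a pediatric-like mode inverts the WM/GM contrast.
Repeat-scan pairs re-render the identical anatomy after a small rigid
re-positioning with fresh noise and bias, and two-group cohorts scale one
structure's volume by a stated factor so diagnostic statistics can be
exercised end to end.

Everything is deterministic given the spec seed, and every ground-truth
region volume is known analytically (4/3*pi*abc per ellipsoid) so that
voxel-count volumetry can be checked against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import (
    LabelMap,
    LabelSchema,
    Volume,
    default_template_grid,
    structural_schema,
    tissue_schema,
)

TISSUE_CODE = {"WM": 1, "GM": 2, "CSF": 3}

# Default intensity means on an arbitrary [0, 1] scale (adult T1 ordering).
ADULT_MEANS = {"background": 0.02, "CSF": 0.2, "GM": 0.55, "WM": 0.75}
INVERTED_MEANS = {"background": 0.02, "CSF": 0.2, "GM": 0.6, "WM": 0.4}


@dataclass(frozen=True)
class StructureSpec:
    """One ellipsoidal substructure: position/size in anatomy mm coordinates."""

    name: str
    tissue: Literal["WM", "GM", "CSF"]
    center_mm: tuple[float, float, float]
    semi_axes_mm: tuple[float, float, float]
    laterality: Literal["left", "right", "midline"] = "midline"

    def __post_init__(self) -> None:
        if min(self.semi_axes_mm) <= 0:
            raise ValueError("semi-axes must be positive")

    @property
    def volume_mm3(self) -> float:
        a, b, c = self.semi_axes_mm
        return 4.0 / 3.0 * np.pi * a * b * c

    def mirrored(self, name: str) -> "StructureSpec":
        cx, cy, cz = self.center_mm
        return replace(self, name=name, center_mm=(-cx, cy, cz), laterality="right")


def _bilateral(name: str, tissue: str, center: tuple, axes: tuple) -> list[StructureSpec]:
    left = StructureSpec(f"{name}_L", tissue, center, axes, "left")  # type: ignore[arg-type]
    return [left, left.mirrored(f"{name}_R")]


def default_structures(scale: float = 1.0) -> tuple[StructureSpec, ...]:
    """Nine bilateral pairs + four midline structures (22 foreground codes).

    Placed to be pairwise disjoint and inside the gray-matter surface of the
    default head; ``scale`` shrinks the whole layout for small grids.
    """
    s = scale
    out: list[StructureSpec] = []
    out += _bilateral("white_matter", "WM", (-14 * s, 14 * s, 2 * s), (5 * s, 8 * s, 6 * s))
    out += _bilateral("cortical_gray_matter", "GM", (-13 * s, -14 * s, 9 * s), (5 * s, 7 * s, 6 * s))
    out += _bilateral("lateral_ventricle", "CSF", (-4.6 * s, 4.3 * s, 8.2 * s), (3 * s, 8 * s, 3 * s))
    out += _bilateral("cerebellum_gray_matter", "GM", (-9 * s, -18 * s, -10 * s), (5 * s, 4.5 * s, 4 * s))
    out += _bilateral("cerebellum_white_matter", "WM", (-5 * s, -12 * s, -15 * s), (3 * s, 3.5 * s, 3 * s))
    out += _bilateral("caudate", "GM", (-5 * s, 13 * s, 0.0), (2.5 * s, 5 * s, 2.5 * s))
    out += _bilateral("hippocampus", "GM", (-14 * s, -10 * s, -6 * s), (6 * s, 4 * s, 4 * s))
    out += _bilateral("globus_pallidus", "GM", (-9 * s, 0.0, 0.0), (2.8 * s, 2.8 * s, 2.8 * s))
    out += _bilateral("putamen", "GM", (-15 * s, 0.0, 0.0), (3 * s, 4.5 * s, 3.5 * s))
    out.append(StructureSpec("brainstem_upper", "WM", (0.0, -6 * s, -11 * s), (3.5 * s, 3.5 * s, 3 * s)))
    out.append(StructureSpec("brainstem_lower", "WM", (0.0, -6 * s, -17.5 * s), (3 * s, 3 * s, 3 * s)))
    out.append(StructureSpec("corpus_callosum", "WM", (0.0, 6 * s, 14 * s), (2 * s, 7 * s, 2.5 * s)))
    out.append(StructureSpec("thalamus_midline", "GM", (0.0, -3 * s, 1 * s), (4 * s, 4 * s, 3 * s)))
    return tuple(out)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic head; the seed fixes all randomness."""

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.0
    head_semi_axes_mm: tuple[float, float, float] = (30.0, 36.0, 28.0)
    gm_shell_mm: float = 4.0
    csf_shell_mm: float = 3.0
    tissue_means: dict | None = None
    noise_sd: float = 0.03
    bias_order: int = 2
    bias_amplitude: float = 0.1
    structures: tuple[StructureSpec, ...] = field(default_factory=default_structures)
    contrast: Literal["adult", "inverted"] = "adult"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bias_order > 2:
            raise ValueError("bias order must be <= 2")
        if not (0 <= self.bias_amplitude <= 0.5):
            raise ValueError("bias amplitude out of range")

    @property
    def means(self) -> dict:
        if self.tissue_means is not None:
            return self.tissue_means
        return ADULT_MEANS if self.contrast == "adult" else INVERTED_MEANS

    @classmethod
    def small(cls, side: int = 64, seed: int = 0, **kw) -> "PhantomSpec":
        """Desk-scale phantom: same anatomy scaled to fit a ``side``^3 grid."""
        s = side / 96.0
        return cls(
            shape=(side, side, side),
            head_semi_axes_mm=(30.0 * s, 36.0 * s, 28.0 * s),
            gm_shell_mm=4.0 * s,
            csf_shell_mm=3.0 * s,
            structures=default_structures(scale=s),
            seed=seed,
            **kw,
        )


def _grid_world_coords(shape, spacing) -> np.ndarray:
    _, affine = default_template_grid(shape[0], spacing)
    idx = np.indices(shape, dtype=np.float32)
    coords = np.einsum(
        "ij,j...->i...", affine[:3, :3].astype(np.float32), idx
    ) + affine[:3, 3].astype(np.float32)[:, None, None, None]
    return coords, affine


def _ellipsoid_mask(coords, center, semi_axes, scale=1.0) -> np.ndarray:
    d = np.zeros(coords.shape[1:], dtype=np.float32)
    for ax in range(3):
        d += ((coords[ax] - center[ax]) / (semi_axes[ax] * scale)) ** 2
    return d <= 1.0


_SUPERSAMPLE = 4  # subvoxel grid per axis for substructure voxelisation


def _ellipsoid_mask_ss(coords, center, semi_axes, offset_vectors, scale=1.0) -> np.ndarray:
    """Supersampled ellipsoid mask: voxel included when at least half of a
    4x4x4 subvoxel point grid falls inside.  Cuts the systematic surplus of
    the centre-point rule on small structures (voxel counts then track the
    analytic 4/3*pi*abc volume to a few percent at 1 mm)."""
    q = np.zeros(coords.shape[1:], dtype=np.float32)
    for ax in range(3):
        q += ((coords[ax] - center[ax]) / (semi_axes[ax] * scale)) ** 2
    cand = q <= 2.5  # generous halo around the boundary
    idx = np.nonzero(cand)
    pts = np.stack([coords[ax][idx] for ax in range(3)], axis=0)
    n_inside = np.zeros(pts.shape[1], dtype=np.int32)
    for off in offset_vectors:
        qq = np.zeros(pts.shape[1], dtype=np.float32)
        for ax in range(3):
            qq += ((pts[ax] + off[ax] - center[ax]) / (semi_axes[ax] * scale)) ** 2
        n_inside += qq <= 1.0
    mask = np.zeros(coords.shape[1:], dtype=bool)
    mask[idx] = n_inside * 2 >= len(offset_vectors)
    return mask


def _subvoxel_offsets(linear: np.ndarray) -> np.ndarray:
    n = _SUPERSAMPLE
    f = (np.arange(n) + 0.5) / n - 0.5
    grid = np.stack(np.meshgrid(f, f, f, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid @ linear.T


def _bias_field(coords, order, amplitude, rng) -> np.ndarray:
    if amplitude == 0 or order == 0:
        return np.ones(coords.shape[1:], dtype=np.float32)
    # random polynomial in normalised coords, rescaled to |log bias| <= log1p(amp)
    span = max(float(np.abs(c).max()) for c in coords)
    u = [c / span for c in coords]
    terms = list(u)
    if order >= 2:
        terms += [u[i] * u[j] for i in range(3) for j in range(i, 3)]
    coeffs = rng.standard_normal(len(terms))
    p = sum(w * t for w, t in zip(coeffs, terms))
    p -= p.mean()
    peak = float(np.abs(p).max())
    if peak > 0:
        p *= np.log1p(amplitude) / peak
    return np.exp(p).astype(np.float32)


def render_phantom(
    spec: PhantomSpec,
    anatomy_transform: np.ndarray | None = None,
    structure_scales: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Volume, LabelMap, LabelMap]:
    """Render the phantom; optionally move/scale the anatomy first.

    ``anatomy_transform`` is a world-to-world affine applied to the anatomy
    (a point u of the canonical anatomy appears at world x = T u), so rigid
    re-positioning and global head scaling re-use one code path.
    ``structure_scales`` maps structure name -> volumetric factor (semi-axes
    are scaled by its cube root).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    coords, affine = _grid_world_coords(spec.shape, spec.spacing_mm)
    offset_linear = affine[:3, :3].copy()
    if anatomy_transform is not None:
        T = np.linalg.inv(np.asarray(anatomy_transform, dtype=float))
        coords = np.einsum(
            "ij,j...->i...", T[:3, :3].astype(np.float32), coords
        ) + T[:3, 3].astype(np.float32)[:, None, None, None]
        offset_linear = T[:3, :3] @ offset_linear
    offset_vectors = _subvoxel_offsets(offset_linear)

    hx, hy, hz = spec.head_semi_axes_mm
    csf = _ellipsoid_mask(coords, (0, 0, 0), (hx, hy, hz))
    gm = _ellipsoid_mask(
        coords, (0, 0, 0), (hx - spec.csf_shell_mm, hy - spec.csf_shell_mm, hz - spec.csf_shell_mm)
    )
    wm = _ellipsoid_mask(
        coords,
        (0, 0, 0),
        (
            hx - spec.csf_shell_mm - spec.gm_shell_mm,
            hy - spec.csf_shell_mm - spec.gm_shell_mm,
            hz - spec.csf_shell_mm - spec.gm_shell_mm,
        ),
    )
    tissue = np.zeros(spec.shape, dtype=np.int16)
    tissue[csf] = TISSUE_CODE["CSF"]
    tissue[gm] = TISSUE_CODE["GM"]
    tissue[wm] = TISSUE_CODE["WM"]

    schema = structural_schema_for(spec.structures)
    struct = np.zeros(spec.shape, dtype=np.int16)
    gm_surface = (
        hx - spec.csf_shell_mm,
        hy - spec.csf_shell_mm,
        hz - spec.csf_shell_mm,
    )
    for code, st in enumerate(spec.structures, start=1):
        vol_scale = 1.0
        if structure_scales and st.name in structure_scales:
            vol_scale = structure_scales[st.name] ** (1.0 / 3.0)
        m = _ellipsoid_mask_ss(
            coords, st.center_mm, st.semi_axes_mm, offset_vectors, scale=vol_scale
        )
        if not m.any():
            raise ValueError(f"structure {st.name} renders to zero voxels")
        inside = _ellipsoid_mask(coords, (0, 0, 0), gm_surface)
        if (m & ~inside).any():
            raise ValueError(f"structure {st.name} outside head")
        if (struct[m] != 0).any():
            hit = int(np.bincount(struct[m])[1:].argmax()) + 1
            raise ValueError(
                f"structure {st.name} overlaps {schema.name_of(hit)}"
            )
        struct[m] = code
        tissue[m] = TISSUE_CODE[st.tissue]

    means = spec.means
    lut = np.array(
        [means["background"], means["WM"], means["GM"], means["CSF"]], dtype=np.float32
    )
    intensity = lut[tissue]
    intensity *= _bias_field(coords, spec.bias_order, spec.bias_amplitude, rng)
    if spec.noise_sd > 0:
        intensity += rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)

    vol = Volume(data=intensity, affine=affine)
    return (
        vol,
        LabelMap(labels=tissue, schema=tissue_schema(), affine=affine),
        LabelMap(labels=struct, schema=schema, affine=affine),
    )


def structural_schema_for(structures: Sequence[StructureSpec]) -> LabelSchema:
    from .core import SchemaEntry

    entries = [SchemaEntry(0, "background")]
    entries += [
        SchemaEntry(i, st.name, st.laterality) for i, st in enumerate(structures, start=1)
    ]
    return LabelSchema(task="structural", entries=tuple(entries))


def make_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMap, LabelMap]:
    """Deterministic phantom for a spec (same spec + seed -> identical voxels)."""
    return render_phantom(spec)


def make_template(side: int = 96) -> Volume:
    """Noise- and bias-free phantom used as the bundled registration template."""
    spec = PhantomSpec.small(side) if side != 96 else PhantomSpec()
    spec = replace(spec, noise_sd=0.0, bias_amplitude=0.0)
    vol, _, _ = render_phantom(spec)
    return vol


def _rigid_transform(rng, max_trans_mm: float, max_rot_deg: float) -> np.ndarray:
    t = rng.uniform(-max_trans_mm, max_trans_mm, size=3)
    ang = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, size=3))
    cx, sx = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cz, sz = np.cos(ang[2]), np.sin(ang[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    T = np.eye(4)
    T[:3, :3] = Rz @ Ry @ Rx
    T[:3, 3] = t
    return T


def make_retest_pair(
    spec: PhantomSpec,
    max_trans_mm: float = 2.0,
    max_rot_deg: float = 2.0,
    seed: int | None = None,
):
    """Test-retest pair: identical anatomy, re-positioned, fresh noise and bias.

    Returns ``(vol1, tissue1, struct1, vol2, tissue2, struct2, transform)``
    where ``transform`` is the applied anatomy world-to-world rigid motion.
    True (pre-voxelisation) region volumes of the two scans are equal by
    construction.
    """
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    v1, t1, s1 = render_phantom(spec, rng=rng)
    T = _rigid_transform(rng, max_trans_mm, max_rot_deg)
    # reject motions that push the head outside the grid
    half_extent = min(spec.shape) * spec.spacing_mm / 2.0
    if max(spec.head_semi_axes_mm) + max_trans_mm + 2 > half_extent:
        raise ValueError("motion may push head outside grid")
    v2, t2, s2 = render_phantom(spec, anatomy_transform=T, rng=rng)
    return v1, t1, s1, v2, t2, s2, T


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort with one volumetrically affected structure."""

    n_per_group: int = 50
    affected_structure: str = "hippocampus_L"
    scale_factor: float = 0.9
    volume_cv: float = 0.05
    head_scale_cv: float = 0.03
    phantom: PhantomSpec = field(default_factory=lambda: PhantomSpec.small(64))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale factor must be > 0")
        if self.n_per_group < 2:
            raise ValueError("need n >= 2 per group")


def scale_factor_for_cohens_d(d: float, cv: float) -> float:
    """Volumetric group-B factor giving Cohen's d between group volume means.

    Solves d = (1 - f) / (cv * sqrt((1 + f^2)/2)) for f in (0, 1]; the pooled
    SD accounts for group B's proportionally smaller spread.
    """
    if d == 0:
        return 1.0
    return brentq(
        lambda f: (1 - f) / (cv * np.sqrt((1 + f**2) / 2)) - d, 1e-3, 1.0
    )


@dataclass(frozen=True)
class CohortSubject:
    subject_id: str
    group: Literal["A", "B"]
    head_scale: float
    volume: Volume
    tissue: LabelMap
    structural: LabelMap
    true_volumes_mm3: dict


def make_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Render a two-group cohort; group B's affected structure is scaled.

    Every subject carries a global head-scale jitter (exercising head-size
    normalization) and independent per-structure volume jitter with the
    stated coefficient of variation.
    """
    names = [st.name for st in spec.phantom.structures]
    if spec.affected_structure not in names:
        raise ValueError(f"unknown structure {spec.affected_structure}")
    rng = np.random.default_rng(spec.seed)
    subjects: list[CohortSubject] = []
    for group in ("A", "B"):
        for i in range(spec.n_per_group):
            head_scale = float(1.0 + spec.head_scale_cv * rng.standard_normal())
            scales = {
                name: max(0.2, 1.0 + spec.volume_cv * rng.standard_normal())
                for name in names
            }
            if group == "B":
                scales[spec.affected_structure] *= spec.scale_factor
            T = np.diag([head_scale, head_scale, head_scale, 1.0])
            sub_seed = int(rng.integers(0, 2**31 - 1))
            sub_rng = np.random.default_rng(sub_seed)
            vol, tis, struct = render_phantom(
                spec.phantom, anatomy_transform=T, structure_scales=scales, rng=sub_rng
            )
            true_vols = {
                st.name: st.volume_mm3 * scales[st.name] * head_scale**3
                for st in spec.phantom.structures
            }
            subjects.append(
                CohortSubject(
                    subject_id=f"{group}{i:03d}",
                    group=group,  # type: ignore[arg-type]
                    head_scale=head_scale,
                    volume=vol,
                    tissue=tis,
                    structural=struct,
                    true_volumes_mm3=true_vols,
                )
            )
    return subjects
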