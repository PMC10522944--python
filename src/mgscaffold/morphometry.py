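"""3D degradation morphometry of segmented scaffolds.

From a 4-label phase map this module computes per-phase material
volumes and the degraded fraction, the scaffold surface area by
marching-cubes triangle summation, and the spatial partition of the
degraded conversion layer into luminal (toward the blood flow), lateral
(circumferential side faces) and abluminal (toward the vessel wall)
compartments. Severely degraded material is excluded from the regional
partition, which analyzes the mildly degraded layer only.

The regional rule: for every degraded voxel, the escape direction is
the vector to its nearest background voxel; comparing that direction
with the outward radial direction from the scaffold axis classifies the
voxel as abluminal (within a cone around +r), luminal (cone around -r)
or lateral (everything else). The default half-angle of 45 degrees
gives the radial and lateral classes equal angular budgets, with the
lateral band counting both side faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

from .volumes import (
    LABEL_BACKGROUND,
    LABEL_DEGRADED,
    LABEL_METAL,
    LABEL_SEVERE,
    LabelVolume,
)

DEFAULT_CONE_HALF_ANGLE_DEG = 45.0
REGIONS = ("luminal", "lateral", "abluminal")


@dataclass
class MorphometryReport:
    """Per-phase volumes (mm^3), degraded fraction, surface area (mm^2)
    and regional partition of the mildly degraded layer."""

    volume_metallic_mm3: float = 0.0
    volume_degraded_mm3: float = 0.0
    volume_severe_mm3: float = 0.0
    fraction_degraded: float = 0.0
    fraction_defined: bool = True
    surface_area_mm2: float | None = None
    regional_volumes_mm3: dict[str, float] = field(default_factory=dict)
    luminal_abluminal_ratio: float | None = None

    @property
    def total_solid_mm3(self) -> float:
        return self.volume_metallic_mm3 + self.volume_degraded_mm3 + self.volume_severe_mm3

    def as_dict(self) -> dict:
        d = {
            "volume_metallic_mm3": self.volume_metallic_mm3,
            "volume_degraded_mm3": self.volume_degraded_mm3,
            "volume_severe_mm3": self.volume_severe_mm3,
            "fraction_degraded": self.fraction_degraded,
            "fraction_defined": self.fraction_defined,
            "surface_area_mm2": self.surface_area_mm2,
            "luminal_abluminal_ratio": self.luminal_abluminal_ratio,
        }
        for r in REGIONS:
            d[f"volume_{r}_mm3"] = self.regional_volumes_mm3.get(r)
        return d


@dataclass
class ScaffoldAxis:
    """A line (point + unit direction) approximating the scaffold axis."""

    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("axis direction must be non-zero")
        self.direction = self.direction / n


# ---------------------------------------------------------------------------


def phase_volumes(labels: LabelVolume) -> MorphometryReport:
    """Exact per-phase volumes by voxel counting.

    The degraded fraction is (V2 + V3) / (V1 + V2 + V3), i.e. degraded
    material over the scaffold's total solid volume; on an empty volume
    it is reported as 0 with ``fraction_defined`` False.
    """
    vv = labels.voxel_volume_mm3()
    counts = np.bincount(labels.labels.ravel(), minlength=4)
    v1, v2, v3 = (float(counts[k] * vv) for k in (LABEL_METAL, LABEL_DEGRADED, LABEL_SEVERE))
    solid = v1 + v2 + v3
    if solid > 0:
        frac, defined = (v2 + v3) / solid, True
    else:
        frac, defined = 0.0, False
    return MorphometryReport(
        volume_metallic_mm3=v1,
        volume_degraded_mm3=v2,
        volume_severe_mm3=v3,
        fraction_degraded=frac,
        fraction_defined=defined,
    )


def _mask_mesh(labels: LabelVolume, phase_set) -> tuple[np.ndarray, np.ndarray]:
    mask = np.isin(labels.labels, list(phase_set))
    if not mask.any():
        raise ValueError("empty mask for the requested phases")
    padded = np.pad(mask, 1).astype(np.float32)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5)
    return verts - 1.0, faces


def surface_area(labels: LabelVolume, phase_set=(1, 2, 3)) -> float:
    """Surface area (mm^2) of the union of the given phases.

    Marching cubes at iso-level 0.5 on the binary mask (padded so outer
    boundaries close), summing triangle areas; no smoothing, so the
    measure is a pure function of the voxel mask.
    """
    mask = np.isin(labels.labels, list(phase_set))
    if not mask.any():
        return 0.0
    verts, faces = _mask_mesh(labels, phase_set)
    area_vox = measure.mesh_surface_area(verts, faces)
    return float(area_vox * (labels.voxel_size_um * 1e-3) ** 2)


def estimate_axis(labels: LabelVolume, min_voxels: int = 100) -> ScaffoldAxis:
    """Principal direction of the non-background voxel cloud (PCA)."""
    coords = np.argwhere(labels.labels != LABEL_BACKGROUND)
    if coords.shape[0] < min_voxels:
        raise ValueError(
            f"need at least {min_voxels} non-background voxels, got {coords.shape[0]}"
        )
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    return ScaffoldAxis(point=centroid, direction=direction)


def partition_strut_regions(
    labels: LabelVolume,
    axis: ScaffoldAxis | None = None,
    cone_half_angle_deg: float = DEFAULT_CONE_HALF_ANGLE_DEG,
) -> dict[str, float]:
    """Partition the mildly degraded layer (label 2) into luminal,
    lateral and abluminal volumes (mm^3).

    Severely degraded voxels (label 3) are excluded entirely. The sum of
    the three regional volumes equals the total label-2 volume.
    """
    lab = labels.labels
    degraded = lab == LABEL_DEGRADED
    if not degraded.any():
        raise ValueError("no degraded (label 2) voxels to partition")
    if axis is None:
        axis = estimate_axis(labels)

    # nearest background voxel for every non-background voxel
    _, idx = ndimage.distance_transform_edt(
        lab != LABEL_BACKGROUND, return_indices=True
    )
    pos = np.argwhere(degraded)
    nearest = idx[:, degraded].T.astype(float)
    escape = nearest - pos
    en = np.linalg.norm(escape, axis=1)
    valid = en > 0
    escape[valid] /= en[valid, None]

    d = axis.direction
    rel = pos - axis.point
    radial = rel - (rel @ d)[:, None] * d[None]
    rn = np.linalg.norm(radial, axis=1)
    on_axis = rn == 0
    radial[~on_axis] /= rn[~on_axis, None]

    cos_thr = np.cos(np.deg2rad(cone_half_angle_deg))
    cosang = np.einsum("ij,ij->i", escape, radial)
    abluminal = valid & ~on_axis & (cosang > cos_thr)
    luminal = valid & ~on_axis & (cosang < -cos_thr)
    lateral = ~(abluminal | luminal)

    vv = labels.voxel_volume_mm3()
    return {
        "luminal": float(luminal.sum() * vv),
        "lateral": float(lateral.sum() * vv),
        "abluminal": float(abluminal.sum() * vv),
    }


def luminal_abluminal_ratio(regional_volumes: dict[str, float]) -> float | None:
    """Ratio of luminal to abluminal degraded volume; None if undefined."""
    ab = regional_volumes.get("abluminal", 0.0)
    if ab <= 0:
        return None
    return regional_volumes.get("luminal", 0.0) / ab


def full_report(
    labels: LabelVolume,
    cone_half_angle_deg: float = DEFAULT_CONE_HALF_ANGLE_DEG,
) -> MorphometryReport:
    """Volumes, fraction, surface area and regional partition in one call."""
    report = phase_volumes(labels)
    solid = (LABEL_METAL, LABEL_DEGRADED, LABEL_SEVERE)
    if report.total_solid_mm3 > 0:
        report.surface_area_mm2 = surface_area(labels, solid)
        if (labels.labels == LABEL_DEGRADED).any():
            # the stacking-axis hint, when present, is more robust than
            # PCA for short volumes whose lateral extent rivals their height
            axis = None
            if labels.axis_hint is not None:
                coords = np.argwhere(labels.labels != LABEL_BACKGROUND)
                axis = ScaffoldAxis(
                    point=coords.mean(axis=0), direction=labels.axis_hint
                )
            report.regional_volumes_mm3 = partition_strut_regions(
                labels, axis=axis, cone_half_angle_deg=cone_half_angle_deg
            )
            report.luminal_abluminal_ratio = luminal_abluminal_ratio(
                report.regional_volumes_mm3
            )
    return report


def export_mesh(
    labels: LabelVolume, phase_set=(1, 2, 3), path: str | Path = "scaffold.stl"
):
    """Export the marching-cubes isosurface as binary STL or PLY (mm units)."""
    import trimesh

    verts, faces = _mask_mesh(labels, phase_set)
    mesh = trimesh.Trimesh(
        vertices=verts * labels.voxel_size_um * 1e-3, faces=faces, process=False
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    mesh.export(path)
    return mesh
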