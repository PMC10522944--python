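"""Synthetic scaffold phantoms with ground-truth corrosion labels.

Bioresorbable magnesium scaffolds are laser-cut crown-and-link lattices:
sinusoidal rings ("crowns") on a thin cylindrical shell, connected by
axial bridges ("links"). After weeks in vivo the struts corrode from the
surface inward into a conversion layer (label 2), preferentially at the
highly bent crown apices, while a few randomly located regions degrade
severely (label 3), swelling beyond the original strut envelope and
breaking up with cracks.

This module generates such scaffolds voxel-by-voxel together with exact
ground-truth labels, renders them into noisy, blurred grey-value volumes
emulating reconstructed micro-CT data, and can split a volume into
vertically overlapping sub-scans the way a tall sample is imaged in
several acquisitions. Every stochastic step is driven by the spec's seed
and is bit-reproducible.

Default geometry follows the implanted devices: 15 mm length, 95 or
130 um wall thickness, 110 or 130 um strut width, eight crowns and
twelve links, (3.07 um)^3 voxels. At that voxel size a full scaffold is
~4900 slices of 600+ voxels diameter, so tests and examples use
proportionally scaled-down specs (see :meth:`PhantomSpec.scaled_down`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volumes import (
    LABEL_BACKGROUND,
    LABEL_DEGRADED,
    LABEL_METAL,
    LABEL_SEVERE,
    GreyVolume,
    LabelVolume,
)

# Grey-value means per phase, 16-bit range. Metallic Mg is the brightest
# phase in reconstructed data, the degraded conversion layer slightly
# darker, severely degraded material darker still, soft tissue darkest.
DEFAULT_GREY_MEANS: dict[int, float] = {
    LABEL_BACKGROUND: 12000.0,
    LABEL_SEVERE: 28000.0,
    LABEL_DEGRADED: 40000.0,
    LABEL_METAL: 52000.0,
}


@dataclass
class PhantomSpec:
    """Parametric scaffold + degradation + imaging model.

    Lengths are physical: mm for the device-scale fields, um for strut
    scale fields and the voxel size.
    """

    scaffold_length_mm: float = 15.0
    outer_diameter_mm: float = 1.8
    wall_thickness_um: float = 95.0
    strut_width_um: float = 110.0
    n_crowns: int = 8
    n_links: int = 12
    ring_pitch_um: float = 1500.0
    voxel_size_um: float = 3.07
    slight_degradation_fraction: float = 0.35
    curvature_bias: float = 4.0
    n_severe_blobs: int = 2
    severe_blob_radius_um: float = 60.0
    crack_texture: bool = True
    phase_grey_means: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_GREY_MEANS)
    )
    noise_sd: float = 1200.0
    psf_sigma_um: float = 3.0
    margin_um: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scaffold_length_mm <= 0:
            raise ValueError("scaffold_length_mm must be positive")
        if self.outer_diameter_mm <= 0:
            raise ValueError("outer_diameter_mm must be positive")
        if self.wall_thickness_um >= self.outer_diameter_mm * 1e3 / 2:
            raise ValueError("wall_thickness must be below outer radius")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        for name in ("wall_thickness_um", "strut_width_um"):
            if getattr(self, name) / self.voxel_size_um < 2:
                raise ValueError(
                    f"{name} spans fewer than 2 voxels at "
                    f"{self.voxel_size_um} um: undersampled geometry"
                )
        if not 0.0 <= self.slight_degradation_fraction <= 1.0:
            raise ValueError("slight_degradation_fraction must lie in [0, 1]")
        if self.curvature_bias < 0:
            raise ValueError("curvature_bias must be >= 0")
        if self.n_severe_blobs < 0:
            raise ValueError("n_severe_blobs must be >= 0")
        if self.noise_sd < 0 or self.psf_sigma_um < 0:
            raise ValueError("noise_sd and psf_sigma_um must be >= 0")
        if self.n_crowns < 1 or self.n_links < 0:
            raise ValueError("need at least one crown and n_links >= 0")
        means = [self.phase_grey_means[k] for k in sorted(self.phase_grey_means)]
        if len(set(means)) != len(means):
            raise ValueError("phase grey means must be pairwise distinct")

    def replace(self, **kw) -> "PhantomSpec":
        return dataclasses.replace(self, **kw)

    @classmethod
    def scaled_down(cls, **overrides) -> "PhantomSpec":
        """A geometrically similar spec small enough for quick runs.

        Keeps the true wall thickness and strut width but shortens the
        device, shrinks its diameter and coarsens the grid to 8 um
        voxels, yielding volumes of roughly 100^3 voxels.
        """
        base = dict(
            scaffold_length_mm=0.8,
            outer_diameter_mm=0.62,
            wall_thickness_um=95.0,
            strut_width_um=110.0,
            n_crowns=8,
            n_links=4,
            ring_pitch_um=400.0,
            voxel_size_um=8.0,
            severe_blob_radius_um=60.0,
            margin_um=80.0,
        )
        base.update(overrides)
        return cls(**base)


# ---------------------------------------------------------------------------
# geometry


def _cylinder_coords(spec: PhantomSpec):
    """Voxel-centre coordinate fields (z, r, theta) in um, plus shape."""
    vs = spec.voxel_size_um
    nz = int(round(spec.scaffold_length_mm * 1e3 / vs))
    if nz < 1:
        raise ValueError("scaffold shorter than one voxel")
    margin = spec.margin_um
    lateral_um = spec.outer_diameter_mm * 1e3 + 2 * margin
    nxy = int(np.ceil(lateral_um / vs))
    c = (nxy - 1) / 2.0  # centre in voxel units
    yy, xx = np.meshgrid(np.arange(nxy), np.arange(nxy), indexing="ij")
    dy = (yy - c) * vs
    dx = (xx - c) * vs
    r = np.hypot(dy, dx)
    theta = np.arctan2(dx, dy)  # [-pi, pi), azimuth around axis 0
    z = (np.arange(nz) + 0.5) * vs
    return nz, nxy, z, r, theta


def build_scaffold_geometry(spec: PhantomSpec) -> LabelVolume:
    """Voxelize the crown-and-link lattice; metallic voxels get label 1.

    Rings are sinusoids z(theta) = z_i + A sin(n_crowns * theta) on the
    cylindrical shell, with amplitude A equal to half the ring pitch;
    links are straight axial bridges at evenly spaced azimuths. The
    output is deterministic for a given spec.
    """
    spec.validate()
    nz, nxy, z, r, theta = _cylinder_coords(spec)
    vs = spec.voxel_size_um

    r_out = spec.outer_diameter_mm * 1e3 / 2
    r_in = r_out - spec.wall_thickness_um
    shell = (r >= r_in) & (r <= r_out)  # (nxy, nxy)

    length_um = spec.scaffold_length_mm * 1e3
    n_rings = max(1, int(round(length_um / spec.ring_pitch_um)))
    pitch = length_um / n_rings
    amplitude = pitch / 2.0
    half_w = spec.strut_width_um / 2.0

    ring_profile = amplitude * np.sin(spec.n_crowns * theta)  # (nxy, nxy)
    ring_centers = (np.arange(n_rings) + 0.5) * pitch

    labels = np.zeros((nz, nxy, nxy), dtype=np.uint8)
    # rings: |z - z_i(theta)| <= half strut width, evaluated per slice
    for iz in range(nz):
        dz = np.abs(z[iz] - (ring_centers[:, None, None] + ring_profile[None]))
        in_ring = (dz.min(axis=0) <= half_w) & shell
        labels[iz][in_ring] = LABEL_METAL

    if spec.n_links > 0:
        link_angles = 2 * np.pi * np.arange(spec.n_links) / spec.n_links
        dtheta = np.abs(
            ((theta[None] - link_angles[:, None, None]) + np.pi) % (2 * np.pi) - np.pi
        ).min(axis=0)
        # arc distance on the mid-wall radius
        in_link = (dtheta * (r_in + r_out) / 2 <= half_w) & shell
        labels[:, in_link] = LABEL_METAL

    # reject undersampled output (paranoia beyond the spec check)
    if not labels.any():
        raise ValueError("spec produced an empty scaffold")
    return LabelVolume(labels=labels, voxel_size_um=vs, axis_hint=np.array([1.0, 0, 0]))


# ---------------------------------------------------------------------------
# degradation


def _curvature_field(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    """Normalized magnitude of the ring centreline's axial curvature.

    For z(theta) = A sin(k theta) the curvature is proportional to
    |sin(k theta)|, maximal at crown apices. Links and troughs between
    crowns get low weight.
    """
    return np.abs(np.sin(spec.n_crowns * theta))


def _smooth_shell_noise(
    rng: np.random.Generator, nz: int, ntheta: int, smooth: float = 3.0
) -> np.ndarray:
    """Smooth multiplicative field on the (z, theta) shell surface.

    Periodic in theta; unit median. Controls how deep the conversion
    layer reaches locally, so slight degradation is patchy rather than a
    uniform skin.
    """
    coarse = rng.standard_normal((max(2, nz // 8), 24))
    f = ndimage.zoom(coarse, (nz / coarse.shape[0], ntheta / coarse.shape[1]), order=1)
    f = ndimage.gaussian_filter(f, (smooth, 4 * smooth), mode=("nearest", "wrap"))
    f = f[:nz, :ntheta]
    sd = f.std() or 1.0
    return np.exp(0.8 * f / sd)


def apply_degradation(geometry: LabelVolume, spec: PhantomSpec) -> LabelVolume:
    """Convert metallic voxels into degradation phases.

    Slight degradation (label 2) grows from the strut surface inward:
    a voxel converts when its Euclidean depth below the surface is under
    a local threshold tau * (1 + curvature_bias*|curvature|) * noise,
    where the noise field lives on the (z, theta) shell surface. tau is
    solved by bisection so that the converted fraction of the original
    metallic volume matches ``slight_degradation_fraction``. Because the
    threshold varies only along the shell, the converted set is always a
    surface-inward layer.

    Severe degradation (label 3) is ``n_severe_blobs`` spherical regions
    at random strut locations; each blob swells past the strut envelope
    by dilation and, when ``crack_texture`` is on, is broken by thin
    empty planes.
    """
    labels = geometry.labels
    present = np.unique(labels)
    if np.setdiff1d(present, [LABEL_BACKGROUND, LABEL_METAL]).size:
        raise ValueError("apply_degradation expects labels in {0, 1} only")
    metal = labels == LABEL_METAL
    n_metal = int(metal.sum())
    if n_metal == 0:
        raise ValueError("geometry contains no metallic voxels")

    out = labels.copy()
    vs = geometry.voxel_size_um
    rng = np.random.default_rng([spec.seed, 0x5D])

    if spec.slight_degradation_fraction > 0:
        depth = ndimage.distance_transform_edt(metal)  # voxels below surface
        nz, ny, nx = labels.shape
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        theta = np.arctan2(xx - cx, yy - cy)
        ntheta = 256
        tbin = ((theta + np.pi) / (2 * np.pi) * ntheta).astype(int) % ntheta
        noise = _smooth_shell_noise(rng, nz, ntheta)
        bin_angles = (np.arange(ntheta) + 0.5) / ntheta * 2 * np.pi - np.pi
        curv = _curvature_field(spec, bin_angles)
        site = (1.0 + spec.curvature_bias * curv)[None, :] * noise  # (nz, ntheta)
        zi = np.nonzero(metal)
        s_vox = site[zi[0], tbin[zi[1], zi[2]]]
        d_vox = depth[zi]

        target = spec.slight_degradation_fraction * n_metal
        lo, hi = 0.0, float(d_vox.max() / s_vox.min()) + 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if (d_vox <= mid * s_vox).sum() < target:
                lo = mid
            else:
                hi = mid
        tau = 0.5 * (lo + hi)
        conv = d_vox <= tau * s_vox
        out[zi[0][conv], zi[1][conv], zi[2][conv]] = LABEL_DEGRADED

    if spec.n_severe_blobs > 0:
        strut_idx = np.flatnonzero(labels.reshape(-1) == LABEL_METAL)
        centers = strut_idx[
            rng.choice(strut_idx.size, size=spec.n_severe_blobs, replace=False)
        ]
        rad_vox = spec.severe_blob_radius_um / vs
        dil = max(1, int(round(rad_vox * 0.25)))
        grid = np.indices(labels.shape, sparse=True)
        for flat in centers:
            cz, cy_, cx_ = np.unravel_index(flat, labels.shape)
            d2 = (
                (grid[0] - cz) ** 2 + (grid[1] - cy_) ** 2 + (grid[2] - cx_) ** 2
            )
            sphere = d2 <= rad_vox**2
            core = sphere & (labels == LABEL_METAL)
            if not core.any():
                core = sphere & (out != LABEL_BACKGROUND)
            # swollen degradation products occupy more than the strut did
            blob = ndimage.binary_dilation(core, iterations=dil) & sphere
            out[blob] = LABEL_SEVERE
            if spec.crack_texture:
                normal = rng.standard_normal(3)
                normal /= np.linalg.norm(normal)
                dist = (
                    (grid[0] - cz) * normal[0]
                    + (grid[1] - cy_) * normal[1]
                    + (grid[2] - cx_) * normal[2]
                )
                crack = blob & (np.abs(dist) <= 0.8)
                out[crack] = LABEL_BACKGROUND

    return LabelVolume(
        labels=out, voxel_size_um=vs, axis_hint=geometry.axis_hint
    )


# ---------------------------------------------------------------------------
# rendering and scan splitting


def render_grey(labels: LabelVolume, spec: PhantomSpec) -> GreyVolume:
    """Render a label volume into a 16-bit grey volume.

    Each phase maps to its mean grey value; the image is blurred with an
    isotropic Gaussian point-spread function and seeded Gaussian noise
    is added, then clipped and quantized to uint16.
    """
    img = np.empty(labels.shape, dtype=np.float32)
    for phase, mean in spec.phase_grey_means.items():
        img[labels.labels == phase] = mean
    sigma_vox = spec.psf_sigma_um / labels.voxel_size_um
    if sigma_vox > 0:
        img = ndimage.gaussian_filter(img, sigma_vox)
    if spec.noise_sd > 0:
        rng = np.random.default_rng([spec.seed, 0x6E])
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)
    img = np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return GreyVolume(
        intensities=img,
        voxel_size_um=labels.voxel_size_um,
        metadata={"source": "phantom", "seed": spec.seed},
    )


def split_scans(volume: GreyVolume, n_scans: int, overlap_um: float) -> list[GreyVolume]:
    """Cut a volume into vertically overlapping sub-scans.

    Adjacent blocks share ``round(overlap_um / voxel_size)`` slices, as
    when a tall sample is covered by several acquisitions. Stitching the
    blocks back (see :mod:`mgscaffold.stitch`) reproduces the input
    exactly.
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    nz = volume.shape[0]
    ov = int(round(overlap_um / volume.voxel_size_um))
    if ov < 0:
        raise ValueError("overlap must be >= 0")
    total = nz + (n_scans - 1) * ov
    base, rem = divmod(total, n_scans)
    heights = [base + (1 if i < rem else 0) for i in range(n_scans)]
    if any(h <= ov for h in heights) and n_scans > 1:
        raise ValueError(
            f"overlap of {ov} slices too large for {n_scans} scans of a "
            f"{nz}-slice volume"
        )
    scans = []
    start = 0
    for i, h in enumerate(heights):
        block = volume.intensities[start : start + h]
        meta = dict(volume.metadata)
        meta.update({"scan_index": i, "overlap_slices": ov})
        scans.append(
            GreyVolume(block.copy(), volume.voxel_size_um, metadata=meta)
        )
        start += h - ov
    return scans


def ground_truth_report(labels: LabelVolume):
    """Exact morphometry from ground-truth labels (voxel counting)."""
    from .morphometry import phase_volumes

    return phase_volumes(labels)
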