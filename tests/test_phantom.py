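"""Synthetic scaffold generator: geometry, degradation, rendering, splitting."""

import numpy as np
import pytest
from scipy import ndimage

import mgscaffold as mg

from conftest import make_phantom


@pytest.fixture(scope="module")
def degraded_no_severe():
    spec = mg.PhantomSpec.scaled_down(seed=3, n_severe_blobs=0)
    return mg.apply_degradation(mg.build_scaffold_geometry(spec), spec), spec


# -- spec validation ---------------------------------------------------------


@pytest.mark.parametrize(
    "overrides",
    [
        {"scaffold_length_mm": 0.0},
        {"slight_degradation_fraction": 1.2},
        {"wall_thickness_um": 10.0},  # < 2 voxels at 8 um
        {"strut_width_um": 12.0},
        {"noise_sd": -1.0},
        {"n_severe_blobs": -1},
    ],
)
def test_invalid_specs_rejected(overrides):
    with pytest.raises(ValueError):
        mg.PhantomSpec.scaled_down(**overrides)


def test_grey_means_must_be_distinct():
    with pytest.raises(ValueError, match="distinct"):
        mg.PhantomSpec.scaled_down(
            phase_grey_means={0: 100.0, 1: 100.0, 2: 200.0, 3: 300.0}
        )


# -- geometry ----------------------------------------------------------------


def test_wall_radial_extent_matches_spec():
    # 130 um wall at 3.07 um voxels spans ~42 voxels radially
    spec = mg.PhantomSpec.scaled_down(
        scaffold_length_mm=0.25,
        outer_diameter_mm=0.6,
        wall_thickness_um=130.0,
        strut_width_um=130.0,
        voxel_size_um=3.07,
        ring_pitch_um=250.0,
        n_links=4,
    )
    geom = mg.build_scaffold_geometry(spec)
    # radial profile through a link (links sit at angle 0 == +y from centre)
    nz, ny, nx = geom.shape
    cx = (nx - 1) / 2
    col = geom.labels[nz // 2, :, int(round(cx))]
    nzv = np.flatnonzero(col)
    first_run = np.split(nzv, np.where(np.diff(nzv) > 1)[0] + 1)[0]
    extent = first_run.max() - first_run.min() + 1
    assert abs(extent - 130.0 / 3.07) <= 2


def test_geometry_deterministic_and_binary(small_spec):
    a = mg.build_scaffold_geometry(small_spec)
    b = mg.build_scaffold_geometry(small_spec)
    assert np.array_equal(a.labels, b.labels)
    assert set(np.unique(a.labels)) <= {0, 1}


def test_crown_count_visible_in_ring_profile(small_spec):
    """A ring's z-position oscillates with n_crowns periods around the tube."""
    geom = mg.build_scaffold_geometry(small_spec)
    nz, ny, nx = geom.shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    # mean z of metal voxels per azimuthal bin, first ring only
    zz, yy, xx = np.nonzero(geom.labels[: nz // 2])
    theta = np.arctan2(xx - cx, yy - cy)
    nbins = 64
    bins = ((theta + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins
    prof = np.array(
        [zz[bins == b].mean() for b in range(nbins) if (bins == b).any()]
    )
    # count sign changes of the centred profile: 2 per sinusoid period
    centred = prof - prof.mean()
    crossings = int((np.diff(np.sign(centred)) != 0).sum())
    assert abs(crossings - 2 * small_spec.n_crowns) <= 2


# -- degradation -------------------------------------------------------------


def test_no_degradation_is_identity(small_spec):
    spec = small_spec.replace(slight_degradation_fraction=0.0, n_severe_blobs=0)
    geom = mg.build_scaffold_geometry(spec)
    out = mg.apply_degradation(geom, spec)
    assert np.array_equal(out.labels, geom.labels)


def test_degradation_deterministic(small_spec):
    geom = mg.build_scaffold_geometry(small_spec)
    a = mg.apply_degradation(geom, small_spec)
    b = mg.apply_degradation(geom, small_spec)
    assert np.array_equal(a.labels, b.labels)


def test_degraded_fraction_hits_target():
    spec = mg.PhantomSpec.scaled_down(
        seed=7, slight_degradation_fraction=0.4, n_severe_blobs=0
    )
    out = mg.apply_degradation(mg.build_scaffold_geometry(spec), spec)
    counts = np.bincount(out.labels.ravel(), minlength=4)
    frac = counts[2] / counts[1:].sum()
    assert 0.36 <= frac <= 0.44


def test_label_conservation(small_spec):
    geom = mg.build_scaffold_geometry(small_spec)
    out = mg.apply_degradation(geom, small_spec)
    # background never becomes metallic or mildly degraded
    was_bg = geom.labels == 0
    assert not np.isin(out.labels[was_bg], [1, 2]).any()
    # mild degradation only converts metal
    assert (geom.labels[out.labels == 2] == 1).all()


def test_severe_blobs_swell_beyond_strut(small_spec):
    geom = mg.build_scaffold_geometry(small_spec)
    out = mg.apply_degradation(geom, small_spec)
    severe = out.labels == 3
    assert severe.any()
    # dilation pushed severe material into former background
    assert (severe & (geom.labels == 0)).any()


def test_degradation_requires_metal(small_spec):
    empty = mg.LabelVolume(np.zeros((8, 8, 8), dtype=np.uint8), 8.0)
    with pytest.raises(ValueError, match="no metallic"):
        mg.apply_degradation(empty, small_spec)
    tainted = mg.LabelVolume(np.full((8, 8, 8), 2, dtype=np.uint8), 8.0)
    with pytest.raises(ValueError, match="labels in"):
        mg.apply_degradation(tainted, small_spec)


def test_surface_inward_no_degradation_sealed_behind_metal(degraded_no_severe):
    """Flood-filling from the background through non-metal voxels must
    reach every degraded voxel: the conversion layer always lies between
    background and remaining metal, never enclosed by it."""
    out, _ = degraded_no_severe
    lab = out.labels
    assert lab[0, 0, 0] == 0
    seed = np.zeros(lab.shape, dtype=bool)
    seed[0, 0, 0] = True
    reach = ndimage.binary_propagation(
        seed, mask=lab != 1, structure=ndimage.generate_binary_structure(3, 1)
    )
    assert not ((lab == 2) & ~reach).any()


def test_surface_inward_ordering_on_radial_rays(degraded_no_severe):
    """Entering a strut along a radial ray, degraded material comes
    before metal in almost every crossing (small discretization slack)."""
    out, _ = degraded_no_severe
    lab = out.labels
    nz, ny, nx = lab.shape
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    viol = runs = 0
    rr = np.arange(min(ny, nx) // 2 - 1, 0, -1)
    for iz in range(0, nz, 3):
        for ang in np.linspace(0, 2 * np.pi, 60, endpoint=False):
            ys = np.clip(np.round(cy + rr * np.cos(ang)).astype(int), 0, ny - 1)
            xs = np.clip(np.round(cx + rr * np.sin(ang)).astype(int), 0, nx - 1)
            col = lab[iz, ys, xs]
            nzv = np.flatnonzero(col)
            if nzv.size == 0:
                continue
            for run in np.split(nzv, np.where(np.diff(nzv) > 1)[0] + 1):
                vals = col[run]
                runs += 1
                if 2 in vals and vals[0] == 1:
                    viol += 1
    assert runs > 500
    assert viol / runs < 0.05


# -- rendering ---------------------------------------------------------------


def test_render_noiseless_is_exact_mean_map(small_spec):
    spec = small_spec.replace(noise_sd=0.0, psf_sigma_um=0.0)
    truth = mg.apply_degradation(mg.build_scaffold_geometry(spec), spec)
    grey = mg.render_grey(truth, spec)
    for phase, mean in spec.phase_grey_means.items():
        vals = grey.intensities[truth.labels == phase]
        if vals.size:
            assert (vals == int(mean)).all()


def test_render_deterministic(small_spec, small_phantom):
    grey, truth = small_phantom
    again = mg.render_grey(truth, small_spec)
    assert np.array_equal(grey.intensities, again.intensities)


def test_render_histograms_separable_at_low_noise():
    """Noise sd 100 around means 10000 apart: phase histograms overlap
    by far less than 0.1% (midpoint threshold classification)."""
    rng_lab = np.random.default_rng(0)
    lab = mg.LabelVolume(
        rng_lab.integers(0, 2, (40, 40, 40)).astype(np.uint8), 8.0
    )
    spec = mg.PhantomSpec.scaled_down(
        noise_sd=100.0,
        psf_sigma_um=0.0,
        phase_grey_means={0: 20000.0, 1: 30000.0, 2: 40000.0, 3: 50000.0},
        seed=1,
    )
    grey = mg.render_grey(lab, spec)
    mid = 25000
    v0 = grey.intensities[lab.labels == 0]
    v1 = grey.intensities[lab.labels == 1]
    misrate = ((v0 > mid).sum() + (v1 < mid).sum()) / (v0.size + v1.size)
    assert misrate < 0.001


# -- scan splitting ----------------------------------------------------------


def test_split_single_scan_is_identity(small_phantom):
    grey, _ = small_phantom
    (only,) = mg.split_scans(grey, 1, 750.0)
    assert np.array_equal(only.intensities, grey.intensities)


def test_split_heights_match_overlap_arithmetic():
    # 3852 slices, 2 scans, 750 um overlap at 3.07 um (= 244 slices)
    vol = mg.GreyVolume(np.zeros((3852, 2, 2), dtype=np.uint16), 3.07)
    scans = mg.split_scans(vol, 2, 750.0)
    assert [s.shape[0] for s in scans] == [2048, 2048]
    assert 2048 + 2048 - round(750 / 3.07) == 3852


def test_split_overlap_too_large_rejected():
    vol = mg.GreyVolume(np.zeros((30, 2, 2), dtype=np.uint16), 1.0)
    with pytest.raises(ValueError, match="too large"):
        mg.split_scans(vol, 4, 28.0)


def test_split_stitch_roundtrip_bit_exact(small_phantom):
    grey, _ = small_phantom
    for n in (2, 3):
        scans = mg.split_scans(grey, n, 96.0)
        series = mg.ScanSeries(scans=scans, nominal_overlap_um=96.0)
        back = mg.stitch_scans(series)
        assert np.array_equal(back.intensities, grey.intensities)


# -- ground truth report -----------------------------------------------------


def test_ground_truth_report_exact_volumes():
    lab = np.zeros((100, 100, 100), dtype=np.uint8)
    lab[:40] = 1  # 4e5 metal voxels
    vol = mg.LabelVolume(lab, 3.07)
    rep = mg.ground_truth_report(vol)
    assert rep.volume_metallic_mm3 == pytest.approx(
        (3.07e-3) ** 3 * 4e5, rel=1e-12
    )
    # a million labelled voxels at 3.07 um are 2.894e-2 mm^3
    assert (3.07e-3) ** 3 * 1e6 == pytest.approx(2.894e-2, abs=5e-5)


def test_ground_truth_report_empty_and_conservation(small_phantom):
    empty = mg.LabelVolume(np.zeros((5, 5, 5), dtype=np.uint8), 8.0)
    rep = mg.ground_truth_report(empty)
    assert rep.total_solid_mm3 == 0.0
    assert not rep.fraction_defined

    _, truth = small_phantom
    rep = mg.ground_truth_report(truth)
    expected = (truth.labels != 0).sum() * truth.voxel_volume_mm3()
    assert rep.total_solid_mm3 == pytest.approx(expected, rel=1e-12)
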