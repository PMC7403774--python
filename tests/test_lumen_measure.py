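"""Plane placement, reslicing, lumen segmentation, area traces."""

import numpy as np
import pytest
from skimage.transform import rotate

from tubepump.errors import InvalidConfigurationError, OutOfBoundsError
from tubepump.frames import OpticsConfig
from tubepump.lumen_measure import (
    LumenTrace,
    SegmentationConfig,
    area_trace,
    averaged_area,
    extract_plane_image,
    place_planes,
    pooled_threshold,
    segment_lumen,
)
from tubepump.oct_recon import Volume4D, gate_and_synchronize
from tubepump.phantom import make_wall_kinematics, render_bscan_sequence


def test_place_planes_geometry():
    l1, l2, l3 = place_planes(np.array([0.0, 0, 0]), np.array([0, 0, 1.0]), spacing_um=30)
    assert np.allclose(l3.origin_um - l1.origin_um, [0, 0, 60])
    assert np.allclose(l1.origin_um, [0, 0, -30])
    assert l1.label == "L1" and l2.label == "L2" and l3.label == "L3"
    assert np.allclose(l1.normal, l2.normal) and np.allclose(l2.normal, l3.normal)


def test_place_planes_degenerate_inputs():
    with pytest.raises(InvalidConfigurationError):
        place_planes(np.zeros(3), np.zeros(3), spacing_um=30)
    with pytest.raises(InvalidConfigurationError):
        place_planes(np.zeros(3), np.array([1.0, 0, 0]), spacing_um=0)


def _cylinder_volume(radius_um=20.0, n_slices=40, n_px=64, pixel_um=2.0):
    """Synthetic Volume4D: dark cylinder along the slice axis in bright tissue."""
    yy, xx = np.mgrid[0:n_px, 0:n_px]
    c = (n_px - 1) / 2.0
    dist = np.hypot(yy - c, xx - c) * pixel_um
    img = np.where(dist < radius_um, -20.0, 0.0)
    img = np.where(dist > radius_um + 16, -30.0, img)
    structural = np.broadcast_to(img, (1, n_slices, n_px, n_px)).copy()
    optics = OpticsConfig(axial_pixel_um=pixel_um, lateral_pixel_um=pixel_um)
    return Volume4D(
        structural=structural,
        velocity_mm_s=np.zeros_like(structural),
        volume_rate_hz=100.0,
        period_s=0.01,
        phase_count=1,
        slice_positions_um=np.arange(n_slices) * pixel_um,
        optics=optics,
    )


def test_extract_axis_aligned_plane_matches_slice():
    vol = _cylinder_volume()
    # plane grid on exact voxel centres: values come straight off the slice
    l1, l2, l3 = place_planes(np.array([40.0, 64.0, 64.0]), np.array([1.0, 0, 0]),
                              spacing_um=30, pixel_um=2.0, half_extent_um=50.0)
    struct, velo = extract_plane_image(vol, l2, 0)
    assert set(np.unique(struct)).issubset({-30.0, -20.0, 0.0})
    assert np.allclose(velo, 0.0)


def test_tilted_plane_area_scales_with_cos():
    vol = _cylinder_volume()
    cfg = SegmentationConfig(threshold_db=-10.0, n_replicates=1,
                             smooth_sigma_px=0, opening_iterations=0)
    perp = place_planes(np.array([40.0, 63.0, 63.0]), np.array([1.0, 0, 0]),
                        spacing_um=30, pixel_um=2.0, half_extent_um=50.0)[1]
    tilt = place_planes(np.array([40.0, 63.0, 63.0]), np.array([1.0, 1.0, 0]),
                        spacing_um=30, pixel_um=2.0, half_extent_um=50.0)[1]
    a_perp = segment_lumen(extract_plane_image(vol, perp, 0)[0], cfg)[0].sum() * 4.0
    a_tilt = segment_lumen(extract_plane_image(vol, tilt, 0)[0], cfg)[0].sum() * 4.0
    truth = np.pi * 20.0**2
    assert a_perp == pytest.approx(truth, rel=0.07)
    assert a_tilt / a_perp == pytest.approx(1.0 / np.cos(np.pi / 4), rel=0.08)


def test_extract_plane_bounds_checks():
    vol = _cylinder_volume()
    plane = place_planes(np.array([40.0, 63.0, 63.0]), np.array([1.0, 0, 0]),
                         spacing_um=30)[1]
    with pytest.raises(OutOfBoundsError):
        extract_plane_image(vol, plane, 5)  # phase out of range
    far = place_planes(np.array([1e5, 63.0, 63.0]), np.array([1.0, 0, 0]),
                       spacing_um=30)[1]
    with pytest.raises(OutOfBoundsError):
        extract_plane_image(vol, far, 0)


def test_segment_synthetic_disk_area():
    n = 128
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    img = np.where(np.hypot(yy - c, xx - c) < 50, -15.0, 0.0)
    cfg = SegmentationConfig(threshold_db=-7.0, n_replicates=3,
                             smooth_sigma_px=0, opening_iterations=0)
    masks = segment_lumen(img, cfg)
    area = masks[1].sum()  # 1 um pixels
    assert area == pytest.approx(np.pi * 50**2, rel=0.02)


def test_segment_closed_lumen_returns_empty():
    img = np.zeros((64, 64))  # uniform bright: nothing below threshold
    cfg = SegmentationConfig(threshold_db=-5.0)
    masks = segment_lumen(img, cfg)
    assert all(m.sum() == 0 for m in masks)


def test_segment_imported_mask_passthrough():
    img = np.zeros((32, 32))
    mask = np.zeros((32, 32), dtype=bool)
    mask[10:20, 10:20] = True
    cfg = SegmentationConfig(method="imported_mask")
    out = segment_lumen(img, cfg, imported_masks=[mask])
    assert np.array_equal(out[0], mask)
    with pytest.raises(InvalidConfigurationError):
        segment_lumen(img, cfg, imported_masks=[mask[:10]])


def test_area_invariant_under_rotation():
    rng = np.random.default_rng(0)
    n = 128
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    img = np.where(np.hypot(yy - c, xx - c) < 40, -15.0, 0.0)
    img += rng.normal(0, 0.5, img.shape)
    cfg = SegmentationConfig(threshold_db=-7.0, n_replicates=1)
    a0 = segment_lumen(img, cfg)[0].sum()
    a30 = segment_lumen(rotate(img, 30, mode="edge"), cfg)[0].sum()
    assert abs(a30 / a0 - 1) < 0.01


def _single_slice_volume(kin, optics, z_um, seed=3, n_frames=200,
                         image_shape=(64, 64)):
    seq = render_bscan_sequence(kin, None, optics, z_um, n_frames=n_frames,
                                seed=seed, theta_deg=0.0, image_shape=image_shape)
    return gate_and_synchronize([seq])


def test_area_trace_tracks_sinusoidal_radius():
    """Segmented A(t) matches pi r(t)^2 through the cycle on a rendered slice."""
    optics = OpticsConfig(axial_pixel_um=1.0, lateral_pixel_um=1.0)
    kin = make_wall_kinematics(
        "suction", period_s=0.5, base_radius_um=26, amplitude_um=12,
        wave_speed_mm_s=1e6, axis_length_um=100, n_t=128,
        profile_fn=lambda u: 0.5 + 0.5 * np.sin(2 * np.pi * u),
    )
    vol = _single_slice_volume(kin, optics, 50.0, image_shape=(128, 128))
    plane = place_planes(np.array([0.0, 63.5, 63.5]), np.array([1.0, 0, 0]),
                         spacing_um=30, pixel_um=1.0)[1]
    trace = area_trace(vol, plane)
    # the fold's phase origin is the sequence start (phase 0 of the cycle)
    times = vol.phase_times_s
    truth = np.pi * np.asarray(kin.radius_fn(np.asarray(50.0), times)) ** 2
    err = np.abs(trace.areas_mean_um2 - truth)
    # 3% of peak area, plus one pixel ring of slack at the boundary
    assert err.max() < 0.03 * truth.max() + 2 * np.pi * np.sqrt(truth.max() / np.pi) * 2.0
    # replicate spread stays below 5% of the area where the lumen is wide open
    wide = truth >= 0.5 * truth.max()
    assert np.max(trace.areas_std_um2[wide] / truth[wide]) < 0.05
    assert not trace.closed_flag.any()


def test_averaged_area_mean_and_grid_check():
    times = np.arange(5) / 100.0
    mk = lambda a: LumenTrace("L1", times, np.full(5, float(a)), np.zeros(5),
                              np.full((5, 1), float(a)), np.zeros(5, bool), 4.0)
    aa = averaged_area(mk(100.0), mk(50.0))
    assert np.allclose(aa, 75.0)
    other = LumenTrace("L3", times + 1.0, np.ones(5), np.zeros(5),
                       np.ones((5, 1)), np.zeros(5, bool), 4.0)
    with pytest.raises(InvalidConfigurationError):
        averaged_area(mk(1.0), other)


def test_pooled_threshold_sits_between_blood_and_wall():
    rng = np.random.default_rng(2)
    n = 64
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    d = np.hypot(yy - c, xx - c)
    imgs = []
    for _ in range(5):
        img = np.where(d < 20, -12.0, np.where(d < 28, 0.0, -27.0))
        imgs.append(img + rng.normal(0, 1.0, img.shape))
    thr = pooled_threshold(imgs, SegmentationConfig())
    assert -12.0 < thr < 0.0
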