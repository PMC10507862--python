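import math

import numpy as np
import pytest

from bilgmd import (
    CameraRig,
    Channel,
    ChannelParams,
    SceneSpec,
    StereoFrameSequence,
    add_noise,
    make_trajectory,
    project_rectangle,
    render_sequence,
)
from bilgmd.experiments import RIG_SMALL


def test_projection_column_offset_matches_pinhole_disparity(tiny_rig):
    """b=0.1, f=0.004 m, 2 um pixels at 2 m -> 100 px column offset."""
    left, right = project_rectangle(
        CameraRig(baseline_m=0.1, focal_m=0.004, pixel_size_m=2e-6,
                  rows=600, cols=600),
        center_depth_m=2.0, center_lateral_m=0.0,
        halfwidth_m=0.0002, halfheight_m=0.0002,
    )
    assert left.col0 - right.col0 == 100
    assert left.col1 - right.col1 == 100
    assert (left.row0, left.row1) == (right.row0, right.row1)


def test_disparity_vanishes_at_infinite_distance():
    rig = CameraRig(baseline_m=0.1, focal_m=0.004, pixel_size_m=2e-6,
                    rows=600, cols=600)
    left, right = project_rectangle(rig, 1e9, 0.0, 1e6, 1e6)
    assert left == right


def test_projected_width_scales_linearly_with_object_size():
    rig = CameraRig(baseline_m=0.02, focal_m=0.004, pixel_size_m=8e-6,
                    rows=400, cols=400)
    _, small = project_rectangle(rig, 1.0, 0.0, 0.05, 0.05)
    _, large = project_rectangle(rig, 1.0, 0.0, 0.10, 0.05)
    w_small = small.col1 - small.col0
    w_large = large.col1 - large.col0
    assert abs(w_large - 2 * w_small) <= 1  # rounding slack


def test_projection_rejects_nonpositive_depth(tiny_rig):
    with pytest.raises(ValueError):
        project_rectangle(tiny_rig, 0.0, 0.0, 0.1, 0.1)


def test_constant_speed_approach_is_arithmetic_in_depth():
    traj = make_trajectory(
        "approaching", RIG_SMALL,
        start_depth_m=5.0, speed_m_per_frame=0.05, n_frames=60,
    )
    assert np.all(np.diff(traj.depth_m) < 0)
    assert traj.depth_m[59] == pytest.approx(2.05)


def test_translation_holds_depth_fixed():
    traj = make_trajectory(
        "translating_left", RIG_SMALL, depth_m=3.0, n_frames=40,
        lateral_speed_m_per_frame=0.01,
    )
    assert np.all(traj.depth_m == 3.0)
    assert np.all(np.diff(traj.lateral_m) < 0)


def test_decelerating_pattern_grows_image_size_linearly():
    """Inverse-depth ramps make the projected width climb a constant
    pixel amount per frame (within rounding)."""
    rig = RIG_SMALL
    traj = make_trajectory(
        "approach_pattern_2", rig,
        start_depth_m=2.0, end_depth_m=0.5, n_frames=20,
        halfwidth_m=0.08, halfheight_m=0.08, stationary_frames=0,
        # head-on along the right camera's axis: no lateral drift, so the
        # rendered width reflects the size ramp alone
        lateral_start_m=rig.baseline_m / 2,
    )
    widths = []
    for depth, lateral in zip(traj.depth_m, traj.lateral_m):
        _, right = project_rectangle(
            rig, depth, lateral, traj.object_halfwidth_m, traj.object_halfheight_m
        )
        widths.append(right.col1 - right.col0)
    exact = 2.0 * traj.object_halfwidth_m * rig.focal_px / traj.depth_m
    # the exact width ramp is linear in t...
    np.testing.assert_allclose(np.diff(exact), np.diff(exact)[0], rtol=1e-9)
    # ...and the rendered width tracks it to within one pixel (a span of
    # [c-hw, c+hw] covers 2*hw + 1 pixel centres, hence the +1)
    assert np.all(np.abs(np.asarray(widths) - (exact + 1.0)) <= 1.0)


def test_decelerating_pattern_three_shrinks_depth_decrements():
    traj = make_trajectory(
        "approach_pattern_3", RIG_SMALL,
        start_depth_m=1.0, initial_speed_m_per_frame=0.05, n_frames=20,
        stationary_frames=5,
    )
    motion = traj.depth_m[5:-5]
    decrements = -np.diff(motion)
    assert np.all(decrements > 0)
    np.testing.assert_allclose(decrements[1:] / decrements[:-1], 0.9, rtol=1e-9)
    # stationary padding present on both ends
    assert np.all(traj.depth_m[:5] == traj.depth_m[0])
    assert np.all(traj.depth_m[-5:] == traj.depth_m[-1])


def test_overshooting_approach_rejected():
    with pytest.raises(ValueError):
        make_trajectory("approaching", RIG_SMALL, start_depth_m=1.0,
                        speed_m_per_frame=0.1, n_frames=20)


def _render(mode="approaching", object_gray=0.0, background_gray=0.5, **kw):
    params = dict(start_depth_m=1.2, speed_m_per_frame=0.05, n_frames=8,
                  halfwidth_m=0.1, halfheight_m=0.1)
    params.update(kw)
    traj = make_trajectory(mode, RIG_SMALL, **params)
    spec = SceneSpec(mode=mode, object_gray=object_gray,
                     background_gray=background_gray)
    return render_sequence(RIG_SMALL, traj, spec)


def test_left_frame_is_right_frame_shifted_by_truth_disparity():
    seq = _render()
    for t in range(len(seq)):
        dp = int(seq.truth_disparity_px[t])
        cols = seq.left.shape[2]
        np.testing.assert_array_equal(
            seq.left[t][:, dp:], seq.right[t][:, : cols - dp]
        )
        assert np.all(seq.left[t][:, :dp] == 128)  # pure background strip


def test_stationary_scene_renders_identical_frames_and_silent_p_layer():
    traj = make_trajectory("approaching", RIG_SMALL, start_depth_m=1.0,
                           speed_m_per_frame=1e-9, n_frames=3,
                           halfwidth_m=0.1, halfheight_m=0.1)
    seq = render_sequence(RIG_SMALL, traj, SceneSpec(mode="approaching"))
    np.testing.assert_array_equal(seq.left[0], seq.left[1])
    ch = Channel(ChannelParams(), seq.frame_shape)
    assert not any(ch.step(f).any() for f in seq.left)


def test_brightness_swap_preserves_contrast_magnitude():
    dark = _render(object_gray=0.0, background_gray=0.5)
    bright = _render(object_gray=1.0, background_gray=0.5)
    bg = 127.5
    np.testing.assert_allclose(
        np.abs(dark.left.astype(float) - bg),
        np.abs(bright.left.astype(float) - bg),
        atol=0.5,  # half-up quantisation of the two grey levels
    )


def test_truth_disparity_monotone_for_depth_motion():
    approach = _render()
    recede = _render("receding", start_depth_m=0.8)
    assert np.all(np.diff(approach.truth_disparity_px) >= 0)
    assert np.any(np.diff(approach.truth_disparity_px) > 0)
    assert np.all(np.diff(recede.truth_disparity_px) <= 0)


def test_truth_disparity_constant_for_lateral_and_grating_modes():
    translate = _render("translating_right", depth_m=2.0,
                        lateral_start_m=-0.2, lateral_speed_m_per_frame=0.01)
    assert len(set(translate.truth_disparity_px)) == 1
    grating = render_sequence(
        RIG_SMALL, make_trajectory("grating", RIG_SMALL, n_frames=6),
        SceneSpec(mode="grating"),
    )
    assert np.all(grating.truth_disparity_px == 0)
    np.testing.assert_array_equal(grating.left, grating.right)


def test_elongating_object_grows_only_one_visible_edge():
    seq = _render("elongating", depth_m=2.0, lateral_start_m=-0.2,
                  lateral_speed_m_per_frame=0.02, n_frames=10)
    extents = [(frame != 128).sum() for frame in seq.right]
    assert all(b >= a for a, b in zip(extents, extents[1:]))
    assert extents[-1] > extents[0]
    # the left image column (fixed edge side) stays object-coloured
    assert np.all(seq.right[:, 100, 0] == seq.right[0, 100, 0])


def test_noise_zero_variance_is_identity_and_seeded_noise_reproducible():
    seq = _render()
    assert add_noise(seq, 0.0, seed=3) is seq
    a = add_noise(seq, 0.01, seed=3)
    b = add_noise(seq, 0.01, seed=3)
    np.testing.assert_array_equal(a.left, b.left)
    np.testing.assert_array_equal(a.right, b.right)
    assert not np.array_equal(a.left, seq.left)
    with pytest.raises(ValueError):
        add_noise(seq, -0.1, seed=0)


def test_noise_sample_variance_matches_requested_level():
    """Variance 0.05 on a mid-grey 600x600 frame, measured after clamping,
    lands within 5% of the nominal level."""
    rig = CameraRig(baseline_m=0.02, focal_m=0.004, pixel_size_m=8e-6,
                    rows=600, cols=600)
    frame = np.full((1, 600, 600), 128, dtype=np.uint8)
    seq = StereoFrameSequence(left=frame.copy(), right=frame.copy())
    noisy = add_noise(seq, 0.05, seed=11)
    delta = (noisy.left.astype(float) - 128.0) / 255.0
    assert delta.var() == pytest.approx(0.05, rel=0.05)


def test_scene_spec_validation():
    with pytest.raises(ValueError):
        SceneSpec(mode="approaching", object_gray=0.5, background_gray=0.5)
    with pytest.raises(ValueError):
        SceneSpec(mode="warp_drive")
    with pytest.raises(ValueError):
        SceneSpec(mode="approaching", noise_variance=-1.0)


def test_save_and_load_roundtrip(tmp_path):
    seq = _render()
    seq.save(tmp_path)
    assert (tmp_path / "left" / "000000.png").exists()
    loaded = StereoFrameSequence.load(
        tmp_path / "left", tmp_path / "right", tmp_path / "truth.csv"
    )
    np.testing.assert_array_equal(loaded.left, seq.left)
    np.testing.assert_array_equal(loaded.right, seq.right)
    np.testing.assert_array_equal(loaded.truth_disparity_px, seq.truth_disparity_px)
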