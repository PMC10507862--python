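import numpy as np
import pytest

from bilgmd import (
    Channel,
    ChannelParams,
    ChannelState,
    grouping,
    lateral_inhibition,
    persistence_coefficients,
    photoreceptor,
    summation,
)

from oracle import run_cascade


def test_persistence_coefficients_follow_logistic_decay():
    a = persistence_coefficients(2)
    assert a[0] == pytest.approx(1.0 / (1.0 + np.e), abs=1e-12)
    assert a[0] == pytest.approx(0.26894, abs=1e-5)
    assert a[1] == pytest.approx(1.0 / (1.0 + np.e**2), abs=1e-12)


@pytest.mark.parametrize("n_p", [0, 1, 2])
def test_constant_luminance_gives_zero_photoreceptor_output(n_p):
    params = ChannelParams(n_p=n_p)
    state = ChannelState(shape=(5, 5))
    frame = np.full((5, 5), 128.0)
    for _ in range(4):
        p = photoreceptor(frame, state, params)
        assert not p.any()


def test_photoreceptor_step_response_decays_through_history():
    """A single 100->160 luminance step echoes as 60, 60*a1, 60*a1^2..."""
    params = ChannelParams(n_p=1)
    state = ChannelState(shape=(3, 3))
    a1 = 1.0 / (1.0 + np.e)
    low = np.full((3, 3), 100.0)
    high = low.copy()
    high[1, 1] = 160.0
    photoreceptor(low, state, params)          # primes the luminance buffer
    p_t = photoreceptor(high, state, params)
    assert p_t[1, 1] == pytest.approx(60.0)
    p_t1 = photoreceptor(high, state, params)  # luminance constant again
    assert p_t1[1, 1] == pytest.approx(60.0 * a1, abs=1e-6)
    assert p_t1[1, 1] == pytest.approx(16.14, abs=0.01)
    p_t2 = photoreceptor(high, state, params)
    assert p_t2[1, 1] == pytest.approx(60.0 * a1 * a1, abs=1e-6)
    assert p_t2[1, 1] == pytest.approx(4.34, abs=0.01)


def test_photoreceptor_rejects_mismatched_frame():
    state = ChannelState(shape=(4, 4))
    with pytest.raises(ValueError):
        photoreceptor(np.zeros((3, 4)), state, ChannelParams())


def test_lateral_inhibition_spreads_single_pixel(params):
    prev_p = np.zeros((5, 5))
    prev_p[2, 2] = 8.0
    i_map = lateral_inhibition(prev_p, params)
    assert i_map[2, 2] == 0.0
    for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
        assert i_map[r, c] == pytest.approx(2.0)
    for r, c in [(1, 1), (1, 3), (3, 1), (3, 3)]:
        assert i_map[r, c] == pytest.approx(1.0)


def test_lateral_inhibition_uniform_field_sums_to_1_5x(params):
    i_map = lateral_inhibition(np.full((7, 7), 4.0), params)
    assert i_map[3, 3] == pytest.approx(6.0)  # 1.5 * 4 in the interior


@pytest.mark.parametrize(
    "e, i, expected", [(10.0, 10.0, 7.0), (1.0, 10.0, 0.0), (-10.0, 10.0, 7.0)]
)
def test_summation_rectifies_excitation_minus_weighted_inhibition(
    params, e, i, expected
):
    out = summation(np.full((3, 3), e), np.full((3, 3), i), params)
    assert out[1, 1] == pytest.approx(expected)


def test_grouping_filters_isolated_but_keeps_clustered_excitation(params):
    s = np.zeros((9, 9))
    s[4, 4] = 3.0
    # isolated pixel: Ce = 1/3, w = 1/12 + 0.01, G ~ 10.7 < T_de -> zeroed
    assert not grouping(s, params).any()
    block = np.zeros((12, 12))
    block[3:9, 3:9] = 60.0
    g = grouping(block, params)
    # interior of the cluster: Ce = 60, w = 15.01, G = 239.8 >= T_de
    assert g[5, 5] == pytest.approx(60.0 * 60.0 / (60.0 / 4.0 + 0.01), rel=1e-9)
    assert g[5, 5] == pytest.approx(239.84, abs=0.01)


def test_grouping_amplifies_cluster_interiors_above_isolated_pixels(params):
    v = 45.0
    lone = np.zeros((9, 9))
    lone[4, 4] = v
    block = np.zeros((9, 9))
    block[2:7, 2:7] = v
    g_lone = grouping(lone, params)[4, 4]
    g_block = grouping(block, params)[4, 4]
    assert g_block > g_lone
    assert g_block >= v * v / (v / params.grouping_gain + params.grouping_eps) - 1e-9


def test_grouping_of_zero_map_is_zero(params):
    assert not grouping(np.zeros((6, 6)), params).any()


def test_brightness_symmetry_of_cascade(rng):
    """Inverting luminance about any pivot leaves Ĝ unchanged (|P|, |I|)."""
    frames = rng.integers(0, 256, size=(6, 10, 10)).astype(float)
    ch_a = Channel(ChannelParams(), (10, 10))
    ch_b = Channel(ChannelParams(), (10, 10))
    for frame in frames:
        g_a = ch_a.step(frame)
        g_b = ch_b.step(255.0 - frame)
        np.testing.assert_allclose(g_a, g_b, atol=1e-9)


def test_stationary_stream_yields_silent_output(rng):
    frame = rng.integers(0, 256, size=(12, 12)).astype(float)
    ch = Channel(ChannelParams(), (12, 12))
    for _ in range(3):
        assert not ch.step(frame).any()


@pytest.mark.parametrize("n_p", [0, 1, 2])
def test_cascade_matches_nested_loop_oracle(rng, n_p):
    """Vectorised layers equal a literal per-pixel evaluation."""
    for _ in range(25):
        rows, cols = rng.integers(3, 10, size=2)
        frames = rng.integers(0, 256, size=(5, rows, cols)).astype(float)
        expected = run_cascade(frames, n_p=n_p)
        ch = Channel(ChannelParams(n_p=n_p), (rows, cols))
        for t, frame in enumerate(frames):
            layers = ch.step_layers(frame)
            for key, ref in zip(("P", "I", "S", "G"), expected[t]):
                np.testing.assert_allclose(layers[key], ref, atol=1e-9)


def test_invalid_persistence_depth_rejected():
    with pytest.raises(ValueError):
        ChannelParams(n_p=3)
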