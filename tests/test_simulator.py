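"""Material library and signal-generation invariants."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tactile_avatar import (
    SimulationConfig,
    build_material_library,
    hardness_bin,
    iter_corpus,
    record_corpus,
    side_middle_masks,
    simulate_slide,
    simulate_touch,
)
from tactile_avatar.simulator import touch_slope_v_per_s

NOISELESS = SimulationConfig(noise_level=0.0)


@pytest.mark.parametrize("n", [1, 5, 42])
def test_library_ranks_bins_roughness(n):
    lib = build_material_library(n, seed=1)
    assert sorted(m.true_rank for m in lib) == list(range(1, n + 1))
    assert all(1 <= m.hardness_bin <= 5 for m in lib)
    rough = [m.roughness_level for m in lib]
    assert np.all(np.diff(rough) >= 0)
    assert all(m.pattern_pitch_um > 0 for m in lib)


def test_library_hardness_spans_full_scale():
    lib = build_material_library(42, seed=1)
    duro = [m.durometer_hardness for m in lib]
    assert min(duro) == 20.0 and max(duro) == 90.0
    assert {m.hardness_bin for m in lib} == {1, 2, 3, 4, 5}


def test_hardness_bin_edges():
    assert [hardness_bin(d) for d in (20, 40, 41, 50, 51, 60, 61, 70, 71, 90)] == [
        1, 1, 2, 2, 3, 3, 4, 4, 5, 5,
    ]
    with pytest.raises(ValueError):
        hardness_bin(10.0)


def test_library_middle_ranks_more_similar():
    # inter-neighbour log-pitch gaps are smaller inside the middle band
    lib = build_material_library(42, seed=1)
    logp = np.log([m.pattern_pitch_um for m in lib])
    gaps = np.diff(logp)
    _, middle = side_middle_masks(42)
    inner = middle[1:] & middle[:-1]
    outer = ~middle[1:] & ~middle[:-1]
    assert gaps[inner].mean() < gaps[outer].mean()


def test_library_seeded_determinism_and_errors():
    assert build_material_library(42, seed=1) == build_material_library(42, seed=1)
    assert build_material_library(42, seed=1) != build_material_library(42, seed=2)
    with pytest.raises(ValueError):
        build_material_library(0, seed=1)


def test_side_middle_masks_study_scale():
    side, middle = side_middle_masks(42)
    ranks = np.arange(1, 43)
    assert set(ranks[middle]) == set(range(11, 31))
    assert side.sum() == 22 and middle.sum() == 20


def _material(durometer, pitch=1000.0, gain=1.0, rough=0.0, amps=(1.0, 0, 0, 0)):
    return replace(
        build_material_library(1, seed=0)[0],
        durometer_hardness=durometer,
        pattern_pitch_um=pitch,
        piezo_gain=gain,
        roughness_level=rough,
        harmonic_amplitudes=amps,
    )


def test_touch_slope_follows_durometer_ordering():
    # the measured pair: durometers 85.1 (hard, steep) vs 24.9 (soft, shallow)
    hard, soft = _material(85.1), _material(24.9)
    t_hard = simulate_touch(hard, 1.2, NOISELESS)
    t_soft = simulate_touch(soft, 1.2, NOISELESS)
    slope = lambda tr: np.max(np.diff(tr)) * NOISELESS.sample_rate
    assert slope(t_hard) > slope(t_soft)


def test_touch_slope_map_matches_affine_form():
    # brute-force the slope map over a hardness grid against the affine law
    grid = [25.0, 45.0, 55.0, 65.0, 85.0]  # one value per hardness bin
    slopes = []
    for d in grid:
        trace = simulate_touch(_material(d), 1.2, NOISELESS)
        slopes.append(np.max(np.diff(trace)) * NOISELESS.sample_rate)
    assert np.all(np.diff(slopes) > 0)
    expected = [touch_slope_v_per_s(_material(d), 1.2, NOISELESS) for d in grid]
    np.testing.assert_allclose(slopes, expected, rtol=1e-6)


def test_touch_zero_force_and_errors():
    trace = simulate_touch(_material(50.0), 0.0, NOISELESS)
    assert np.all(trace == 0.0)
    noisy = simulate_touch(
        _material(50.0), 0.0, replace(NOISELESS, noise_level=0.1),
        rng=np.random.default_rng(0),
    )
    assert abs(noisy.mean()) < 0.02
    with pytest.raises(ValueError):
        simulate_touch(_material(50.0), -1.0, NOISELESS)


@given(
    d1=st.floats(20.0, 90.0),
    d2=st.floats(20.0, 90.0),
)
def test_touch_slope_sign_matches_durometer_sign(d1, d2):
    s1 = touch_slope_v_per_s(_material(d1), 1.2, NOISELESS)
    s2 = touch_slope_v_per_s(_material(d2), 1.2, NOISELESS)
    assert np.sign(s1 - s2) == np.sign(d1 - d2)


def test_slide_spectral_peak_at_velocity_over_pitch():
    # 400 um pitch at 4 cm/s -> 100 Hz fundamental, 0.01 s between peaks
    mat = _material(50.0, pitch=400.0)
    trace = simulate_slide(mat, 4.0, 2.0, NOISELESS)
    freqs = np.fft.rfftfreq(trace.size, 1e-3)
    assert freqs[np.argmax(np.abs(np.fft.rfft(trace)))] == pytest.approx(100.0, abs=0.5)


def test_slide_fft_argmax_vs_zero_crossing_oracle():
    # 4000 um at 4 cm/s -> 10 Hz; zero crossings count the same frequency
    mat = _material(50.0, pitch=4000.0)
    trace = simulate_slide(mat, 4.0, 2.0, NOISELESS)
    freqs = np.fft.rfftfreq(trace.size, 1e-3)
    f_fft = freqs[np.argmax(np.abs(np.fft.rfft(trace)))]
    assert f_fft == pytest.approx(10.0, abs=0.5)  # one resolution bin
    crossings = np.sum(np.diff(np.signbit(trace)))
    f_zc = crossings / 2.0 / 2.0  # crossings / 2 per cycle / duration
    assert f_zc == pytest.approx(10.0, abs=0.5)


def test_slide_pure_tone_has_single_dominant_peak():
    mat = _material(50.0, pitch=1000.0)
    trace = simulate_slide(mat, 4.0, 2.0, NOISELESS)
    mag = np.abs(np.fft.rfft(trace))
    top, second = np.sort(mag)[-2:][::-1]
    assert top > 10 * second


def test_slide_invalid_arguments():
    mat = _material(50.0)
    with pytest.raises(ValueError):
        simulate_slide(mat, 0.0, 1.0, NOISELESS)
    with pytest.raises(ValueError):
        simulate_slide(mat, 4.0, 0.0, NOISELESS)


def test_corpus_counts_aggregation_and_determinism():
    lib = build_material_library(3, seed=4)
    cfg = SimulationConfig(n_materials=3, n_trials_per_material=4, seed=5)
    corpus = record_corpus(lib, cfg)
    assert len(corpus) == 12
    rec = corpus[0]
    assert rec.touch_traces.shape[0] == cfg.n_cells
    np.testing.assert_array_equal(
        rec.aggregated_touch, rec.touch_traces.mean(axis=0)
    )
    corpus2 = record_corpus(lib, cfg)
    np.testing.assert_array_equal(rec.slide_traces, corpus2[0].slide_traces)


def test_corpus_noiseless_trials_identical():
    lib = build_material_library(2, seed=4)
    cfg = SimulationConfig(
        n_materials=2, n_trials_per_material=3, seed=5, noise_level=0.0
    )
    corpus = record_corpus(lib, cfg)
    np.testing.assert_array_equal(corpus[0].touch_traces, corpus[1].touch_traces)
    np.testing.assert_array_equal(corpus[0].slide_traces, corpus[2].slide_traces)


def test_corpus_empty_library_rejected():
    cfg = SimulationConfig(n_materials=1, n_trials_per_material=1)
    with pytest.raises(ValueError):
        next(iter_corpus([], cfg))


def test_config_validation():
    for kwargs in (
        {"n_materials": 0},
        {"n_trials_per_material": 0},
        {"noise_level": -0.1},
    ):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
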