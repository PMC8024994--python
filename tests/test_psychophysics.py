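"""Ranking generator and decision-metric oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from tactile_avatar import (
    CohortParams,
    DecisionMatrix,
    DegenerateHistogramError,
    Participant,
    decision_histogram,
    decision_histograms,
    decision_std,
    h_a_rmse,
    histogram_kurtosis,
    sample_cohort,
    sample_participant,
    simulate_decision_matrix,
    split_groups,
    tactile_decision_rmse,
)
from tactile_avatar.simulator import side_middle_masks


def _noiseless_participant(m=6):
    return Participant(
        participant_id=0, group="S", bias=np.zeros(m), sigma=np.zeros(m), seed=0
    )


# ------------------------------------------------------------- generator


@given(st.sampled_from(["S", "D"]), st.integers(0, 1000))
def test_every_trial_is_a_permutation(group, seed):
    p = sample_participant(group, m_count=9, seed=seed)
    mx = simulate_decision_matrix(p, n_trials=5)
    m = mx.n_materials
    assert np.all(mx.ranks.sum(axis=1) == m * (m + 1) // 2)
    for row in mx.ranks:
        assert sorted(row) == list(range(1, m + 1))


def test_noiseless_participant_ranks_identically():
    mx = simulate_decision_matrix(_noiseless_participant(), n_trials=4)
    np.testing.assert_array_equal(mx.ranks, np.tile(np.arange(1, 7), (4, 1)))
    np.testing.assert_array_equal(decision_std(mx), np.zeros(6))


def test_participant_group_label_validation():
    with pytest.raises(ValueError):
        sample_participant("X", 10, seed=0)


def test_participant_seeded_determinism():
    a = sample_participant("S", 42, seed=5)
    b = sample_participant("S", 42, seed=5)
    np.testing.assert_array_equal(a.sigma, b.sigma)
    np.testing.assert_array_equal(a.bias, b.bias)


def test_group_noise_ordering_monte_carlo():
    # D participants are noisier than S on average; middle > side within both
    sig_s = np.stack(
        [sample_participant("S", 42, seed=i).sigma for i in range(500)]
    )
    sig_d = np.stack(
        [sample_participant("D", 42, seed=i + 500).sigma for i in range(500)]
    )
    assert sig_d.mean() > sig_s.mean()
    side, middle = side_middle_masks(42)
    for sig in (sig_s, sig_d):
        assert sig[:, middle].mean() > sig[:, side].mean()


def test_cohort_composition_matches_study():
    cohort = sample_cohort(7, 3, 42, seed=0)
    assert [p.group for p in cohort] == ["S"] * 7 + ["D"] * 3
    assert [p.participant_id for p in cohort] == list(range(1, 11))


def test_decision_std_tracks_latent_noise():
    quiet = sample_participant("S", 20, seed=1)
    noisy = Participant(2, "S", quiet.bias, quiet.sigma * 4.0, seed=1)
    std_q = decision_std(simulate_decision_matrix(quiet, 200))
    std_n = decision_std(simulate_decision_matrix(noisy, 200))
    assert std_n.mean() > std_q.mean()


def test_middle_materials_more_confused_than_side():
    # generator calibration: over >= 20 participants the middle band shows
    # more trial-to-trial decision spread than the side bands
    side, middle = side_middle_masks(42)
    diffs = []
    for p in sample_cohort(14, 6, 42, seed=3):
        stds = decision_std(simulate_decision_matrix(p, 20))
        diffs.append(stds[middle].mean() - stds[side].mean())
    t, pval = stats.ttest_1samp(diffs, 0.0, alternative="greater")
    assert pval < 0.01


# ------------------------------------------------------------ histograms


def test_histogram_identical_trials_one_hot():
    mx = simulate_decision_matrix(_noiseless_participant(), n_trials=20)
    h = decision_histogram(mx, 3)
    expected = np.zeros(6)
    expected[2] = 1.0
    np.testing.assert_array_equal(h.probs, expected)


def test_histogram_direct_count_and_moment_identity():
    ranks = np.array([[5, 1, 2, 3, 4, 6]] * 10 + [[6, 1, 2, 3, 4, 5]] * 10)
    mx = DecisionMatrix(participant_id=1, ranks=ranks)
    h = decision_histogram(mx, 1)
    np.testing.assert_allclose(h.probs, [0, 0, 0, 0, 0.5, 0.5])
    assert h.mean == pytest.approx(ranks[:, 0].mean())
    # all rows of the histogram table sum to one
    table = decision_histograms(mx)
    np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-9)


def test_histogram_mean_equals_matrix_column_mean():
    p = sample_participant("D", 8, seed=11)
    mx = simulate_decision_matrix(p, 25)
    for mid in range(1, 9):
        assert decision_histogram(mx, mid).mean == pytest.approx(
            mx.ranks[:, mid - 1].mean()
        )


# -------------------------------------------------------------- metrics


def test_decision_rmse_zero_for_reference_participant():
    ranks = np.tile([1, 2, 3], (4, 1))
    mx = DecisionMatrix(1, ranks)
    assert tactile_decision_rmse([mx], reference=np.array([1, 2, 3]))[0] == 0.0


def test_decision_rmse_constant_offset_is_one():
    mx = DecisionMatrix(1, np.array([[2, 3, 4], [2, 3, 4]]))
    assert tactile_decision_rmse([mx], reference=np.array([1, 2, 3]))[0] == pytest.approx(1.0)


def test_decision_rmse_matches_bruteforce_enumeration():
    # 2 participants x 2 trials x 3 materials, hand-enumerated double sum
    m1 = DecisionMatrix(1, np.array([[1, 2, 3], [2, 1, 3]]))
    m2 = DecisionMatrix(2, np.array([[3, 2, 1], [1, 3, 2]]))
    matrices = [m1, m2]
    all_ranks = np.concatenate([m1.ranks, m2.ranks])
    ref = all_ranks.mean(axis=0)
    expected = []
    for mx in matrices:
        acc = 0.0
        for i in range(mx.n_trials):
            for m in range(mx.n_materials):
                acc += (mx.ranks[i, m] - ref[m]) ** 2
        expected.append(np.sqrt(acc / (mx.n_trials * mx.n_materials)))
    np.testing.assert_allclose(
        tactile_decision_rmse(matrices), expected, atol=1e-12
    )


def test_decision_rmse_empty_input_rejected():
    with pytest.raises(ValueError):
        tactile_decision_rmse([])


def test_h_a_rmse_zero_when_avatar_matches():
    mx = DecisionMatrix(1, np.array([[1, 2, 3], [3, 2, 1]]))
    np.testing.assert_allclose(
        h_a_rmse([mx], mx.mean_decision()[None, :]), np.zeros(3), atol=1e-12
    )


def test_h_a_rmse_constant_offset_single_participant():
    mx = DecisionMatrix(1, np.array([[1, 2, 3], [1, 2, 3]]))
    avatar = mx.mean_decision()[None, :] + 2.0
    np.testing.assert_allclose(h_a_rmse([mx], avatar), 2.0 * np.ones(3))


def test_h_a_rmse_matches_direct_enumeration():
    m1 = DecisionMatrix(1, np.array([[1, 3, 2], [2, 3, 1]]))
    m2 = DecisionMatrix(2, np.array([[3, 1, 2], [3, 2, 1]]))
    avatar = np.array([[1.5, 2.5, 2.0], [2.0, 2.0, 2.0]])
    expected = []
    for m in range(3):
        acc = 0.0
        for s, mx in enumerate((m1, m2)):
            acc += (mx.ranks[:, m].mean() - avatar[s, m]) ** 2
        expected.append(np.sqrt(acc / 2))
    np.testing.assert_allclose(h_a_rmse([m1, m2], avatar), expected, atol=1e-12)


def test_h_a_rmse_material_mismatch_rejected():
    mx = DecisionMatrix(1, np.array([[1, 2, 3], [1, 2, 3]]))
    with pytest.raises(ValueError):
        h_a_rmse([mx], np.ones((1, 4)))


def test_decision_std_closed_forms():
    mx = DecisionMatrix(1, np.array([[4, 1], [6, 1]]))
    np.testing.assert_allclose(decision_std(mx), [1.0, 0.0])
    with pytest.raises(ValueError):
        decision_std(DecisionMatrix(1, np.array([[1, 2]])))


def test_decision_std_matches_textbook_formula():
    rng = np.random.default_rng(0)
    ranks = rng.integers(1, 10, size=(15, 6))
    mx = DecisionMatrix(1, ranks)
    expected = np.sqrt(
        np.mean((ranks - ranks.mean(axis=0, keepdims=True)) ** 2, axis=0)
    )
    np.testing.assert_allclose(decision_std(mx), expected, atol=1e-12)


# -------------------------------------------------------------- kurtosis


def test_kurtosis_two_point_symmetric_is_one():
    probs = np.zeros(10)
    probs[3] = probs[5] = 0.5
    assert histogram_kurtosis(probs) == pytest.approx(1.0)


def test_kurtosis_one_hot_undefined():
    probs = np.zeros(10)
    probs[4] = 1.0
    with pytest.raises(DegenerateHistogramError):
        histogram_kurtosis(probs)


def _numeric_kurtosis(probs):
    ranks = np.arange(1, len(probs) + 1, dtype=float)
    mu = np.sum(ranks * probs)
    cm = [np.sum((ranks - mu) ** k * probs) for k in (2, 4)]
    return cm[1] / cm[0] ** 2


def test_kurtosis_gaussian_sharper_than_uniform():
    ranks = np.arange(1, 22)
    narrow = np.exp(-0.5 * ((ranks - 11) / 1.5) ** 2)
    narrow /= narrow.sum()
    uniform = np.full(21, 1 / 21)
    k_narrow = histogram_kurtosis(narrow)
    k_uniform = histogram_kurtosis(uniform)
    assert k_narrow > k_uniform
    assert k_narrow == pytest.approx(_numeric_kurtosis(narrow), abs=1e-12)
    assert k_uniform == pytest.approx(_numeric_kurtosis(uniform), abs=1e-12)


# ---------------------------------------------------------------- groups


def test_split_groups_threshold_and_ties():
    assert split_groups([1.0, 1.0, 4.0]) == ["S", "S", "D"]
    assert split_groups([2.0, 2.0]) == ["D", "D"]  # at the mean -> D
    with pytest.raises(ValueError):
        split_groups([1.0])


def test_default_cohort_splits_seven_three():
    cohort = sample_cohort(7, 3, 42, seed=0)
    matrices = [simulate_decision_matrix(p, 20) for p in cohort]
    labels = split_groups(tactile_decision_rmse(matrices))
    assert labels == [p.group for p in cohort]
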