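"""Split-half estimators against exhaustive enumeration and theory."""

import itertools

import numpy as np
import pytest

from psyflex import (ConfigurationError, half_vs_half_switch_rate,
                     permutation_split_half, reversal_split_half,
                     spearman_brown)
from conftest import toy_log


# --- Spearman-Brown -------------------------------------------------------

@pytest.mark.parametrize("r, expected", [
    (0.5, 2 * 0.5 / 1.5),
    (1.0, 1.0),
    (0.87, 0.9305),    # published uncorrected/corrected pair
    (0.55, 0.7097),
])
def test_spearman_brown_values(r, expected):
    assert spearman_brown(r) == pytest.approx(expected, abs=5e-5)


def test_spearman_brown_monotone_and_bounded():
    grid = np.linspace(-0.99, 1.0, 200)
    vals = np.array([spearman_brown(r) for r in grid])
    assert (np.diff(vals) > 0).all()
    pos = vals[grid >= 0]
    assert pos.min() >= 0.0 and pos.max() <= 1.0


def test_spearman_brown_undefined_at_minus_one():
    with pytest.raises(ConfigurationError):
        spearman_brown(-1.0)


# --- enumeration oracles --------------------------------------------------

def _enumerate_cost_splits(arrays):
    """All equally likely (half1 index, half2 index) values for one subject
    holding (switch, baseline) trial arrays; halves are unordered picks of
    ceil(L/2) trials into split 1."""
    sw, ba = (np.asarray(a, dtype=float) for a in arrays)
    options = []
    for arr in (sw, ba):
        h = (len(arr) + 1) // 2
        halves = []
        for combo in itertools.combinations(range(len(arr)), h):
            rest = [i for i in range(len(arr)) if i not in combo]
            halves.append((arr[list(combo)].mean(), arr[rest].mean()))
        options.append(halves)
    return [(s1 - b1, s2 - b2)
            for (s1, s2), (b1, b2) in itertools.product(*options)]


def _exhaustive_expected_r(subject_options):
    """Expected split-half correlation over every joint assignment of
    subject-level half splits (uniform, independent across subjects)."""
    rs = []
    for combo in itertools.product(*subject_options):
        h1 = np.array([c[0] for c in combo])
        h2 = np.array([c[1] for c in combo])
        if h1.std() == 0 or h2.std() == 0:
            continue
        rs.append(np.corrcoef(h1, h2)[0, 1])
    return float(np.mean(rs))


def test_cost_split_half_matches_enumeration():
    """4 subjects x 2 trials per condition: the Monte-Carlo estimate equals
    the exhaustive average over all half-splits."""
    rng = np.random.default_rng(2)
    subject_values = {
        s: (rng.normal(1000 + 150 * s, 40, 2), rng.normal(700, 30, 2))
        for s in range(4)
    }
    oracle = _exhaustive_expected_r(
        [_enumerate_cost_splits(v) for v in subject_values.values()])
    est = permutation_split_half(subject_values, n_iterations=40000, seed=7)
    assert est.r_uncorrected == pytest.approx(oracle, abs=0.01)


def test_reversal_split_half_matches_enumeration():
    """3 subjects x 4 reversals vs the full enumeration over shuffles."""
    lists = {0: [1, 3, 0, 2], 1: [0, 0, 1, 1], 2: [4, 2, 3, 5]}
    options = []
    for v in lists.values():
        arr = np.asarray(v, dtype=float)
        halves = []
        for combo in itertools.combinations(range(4), 2):
            rest = [i for i in range(4) if i not in combo]
            halves.append((arr[list(combo)].mean(), arr[rest].mean()))
        options.append(halves)
    oracle = _exhaustive_expected_r(options)
    est = reversal_split_half(lists, n_iterations=40000, seed=3)
    assert est.r_uncorrected == pytest.approx(oracle, abs=0.01)


# --- limiting and degenerate cases ---------------------------------------

def test_noiseless_subjects_give_perfect_reliability():
    """Zero within-subject variance with between-subject spread: r = 1 in
    every iteration."""
    subject_values = {s: (np.full(10, 900.0 + 80 * s), np.full(10, 600.0))
                      for s in range(6)}
    est = permutation_split_half(subject_values, n_iterations=200, seed=1)
    assert est.r_uncorrected == pytest.approx(1.0)
    assert est.r_sb == pytest.approx(1.0)
    assert est.ci95 == (pytest.approx(1.0), pytest.approx(1.0))


def test_constant_lists_give_r_one():
    lists = {s: [s + 1.0] * 10 for s in range(5)}
    est = reversal_split_half(lists, n_iterations=100, seed=2)
    assert est.r_uncorrected == pytest.approx(1.0)


def test_single_trial_subject_dropped_with_warning():
    subject_values = {0: (np.array([900.0]), np.array([600.0, 620.0]))}
    subject_values.update({s: (np.random.default_rng(s).normal(900, 50, 4),
                               np.random.default_rng(s + 9).normal(600, 50, 4))
                           for s in range(1, 5)})
    est = permutation_split_half(subject_values, n_iterations=50, seed=0)
    assert est.n_subjects == 4
    assert any("fewer than 2 trials" in w for w in est.warnings)


def test_convergence_across_seeds(small_pre):
    """Two 2,000-iteration runs with different seeds agree within the
    percentile-CI width."""
    from psyflex import split_half_from_log
    a = split_half_from_log(small_pre, "sc_rt_cog", n_iterations=2000, seed=1)
    b = split_half_from_log(small_pre, "sc_rt_cog", n_iterations=2000, seed=99)
    ci_width = a.ci95[1] - a.ci95[0]
    assert abs(a.r_uncorrected - b.r_uncorrected) < ci_width


# --- half-vs-half switch rate --------------------------------------------

def _ambiguous_log(switch_matrix):
    rows = []
    for s, trials in enumerate(switch_matrix):
        for sw in trials:
            rows.append((s, "cognitive", "ambiguous", "parity", "left",
                         "right" if sw else "left", 1, 800.0))
    return toy_log(rows)


def test_half_vs_half_perfectly_consistent_subjects():
    # halves identical per subject: k/2 switches in each half of 20 trials
    mat = [([1] * (k // 2) + [0] * (10 - k // 2)) * 2 for k in (2, 6, 10, 14, 18)]
    est = half_vs_half_switch_rate(_ambiguous_log(mat))
    assert est.r_uncorrected == pytest.approx(1.0)
    assert est.r_sb is None


def test_half_vs_half_matches_binomial_theory():
    """Heterogeneous switch propensities, 20 trials: the estimate sits within
    .05 of the analytic reliability Var(h theta) / (Var(h theta) +
    h E[theta(1-theta)]) for h = 10-trial half counts."""
    rng = np.random.default_rng(12)
    n, h = 500, 10
    theta = rng.uniform(0.0, 1.0, n)
    mat = (rng.random((n, 2 * h)) < theta[:, None]).astype(int)
    est = half_vs_half_switch_rate(_ambiguous_log(mat))
    var_b = (h ** 2) * theta.var()
    var_w = h * np.mean(theta * (1 - theta))
    expected = var_b / (var_b + var_w)
    assert est.r_uncorrected == pytest.approx(expected, abs=0.05)


def test_two_subjects_flagged_unstable():
    mat = [[0, 0, 0, 0], [1, 1, 0, 1]]
    est = half_vs_half_switch_rate(_ambiguous_log(mat))
    assert abs(est.r_uncorrected) == pytest.approx(1.0)
    assert any("degenerate" in w for w in est.warnings)


def test_zero_variance_half_reported_missing():
    mat = [[1, 0] * 5, [1, 0] * 5, [1, 0] * 5]   # identical counts everywhere
    est = half_vs_half_switch_rate(_ambiguous_log(mat))
    assert np.isnan(est.r_uncorrected)


def test_random_splits_of_binary_data_overstate_reliability():
    """The degeneracy the half-vs-half procedure avoids: random splits of
    binary switch/stay data with within-session dependence distribute each
    subject's response runs evenly over both halves, so the estimate exceeds
    the generative (switch-propensity) reliability."""
    rng = np.random.default_rng(5)
    n, L = 60, 20
    theta = rng.uniform(0.2, 0.8, n)
    # strong serial dependence: the subject re-decides stay-vs-switch only
    # every 5 trials, so responses come in runs
    block = (rng.random((n, L // 5)) < theta[:, None]).astype(float)
    trials = np.repeat(block, 5, axis=1)
    subject_values = {s: (trials[s],) for s in range(n)}
    est = permutation_split_half(subject_values, n_iterations=2000, seed=6,
                                 signs=(1,))
    h = L // 2
    analytic = theta.var() / (theta.var() + np.mean(theta * (1 - theta)) / h)
    assert est.r_uncorrected > analytic + 0.05
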