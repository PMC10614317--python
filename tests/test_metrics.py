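"""AUC/DeLong, NRI, IDI and Hosmer-Lemeshow: worked examples, oracles, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from incrisk import (
    DataError,
    auc_mann_whitney,
    delong_paired_test,
    hosmer_lemeshow,
    idi,
    nri,
)


def brute_force_auc(scores, labels):
    """Pair-enumeration oracle: 1 per concordant pair, 0.5 per tie."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    ev, ne = s[y], s[~y]
    wins = (ev[:, None] > ne[None, :]).sum() + 0.5 * (ev[:, None] == ne[None, :]).sum()
    return wins / (len(ev) * len(ne))


# -- AUC ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.5, 0.5], [1, 0], 0.5),
        ([0.9, 0.3, 0.4, 0.1], [1, 1, 0, 0], 0.75),
    ],
)
def test_auc_worked_examples(scores, labels, expected):
    assert auc_mann_whitney(scores, labels).auc == pytest.approx(expected, abs=1e-12)


def test_auc_midrank_equals_pair_enumeration_on_random_instances():
    rng = np.random.default_rng(10)
    for _ in range(300):
        n = rng.integers(4, 201)
        m = rng.integers(1, n)
        y = np.r_[np.ones(m), np.zeros(n - m)].astype(int)
        # coarse grid forces plenty of ties
        s = rng.integers(0, 6, n) / 5 + rng.choice([0.0, 0.001]) * rng.integers(0, 3, n)
        assert auc_mann_whitney(s, y).auc == pytest.approx(brute_force_auc(s, y), abs=1e-12)


@given(
    st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=2, max_size=40),
    st.data(),
)
def test_auc_matches_oracle_under_arbitrary_ties(scores, data):
    n = len(scores)
    m = data.draw(st.integers(min_value=1, max_value=n - 1))
    labels = np.r_[np.ones(m), np.zeros(n - m)].astype(int)
    assert auc_mann_whitney(scores, labels).auc == pytest.approx(
        brute_force_auc(scores, labels), abs=1e-12
    )


def test_auc_requires_both_classes():
    with pytest.raises(DataError):
        auc_mann_whitney([0.1, 0.2], [1, 1])


def test_auc_ci_is_clipped_to_unit_interval():
    res = auc_mann_whitney([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert res.ci95[0] >= 0.0 and res.ci95[1] <= 1.0


# -- DeLong -------------------------------------------------------------------


def test_identical_scores_give_zero_delta_and_p_one():
    rng = np.random.default_rng(11)
    s = rng.standard_normal(40)
    y = (rng.random(40) < 0.4).astype(int)
    y[0], y[1] = 1, 0
    delta, z, p = delong_paired_test(s, s, y)
    assert delta == 0.0 and p == 1.0


def test_delong_variance_close_to_jackknife():
    rng = np.random.default_rng(12)
    for m, n0 in [(12, 18), (80, 120)]:
        s = np.r_[rng.normal(1, 1, m), rng.normal(0, 1, n0)]
        y = np.r_[np.ones(m), np.zeros(n0)].astype(int)
        res = auc_mann_whitney(s, y)
        n = m + n0
        thetas = np.array(
            [auc_mann_whitney(np.delete(s, i), np.delete(y, i)).auc for i in range(n)]
        )
        var_jack = (n - 1) / n * np.sum((thetas - thetas.mean()) ** 2)
        assert res.variance == pytest.approx(var_jack, rel=0.10)


def test_delong_detects_a_genuinely_better_marker():
    rng = np.random.default_rng(13)
    n = 400
    y = np.r_[np.ones(150), np.zeros(250)].astype(int)
    good = y + 0.5 * rng.standard_normal(n)
    bad = y + 3.0 * rng.standard_normal(n)
    delta, z, p = delong_paired_test(bad, good, y)
    assert delta > 0 and p < 1e-4


# -- NRI ----------------------------------------------------------------------


def test_nri_identity_gives_zero_with_p_one():
    p_ref = [0.2, 0.7, 0.4, 0.9]
    res = nri(p_ref, p_ref, [1, 1, 0, 0])
    assert res.nri == 0.0 and res.p == 1.0


def test_nri_hand_counted_example():
    """Events: one up-crossing, one down-crossing (net 0); non-events: one of
    two reclassified down (net 0.5)."""
    p_ref = [0.3, 0.4, 0.6, 0.7, 0.6, 0.3]
    p_new = [0.6, 0.4, 0.6, 0.4, 0.4, 0.3]
    labels = [1, 1, 1, 1, 0, 0]
    res = nri(p_ref, p_new, labels)
    assert res.event_net == pytest.approx(0.0)
    assert res.nonevent_net == pytest.approx(0.5)
    assert res.nri == pytest.approx(0.5)
    assert res.percent_reclassified_by_stratum["nonevents"] == pytest.approx(50.0)


def test_nri_attains_its_printed_extremes():
    p_ref = [0.1] * 10 + [0.9] * 10
    p_new = [0.9] * 10 + [0.1] * 10
    labels = [1] * 10 + [0] * 10
    assert nri(p_ref, p_new, labels).nri == pytest.approx(2.0)
    assert nri(p_new, p_ref, labels).nri == pytest.approx(-2.0)


def test_threshold_boundary_counts_as_high_risk():
    res = nri([0.49, 0.4], [0.5, 0.4], [1, 0])
    assert res.event_net == pytest.approx(1.0)


def test_nri_invariant_to_monotone_maps_fixing_the_threshold():
    rng = np.random.default_rng(14)
    p_ref = rng.random(200)
    p_new = rng.random(200)
    y = (rng.random(200) < 0.4).astype(int)
    y[0], y[1] = 1, 0

    def warp(p):  # strictly monotone, fixes 0.5 and the side of it
        p = np.asarray(p)
        lo = 0.5 * (p / 0.5) ** 2
        hi = 0.5 + 0.5 * (np.clip(p - 0.5, 0.0, None) / 0.5) ** 0.7
        return np.where(p < 0.5, lo, hi)

    a = nri(p_ref, p_new, y)
    b = nri(warp(p_ref), warp(p_new), y)
    assert a.nri == pytest.approx(b.nri, abs=1e-12)


# -- IDI ----------------------------------------------------------------------


def test_idi_identity_is_zero():
    p_ref = [0.2, 0.7, 0.4]
    assert idi(p_ref, p_ref, [1, 0, 0]).idi == 0.0


def test_idi_hand_arithmetic_example():
    p_ref = [0.2, 0.4, 0.5, 0.3]
    p_new = [0.5, 0.5, 0.2, 0.2]
    labels = [1, 1, 0, 0]
    res = idi(p_ref, p_new, labels)
    assert res.delta_event_mean == pytest.approx(0.2)
    assert res.delta_nonevent_mean == pytest.approx(-0.2)
    assert res.idi == pytest.approx(0.4)


def test_idi_attains_its_printed_extremes():
    p_ref = [0.0] * 5 + [1.0] * 5
    p_new = [1.0] * 5 + [0.0] * 5
    labels = [1] * 5 + [0] * 5
    assert idi(p_ref, p_new, labels).idi == pytest.approx(2.0)
    assert idi(p_new, p_ref, labels).idi == pytest.approx(-2.0)


def test_idi_equals_integral_formulation():
    """Trapezoidal integral of sensitivity minus one-minus-specificity over a
    fine cutoff grid reproduces the mean-difference IDI."""
    rng = np.random.default_rng(15)
    n = 500
    y = (rng.random(n) < 0.35).astype(int)
    p_ref = np.clip(0.3 * y + 0.3 * rng.random(n), 0.001, 0.999)
    p_new = np.clip(0.5 * y + 0.25 * rng.random(n), 0.001, 0.999)

    def integral_is_ip(p):
        grid = np.linspace(0, 1, 4001)
        sens = [(p[y == 1] >= c).mean() for c in grid]
        fpr = [(p[y == 0] >= c).mean() for c in grid]
        return np.trapezoid(sens, grid), np.trapezoid(fpr, grid)

    is_new, ip_new = integral_is_ip(p_new)
    is_ref, ip_ref = integral_is_ip(p_ref)
    integral_idi = (is_new - is_ref) - (ip_new - ip_ref)
    assert idi(p_ref, p_new, y).idi == pytest.approx(integral_idi, abs=1e-3)


# -- antisymmetry & range (shared) -------------------------------------------


@given(st.data())
def test_nri_idi_antisymmetry_and_range(data):
    n = data.draw(st.integers(min_value=4, max_value=60))
    probs = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)
    p_ref = np.array(data.draw(st.lists(probs, min_size=n, max_size=n)))
    p_new = np.array(data.draw(st.lists(probs, min_size=n, max_size=n)))
    m = data.draw(st.integers(min_value=1, max_value=n - 1))
    y = np.r_[np.ones(m), np.zeros(n - m)].astype(int)
    r_ab, r_ba = nri(p_ref, p_new, y), nri(p_new, p_ref, y)
    assert r_ab.nri == pytest.approx(-r_ba.nri, abs=1e-12)
    assert -2.0 <= r_ab.nri <= 2.0
    i_ab, i_ba = idi(p_ref, p_new, y), idi(p_new, p_ref, y)
    assert i_ab.idi == pytest.approx(-i_ba.idi, abs=1e-12)
    assert -2.0 <= i_ab.idi <= 2.0


# -- Hosmer-Lemeshow ----------------------------------------------------------


def test_hl_zero_when_observed_equals_expected():
    # two groups of 4 with p=0.25 and exactly 1 event each
    p = [0.25] * 4 + [0.75] * 4
    y = [1, 0, 0, 0, 1, 1, 1, 0]
    res = hosmer_lemeshow(p, y, n_groups=2)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)


def test_hl_two_group_hand_example():
    p = [0.2] * 5 + [0.8] * 5
    y = [1, 1, 0, 0, 0, 1, 1, 1, 0, 0]
    res = hosmer_lemeshow(p, y, n_groups=2)
    assert res.chi2 == pytest.approx(2.5, abs=1e-12)
    assert res.n_groups == 2


def test_hl_groups_partition_all_cases():
    rng = np.random.default_rng(16)
    p = rng.uniform(0.05, 0.95, 237)
    y = (rng.random(237) < p).astype(int)
    res = hosmer_lemeshow(p, y, n_groups=10)
    assert res.groups["n"].sum() == 237
    assert res.df == res.n_groups - 2


def test_hl_ties_stay_in_the_lower_group():
    p = [0.3] * 7 + [0.7] * 3
    y = [0] * 7 + [1] * 3
    res = hosmer_lemeshow(p, y, n_groups=2)
    # the tie-block of 0.3s cannot be split: group sizes are 7 and 3
    assert res.groups["n"].tolist() == [7, 3]


def test_hl_rejects_out_of_range_probabilities():
    with pytest.raises(DataError):
        hosmer_lemeshow([0.0, 0.5, 0.7, 0.2], [0, 1, 1, 0], n_groups=2)
    with pytest.raises(DataError, match="n_groups"):
        hosmer_lemeshow([0.4, 0.6], [0, 1], n_groups=10)


# -- ROC overlay --------------------------------------------------------------


def test_roc_points_trace_the_empirical_curve():
    from incrisk import roc_points

    fpr, tpr = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert fpr[0] == 0.0 and tpr[-1] == 1.0
    assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()
    # perfect separation: TPR reaches 1 while FPR is still 0
    assert tpr[np.flatnonzero(fpr > 0)[0] - 1] == 1.0


def test_roc_overlay_draws_one_curve_per_model(tmp_path):
    import matplotlib
    matplotlib.use("Agg")
    from incrisk import plot_roc_overlay

    rng = np.random.default_rng(17)
    y = np.r_[np.ones(30), np.zeros(70)].astype(int)
    ax = plot_roc_overlay(
        {"ref": y + rng.standard_normal(100), "new": y + 0.5 * rng.standard_normal(100)},
        y,
    )
    assert len(ax.get_lines()) == 3  # two curves + diagonal
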