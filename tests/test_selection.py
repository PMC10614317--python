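"""Univariate screening, stepwise selection, and the nested model specs."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from incrisk import (
    CohortSimulator,
    CohortTable,
    ConfigurationError,
    DataDictionary,
    dichotomize,
    dictionary_for_params,
    stepwise_select,
    table2_model_specs,
    univariate_screen,
)


def _covariate_cohort(columns: dict) -> CohortTable:
    n = len(next(iter(columns.values())))
    roles = {"patient_id": "id", "baseline_score": "score", "cac_agatston": "cac"}
    df = pd.DataFrame(columns)
    for c in columns:
        roles[c] = "covariate"
    df["patient_id"] = [f"P{i}" for i in range(n)]
    df["baseline_score"] = 0.5
    df["cac_agatston"] = 0.0
    return CohortTable(df, DataDictionary(roles=roles))


def _marker_cohort(markers: dict) -> CohortTable:
    n = len(next(iter(markers.values())))
    roles = {"patient_id": "id", "baseline_score": "score", "cac_agatston": "cac"}
    assays = {}
    df = pd.DataFrame(markers)
    for c in markers:
        roles[c] = "marker"
        assays[c] = "ELISA"
    df["patient_id"] = [f"P{i}" for i in range(n)]
    df["baseline_score"] = 0.5
    df["cac_agatston"] = 0.0
    return CohortTable(df, DataDictionary(roles=roles, assays=assays))


def test_constant_marker_is_non_estimable():
    y = np.r_[np.ones(20), np.zeros(20)]
    t = _marker_cohort({"flat": np.full(40, 3.0)})
    res = univariate_screen(t, y, markers=["flat"])
    assert not res.table.loc["flat", "estimable"]
    assert res.significant == []


def test_strong_signal_marker_has_large_positive_odds_ratio():
    rng = np.random.default_rng(0)
    y = np.r_[np.ones(50), np.zeros(50)]
    marker = np.exp(y + 0.5 * rng.standard_normal(100))
    t = _marker_cohort({"sig": marker})
    res = univariate_screen(t, y, markers=["sig"])
    row = res.table.loc["sig"]
    assert row["estimable"]
    assert row["odds_ratio"] > 1
    assert row["p"] < 1e-6


def test_separating_marker_is_flagged_non_estimable():
    """A marker that perfectly separates the outcome has no finite MLE and is
    excluded from the significance list rather than reported with a huge OR."""
    y = np.r_[np.ones(50), np.zeros(50)]
    marker = np.exp(y)  # two disjoint concentration bands
    t = _marker_cohort({"sep": marker})
    res = univariate_screen(t, y, markers=["sep"])
    assert not res.table.loc["sep", "estimable"]
    assert res.significant == []


def test_screen_reports_ci_containing_point_estimate(study_cohort):
    y = dichotomize(study_cohort, 100)
    res = univariate_screen(study_cohort, y)
    est = res.table[res.table["estimable"]]
    assert ((est["ci_low"] <= est["odds_ratio"]) & (est["odds_ratio"] <= est["ci_high"])).all()
    # significance flag is exactly p < alpha
    assert set(res.significant) == set(est.index[est["p"] < res.alpha])


def test_active_markers_screen_significant_more_often_than_inert(study_params):
    """Known-truth simulation: flag rates of signal vs inert markers."""
    active = [m.name for m in study_params.marker_panel if m.effect != 0]
    inert = [m.name for m in study_params.marker_panel if m.effect == 0]
    dd = dictionary_for_params(study_params)
    sim = CohortSimulator(study_params)
    hits = {name: 0 for name in active + inert}
    reps = 150
    for s in range(reps):
        t = CohortTable(sim.sample(n=561, seed=3000 + s), dd)
        res = univariate_screen(t, dichotomize(t, 100))
        for name in res.significant:
            hits[name] += 1
    active_rate = np.mean([hits[m] / reps for m in active])
    inert_rate = np.mean([hits[m] / reps for m in inert])
    assert active_rate > 0.5
    assert inert_rate < 0.15
    assert active_rate > inert_rate + 0.4


def test_stepwise_returns_empty_when_nothing_passes_entry():
    rng = np.random.default_rng(1)
    y = (rng.random(300) < 0.3).astype(float)
    t = _covariate_cohort({f"x{i}": rng.standard_normal(300) for i in range(4)})
    spec = stepwise_select(t, y, [f"x{i}" for i in range(4)], p_enter=1e-6, p_remove=1e-5)
    assert spec.predictors == ()


def test_stepwise_recovers_single_strong_predictor():
    """One strong predictor (1.0 SD effect) among 9 inert, n=2000: with a
    stringent entry threshold the exact set {strong} is selected in >=95%
    of seeds (a 0.05 entry admits an inert term whenever min of 9 null
    p-values dips below it, so the exact-set rate is necessarily lower)."""
    rng = np.random.default_rng(2)
    exact = 0
    reps = 60
    for _ in range(reps):
        x = rng.standard_normal((2000, 10))
        y = (rng.random(2000) < expit(-0.5 + x[:, 0])).astype(float)
        t = _covariate_cohort({"strong": x[:, 0],
                               **{f"inert{i}": x[:, i + 1] for i in range(9)}})
        spec = stepwise_select(t, y, ["strong"] + [f"inert{i}" for i in range(9)],
                               p_enter=0.005, p_remove=0.01)
        exact += set(spec.predictors) == {"strong"}
    assert exact / reps >= 0.95


def test_stepwise_contract_on_study_markers(study_cohort):
    """Selection is a subset of the candidates and every retained term is
    significant at the removal threshold."""
    from incrisk import MarkerTransform, fit_logistic, ModelSpec

    t = study_cohort
    cands = []
    for name in ["cystatin_c", "osteopontin", "ccl18", "ykl40",
                 "cd40_ligand", "leptin", "osteoprotegerin", "tnfr1"]:
        t.data["z_" + name] = MarkerTransform().fit_transform(t.data[name])
        cands.append("z_" + name)
    y = dichotomize(t, 100)
    spec = stepwise_select(t, y, cands)
    assert set(spec.predictors) <= set(cands)
    if spec.predictors:
        fit = fit_logistic(t, y, ModelSpec("sel", spec.predictors))
        assert (fit.wald_table()["p"].iloc[1:] < 0.10).all()


def test_table2_specs_cover_the_four_nested_models():
    specs = table2_model_specs(["z_a", "z_b"], ["z_m"])
    assert [s.name for s in specs] == [
        "reference", "reference+cytokines", "reference+MRM", "reference+cytokines+MRM",
    ]
    assert [s.label for s in specs] == [
        "ACC/AHA", "ACC/AHA + cytokines", "ACC/AHA + MRM", "ACC/AHA + cytokines + MRM",
    ]
    assert specs[0].predictors == ("baseline_score",)
    assert set(specs[3].predictors) == {"baseline_score", "z_a", "z_b", "z_m"}


def test_table2_specs_warn_on_empty_mrm_panel():
    with pytest.warns(UserWarning, match="MRM"):
        specs = table2_model_specs(["z_a"], [])
    assert specs[1].predictors == specs[3].predictors


def test_table2_specs_reject_overlapping_panels():
    with pytest.raises(ConfigurationError, match="overlap"):
        table2_model_specs(["z_a"], ["z_a"])
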