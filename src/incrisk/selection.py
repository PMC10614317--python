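"""Biomarker screening and stepwise selection.

The univariate screen regresses the outcome on one transformed marker at a
time (default transform: natural log, then z-standardization, so odds ratios
are per 1 SD of log concentration) and flags markers with Wald p below
alpha. The stepwise procedure is forward selection with backward
elimination on Wald p-values, the behaviour of classic stepwise logistic
routines: default entry p 0.05, removal p 0.10.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .errors import ConfigurationError, DataError, IncriskError
from .logistic import FittedLogistic, LogisticIRLS, ModelSpec, fit_logistic

__all__ = [
    "MarkerTransform",
    "ScreenResult",
    "univariate_screen",
    "stepwise_select",
    "table2_model_specs",
]


class MarkerTransform:
    """Log + z-standardization of marker columns, sklearn-transformer style.

    Standardization constants are learned on the fitting (training) data and
    reapplied verbatim elsewhere, so validation-half predictions use
    training-derived scales.
    """

    def __init__(self, log: bool = True, standardize: bool = True):
        self.log = log
        self.standardize = standardize

    def fit(self, values: pd.Series | np.ndarray):
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if self.log:
            if (x <= 0).any():
                raise DataError("log transform requires strictly positive marker values")
            x = np.log(x)
        self.mean_ = float(np.mean(x)) if self.standardize else 0.0
        self.sd_ = float(np.std(x, ddof=0)) if self.standardize else 1.0
        return self

    def transform(self, values) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        out = np.full(x.shape, np.nan)
        ok = np.isfinite(x)
        v = x[ok]
        if self.log:
            if (v <= 0).any():
                raise DataError("log transform requires strictly positive marker values")
            v = np.log(v)
        if self.standardize:
            if self.sd_ == 0:
                raise DataError("constant marker: zero SD under transform")
            v = (v - self.mean_) / self.sd_
        out[ok] = v
        return out

    def fit_transform(self, values) -> np.ndarray:
        return self.fit(values).transform(values)


@dataclass
class ScreenResult:
    """Per-marker univariate associations with the dichotomized outcome."""

    table: pd.DataFrame  # index=marker; odds_ratio, ci_low, ci_high, p, n, estimable
    alpha: float

    @property
    def significant(self) -> list[str]:
        t = self.table
        return list(t.index[t["estimable"] & (t["p"] < self.alpha)])

    def to_dict(self) -> dict:
        return {"alpha": self.alpha,
                "markers": self.table.reset_index().to_dict(orient="records")}


def univariate_screen(table: CohortTable, outcome, markers=None,
                      alpha: float = 0.05,
                      transform: MarkerTransform | None = None,
                      adjust_for: tuple[str, ...] = ()) -> ScreenResult:
    """Screen each marker in a one-at-a-time logistic model.

    Markers with missing values (MRM panel) are screened on their available
    cases. Constant or separation-inducing markers are flagged non-estimable
    and excluded from the significance list. ``adjust_for`` optionally adds
    covariate columns to every screening model.
    """
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")
    dd = table.dictionary
    markers = list(markers) if markers is not None else dd.markers()
    missing = [m for m in markers if m not in table.data.columns]
    if missing:
        raise DataError(f"marker columns absent from cohort: {missing}")
    y_all = np.asarray(outcome, dtype=float)
    rows = []
    for name in markers:
        raw = table.data[name].to_numpy(dtype=float)
        ok = np.isfinite(raw)
        rec = {"marker": name, "n": int(ok.sum()), "odds_ratio": np.nan,
               "ci_low": np.nan, "ci_high": np.nan, "p": np.nan, "estimable": False}
        try:
            tr = (transform or MarkerTransform()).fit(raw[ok])
            z = tr.transform(raw[ok])
            X = z[:, None]
            if adjust_for:
                X = np.column_stack([z] + [
                    table.data[c].to_numpy(dtype=float)[ok] for c in adjust_for
                ])
            est = LogisticIRLS().fit(X, y_all[ok])
            wt = est.wald_table()
            beta, se, p = wt.loc[1, "estimate"], wt.loc[1, "se"], wt.loc[1, "p"]
            rec.update(
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.959963984540054 * se)),
                ci_high=float(np.exp(beta + 1.959963984540054 * se)),
                p=float(p),
                estimable=True,
            )
        except IncriskError:
            pass  # constant marker, separation, or non-convergence: non-estimable
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("marker")
    return ScreenResult(table=out, alpha=alpha)


def _wald_p(fit: FittedLogistic) -> pd.Series:
    """Wald p per predictor (intercept excluded)."""
    return fit.wald_table()["p"].iloc[1:]


def stepwise_select(table: CohortTable, outcome, candidates,
                    p_enter: float = 0.05, p_remove: float = 0.10,
                    name: str = "stepwise") -> ModelSpec:
    """Forward stepwise with backward elimination on Wald p-values.

    At each step the candidate with the smallest entry p < ``p_enter`` joins
    the model (ties broken on p then name); afterwards any included term
    whose p exceeds ``p_remove`` is dropped, worst first. Terminates when no
    addition or removal is possible; may return an empty spec.
    """
    if p_enter > p_remove:
        raise ConfigurationError("p_enter must be <= p_remove")
    candidates = list(candidates)
    missing = [c for c in candidates if c not in table.data.columns]
    if missing:
        raise DataError(f"candidate columns absent from cohort: {missing}")
    y = np.asarray(outcome, dtype=float)
    included: list[str] = []
    seen_states = set()
    for _ in range(4 * len(candidates) + 8):
        state = tuple(sorted(included))
        if state in seen_states:
            break  # cycle guard: no new state, stop
        seen_states.add(state)
        # forward step
        entries = []
        for cand in candidates:
            if cand in included:
                continue
            try:
                fit = fit_logistic(table, y, ModelSpec("trial", (*included, cand)))
            except IncriskError:
                continue
            entries.append((float(_wald_p(fit).iloc[-1]), cand))
        entries.sort()
        added = False
        if entries and entries[0][0] < p_enter:
            included.append(entries[0][1])
            added = True
        # backward step(s)
        removed = False
        while included:
            fit = fit_logistic(table, y, ModelSpec("trial", tuple(included)))
            pvals = _wald_p(fit)
            worst = pvals.idxmax()
            if float(pvals.loc[worst]) > p_remove:
                included.remove(worst)
                removed = True
            else:
                break
        if not added and not removed:
            break
    return ModelSpec(name, tuple(included))


REFERENCE = "reference"
REF_CYTOKINES = "reference+cytokines"
REF_MRM = "reference+MRM"
REF_COMBINED = "reference+cytokines+MRM"

_LABELS = {
    REFERENCE: "ACC/AHA",
    REF_CYTOKINES: "ACC/AHA + cytokines",
    REF_MRM: "ACC/AHA + MRM",
    REF_COMBINED: "ACC/AHA + cytokines + MRM",
}


def table2_model_specs(selected_elisa, selected_mrm,
                       score_column: str = "baseline_score") -> list[ModelSpec]:
    """The four nested model specifications: reference score alone, plus the
    ELISA (cytokine) panel, plus the MRM panel, plus both."""
    selected_elisa = tuple(selected_elisa)
    selected_mrm = tuple(selected_mrm)
    overlap = set(selected_elisa) & set(selected_mrm)
    if overlap:
        raise ConfigurationError(f"ELISA and MRM panels overlap: {sorted(overlap)}")
    if not selected_mrm:
        warnings.warn("empty MRM panel: the MRM and combined specs coincide with "
                      "the cytokine spec", stacklevel=2)
    if not selected_elisa:
        warnings.warn("empty cytokine panel: the cytokine spec coincides with the "
                      "reference", stacklevel=2)
    return [
        ModelSpec(REFERENCE, (score_column,), _LABELS[REFERENCE]),
        ModelSpec(REF_CYTOKINES, (score_column, *selected_elisa), _LABELS[REF_CYTOKINES]),
        ModelSpec(REF_MRM, (score_column, *selected_mrm), _LABELS[REF_MRM]),
        ModelSpec(REF_COMBINED, (score_column, *selected_elisa, *selected_mrm),
                  _LABELS[REF_COMBINED]),
    ]
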