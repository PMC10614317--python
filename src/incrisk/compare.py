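"""Model-comparison engine: bundle discrimination, reclassification and
calibration statistics for a new model against a nested reference, on a
common case set."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable, complete_case_subset
from .errors import DataError
from .logistic import FittedLogistic
from .metrics import (
    AUCResult,
    HLResult,
    IDIResult,
    NRIResult,
    auc_mann_whitney,
    delong_paired_test,
    hosmer_lemeshow,
    idi,
    nri,
)

__all__ = ["ComparisonResult", "compare_models"]


@dataclass
class ComparisonResult:
    """Reference-vs-new model comparison on one outcome and cohort half."""

    outcome_threshold: float
    cohort_label: str
    reference_name: str
    new_name: str
    auc_reference: AUCResult
    auc_new: AUCResult
    delta_auc: float
    delong_z: float
    delong_p: float
    nri: NRIResult
    idi: IDIResult
    hl_reference: HLResult
    hl_new: HLResult
    n_common_cases: int

    def to_dict(self) -> dict:
        return {
            "outcome_threshold": self.outcome_threshold,
            "cohort_label": self.cohort_label,
            "reference_name": self.reference_name,
            "new_name": self.new_name,
            "auc_reference": self.auc_reference.to_dict(),
            "auc_new": self.auc_new.to_dict(),
            "delta_auc": self.delta_auc,
            "delong_z": self.delong_z,
            "delong_p": self.delong_p,
            "nri": self.nri.to_dict(),
            "idi": self.idi.to_dict(),
            "hl_reference": self.hl_reference.to_dict(),
            "hl_new": self.hl_new.to_dict(),
            "n_common_cases": self.n_common_cases,
        }


def compare_models(fit_ref: FittedLogistic, fit_new: FittedLogistic,
                   table: CohortTable, outcome, cohort_label: str = "",
                   nri_threshold: float = 0.5, hl_groups: int = 10,
                   outcome_threshold: float = float("nan")) -> ComparisonResult:
    """Evaluate both fitted models on the same cases of ``table``.

    Both models must have been fit on an identical case set (enforce by
    fitting on the complete-case subset of the union of predictors). The
    evaluation table is restricted to its own complete cases on that union,
    so both ROC curves derive from the same cases; when ``table`` is the
    validation half, the training-fit coefficients are simply applied.
    """
    if tuple(fit_ref.case_ids) != tuple(fit_new.case_ids):
        raise DataError(
            "reference and new model were fit on different case sets; refit both "
            "on the complete-case subset of the union of their predictors"
        )
    union = list(dict.fromkeys(fit_ref.spec.predictors + fit_new.spec.predictors))
    sub = complete_case_subset(table, union)
    y = np.asarray(outcome, dtype=float)
    if len(y) == len(table):
        y = y[np.asarray(table.data.index.get_indexer(sub.data.index))]
    elif len(y) != len(sub):
        raise DataError("outcome length matches neither the table nor its complete cases")
    p_ref = fit_ref.predict_proba(sub)
    p_new = fit_new.predict_proba(sub)
    auc_ref = auc_mann_whitney(p_ref, y)
    auc_new = auc_mann_whitney(p_new, y)
    delta, z, p_delong = delong_paired_test(p_ref, p_new, y)
    return ComparisonResult(
        outcome_threshold=outcome_threshold,
        cohort_label=cohort_label,
        reference_name=fit_ref.spec.name,
        new_name=fit_new.spec.name,
        auc_reference=auc_ref,
        auc_new=auc_new,
        delta_auc=delta,
        delong_z=z,
        delong_p=p_delong,
        nri=nri(p_ref, p_new, y, threshold=nri_threshold),
        idi=idi(p_ref, p_new, y),
        hl_reference=hosmer_lemeshow(p_ref, y, n_groups=hl_groups),
        hl_new=hosmer_lemeshow(p_new, y, n_groups=hl_groups),
        n_common_cases=len(sub),
    )
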