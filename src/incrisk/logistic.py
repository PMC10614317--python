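"""Maximum-likelihood logistic regression by iteratively reweighted least squares.

The estimator follows the scikit-learn protocol (``fit`` / ``predict_proba``
/ ``get_params``) but is an unpenalized ML fit with an observed-information
covariance matrix, Wald inference, step-halving to keep the log-likelihood
monotone, and explicit detection of complete separation — the behaviour a
biostatistician expects from a GLM routine rather than a penalized classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .cohort import CohortTable
from .errors import ConvergenceError, DataError, SeparationError

__all__ = ["LogisticIRLS", "ModelSpec", "FittedLogistic", "fit_logistic"]


class LogisticIRLS(BaseEstimator):
    """Unpenalized logistic regression via IRLS (Newton with step-halving).

    Parameters
    ----------
    tol : float
        Relative log-likelihood change declaring convergence.
    max_iter : int
        Maximum Newton iterations before raising ``ConvergenceError``.
    separation_bound : float
        Coefficient magnitude beyond which, with a non-vanishing gradient,
        complete separation is declared.
    ridge : float
        Optional tiny L2 stabilizer (off by default); a fallback for
        separated data when explicitly requested.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ndarray, slope coefficients (log-odds scale)
    intercept_ : float
    covariance_ : ndarray, inverse observed information (intercept first)
    loglik_, n_iter_, converged_
    """

    def __init__(self, tol: float = 1e-10, max_iter: int = 100,
                 separation_bound: float = 15.0, ridge: float = 0.0):
        self.tol = tol
        self.max_iter = max_iter
        self.separation_bound = separation_bound
        self.ridge = ridge

    # -- core fit -------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != y.shape[0]:
            raise DataError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
        if not np.isin(y, (0.0, 1.0)).all():
            raise DataError("outcome must be binary 0/1")
        n_events = int(y.sum())
        if n_events == 0 or n_events == len(y):
            raise DataError("need at least one event and one non-event")
        if not np.isfinite(X).all():
            raise DataError("predictors contain missing or non-finite values")

        Xd = np.column_stack([np.ones(len(y)), X])
        k = Xd.shape[1]
        beta = np.zeros(k)
        # start from the intercept-only MLE
        pbar = y.mean()
        beta[0] = np.log(pbar / (1.0 - pbar))

        def objective(b):  # penalized when ridge > 0
            return self._loglik(Xd, y, b) - 0.5 * self.ridge * float(b @ b)

        ll = objective(beta)
        self.loglik_path_ = [ll]
        for it in range(1, self.max_iter + 1):
            p = expit(Xd @ beta)
            grad = Xd.T @ (y - p) - self.ridge * beta
            w = p * (1.0 - p)
            info = (Xd * w[:, None]).T @ Xd + self.ridge * np.eye(k)
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(info, grad, rcond=None)[0]
            # step-halving keeps the (penalized) log-likelihood non-decreasing
            scale = 1.0
            for _ in range(30):
                cand = beta + scale * step
                if objective(cand) >= ll - 1e-12:
                    break
                scale *= 0.5
            beta = beta + scale * step
            ll_new = objective(beta)
            self.loglik_path_.append(ll_new)
            grad_norm = float(np.max(np.abs(
                Xd.T @ (y - expit(Xd @ beta)) - self.ridge * beta
            )))
            if np.max(np.abs(beta)) > self.separation_bound and grad_norm > 1e-4 \
                    and self.ridge == 0.0:
                raise SeparationError(
                    "complete or quasi-complete separation detected "
                    f"(|coef| > {self.separation_bound} with gradient {grad_norm:.2e}); "
                    "consider the ridge fallback"
                )
            rel = abs(ll_new - ll) / (abs(ll) + 1e-12)
            ll = ll_new
            if rel < self.tol or grad_norm < 1e-9:
                if np.max(np.abs(beta)) > self.separation_bound and self.ridge == 0.0:
                    # diverged coefficients with a saturated likelihood: the
                    # MLE lies at infinity along a separating direction
                    raise SeparationError(
                        "complete or quasi-complete separation detected "
                        f"(coefficients reached |{np.max(np.abs(beta)):.1f}| > "
                        f"{self.separation_bound} at convergence)"
                    )
                self._finalize(Xd, y, beta, ll, it, converged=True)
                return self
        raise ConvergenceError(
            f"IRLS did not converge in {self.max_iter} iterations",
            last_coef=beta, last_loglik=ll, n_iter=self.max_iter,
        )

    @staticmethod
    def _loglik(Xd, y, beta):
        eta = Xd @ beta
        # log(1+exp(eta)) computed stably
        return float(y @ eta - np.logaddexp(0.0, eta).sum())

    def _finalize(self, Xd, y, beta, ll, it, converged):
        if self.ridge:
            ll = self._loglik(Xd, y, beta)  # report the unpenalized log-likelihood
        p = expit(Xd @ beta)
        w = p * (1.0 - p)
        info = (Xd * w[:, None]).T @ Xd + self.ridge * np.eye(Xd.shape[1])
        cov = np.linalg.pinv(info)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.covariance_ = 0.5 * (cov + cov.T)
        self.loglik_ = ll
        self.n_iter_ = it
        self.converged_ = converged
        self.fitted_probabilities_ = np.clip(p, 1e-10, 1.0 - 1e-10)
        self.n_cases_ = len(y)
        self.n_events_ = int(y.sum())

    # -- prediction -----------------------------------------------------------

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        # keep probabilities strictly inside (0,1): extreme linear predictors
        # otherwise saturate to exactly 0/1 in floating point
        p1 = np.clip(expit(self.decision_function(X)), 1e-10, 1.0 - 1e-10)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)

    # -- inference ------------------------------------------------------------

    def wald_table(self) -> pd.DataFrame:
        """Per-term estimate, SE, z, two-sided p (intercept first)."""
        est = np.concatenate([[self.intercept_], self.coef_])
        se = np.sqrt(np.clip(np.diag(self.covariance_), 0.0, None))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, est / se, np.inf * np.sign(est))
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame({"estimate": est, "se": se, "z": z, "p": p})


@dataclass(frozen=True)
class ModelSpec:
    """A named ordered predictor set defining one nested model."""

    name: str
    predictors: tuple[str, ...]
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "predictors", tuple(self.predictors))
        if len(set(self.predictors)) != len(self.predictors):
            raise DataError(f"model {self.name!r}: duplicate predictors")
        if not self.label:
            object.__setattr__(self, "label", self.name)


@dataclass
class FittedLogistic:
    """One fitted logistic model bound to the case set it was fit on."""

    spec: ModelSpec
    estimator: LogisticIRLS
    case_ids: tuple
    coefficients: dict[str, float] = field(init=False)

    def __post_init__(self):
        names = ("intercept",) + self.spec.predictors
        est = np.concatenate([[self.estimator.intercept_], self.estimator.coef_])
        self.coefficients = dict(zip(names, est.tolist()))

    @property
    def covariance(self) -> np.ndarray:
        return self.estimator.covariance_

    @property
    def converged(self) -> bool:
        return self.estimator.converged_

    @property
    def n_cases(self) -> int:
        return self.estimator.n_cases_

    @property
    def n_events(self) -> int:
        return self.estimator.n_events_

    @property
    def fitted_probabilities(self) -> np.ndarray:
        return self.estimator.fitted_probabilities_

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        """Event probabilities for the rows of ``table`` (must be complete)."""
        missing = [c for c in self.spec.predictors if c not in table.data.columns]
        if missing:
            raise DataError(f"predictor columns absent from cohort: {missing}")
        X = table.data[list(self.spec.predictors)].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise DataError(
                f"model {self.spec.name!r}: missing predictor values in evaluation table; "
                "take a complete-case subset first"
            )
        return self.estimator.predict_proba(X)[:, 1]

    def wald_table(self) -> pd.DataFrame:
        tab = self.estimator.wald_table()
        tab.index = ["intercept", *self.spec.predictors]
        return tab

    def to_dict(self) -> dict:
        se = np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))
        return {
            "spec": {"name": self.spec.name, "label": self.spec.label,
                     "predictors": list(self.spec.predictors)},
            "coefficients": self.coefficients,
            "se": dict(zip(["intercept", *self.spec.predictors], se.tolist())),
            "n_cases": self.n_cases,
            "n_events": self.n_events,
            "converged": bool(self.converged),
            "loglik": self.estimator.loglik_,
        }


def fit_logistic(table: CohortTable, outcome, spec: ModelSpec,
                 tol: float = 1e-10, max_iter: int = 100,
                 ridge: float = 0.0, ridge_fallback: bool = False) -> FittedLogistic:
    """ML logistic fit of ``outcome ~ spec.predictors`` on a complete-case table.

    With ``ridge_fallback=True`` a fit that hits complete separation is
    retried with a weak L2 penalty (ridge 1e-2) instead of raising — useful
    in pipelines over many small resamples where quasi-separation is an
    occasional nuisance rather than a modelling failure.
    """
    missing = [c for c in spec.predictors if c not in table.data.columns]
    if missing:
        raise DataError(f"predictor columns absent from cohort: {missing}")
    X = table.data[list(spec.predictors)].to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.shape[1] == 0:
        X = np.empty((len(y), 0))
    est = LogisticIRLS(tol=tol, max_iter=max_iter, ridge=ridge)
    try:
        est.fit(X, y)
    except SeparationError:
        if not ridge_fallback:
            raise
        est = LogisticIRLS(tol=tol, max_iter=max_iter, ridge=1e-2)
        est.fit(X, y)
    return FittedLogistic(spec=spec, estimator=est,
                          case_ids=tuple(table.patient_ids.tolist()))
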