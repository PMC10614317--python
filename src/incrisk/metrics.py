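"""Discrimination, reclassification, and calibration statistics.

Implements the Mann-Whitney AUC with DeLong structural-component variance
and the paired z-test for two correlated ROC curves; the two-category net
reclassification improvement (NRI) at a single risk threshold; the
integrated discrimination improvement (IDI, the discrimination-slope
difference); and the Hosmer-Lemeshow decile goodness-of-fit test.

Conventions
-----------
* NRI is the SUM of the event and non-event net reclassification
  proportions (range -2..+2); a predicted probability exactly at the
  threshold counts as high risk.
* IDI = [mean Δp among events] - [mean Δp among non-events] with
  Δp = p_new - p_ref; equivalent to the difference of the integrals of
  sensitivity and one-minus-specificity over all cutoffs (range -2..+2).
* Degenerate zero-variance comparisons with a zero point estimate return
  p = 1; with a nonzero estimate they raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata

from .errors import DataError

__all__ = [
    "AUCResult",
    "NRIResult",
    "IDIResult",
    "HLResult",
    "auc_mann_whitney",
    "delong_paired_test",
    "nri",
    "idi",
    "hosmer_lemeshow",
]

_Z975 = norm.ppf(0.975)


def _check_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise DataError("labels must be binary 0/1")
    y = y.astype(bool)
    if y.all() or not y.any():
        raise DataError("need at least one event and one non-event")
    return y


def _delong_components(scores: np.ndarray, y: np.ndarray):
    """Structural components V10 (per event) and V01 (per non-event).

    Midrank construction: mean(V10) is the Mann-Whitney AUC with ties
    counted 1/2, in O(n log n).
    """
    x = np.asarray(scores, dtype=float)
    m, n0 = int(y.sum()), int((~y).sum())
    r_all = rankdata(x)
    r_e = rankdata(x[y])
    r_ne = rankdata(x[~y])
    v10 = (r_all[y] - r_e) / n0
    v01 = 1.0 - (r_all[~y] - r_ne) / m
    return v10, v01


@dataclass
class AUCResult:
    auc: float
    variance: float
    ci95: tuple[float, float]
    n_events: int
    n_nonevents: int

    def to_dict(self) -> dict:
        return {"auc": self.auc, "variance": self.variance,
                "ci95": list(self.ci95), "n_events": self.n_events,
                "n_nonevents": self.n_nonevents}


def auc_mann_whitney(scores, labels) -> AUCResult:
    """AUC over all event/non-event pairs (ties count 1/2), DeLong variance,
    Wald 95% CI clipped to [0, 1]."""
    y = _check_labels(labels)
    x = np.asarray(scores, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise DataError("scores and labels differ in length")
    v10, v01 = _delong_components(x, y)
    auc = float(np.mean(v10))
    m, n0 = len(v10), len(v01)
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n0 > 1 else 0.0
    var = s10 / m + s01 / n0
    half = _Z975 * np.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return AUCResult(auc=auc, variance=var, ci95=ci, n_events=m, n_nonevents=n0)


def delong_paired_test(scores_ref, scores_new, labels):
    """DeLong z-test for the difference of two correlated AUCs.

    Both score vectors must be aligned to the same cases. Returns
    ``(delta_auc, z, p)`` with ``delta_auc = AUC_new - AUC_ref``.
    """
    y = _check_labels(labels)
    a = np.asarray(scores_ref, dtype=float)
    b = np.asarray(scores_new, dtype=float)
    if a.shape[0] != y.shape[0] or b.shape[0] != y.shape[0]:
        raise DataError("score vectors and labels differ in length")
    if int(y.sum()) < 2 or int((~y).sum()) < 2:
        raise DataError("paired DeLong test needs >= 2 events and >= 2 non-events")
    v10_a, v01_a = _delong_components(a, y)
    v10_b, v01_b = _delong_components(b, y)
    m, n0 = len(v10_a), len(v01_a)
    delta = float(np.mean(v10_b) - np.mean(v10_a))
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    if var <= 0 or not np.isfinite(var):
        if abs(delta) < 1e-12:
            return 0.0, 0.0, 1.0
        raise DataError("zero DeLong variance with a nonzero AUC difference")
    z = delta / np.sqrt(var)
    return delta, float(z), float(2.0 * norm.sf(abs(z)))


@dataclass
class NRIResult:
    threshold: float
    event_net: float
    nonevent_net: float
    nri: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    percent_reclassified_by_stratum: dict[str, float] = field(default_factory=dict)
    n_events: int = 0
    n_nonevents: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95"] = list(self.ci95)
        return d


def nri(p_ref, p_new, labels, threshold: float = 0.5) -> NRIResult:
    """Two-category net reclassification improvement at one risk threshold.

    A case is high risk iff its predicted probability is >= ``threshold``.
    event_net = (events up - events down)/n_events; nonevent_net =
    (non-events down - non-events up)/n_nonevents; NRI is their sum.
    SE is the asymptotic binomial-difference form; z = NRI/SE.
    """
    y = _check_labels(labels)
    pr = np.asarray(p_ref, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    for name, v in (("p_ref", pr), ("p_new", pn)):
        if v.shape[0] != y.shape[0]:
            raise DataError(f"{name} and labels differ in length")
        if ((v < 0) | (v > 1)).any() or not np.isfinite(v).all():
            raise DataError(f"{name} must lie in [0, 1]")
    if not 0.0 < threshold < 1.0:
        raise DataError("threshold must be in (0, 1)")
    high_ref = pr >= threshold
    high_new = pn >= threshold
    up = ~high_ref & high_new
    down = high_ref & ~high_new
    m = int(y.sum())
    n0 = int((~y).sum())
    p_up_e = up[y].sum() / m
    p_down_e = down[y].sum() / m
    p_up_ne = up[~y].sum() / n0
    p_down_ne = down[~y].sum() / n0
    event_net = p_up_e - p_down_e
    nonevent_net = p_down_ne - p_up_ne
    value = event_net + nonevent_net
    se = float(np.sqrt((p_up_e + p_down_e) / m + (p_up_ne + p_down_ne) / n0))
    if se == 0.0:
        if value == 0.0:
            z, p = 0.0, 1.0
        else:
            raise DataError("zero NRI standard error with a nonzero estimate")
    else:
        z = value / se
        p = float(2.0 * norm.sf(abs(z)))
    ci = (value - _Z975 * se, value + _Z975 * se)
    return NRIResult(
        threshold=threshold, event_net=float(event_net),
        nonevent_net=float(nonevent_net), nri=float(value), se=se,
        z=float(z), p=p, ci95=ci,
        percent_reclassified_by_stratum={
            "events": 100.0 * float(event_net),
            "nonevents": 100.0 * float(nonevent_net),
        },
        n_events=m, n_nonevents=n0,
    )


@dataclass
class IDIResult:
    idi: float
    delta_event_mean: float
    delta_nonevent_mean: float
    se: float
    z: float
    p: float
    ci95: tuple[float, float]
    n_events: int = 0
    n_nonevents: int = 0

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci95"] = list(self.ci95)
        return d


def idi(p_ref, p_new, labels) -> IDIResult:
    """Integrated discrimination improvement (discrimination-slope difference)."""
    y = _check_labels(labels)
    pr = np.asarray(p_ref, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    for name, v in (("p_ref", pr), ("p_new", pn)):
        if v.shape[0] != y.shape[0]:
            raise DataError(f"{name} and labels differ in length")
        if ((v < 0) | (v > 1)).any() or not np.isfinite(v).all():
            raise DataError(f"{name} must lie in [0, 1]")
    d = pn - pr
    de, dn = d[y], d[~y]
    delta_e = float(np.mean(de))
    delta_ne = float(np.mean(dn))
    value = delta_e - delta_ne
    var_e = float(np.var(de, ddof=1)) if len(de) > 1 else 0.0
    var_ne = float(np.var(dn, ddof=1)) if len(dn) > 1 else 0.0
    se = float(np.sqrt(var_e / len(de) + var_ne / len(dn)))
    if se == 0.0:
        if value == 0.0:
            z, p = 0.0, 1.0
        else:
            z = np.inf if value > 0 else -np.inf
            p = 0.0
    else:
        z = value / se
        p = float(2.0 * norm.sf(abs(z)))
    ci = (value - _Z975 * se, value + _Z975 * se)
    return IDIResult(idi=float(value), delta_event_mean=delta_e,
                     delta_nonevent_mean=delta_ne, se=se, z=float(z), p=p,
                     ci95=ci, n_events=int(y.sum()), n_nonevents=int((~y).sum()))


@dataclass
class HLResult:
    chi2: float
    n_groups: int
    df: int
    p: float
    groups: pd.DataFrame  # per-group n, observed, expected, mean_p

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "n_groups": self.n_groups, "df": self.df,
                "p": self.p, "groups": self.groups.to_dict(orient="records")}


def hosmer_lemeshow(p, labels, n_groups: int = 10) -> HLResult:
    """Hosmer-Lemeshow goodness-of-fit test on probability-sorted groups.

    Cases are sorted by predicted probability and cut into ``n_groups``
    near-equal groups (deciles by default); tied probabilities stay in the
    lower group. Both the event and non-event cells contribute to the
    chi-square; df = groups - 2.
    """
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise DataError("labels must be binary 0/1")
    pv = np.asarray(p, dtype=float)
    if pv.shape[0] != y.shape[0]:
        raise DataError("probabilities and labels differ in length")
    if ((pv <= 0) | (pv >= 1)).any() or not np.isfinite(pv).all():
        raise DataError("probabilities must lie strictly inside (0, 1)")
    n = len(pv)
    if n < n_groups:
        raise DataError(f"need at least n_groups={n_groups} cases, got {n}")
    order = np.argsort(pv, kind="stable")
    ps, ys = pv[order], y[order]
    # nominal equal-count boundaries, then push each boundary past ties so
    # tied probabilities land in the lower group
    bounds = [round(k * n / n_groups) for k in range(1, n_groups)]
    adj = []
    for b in bounds:
        while 0 < b < n and ps[b] == ps[b - 1]:
            b += 1
        adj.append(b)
    edges = [0] + sorted(set(min(b, n) for b in adj)) + [n]
    edges = sorted(set(edges))
    rows = []
    chi2 = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi <= lo:
            continue
        ng = hi - lo
        obs = float(ys[lo:hi].sum())
        exp = float(ps[lo:hi].sum())
        if exp <= 0.0 or exp >= ng:
            raise DataError(
                "a Hosmer-Lemeshow group has expected events of 0 or its full size; "
                "use fewer groups"
            )
        chi2 += (obs - exp) ** 2 / exp + ((ng - obs) - (ng - exp)) ** 2 / (ng - exp)
        rows.append({"n": ng, "observed": obs, "expected": exp,
                     "mean_p": float(ps[lo:hi].mean())})
    g = len(rows)
    df = g - 2
    pval = float(chi2_dist.sf(chi2, df)) if df > 0 else float("nan")
    return HLResult(chi2=float(chi2), n_groups=g, df=df, p=pval,
                    groups=pd.DataFrame(rows))
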