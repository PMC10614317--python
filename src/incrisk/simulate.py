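"""Synthetic rheumatoid-arthritis cohort generator.

Emulates the statistical structure of a clinic-based RA cohort in which
coronary artery calcification (CAC, Agatston units) is the outcome: a
zero-heavy, right-skewed CAC distribution, a precomputed baseline
cardiovascular risk score in (0, 1), a panel of circulating protein
biomarkers (ELISA and mass-spectrometry MRM assays, the latter observed
only in a patient subset), and standard demographic covariates.

The generative model is a single latent atherosclerosis liability ``L``:

* covariates (age, sex, hypertension, smoking) feed a linear predictor
  that forms part of ``L``;
* the baseline risk score is an inverse-logit readout of ``L`` plus
  Gaussian measurement noise (the score's discrimination for CAC is set
  by that noise scale, not by re-deriving pooled-cohort coefficients);
* each biomarker's standardized log-concentration loads on ``L`` with a
  marker-specific ``effect`` (0 = inert) plus one shared Gaussian factor
  inducing background inter-marker correlation;
* CAC follows a two-part model driven by ``L``: a Bernoulli zero mass
  (logistic in ``L``) and a lognormal positive part.

Because both the score and the markers are noisy readouts of the same
liability, biomarkers carry genuine incremental information over the
score — the structure the downstream reclassification analysis assumes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import CalibrationError, ConfigurationError

__all__ = [
    "MarkerSpec",
    "CovariateSpec",
    "CacModel",
    "SyntheticParams",
    "CohortSimulator",
    "default_params",
    "generate_cohort",
    "calibrate_cac_intercepts",
    "write_params",
    "read_params",
]

ELISA = "ELISA"
MRM = "MRM"


@dataclass(frozen=True)
class MarkerSpec:
    """One circulating biomarker.

    ``effect`` is the loading of the standardized log concentration on the
    CAC liability (log-odds scale per SD); 0 marks an inert marker.
    """

    name: str
    assay: str
    log_mean: float
    log_sd: float
    effect: float = 0.0

    def validate(self) -> None:
        if self.assay not in (ELISA, MRM):
            raise ConfigurationError(
                f"marker {self.name!r}: assay must be 'ELISA' or 'MRM', got {self.assay!r}"
            )
        if not self.log_sd > 0:
            raise ConfigurationError(f"marker {self.name!r}: log_sd must be > 0")


@dataclass(frozen=True)
class CovariateSpec:
    """Distributional parameters of the demographic covariates."""

    age_mean: float = 57.6
    age_sd: float = 10.5
    prop_female: float = 0.77
    prop_hypertensive: float = 0.42
    prop_current_smoker: float = 0.14

    def validate(self) -> None:
        if not self.age_sd > 0:
            raise ConfigurationError("covariate_spec.age_sd must be > 0")
        for name in ("prop_female", "prop_hypertensive", "prop_current_smoker"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"covariate_spec.{name} must be in [0, 1]")


@dataclass(frozen=True)
class CacModel:
    """Two-part Agatston model: Bernoulli zero mass + lognormal positive part.

    Both parts are linear in the standardized liability; the two intercepts
    are the calibration handles used to hit target prevalences.
    """

    zero_intercept: float
    zero_slope: float
    logmean_intercept: float
    logmean_slope: float
    log_sd: float

    def validate(self) -> None:
        if not self.log_sd > 0:
            raise ConfigurationError("cac_model.log_sd must be > 0")


@dataclass(frozen=True)
class SyntheticParams:
    """Complete generative configuration for one synthetic cohort."""

    n_patients: int
    seed: int
    covariate_spec: CovariateSpec
    baseline_score_coefs: dict[str, float]
    marker_panel: tuple[MarkerSpec, ...]
    cac_model: CacModel
    mrm_observed_fraction: float
    prevalence_targets: tuple[float, float, float] = (0.55, 0.30, 0.16)
    # latent structure
    latent_noise_sd: float = 1.0
    marker_shared_corr: float = 0.2
    # baseline-score readout: expit(intercept + scale * (L_std + N(0, noise_sd)))
    score_intercept: float = -1.9
    score_scale: float = 1.1
    score_noise_sd: float = 1.10

    def __post_init__(self):
        object.__setattr__(self, "marker_panel", tuple(self.marker_panel))
        object.__setattr__(self, "baseline_score_coefs", dict(self.baseline_score_coefs))
        object.__setattr__(self, "prevalence_targets", tuple(self.prevalence_targets))

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ConfigurationError("n_patients must be >= 2")
        if not 0.0 <= self.mrm_observed_fraction <= 1.0:
            raise ConfigurationError("mrm_observed_fraction must be in [0, 1]")
        if not all(0.0 <= t <= 1.0 for t in self.prevalence_targets):
            raise ConfigurationError("prevalence_targets must be proportions in [0, 1]")
        if not self.latent_noise_sd > 0:
            raise ConfigurationError("latent_noise_sd must be > 0")
        if not 0.0 <= self.marker_shared_corr < 1.0:
            raise ConfigurationError("marker_shared_corr must be in [0, 1)")
        if not self.score_noise_sd >= 0:
            raise ConfigurationError("score_noise_sd must be >= 0")
        self.covariate_spec.validate()
        self.cac_model.validate()
        names = [m.name for m in self.marker_panel]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ConfigurationError(f"marker names not unique: {dupes}")
        for m in self.marker_panel:
            m.validate()
        known = {"age", "female", "hypertension", "current_smoker"}
        unknown = set(self.baseline_score_coefs) - known
        if unknown:
            raise ConfigurationError(
                f"baseline_score_coefs references unknown covariates: {sorted(unknown)}"
            )

    # -- liability bookkeeping ------------------------------------------------

    @property
    def latent_sd(self) -> float:
        """Theoretical SD of the liability L (covariates standardized)."""
        var_cov = sum(c * c for c in self.baseline_score_coefs.values())
        return float(np.sqrt(var_cov + self.latent_noise_sd**2))

    def elisa_markers(self) -> list[MarkerSpec]:
        return [m for m in self.marker_panel if m.assay == ELISA]

    def mrm_markers(self) -> list[MarkerSpec]:
        return [m for m in self.marker_panel if m.assay == MRM]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticParams":
        d = dict(d)
        d["covariate_spec"] = CovariateSpec(**d["covariate_spec"])
        d["cac_model"] = CacModel(**d["cac_model"])
        d["marker_panel"] = tuple(MarkerSpec(**m) for m in d["marker_panel"])
        d["prevalence_targets"] = tuple(d["prevalence_targets"])
        return cls(**d)


# -- default study-like configuration ----------------------------------------

# 8 ELISA markers carrying signal (the four strongest mirror the panel retained
# by multivariable selection), 3 signal MRM peptides, and 12 inert ELISA
# markers forming the background panel.
_ACTIVE_ELISA = [
    ("cystatin_c", 6.8, 0.35, 0.90),
    ("osteopontin", 3.9, 0.55, 0.80),
    ("ccl18", 4.6, 0.50, 0.75),
    ("ykl40", 4.1, 0.70, 0.70),
    ("cd40_ligand", 0.9, 0.60, 0.35),
    ("leptin", 2.7, 0.80, 0.30),
    ("osteoprotegerin", 1.5, 0.45, 0.35),
    ("tnfr1", 7.0, 0.40, 0.40),
]
_ACTIVE_MRM = [
    ("SerD1_NFGYTLR", 2.1, 0.40, -0.85),
    ("PON1_IQNILTEEPK", 1.6, 0.45, -0.75),
    ("Clusterin_IDSLLENDR", 2.4, 0.40, 0.80),
]
_INERT_ELISA = [
    "adiponectin",
    "e_selectin",
    "icam1",
    "vcam1",
    "mmp3",
    "mmp9",
    "myeloperoxidase",
    "nt_probnp",
    "pai1",
    "resistin",
    "serum_amyloid_a",
    "vegf",
]


def default_params(n_patients: int = 561, seed: int = 20561) -> SyntheticParams:
    """Study-condition defaults: n=561, 77% female, mean age 57.6 (SD 10.5),
    CAC prevalence targets (0.55, 0.30, 0.16), MRM observed in 140/561, and a
    baseline score whose stand-alone discrimination for CAC>100 sits in the
    0.77-0.82 AUC band."""
    panel = [MarkerSpec(n, ELISA, lm, ls, e) for n, lm, ls, e in _ACTIVE_ELISA]
    panel += [MarkerSpec(n, MRM, lm, ls, e) for n, lm, ls, e in _ACTIVE_MRM]
    panel += [
        MarkerSpec(name, ELISA, 2.0 + 0.25 * i, 0.5, 0.0)
        for i, name in enumerate(_INERT_ELISA)
    ]
    return SyntheticParams(
        n_patients=n_patients,
        seed=seed,
        covariate_spec=CovariateSpec(),
        baseline_score_coefs={
            "age": 0.75,
            "female": -0.35,
            "hypertension": 0.40,
            "current_smoker": 0.25,
        },
        marker_panel=tuple(panel),
        # Intercepts are the fixed point of calibrate_cac_intercepts at the
        # default prevalence targets; slopes and the lognormal SD set the
        # spread of the positive Agatston part so both the >100 and >300
        # cut points are reachable simultaneously.
        cac_model=CacModel(
            zero_intercept=0.3249643743,
            zero_slope=2.0,
            logmean_intercept=3.9356303172,
            logmean_slope=1.6,
            log_sd=1.0,
        ),
        mrm_observed_fraction=140 / 561,
        prevalence_targets=(0.55, 0.30, 0.16),
    )


# -- generation ---------------------------------------------------------------


class CohortSimulator:
    """Draw synthetic cohorts from a :class:`SyntheticParams` configuration.

    All randomness flows from one seeded :class:`numpy.random.Generator`; the
    same (params, seed) always yields an identical table.
    """

    def __init__(self, params: SyntheticParams):
        params.validate()
        self.params = params

    def get_params(self) -> SyntheticParams:
        return self.params

    # Draw order is part of the contract: changing it changes outputs for a
    # fixed seed, so keep covariates -> latent -> markers -> score -> CAC -> MRM mask.
    def sample(self, n: int | None = None, seed: int | None = None,
               include_latent: bool = False) -> pd.DataFrame:
        p = self.params
        n = p.n_patients if n is None else int(n)
        if n < 2:
            raise ConfigurationError("n_patients must be >= 2")
        rng = np.random.default_rng(p.seed if seed is None else seed)
        cov = p.covariate_spec

        age = rng.normal(cov.age_mean, cov.age_sd, size=n)
        female = (rng.random(n) < cov.prop_female).astype(int)
        hypertension = (rng.random(n) < cov.prop_hypertensive).astype(int)
        smoker = (rng.random(n) < cov.prop_current_smoker).astype(int)

        def z(x, mean, sd):
            return (x - mean) / sd if sd > 0 else np.zeros_like(x, dtype=float)

        def zb(x, prop):
            sd = np.sqrt(prop * (1 - prop))
            return (x - prop) / sd if sd > 0 else np.zeros_like(x, dtype=float)

        c = p.baseline_score_coefs
        eta_cov = (
            c.get("age", 0.0) * z(age, cov.age_mean, cov.age_sd)
            + c.get("female", 0.0) * zb(female, cov.prop_female)
            + c.get("hypertension", 0.0) * zb(hypertension, cov.prop_hypertensive)
            + c.get("current_smoker", 0.0) * zb(smoker, cov.prop_current_smoker)
        )
        liability = eta_cov + rng.normal(0.0, p.latent_noise_sd, size=n)
        l_std = liability / p.latent_sd

        shared = rng.normal(size=n)  # one common factor across the panel
        rho = p.marker_shared_corr
        markers = {}
        for m in p.marker_panel:
            raw = (
                m.effect * l_std
                + np.sqrt(rho) * shared
                + np.sqrt(1.0 - rho) * rng.normal(size=n)
            )
            z_std = raw / np.sqrt(1.0 + m.effect**2)
            markers[m.name] = np.exp(m.log_mean + m.log_sd * z_std)

        score_noise = rng.normal(0.0, p.score_noise_sd, size=n)
        baseline_score = expit(p.score_intercept + p.score_scale * (l_std + score_noise))

        cm = p.cac_model
        p_pos = expit(cm.zero_intercept + cm.zero_slope * l_std)
        positive = rng.random(n) < p_pos
        log_cac = cm.logmean_intercept + cm.logmean_slope * l_std + rng.normal(
            0.0, cm.log_sd, size=n
        )
        cac = np.where(positive, np.exp(log_cac), 0.0)

        table = pd.DataFrame(
            {
                "patient_id": [f"P{i + 1:05d}" for i in range(n)],
                "age": np.round(age, 3),
                "female": female,
                "hypertension": hypertension,
                "current_smoker": smoker,
                "baseline_score": baseline_score,
            }
        )
        for m in p.marker_panel:
            table[m.name] = markers[m.name]
        mrm_cols = [m.name for m in p.mrm_markers()]
        if mrm_cols:
            observed = rng.random(n) < p.mrm_observed_fraction
            table.loc[~observed, mrm_cols] = np.nan
        table["cac_agatston"] = cac
        if include_latent:
            table["latent_risk"] = l_std
        return table


def generate_cohort(params: SyntheticParams, include_latent: bool = False) -> pd.DataFrame:
    """Generate one cohort table; deterministic given ``params.seed``."""
    return CohortSimulator(params).sample(include_latent=include_latent)


# -- prevalence calibration ---------------------------------------------------

_THRESHOLDS = (0.0, 100.0, 300.0)


def _probe_liability(params: SyntheticParams, n_probe: int) -> np.ndarray:
    """Standardized liability draws used for smooth expected-prevalence curves.

    Seeded independently of cohort generation (but deterministically from
    params.seed) so recalibration is a fixed point."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xCAC]))
    return rng.normal(size=n_probe)


def _expected_prevalences(l_std, zero_intercept, zero_slope,
                          logmean_intercept, logmean_slope, log_sd):
    """E[P(CAC > t)] for t in (0, 100, 300), averaged over probe liabilities."""
    p_pos = expit(zero_intercept + zero_slope * l_std)
    out = [float(np.mean(p_pos))]
    for t in _THRESHOLDS[1:]:
        tail = norm.sf((np.log(t) - logmean_intercept - logmean_slope * l_std) / log_sd)
        out.append(float(np.mean(p_pos * tail)))
    return tuple(out)


def _bisect(f, lo, hi, target, tol=1e-6, max_iter=200):
    """Root of f(x) = target for f increasing on [lo, hi]."""
    flo, fhi = f(lo), f(hi)
    if not (flo <= target <= fhi):
        return None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if f(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def calibrate_cac_intercepts(params: SyntheticParams, n_probe: int = 100_000,
                             tol: float = 0.01) -> SyntheticParams:
    """Adjust the two CAC intercepts so simulated prevalences of CAC>0, >100,
    >300 match ``params.prevalence_targets`` within ``tol``.

    Bisection on smooth expected prevalences over a probe liability sample:
    the zero-inflation intercept pins P(CAC>0), then the lognormal mean
    intercept pins P(CAC>100); P(CAC>300) is determined by the (fixed)
    slopes and lognormal SD and is verified against its target.
    """
    params.validate()
    t0, t100, t300 = params.prevalence_targets
    if not (t0 > t100 > t300):
        raise ConfigurationError(
            "prevalence_targets must be strictly decreasing across thresholds 0, 100, 300"
        )
    l_std = _probe_liability(params, n_probe)
    cm = params.cac_model

    def prev0(a0):
        return float(np.mean(expit(a0 + cm.zero_slope * l_std)))

    a0 = _bisect(prev0, -30.0, 30.0, t0)
    if a0 is None:
        ach = _expected_prevalences(l_std, cm.zero_intercept, cm.zero_slope,
                                    cm.logmean_intercept, cm.logmean_slope, cm.log_sd)
        raise CalibrationError(
            f"P(CAC>0) target {t0} unreachable under the two-part model "
            f"(attainable range ({prev0(-30.0):.4f}, {prev0(30.0):.4f})); "
            f"best achieved prevalences {ach}",
            achieved=ach,
        )

    def prev100(mu0):
        return _expected_prevalences(l_std, a0, cm.zero_slope, mu0,
                                     cm.logmean_slope, cm.log_sd)[1]

    mu0 = _bisect(prev100, np.log(100.0) - 40.0, np.log(100.0) + 40.0, t100)
    if mu0 is None:
        ach = _expected_prevalences(l_std, a0, cm.zero_slope, cm.logmean_intercept,
                                    cm.logmean_slope, cm.log_sd)
        raise CalibrationError(
            f"P(CAC>100) target {t100} unreachable (bounded above by P(CAC>0)={t0}); "
            f"best achieved prevalences {ach}",
            achieved=ach,
        )

    achieved = _expected_prevalences(l_std, a0, cm.zero_slope, mu0,
                                     cm.logmean_slope, cm.log_sd)
    if abs(achieved[2] - t300) > tol:
        raise CalibrationError(
            f"P(CAC>300) target {t300} unreachable with the configured lognormal "
            f"slope/SD (achieved {achieved[2]:.4f} after matching CAC>0 and CAC>100); "
            f"best achieved prevalences {achieved}",
            achieved=achieved,
        )
    return replace(params, cac_model=replace(cm, zero_intercept=a0, logmean_intercept=mu0))


# -- params I/O ---------------------------------------------------------------


def write_params(params: SyntheticParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=2)


def read_params(path) -> SyntheticParams:
    with open(path) as fh:
        return SyntheticParams.from_dict(json.load(fh))
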