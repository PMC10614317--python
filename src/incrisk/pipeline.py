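"""Full study-replica pipeline.

Order of operations (selection strictly on the training half):

1. load or simulate the cohort;
2. random 50:50 training/validation split;
3. univariate screen of every marker on the training half;
4. stepwise selection within the significant ELISA candidates and, separately,
   within the significant MRM candidates;
5. the four nested model specs (reference score alone, +cytokines, +MRM, +both);
6. for each outcome threshold, fit each comparison's reference and new model on
   the training-half complete cases of their predictor union, then evaluate the
   comparison on the training half and on the validation half (training-fit
   coefficients applied, unless refitting is requested).

Marker columns enter models as log-transformed, z-standardized values with
standardization constants learned on the training half.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortTable,
    complete_case_subset,
    dichotomize,
    dictionary_for_params,
    read_cohort,
    split_cohort,
)
from .compare import ComparisonResult, compare_models
from .errors import ConfigurationError, IncriskError
from .logistic import ModelSpec, fit_logistic
from .metrics import auc_mann_whitney, hosmer_lemeshow
from .selection import MarkerTransform, ScreenResult, stepwise_select, table2_model_specs, univariate_screen
from .simulate import SyntheticParams, default_params, generate_cohort

__all__ = ["AnalysisConfig", "ReportBundle", "run_analysis", "render_table2"]

log = logging.getLogger("incrisk")

TRAINING = "training"
VALIDATION = "validation"


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    cohort_csv: str | None = None
    dictionary_path: str | None = None
    synthetic: SyntheticParams | None = None
    seed: int = 0
    split_ratio: float = 0.5
    split_sizes: tuple[int, int] | None = None
    thresholds: tuple[float, ...] = (100.0, 300.0)
    alpha: float = 0.05
    nri_threshold: float = 0.5
    hl_groups: int = 10
    p_enter: float = 0.05
    p_remove: float = 0.10
    elisa_panel_override: tuple[str, ...] | None = None
    mrm_panel_override: tuple[str, ...] | None = None
    refit_validation: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if (self.cohort_csv is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one input source required: cohort_csv or synthetic"
            )
        if self.cohort_csv is not None and self.dictionary_path is None:
            raise ConfigurationError("dictionary_path required with cohort_csv")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must be in (0, 1)")
        if not 0 < self.nri_threshold < 1:
            raise ConfigurationError("nri_threshold must be in (0, 1)")
        if list(self.thresholds) != sorted(self.thresholds) or min(self.thresholds) <= 0:
            raise ConfigurationError("thresholds must be positive and increasing")
        if self.p_enter > self.p_remove:
            raise ConfigurationError("p_enter must be <= p_remove")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """All comparisons plus the selection trace and run metadata."""

    comparisons: list[ComparisonResult]
    reference_rows: list[dict]  # stand-alone reference AUC/H-L per outcome x half
    screens: dict[float, ScreenResult]
    selected_elisa: tuple[str, ...]
    selected_mrm: tuple[str, ...]
    metadata: dict

    def to_dict(self) -> dict:
        return {
            "metadata": self.metadata,
            "selected_elisa": list(self.selected_elisa),
            "selected_mrm": list(self.selected_mrm),
            "screens": {str(k): v.to_dict() for k, v in self.screens.items()},
            "reference_rows": self.reference_rows,
            "comparisons": [c.to_dict() for c in self.comparisons],
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)


def _zcol(name: str) -> str:
    return f"z_log_{name}"


def _transform_markers(table: CohortTable, train_mask, marker_names) -> CohortTable:
    """Append z_log_* columns standardized on the training half."""
    df = table.data.copy()
    for name in marker_names:
        tr = MarkerTransform().fit(df.loc[train_mask, name])
        df[_zcol(name)] = tr.transform(df[name])
    return CohortTable(df, table.dictionary)


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Execute the full pipeline; deterministic under (config, seed)."""
    config.validate()

    # -- load -----------------------------------------------------------------
    try:
        if config.synthetic is not None:
            params = config.synthetic
            table = CohortTable(generate_cohort(params), dictionary_for_params(params))
        else:
            table = read_cohort(config.cohort_csv, config.dictionary_path)
    except IncriskError as err:
        raise type(err)(f"[load] {err}") from err
    dd = table.dictionary
    log.info("load: n=%d, markers=%d", len(table), len(dd.markers()))

    # -- split ----------------------------------------------------------------
    labels = split_cohort(table, ratio=config.split_ratio, seed=config.seed,
                          sizes=config.split_sizes)
    train_mask = labels == TRAINING
    halves = {TRAINING: table.subset(train_mask),
              VALIDATION: table.subset(~train_mask)}
    log.info("split: training=%d validation=%d", train_mask.sum(), (~train_mask).sum())

    # -- marker transform (training-half constants) ---------------------------
    table_z = _transform_markers(table, train_mask, dd.markers())
    halves = {k: table_z.subset(labels == k) for k in (TRAINING, VALIDATION)}
    train = halves[TRAINING]

    score_col = dd.score_column
    screens: dict[float, ScreenResult] = {}
    bundle_comparisons: list[ComparisonResult] = []
    reference_rows: list[dict] = []

    # Selection uses the lower outcome threshold (the primary endpoint);
    # panel overrides bypass screening entirely.
    sel_threshold = config.thresholds[0]
    y_sel = dichotomize(train, sel_threshold)
    sig_elisa: list[str] = []
    sig_mrm: list[str] = []
    if config.elisa_panel_override is None or config.mrm_panel_override is None:
        screen = univariate_screen(train, y_sel, markers=dd.markers(), alpha=config.alpha)
        screens[sel_threshold] = screen
        sig_elisa = [m for m in screen.significant if dd.assays[m] == "ELISA"]
        sig_mrm = [m for m in screen.significant if dd.assays[m] == "MRM"]
        log.info("screen: %d significant (%d ELISA, %d MRM)",
                 len(screen.significant), len(sig_elisa), len(sig_mrm))

    def _stepwise_panel(markers, name):
        cols = [_zcol(m) for m in markers]
        if not cols:
            return ()
        sub = complete_case_subset(train, cols)
        spec = stepwise_select(sub, dichotomize(sub, sel_threshold), cols,
                               p_enter=config.p_enter, p_remove=config.p_remove,
                               name=name)
        return tuple(m for m in markers if _zcol(m) in spec.predictors)

    if config.elisa_panel_override is not None:
        selected_elisa = tuple(config.elisa_panel_override)
    else:
        selected_elisa = _stepwise_panel(sig_elisa, "elisa")
    if config.mrm_panel_override is not None:
        selected_mrm = tuple(config.mrm_panel_override)
    else:
        selected_mrm = _stepwise_panel(sig_mrm, "mrm")
    log.info("selected panels: ELISA=%s MRM=%s", selected_elisa, selected_mrm)

    specs = table2_model_specs([_zcol(m) for m in selected_elisa],
                               [_zcol(m) for m in selected_mrm],
                               score_column=score_col)
    ref_spec = specs[0]
    # degenerate (empty-panel) specs duplicate the reference or each other;
    # drop them so an all-empty selection downgrades to a reference-only report
    seen = {tuple(sorted(ref_spec.predictors))}
    new_specs = []
    for s in specs[1:]:
        key = tuple(sorted(s.predictors))
        if key not in seen:
            seen.add(key)
            new_specs.append(s)

    # -- fit + evaluate -------------------------------------------------------
    for threshold in config.thresholds:
        # stand-alone reference row per half
        ref_fit_all = fit_logistic(train, dichotomize(train, threshold), ref_spec,
                                   ridge_fallback=True)
        for half_name, half in halves.items():
            fit_here = (fit_logistic(half, dichotomize(half, threshold), ref_spec,
                                     ridge_fallback=True)
                        if (config.refit_validation and half_name == VALIDATION)
                        else ref_fit_all)
            p_hat = fit_here.predict_proba(half)
            y_half = dichotomize(half, threshold)
            reference_rows.append({
                "outcome_threshold": threshold,
                "cohort_label": half_name,
                "model": ref_spec.name,
                "label": ref_spec.label,
                "n": len(half),
                "auc": auc_mann_whitney(p_hat, y_half).to_dict(),
                "hl": hosmer_lemeshow(p_hat, y_half, n_groups=config.hl_groups).to_dict(),
            })
        for new_spec in new_specs:
            union = list(dict.fromkeys(ref_spec.predictors + new_spec.predictors))
            train_cc = complete_case_subset(train, union)
            y_tr = dichotomize(train_cc, threshold)
            try:
                fit_ref = fit_logistic(train_cc, y_tr, ref_spec, ridge_fallback=True)
                fit_new = fit_logistic(train_cc, y_tr, new_spec, ridge_fallback=True)
            except IncriskError as err:
                raise type(err)(f"[fit:{new_spec.name}@{threshold}] {err}") from err
            for half_name, half in halves.items():
                if config.refit_validation and half_name == VALIDATION:
                    half_cc = complete_case_subset(half, union)
                    y_cc = dichotomize(half_cc, threshold)
                    f_ref = fit_logistic(half_cc, y_cc, ref_spec, ridge_fallback=True)
                    f_new = fit_logistic(half_cc, y_cc, new_spec, ridge_fallback=True)
                else:
                    f_ref, f_new = fit_ref, fit_new
                half_cc = complete_case_subset(half, union)
                y_half = dichotomize(half_cc, threshold)
                try:
                    cmp_ = compare_models(
                        f_ref, f_new, half_cc, y_half, cohort_label=half_name,
                        nri_threshold=config.nri_threshold, hl_groups=config.hl_groups,
                        outcome_threshold=threshold,
                    )
                except IncriskError as err:
                    raise type(err)(
                        f"[evaluate:{new_spec.name}@{threshold}/{half_name}] {err}"
                    ) from err
                bundle_comparisons.append(cmp_)
                log.info("evaluate %s@%g/%s: dAUC=%.3f NRI=%.3f IDI=%.3f",
                         new_spec.name, threshold, half_name,
                         cmp_.delta_auc, cmp_.nri.nri, cmp_.idi.idi)

    metadata = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
        "n_patients": len(table),
        "n_training": int(train_mask.sum()),
        "n_validation": int((~train_mask).sum()),
    }
    bundle = ReportBundle(
        comparisons=bundle_comparisons,
        reference_rows=reference_rows,
        screens=screens,
        selected_elisa=selected_elisa,
        selected_mrm=selected_mrm,
        metadata=metadata,
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle.write_json(out / "report_bundle.json")
        render_table2(bundle, out)
    return bundle


def _fmt_ci(value, ci):
    return f"{value:.3f} ({ci[0]:.3f}-{ci[1]:.3f})"


_NEW_LABELS = {
    "reference+cytokines": "ACC/AHA + cytokines",
    "reference+MRM": "ACC/AHA + MRM",
    "reference+cytokines+MRM": "ACC/AHA + cytokines + MRM",
}


def render_table2(bundle, out_dir) -> list[Path]:
    """Flat CSV (plus JSON twin) per outcome, mirroring the study's
    discrimination / calibration / reclassification table layout.

    Accepts a :class:`ReportBundle` or its serialized dict form.
    """
    data = bundle.to_dict() if isinstance(bundle, ReportBundle) else bundle
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    thresholds = sorted({r["outcome_threshold"] for r in data["reference_rows"]})
    for threshold in thresholds:
        rows = []
        for half in (TRAINING, VALIDATION):
            for ref_row in data["reference_rows"]:
                if ref_row["outcome_threshold"] != threshold or ref_row["cohort_label"] != half:
                    continue
                rows.append({
                    "cohort": half,
                    "model": ref_row["label"],
                    "n": ref_row["n"],
                    "auc_95ci": _fmt_ci(ref_row["auc"]["auc"], ref_row["auc"]["ci95"]),
                    "auc": ref_row["auc"]["auc"],
                    "p_vs_reference": "Ref",
                    "hl_p": ref_row["hl"]["p"],
                    "nri_95ci": "", "nri": "", "nri_p": "",
                    "pct_net_events": "", "pct_net_nonevents": "",
                    "idi_95ci": "", "idi": "", "idi_p": "",
                })
            for c in data["comparisons"]:
                if c["outcome_threshold"] != threshold or c["cohort_label"] != half:
                    continue
                rows.append({
                    "cohort": half,
                    "model": _NEW_LABELS.get(c["new_name"], c["new_name"]),
                    "n": c["n_common_cases"],
                    "auc_95ci": _fmt_ci(c["auc_new"]["auc"], c["auc_new"]["ci95"]),
                    "auc": c["auc_new"]["auc"],
                    "p_vs_reference": c["delong_p"],
                    "hl_p": c["hl_new"]["p"],
                    "nri_95ci": _fmt_ci(c["nri"]["nri"], c["nri"]["ci95"]),
                    "nri": c["nri"]["nri"],
                    "nri_p": c["nri"]["p"],
                    "pct_net_events": c["nri"]["percent_reclassified_by_stratum"]["events"],
                    "pct_net_nonevents": c["nri"]["percent_reclassified_by_stratum"]["nonevents"],
                    "idi_95ci": _fmt_ci(c["idi"]["idi"], c["idi"]["ci95"]),
                    "idi": c["idi"]["idi"],
                    "idi_p": c["idi"]["p"],
                })
        frame = pd.DataFrame(rows)
        stem = f"table2_cac_gt_{int(threshold)}"
        csv_path = out_dir / f"{stem}.csv"
        frame.to_csv(csv_path, index=False)
        with open(out_dir / f"{stem}.json", "w") as fh:
            json.dump(rows, fh, indent=2, default=float)
        written.append(csv_path)
    return written
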