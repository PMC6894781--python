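"""Feature-set settings for the discrimination and prediction analyses.

The settings mirror the study design:

* D1/R1 — all 13 speech features;
* D2 — features whose group comparison was significant in the F or t test;
* D3 — the subset with the best LOOCV accuracy among all 8191 subsets;
* R2 — the D2 features significantly correlated with the target score;
* R3 — the D3 subset reused for regression;
* R4 — the subset with the smallest LOOCV RMSE among all 8191 subsets.

Classification discriminates ASD vs TD; regression predicts a symptom
score domain (reciprocity, communication or repetitive).  All settings
operate on the analysis-scale features (after the log/shifted-log
transforms of the turn-taking features).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import (
    EvalMetrics,
    LoocvEngine,
    ModelConfig,
    SubsetSearchResult,
    classification_metrics,
    exhaustive_subset_search,
    regression_metrics,
)
from .session import FEATURE_ORDER, CohortTable
from .stats import (
    apply_transforms,
    comparison_table,
    correlation_table,
    fit_transforms,
    prepare_correlation_inputs,
)

CLASSIFY_SETTINGS = ("D1", "D2", "D3")
REGRESS_SETTINGS = ("R1", "R2", "R3", "R4")


@dataclass
class SettingReport:
    """Outcome of one setting on one cohort."""

    setting: str
    task: Literal["classify", "regress"]
    domain: str | None
    features: tuple[str, ...]
    participant_ids: tuple[str, ...]
    predictions: np.ndarray | None
    metrics: EvalMetrics | None
    criterion: float | None = None
    n_subsets_evaluated: int | None = None
    search_top: list[SubsetSearchResult] | None = None
    single_feature: pd.DataFrame | None = None
    ablation: pd.DataFrame | None = None
    note: str | None = None

    @property
    def empty(self) -> bool:
        return not self.features


def _complete_rows(
    cohort: CohortTable, domain: str | None
) -> tuple[pd.DataFrame, pd.Series]:
    """Analysis-scale matrix and target for rows without missing values."""
    X = apply_transforms(cohort, fit_transforms(cohort))
    meta = cohort.data.set_index("participant_id")
    if domain is None:
        target = meta["group"]
    else:
        target = meta[domain].astype(float)
    keep = X.notna().all(axis=1) & target.notna()
    return X.loc[keep], target.loc[keep]


def significant_features(comparison: pd.DataFrame) -> list[str]:
    """Features significant in the F or t test after B-H adjustment (D2)."""
    sig = comparison["significant_F"] | comparison["significant_t"]
    return [f for f in comparison.loc[sig, "feature"]]


def correlated_features(
    correlations: pd.DataFrame, domain: str, alpha: float = 0.05
) -> list[str]:
    sub = correlations[
        (correlations["domain"] == domain) & (correlations["adjusted_p"] < alpha)
    ]
    return list(sub["feature"])


def run_setting(
    cohort: CohortTable,
    setting: str,
    domain: str | None = None,
    cfg: ModelConfig = ModelConfig(),
    comparison: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    d3_features: Sequence[str] | None = None,
    top_n: int = 20,
    with_ablation: bool = True,
) -> SettingReport:
    """Run one discrimination (D*) or prediction (R*) setting end to end.

    ``comparison``/``correlations`` may pass precomputed tables (from
    :func:`dyadspeech.stats.comparison_table` and
    :func:`dyadspeech.stats.correlation_table`); they are computed on the
    fly when needed.  ``d3_features`` supplies the discrimination winner
    for Setting R3 (computed by running D3 when omitted).  An empty
    feature set (possible for D2/R2) yields an empty report, not an error.
    """
    setting = setting.upper()
    if setting in CLASSIFY_SETTINGS:
        task: Literal["classify", "regress"] = "classify"
        if domain is not None:
            raise ValidationError("classification settings take no score domain")
    elif setting in REGRESS_SETTINGS:
        task = "regress"
        if domain is None:
            raise ValidationError(f"setting {setting} requires a score domain")
    else:
        raise ValidationError(f"unknown setting {setting!r}")

    X, target = _complete_rows(cohort, domain)
    ids = tuple(X.index.astype(str))
    search: list[SubsetSearchResult] | None = None
    note = None

    if setting in ("D1", "R1"):
        features = list(FEATURE_ORDER)
    elif setting == "D2":
        if comparison is None:
            comparison = comparison_table(cohort)
        features = significant_features(comparison)
        if not features:
            note = "no feature passed the F/t significance screen"
    elif setting == "R2":
        if comparison is None:
            comparison = comparison_table(cohort)
        d2 = significant_features(comparison)
        if correlations is None:
            feats, values = prepare_correlation_inputs(cohort, comparison)
            correlations = correlation_table(
                cohort, feats, feature_values=values, group=None
            )
        features = [f for f in d2 if f in correlated_features(correlations, domain)]
        if not features:
            note = "no D2 feature correlates significantly with the score"
    elif setting == "R3":
        if d3_features is None:
            d3_features = run_setting(
                cohort, "D3", cfg=cfg, comparison=comparison, with_ablation=False
            ).features
        features = list(d3_features)
    else:  # D3 / R4: exhaustive search
        engine = LoocvEngine(X.to_numpy(), target.to_numpy(), task, cfg)
        search = exhaustive_subset_search(
            X.to_numpy(), target.to_numpy(), task=task, cfg=cfg,
            feature_names=list(X.columns),
        )
        features = list(search[0].features)

    if not features:
        return SettingReport(
            setting, task, domain, (), ids, None, None, note=note,
            n_subsets_evaluated=len(search) if search else None,
        )

    cols = [X.columns.get_loc(f) for f in features]
    engine = LoocvEngine(X.to_numpy(), target.to_numpy(), task, cfg)
    preds = engine.decode(engine.predictions(cols))
    if task == "classify":
        metrics = classification_metrics(target.to_numpy(), preds)
        criterion = float(np.mean(preds == target.to_numpy()))
    else:
        metrics = regression_metrics(target.to_numpy(), preds)
        criterion = metrics.rmse

    single = ablation = None
    if with_ablation and setting in ("D3", "R4"):
        single = _single_feature_table(engine, X, target, features, task)
        ablation = _ablation_table(engine, X, target, features, task)

    return SettingReport(
        setting, task, domain, tuple(features), ids, preds, metrics,
        criterion=criterion,
        n_subsets_evaluated=len(search) if search else None,
        search_top=search[:top_n] if search else None,
        single_feature=single, ablation=ablation, note=note,
    )


def _single_feature_table(engine, X, target, features, task) -> pd.DataFrame:
    """Each selected feature used alone (the per-feature ablation table)."""
    rows = []
    y = target.to_numpy()
    for f in features:
        preds = engine.decode(engine.predictions([X.columns.get_loc(f)]))
        if task == "classify":
            m = classification_metrics(y, preds)
            rows.append(
                {"feature": f, "accuracy_pct": m.accuracy_pct,
                 "f_measure_pct": m.f_measure_pct}
            )
        else:
            m = regression_metrics(y, preds)
            rows.append({"feature": f, "r_single": m.r, "mae": m.mae, "rmse": m.rmse})
    return pd.DataFrame(rows)


def _ablation_table(engine, X, target, features, task) -> pd.DataFrame:
    """The best subset with each feature left out in turn."""
    rows = []
    y = target.to_numpy()
    for f in features:
        remaining = [g for g in features if g != f]
        if not remaining:
            continue
        cols = [X.columns.get_loc(g) for g in remaining]
        preds = engine.decode(engine.predictions(cols))
        if task == "classify":
            m = classification_metrics(y, preds)
            rows.append(
                {"omitted": f, "accuracy_pct": m.accuracy_pct,
                 "f_measure_pct": m.f_measure_pct}
            )
        else:
            m = regression_metrics(y, preds)
            rows.append({"omitted": f, "r_omitted": m.r, "mae": m.mae, "rmse": m.rmse})
    return pd.DataFrame(rows)
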