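"""Cohort-level statistics.

Implements the group-comparison battery: Kolmogorov-Smirnov normality
screening, log/shifted-log transforms of the right-skewed turn-taking
features, two-sided F tests on variances and t tests on means with
Benjamini-Hochberg correction per test family, the distance-from-TD-mean
transform for features whose groups differ in spread but not location,
and feature-score correlations with an optional permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .session import FEATURE_ORDER, SCORE_DOMAINS, CohortTable

#: Features transformed before group comparison: the mean turn-taking gap can
#: be negative, so it gets a shifted log; the gap SD and pause-to-turn ratio
#: are positive and get a plain log.
LOG_FEATURES = ("sd_turn_gap_s", "pause_to_turn_ratio")
SHIFTED_LOG_FEATURES = ("mean_turn_gap_s",)


@dataclass(frozen=True)
class TransformSpec:
    """Per-feature transform used on the analysis scale."""

    feature: str
    kind: Literal["none", "log", "shifted_log"]
    shift_c: float = 0.0

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "none":
            return x
        shifted = x + self.shift_c if self.kind == "shifted_log" else x
        bad = np.nonzero(shifted <= 0)[0]
        if bad.size:
            raise ValidationError(
                f"{self.feature}: log of non-positive value at row {bad[0]}"
            )
        return np.log(shifted)

    def invert(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if self.kind == "none":
            return y
        x = np.exp(y)
        return x - self.shift_c if self.kind == "shifted_log" else x


def ks_normality(
    values: Sequence[float], lilliefors_correction: bool = False
) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's own moments.

    With ``lilliefors_correction`` the p-value accounts for the estimated
    parameters (Lilliefors test); otherwise the classical KS p-value is
    returned, which is anti-conservative when moments are estimated.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValidationError(f"need n >= 4 for the KS test, got {x.size}")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValidationError("constant sample: KS test undefined")
    if lilliefors_correction:
        d, p = lilliefors(x, dist="norm")
        return float(d), float(p)
    d, p = sps.kstest(x, "norm", args=(np.mean(x), sd))
    return float(d), float(p)


def fit_transforms(cohort: CohortTable) -> list[TransformSpec]:
    """Fit the per-feature transforms on the pooled cohort.

    The mean turn-taking gap is shifted so that the pooled minimum equals 1
    before the log (its log is 0 at the cohort minimum); the gap SD and
    pause-to-turn ratio get a plain log; all other features are untouched.
    """
    specs: list[TransformSpec] = []
    df = cohort.data
    for feature in FEATURE_ORDER:
        if feature in SHIFTED_LOG_FEATURES:
            values = df[feature].dropna()
            if values.empty:
                raise ValidationError(f"{feature}: no finite values to fit shift")
            specs.append(TransformSpec(feature, "shifted_log", 1.0 - float(values.min())))
        elif feature in LOG_FEATURES:
            specs.append(TransformSpec(feature, "log"))
        else:
            specs.append(TransformSpec(feature, "none"))
    return specs


def apply_transforms(
    cohort: CohortTable,
    specs: Sequence[TransformSpec],
    on_nonpositive: Literal["error", "undefined"] = "undefined",
) -> pd.DataFrame:
    """Feature matrix on the analysis scale, indexed by participant.

    A non-positive value under a log transform (e.g. a zero pause-to-turn
    ratio) is reported as undefined (NaN) by default rather than imputed;
    ``on_nonpositive="error"`` raises instead, naming the participant.
    """
    df = cohort.data.set_index("participant_id")
    out = pd.DataFrame(index=df.index)
    by_name = {s.feature: s for s in specs}
    for feature in FEATURE_ORDER:
        spec = by_name.get(feature, TransformSpec(feature, "none"))
        values = df[feature].to_numpy(dtype=float)
        transformed = np.full_like(values, np.nan)
        ok = np.isfinite(values)
        if spec.kind != "none":
            arg = values + spec.shift_c if spec.kind == "shifted_log" else values
            bad = ok & (arg <= 0)
            if bad.any():
                if on_nonpositive == "error":
                    raise ValidationError(
                        f"{feature}: log of non-positive value for participant "
                        f"{df.index[np.nonzero(bad)[0][0]]!r}"
                    )
                ok &= ~bad
        transformed[ok] = spec.apply(values[ok])
        out[feature] = transformed
    return out


def variance_ratio_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided F test for equal variances.

    F is the ratio of sample variances (x over y); the p-value doubles the
    smaller tail of F(n_x-1, n_y-1), capped at 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need n >= 2 in both groups")
    vx = np.var(x, ddof=1)
    vy = np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        raise ValidationError("zero variance in one group: F test undefined")
    f = vx / vy
    dist = sps.f(x.size - 1, y.size - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return float(f), float(min(p, 1.0))


def mean_difference_test(
    x: Sequence[float],
    y: Sequence[float],
    variant: Literal["welch", "pooled"] = "welch",
) -> tuple[float, float]:
    """Two-sided t test for equal means (Welch by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("need n >= 2 in both groups")
    t, p = sps.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return float(t), float(p)


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def td_distance(x, m_td: float):
    """Distance-from-TD-mean transform, |x - m_TD|.

    Used for features where the ASD group differs from TD in spread but not
    location, so that both unusually high and unusually low values map to a
    large score.  Accepts scalars or arrays.
    """
    if not math.isfinite(m_td):
        raise ValidationError("TD mean must be finite")
    return np.abs(np.asarray(x, dtype=float) - m_td) if np.ndim(x) else abs(x - m_td)


def prepare_correlation_inputs(
    cohort: CohortTable, comparison: pd.DataFrame
) -> tuple[list[str], pd.DataFrame]:
    """Feature values for the score-correlation analysis.

    Selects the features significant in the F or t test and, for those
    significant under F but *not* t (groups differing in spread, not
    location), replaces the raw values by the distance from the TD-group
    mean, so that both unusually high and unusually low values map to
    large scores.  Returns the selected feature names and a per-participant
    value table.
    """
    sig = comparison[comparison["significant_F"] | comparison["significant_t"]]
    features = list(sig["feature"])
    df = cohort.data.set_index("participant_id")
    td = cohort.group("TD").set_index("participant_id")
    values = pd.DataFrame(index=df.index)
    spread_only = set(
        sig.loc[sig["significant_F"] & ~sig["significant_t"], "feature"]
    )
    for feature in features:
        x = df[feature].astype(float)
        if feature in spread_only:
            values[feature] = td_distance(x.to_numpy(), float(td[feature].mean()))
        else:
            values[feature] = x
    return features, values


def permutation_corr_pvalue(
    x: np.ndarray, y: np.ndarray, n_perm: int, seed: int
) -> float:
    """Two-sided permutation p-value for the Pearson correlation.

    p = (1 + #{|r_perm| >= |r_obs|}) / (1 + n_perm), with y permuted by a
    seeded generator; bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    xc = x - x.mean()
    denom_x = np.sqrt((xc**2).sum())
    r_obs = abs(float(np.corrcoef(x, y)[0, 1]))
    yc = y - y.mean()
    denom_y = np.sqrt((yc**2).sum())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(yc)
        r = abs(float((xc * perm).sum() / (denom_x * denom_y)))
        if r >= r_obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm)


@dataclass(frozen=True)
class CorrelationRow:
    feature: str
    domain: str
    n: int
    r: float
    p: float
    method: Literal["pearson", "permutation"]
    adjusted_p: float = math.nan


def correlate_with_scores(
    cohort: CohortTable,
    feature: str,
    domain: str,
    method: Literal["pearson", "permutation"] = "pearson",
    group: str | None = "ASD",
    feature_values: pd.Series | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationRow:
    """Pearson correlation between one feature and one symptom-score domain.

    Runs on the given group's rows (ASD by default).  ``feature_values``
    may supply pre-transformed values (analysis scale or distance-from-TD),
    indexed by participant; otherwise the raw feature column is used.
    ``method="permutation"`` replaces the parametric p-value with a seeded
    permutation p-value, for features with non-normal distributions.
    """
    if domain not in SCORE_DOMAINS:
        raise ValidationError(f"unknown score domain {domain!r}")
    df = cohort.data if group is None else cohort.group(group)
    df = df.set_index("participant_id")
    if feature_values is not None:
        x = feature_values.reindex(df.index).to_numpy(dtype=float)
    else:
        x = df[feature].to_numpy(dtype=float)
    y = df[domain].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValidationError(f"need >= 4 complete pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant feature or score: correlation undefined")
    r, p_param = sps.pearsonr(x, y)
    if method == "permutation":
        p = permutation_corr_pvalue(x, y, n_perm, seed)
    else:
        p = float(p_param)
    return CorrelationRow(feature, domain, int(x.size), float(r), p, method)


def correlation_table(
    cohort: CohortTable,
    features: Sequence[str],
    feature_values: pd.DataFrame | None = None,
    permutation_features: Sequence[str] = (),
    group: str | None = "ASD",
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlations of several features with all three score domains.

    B-H adjustment is applied within each domain across the tested
    features.  ``permutation_features`` names features whose p-values come
    from the permutation test instead of the parametric one.
    """
    rows = []
    for domain in SCORE_DOMAINS:
        domain_rows = []
        for feature in features:
            fv = feature_values[feature] if feature_values is not None else None
            method = "permutation" if feature in permutation_features else "pearson"
            row = correlate_with_scores(
                cohort, feature, domain, method=method, group=group,
                feature_values=fv, n_perm=n_perm, seed=seed,
            )
            domain_rows.append(row)
        adj = bh_adjust([row.p for row in domain_rows])
        for row, ap in zip(domain_rows, adj):
            rows.append(
                {
                    "feature": row.feature,
                    "domain": row.domain,
                    "n": row.n,
                    "r": row.r,
                    "p": row.p,
                    "adjusted_p": float(ap),
                    "method": row.method,
                }
            )
    return pd.DataFrame(rows)


def comparison_table(
    cohort: CohortTable,
    t_variant: Literal["welch", "pooled"] = "welch",
    bh_family: Literal["per_test", "pooled"] = "per_test",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Group comparison of all 13 features on the analysis scale.

    Applies the fitted transforms, then per feature an F test on variances
    and a t test on means (ASD vs TD); B-H correction is applied within the
    F-test family and within the t-test family (or across both with
    ``bh_family="pooled"``).  Group means/SDs are reported on the analysis
    (transformed) scale, with sample SDs.
    """
    asd = cohort.group("ASD")
    td = cohort.group("TD")
    if asd.empty or td.empty:
        raise ValidationError("both ASD and TD groups must be non-empty")
    specs = fit_transforms(cohort)
    transformed = apply_transforms(cohort, specs)
    groups = cohort.data.set_index("participant_id")["group"]

    rows = []
    for feature in FEATURE_ORDER:
        x = transformed.loc[groups == "ASD", feature].dropna().to_numpy()
        y = transformed.loc[groups == "TD", feature].dropna().to_numpy()
        f_stat, p_f = variance_ratio_test(x, y)
        t_stat, p_t = mean_difference_test(x, y, variant=t_variant)
        rows.append(
            {
                "feature": feature,
                "n_asd": x.size,
                "n_td": y.size,
                "mean_asd": float(np.mean(x)),
                "sd_asd": float(np.std(x, ddof=1)),
                "mean_td": float(np.mean(y)),
                "sd_td": float(np.std(y, ddof=1)),
                "F": f_stat,
                "p_F": p_f,
                "t": t_stat,
                "p_t": p_t,
            }
        )
    table = pd.DataFrame(rows)
    if bh_family == "pooled":
        adj = bh_adjust(np.concatenate([table["p_F"], table["p_t"]]))
        table["adjusted_p_F"] = adj[: len(table)]
        table["adjusted_p_t"] = adj[len(table):]
    else:
        table["adjusted_p_F"] = bh_adjust(table["p_F"])
        table["adjusted_p_t"] = bh_adjust(table["p_t"])
    table["significant_F"] = table["adjusted_p_F"] < alpha
    table["significant_t"] = table["adjusted_p_t"] < alpha
    return table
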