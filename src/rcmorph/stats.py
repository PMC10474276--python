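"""Cohort-level validation and population statistics.

This module implements the statistical layer of the pipeline:

* normality-gated correlation (Pearson when both series pass Shapiro–Wilk at
  alpha, Spearman otherwise) — the rule used for every correlation table;
* the partial-versus-full-coverage correlation table (raw volume, normalized
  volume, relative contribution at 10/20/30/40% lateral coverage against
  complete coverage);
* the scapula-normalization correlation sweep (cumulative scapula volume vs
  cumulative muscle volume at each percent location, overall and by sex);
* two-way (sex × age-bin) ANOVA with Type III sums of squares, partial η²
  effect sizes, and Bonferroni-corrected pairwise post-hoc comparisons;
* a normative reference database of sex × age-bin cell means/SDs per muscle
  and metric at a chosen coverage, yielding demographic-matched z-scores.

Type III sums of squares are used because the cohort cells are generally
unbalanced; ``ss_type=2`` is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps
from sklearn.base import BaseEstimator
from statsmodels.stats.anova import anova_lm

from .curves import VolumeCurveSet
from .schema import ScanRecord, age_bin_label

__all__ = [
    "CorrelationResult",
    "AnovaResult",
    "NormativeReference",
    "StatsError",
    "correlation_gated",
    "partial_vs_full_analysis",
    "scapula_muscle_correlation_sweep",
    "two_way_anova",
    "build_reference_database",
    "z_score",
]

ALPHA = 0.05


class StatsError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass(frozen=True)
class CorrelationResult:
    """A gated correlation: method chosen by per-series normality tests."""

    method: str  # "pearson" | "spearman"
    r: float
    p: float
    n: int
    shapiro_p: tuple[float, float]


def correlation_gated(
    x: Sequence[float], y: Sequence[float], alpha: float = ALPHA
) -> CorrelationResult:
    """Correlate two series, choosing Pearson or Spearman by normality.

    Pearson's r is used when both series pass Shapiro–Wilk normality
    (p > alpha on each); otherwise Spearman's rank correlation.  Pairs with
    a missing value in either series are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 4:
        raise StatsError(f"need at least 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("correlation undefined for a constant series")
    sw_x = float(sps.shapiro(x).pvalue)
    sw_y = float(sps.shapiro(y).pvalue)
    if sw_x > alpha and sw_y > alpha:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(method=method, r=float(r), p=float(p), n=n,
                             shapiro_p=(sw_x, sw_y))


# ---------------------------------------------------------------------------
# partial vs full coverage
# ---------------------------------------------------------------------------


def _metric_at(curves: VolumeCurveSet, roi: str, p: int) -> dict[str, float]:
    out = {"raw_volume": np.nan, "normalized_volume": np.nan, "relative_contribution": np.nan}
    if roi == "scapula":
        out["raw_volume"] = curves.value("scapula", p)
        return out
    mv = curves.muscle_with_fat(roi, p)
    scap = curves.value("scapula", p)
    total = sum(curves.muscle_with_fat(m, p) for m in curves.schema.muscles)
    out["raw_volume"] = mv
    out["normalized_volume"] = mv / scap if scap > 0 else np.nan
    out["relative_contribution"] = mv / total * 100.0 if total > 0 else np.nan
    return out


def partial_vs_full_analysis(
    curve_sets: Sequence[VolumeCurveSet],
    coverages: Sequence[int] = (10, 20, 30, 40),
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Correlate metrics at partial lateral coverages against full coverage.

    Every scan must be complete-coverage (coverage 100%); for each scan the
    raw volume, normalized volume and relative contribution are evaluated at
    each truncation point and at p = 100, then correlated across scans with
    the normality-gated rule.  Rows: (roi, metric, coverage_pct) with r, p,
    method, n — the shape of a partial-vs-full correlation table.  The
    scapula appears for raw volume only (its normalized metrics are
    degenerate by construction).
    """
    if len(curve_sets) < 4:
        raise StatsError(f"need at least 4 complete-coverage scans, got {len(curve_sets)}")
    for cs in curve_sets:
        if cs.coverage_percent < 100.0 - 1e-9:
            raise StatsError("partial_vs_full_analysis requires complete-coverage scans")
    rois = ["scapula", *curve_sets[0].schema.muscles]
    rows = []
    for roi in rois:
        metrics = ["raw_volume"] if roi == "scapula" else [
            "raw_volume", "normalized_volume", "relative_contribution"
        ]
        full = {m: np.array([_metric_at(cs, roi, 100)[m] for cs in curve_sets]) for m in metrics}
        for cov in coverages:
            partial = {m: np.array([_metric_at(cs, roi, int(cov))[m] for cs in curve_sets])
                       for m in metrics}
            for m in metrics:
                try:
                    res = correlation_gated(partial[m], full[m], alpha=alpha)
                    rows.append((roi, m, int(cov), res.r, res.p, res.method, res.n))
                except StatsError:
                    # constant series across the cohort: correlation undefined
                    rows.append((roi, m, int(cov), np.nan, np.nan, "undefined",
                                 len(curve_sets)))
    return pd.DataFrame(
        rows, columns=["roi", "metric", "coverage_pct", "r", "p", "method", "n"]
    )


def scapula_muscle_correlation_sweep(
    curve_sets: Sequence[VolumeCurveSet],
    records: Sequence[ScanRecord],
    p_range: Sequence[int] = tuple(range(30, 41)),
    strata: Sequence[str] = ("all", "male", "female"),
    max_age_years: float = 40.0,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Correlate cumulative scapula volume against each muscle's volume per location.

    Validates the scapula as a patient-size normalizer: at each percent
    location in ``p_range``, the cumulative scapular volume is correlated
    (gated rule) with each muscle's cumulative volume (including fat) across
    scans, overall and within each sex.  Scans at or above ``max_age_years``
    are excluded to avoid confounding by age-related atrophy.
    """
    if len(curve_sets) != len(records):
        raise ValueError("curve_sets and records must align")
    keep = [i for i, r in enumerate(records) if r.age_years < max_age_years]
    rows = []
    for stratum in strata:
        idx = keep if stratum == "all" else [i for i in keep if records[i].sex == stratum]
        if len(idx) < 4:
            raise StatsError(f"stratum {stratum!r} has {len(idx)} scans (< 4)")
        for p in p_range:
            scap = np.array([curve_sets[i].value("scapula", int(p)) for i in idx])
            for muscle in curve_sets[0].schema.muscles:
                mus = np.array([curve_sets[i].muscle_with_fat(muscle, int(p)) for i in idx])
                res = correlation_gated(scap, mus, alpha=alpha)
                rows.append((stratum, muscle, int(p), res.r, res.p, res.method, res.n))
    return pd.DataFrame(rows, columns=["stratum", "muscle", "p", "r", "p_value", "method", "n"])


# ---------------------------------------------------------------------------
# two-way ANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnovaResult:
    """Two-way factorial ANOVA summary with effect sizes and post-hoc tests.

    ``effects`` has one row per effect (sex, age_bin, sex:age_bin) with the
    F statistic, its degrees of freedom, p value and partial η²
    (SS_effect / (SS_effect + SS_error)).  ``posthoc`` holds Bonferroni-
    adjusted pairwise comparisons within each significant main effect.
    """

    effects: pd.DataFrame
    posthoc: pd.DataFrame
    ss_error: float
    df_error: int


def two_way_anova(
    values: Sequence[float],
    sex: Sequence[str],
    age_bin: Sequence[str],
    ss_type: int = 3,
    alpha: float = ALPHA,
    on_empty_cell: str = "warn",
) -> AnovaResult:
    """Sex × age-bin factorial ANOVA with interaction.

    Type III sums of squares (via sum-to-zero contrasts) by default, suited
    to unbalanced cell counts; partial η² per effect; pairwise post-hoc
    comparisons (pooled-error t tests with Bonferroni adjustment over all
    pairs within the factor) for each main effect significant at ``alpha``.
    ``on_empty_cell``: 'raise' aborts on an empty design cell, 'warn'
    proceeds with the estimable effects.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "sex": pd.Categorical(sex),
        "age_bin": pd.Categorical(age_bin),
    }).dropna()
    if df["sex"].nunique() < 2 or df["age_bin"].nunique() < 2:
        raise StatsError("need at least two levels per factor")
    cell_counts = df.groupby(["sex", "age_bin"], observed=False).size()
    if (cell_counts == 0).any():
        empty = cell_counts[cell_counts == 0].index.tolist()
        if on_empty_cell == "raise":
            raise StatsError(f"empty design cells: {empty}")
        import warnings

        warnings.warn(f"empty design cells {empty}; interaction effects may be inestimable")
    if ss_type == 3:
        formula = "value ~ C(sex, Sum) * C(age_bin, Sum)"
    else:
        formula = "value ~ C(sex) * C(age_bin)"
    fit = smf.ols(formula, data=df).fit()
    table = anova_lm(fit, typ=ss_type)
    ss_error = float(table.loc["Residual", "sum_sq"])
    df_error = int(table.loc["Residual", "df"])
    name_map = {}
    for idx in table.index:
        if "sex" in idx and "age_bin" in idx:
            name_map[idx] = "sex:age_bin"
        elif "sex" in idx:
            name_map[idx] = "sex"
        elif "age_bin" in idx:
            name_map[idx] = "age_bin"
    rows = []
    for idx, effect in name_map.items():
        ss = float(table.loc[idx, "sum_sq"])
        rows.append({
            "effect": effect,
            "F": float(table.loc[idx, "F"]),
            "df1": int(table.loc[idx, "df"]),
            "df2": df_error,
            "p": float(table.loc[idx, "PR(>F)"]),
            "partial_eta_sq": ss / (ss + ss_error) if (ss + ss_error) > 0 else 0.0,
        })
    effects = pd.DataFrame(rows).set_index("effect")

    mse = ss_error / df_error if df_error > 0 else np.nan
    ph_rows = []
    for factor in ("sex", "age_bin"):
        if factor not in effects.index or not effects.loc[factor, "p"] < alpha:
            continue
        groups = df.groupby(factor, observed=True)["value"]
        stats_by_level = {lvl: (g.mean(), len(g)) for lvl, g in groups}
        pairs = list(combinations(sorted(stats_by_level), 2))
        for a, b in pairs:
            (ma, na), (mb, nb) = stats_by_level[a], stats_by_level[b]
            se = np.sqrt(mse * (1.0 / na + 1.0 / nb))
            t = (ma - mb) / se if se > 0 else np.nan
            p_raw = 2.0 * sps.t.sf(abs(t), df_error)
            ph_rows.append({
                "effect": factor, "level_a": str(a), "level_b": str(b),
                "mean_diff": ma - mb, "t": t,
                "p_bonferroni": min(1.0, p_raw * len(pairs)),
            })
    posthoc = pd.DataFrame(
        ph_rows, columns=["effect", "level_a", "level_b", "mean_diff", "t", "p_bonferroni"]
    )
    return AnovaResult(effects=effects, posthoc=posthoc, ss_error=ss_error, df_error=df_error)


# ---------------------------------------------------------------------------
# normative reference database / z-scores
# ---------------------------------------------------------------------------


class NormativeReference(BaseEstimator):
    """Sex × age-bin normative reference database for muscle metrics.

    Fit on a tidy cohort frame with columns ``scan_id, sex, age_years,
    muscle, metric, value`` (metric values evaluated at the analysis
    coverage ``p_star``); yields demographic-matched z-scores.  Cells with
    fewer than two scans or zero spread are flagged unusable.

    Attributes
    ----------
    cells_ : DataFrame
        One row per (sex, age_bin, muscle, metric): mean, sd, n, usable.
    p_star : int
        Percent-coverage location the metrics were evaluated at.
    """

    def __init__(self, p_star: int = 30):
        self.p_star = p_star

    def fit(self, cohort: pd.DataFrame, y=None) -> "NormativeReference":
        required = {"scan_id", "sex", "age_years", "muscle", "metric", "value"}
        missing = required - set(cohort.columns)
        if missing:
            raise ValueError(f"cohort frame missing columns {sorted(missing)}")
        if cohort.empty:
            raise StatsError("no eligible scans to build a reference database")
        work = cohort.copy()
        work["age_bin"] = work["age_years"].map(age_bin_label)
        grouped = work.groupby(["sex", "age_bin", "muscle", "metric"], observed=True)["value"]
        cells = grouped.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
        cells["sd"] = cells["sd"].fillna(0.0)
        # numerically-zero spread (identical values up to round-off) is unusable
        tiny = 1e-12 * np.maximum(np.abs(cells["mean"]), 1.0)
        cells.loc[cells["sd"] <= tiny, "sd"] = 0.0
        cells["usable"] = (cells["n"] >= 2) & (cells["sd"] > 0)
        self.cells_ = cells
        return self

    def _cell(self, sex: str, age_years: float, muscle: str, metric: str) -> pd.Series:
        bin_label = age_bin_label(age_years)
        sel = self.cells_[
            (self.cells_["sex"] == sex)
            & (self.cells_["age_bin"] == bin_label)
            & (self.cells_["muscle"] == muscle)
            & (self.cells_["metric"] == metric)
        ]
        if sel.empty:
            raise StatsError(f"no reference cell for {sex}/{bin_label}/{muscle}/{metric}")
        cell = sel.iloc[0]
        if not cell["usable"]:
            raise StatsError(
                f"reference cell {sex}/{bin_label}/{muscle}/{metric} unusable "
                f"(n={int(cell['n'])}, sd={cell['sd']:.4g})"
            )
        return cell

    def z_score(self, value: float, sex: str, age_years: float, muscle: str, metric: str) -> float:
        """z = (value − cell mean) / cell SD for the matching demographic cell."""
        cell = self._cell(sex, age_years, muscle, metric)
        return float((value - cell["mean"]) / cell["sd"])

    def transform(self, queries: pd.DataFrame) -> pd.DataFrame:
        """Append a ``z`` column to a tidy query frame (same columns as fit)."""
        out = queries.copy()
        out["z"] = [
            self.z_score(row.value, row.sex, row.age_years, row.muscle, row.metric)
            for row in queries.itertuples()
        ]
        return out


def build_reference_database(cohort: pd.DataFrame, p_star: int = 30) -> NormativeReference:
    """Fit a :class:`NormativeReference` on a tidy cohort metrics frame."""
    return NormativeReference(p_star=p_star).fit(cohort)


def z_score(
    db: NormativeReference, value: float, sex: str, age_years: float, muscle: str, metric: str
) -> float:
    """Functional wrapper for :meth:`NormativeReference.z_score`."""
    return db.z_score(value, sex, age_years, muscle, metric)
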