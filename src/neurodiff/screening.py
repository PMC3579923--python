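"""Screening of features robust to scan-order intensity autocorrelation.

Spatial illumination inhomogeneity plus line-wise scanning of the wells
makes consecutive images correlated; features that track the illumination
rather than the cells inherit that serial correlation. Each feature is
tested for AR(p)-type autocorrelation with the Breusch-Godfrey test on every
(condition, well) series in scan order, the evidence is aggregated by the
median test statistic across series, and the k least-autocorrelated features
are kept. The screening never looks at class labels, so it cannot leak the
differentiation signal into feature selection.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError, ValidationError
from .io import TABLE_META_COLUMNS


def breusch_godfrey_test(series, order: int = 1) -> tuple[float, float]:
    """Breusch-Godfrey LM test of AR(``order``) residual autocorrelation.

    The main regression is intercept-only; the auxiliary regression explains
    the residuals by an intercept plus ``order`` lagged residuals (pre-sample
    lags set to zero). The statistic is n times the auxiliary R-squared,
    asymptotically chi-square with ``order`` degrees of freedom.
    """
    x = np.asarray(series, dtype=np.float64)
    if order < 1:
        raise ValidationError("order must be >= 1")
    n = x.size
    if n <= order + 2:
        raise ValidationError("series too short for the requested lag order")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant series has no residual variation")
    e = x - x.mean()
    Z = np.ones((n, order + 1))
    for lag in range(1, order + 1):
        Z[lag:, lag] = e[:-lag]
        Z[:lag, lag] = 0.0
    beta, _, _, _ = np.linalg.lstsq(Z, e, rcond=None)
    fitted = Z @ beta
    ss_res = float(np.sum((e - fitted) ** 2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    statistic = n * r2
    p_value = float(sps.chi2.sf(statistic, df=order))
    return float(statistic), p_value


@dataclasses.dataclass
class AutocorrelationReport:
    order: int
    k: int
    per_series: dict      # (feature, condition, well) -> {statistic, p_value}
    aggregate: dict       # feature -> median statistic across series
    ranking: list         # all features, least autocorrelated first
    selected_features: list

    def to_dict(self) -> dict:
        return {
            "order": self.order, "k": self.k,
            "aggregate": self.aggregate, "ranking": self.ranking,
            "selected_features": self.selected_features,
            "per_series": {"|".join(map(str, k)): v
                           for k, v in self.per_series.items()},
        }


def _feature_columns(table: pd.DataFrame) -> list[str]:
    skip = set(TABLE_META_COLUMNS) | {"transformed"}
    return [c for c in table.columns
            if c not in skip and pd.api.types.is_numeric_dtype(table[c])]


def rank_features_by_autocorrelation(table: pd.DataFrame, order: int = 1,
                                     k: int = 20) -> AutocorrelationReport:
    """Rank features by serial-correlation evidence and keep the ``k`` least.

    Series are formed per (condition, well), ordered by day then scan index.
    Constant series carry no evidence and are excluded from the per-feature
    median. Ranking ties break lexicographically by feature name.
    """
    features = _feature_columns(table)
    if k > len(features):
        raise ValidationError(f"k={k} exceeds the {len(features)} available features")
    ordered = table.sort_values(["condition", "well", "day", "scan_index"],
                                kind="stable")
    per_series, aggregate = {}, {}
    for feat in features:
        stats_f = []
        for (cond, well), g in ordered.groupby(["condition", "well"], sort=True):
            series = g[feat].to_numpy()
            try:
                stat, p = breusch_godfrey_test(series, order)
            except DegenerateInputError:
                continue
            per_series[(feat, cond, well)] = {"statistic": stat, "p_value": p}
            stats_f.append(stat)
        aggregate[feat] = float(np.median(stats_f)) if stats_f else 0.0
    ranking = sorted(features, key=lambda f: (aggregate[f], f))
    return AutocorrelationReport(order=order, k=k, per_series=per_series,
                                 aggregate=aggregate, ranking=ranking,
                                 selected_features=ranking[:k])


class AutocorrelationScreen:
    """Selector-style front end: ``fit`` ranks, ``transform`` keeps the k
    least-autocorrelated feature columns (metadata columns pass through)."""

    def __init__(self, order: int = 1, k: int = 20):
        self.order = order
        self.k = k

    def fit(self, table: pd.DataFrame, y=None):
        self.report_ = rank_features_by_autocorrelation(table, self.order, self.k)
        self.selected_features_ = list(self.report_.selected_features)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        meta = [c for c in table.columns if c in set(TABLE_META_COLUMNS) | {"transformed"}]
        return table[meta + self.selected_features_]

    def fit_transform(self, table: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(table, y).transform(table)

    def get_params(self, deep: bool = True) -> dict:
        return {"order": self.order, "k": self.k}

    def set_params(self, **kw):
        for key, v in kw.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, v)
        return self
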