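"""Assemble analysis inputs from monthly flow and covariate series.

The flow measure is the monthly count of crossing attempts

    Y_t = A_t + P_t + D_t

the sum of sea arrivals, pushbacks to the departure coast, and recorded
migrant deaths.  This module builds that series, the mortality rate per
1000 attempts, the lagged covariate design matrix (lags t-1 ... t-6), the
log transform used to stabilise the variance, and performs single
imputation of isolated missing covariate points with a Kalman smoother.

Containers are thin wrappers over pandas DataFrames keyed on a
first-of-month ``DatetimeIndex``; all joins use that key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    AlignmentError,
    ImputationError,
    ValidationError,
    FlowImpactError,
)

__all__ = [
    "FlowSeries",
    "CovariatePanel",
    "InterventionSpec",
    "assemble_crossing_attempts",
    "mortality_rate",
    "aggregate_to_monthly",
    "impute_missing_kalman",
    "KalmanImputer",
    "build_design_matrix",
    "LagDesignTransformer",
    "log_transform",
    "inverse_log_transform",
    "resolve_intervention_month",
]


def _check_month_index(idx: pd.Index, what: str) -> pd.DatetimeIndex:
    if not isinstance(idx, pd.DatetimeIndex):
        raise AlignmentError(f"{what}: index must be a DatetimeIndex of months")
    if len(idx) > 1:
        expected = pd.date_range(idx[0], periods=len(idx), freq="MS")
        if not idx.equals(expected):
            raise AlignmentError(
                f"{what}: months must be consecutive first-of-month dates "
                "with no gaps"
            )
    return idx


@dataclass
class FlowSeries:
    """Aligned monthly arrivals, pushbacks, deaths and the derived total.

    Maintains the exact integer identity ``attempts = arrivals + pushbacks
    + deaths`` at every month; construction fails if it does not hold.
    """

    data: pd.DataFrame  # columns: arrivals, pushbacks, deaths, attempts

    def __post_init__(self) -> None:
        required = {"arrivals", "pushbacks", "deaths", "attempts"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"FlowSeries missing columns {sorted(missing)}")
        _check_month_index(self.data.index, "FlowSeries")
        if (self.data[list(required)] < 0).any().any():
            raise ValidationError("FlowSeries: counts must be non-negative")
        total = self.data.arrivals + self.data.pushbacks + self.data.deaths
        if not (total == self.data.attempts).all():
            raise ValidationError(
                "FlowSeries: attempts != arrivals + pushbacks + deaths"
            )

    @classmethod
    def from_components(cls, arrivals, pushbacks, deaths) -> "FlowSeries":
        return assemble_crossing_attempts(arrivals, pushbacks, deaths)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def arrivals(self) -> pd.Series:
        return self.data["arrivals"]

    @property
    def pushbacks(self) -> pd.Series:
        return self.data["pushbacks"]

    @property
    def deaths(self) -> pd.Series:
        return self.data["deaths"]

    @property
    def attempts(self) -> pd.Series:
        return self.data["attempts"]

    def to_csv(self, path) -> None:
        self.data.rename_axis("month").to_csv(path, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path) -> "FlowSeries":
        df = pd.read_csv(path, parse_dates=["month"], index_col="month")
        return cls(df)


@dataclass
class CovariatePanel:
    """Named monthly covariate columns, with lag and scaling metadata.

    ``lag_tags`` maps each column to its ``(base name, lag)`` pair (lag 0
    for original columns); ``scaling`` records the (mean, sd) used if the
    panel was standardized, so the transform is reproducible.
    """

    data: pd.DataFrame
    lag_tags: dict[str, tuple[str, int]] = field(default_factory=dict)
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_month_index(self.data.index, "CovariatePanel")
        if not self.lag_tags:
            self.lag_tags = {c: (c, 0) for c in self.data.columns}

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def columns(self):
        return self.data.columns

    def to_csv(self, path) -> None:
        self.data.rename_axis("month").to_csv(path, date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, path) -> "CovariatePanel":
        df = pd.read_csv(path, parse_dates=["month"], index_col="month")
        return cls(df)


@dataclass
class InterventionSpec:
    """A named intervention with a calendar start date.

    The month containing ``start_date`` is the first post-intervention
    month tau, even for mid-month starts: any partial-month treatment
    effect must not leak into the training window.
    """

    name: str
    start_date: pd.Timestamp

    def __post_init__(self) -> None:
        self.start_date = pd.Timestamp(self.start_date)

    @property
    def tau_month(self) -> pd.Timestamp:
        return self.start_date.normalize().replace(day=1)


def assemble_crossing_attempts(arrivals, pushbacks, deaths) -> FlowSeries:
    """Build the crossing-attempts series Y = A + P + D.

    The three inputs must share an identical, gapless monthly index.
    """
    a, p, d = (pd.Series(s) for s in (arrivals, pushbacks, deaths))
    if not (a.index.equals(p.index) and a.index.equals(d.index)):
        raise AlignmentError(
            "arrivals, pushbacks and deaths must share an identical month index"
        )
    _check_month_index(a.index, "assemble_crossing_attempts")
    for name, s in (("arrivals", a), ("pushbacks", p), ("deaths", d)):
        if s.isna().any():
            raise ValidationError(f"{name} contains missing values")
        if (s < 0).any():
            raise ValidationError(f"{name} contains negative counts")
    df = pd.DataFrame(
        {
            "arrivals": a.astype(np.int64),
            "pushbacks": p.astype(np.int64),
            "deaths": d.astype(np.int64),
        }
    )
    df["attempts"] = df.sum(axis=1)
    return FlowSeries(df)


def mortality_rate(flow: FlowSeries) -> pd.Series:
    """Deaths per 1000 crossing attempts; NaN where no attempts occurred."""
    y = flow.attempts.astype(float)
    rate = 1000.0 * flow.deaths / y.where(y > 0)
    return rate.rename("mortality_per_1000")


def aggregate_to_monthly(series: pd.Series, how: str = "sum") -> pd.Series:
    """Aggregate a sub-monthly series to calendar months.

    ``how='sum'`` for counts, ``how='mean'`` for rates/indices.  Months
    with no observations yield NaN (to be imputed downstream).
    """
    if how not in ("sum", "mean"):
        raise ValueError(f"how must be 'sum' or 'mean', got {how!r}")
    if not isinstance(series.index, pd.DatetimeIndex):
        raise AlignmentError("aggregate_to_monthly requires a DatetimeIndex")
    grouped = series.resample("MS")
    if how == "sum":
        return grouped.sum(min_count=1)
    return grouped.mean()


class KalmanImputer(TransformerMixin, BaseEstimator):
    """Single imputation of isolated missing points via Kalman smoothing.

    For each column, a local-linear-trend state-space model is fitted by
    maximum likelihood to the observed points and missing entries are
    replaced by the smoothed state mean.  Observed values are never
    modified.  Columns without missing values pass through untouched.

    Parameters
    ----------
    max_missing_frac : float
        Refuse to impute a column with more than this fraction missing
        (single imputation is only appropriate for isolated gaps).
    """

    def __init__(self, max_missing_frac: float = 0.10):
        self.max_missing_frac = max_missing_frac

    def fit(self, X, y=None):
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else len(X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        self.imputed_ = {}
        for col in out.columns:
            s = out[col]
            if not s.isna().any():
                continue
            out[col] = _impute_column(s, self.max_missing_frac)
            self.imputed_[col] = list(s.index[s.isna()])
        return out


def _impute_column(series: pd.Series, max_missing_frac: float) -> pd.Series:
    from statsmodels.tsa.statespace.structural import UnobservedComponents

    n_missing = int(series.isna().sum())
    if n_missing == len(series):
        raise ImputationError("cannot impute an all-missing series")
    # single imputation is for isolated gaps: allow at most ~10% missing
    # (but always at least one point, so short fixtures remain usable)
    allowed = max(1, int(round(max_missing_frac * len(series))))
    if n_missing > allowed:
        raise ImputationError(
            f"{series.name or 'series'}: {n_missing}/{len(series)} missing "
            f"exceeds the {max_missing_frac:.0%} single-imputation limit"
        )
    values = series.to_numpy(float)
    model = UnobservedComponents(values, level="local linear trend")
    with np.errstate(all="ignore"):
        res = model.fit(disp=False, maxiter=200)
    smoothed = res.smoothed_state[0]
    out = series.copy()
    mask = series.isna().to_numpy()
    out.iloc[mask] = smoothed[mask]
    return out


def impute_missing_kalman(series: pd.Series) -> pd.Series:
    """Impute isolated missing points of one monthly series (see KalmanImputer)."""
    if not series.isna().any():
        return series.copy()
    return _impute_column(series, max_missing_frac=0.10)


class LagDesignTransformer(TransformerMixin, BaseEstimator):
    """Expand a covariate panel with lagged copies and optional scaling.

    Each base column gains lagged copies at t-1 ... t-``max_lag``; the
    first ``max_lag`` months (which would contain undefined lags) are
    dropped from the index.  If ``standardize``, every output column is
    centered and scaled using statistics from the fit window only — fit on
    the pre-intervention months so the counterfactual never uses
    post-intervention information.
    """

    def __init__(self, max_lag: int = 6, standardize: bool = True):
        self.max_lag = max_lag
        self.standardize = standardize

    @staticmethod
    def _expand(df: pd.DataFrame, max_lag: int) -> tuple[pd.DataFrame, dict]:
        if max_lag >= len(df):
            raise ValueError(
                f"max_lag={max_lag} must be smaller than the series length {len(df)}"
            )
        pieces = {c: df[c] for c in df.columns}
        tags = {c: (c, 0) for c in df.columns}
        for j in range(1, max_lag + 1):
            for c in df.columns:
                name = f"{c}.lag{j}"
                pieces[name] = df[c].shift(j)
                tags[name] = (c, j)
        wide = pd.DataFrame(pieces)
        return wide.iloc[max_lag:], tags

    def fit(self, X: pd.DataFrame, y=None):
        wide, tags = self._expand(X, self.max_lag)
        self.lag_tags_ = tags
        self.scaling_ = {}
        if self.standardize:
            for c in wide.columns:
                mu = float(wide[c].mean())
                sd = float(wide[c].std(ddof=0))
                self.scaling_[c] = (mu, sd if sd > 0 else 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        wide, _ = self._expand(X, self.max_lag)
        if self.standardize:
            for c in wide.columns:
                mu, sd = self.scaling_[c]
                wide[c] = (wide[c] - mu) / sd
        return wide


def build_design_matrix(
    panel: CovariatePanel,
    max_lag: int = 6,
    standardize: bool = True,
    stats_through: pd.Timestamp | None = None,
) -> CovariatePanel:
    """Build the lagged (and optionally standardized) design panel.

    ``stats_through``: if given, standardization statistics are computed on
    months strictly before this date (the pre-intervention window) and then
    applied to the whole panel, so the post-period design carries no
    information about its own distribution into the fit.
    """
    if panel.data.isna().any().any():
        raise ValidationError(
            "panel contains missing values; impute before building the design"
        )
    tr = LagDesignTransformer(max_lag=max_lag, standardize=standardize)
    if stats_through is not None:
        fit_df = panel.data.loc[panel.data.index < pd.Timestamp(stats_through)]
        if len(fit_df) <= max_lag:
            raise ValueError("pre-period too short for the requested max_lag")
        tr.fit(fit_df)
    else:
        tr.fit(panel.data)
    out = tr.transform(panel.data)
    return CovariatePanel(out, lag_tags=dict(tr.lag_tags_), scaling=dict(tr.scaling_))


def log_transform(y, offset: float = 1.0) -> pd.Series:
    """log(Y + offset) of the attempts series (variance stabilisation).

    ``offset`` must be positive when the series contains zeros; the default
    offset 1 (log1p) changes large counts negligibly while keeping zero
    months finite.  Accepts a FlowSeries or a numeric series.
    """
    if isinstance(y, FlowSeries):
        y = y.attempts
    y = pd.Series(y, dtype=float)
    if offset < 0:
        raise ValueError("offset must be >= 0")
    if offset == 0 and (y <= 0).any():
        raise FlowImpactError(
            "series contains zeros; a positive offset is required for the log"
        )
    return np.log(y + offset)


def inverse_log_transform(z, offset: float = 1.0):
    """Inverse of :func:`log_transform`: exp(z) - offset."""
    return np.exp(z) - offset


def resolve_intervention_month(
    spec: InterventionSpec, index: pd.DatetimeIndex
) -> pd.Timestamp:
    """Map an intervention start date to its month tau within ``index``.

    tau is the calendar month containing the start date; the pre-period is
    all months strictly before tau and the post-period all months >= tau.
    """
    tau = spec.tau_month
    if tau not in index:
        raise ValueError(
            f"intervention {spec.name!r} start month {tau.date()} is outside "
            "the observation window"
        )
    return tau
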