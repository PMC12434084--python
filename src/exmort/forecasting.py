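"""Phase I: per-cause trend + yearly-seasonality forecasting.

Each cause is fitted independently by ordinary least squares on a linear
trend plus a truncated Fourier series at the yearly period (the model class
an additive seasonal forecaster such as Prophet reduces to when changepoints
and extra seasonalities are switched off).  This keeps the fit deterministic
and dependency-free.  A within-week cycle cannot exist in weekly-aggregated
counts, so no "weekly seasonality" term is included.

Forecasts are kept real-valued: rounding to integers would create spurious
ties in the downstream strict-exceedance comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .errors import ConfigError, FittingError
from .panel import FORECAST, WEEK, MortalityPanel
from .simulate import YEARLY_PERIOD_WEEKS


@dataclass
class ForecastConfig:
    """Settings of the harmonic trend forecaster.

    horizon:        forecast length in weeks (default 104, two years)
    fourier_order:  number of yearly sine/cosine harmonic pairs
    period_weeks:   seasonal period in weeks (365.25/7 by default)
    scale:          'identity' fits counts directly; 'log1p' fits log(1+y) and
                    back-transforms, guaranteeing nonnegative forecasts
    clip_negative:  floor identity-scale forecasts at 0
    """

    horizon: int = 104
    fourier_order: int = 10
    period_weeks: float = YEARLY_PERIOD_WEEKS
    scale: str = "identity"
    clip_negative: bool = True

    def validate(self) -> None:
        if self.horizon < 1:
            raise ConfigError("horizon must be >= 1")
        if self.fourier_order < 1:
            raise ConfigError("fourier_order must be >= 1")
        if self.period_weeks <= 0:
            raise ConfigError("period_weeks must be positive")
        if self.scale not in ("identity", "log1p"):
            raise ConfigError(f"unknown scale {self.scale!r}")

    @property
    def n_params(self) -> int:
        return 2 + 2 * self.fourier_order


@runtime_checkable
class Forecaster(Protocol):
    """Adapter interface for plugging in an external seasonal forecaster."""

    def fit(self, panel: MortalityPanel) -> "Forecaster": ...

    def forecast(self, horizon: int | None = None) -> MortalityPanel: ...


def _design(t: np.ndarray, config: ForecastConfig) -> np.ndarray:
    cols = [np.ones_like(t, dtype=float), t.astype(float)]
    for j in range(1, config.fourier_order + 1):
        w = 2.0 * np.pi * j * t / config.period_weeks
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


class HarmonicTrendForecaster:
    """OLS fit of counts against [1, t, sin(2*pi*j*t/P), cos(2*pi*j*t/P)].

    Fitted attributes (set by :meth:`fit`):

    coef_         (n_causes, 2 + 2*fourier_order) coefficient matrix
    train_dates_  the training date range
    cause_labels_ cause labels in training order
    """

    def __init__(self, config: ForecastConfig | None = None):
        self.config = config or ForecastConfig()
        self.config.validate()

    def fit(self, panel: MortalityPanel) -> "HarmonicTrendForecaster":
        p = self.config.n_params
        if panel.n_weeks < 2 * p:
            raise FittingError(
                f"need at least {2 * p} weeks to fit {p} parameters per cause, "
                f"got {panel.n_weeks}"
            )
        t = np.arange(panel.n_weeks)
        X = _design(t, self.config)
        if np.linalg.matrix_rank(X) < p:
            raise FittingError("rank-deficient design matrix")
        y = panel.counts
        if self.config.scale == "log1p":
            y = np.log1p(y)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        self.coef_ = coef.T  # (K, p)
        self.train_dates_ = panel.dates
        self.cause_labels_ = list(panel.cause_labels)
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise FittingError("forecaster is not fitted")

    def _predict_at(self, t: np.ndarray) -> np.ndarray:
        X = _design(t, self.config)
        yhat = X @ self.coef_.T
        if self.config.scale == "log1p":
            yhat = np.expm1(yhat)
        if self.config.clip_negative:
            yhat = np.maximum(yhat, 0.0)
        return yhat

    def fitted_values(self) -> np.ndarray:
        """In-sample predicted counts over the training weeks."""
        self._check_fitted()
        return self._predict_at(np.arange(len(self.train_dates_)))

    def forecast(self, horizon: int | None = None) -> MortalityPanel:
        """Forecast ``horizon`` weeks continuing at 7-day spacing from training."""
        self._check_fitted()
        horizon = self.config.horizon if horizon is None else int(horizon)
        if horizon < 1:
            raise ConfigError("horizon must be >= 1")
        n = len(self.train_dates_)
        yhat = self._predict_at(np.arange(n, n + horizon))
        dates = pd.date_range(self.train_dates_[-1] + WEEK, periods=horizon, freq="7D")
        return MortalityPanel(
            dates, yhat, self.cause_labels_, segments=[FORECAST] * horizon
        )


def fit_forecaster(
    panel: MortalityPanel, config: ForecastConfig | None = None
) -> HarmonicTrendForecaster:
    return HarmonicTrendForecaster(config).fit(panel)


def fitted_correlations(panel: MortalityPanel, model: HarmonicTrendForecaster) -> pd.Series:
    """Pearson r between observed counts and in-sample fitted values, per cause.

    A zero-variance observed (or fitted) series has no defined correlation;
    it is reported as NaN with a warning.
    """
    model._check_fitted()
    if list(panel.cause_labels) != model.cause_labels_ or not panel.dates.equals(
        model.train_dates_
    ):
        raise FittingError("panel does not match the model's training data")
    fitted = model.fitted_values()
    out = {}
    for j, label in enumerate(panel.cause_labels):
        obs = panel.counts[:, j]
        fit = fitted[:, j]
        if np.std(obs) == 0.0 or np.std(fit) == 0.0:
            warnings.warn(
                f"correlation undefined for {label!r} (zero variance)", stacklevel=2
            )
            out[label] = np.nan
        else:
            out[label] = float(np.corrcoef(obs, fit)[0, 1])
    return pd.Series(out, name="pearson_r")
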