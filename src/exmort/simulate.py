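"""Synthetic weekly multivariate mortality panels.

Emulates the structure of the CDC weekly provisional death-count table:
K nonnegative integer count series at 7-day spacing with a linear trend,
yearly seasonality and strong cross-cause correlation.  Marginals are
negative binomial (gamma-mixed Poisson) because real mortality counts are
overdispersed; dependence across causes enters through a Gaussian copula on
the latent uniforms so the configured marginals are preserved exactly while
the count-scale correlation is (slightly attenuated) controlled by the
latent correlation matrix.

All randomness flows from the explicit ``seed``; no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .panel import MortalityPanel

#: Mean number of weeks per year (365.25 / 7); the yearly seasonal period.
YEARLY_PERIOD_WEEKS = 365.25 / 7.0

#: Cause labels of the 14 CDC weekly provisional cause-of-death series.
DEFAULT_CAUSES = [
    "DIAMEL", "MALNEO", "ALZ", "INFPNE", "CLRD", "HD", "CD",
    "COVIDUC", "SEPTICEMIA", "ODRS", "NNSN", "SSACL", "NATCAUSE", "ALLCAUSE",
]

# Rough weekly U.S. magnitudes for each cause, used as simulation defaults.
_DEFAULT_BASELINES = [
    1900.0, 11500.0, 2400.0, 1000.0, 2900.0, 13000.0, 3200.0,
    5000.0, 750.0, 800.0, 1000.0, 700.0, 55000.0, 60000.0,
]


def _per_cause(value, k: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(k, float(arr))
    if arr.shape != (k,):
        raise ConfigError(f"{name} must be scalar or length {k}, got shape {arr.shape}")
    return arr


def exchangeable_correlation(k: int, rho: float = 0.6) -> np.ndarray:
    """Unit-diagonal correlation matrix with constant off-diagonal ``rho``.

    Positive semidefinite for rho in [-1/(k-1), 1].
    """
    if not -1.0 / max(k - 1, 1) <= rho <= 1.0:
        raise ConfigError(f"exchangeable rho={rho} not PSD for k={k}")
    return np.full((k, k), rho) + (1.0 - rho) * np.eye(k)


@dataclass
class SimulationConfig:
    """Configuration of the synthetic weekly mortality panel generator.

    Defaults emulate a 194-week window of the CDC weekly table: 194 weeks of
    14 cause-of-death series starting at week-ending 2020-01-04, with mild
    linear trends, winter-peaking yearly seasonality and an exchangeable
    latent correlation of 0.6 (count-scale pairwise correlations come out
    high, in the spirit of the strongly correlated real series).
    """

    n_weeks: int = 194
    start_date: str = "2020-01-04"
    causes: list = field(default_factory=lambda: list(DEFAULT_CAUSES))
    baseline: object = field(default_factory=lambda: list(_DEFAULT_BASELINES))
    trend: object = 0.5
    yearly_amplitude: object = 0.10
    yearly_phase: object = 0.0
    cross_correlation: np.ndarray | None = None
    dispersion: object = 200.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_weeks < 2:
            raise ConfigError("n_weeks must be >= 2 (one exceedance pair needed)")
        k = len(self.causes)
        if k == 0 or len(set(map(str, self.causes))) != k:
            raise ConfigError("causes must be non-empty and unique")
        if (self._baseline() <= 0).any():
            raise ConfigError("baseline must be positive for every cause")
        if (self._dispersion() <= 0).any():
            raise ConfigError("dispersion must be positive")
        if (self._amplitude() < 0).any():
            raise ConfigError("yearly_amplitude must be >= 0")
        corr = self.correlation_matrix()
        if corr.shape != (k, k):
            raise ConfigError(f"cross_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("cross_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ConfigError("cross_correlation must have unit diagonal")
        eigmin = np.linalg.eigvalsh(corr).min()
        if eigmin < -1e-10:
            raise ConfigError(
                f"cross_correlation is not positive semidefinite (min eigenvalue {eigmin:.3g})"
            )

    # per-cause parameter vectors -------------------------------------------------
    def _baseline(self) -> np.ndarray:
        return _per_cause(self.baseline, len(self.causes), "baseline")

    def _trend(self) -> np.ndarray:
        return _per_cause(self.trend, len(self.causes), "trend")

    def _amplitude(self) -> np.ndarray:
        return _per_cause(self.yearly_amplitude, len(self.causes), "yearly_amplitude")

    def _phase(self) -> np.ndarray:
        return _per_cause(self.yearly_phase, len(self.causes), "yearly_phase")

    def _dispersion(self) -> np.ndarray:
        return _per_cause(self.dispersion, len(self.causes), "dispersion")

    def correlation_matrix(self) -> np.ndarray:
        if self.cross_correlation is None:
            return exchangeable_correlation(len(self.causes), 0.6)
        return np.asarray(self.cross_correlation, dtype=float)

    def mean_curve(self) -> np.ndarray:
        """Expected count matrix (n_weeks x K) implied by the configuration."""
        t = np.arange(self.n_weeks)[:, None]
        base = self._baseline()[None, :] + self._trend()[None, :] * t
        season = 1.0 + self._amplitude()[None, :] * np.sin(
            2.0 * np.pi * (t - self._phase()[None, :]) / YEARLY_PERIOD_WEEKS
        )
        # keep the mean strictly positive even for aggressive trends/amplitudes
        return np.maximum(base * season, 1e-9)


def generate_panel(config: SimulationConfig) -> MortalityPanel:
    """Draw one synthetic weekly mortality panel.

    Counts for cause k at week t are negative binomial with mean
    ``mean_curve()[t, k]`` and dispersion ``r`` (variance ``mu + mu^2/r``),
    coupled across causes through a Gaussian copula with the configured
    latent correlation.  Identical config and seed give identical output.
    """
    config.validate()
    k = len(config.causes)
    rng = np.random.default_rng(config.seed)
    corr = config.correlation_matrix()
    chol = _psd_cholesky(corr)
    z = rng.standard_normal((config.n_weeks, k)) @ chol.T
    u = stats.norm.cdf(z)
    mu = config.mean_curve()
    r = config._dispersion()[None, :]
    # NB parameterised by size r and prob r/(r+mu): mean mu, var mu + mu^2/r
    counts = stats.nbinom.ppf(u, r, r / (r + mu))
    dates = pd.date_range(config.start_date, periods=config.n_weeks, freq="7D")
    return MortalityPanel(dates, counts, [str(c) for c in config.causes])


def _psd_cholesky(corr: np.ndarray) -> np.ndarray:
    """Cholesky factor, falling back to an eigenvalue square root for PSD
    matrices that are singular (e.g. perfectly correlated pairs)."""
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(corr)
        return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
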