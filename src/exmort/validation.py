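"""Comparing observed-window and forecast-window exceedance probabilities.

The forecaster is judged by whether the exceedance behaviour it implies
matches the observed data: per-cause p-hat estimated separately on the
observed and forecast windows, the Euclidean distance between the two
probability vectors, and a two-sample Wilcoxon rank-sum (Mann-Whitney)
test with continuity correction.

The rank-sum statistic W is reported in the first-sample Mann-Whitney
convention: the number of (x_i, y_j) pairs with x_i > y_j, ties counted as
one half.  The two-sided p-value uses the tie-corrected normal
approximation with continuity correction (no exact-distribution branch).
The rank-sum test treats the two columns as independent samples even
though they are paired per cause; that is how the statistic is defined
here, and the choice is deliberate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ExmortError
from .exceedance import ExceedanceMatrix
from .panel import BOUNDARY, FORECAST, OBSERVED


def windowed_estimates(
    matrix: ExceedanceMatrix, include_boundary: bool = False
) -> pd.DataFrame:
    """Per-cause exceedance proportions on the observed and forecast windows.

    The single boundary row (last observed week vs first forecast week) is
    excluded from both windows by default; ``include_boundary=True`` counts
    it toward the forecast window.
    """
    seg = matrix.segments
    obs_rows = seg == OBSERVED
    fc_rows = seg == FORECAST
    if include_boundary:
        fc_rows = fc_rows | (seg == BOUNDARY)
    if obs_rows.sum() == 0:
        raise ExmortError("observed window is empty")
    if fc_rows.sum() == 0:
        raise ExmortError("forecast window is empty")
    p_obs = matrix.indicators[obs_rows].mean(axis=0)
    p_fc = matrix.indicators[fc_rows].mean(axis=0)
    return pd.DataFrame(
        {
            "p_hat_observed": p_obs,
            "p_hat_forecast": p_fc,
            "abs_diff": np.abs(p_obs - p_fc),
        },
        index=pd.Index(matrix.cause_labels, name="cause"),
    )


def euclidean_distance(x, y) -> float:
    """sqrt of the sum of squared componentwise differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ExmortError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.linalg.norm(x - y))


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sample rank-sum test: (W, two-sided p).

    W is the Mann-Whitney count of the first sample (pairs with x > y, half
    per tie); p comes from the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ExmortError("both samples must be non-empty")
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class ValidationReport:
    """Validation statistics comparing the observed and forecast windows."""

    estimates: pd.DataFrame
    euclidean: float
    wilcoxon_w: float
    wilcoxon_p: float
    alpha: float = 0.05
    correlations: pd.Series | None = None
    window: dict = field(default_factory=dict)

    @property
    def verdict(self) -> str:
        if self.wilcoxon_p >= self.alpha:
            return (
                "no statistically significant difference between observed and "
                f"forecast exceedance probabilities (p = {self.wilcoxon_p:.2f} "
                f">= {self.alpha})"
            )
        return (
            "observed and forecast exceedance probabilities differ "
            f"significantly (p = {self.wilcoxon_p:.2f} < {self.alpha})"
        )

    def to_dict(self) -> dict:
        out = {
            "p_hat": {
                cause: {
                    "observed": float(row["p_hat_observed"]),
                    "forecast": float(row["p_hat_forecast"]),
                    "abs_diff": float(row["abs_diff"]),
                }
                for cause, row in self.estimates.iterrows()
            },
            "euclidean_distance": self.euclidean,
            "wilcoxon_W": self.wilcoxon_w,
            "wilcoxon_p": self.wilcoxon_p,
            "alpha": self.alpha,
            "verdict": self.verdict,
            "window": self.window,
        }
        if self.correlations is not None:
            out["fitted_correlations"] = {
                k: (None if pd.isna(v) else float(v))
                for k, v in self.correlations.items()
            }
        return out

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_csv(self, path) -> None:
        """CSV replica of the comparison table: p_hat,observed,forecast,abs_diff."""
        df = self.estimates.reset_index().rename(
            columns={
                "cause": "p_hat",
                "p_hat_observed": "observed",
                "p_hat_forecast": "forecast",
            }
        )
        df.to_csv(path, index=False)


def validate_windows(
    matrix: ExceedanceMatrix,
    include_boundary: bool = False,
    correlations: pd.Series | None = None,
) -> ValidationReport:
    """Build the full validation report from a tagged exceedance matrix."""
    est = windowed_estimates(matrix, include_boundary=include_boundary)
    dist = euclidean_distance(est["p_hat_observed"], est["p_hat_forecast"])
    w, p = wilcoxon_rank_sum(
        est["p_hat_observed"].to_numpy(), est["p_hat_forecast"].to_numpy()
    )
    seg = matrix.segments
    window = {
        "observed_rows": int((seg == OBSERVED).sum()),
        "forecast_rows": int((seg == FORECAST).sum()),
        "boundary_rows": int((seg == BOUNDARY).sum()),
        "boundary_included_in_forecast": include_boundary,
    }
    return ValidationReport(
        estimates=est,
        euclidean=dist,
        wilcoxon_w=w,
        wilcoxon_p=p,
        correlations=correlations,
        window=window,
    )
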