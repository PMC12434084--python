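"""Phase II: the binary exceedance matrix and WCMI estimation.

The weekly exceedance in mortality count (WEMC) is the event that a cause's
death count in the current week strictly exceeds the previous week's count.
Scanning T weeks of a combined observed+forecast panel yields T-1
consecutive-week comparisons per cause, collected in a binary matrix; the
per-cause count of ones is the weekly change in mortality indicator (WCMI),
modelled as binomial(n = T-1, p_i) with p_i estimated by the observed
proportion.

Each indicator row is attached to the *later* week of its pair.  Either
endpoint convention gives the same n and the same per-cause counts; the
attachment only decides which date labels each row.  The row comparing the
last observed week with the first forecast week is tagged ``boundary`` so
windowed estimates can include or exclude it explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, PanelFormatError
from .panel import BOUNDARY, WEEK, MortalityPanel


@dataclass
class ExceedanceMatrix:
    """(T-1) x K binary matrix of weekly exceedance indicators.

    ``pair_dates[r]`` is the later week of the pair summarised by row r;
    ``segments[r]`` is ``observed`` / ``boundary`` / ``forecast``.
    """

    pair_dates: pd.DatetimeIndex
    indicators: np.ndarray
    cause_labels: list
    segments: np.ndarray

    @property
    def n(self) -> int:
        return self.indicators.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.indicators, columns=self.cause_labels)
        df.insert(0, "pair_date", self.pair_dates.strftime("%Y-%m-%d"))
        df.insert(1, "segment", self.segments)
        return df


@dataclass
class WCMIEstimate:
    """Per-cause exceedance count and estimated success probability."""

    cause: str
    n: int
    ones: int
    p_hat: float

    def rounded(self, ndigits: int = 3) -> float:
        """Display-precision p-hat (estimate tables conventionally print 3 dp)."""
        return round(self.p_hat, ndigits)


@dataclass
class IndependenceResult:
    """Chi-square test of independence between cause and exceedance status."""

    chi2: float
    df: int
    p_value: float
    cramers_v: float
    table: np.ndarray


def combine(observed: MortalityPanel, forecast: MortalityPanel) -> MortalityPanel:
    """Concatenate an observed panel with the forecast that continues it.

    The forecast must start exactly 7 days after the last observed week and
    carry the same cause labels in the same order.
    """
    if list(observed.cause_labels) != list(forecast.cause_labels):
        raise PanelFormatError("cause labels differ between observed and forecast")
    expected = observed.dates[-1] + WEEK
    if forecast.dates[0] != expected:
        raise PanelFormatError(
            f"forecast must start at {expected.date()} "
            f"(7 days after last observed week), got {forecast.dates[0].date()}"
        )
    return MortalityPanel(
        observed.dates.append(forecast.dates),
        np.vstack([observed.counts, forecast.counts]),
        observed.cause_labels,
        segments=np.concatenate([observed.segments, forecast.segments]),
    )


def build_matrix(panel: MortalityPanel) -> ExceedanceMatrix:
    """Binary indicators: 1 where count(week t+1) > count(week t), else 0.

    Ties count as 0 (no exceedance).  A T-week panel yields exactly T-1 rows.
    """
    if panel.n_weeks < 2:
        raise PanelFormatError("need at least 2 weeks to form an exceedance pair")
    ind = (panel.counts[1:] > panel.counts[:-1]).astype(np.int8)
    prev_seg = panel.segments[:-1]
    curr_seg = panel.segments[1:]
    segments = np.where(prev_seg == curr_seg, curr_seg, BOUNDARY).astype(object)
    return ExceedanceMatrix(
        pair_dates=panel.dates[1:],
        indicators=ind,
        cause_labels=list(panel.cause_labels),
        segments=segments,
    )


def estimate_wcmi(matrix: ExceedanceMatrix) -> list[WCMIEstimate]:
    """Per-cause ones-count and proportion, at full precision."""
    if matrix.n == 0:
        raise PanelFormatError("empty exceedance matrix")
    ones = matrix.indicators.sum(axis=0)
    return [
        WCMIEstimate(cause=label, n=matrix.n, ones=int(o), p_hat=int(o) / matrix.n)
        for label, o in zip(matrix.cause_labels, ones)
    ]


def estimates_frame(estimates: list[WCMIEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.cause, e.n, e.ones, e.p_hat) for e in estimates],
        columns=["cause", "n", "ones", "p_hat"],
    )


def chi_square_independence(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Exposed separately so the core can be checked against textbook examples.
    """
    table = np.asarray(table, dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTableError("contingency table has a zero margin")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def independence_test(matrix: ExceedanceMatrix) -> IndependenceResult:
    """Chi-square test that exceedance frequency is homogeneous across causes.

    The contingency table is K x 2: per cause, the count of exceedance weeks
    and of non-exceedance weeks.  Cramer's V uses min(K-1, 1) = 1 in the
    denominator with N = K*n total table entries.
    """
    estimates = estimate_wcmi(matrix)
    table = np.array([[e.ones, e.n - e.ones] for e in estimates], dtype=float)
    chi2, df, p = chi_square_independence(table)
    n_total = table.sum()
    v = float(np.sqrt(chi2 / (n_total * min(table.shape[0] - 1, 1))))
    return IndependenceResult(chi2=chi2, df=df, p_value=p, cramers_v=v, table=table)
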