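"""Weekly mortality count panels.

A :class:`MortalityPanel` is the in-memory form of the wide CSV layout used by
the CDC "Weekly Provisional Counts of Deaths" table: one row per week-ending
date (exact 7-day spacing), one column per cause of death.  Observed and
simulated panels hold nonnegative integers; forecast panels hold nonnegative
reals.  Each row carries a segment tag (``observed`` / ``forecast``) so that
downstream windowed estimates can tell the two apart.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import PanelFormatError

WEEK = pd.Timedelta(days=7)

OBSERVED = "observed"
FORECAST = "forecast"
BOUNDARY = "boundary"

_DATE_COL = "week_ending_date"
_SEGMENT_COL = "segment"


class MortalityPanel:
    """Weeks x causes matrix of weekly mortality counts.

    Parameters
    ----------
    dates:
        Week-ending dates, strictly increasing at exact 7-day spacing.
    counts:
        ``(n_weeks, n_causes)`` array of nonnegative values.  Integers for
        observed/simulated data; forecasts may be real-valued.
    cause_labels:
        Unique column labels, one per cause.
    segments:
        Optional per-row tag, ``observed`` (default) or ``forecast``.
    """

    def __init__(
        self,
        dates: Sequence,
        counts: np.ndarray,
        cause_labels: Sequence[str],
        segments: Sequence[str] | None = None,
    ):
        dates = pd.DatetimeIndex(dates)
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2:
            raise PanelFormatError("counts must be a 2-D weeks x causes array")
        labels = [str(c) for c in cause_labels]
        if len(set(labels)) != len(labels):
            raise PanelFormatError("cause labels must be unique")
        if counts.shape != (len(dates), len(labels)):
            raise PanelFormatError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(dates)} dates x {len(labels)} causes"
            )
        if len(dates) == 0:
            raise PanelFormatError("panel must contain at least one week")
        diffs = np.diff(dates.values)
        if len(diffs) and not (diffs == WEEK.to_timedelta64()).all():
            bad = int(np.argmax(diffs != WEEK.to_timedelta64()))
            raise PanelFormatError(
                f"dates must be strictly increasing at 7-day spacing; "
                f"violation after row {bad} ({dates[bad].date()})"
            )
        if not np.isfinite(counts).all():
            raise PanelFormatError("counts contain non-finite values")
        if (counts < 0).any():
            r, c = np.argwhere(counts < 0)[0]
            raise PanelFormatError(
                f"negative count at row {r} ({dates[r].date()}), column {labels[c]!r}"
            )
        if segments is None:
            segments = [OBSERVED] * len(dates)
        segments = np.asarray(segments, dtype=object)
        if segments.shape != (len(dates),):
            raise PanelFormatError("segments must have one tag per week")

        self.dates = dates
        self.counts = counts
        self.cause_labels = labels
        self.segments = segments

    @property
    def n_weeks(self) -> int:
        return len(self.dates)

    @property
    def n_causes(self) -> int:
        return len(self.cause_labels)

    def to_frame(self, include_segment: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.cause_labels)
        df.insert(0, _DATE_COL, self.dates.strftime("%Y-%m-%d"))
        if include_segment:
            df.insert(1, _SEGMENT_COL, self.segments)
        return df

    def equals(self, other: "MortalityPanel") -> bool:
        return (
            self.cause_labels == other.cause_labels
            and self.dates.equals(other.dates)
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MortalityPanel({self.n_weeks} weeks x {self.n_causes} causes, "
            f"{self.dates[0].date()}..{self.dates[-1].date()})"
        )


def write_panel(panel: MortalityPanel, destination, include_segment: bool = False) -> None:
    """Write a panel as wide CSV: ``week_ending_date,<cause1>,<cause2>,...``."""
    panel.to_frame(include_segment=include_segment).to_csv(destination, index=False)


def read_panel(source, column_mapping: Mapping[str, str] | None = None) -> MortalityPanel:
    """Read a wide weekly-count CSV into a :class:`MortalityPanel`.

    ``column_mapping`` renames verbatim source headers (e.g. the CDC's
    ``"Diabetes mellitus (E10-E14)"``) to short cause labels before validation.
    Raises :class:`PanelFormatError` naming the offending row/column on
    non-numeric cells, negative counts, duplicated dates or irregular spacing.
    """
    df = pd.read_csv(source, dtype=str)
    if _DATE_COL not in df.columns:
        raise PanelFormatError(f"missing required column {_DATE_COL!r}")
    if column_mapping:
        df = df.rename(columns=dict(column_mapping))
    try:
        dates = pd.to_datetime(df[_DATE_COL], format="%Y-%m-%d")
    except (ValueError, TypeError) as exc:
        raise PanelFormatError(f"unparsable date in column {_DATE_COL!r}: {exc}") from exc
    if dates.duplicated().any():
        dup = dates[dates.duplicated()].iloc[0]
        raise PanelFormatError(f"duplicated week-ending date {dup.date()}")

    segments = None
    if _SEGMENT_COL in df.columns:
        segments = df[_SEGMENT_COL].to_numpy(dtype=object)
    cause_cols = [c for c in df.columns if c not in (_DATE_COL, _SEGMENT_COL)]
    if not cause_cols:
        raise PanelFormatError("no cause columns found")
    values = np.empty((len(df), len(cause_cols)))
    for j, col in enumerate(cause_cols):
        parsed = pd.to_numeric(df[col], errors="coerce")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax())
            raise PanelFormatError(
                f"non-numeric cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        values[:, j] = parsed.to_numpy()
    return MortalityPanel(dates, values, cause_cols, segments=segments)
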