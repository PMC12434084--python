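"""Phase III single-cause machinery: WCMI event probabilities.

The WCMI for cause i is modelled as binomial(n, p_i).  This module computes
exact probabilities of point, tail and interval events for one cause, joint
probabilities across causes as independence products, and conditional
probabilities (which, under the validated independence assumption, reduce to
the marginal probabilities).

Interval probabilities are accumulated from log-space pmf terms with
compensated summation, so far-tail intervals do not lose mass to cdf
cancellation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import EventError, UndefinedConditionalError

EVENT_KINDS = ("eq", "le", "lt", "ge", "gt", "between")


@dataclass(frozen=True)
class BinomialSpec:
    """Number of trials and success probability of one WCMI."""

    n: int
    p: float

    def __post_init__(self):
        if self.n < 1:
            raise EventError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise EventError(f"p must be in [0, 1], got {self.p}")


@dataclass(frozen=True)
class EventSpec:
    """One event about a count: eq/le/lt/ge/gt at ``k``, or between [lo, hi].

    ``between`` is inclusive on both ends.  Bounds may lie outside the
    binomial support; they are clamped at evaluation time (events entirely
    outside the support have probability 0 or 1 as logic forces).
    """

    kind: str
    k: int | None = None
    lo: int | None = None
    hi: int | None = None

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise EventError(f"unknown event kind {self.kind!r}")
        if self.kind == "between":
            if self.lo is None or self.hi is None:
                raise EventError("between requires lo and hi")
            if self.lo > self.hi:
                raise EventError(f"between bounds reversed: {self.lo} > {self.hi}")
        elif self.k is None:
            raise EventError(f"{self.kind} requires a bound k")

    def describe(self, label: str = "X") -> str:
        if self.kind == "between":
            return f"{self.lo}<={label}<={self.hi}"
        op = {"eq": "=", "le": "<=", "lt": "<", "ge": ">=", "gt": ">"}[self.kind]
        return f"{label}{op}{self.k}"


def _interval_probability(spec: BinomialSpec, lo: int, hi: int) -> float:
    """P(lo <= X <= hi) via compensated summation of exp(logpmf)."""
    lo = max(lo, 0)
    hi = min(hi, spec.n)
    if lo > hi:
        return 0.0
    ks = np.arange(lo, hi + 1)
    return float(min(1.0, math.fsum(np.exp(stats.binom.logpmf(ks, spec.n, spec.p)))))


def event_probability(spec: BinomialSpec, event: EventSpec) -> float:
    """Exact binomial probability of one event."""
    n = spec.n
    if event.kind == "eq":
        k = event.k
        if k < 0 or k > n:
            return 0.0
        return float(stats.binom.pmf(k, n, spec.p))
    if event.kind == "between":
        return _interval_probability(spec, event.lo, event.hi)
    if event.kind == "lt":
        return event_probability(spec, EventSpec("le", event.k - 1))
    if event.kind == "gt":
        return event_probability(spec, EventSpec("ge", event.k + 1))
    if event.kind == "le":
        if event.k < 0:
            return 0.0
        if event.k >= n:
            return 1.0
        if event.k <= n * spec.p:
            return _interval_probability(spec, 0, event.k)
        return float(stats.binom.cdf(event.k, n, spec.p))
    # ge
    if event.k <= 0:
        return 1.0
    if event.k > n:
        return 0.0
    if event.k >= n * spec.p:
        return _interval_probability(spec, event.k, n)
    return float(stats.binom.sf(event.k - 1, n, spec.p))


def joint_probability(
    events: Sequence[tuple[BinomialSpec, EventSpec]], rounding: str = "none"
) -> float:
    """Product of marginal event probabilities over independent causes.

    ``rounding='two_dp_marginals'`` rounds each marginal to 2 decimals before
    multiplying — a display convention some published tables use; the default
    keeps full precision.
    """
    if not events:
        raise EventError("joint probability of an empty event list is undefined")
    if rounding not in ("none", "two_dp_marginals"):
        raise EventError(f"unknown rounding mode {rounding!r}")
    prob = 1.0
    for spec, event in events:
        m = event_probability(spec, event)
        if rounding == "two_dp_marginals":
            m = round(m, 2)
        prob *= m
    return prob


def conditional_probability(
    target: tuple[BinomialSpec, EventSpec], given: tuple[BinomialSpec, EventSpec]
) -> float:
    """P(target | given) for independent causes: the marginal of the target.

    The conditioning event's probability is evaluated to enforce positivity.
    """
    p_given = event_probability(*given)
    if p_given == 0.0:
        raise UndefinedConditionalError(
            f"conditioning event {given[1].describe()} has probability 0"
        )
    return event_probability(*target)


# ---------------------------------------------------------------------------
# Compact text grammar for events: "C1=141", "C2<136", "138<=C7<=158"
# ---------------------------------------------------------------------------

_SINGLE = re.compile(r"^\s*(\w+)\s*(<=|>=|<|>|=)\s*(-?\d+)\s*$")
_BETWEEN = re.compile(r"^\s*(-?\d+)\s*<=\s*(\w+)\s*<=\s*(-?\d+)\s*$")
_OPS = {"=": "eq", "<=": "le", "<": "lt", ">=": "ge", ">": "gt"}


def parse_event(text: str) -> tuple[str, EventSpec]:
    """Parse one event query, returning (cause label, event).

    Grammar: ``<label><op><int>`` with op in ``= <= < >= >``, or the
    inclusive interval form ``<int><=<label><=<int>``.
    """
    m = _BETWEEN.match(text)
    if m:
        lo, label, hi = m.groups()
        return label, EventSpec("between", lo=int(lo), hi=int(hi))
    m = _SINGLE.match(text)
    if m:
        label, op, k = m.groups()
        return label, EventSpec(_OPS[op], k=int(k))
    raise EventError(f"cannot parse event query {text!r}")


def parse_joint_query(text: str) -> list[tuple[str, EventSpec]]:
    """Parse a comma-joined joint event, e.g. ``C6>130,C7>130``."""
    parts = [p for p in text.split(",") if p.strip()]
    if not parts:
        raise EventError("empty query")
    return [parse_event(p) for p in parts]


def evaluate_queries(
    queries: Iterable[str],
    specs: dict[str, BinomialSpec],
    rounding: str = "none",
) -> list[tuple[str, float]]:
    """Evaluate text queries against a label -> BinomialSpec table."""
    out = []
    for q in queries:
        events = []
        for label, event in parse_joint_query(q):
            if label not in specs:
                raise EventError(f"unknown cause label {label!r} in query {q!r}")
            events.append((specs[label], event))
        out.append((q, joint_probability(events, rounding=rounding)))
    return out
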