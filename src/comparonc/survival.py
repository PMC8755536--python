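"""Kaplan-Meier estimation with delayed entry (left truncation).

Adult survival in managed populations is observed through a window: animals
already adult at the window start enter the risk set at their age on that
date (delayed entry), and animals alive at data extraction are
right-censored.  The product-limit estimator here therefore uses
age-indexed risk sets

    n(t) = #{ i : entry_i < t <= exit_i }

with the special case that an individual whose exit age equals its entry
age is counted in the risk set at that age (otherwise it would be excluded
from its own death event).  Deaths at t precede censorings at t, the
standard tie convention.

Computations run in floating point by default; with ``exact=True`` the
survival products are carried as :class:`fractions.Fraction` so that
downstream identities (e.g. additivity of cause-specific cumulative
incidences) hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np

EventSelector = Literal["all-deaths", "cancer-only", "known-cause-only"]

KNOWN_CAUSES = ("cancer", "other")


@dataclass
class SurvivalCurve:
    """Step-function survival estimate anchored at the maturity age alpha.

    ``survival[i]`` is S evaluated just after the fall at ``event_ages[i]``;
    the left limit at ``event_ages[i]`` is ``survival[i-1]`` (1 before the
    first event).
    """

    event_ages: list
    n_risk: list
    n_event: list
    survival: list
    alpha: float
    last_age: float
    terminated_early: bool = False
    exact: bool = False

    def survival_before(self, age):
        """Left limit S(age-): survival just before ``age``."""
        one = Fraction(1) if self.exact else 1.0
        s = one
        for t, sv in zip(self.event_ages, self.survival):
            if t < age:
                s = sv
            else:
                break
        return s

    def survival_at(self, age):
        """S(age): survival just after any fall at ``age``."""
        one = Fraction(1) if self.exact else 1.0
        s = one
        for t, sv in zip(self.event_ages, self.survival):
            if t <= age:
                s = sv
            else:
                break
        return s

    @property
    def final_survival(self):
        if not self.survival:
            return Fraction(1) if self.exact else 1.0
        return self.survival[-1]


def _is_event(member, selector: EventSelector) -> bool:
    if member.event != "death":
        return False
    if selector == "all-deaths":
        return True
    if selector == "cancer-only":
        return member.cause == "cancer"
    if selector == "known-cause-only":
        return member.cause in KNOWN_CAUSES
    raise ValueError(f"unknown event selector: {selector!r}")


def km_fit(
    members: Sequence,
    event_selector: EventSelector = "all-deaths",
    exact: bool = False,
) -> SurvivalCurve:
    """Product-limit estimator with delayed entry.

    Parameters
    ----------
    members
        Cohort members with ``entry_age``, ``exit_age``, ``event``
        (``"death"``/``"censored"``) and ``cause`` attributes.
    event_selector
        Which deaths count as events; non-selected deaths are treated as
        censorings at their exit age.
    exact
        Carry the survival product in rational arithmetic.
    """
    if len(members) == 0:
        raise ValueError("cannot fit a survival curve to an empty cohort")

    entry = np.asarray([m.entry_age for m in members], dtype=float)
    exit_ = np.asarray([m.exit_age for m in members], dtype=float)
    if np.any(exit_ < entry):
        raise ValueError("exit_age < entry_age in cohort")
    is_event = np.asarray([_is_event(m, event_selector) for m in members])

    event_times, d_counts = np.unique(exit_[is_event], return_counts=True)
    entry_sorted = np.sort(entry)
    exit_sorted = np.sort(exit_)
    # zero-length intervals (entry == exit) need explicit inclusion at t
    zero_len = np.sort(entry[entry == exit_])

    alpha = float(entry.min())
    last_age = float(exit_.max())

    n_at = (
        np.searchsorted(entry_sorted, event_times, side="left")
        - np.searchsorted(exit_sorted, event_times, side="left")
        + np.searchsorted(zero_len, event_times, side="right")
        - np.searchsorted(zero_len, event_times, side="left")
    )

    one = Fraction(1) if exact else 1.0
    s = one
    ages, n_risk, n_event, surv = [], [], [], []
    terminated = False
    for t, n_t, d_t in zip(event_times, n_at, d_counts):
        n_t = int(n_t)
        d_t = int(d_t)
        if n_t <= 0:
            terminated = True
            break
        factor = Fraction(n_t - d_t, n_t) if exact else (1.0 - d_t / n_t)
        s = s * factor
        ages.append(float(t))
        n_risk.append(n_t)
        n_event.append(d_t)
        surv.append(s)

    return SurvivalCurve(
        event_ages=ages,
        n_risk=n_risk,
        n_event=n_event,
        survival=surv,
        alpha=alpha,
        last_age=last_age,
        terminated_early=terminated,
        exact=exact,
    )


@dataclass
class LifeExpectancy:
    value: float
    truncated: bool


def adult_life_expectancy(curve: SurvivalCurve) -> LifeExpectancy:
    """Restricted mean adult lifetime: area under S from alpha to the last
    observed age.  ``truncated`` flags curves that do not reach zero."""
    ages = [curve.alpha] + list(curve.event_ages) + [curve.last_age]
    steps = [1.0] + [float(s) for s in curve.survival] + [float(curve.final_survival)]
    area = 0.0
    for i in range(len(ages) - 1):
        width = max(0.0, ages[i + 1] - ages[i])
        area += steps[i] * width
    truncated = float(curve.final_survival) > 0.0 or curve.terminated_early
    return LifeExpectancy(value=area, truncated=truncated)


@dataclass
class SurvivalQuantile:
    age: float | None
    defined: bool


def survival_quantile(curve: SurvivalCurve, q: float) -> SurvivalQuantile:
    """Smallest event age at which S falls to or below ``q``.

    Undefined (``defined=False``) when the curve never reaches ``q`` —
    species whose 10% survival age is undefined are excluded from
    cumulative-incidence analyses.
    """
    if not (0.0 < q <= 1.0):
        raise ValueError("quantile level must be in (0, 1]")
    for t, s in zip(curve.event_ages, curve.survival):
        # tolerance so exact-boundary crossings survive float round-off
        if float(s) <= q + 1e-12:
            return SurvivalQuantile(age=t, defined=True)
    return SurvivalQuantile(age=None, defined=False)


def curve_table(curve: SurvivalCurve):
    """(age, n_risk, n_event, S) rows for TSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "age": curve.event_ages,
            "n_risk": curve.n_risk,
            "n_event": curve.n_event,
            "S": [float(s) for s in curve.survival],
        }
    )
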