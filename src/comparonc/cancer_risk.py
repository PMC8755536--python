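"""Species-level cancer mortality risk metrics.

Two metrics, both proportions of adults dying of cancer:

* CMR — the crude ratio of cancer-attributed deaths to individuals with
  postmortem pathological records.  Simple, but it ignores live animals
  and the ages at which deaths happen.
* ICM — the cumulative incidence of cancer mortality under competing
  risks, computed on the complete-case cohort (known-cause deaths plus
  right-censored survivors) as

      ICM = sum over cancer event ages t of  S(t-) * d_c(t) / n(t)

  where S is the product-limit survival for death from any known cause
  and d_c(t)/n(t) is the cancer-specific hazard jump at t (a
  "KM-with-one-event-type" fit in which only cancer deaths are events).
  S enters at its left limit, so on a fully observed cohort the
  cause-specific incidences and the terminal survival add exactly to 1
  and ICM reduces to the crude cancer fraction.

Hazard jumps are carried at exact event ages rather than pooled into
time intervals: event times in small managed populations are sparse and
irregular, sometimes a third of the adult lifespan apart, and interval
pooling would blur species comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

from .survival import KNOWN_CAUSES, km_fit, survival_quantile

SConvention = Literal["left", "post"]


def compute_cmr(n_cancer: int, n_necropsied: int) -> float:
    """Crude cancer mortality risk: cancer deaths / necropsied individuals."""
    if n_necropsied < 1:
        raise ValueError("CMR undefined without necropsied individuals")
    if not (0 <= n_cancer <= n_necropsied):
        raise ValueError("need 0 <= n_cancer <= n_necropsied")
    return n_cancer / n_necropsied


def complete_case_subset(members: Sequence) -> list:
    """Known-cause deaths plus right-censored survivors.

    Dead individuals whose cause of death is unspecified are dropped; the
    complete-case design assumes that missingness is unrelated to cause.
    """
    return [
        m
        for m in members
        if m.event == "censored" or (m.event == "death" and m.cause in KNOWN_CAUSES)
    ]


@dataclass
class IcmEstimate:
    value: float | Fraction | None
    defined: bool
    reason: str | None = None


def compute_icm(
    complete_case_members: Sequence,
    cause: str = "cancer",
    exact: bool = False,
    s_convention: SConvention = "left",
) -> IcmEstimate:
    """Cumulative incidence of death from ``cause`` on a complete-case cohort.

    ``s_convention`` selects whether the survival factor at a hazard jump is
    the left limit S(t-) (default; the convention under which cause-specific
    incidences are additive) or the post-jump value S(t).
    """
    members = list(complete_case_members)
    if not members:
        return IcmEstimate(value=None, defined=False, reason="empty complete-case set")
    for m in members:
        if m.event == "death" and m.cause not in KNOWN_CAUSES:
            raise ValueError(
                "compute_icm requires a complete-case cohort "
                "(run complete_case_subset first)"
            )

    surv = km_fit(members, "known-cause-only", exact=exact)
    if cause == "cancer":
        haz = km_fit(members, "cancer-only", exact=exact)
    else:
        haz = _cause_specific_fit(members, cause, exact=exact)

    zero = Fraction(0) if exact else 0.0
    icm = zero
    for t, n_t, d_t in zip(haz.event_ages, haz.n_risk, haz.n_event):
        if s_convention == "left":
            s = surv.survival_before(t)
        else:
            s = surv.survival_at(t)
        jump = Fraction(d_t, n_t) if exact else d_t / n_t
        icm = icm + s * jump
    return IcmEstimate(value=icm, defined=True)


def _cause_specific_fit(members, cause: str, exact: bool):
    """KM fit where only deaths from an arbitrary cause label are events."""

    class _Relabeled:
        __slots__ = ("entry_age", "exit_age", "event", "cause")

        def __init__(self, m):
            self.entry_age = m.entry_age
            self.exit_age = m.exit_age
            self.event = m.event
            self.cause = "cancer" if m.cause == cause else "other"

    return km_fit([_Relabeled(m) for m in members], "cancer-only", exact=exact)


@dataclass
class CancerRiskEstimate:
    species: str
    n_total: int
    n_dead: int
    n_necropsied: int
    n_cancer: int
    cmr: float
    icm: float | None
    icm_eligible: bool


def estimate_species_risk(
    cohort,
    survival_floor: float = 0.10,
    s_convention: SConvention = "left",
) -> CancerRiskEstimate:
    """CMR and ICM for one species cohort.

    ICM is reported only for species whose all-deaths survival curve falls
    to ``survival_floor`` (default 10%) within the observed ages, i.e.
    species in which late-life survival is actually estimable.
    """
    cmr = compute_cmr(cohort.n_cancer, cohort.n_necropsied)
    curve = km_fit(cohort.members, "all-deaths")
    eligible = survival_quantile(curve, survival_floor).defined
    icm_value = None
    if eligible:
        cc = complete_case_subset(cohort.members)
        est = compute_icm(cc, s_convention=s_convention)
        if est.defined:
            icm_value = float(est.value)
        else:
            eligible = False
    return CancerRiskEstimate(
        species=cohort.species,
        n_total=cohort.n_total,
        n_dead=cohort.n_dead,
        n_necropsied=cohort.n_necropsied,
        n_cancer=cohort.n_cancer,
        cmr=cmr,
        icm=icm_value,
        icm_eligible=eligible,
    )


def risk_table(cohorts, species=None, **kwargs):
    """Species-level risk table (the seed of the comparative trait table)."""
    import pandas as pd

    rows = []
    for sp in sorted(cohorts) if species is None else species:
        est = estimate_species_risk(cohorts[sp], **kwargs)
        rows.append(
            {
                "species": est.species,
                "n_total": est.n_total,
                "n_dead": est.n_dead,
                "n_necropsied": est.n_necropsied,
                "n_cancer": est.n_cancer,
                "cmr": est.cmr,
                "icm": est.icm,
                "icm_eligible": est.icm_eligible,
            }
        )
    return pd.DataFrame(rows)
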