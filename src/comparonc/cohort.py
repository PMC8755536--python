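"""Cohort construction from individual-level records.

Turns raw husbandry-style records (one row per animal: species, sex, birth
date and its precision, death date or alive flag, necropsy availability,
cause category) into per-species analysis cohorts of adult individuals
observed through a fixed window, applying the eligibility rules:

* only individuals alive at, or born after, the window start;
* only individuals whose age at sexual maturity (alpha) is reached before
  the extraction date — alpha is sex-specific, with the max of the two
  sexes used for animals of unknown sex;
* birth date known to within 30 days;
* entry age = age at window start for animals already adult then, else
  alpha (delayed entry); exit age = age at death or at extraction.

Ages are exact day differences divided by 365.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
MAX_BIRTH_PRECISION_DAYS = 30
DEFAULT_MIN_NECROPSIED = 20

_SEXES = ("male", "female", "unknown")
_CAUSES = ("cancer", "other", "unknown")


@dataclass(frozen=True)
class IndividualRecord:
    """One animal's demographic history, fate and pathology category."""

    individual_id: str
    species: str
    sex: str
    birth_date: date
    birth_precision_days: int
    death_date: date | None
    alive_at_extraction: bool
    necropsy_available: bool
    cause: str | None

    def __post_init__(self):
        if self.sex not in _SEXES:
            raise ValueError(f"{self.individual_id}: bad sex {self.sex!r}")
        if self.birth_precision_days < 0:
            raise ValueError(f"{self.individual_id}: negative birth precision")
        if (self.death_date is None) != self.alive_at_extraction:
            raise ValueError(
                f"{self.individual_id}: death_date must be present iff dead"
            )
        if self.cause in ("cancer", "other") and not self.necropsy_available:
            raise ValueError(
                f"{self.individual_id}: specified cause requires a necropsy"
            )


@dataclass(frozen=True)
class SpeciesLifeHistory:
    species: str
    alpha_male: float | None
    alpha_female: float | None
    body_mass: float
    order: str
    diet: Mapping[str, str] = field(default_factory=dict)
    domesticated: bool = False

    def __post_init__(self):
        for a in (self.alpha_male, self.alpha_female):
            if a is not None and a <= 0:
                raise ValueError(f"{self.species}: alpha must be positive")
        if self.body_mass is not None and self.body_mass <= 0:
            raise ValueError(f"{self.species}: body mass must be positive")


@dataclass(frozen=True)
class CohortMember:
    individual_id: str
    entry_age: float
    exit_age: float
    event: str  # "death" | "censored"
    necropsy_available: bool
    cause: str | None


@dataclass
class Cohort:
    species: str
    members: list[CohortMember]

    @property
    def n_total(self) -> int:
        return len(self.members)

    @property
    def n_dead(self) -> int:
        return sum(1 for m in self.members if m.event == "death")

    @property
    def n_necropsied(self) -> int:
        return sum(
            1 for m in self.members if m.event == "death" and m.necropsy_available
        )

    @property
    def n_cancer(self) -> int:
        return sum(1 for m in self.members if m.cause == "cancer")


class LifeHistoryLookupError(KeyError):
    pass


def resolve_maturity_age(
    species: str, sex: str, life_history: Mapping[str, SpeciesLifeHistory]
) -> float:
    """Sex-specific age at sexual maturity; max of the sexes when unknown."""
    try:
        lh = life_history[species]
    except KeyError:
        raise LifeHistoryLookupError(f"no life-history entry for {species!r}")
    if sex == "male":
        alpha = lh.alpha_male
    elif sex == "female":
        alpha = lh.alpha_female
    elif sex == "unknown":
        alphas = [a for a in (lh.alpha_male, lh.alpha_female) if a is not None]
        alpha = max(alphas) if alphas else None
    else:
        raise ValueError(f"bad sex {sex!r}")
    if alpha is None:
        raise LifeHistoryLookupError(
            f"{species}: maturity age unavailable for sex {sex!r}"
        )
    return float(alpha)


def _years_between(d0: date, d1: date) -> float:
    return (d1 - d0).days / DAYS_PER_YEAR


@dataclass
class FilterResult:
    cohorts: dict[str, Cohort]
    exclusions: pd.DataFrame  # columns: individual_id, species, reason

    @property
    def n_included(self) -> int:
        return sum(c.n_total for c in self.cohorts.values())

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)


def filter_eligible(
    records: Sequence[IndividualRecord] | pd.DataFrame,
    window_start: date,
    extraction_date: date,
    life_history: Mapping[str, SpeciesLifeHistory],
) -> FilterResult:
    """Apply the eligibility and truncation rules; returns cohorts plus a
    per-individual exclusion log so counts are conserved."""
    if window_start >= extraction_date:
        raise ValueError("window_start must precede extraction_date")
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records
    df = df.copy()

    # resolve alpha per row (vectorised by species x sex)
    alphas = np.full(len(df), np.nan)
    for (sp, sex), idx in df.groupby(["species", "sex"]).groups.items():
        alphas[df.index.get_indexer(idx)] = resolve_maturity_age(
            sp, sex, life_history
        )
    df["alpha"] = alphas

    birth = pd.to_datetime(df["birth_date"], errors="raise")
    death = pd.to_datetime(df["death_date"], errors="coerce")
    dead = ~df["alive"].astype(bool)
    if (dead & death.isna()).any():
        bad = df.loc[dead & death.isna(), "id"].iloc[0]
        raise ValueError(f"record {bad}: dead individual without a death date")

    ws = pd.Timestamp(window_start)
    ex = pd.Timestamp(extraction_date)
    age_at_start = (ws - birth).dt.days / DAYS_PER_YEAR
    exit_date = death.fillna(ex)
    exit_age = (exit_date - birth).dt.days / DAYS_PER_YEAR
    age_at_extraction = (ex - birth).dt.days / DAYS_PER_YEAR

    reason = pd.Series(pd.NA, index=df.index, dtype="object")
    reason[df["birth_precision_days"] > MAX_BIRTH_PRECISION_DAYS] = "imprecise_birth"
    died_before_window = dead & (exit_date < ws)
    reason[reason.isna() & died_before_window] = "dead_before_window"
    never_adult = age_at_extraction < df["alpha"]
    reason[reason.isna() & never_adult] = "matures_after_extraction"
    died_juvenile = dead & (exit_age < df["alpha"])
    reason[reason.isna() & died_juvenile] = "died_before_maturity"

    keep = reason.isna().to_numpy()
    entry_age = np.maximum(df["alpha"].to_numpy(), age_at_start.to_numpy())
    # animals maturing during the window enter at alpha; age_at_start is
    # negative for animals born after the window start, so max() handles both
    event = np.where(dead.to_numpy(), "death", "censored")

    ids = df["id"].astype(str).to_numpy()
    species_arr = df["species"].to_numpy()
    necropsy_arr = df["necropsy"].astype(bool).to_numpy() & dead.to_numpy()
    cause_raw = df["cause"].to_numpy(dtype=object)
    exit_arr = exit_age.to_numpy()

    cohorts: dict[str, Cohort] = {}
    kept_idx = np.flatnonzero(keep)
    by_species: dict[str, list[CohortMember]] = {}
    for i in kept_idx:
        is_dead = event[i] == "death"
        if is_dead and necropsy_arr[i]:
            cause = cause_raw[i]
            if cause not in ("cancer", "other"):
                raise ValueError(f"record {ids[i]}: bad cause {cause!r}")
        else:
            cause = "unknown" if is_dead else None
        by_species.setdefault(species_arr[i], []).append(
            CohortMember(
                individual_id=ids[i],
                entry_age=float(entry_age[i]),
                exit_age=float(exit_arr[i]),
                event=str(event[i]),
                necropsy_available=bool(necropsy_arr[i]),
                cause=cause,
            )
        )
    for sp, members in by_species.items():
        cohorts[sp] = Cohort(species=sp, members=members)

    exclusions = pd.DataFrame(
        {
            "individual_id": df.loc[~keep, "id"].astype(str),
            "species": df.loc[~keep, "species"],
            "reason": reason[~keep],
        }
    ).reset_index(drop=True)
    return FilterResult(cohorts=cohorts, exclusions=exclusions)


def apply_species_thresholds(
    cohorts: Mapping[str, Cohort], min_necropsied: int = DEFAULT_MIN_NECROPSIED
) -> list[str]:
    """Species retained for analysis: at least ``min_necropsied`` adults with
    postmortem records.  Rerun with larger thresholds for sensitivity."""
    if min_necropsied < 1:
        raise ValueError("min_necropsied must be >= 1")
    return sorted(
        sp for sp, c in cohorts.items() if c.n_necropsied >= min_necropsied
    )


def exclude_domesticated(
    species_list: Iterable[str], exclusion_list: Iterable[str] | None = None
) -> list[str]:
    """Drop domesticated species (and wild ancestors) from the analysis set."""
    if exclusion_list is None:
        exclusion_list = default_domesticated_species()
    excl = set(exclusion_list)
    species = list(species_list)
    removed = [sp for sp in species if sp in excl]
    missing = excl - set(species)
    if removed:
        logger.info("excluded domesticated species: %s", ", ".join(sorted(removed)))
    if missing:
        logger.debug(
            "exclusion-list species not present in data: %s", ", ".join(sorted(missing))
        )
    return [sp for sp in species if sp not in excl]


def default_domesticated_species() -> list[str]:
    """Packaged exclusion list of domesticated binomials (user-overridable)."""
    text = (
        resources.files("comparonc").joinpath("data/domesticated_species.txt")
    ).read_text()
    return [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


# ---------------------------------------------------------------------------
# I/O

_RECORD_COLUMNS = [
    "id",
    "species",
    "sex",
    "birth_date",
    "birth_precision_days",
    "death_date",
    "alive",
    "necropsy",
    "cause",
]


def read_records(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"id": str})
    missing = set(_RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records file missing columns: {sorted(missing)}")
    return df


def records_to_frame(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.individual_id for r in records],
            "species": [r.species for r in records],
            "sex": [r.sex for r in records],
            "birth_date": [r.birth_date for r in records],
            "birth_precision_days": [r.birth_precision_days for r in records],
            "death_date": [r.death_date for r in records],
            "alive": [r.alive_at_extraction for r in records],
            "necropsy": [r.necropsy_available for r in records],
            "cause": [r.cause for r in records],
        }
    )


def read_species_table(path: str | Path) -> dict[str, SpeciesLifeHistory]:
    df = pd.read_csv(path)
    diet_cols = [c for c in df.columns if c.startswith("diet_")]
    table: dict[str, SpeciesLifeHistory] = {}
    for _, row in df.iterrows():
        diet = {c[len("diet_"):]: row[c] for c in diet_cols if pd.notna(row[c])}
        table[row["species"]] = SpeciesLifeHistory(
            species=row["species"],
            alpha_male=row.get("alpha_male") if pd.notna(row.get("alpha_male")) else None,
            alpha_female=row.get("alpha_female")
            if pd.notna(row.get("alpha_female"))
            else None,
            body_mass=row["body_mass"],
            order=row.get("order", "unknown"),
            diet=diet,
            domesticated=bool(row.get("domesticated", False)),
        )
    return table
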