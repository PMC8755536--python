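"""End-to-end assembly: records -> cohorts -> survival -> species trait table.

Thin orchestration over the cohort, survival and cancer_risk modules; the
resulting table is the input to every comparative model.
"""

from __future__ import annotations

from datetime import date
from typing import Iterable, Mapping

import pandas as pd

from . import cohort as coh
from .cancer_risk import estimate_species_risk
from .models import recode_diet
from .survival import adult_life_expectancy, km_fit, survival_quantile


def _as_life_history(species_table) -> Mapping[str, coh.SpeciesLifeHistory]:
    if isinstance(species_table, Mapping):
        return species_table
    table = {}
    diet_cols = [c for c in species_table.columns if c.startswith("diet_")]
    for row in species_table.itertuples(index=False):
        d = row._asdict()
        table[d["species"]] = coh.SpeciesLifeHistory(
            species=d["species"],
            alpha_male=d.get("alpha_male"),
            alpha_female=d.get("alpha_female"),
            body_mass=d.get("body_mass"),
            order=d.get("order", "unknown"),
            diet={c[len("diet_"):]: d[c] for c in diet_cols},
            domesticated=bool(d.get("domesticated", False)),
        )
    return table


def build_traits_table(
    records: pd.DataFrame,
    species_table,
    window_start: date = date(2010, 1, 1),
    extraction_date: date = date(2020, 5, 30),
    min_necropsied: int = 20,
    domesticated_exclusions: Iterable[str] | None = (),
    survival_floor: float = 0.10,
) -> pd.DataFrame:
    """Species-level analysis table: risk metrics, adult life expectancy and
    life-history covariates for every species passing the inclusion rules.

    ``domesticated_exclusions``: iterable of binomials to drop, ``None`` for
    the packaged default list, empty (default) for no exclusion.
    """
    life_history = _as_life_history(species_table)
    result = coh.filter_eligible(records, window_start, extraction_date, life_history)
    included = coh.apply_species_thresholds(result.cohorts, min_necropsied)
    if domesticated_exclusions is None or list(domesticated_exclusions):
        included = coh.exclude_domesticated(included, domesticated_exclusions)

    rows = []
    for sp in included:
        c = result.cohorts[sp]
        est = estimate_species_risk(c, survival_floor=survival_floor)
        curve = km_fit(c.members, "all-deaths")
        le = adult_life_expectancy(curve)
        q10 = survival_quantile(curve, survival_floor)
        lh = life_history[sp]
        row = {
            "species": sp,
            "n_total": est.n_total,
            "n_dead": est.n_dead,
            "n_necropsied": est.n_necropsied,
            "n_cancer": est.n_cancer,
            "cmr": est.cmr,
            "icm": est.icm,
            "icm_eligible": est.icm_eligible,
            "alpha": curve.alpha,
            "life_expectancy": le.value,
            "le_truncated": le.truncated,
            "q10_age": q10.age,
            "body_mass": lh.body_mass,
            "order": lh.order,
        }
        for item, level in lh.diet.items():
            row[f"diet_{item}"] = recode_diet(level)
        rows.append(row)
    return pd.DataFrame(rows)


def sex_specific_risk(
    records: pd.DataFrame,
    species_table,
    window_start: date = date(2010, 1, 1),
    extraction_date: date = date(2020, 5, 30),
    min_per_sex: int = 10,
    survival_floor: float = 0.10,
) -> pd.DataFrame:
    """Per-sex CMR/ICM for species with at least ``min_per_sex`` necropsied
    individuals of each sex (the sex-bias analysis table)."""
    life_history = _as_life_history(species_table)
    out: dict[str, dict] = {}
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex]
        res = coh.filter_eligible(sub, window_start, extraction_date, life_history)
        for sp, c in res.cohorts.items():
            if c.n_necropsied < min_per_sex:
                continue
            est = estimate_species_risk(c, survival_floor=survival_floor)
            out.setdefault(sp, {"species": sp})
            out[sp][f"cmr_{sex}"] = est.cmr
            out[sp][f"icm_{sex}"] = est.icm
    df = pd.DataFrame([v for v in out.values()])
    if df.empty:
        return pd.DataFrame(
            columns=["species", "cmr_male", "icm_male", "cmr_female", "icm_female"]
        )
    return df.dropna(subset=["cmr_male", "cmr_female"]).reset_index(drop=True)
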