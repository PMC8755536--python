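"""Synthetic zoo-world generator with known ground truth.

The real individual-level data behind managed-population cancer studies
are access-restricted, so the pipeline is validated on simulated worlds
that reproduce the structure of those data: a fixed observation window
(2010-01-01 to 2020-05-30), adults already alive at the window start
entering left-truncated at their age on that date, survivors
right-censored at extraction, per-individual necropsy missingness, and
species-level cancer-death probabilities generated from a logit-linear
model in log body mass and log adult life expectancy with
phylogenetically correlated residuals of known Pagel's lambda.

Default effect sizes mirror the near-null regime of comparative cancer
data — a slight decrease of risk per body-mass doubling and a moderate
increase per life-expectancy doubling on the logit scale; a
``strong_effects`` preset is provided for power checks.

One master seed fans out to named substreams (tree, traits, individuals)
so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
import random
from dataclasses import dataclass
from datetime import date
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .models import inv_logit
from .phylo import Phylogeny, lambda_transform

WINDOW_START = date(2010, 1, 1)
EXTRACTION_DATE = date(2020, 5, 30)

_SUBSTREAMS = {"tree": 0, "traits": 1, "individuals": 2}


@dataclass
class WorldSpec:
    """Generative parameters of a synthetic world (the ground truth)."""

    n_species: int = 150
    n_individuals: int = 300          # mean per-species sample size
    n_dispersion: float = 0.5         # lognormal sigma of per-species sizes
    # logit-scale cancer-death probability model
    beta0: float = -3.4
    beta_mass: float = -0.15         # per ln(kg): ~ -10% risk per mass doubling
    beta_lifespan: float = 0.6       # per ln(year): ~ +50% risk per doubling
    lambda_true: float = 0.5
    resid_sd: float = 1.8
    # Brownian trait scales (tree has unit depth)
    log_mass_root: float = math.log(10.0)   # kg
    log_mass_sd: float = 3.5
    log_le_root: float = math.log(12.0)     # years
    log_le_sd: float = 0.5
    # life history
    maturity_fraction: float = 0.2   # alpha as a fraction of adult life expectancy
    # observation process
    window_start: date = WINDOW_START
    extraction_date: date = EXTRACTION_DATE
    adult_fraction_at_start: float = 0.6
    necropsy_prob: float = 0.9
    unknown_cause_prob: float = 0.0  # extra record loss among necropsied deaths
    necropsy_mnar_coef: float = 0.0  # >0: cancer deaths likelier to be necropsied
    diet_effect: float = 0.0         # logit shift for mammal-eating species
    unknown_sex_prob: float = 0.12
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        for p in (
            self.adult_fraction_at_start,
            self.necropsy_prob,
            self.unknown_cause_prob,
            self.unknown_sex_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[stream],))
        return np.random.default_rng(ss)


def strong_effects(seed: int = 0, **kwargs) -> WorldSpec:
    """Preset with pronounced mass/lifespan effects for power checks."""
    return WorldSpec(
        beta_mass=-0.5, beta_lifespan=1.5, resid_sd=0.8, seed=seed, **kwargs
    )


def near_null_effects(seed: int = 0, **kwargs) -> WorldSpec:
    """Preset mirroring the near-null comparative regime: per-doubling
    effects of roughly -3% (mass) and +29% (life expectancy) on the logit
    scale — too small to sign-recover reliably at default sample sizes,
    which is the point of the regime."""
    return WorldSpec(
        beta_mass=-0.0438, beta_lifespan=0.412, seed=seed, **kwargs
    )


def mnar_necropsy(seed: int = 0, **kwargs) -> WorldSpec:
    """Stress preset: cause-dependent (missing-not-at-random) necropsy
    availability, for probing sensitivity of the complete-case design."""
    return WorldSpec(necropsy_mnar_coef=0.3, seed=seed, **kwargs)


# ---------------------------------------------------------------------------
# tree


def simulate_tree(n_species: int, seed: int) -> Phylogeny:
    """Pure-birth (Yule) tree with ``n_species`` tips, scaled to unit depth."""
    if n_species < 2:
        raise ValueError("need at least 2 tips")
    from dendropy.simulate import treesim

    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        rng=rng,
        repeat_until_success=True,
    )
    # deterministic canonical labels
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    depth = max(lf.root_distance for lf in tree.leaf_node_iter())
    if depth <= 0.0:
        # the process stops the instant the last tip appears; a 2-tip tree
        # can therefore have zero elapsed time — give the cherry unit depth
        for lf in tree.leaf_node_iter():
            lf.edge.length = 1.0
        return Phylogeny(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return Phylogeny(tree)


# ---------------------------------------------------------------------------
# species traits


def _brownian(rng, L: np.ndarray, root: float, sd: float) -> np.ndarray:
    return root + sd * (L @ rng.standard_normal(L.shape[0]))


def _order_labels(tree: Phylogeny, cut: float = 0.3) -> dict[str, str]:
    """Clade-based taxonomic 'orders': tips grouped by the ancestral lineage
    crossing a fixed depth from the root."""
    t = tree._tree
    t.calc_node_root_distances(return_leaf_distances_only=False)
    labels: dict[str, str] = {}
    counter = 0
    for node in t.preorder_node_iter():
        parent = node.parent_node
        pdist = parent.root_distance if parent is not None else 0.0
        if node.root_distance >= cut > pdist:
            counter += 1
            name = f"order{counter:02d}"
            for lf in node.leaf_iter():
                labels[lf.taxon.label] = name
    for lf in t.leaf_node_iter():
        labels.setdefault(lf.taxon.label, "order00")
    return labels


_DIET_PREVALENCE = {
    "animal": 0.50,
    "invertebrate": 0.40,
    "vertebrate": 0.35,
    "fish": 0.15,
    "reptile": 0.10,
    "bird": 0.15,
    "mammal": 0.20,
}


def simulate_species_traits(tree: Phylogeny, spec: WorldSpec):
    """Species-level trait table plus the generative truth record.

    log body mass and log adult life expectancy evolve by Brownian motion
    on the tree; the cancer-death probability is
    inv-logit(b0 + b_mass*ln m + b_le*ln e + u) with u ~ N(0, sd^2 C(lambda)).
    """
    rng = spec.rng("traits")
    species = sorted(tree.tip_labels)
    _, C1 = tree.covariance(1.0, species=species)
    L1 = linalg.cholesky(C1 + 1e-12 * np.eye(len(species)), lower=True)

    log_mass = _brownian(rng, L1, spec.log_mass_root, spec.log_mass_sd)
    log_le = _brownian(rng, L1, spec.log_le_root, spec.log_le_sd)

    Clam = lambda_transform(C1, spec.lambda_true)
    Llam = linalg.cholesky(Clam + 1e-12 * np.eye(len(species)), lower=True)
    u = spec.resid_sd * (Llam @ rng.standard_normal(len(species)))

    # correlated latent carnivory drives the diet flags
    carn = L1 @ rng.standard_normal(len(species))
    diet_flags = {}
    for item, prev in _DIET_PREVALENCE.items():
        noisy = carn + 0.5 * rng.standard_normal(len(species))
        thresh = np.quantile(noisy, 1.0 - prev)
        diet_flags[item] = (noisy > thresh).astype(int)

    lp = (
        spec.beta0
        + spec.beta_mass * log_mass
        + spec.beta_lifespan * log_le
        + u
        + spec.diet_effect * diet_flags["mammal"]
    )
    p_cancer = inv_logit(lp)

    life_expectancy = np.exp(log_le)
    alpha_f = spec.maturity_fraction * life_expectancy
    alpha_m = 1.1 * alpha_f
    orders = _order_labels(tree)

    df = pd.DataFrame(
        {
            "species": species,
            "body_mass": np.exp(log_mass),
            "life_expectancy_true": life_expectancy,
            "alpha_female": alpha_f,
            "alpha_male": alpha_m,
            "p_cancer": p_cancer,
            "order": [orders[sp] for sp in species],
            "domesticated": False,
        }
    )
    for item, flags in diet_flags.items():
        # four-level labels so the recode path is exercised downstream
        lvl1 = np.where(rng.random(len(species)) < 0.5, "primary", "secondary")
        lvl0 = np.where(rng.random(len(species)) < 0.8, "never", "occasional")
        df[f"diet_{item}"] = np.where(flags == 1, lvl1, lvl0)

    truth = {
        "beta0": spec.beta0,
        "beta_mass": spec.beta_mass,
        "beta_lifespan": spec.beta_lifespan,
        "lambda_true": spec.lambda_true,
        "resid_sd": spec.resid_sd,
        "diet_effect": spec.diet_effect,
        "p_cancer": dict(zip(species, p_cancer.tolist())),
        "life_expectancy": dict(zip(species, life_expectancy.tolist())),
    }
    return df, truth


# ---------------------------------------------------------------------------
# individuals


def simulate_individuals(trait_table: pd.DataFrame, spec: WorldSpec) -> pd.DataFrame:
    """Individual-level records emulating a managed-population extract.

    A fraction of each species is already adult at the window start (ages
    above maturity drawn from the stationary exponential age distribution,
    so their remaining lifetimes stay exponential); the rest are born
    during the window.  Deaths are labelled cancer with the species'
    generative probability when a necropsy record exists; survivors at the
    extraction date are alive/censored.
    """
    rng = spec.rng("individuals")
    ws = np.datetime64(spec.window_start)
    ex = np.datetime64(spec.extraction_date)
    window_days = int((ex - ws) / np.timedelta64(1, "D"))

    # per-species sample sizes: lognormal with mean n_individuals, floored
    # at 30 — managed-population holdings vary over orders of magnitude
    sigma = spec.n_dispersion
    n_per_species = np.maximum(
        30,
        np.round(
            spec.n_individuals
            * rng.lognormal(-0.5 * sigma**2, sigma, size=len(trait_table))
        ).astype(int),
    )

    frames = []
    for row, n in zip(trait_table.itertuples(index=False), n_per_species):
        n = int(n)
        e = row.life_expectancy_true
        sex = rng.choice(
            ["male", "female", "unknown"],
            size=n,
            p=[
                (1 - spec.unknown_sex_prob) / 2,
                (1 - spec.unknown_sex_prob) / 2,
                spec.unknown_sex_prob,
            ],
        )
        alpha = np.where(
            sex == "male",
            row.alpha_male,
            np.where(sex == "female", row.alpha_female, max(row.alpha_male, row.alpha_female)),
        )
        is_initial = rng.random(n) < spec.adult_fraction_at_start

        # stationary excess age, capped at the 1%-survival age (and 120 y)
        # so birthdates stay in a realistic husbandry range; residual
        # lifetimes are exponential either way (memorylessness)
        adult_age_at_ws = np.minimum(
            rng.exponential(e, size=n), min(4.6 * e, 120.0)
        )
        birth_offset_years = np.where(
            is_initial,
            -(alpha + adult_age_at_ws),
            rng.random(n) * (window_days / 365.25),
        )
        birth_days = np.round(birth_offset_years * 365.25).astype(int)
        birth = ws + birth_days.astype("timedelta64[D]")

        adult_lifetime = rng.exponential(e, size=n)
        death_age_years = np.where(
            is_initial, alpha + adult_age_at_ws + adult_lifetime, alpha + adult_lifetime
        )
        death = birth + np.round(death_age_years * 365.25).astype(int).astype(
            "timedelta64[D]"
        )
        dead = death <= ex

        precision = rng.choice([0, 10, 45], size=n, p=[0.85, 0.10, 0.05])

        is_cancer = rng.random(n) < row.p_cancer
        nec_p = np.full(n, spec.necropsy_prob)
        if spec.necropsy_mnar_coef:
            nec_p = np.clip(
                nec_p + spec.necropsy_mnar_coef * (is_cancer.astype(float) - 0.5),
                0.0,
                1.0,
            )
        necropsy = dead & (rng.random(n) < nec_p)
        if spec.unknown_cause_prob:
            necropsy &= rng.random(n) >= spec.unknown_cause_prob
        cause = np.where(
            necropsy, np.where(is_cancer, "cancer", "other"), "unknown"
        )
        cause = np.where(dead, cause, "")

        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{row.species}_{i:05d}" for i in range(n)],
                    "species": row.species,
                    "sex": sex,
                    "birth_date": birth.astype("datetime64[D]").astype(str),
                    "birth_precision_days": precision,
                    "death_date": np.where(
                        dead, death.astype("datetime64[D]").astype(str), ""
                    ),
                    "alive": ~dead,
                    "necropsy": necropsy,
                    "cause": cause,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# world assembly


@dataclass
class World:
    spec: WorldSpec
    tree: Phylogeny
    species_table: pd.DataFrame
    records: pd.DataFrame
    truth: dict


def simulate_world(spec: WorldSpec) -> World:
    tree = simulate_tree(spec.n_species, seed=int(spec.rng("tree").integers(2**31)))
    traits, truth = simulate_species_traits(tree, spec)
    records = simulate_individuals(traits, spec)
    return World(
        spec=spec, tree=tree, species_table=traits, records=records, truth=truth
    )


def write_world(world: World, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.records.to_csv(out / "records.csv", index=False)
    world.species_table.to_csv(out / "species.csv", index=False)
    world.tree.write_newick(out / "tree.nwk")
    truth = dict(world.truth)
    truth["spec"] = {
        k: (v.isoformat() if isinstance(v, date) else v)
        for k, v in dataclasses.asdict(world.spec).items()
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
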