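"""Synthetic study generator with known ground truth.

Emulates the full field design — pellet tables, wildflower quadrat
surveys, crop quadrat measurements and the landscape-area config — from a
:class:`SimulationConfig` holding the true constancy probability,
per-morphotype preference multipliers and per-survey availability weights,
so every pipeline stage can be tested for parameter recovery without field
data.

Generative model for one pellet of ``G`` grains: with probability ``c``
(the constancy parameter) all grains come from a single morphotype drawn
proportional to availability x multiplier; otherwise the grain counts are
Dirichlet-multinomial with mean proportional to availability x multiplier
and concentration 1/theta.  theta = 0 degrades to a pure multinomial — the
exact generative form of the availability-proportional null, which the
null-model coverage tests rely on.  Wildflower quadrat floral units are
negative-binomial around each species' weight over the 15-transect x
10-quadrat survey layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .availability import AvailabilityProfile, CropQuadrat, CropSpec, LandscapeAreas
from .data_model import Dataset, PollenPellet, StudyDesign, TaxonomyMap, write_pellet_table

__all__ = [
    "SpeciesParams",
    "SimulationConfig",
    "GroundTruth",
    "simulate_resources",
    "simulate_pellets",
    "simulate_dataset",
    "make_fixture_suite",
]


@dataclass
class SpeciesParams:
    """Generative parameters for one bee species.

    ``constancy_prob`` is the chance a trip is fully constant (single
    morphotype); ``preference_multipliers`` scale availability into
    collection odds (1 = availability-proportional); ``overdispersion``
    theta controls Dirichlet-multinomial heterogeneity of non-constant
    pellets (0 = pure multinomial).
    """

    constancy_prob: float = 0.8
    preference_multipliers: dict[str, float] = field(default_factory=dict)
    n_pellets_per_colony_day: int = 40
    grains_per_pellet: int = 500
    overdispersion: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.constancy_prob <= 1.0:
            raise ValueError("constancy_prob must lie in [0, 1]")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")
        if any(v <= 0 for v in self.preference_multipliers.values()):
            raise ValueError("preference multipliers must be positive")


@dataclass
class SimulationConfig:
    """Study-level simulation settings (defaults mirror the field design)."""

    seed: int = 0
    n_sites: int = 3
    surveys: Sequence[str] = datasets.SURVEYS
    taxonomy: TaxonomyMap = field(default_factory=datasets.study_taxonomy)
    #: per-survey morphotype -> positive weight (normalised internally)
    availability_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    species_params: dict[str, SpeciesParams] = field(default_factory=dict)
    n_transects_per_site: int = datasets.N_TRANSECTS_PER_SITE
    n_quadrats_per_transect: int = datasets.N_QUADRATS_PER_TRANSECT
    #: mean floral units per quadrat for a weight-1 morphotype
    quadrat_mean_scale: float = 40.0
    #: negative-binomial dispersion (gamma shape) for quadrat counts
    nb_dispersion: float = 2.0
    days_per_site_period: int = 2
    include_crops: bool = True

    @property
    def sites(self) -> list[str]:
        return [f"site{i + 1}" for i in range(self.n_sites)]


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests."""

    availability: dict[str, dict[str, float]] = field(default_factory=dict)
    collection_props: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=dict
    )
    constancy_labels: dict[str, bool] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "availability": self.availability,
                "collection_props": self.collection_props,
                "constancy_labels": self.constancy_labels,
            },
            indent=1,
            sort_keys=True,
        )


def _normalise(weights: Mapping[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("weights must have positive sum")
    return {k: v / total for k, v in weights.items()}


def _effective_props(
    availability: Mapping[str, float], multipliers: Mapping[str, float]
) -> dict[str, float]:
    """Collection proportions: availability x multiplier, renormalised."""
    w = {m: v * multipliers.get(m, 1.0) for m, v in availability.items() if v > 0}
    return _normalise(w)


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------


def simulate_resources(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[CropSpec], LandscapeAreas, GroundTruth]:
    """Generate quadrat records, crop specs and landscape areas.

    Each survey's weights are spread over the member species of each
    weighted morphotype; per-quadrat floral units are negative-binomial
    (gamma-Poisson) around the species' share of ``quadrat_mean_scale``.
    Morphotype availability recovered by the efc pipeline converges to the
    configured weights as counts grow.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    truth = GroundTruth()
    rows = []
    for survey in config.surveys:
        weights = _normalise(config.availability_weights.get(survey, {}))
        truth.availability[survey] = weights
        species_mean: dict[str, float] = {}
        for m, w in weights.items():
            members = config.taxonomy.members_of(m)
            if not members:
                continue  # pollen-only morphotype: never in resources
            share = w * config.quadrat_mean_scale / len(members)
            for sp in members:
                species_mean[sp] = species_mean.get(sp, 0.0) + share
        for site in config.sites:
            for t in range(config.n_transects_per_site):
                for q in range(config.n_quadrats_per_transect):
                    for sp in sorted(species_mean):
                        mu = species_mean[sp]
                        # gamma-Poisson mixture == negative binomial
                        lam = rng.gamma(config.nb_dispersion, mu / config.nb_dispersion)
                        units = int(rng.poisson(lam))
                        if units > 0:
                            rows.append(
                                (site, survey, f"T{t + 1}", f"Q{q + 1}", sp, units)
                            )
    records = pd.DataFrame(
        rows,
        columns=["site", "survey", "transect", "quadrat", "species", "floral_units"],
    )

    crops: list[CropSpec] = []
    if config.include_crops:
        crops = [
            CropSpec(
                "alfalfa",
                area_ha=40.0,
                quadrats=[
                    CropQuadrat(racemes=float(rng.poisson(20))) for _ in range(15)
                ],
            ),
            CropSpec(
                "corn",
                area_ha=60.0,
                quadrats=[CropQuadrat(stalks=float(rng.poisson(30))) for _ in range(9)],
            ),
            CropSpec(
                "soybean",
                area_ha=35.0,
                quadrats=[
                    CropQuadrat(
                        stems=float(rng.poisson(100)),
                        racemes_per_stem=tuple(
                            float(x) for x in rng.poisson(4, size=5)
                        ),
                    )
                    for _ in range(9)
                ],
            ),
        ]
    areas = LandscapeAreas(
        total_area_ha=datasets.TOTAL_AREA_HA,
        crop_areas={c.crop: c.area_ha for c in crops},
        minor_crop_area_ha=17.0 if crops else 0.0,
    )
    return records, crops, areas, truth


# ---------------------------------------------------------------------------
# Pellets
# ---------------------------------------------------------------------------


def simulate_pellets(
    availability: AvailabilityProfile | Mapping[str, float],
    params: SpeciesParams,
    n: int,
    rng: np.random.Generator | int | None = None,
    *,
    bee_species: str = "honeybee",
    site: str = "site1",
    day: str = "2016-06-15",
    period: str = "P1",
    id_prefix: str = "HB",
) -> tuple[list[PollenPellet], GroundTruth]:
    """Draw ``n`` pellets from the constancy + Dirichlet-multinomial model."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    props = (
        availability.proportions
        if isinstance(availability, AvailabilityProfile)
        else dict(availability)
    )
    eff = _effective_props(props, params.preference_multipliers)
    morphs = sorted(eff)
    p = np.array([eff[m] for m in morphs])
    G = params.grains_per_pellet
    theta = params.overdispersion

    truth = GroundTruth()
    truth.collection_props = {bee_species: {period: eff}}
    pellets = []
    for i in range(n):
        pid = f"{id_prefix}{i + 1:04d}"
        constant = bool(rng.random() < params.constancy_prob)
        truth.constancy_labels[pid] = constant
        if constant:
            m = morphs[rng.choice(len(morphs), p=p)]
            counts = {m: G}
        else:
            if theta > 0:
                probs = rng.dirichlet(p / theta)
            else:
                probs = p
            draw = rng.multinomial(G, probs)
            counts = {m: int(c) for m, c in zip(morphs, draw) if c > 0}
        pellets.append(
            PollenPellet(
                bee_species=bee_species,
                site=site,
                day=day,
                period=period,
                pellet_id=pid,
                counts=counts,
                grains_total=G,
            )
        )
    return pellets, truth


def simulate_dataset(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[Dataset, pd.DataFrame, list[CropSpec], LandscapeAreas, GroundTruth]:
    """Full study simulation: resources plus pellets for every colony-day."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records, crops, areas, truth = simulate_resources(config, rng)
    design = StudyDesign(
        period_to_survey=dict(datasets.PERIOD_TO_SURVEY),
        sites=config.sites,
        surveys=list(config.surveys),
    )
    day_index = {
        "P1": "06", "P2": "07", "P3": "07", "P4": "08", "P5": "09",
    }
    pellets: list[PollenPellet] = []
    for bee, params in sorted(config.species_params.items()):
        truth.collection_props.setdefault(bee, {})
        for period, survey in sorted(datasets.PERIOD_TO_SURVEY.items()):
            weights = truth.availability.get(survey)
            if not weights:
                continue
            eff = _effective_props(weights, params.preference_multipliers)
            truth.collection_props[bee][period] = eff
            for site in config.sites:
                for d in range(config.days_per_site_period):
                    day = f"2016-{day_index[period]}-{10 + 3 * d:02d}"
                    prefix = f"{bee[:2].upper()}_{site}_{period}_d{d}_"
                    day_pellets, sub_truth = simulate_pellets(
                        weights,
                        params,
                        params.n_pellets_per_colony_day,
                        rng,
                        bee_species=bee,
                        site=site,
                        day=day,
                        period=period,
                        id_prefix=prefix,
                    )
                    pellets.extend(day_pellets)
                    truth.constancy_labels.update(sub_truth.constancy_labels)
    return Dataset(pellets, config.taxonomy, design), records, crops, areas, truth


def species_contrast_scenario() -> tuple[dict[str, float], dict[str, SpeciesParams]]:
    """Honeybee-like vs bumblebee-like parameters over a mid-season landscape.

    The honeybee profile couples high trip constancy with a strong
    concentration on Fabaceae pollen (the signature of waggle-dance
    recruitment onto mass-flowering legumes); the bumblebee profile couples
    low constancy with a more even spread across families.  Constancy
    probabilities use the two species' reported daily means (0.87 vs 0.62).
    """
    availability = {
        "Fabaceae_Tricolporate": 0.45,
        "Lotus_corniculatus": 0.10,
        "Apiaceae": 0.20,
        "Asteraceae_Spines": 0.15,
        "Asteraceae_Lophate": 0.05,
        "Monarda_fistulosa": 0.05,
    }
    params = {
        "honeybee": SpeciesParams(
            constancy_prob=0.87,
            preference_multipliers={
                "Fabaceae_Tricolporate": 4.0,
                "Lotus_corniculatus": 4.0,
            },
            n_pellets_per_colony_day=40,
            overdispersion=0.15,
        ),
        "bumblebee": SpeciesParams(
            constancy_prob=0.62,
            preference_multipliers={"Asteraceae_Spines": 2.0},
            n_pellets_per_colony_day=20,
            overdispersion=0.15,
        ),
    }
    return availability, params


# ---------------------------------------------------------------------------
# Fixture suites
# ---------------------------------------------------------------------------


def _default_weights(
    taxonomy: TaxonomyMap, surveys: Sequence[str], rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Season-varying weights over the resource-side morphotypes."""
    resource_morphs = [m for m in taxonomy.morphotypes if taxonomy.members_of(m)]
    out = {}
    for survey in surveys:
        w = rng.dirichlet(np.full(len(resource_morphs), 1.5))
        out[survey] = {m: float(v) for m, v in zip(resource_morphs, w) if v > 1e-3}
    return out


def _study_config(seed: int) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    tax = datasets.study_taxonomy()
    cfg = SimulationConfig(
        seed=seed,
        n_sites=3,
        taxonomy=tax,
        availability_weights=_default_weights(tax, datasets.SURVEYS, rng),
        species_params={
            "honeybee": SpeciesParams(
                constancy_prob=0.87,
                n_pellets_per_colony_day=40,
                overdispersion=0.15,
            ),
            "bumblebee": SpeciesParams(
                constancy_prob=0.62,
                n_pellets_per_colony_day=20,
                overdispersion=0.15,
            ),
        },
        days_per_site_period=2,
    )
    return cfg


def _tiny_config(seed: int) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    tax = datasets.study_taxonomy()
    cfg = SimulationConfig(
        seed=seed,
        n_sites=1,
        taxonomy=tax,
        availability_weights=_default_weights(tax, datasets.SURVEYS, rng),
        species_params={
            "honeybee": SpeciesParams(constancy_prob=0.9, n_pellets_per_colony_day=6),
            "bumblebee": SpeciesParams(constancy_prob=0.5, n_pellets_per_colony_day=4),
        },
        n_transects_per_site=2,
        n_quadrats_per_transect=3,
        days_per_site_period=1,
    )
    return cfg


def make_fixture_suite(out_dir, scale: str = "tiny", seed: int = 0) -> dict[str, Path]:
    """Write a complete, mutually consistent input file set.

    ``tiny`` runs the full pipeline in seconds; ``study`` mirrors the field
    design (2 bee species x 3 sites x 5 periods, 40/20 pellets per colony
    day, the 28-morphotype / 16-family inventory).  Same seed, byte-
    identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = {"tiny": _tiny_config, "study": _study_config}[scale](seed)
    dataset, records, crops, areas, truth = simulate_dataset(cfg)

    paths = {
        "pellets": out / "pellets.csv",
        "taxonomy": out / "taxonomy.csv",
        "quadrats": out / "quadrats.csv",
        "crops": out / "crops.csv",
        "areas": out / "areas.yaml",
        "ground_truth": out / "ground_truth.json",
    }
    write_pellet_table(dataset, paths["pellets"])
    cfg.taxonomy.to_frame().to_csv(paths["taxonomy"], index=False)
    records.to_csv(paths["quadrats"], index=False)

    crop_rows = []
    for spec in crops:
        for qi, q in enumerate(spec.quadrats, start=1):
            if q.racemes is not None:
                crop_rows.append((spec.crop, f"Q{qi}", "racemes", q.racemes))
            if q.stalks is not None:
                crop_rows.append((spec.crop, f"Q{qi}", "stalks", q.stalks))
            if q.stems is not None:
                crop_rows.append((spec.crop, f"Q{qi}", "stems", q.stems))
                for r in q.racemes_per_stem or ():
                    crop_rows.append((spec.crop, f"Q{qi}", "racemes_per_stem", r))
    pd.DataFrame(crop_rows, columns=["crop", "quadrat", "measure", "value"]).to_csv(
        paths["crops"], index=False
    )

    areas_cfg = {
        "total_area_ha": areas.total_area_ha,
        "minor_crop_area_ha": areas.minor_crop_area_ha,
        "crops": {
            c.crop: {
                "area_ha": c.area_ha,
                "flowering_surveys": sorted(c.flowering_surveys),
            }
            for c in crops
        },
    }
    with open(paths["areas"], "w") as fh:
        yaml.safe_dump(areas_cfg, fh, sort_keys=True)
    paths["ground_truth"].write_text(truth.to_json())
    return paths
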