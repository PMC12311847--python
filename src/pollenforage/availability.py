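"""Floral resource availability: crop densities, efc and morphotype shares.

Resource availability is estimated over a fixed landscape area (339 ha in
the original design) split between crop fields and wildflowers.  Wildflower
floral units (open flowers, racemes, umbels or heads, treated as equivalent
counts) are summed over 150 1 m^2 quadrats per survey; crop floral
densities come from dedicated quadrat protocols (alfalfa racemes per 1 m^2;
corn stalks per 2 m^2 quadrat halved to match; soybean racemes/stem on a
50% stem subsample extrapolated to the quadrat) and are scaled to the same
notional 150 quadrats.  Each total is then weighted by the proportional
area its stratum occupies — the estimated floral count (efc) — and
morphotype availability is the share of summed member-species efcs in the
survey's total efc.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import TaxonomyMap, TaxonomyError, ValidationError
from .metrics import simpson_index

__all__ = [
    "CropQuadrat",
    "CropSpec",
    "LandscapeAreas",
    "AvailabilityProfile",
    "crop_floral_density",
    "wildflower_survey_counts",
    "estimated_floral_counts",
    "morphotype_availability",
    "wildflower_richness_diversity",
    "read_quadrat_table",
    "read_crop_table",
    "read_areas_config",
    "survey_availability",
]

QUADRAT_COLUMNS = ["site", "survey", "transect", "quadrat", "species", "floral_units"]

#: Wildflower survey effort: 150 1 m^2 quadrats (3 sites x 5 transects x 10).
N_SURVEY_QUADRATS = 150

#: Canonical plant species contributing each crop's pollen.
CROP_SPECIES = {"alfalfa": "Medicago_sativa", "corn": "Zea_mays", "soybean": "Glycine_max"}

#: Default bloom windows.  Corn and soybean have one mass-flowering period
#: (late July to early August); alfalfa is perennial, repeatedly cut and
#: re-flowering, so it defaults to every survey.  Configurable per study.
DEFAULT_FLOWERING = {
    "alfalfa": {"June", "July", "August", "September"},
    "corn": {"July", "August"},
    "soybean": {"July", "August"},
}


@dataclass(frozen=True)
class CropQuadrat:
    """One crop quadrat measurement; fields depend on the crop protocol.

    alfalfa: ``racemes`` (per 1 m^2).  corn: ``stalks`` (per 2 m^2 quadrat).
    soybean: ``stems`` plus the ``racemes_per_stem`` subsample (~50% of stems).
    """

    racemes: float | None = None
    stalks: float | None = None
    stems: float | None = None
    racemes_per_stem: tuple[float, ...] | None = None


@dataclass
class CropSpec:
    """A focal crop: its area, quadrat measurements and bloom window."""

    crop: str
    area_ha: float
    quadrats: list[CropQuadrat] = field(default_factory=list)
    flowering_surveys: set[str] = field(default_factory=set)
    plant_species: str = ""

    def __post_init__(self):
        if self.area_ha < 0:
            raise ValidationError(f"{self.crop}: negative area")
        if not self.flowering_surveys:
            self.flowering_surveys = set(DEFAULT_FLOWERING.get(self.crop, set()))
        if not self.plant_species:
            self.plant_species = CROP_SPECIES.get(self.crop, self.crop)


@dataclass
class LandscapeAreas:
    """Area allocation of the surveyed landscape.

    Wildflower area is derived: total minus all crop hectares (focal crops
    plus any minor crops, whose area is subtracted even though they
    contribute no floral counts).
    """

    total_area_ha: float
    crop_areas: dict[str, float] = field(default_factory=dict)
    minor_crop_area_ha: float = 0.0

    def __post_init__(self):
        if self.total_area_ha <= 0:
            raise ValidationError("total_area_ha must be positive")
        if any(a < 0 for a in self.crop_areas.values()) or self.minor_crop_area_ha < 0:
            raise ValidationError("crop areas must be non-negative")
        if sum(self.crop_areas.values()) + self.minor_crop_area_ha > self.total_area_ha:
            raise ValidationError("crop areas exceed the total landscape area")

    @property
    def wildflower_area_ha(self) -> float:
        return self.total_area_ha - sum(self.crop_areas.values()) - self.minor_crop_area_ha

    def proportion(self, crop: str) -> float:
        return self.crop_areas.get(crop, 0.0) / self.total_area_ha

    @property
    def wildflower_proportion(self) -> float:
        return self.wildflower_area_ha / self.total_area_ha


@dataclass
class AvailabilityProfile:
    """Per-survey morphotype availability derived from efc.

    ``proportions`` sum to 1; ``efc`` keeps the underlying per-plant-species
    estimated floral counts for inspection.
    """

    survey: str
    proportions: dict[str, float]
    efc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if any(v < 0 for v in self.proportions.values()):
            raise ValidationError("availability proportions must be non-negative")
        s = sum(self.proportions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValidationError(f"availability proportions sum to {s}, not 1")

    @property
    def morphotypes(self) -> list[str]:
        return list(self.proportions)


# ---------------------------------------------------------------------------
# Crop floral density
# ---------------------------------------------------------------------------


def crop_floral_density(spec: CropSpec) -> float:
    """Floral units per 1 m^2 for a focal crop.

    alfalfa: mean racemes over the 1 m^2 quadrats.  corn: mean stalks per
    (2 m^2) quadrat divided by two to match the 1 m^2 quadrat size.
    soybean: per quadrat, the subsample mean racemes/stem times the stem
    count, then averaged over quadrats.
    """
    if not spec.quadrats:
        raise ValidationError(f"{spec.crop}: no quadrat measurements")
    if spec.crop == "alfalfa":
        vals = [q.racemes for q in spec.quadrats]
        if any(v is None for v in vals):
            raise ValidationError("alfalfa quadrat missing raceme count")
        return float(np.mean(vals))
    if spec.crop == "corn":
        vals = [q.stalks for q in spec.quadrats]
        if any(v is None for v in vals):
            raise ValidationError("corn quadrat missing stalk count")
        return float(np.mean(vals)) / 2.0
    if spec.crop == "soybean":
        per_quadrat = []
        for q in spec.quadrats:
            if q.stems is None or not q.racemes_per_stem:
                raise ValidationError(
                    "soybean quadrat missing stems or racemes-per-stem subsample"
                )
            per_quadrat.append(float(np.mean(q.racemes_per_stem)) * q.stems)
        return float(np.mean(per_quadrat))
    raise ValidationError(f"unknown crop {spec.crop!r}")


# ---------------------------------------------------------------------------
# Wildflower counts and efc
# ---------------------------------------------------------------------------


def wildflower_survey_counts(records: pd.DataFrame, survey: str) -> dict[str, float]:
    """Per-species floral-unit totals over one survey's quadrats.

    Species never recorded in the survey are simply absent (not
    zero-filled); totals are invariant to record order.
    """
    sub = records[records["survey"] == survey]
    totals = sub.groupby("species")["floral_units"].sum()
    return {sp: float(v) for sp, v in totals.items() if v > 0}


def estimated_floral_counts(
    wild_counts: Mapping[str, float],
    crops: Sequence[CropSpec],
    areas: LandscapeAreas,
    survey: str,
    n_quadrats: int = N_SURVEY_QUADRATS,
) -> dict[str, float]:
    """Area-weighted estimated floral counts (efc) per plant species.

    Wildflower species: survey total floral units x (wildflower area /
    total area).  Crops flowering during the survey: density per m^2 x
    ``n_quadrats`` (to be commensurate with the wildflower totals) x
    (crop area / total area).  A crop outside its bloom window contributes
    nothing.
    """
    efc: dict[str, float] = {}
    wf_prop = areas.wildflower_proportion
    for sp, units in wild_counts.items():
        efc[sp] = float(units) * wf_prop
    for spec in crops:
        if survey not in spec.flowering_surveys:
            continue
        density = crop_floral_density(spec)
        prop = areas.proportion(spec.crop)
        value = density * n_quadrats * prop
        efc[spec.plant_species] = efc.get(spec.plant_species, 0.0) + value
    return efc


def morphotype_availability(
    efc: Mapping[str, float],
    taxonomy: TaxonomyMap,
    survey: str,
) -> AvailabilityProfile:
    """Fold per-species efcs into morphotype availability proportions."""
    if not efc:
        raise ValidationError(f"{survey}: no efc values to aggregate")
    by_morph: dict[str, float] = {}
    for sp, value in efc.items():
        m = taxonomy.morphotype_of_species(sp)  # TaxonomyError if missing
        by_morph[m] = by_morph.get(m, 0.0) + value
    total = sum(by_morph.values())
    if total <= 0:
        raise ValidationError(f"{survey}: total efc is zero")
    props = {m: v / total for m, v in by_morph.items()}
    return AvailabilityProfile(survey=survey, proportions=props, efc=dict(efc))


def survey_availability(
    records: pd.DataFrame,
    crops: Sequence[CropSpec],
    areas: LandscapeAreas,
    taxonomy: TaxonomyMap,
    surveys: Iterable[str] = ("June", "July", "August", "September"),
    n_quadrats: int = N_SURVEY_QUADRATS,
) -> dict[str, AvailabilityProfile]:
    """End-to-end availability: quadrat records + crops -> one profile per survey."""
    out = {}
    for survey in surveys:
        wild = wildflower_survey_counts(records, survey)
        efc = estimated_floral_counts(wild, crops, areas, survey, n_quadrats)
        if efc:
            out[survey] = morphotype_availability(efc, taxonomy, survey)
        else:
            warnings.warn(f"{survey}: no floral resources recorded", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Wildflower richness / diversity
# ---------------------------------------------------------------------------


def wildflower_richness_diversity(
    records: pd.DataFrame,
    level: str = "species",
    taxonomy: TaxonomyMap | None = None,
) -> pd.DataFrame:
    """Richness S and Simpson diversity per site x survey.

    Floral-unit abundances are pooled across a site's transects for each
    survey (the full design yields 12 value pairs: 3 sites x 4 surveys);
    ``level`` regroups species into their pollen morphotype or plant family
    through the taxonomy before computing S and SDI.
    """
    if level not in ("species", "family", "morphotype"):
        raise ValueError(f"unknown level {level!r}")

    def relabel(sp: str) -> str:
        if level == "species":
            return sp
        if taxonomy is None:
            raise ValueError(f"{level}-level summaries require a taxonomy")
        m = taxonomy.morphotype_of_species(sp)
        return m if level == "morphotype" else taxonomy.family_of(m)

    rows = []
    for (site, survey), grp in records.groupby(["site", "survey"], sort=True):
        pooled: dict[str, float] = {}
        for sp, units in zip(grp["species"], grp["floral_units"]):
            if units <= 0:
                continue
            lab = relabel(sp)
            pooled[lab] = pooled.get(lab, 0.0) + float(units)
        if not pooled:
            continue
        rows.append(
            {
                "site": site,
                "survey": survey,
                "level": level,
                "richness_S": len(pooled),
                "diversity_SDI": simpson_index(list(pooled.values())),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_quadrat_table(path) -> pd.DataFrame:
    """Read the wildflower quadrat table (long format, one species-record/row)."""
    df = pd.read_csv(path, dtype={"floral_units": float}, keep_default_na=False)
    missing = set(QUADRAT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"quadrat table missing column(s): {sorted(missing)}")
    if (df["floral_units"] < 0).any():
        raise ValidationError("negative floral_units in quadrat table")
    return df


def read_crop_table(path, areas_config: Mapping | None = None) -> list[CropSpec]:
    """Read crop quadrat measurements (long format: crop,quadrat,measure,value).

    Measures: ``racemes`` (alfalfa), ``stalks`` (corn), ``stems`` and
    ``racemes_per_stem`` (soybean; repeated rows form the subsample).
    Areas and bloom windows come from ``areas_config`` (see
    :func:`read_areas_config`).
    """
    df = pd.read_csv(path, keep_default_na=False)
    missing = {"crop", "quadrat", "measure", "value"} - set(df.columns)
    if missing:
        raise ValidationError(f"crop table missing column(s): {sorted(missing)}")
    cfg = dict(areas_config or {})
    crop_cfg = cfg.get("crops", {})
    specs = []
    for crop, grp in df.groupby("crop", sort=True):
        quadrats = []
        for _, qgrp in grp.groupby("quadrat", sort=True):
            vals: dict[str, list[float]] = {}
            for meas, val in zip(qgrp["measure"], qgrp["value"]):
                vals.setdefault(meas, []).append(float(val))
            quadrats.append(
                CropQuadrat(
                    racemes=vals.get("racemes", [None])[0],
                    stalks=vals.get("stalks", [None])[0],
                    stems=vals.get("stems", [None])[0],
                    racemes_per_stem=tuple(vals["racemes_per_stem"])
                    if "racemes_per_stem" in vals
                    else None,
                )
            )
        this = crop_cfg.get(crop, {})
        specs.append(
            CropSpec(
                crop=crop,
                area_ha=float(this.get("area_ha", 0.0)),
                quadrats=quadrats,
                flowering_surveys=set(this.get("flowering_surveys", ())),
            )
        )
    return specs


def read_areas_config(path) -> tuple[LandscapeAreas, dict]:
    """Read the YAML areas config.

    Expected shape::

        total_area_ha: 339
        minor_crop_area_ha: 12
        crops:
          alfalfa: {area_ha: 40, flowering_surveys: [June, July, August, September]}
          corn:    {area_ha: 60, flowering_surveys: [July, August]}
          soybean: {area_ha: 35, flowering_surveys: [July, August]}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    areas = LandscapeAreas(
        total_area_ha=float(cfg["total_area_ha"]),
        crop_areas={c: float(d.get("area_ha", 0.0)) for c, d in cfg.get("crops", {}).items()},
        minor_crop_area_ha=float(cfg.get("minor_crop_area_ha", 0.0)),
    )
    return areas, cfg
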