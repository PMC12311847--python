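"""Core types and table I/O for corbicular pollen-load data.

The sampling unit is the pollen pellet: the packed corbicular load of one
returning forager, of which ~500 grains were counted under light microscopy
and assigned to morphotypes (categories defined by grain size, shape and
ornamentation; a morphotype may pool several plant species).  This module
houses the pellet/taxonomy/design containers, the delimited-table readers
and writers, the per-pellet rare-morphotype filter, family-level pooling,
and the alignment of the five pollen-collection periods onto the four
resource surveys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PollenPellet",
    "TaxonomyMap",
    "StudyDesign",
    "Dataset",
    "ValidationError",
    "TaxonomyError",
    "read_pellet_table",
    "write_pellet_table",
    "read_taxonomy_table",
    "apply_rare_filter",
    "to_proportions",
    "pool_to_family",
    "pool_periods_to_surveys",
]

PELLET_COLUMNS = [
    "bee_species",
    "site",
    "date",
    "period",
    "pellet_id",
    "morphotype",
    "grains",
]

VALID_PERIODS = ("P1", "P2", "P3", "P4", "P5")
VALID_BEE_SPECIES = ("honeybee", "bumblebee")

#: Default per-pellet exclusion threshold: any morphotype making up less
#: than 3% of the counted grains in a pellet is excluded from analysis.
RARE_FRACTION = 0.03


class ValidationError(ValueError):
    """A pellet table row violates the format contract."""


class TaxonomyError(KeyError):
    """A morphotype or plant species cannot be resolved in the taxonomy."""


@dataclass(frozen=True)
class PollenPellet:
    """One forager's pollen load as morphotype grain counts.

    ``grains_total`` is the number of grains counted on the slide (target
    500); after the rare-morphotype filter the sum of ``counts`` may fall
    below it.  Counts are never renormalised — downstream proportions use
    the retained sum.
    """

    bee_species: str
    site: str
    day: str
    period: str
    pellet_id: str
    counts: Mapping[str, int]
    grains_total: int = 500
    dry_weight_mg: float | None = None

    def __post_init__(self):
        if self.grains_total <= 0:
            raise ValidationError(f"pellet {self.pellet_id}: grains_total must be > 0")
        if any(c < 0 for c in self.counts.values()):
            raise ValidationError(f"pellet {self.pellet_id}: negative grain count")
        if sum(self.counts.values()) > self.grains_total:
            raise ValidationError(
                f"pellet {self.pellet_id}: counts sum exceeds grains_total"
            )

    @property
    def total(self) -> int:
        """Sum of retained grain counts."""
        return sum(self.counts.values())

    def proportions(self) -> dict[str, float]:
        return to_proportions(self)

    def filter_rare(self, min_frac: float = RARE_FRACTION) -> "PollenPellet":
        return apply_rare_filter(self, min_frac)

    def pooled_to_family(self, taxonomy: "TaxonomyMap") -> "PollenPellet":
        return pool_to_family(self, taxonomy)

    def dominant_fraction(self) -> float:
        """Largest single-category share of the retained grains."""
        if self.total == 0:
            raise ValidationError(f"pellet {self.pellet_id}: zero retained grains")
        return max(self.counts.values()) / self.total


class TaxonomyMap:
    """Morphotype <-> plant family <-> member plant species.

    Every morphotype maps to exactly one family; every plant species
    belongs to exactly one morphotype.  Pollen-only morphotypes may have an
    empty member list.
    """

    UNKNOWN_FAMILY = "UNKNOWN"

    def __init__(self, mapping: Mapping[str, tuple[str, list[str]]]):
        self._family: dict[str, str] = {}
        self._members: dict[str, list[str]] = {}
        self._species_to_morphotype: dict[str, str] = {}
        for morphotype, (fam, members) in mapping.items():
            self.add(morphotype, fam, members)

    def add(self, morphotype: str, family_name: str, members: Iterable[str] = ()):
        if morphotype in self._family:
            raise TaxonomyError(f"duplicate morphotype {morphotype!r}")
        self._family[morphotype] = family_name
        self._members[morphotype] = []
        for sp in members:
            if sp in self._species_to_morphotype:
                raise TaxonomyError(
                    f"plant species {sp!r} already assigned to "
                    f"{self._species_to_morphotype[sp]!r}"
                )
            self._species_to_morphotype[sp] = morphotype
            self._members[morphotype].append(sp)

    def register_unknown(self, morphotype: str):
        """Auto-register a pellet-only morphotype under the UNKNOWN family."""
        self.add(morphotype, self.UNKNOWN_FAMILY, [])

    def __contains__(self, morphotype: str) -> bool:
        return morphotype in self._family

    def __len__(self) -> int:
        return len(self._family)

    @property
    def morphotypes(self) -> list[str]:
        return list(self._family)

    @property
    def families(self) -> list[str]:
        return sorted(set(self._family.values()))

    def family_of(self, morphotype: str) -> str:
        try:
            return self._family[morphotype]
        except KeyError:
            raise TaxonomyError(f"unresolvable morphotype {morphotype!r}") from None

    def members_of(self, morphotype: str) -> list[str]:
        try:
            return list(self._members[morphotype])
        except KeyError:
            raise TaxonomyError(f"unresolvable morphotype {morphotype!r}") from None

    def morphotype_of_species(self, species: str) -> str:
        try:
            return self._species_to_morphotype[species]
        except KeyError:
            raise TaxonomyError(f"plant species {species!r} not in taxonomy") from None

    def relabel(self, category: str, level: str) -> str:
        """Map a morphotype to its label at ``level`` ('morphotype'|'family')."""
        if level == "morphotype":
            return category
        if level == "family":
            return self.family_of(category)
        raise ValueError(f"unknown level {level!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "morphotype": list(self._family),
                "family": [self._family[m] for m in self._family],
                "member_species": [
                    ";".join(self._members[m]) for m in self._family
                ],
            }
        )


@dataclass(frozen=True)
class StudyDesign:
    """Period->survey alignment, sites and survey order.

    Pellets were collected over five periods (P1..P5) but floral resources
    surveyed monthly (June..September); both July periods map onto the July
    survey.
    """

    period_to_survey: Mapping[str, str]
    sites: list[str] = field(default_factory=list)
    surveys: list[str] = field(
        default_factory=lambda: ["June", "July", "August", "September"]
    )

    def __post_init__(self):
        missing = [p for p in VALID_PERIODS if p not in self.period_to_survey]
        if missing:
            raise ValidationError(f"period_to_survey not total: missing {missing}")
        bad = set(self.period_to_survey.values()) - set(self.surveys)
        if bad:
            raise ValidationError(f"period maps to unknown survey(s): {sorted(bad)}")

    def survey_of(self, period: str) -> str:
        try:
            return self.period_to_survey[period]
        except KeyError:
            raise ValidationError(f"unknown period {period!r}") from None


def default_design(sites: Iterable[str] = ()) -> StudyDesign:
    return StudyDesign(
        period_to_survey={
            "P1": "June",
            "P2": "July",
            "P3": "July",
            "P4": "August",
            "P5": "September",
        },
        sites=list(sites),
    )


@dataclass
class Dataset:
    """A pellet collection with its taxonomy and study design."""

    pellets: list[PollenPellet]
    taxonomy: TaxonomyMap
    design: StudyDesign

    def __len__(self) -> int:
        return len(self.pellets)

    def validate(self) -> list[str]:
        """Row-level diagnostics; empty when the dataset is consistent."""
        issues = []
        for p in self.pellets:
            if p.period not in self.design.period_to_survey:
                issues.append(f"pellet {p.pellet_id}: unknown period {p.period!r}")
            for m in p.counts:
                if m not in self.taxonomy:
                    issues.append(
                        f"pellet {p.pellet_id}: morphotype {m!r} not in taxonomy"
                    )
        return issues

    def filtered(self, min_frac: float = RARE_FRACTION) -> "Dataset":
        """Apply the per-pellet rare-morphotype filter to every pellet."""
        return Dataset(
            [apply_rare_filter(p, min_frac) for p in self.pellets],
            self.taxonomy,
            self.design,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def apply_rare_filter(
    pellet: PollenPellet, min_frac: float = RARE_FRACTION
) -> PollenPellet:
    """Drop morphotypes below the per-pellet abundance threshold.

    A morphotype whose share of the pellet's counted grains is below
    ``min_frac`` is excluded; a share of exactly ``min_frac`` is retained
    (the rule is "at least 3%").  Retained counts are unchanged, never
    renormalised.  The denominator is the pellet's current count sum, so
    the operation is idempotent (survivors' shares only grow when rare
    categories are removed).
    """
    total = pellet.total
    if total == 0:
        raise ValidationError(f"pellet {pellet.pellet_id}: no grains to filter")
    kept = {m: c for m, c in pellet.counts.items() if c / total >= min_frac}
    return replace(pellet, counts=kept)


def to_proportions(pellet: PollenPellet) -> dict[str, float]:
    """Per-morphotype share of the pellet's retained grains (sums to 1)."""
    total = pellet.total
    if total == 0:
        raise ValidationError(
            f"pellet {pellet.pellet_id}: proportions undefined for zero total"
        )
    return {m: c / total for m, c in pellet.counts.items()}


def pool_to_family(pellet: PollenPellet, taxonomy: TaxonomyMap) -> PollenPellet:
    """Sum the pellet's counts within plant families; grains are conserved."""
    pooled: dict[str, int] = {}
    for m, c in pellet.counts.items():
        fam = taxonomy.family_of(m)
        pooled[fam] = pooled.get(fam, 0) + c
    return replace(pellet, counts=pooled)


def pool_periods_to_surveys(dataset: Dataset) -> dict[str, list[PollenPellet]]:
    """Partition pellets by resource survey via the design's period map.

    Both July collection periods land under the July survey; the pellet
    multiset is conserved.
    """
    out: dict[str, list[PollenPellet]] = {s: [] for s in dataset.design.surveys}
    for p in dataset.pellets:
        out[dataset.design.survey_of(p.period)].append(p)
    return out


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def read_taxonomy_table(path) -> TaxonomyMap:
    """Read a taxonomy table (morphotype,family,member_species).

    ``member_species`` is a semicolon-separated species list (may be empty).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"morphotype", "family", "member_species"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"taxonomy table missing column(s): {sorted(missing)}")
    tax = TaxonomyMap({})
    for _, row in df.iterrows():
        members = [s for s in row["member_species"].split(";") if s]
        tax.add(row["morphotype"], row["family"], members)
    return tax


def read_pellet_table(
    path,
    taxonomy: TaxonomyMap,
    design: StudyDesign | None = None,
    *,
    strict: bool = False,
) -> Dataset:
    """Read a long-format pellet table into a :class:`Dataset`.

    One row per (pellet, morphotype); pellets are keyed by
    (bee_species, site, date, period, pellet_id).  Morphotypes absent from
    the taxonomy are auto-registered under the UNKNOWN family (pollen-only
    morphotypes are a real feature of pellet data) unless ``strict`` is
    set, in which case they raise :class:`TaxonomyError`.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(PELLET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"pellet table missing column(s): {sorted(missing)}")

    grains = pd.to_numeric(df["grains"], errors="coerce")
    bad = df.index[grains.isna() | (grains < 0) | (grains % 1 != 0)]
    if len(bad):
        # +2: header line plus 1-based numbering
        rows = ", ".join(str(i + 2) for i in bad[:10])
        raise ValidationError(f"invalid grain count at file line(s) {rows}")
    bad_period = df.index[~df["period"].isin(VALID_PERIODS)]
    if len(bad_period):
        rows = ", ".join(str(i + 2) for i in bad_period[:10])
        raise ValidationError(f"unknown period label at file line(s) {rows}")
    df = df.assign(grains=grains.astype(int))

    pellets: list[PollenPellet] = []
    keys = ["bee_species", "site", "date", "period", "pellet_id"]
    if len(df):
        for (bee, site, day, period, pid), grp in df.groupby(keys, sort=True):
            counts: dict[str, int] = {}
            for m, g in zip(grp["morphotype"], grp["grains"]):
                counts[m] = counts.get(m, 0) + g
                if m not in taxonomy:
                    if strict:
                        raise TaxonomyError(
                            f"pellet {pid}: morphotype {m!r} not in taxonomy"
                        )
                    taxonomy.register_unknown(m)
            pellets.append(
                PollenPellet(
                    bee_species=bee,
                    site=site,
                    day=day,
                    period=period,
                    pellet_id=pid,
                    counts=counts,
                    grains_total=int(grp["grains"].sum()),
                )
            )
    if design is None:
        design = default_design(sorted({p.site for p in pellets}))
    ds = Dataset(pellets, taxonomy, design)
    unknown = [m for m in taxonomy.morphotypes
               if taxonomy.family_of(m) == TaxonomyMap.UNKNOWN_FAMILY]
    if unknown:
        warnings.warn(
            f"{len(unknown)} morphotype(s) auto-registered as UNKNOWN family: "
            f"{unknown[:5]}",
            stacklevel=2,
        )
    return ds


def write_pellet_table(dataset: Dataset, path) -> None:
    """Write a Dataset back to the long-format pellet table (round-trips)."""
    rows = []
    for p in dataset.pellets:
        for m in sorted(p.counts):
            rows.append(
                (p.bee_species, p.site, p.day, p.period, p.pellet_id, m, p.counts[m])
            )
    pd.DataFrame(rows, columns=PELLET_COLUMNS).to_csv(path, index=False)
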