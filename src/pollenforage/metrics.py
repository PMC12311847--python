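"""Foraging metrics: flower constancy, pollen richness and Simpson diversity.

All three statistics are computed per colony-day (one bee species at one
site on one sampling day) at either the morphotype or the plant-family
level.  A foraging trip is flower constant when at least 97% of the
pellet's retained grains come from a single category; the daily constancy
statistic is the share of sampled foragers whose trip was constant.
Richness S is the number of distinct categories over the day's pellets, and
diversity is the Simpson index SDI = 1 - sum(p_i^2) on the day-pooled grain
counts (0 for a single category, approaching 1 for many even categories).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    Dataset,
    PollenPellet,
    TaxonomyMap,
    ValidationError,
    RARE_FRACTION,
    pool_to_family,
)

__all__ = [
    "ColonyDaySummary",
    "CONSTANCY_THRESHOLD",
    "is_constant",
    "daily_constancy",
    "pollen_richness",
    "simpson_diversity",
    "simpson_index",
    "summarize_dataset",
]

#: A pellet is flower constant when >= 97% of its grains are one category.
CONSTANCY_THRESHOLD = 0.97

LEVELS = ("morphotype", "family")


@dataclass(frozen=True)
class ColonyDaySummary:
    """Constancy, richness and diversity for one colony-day at one level."""

    bee_species: str
    site: str
    day: str
    period: str
    level: str
    constancy: float
    richness_S: int
    diversity_SDI: float
    n_pellets: int


def _at_level(
    pellets: Iterable[PollenPellet], level: str, taxonomy: TaxonomyMap | None
) -> list[PollenPellet]:
    if level == "morphotype":
        return list(pellets)
    if level == "family":
        if taxonomy is None:
            raise ValueError("family-level metrics require a taxonomy")
        return [pool_to_family(p, taxonomy) for p in pellets]
    raise ValueError(f"unknown level {level!r}")


def is_constant(
    pellet: PollenPellet, threshold: float = CONSTANCY_THRESHOLD
) -> bool:
    """Whether a single category makes up at least ``threshold`` of the pellet."""
    return pellet.dominant_fraction() >= threshold


def daily_constancy(
    pellets: Sequence[PollenPellet],
    level: str = "morphotype",
    taxonomy: TaxonomyMap | None = None,
    threshold: float = CONSTANCY_THRESHOLD,
) -> float:
    """Share of the day's sampled foragers whose trip was flower constant."""
    pellets = _at_level(pellets, level, taxonomy)
    if not pellets:
        raise ValidationError("daily constancy undefined for an empty colony-day")
    return sum(is_constant(p, threshold) for p in pellets) / len(pellets)


def pollen_richness(
    pellets: Sequence[PollenPellet],
    level: str = "morphotype",
    taxonomy: TaxonomyMap | None = None,
) -> int:
    """Number of distinct categories over the day's pellets (union)."""
    pellets = _at_level(pellets, level, taxonomy)
    cats: set[str] = set()
    for p in pellets:
        cats.update(m for m, c in p.counts.items() if c > 0)
    return len(cats)


def simpson_index(abundances: Sequence[float]) -> float:
    """SDI = 1 - sum(p_i^2) for an abundance vector (any positive scale)."""
    a = np.asarray(abundances, dtype=float)
    a = a[a > 0]
    total = a.sum()
    if total <= 0:
        raise ValidationError("Simpson diversity undefined for zero total abundance")
    p = a / total
    return float(1.0 - np.sum(p * p))


def simpson_diversity(
    pellets: Sequence[PollenPellet],
    level: str = "morphotype",
    taxonomy: TaxonomyMap | None = None,
) -> float:
    """Simpson diversity of the colony-day's pooled grain counts.

    Grains are pooled over all of the day's pellets before computing
    1 - sum(p^2); with k categories the value is bounded by 1 - 1/k,
    attained at the uniform composition.
    """
    pellets = _at_level(pellets, level, taxonomy)
    pooled: dict[str, int] = {}
    for p in pellets:
        for m, c in p.counts.items():
            pooled[m] = pooled.get(m, 0) + c
    return simpson_index(list(pooled.values()))


def summarize_dataset(
    dataset: Dataset,
    *,
    min_frac: float | None = RARE_FRACTION,
    threshold: float = CONSTANCY_THRESHOLD,
    levels: Sequence[str] = LEVELS,
) -> pd.DataFrame:
    """Tidy per-colony-day summary table at each requested level.

    The per-pellet rare-morphotype filter is applied first (pass
    ``min_frac=None`` to skip it); constancy is then evaluated on the
    retained counts.  Returns one row per (bee_species, site, day, level),
    deterministically ordered, with the columns of
    :class:`ColonyDaySummary`.
    """
    ds = dataset if min_frac is None else dataset.filtered(min_frac)
    groups: dict[tuple, list[PollenPellet]] = {}
    for p in ds.pellets:
        groups.setdefault((p.bee_species, p.site, p.day, p.period), []).append(p)

    rows = []
    for key in sorted(groups):
        bee, site, day, period = key
        pellets = groups[key]
        for level in levels:
            rows.append(
                ColonyDaySummary(
                    bee_species=bee,
                    site=site,
                    day=day,
                    period=period,
                    level=level,
                    constancy=daily_constancy(pellets, level, ds.taxonomy, threshold),
                    richness_S=pollen_richness(pellets, level, ds.taxonomy),
                    diversity_SDI=simpson_diversity(pellets, level, ds.taxonomy),
                    n_pellets=len(pellets),
                )
            )
    return pd.DataFrame([asdict(r) for r in rows])
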