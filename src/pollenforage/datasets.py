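"""Packaged constants from a season-long two-bee-species foraging study.

A published field study in a 339-hectare north-temperate agricultural
landscape (three apiary sites, June–September) sampled corbicular pollen
loads from returning honeybee (*Apis mellifera*) and common eastern bumble
bee (*Bombus impatiens*) foragers over five collection periods, and surveyed
floral resources (three focal crops plus wildflower transects) over four
monthly surveys.  This module carries the study's printed design constants
and its season-pooled morphotype inventory so that the overlap
classification and study-scale fixtures can be reproduced without field
data.

Morphotype families follow the study's family-level pooling (Hemerocallis
is filed under Liliaceae in the traditional circumscription, giving the
study's 16 pollen-side plant families).  Member-species lists for the
multi-species morphotypes are published only for Fabaceae_Tricolporate
(alfalfa, soybean, crown vetch, white clover); the remaining multi-species
memberships here are synthetic, representative upper-midwest taxa used by
the fixture generator, not a published list.
"""

from __future__ import annotations

from .data_model import StudyDesign, TaxonomyMap

#: Total resource-availability area (hectares): all habitat within the
#: 500 m radii around the three sites plus the research-station crop fields.
TOTAL_AREA_HA = 339.0

#: Pollen collection periods -> resource survey months.  Pellets were
#: collected over five periods but resources surveyed four times, so the
#: two July periods are pooled onto the July survey.
PERIOD_TO_SURVEY = {
    "P1": "June",
    "P2": "July",
    "P3": "July",
    "P4": "August",
    "P5": "September",
}

SURVEYS = ("June", "July", "August", "September")
SITES = ("site1", "site2", "site3")
BEE_SPECIES = ("honeybee", "bumblebee")

#: Per-colony-day pellet targets (honeybee colonies are much larger, so the
#: study doubled their sample).
PELLETS_PER_DAY = {"honeybee": 40, "bumblebee": 20}

GRAINS_PER_PELLET = 500

#: Wildflower survey layout: 5 transects per site x 3 sites, 10 quadrats
#: of 1 m^2 per transect => 150 quadrats per survey.
N_TRANSECTS_PER_SITE = 5
N_QUADRATS_PER_TRANSECT = 10
N_SURVEY_QUADRATS = 150

# ---------------------------------------------------------------------------
# Season-pooled morphotype inventory.
# class: "both" = identified in bee-collected pollen and in resources,
# "pollen_only" / "resource_only" accordingly.  members = plant species
# grouped into the morphotype (synthetic-representative where unpublished).
# ---------------------------------------------------------------------------

MORPHOTYPE_INVENTORY: dict[str, dict] = {
    # -- identified in both pollen and resources ---------------------------
    "Apiaceae": {
        "family": "Apiaceae",
        "class": "both",
        "members": ["Daucus_carota"],
    },
    "Asteraceae_Lophate": {
        "family": "Asteraceae",
        "class": "both",
        # three lophate (Cichorieae-type) species; synthetic-representative
        "members": ["Cichorium_intybus", "Taraxacum_officinale", "Lactuca_serriola"],
    },
    "Asteraceae_Spines": {
        "family": "Asteraceae",
        "class": "both",
        # six echinate species; synthetic-representative
        "members": [
            "Cirsium_arvense",
            "Cirsium_vulgare",
            "Erigeron_annuus",
            "Symphyotrichum_ericoides",
            "Solidago_canadensis",
            "Helianthus_annuus",
        ],
    },
    "Caryophyllaceae": {
        "family": "Caryophyllaceae",
        "class": "both",
        "members": ["Silene_latifolia"],
    },
    "Fabaceae_Tricolporate": {
        "family": "Fabaceae",
        "class": "both",
        # published membership: alfalfa, soybean, crown vetch, white clover
        "members": [
            "Medicago_sativa",
            "Glycine_max",
            "Securigera_varia",
            "Trifolium_repens",
        ],
    },
    "Lotus_corniculatus": {
        "family": "Fabaceae",
        "class": "both",
        "members": ["Lotus_corniculatus"],
    },
    "Monarda_fistulosa": {
        "family": "Lamiaceae",
        "class": "both",
        "members": ["Monarda_fistulosa"],
    },
    "Poaceae": {
        "family": "Poaceae",
        "class": "both",
        "members": ["Zea_mays", "Setaria_viridis"],
    },
    "Rosaceae": {
        "family": "Rosaceae",
        "class": "both",
        "members": ["Potentilla_recta"],
    },
    "Trifolium_pratense": {
        "family": "Fabaceae",
        "class": "both",
        "members": ["Trifolium_pratense"],
    },
    # -- pollen only (collected by bees, never seen in resource surveys) ---
    "Brassicaceae": {"family": "Brassicaceae", "class": "pollen_only", "members": []},
    "Commelinaceae": {"family": "Commelinaceae", "class": "pollen_only", "members": []},
    "Fagaceae": {"family": "Fagaceae", "class": "pollen_only", "members": []},
    "Geraniaceae": {"family": "Geraniaceae", "class": "pollen_only", "members": []},
    "Hemerocallis_spp": {"family": "Liliaceae", "class": "pollen_only", "members": []},
    "Iridaceae": {"family": "Iridaceae", "class": "pollen_only", "members": []},
    "Liliaceae": {"family": "Liliaceae", "class": "pollen_only", "members": []},
    "Onagraceae": {"family": "Onagraceae", "class": "pollen_only", "members": []},
    "Scrophulariaceae": {
        "family": "Scrophulariaceae",
        "class": "pollen_only",
        "members": [],
    },
    "Tilia_americana": {"family": "Malvaceae", "class": "pollen_only", "members": []},
    # -- resource only (surveyed, never found in pellets) ------------------
    "Asteraceae_Unknown": {
        "family": "Asteraceae",
        "class": "resource_only",
        "members": ["Asteraceae_unidentified"],
    },
    "Fabaceae_Unknown": {
        "family": "Fabaceae",
        "class": "resource_only",
        "members": ["Fabaceae_unidentified"],
    },
    "Glechoma_hederacea": {
        "family": "Lamiaceae",
        "class": "resource_only",
        "members": ["Glechoma_hederacea"],
    },
    "Leles_spp": {
        "family": "Liliaceae",
        "class": "resource_only",
        "members": ["Leles_sp"],
    },
    "Linaria_vulgaris": {
        "family": "Scrophulariaceae",
        "class": "resource_only",
        "members": ["Linaria_vulgaris"],
    },
    "Oxalis_spp": {
        "family": "Oxalidaceae",
        "class": "resource_only",
        "members": ["Oxalis_stricta"],
    },
    "Phlox_spp": {
        "family": "Polemoniaceae",
        "class": "resource_only",
        "members": ["Phlox_divaricata"],
    },
    "Solanum_nigrum": {
        "family": "Solanaceae",
        "class": "resource_only",
        "members": ["Solanum_nigrum"],
    },
}


def morphotypes(overlap_class: str | None = None) -> list[str]:
    """Morphotype names, optionally restricted to one overlap class."""
    if overlap_class is None:
        return list(MORPHOTYPE_INVENTORY)
    return [
        m for m, d in MORPHOTYPE_INVENTORY.items() if d["class"] == overlap_class
    ]


def pollen_morphotypes() -> list[str]:
    """Season-pooled morphotype list seen in bee-collected pollen."""
    return morphotypes("both") + morphotypes("pollen_only")


def resource_morphotypes() -> list[str]:
    """Season-pooled morphotype list seen in floral resources."""
    return morphotypes("both") + morphotypes("resource_only")


def study_taxonomy() -> TaxonomyMap:
    """The study inventory as a :class:`TaxonomyMap`."""
    return TaxonomyMap(
        {
            m: (d["family"], list(d["members"]))
            for m, d in MORPHOTYPE_INVENTORY.items()
        }
    )


def study_design(sites=SITES) -> StudyDesign:
    """The study's period->survey alignment and site list."""
    return StudyDesign(
        period_to_survey=dict(PERIOD_TO_SURVEY),
        sites=list(sites),
        surveys=list(SURVEYS),
    )
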