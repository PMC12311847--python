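"""Crop floral densities, efc area weighting and availability proportions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollenforage.availability import (
    AvailabilityProfile,
    CropQuadrat,
    CropSpec,
    LandscapeAreas,
    crop_floral_density,
    estimated_floral_counts,
    morphotype_availability,
    wildflower_richness_diversity,
    wildflower_survey_counts,
)
from pollenforage.data_model import TaxonomyError, TaxonomyMap, ValidationError
from pollenforage.datasets import study_taxonomy


class TestCropDensity:
    def test_corn_stalks_halved_to_one_square_metre(self):
        spec = CropSpec("corn", 10, [CropQuadrat(stalks=30)])
        assert crop_floral_density(spec) == 15.0

    def test_soybean_racemes_extrapolated_from_stem_subsample(self):
        spec = CropSpec("soybean", 10, [CropQuadrat(stems=100, racemes_per_stem=(4.0,))])
        assert crop_floral_density(spec) == 400.0

    def test_alfalfa_mean_racemes(self):
        spec = CropSpec("alfalfa", 10, [CropQuadrat(racemes=18), CropQuadrat(racemes=22)])
        assert crop_floral_density(spec) == 20.0

    def test_soybean_empty_subsample_is_estimation_error(self):
        spec = CropSpec("soybean", 10, [CropQuadrat(stems=100, racemes_per_stem=())])
        with pytest.raises(ValidationError):
            crop_floral_density(spec)


class TestWildflowerCounts:
    def test_sums_within_survey_and_order_invariance(self):
        rows = [
            ("site1", "June", "T1", "Q1", "X", 10),
            ("site1", "June", "T1", "Q2", "X", 5),
            ("site2", "June", "T2", "Q1", "X", 5),
            ("site1", "July", "T1", "Q1", "X", 99),
            ("site1", "June", "T1", "Q3", "Y", 7),
        ]
        df = pd.DataFrame(
            rows, columns=["site", "survey", "transect", "quadrat", "species", "floral_units"]
        )
        assert wildflower_survey_counts(df, "June") == {"X": 20, "Y": 7}
        shuffled = df.sample(frac=1, random_state=1)
        assert wildflower_survey_counts(shuffled, "June") == {"X": 20, "Y": 7}
        assert wildflower_survey_counts(df, "September") == {}


AREAS = LandscapeAreas(
    total_area_ha=100.0, crop_areas={"alfalfa": 30.0}, minor_crop_area_ha=30.0
)  # wildflower proportion 0.4, alfalfa proportion 0.3


class TestEfc:
    def test_wild_species_weighted_by_wildflower_area(self):
        efc = estimated_floral_counts({"X": 300.0}, [], AREAS, "June")
        assert efc == {"X": pytest.approx(120.0)}

    def test_crop_scaled_to_survey_quadrats_and_area(self):
        alfalfa = CropSpec("alfalfa", 30.0, [CropQuadrat(racemes=20)])
        efc = estimated_floral_counts({}, [alfalfa], AREAS, "June")
        # 20 per m2 x 150 quadrats x 0.3 = 900
        assert efc == {"Medicago_sativa": pytest.approx(900.0)}

    def test_crop_outside_bloom_window_contributes_nothing(self):
        corn = CropSpec("corn", 30.0, [CropQuadrat(stalks=30)],
                        flowering_surveys={"July", "August"})
        assert estimated_floral_counts({}, [corn], AREAS, "June") == {}
        assert "Zea_mays" in estimated_floral_counts({}, [corn], AREAS, "July")

    def test_zero_iff_no_counts_or_no_area(self):
        no_area = LandscapeAreas(100.0, crop_areas={"corn": 0.0})
        corn = CropSpec("corn", 0.0, [CropQuadrat(stalks=30)])
        efc = estimated_floral_counts({"X": 0.0}, [corn], no_area, "July")
        assert efc.get("Zea_mays", 0.0) == 0.0
        assert efc["X"] == 0.0


class TestMorphotypeAvailability:
    def test_hand_arithmetic(self):
        tax = TaxonomyMap({"M1": ("F1", ["X", "Y"]), "M2": ("F2", ["Z"])})
        prof = morphotype_availability({"X": 120.0, "Y": 900.0, "Z": 180.0}, tax, "June")
        assert prof.proportions == {
            "M1": pytest.approx(0.85),
            "M2": pytest.approx(0.15),
        }

    def test_single_species_identity(self):
        tax = TaxonomyMap({"M1": ("F1", ["X"])})
        prof = morphotype_availability({"X": 5.0}, tax, "June")
        assert prof.proportions == {"M1": 1.0}

    def test_crop_species_fold_into_fabaceae_tricolporate(self):
        tax = study_taxonomy()
        efc = {
            "Medicago_sativa": 100.0,
            "Glycine_max": 50.0,
            "Securigera_varia": 25.0,
            "Trifolium_repens": 25.0,
            "Lotus_corniculatus": 100.0,
        }
        prof = morphotype_availability(efc, tax, "July")
        assert prof.proportions["Fabaceae_Tricolporate"] == pytest.approx(200 / 300)
        assert prof.proportions["Lotus_corniculatus"] == pytest.approx(100 / 300)

    def test_unresolvable_species_is_taxonomy_error(self):
        tax = TaxonomyMap({"M1": ("F1", ["X"])})
        with pytest.raises(TaxonomyError, match="Nessie"):
            morphotype_availability({"Nessie": 1.0}, tax, "June")

    @given(
        efcs=st.dictionaries(
            st.sampled_from(["X", "Y", "Z"]),
            st.floats(0.01, 1e6),
            min_size=1,
        ),
        factor=st.floats(0.01, 1e3),
    )
    @settings(derandomize=True, max_examples=100)
    def test_sum_to_one_and_scale_invariance(self, efcs, factor):
        tax = TaxonomyMap({"M1": ("F1", ["X", "Y"]), "M2": ("F2", ["Z"])})
        p1 = morphotype_availability(efcs, tax, "June").proportions
        p2 = morphotype_availability(
            {k: v * factor for k, v in efcs.items()}, tax, "June"
        ).proportions
        assert sum(p1.values()) == pytest.approx(1.0, abs=1e-9)
        for m in p1:
            assert p1[m] == pytest.approx(p2[m], rel=1e-9)

    def test_removing_a_crop_reweights_remaining_upward(self):
        tax = study_taxonomy()
        areas = LandscapeAreas(100.0, crop_areas={"corn": 30.0})
        wild = {"Daucus_carota": 200.0, "Cirsium_arvense": 100.0}
        corn = CropSpec("corn", 30.0, [CropQuadrat(stalks=30)])
        with_corn = morphotype_availability(
            estimated_floral_counts(wild, [corn], areas, "July"), tax, "July"
        ).proportions
        corn_off = CropSpec("corn", 30.0, [CropQuadrat(stalks=30)],
                            flowering_surveys={"August"})
        without = morphotype_availability(
            estimated_floral_counts(wild, [corn_off], areas, "July"), tax, "July"
        ).proportions
        for m in ("Apiaceae", "Asteraceae_Spines"):
            assert without[m] > with_corn[m]


class TestLandscapeAreas:
    def test_wildflower_area_is_the_remainder(self):
        assert AREAS.wildflower_area_ha == pytest.approx(40.0)
        assert AREAS.wildflower_proportion + AREAS.proportion("alfalfa") + 0.3 == (
            pytest.approx(1.0)
        )

    def test_overcommitted_area_rejected(self):
        with pytest.raises(ValidationError):
            LandscapeAreas(100.0, crop_areas={"corn": 80.0, "soybean": 30.0})


class TestAvailabilityProfile:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            AvailabilityProfile("June", {"M1": 0.6, "M2": 0.6})


class TestWildflowerRichnessDiversity:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["site", "survey", "transect", "quadrat", "species", "floral_units"]
        )

    def test_single_species_and_even_pair(self):
        df = self._records(
            [
                ("site1", "June", "T1", "Q1", "X", 10),
                ("site1", "July", "T1", "Q1", "X", 5),
                ("site1", "July", "T2", "Q1", "Y", 5),
            ]
        )
        out = wildflower_richness_diversity(df, "species")
        june = out[out["survey"] == "June"].iloc[0]
        assert june["richness_S"] == 1 and june["diversity_SDI"] == 0.0
        july = out[out["survey"] == "July"].iloc[0]
        assert july["richness_S"] == 2 and july["diversity_SDI"] == pytest.approx(0.5)

    def test_family_richness_never_exceeds_species_richness(self):
        tax = study_taxonomy()
        species = [sp for m in tax.morphotypes for sp in tax.members_of(m)]
        rng = np.random.default_rng(9)
        for _ in range(20):
            rows = [
                ("site1", "June", "T1", f"Q{i}",
                 species[rng.integers(len(species))], int(rng.integers(1, 50)))
                for i in range(int(rng.integers(1, 15)))
            ]
            df = self._records(rows)
            s_sp = wildflower_richness_diversity(df, "species").iloc[0]["richness_S"]
            s_fam = wildflower_richness_diversity(df, "family", tax).iloc[0]["richness_S"]
            assert s_fam <= s_sp
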