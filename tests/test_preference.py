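"""Proportion-preserving chi-square tables and the resampling null model."""

import numpy as np
import pytest
from scipy import stats

import matplotlib

matplotlib.use("Agg")

from pollenforage.availability import AvailabilityProfile
from pollenforage.data_model import ValidationError
from pollenforage.preference import (
    PreferenceModel,
    build_test_table,
    classify_overlap,
    contingency_chisq,
    gof_chisq,
    null_model_preferences,
    pooled_proportions,
    scale_to_counts,
)
from pollenforage.simulate import SpeciesParams, simulate_pellets

from conftest import make_pellet


def brute_force_gof(obs, exp):
    """Independent oracle: literal sum of (O-E)^2/E."""
    return sum((o - e) ** 2 / e for o, e in zip(obs, exp))


def brute_force_contingency(table):
    """Independent oracle: margin-based expectations, then sum of (O-E)^2/E."""
    table = np.asarray(table, dtype=float)
    grand = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / grand
            stat += (table[i, j] - e) ** 2 / e
    return stat


class TestScaleToCounts:
    def test_exact_when_divisible(self):
        assert scale_to_counts({"A": 0.6, "B": 0.4}) == {"A": 300, "B": 200}

    def test_largest_remainder_totals(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            k = int(rng.integers(2, 10))
            p = rng.dirichlet(np.ones(k))
            props = {f"c{i}": float(v) for i, v in enumerate(p)}
            counts = scale_to_counts(props)
            assert sum(counts.values()) == 500
            for c, v in counts.items():
                assert abs(v - props[c] * 500) < 1.0


class TestBuildTestTable:
    def test_shared_categories_scale_to_500(self):
        t = build_test_table({"A": 0.6, "B": 0.4}, {"A": 0.5, "B": 0.5})
        assert t.observed == {"A": 300, "B": 200}
        assert t.expected == {"A": 250, "B": 250}
        assert t.df == 1

    def test_one_sided_categories_pool_into_other(self):
        t = build_test_table({"A": 0.6, "C": 0.4}, {"A": 0.5, "D": 0.5})
        assert t.categories == ["A", "other"]
        assert t.observed == {"A": 300, "other": 200}
        assert t.expected == {"A": 250, "other": 250}
        assert sum(t.observed.values()) == sum(t.expected.values()) == 500

    def test_small_shared_count_folds_into_other(self):
        t = build_test_table({"A": 0.99, "B": 0.01}, {"A": 0.99, "B": 0.01})
        # B scales to 5, not > 5, so it is pooled on both sides
        assert t.categories == ["A", "other"]
        assert t.observed["other"] == 5 and t.expected["other"] == 5

    def test_retained_proportions_preserved_exactly(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            k = int(rng.integers(3, 8))
            obs = {f"m{i}": float(v) for i, v in enumerate(rng.dirichlet(np.ones(k)))}
            exp = {f"m{i}": float(v) for i, v in enumerate(rng.dirichlet(np.ones(k)))}
            t = build_test_table(obs, exp)
            for c in t.observed_props:
                assert t.observed_props[c] == obs[c]  # bit-exact
                assert t.expected_props[c] == exp[c]
            assert sum(t.observed.values()) == 500
            assert sum(t.expected.values()) == 500

    def test_insufficient_categories_error(self):
        with pytest.raises(ValidationError):
            build_test_table({"A": 1.0}, {"A": 1.0})


class TestGofChisq:
    def test_hand_evaluation(self):
        t = build_test_table({"A": 0.6, "B": 0.4}, {"A": 0.5, "B": 0.5})
        r = gof_chisq(t)
        # 50^2/250 + 50^2/250 = 20
        assert r.statistic == pytest.approx(20.0)
        assert r.df == 1
        assert r.pvalue == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_identity_when_observed_equals_expected(self):
        t = build_test_table({"A": 0.6, "B": 0.4}, {"A": 0.6, "B": 0.4})
        assert gof_chisq(t).statistic == 0.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            k = int(rng.integers(2, 9))
            obs = {f"m{i}": float(v) for i, v in enumerate(rng.dirichlet(np.ones(k)))}
            exp = {f"m{i}": float(v) for i, v in enumerate(rng.dirichlet(np.ones(k)))}
            try:
                t = build_test_table(obs, exp)
                r = gof_chisq(t)  # zero-expectation draws are degenerate
            except ValidationError:
                continue
            oracle = brute_force_gof(
                [t.observed[c] for c in t.categories],
                [t.expected[c] for c in t.categories],
            )
            assert r.statistic == pytest.approx(oracle, abs=1e-9)

    def test_zero_expected_is_degenerate(self):
        t = build_test_table({"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5})
        t.expected["B"] = 0
        with pytest.raises(ValidationError):
            gof_chisq(t)


class TestContingencyChisq:
    def test_hand_evaluation_from_margins(self):
        r, table = contingency_chisq({"A": 100, "B": 400}, {"A": 400, "B": 100})
        assert r.statistic == pytest.approx(360.0)
        assert r.df == 1

    def test_identical_rows_and_row_symmetry(self):
        a = {"A": 200, "B": 300}
        r, _ = contingency_chisq(a, dict(a))
        assert r.statistic == pytest.approx(0.0)
        r1, _ = contingency_chisq({"A": 100, "B": 400}, {"A": 350, "B": 150})
        r2, _ = contingency_chisq({"A": 350, "B": 150}, {"A": 100, "B": 400})
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            a = {f"m{i}": int(v) for i, v in enumerate(rng.integers(6, 300, size=k))}
            b = {f"m{i}": int(v) for i, v in enumerate(rng.integers(6, 300, size=k))}
            r, table = contingency_chisq(a, b)
            assert r.statistic == pytest.approx(
                brute_force_contingency(table.to_numpy()), abs=1e-9
            )
            assert r.df == table.shape[1] - 1


class TestNullModel:
    def _profile(self, props, survey="June"):
        return AvailabilityProfile(survey, props)

    def test_degenerate_availability_is_proportional(self):
        prof = self._profile({"M": 1.0})
        pellets = [make_pellet({"M": 500}, pid=str(i)) for i in range(5)]
        res = null_model_preferences(pellets, prof, seed=0)
        assert res.classifications() == {"M": "proportional"}

    def test_zero_availability_morphotype_unassessable(self):
        prof = self._profile({"M": 0.7, "N": 0.3})
        pellets = [make_pellet({"M": 400, "Ghost": 100}, pid="1")]
        res = null_model_preferences(pellets, prof, seed=0)
        assert res.classifications()["Ghost"] == "unassessable"
        row = [r for r in res if r.morphotype == "Ghost"][0]
        assert np.isnan(row.ci_low)

    def test_blatant_preference_detected(self):
        prof = self._profile({"M": 0.5, "N": 0.5})
        pellets = [make_pellet({"M": 500}, pid=str(i)) for i in range(40)]
        res = null_model_preferences(pellets, prof, seed=1)
        assert res.classifications() == {"M": "preference", "N": "avoidance"}

    def test_seed_reproducibility_and_order_invariance(self):
        rng = np.random.default_rng(10)
        prof = self._profile({"M": 0.5, "N": 0.3, "O": 0.2})
        pellets, _ = simulate_pellets(
            prof.proportions, SpeciesParams(constancy_prob=0.3), 30, rng
        )
        a = null_model_preferences(pellets, prof, seed=99).to_frame()
        b = null_model_preferences(pellets, prof, seed=99).to_frame()
        assert a.equals(b)
        c = null_model_preferences(pellets[::-1], prof, seed=99).to_frame()
        assert a["classification"].tolist() == c["classification"].tolist()

    def test_pooled_and_per_pellet_nulls_agree_in_distribution(self):
        prof = self._profile({"M": 0.6, "N": 0.4})
        pellets = [make_pellet({"M": 300, "N": 200}, pid=str(i)) for i in range(20)]
        model = PreferenceModel(pellets, prof)
        rng = np.random.default_rng(0)
        pooled = model._null_draws(4000, rng, "pooled")
        per_pellet = model._null_draws(4000, rng, "per_pellet")
        # same exact distribution: means and spreads agree to MC error
        assert pooled.mean(axis=0) == pytest.approx(per_pellet.mean(axis=0), abs=3e-4)
        assert pooled.std(axis=0) == pytest.approx(per_pellet.std(axis=0), rel=0.15)

    def test_small_iteration_count_warns(self):
        prof = self._profile({"M": 1.0})
        pellets = [make_pellet({"M": 500})]
        with pytest.warns(UserWarning, match="unstable"):
            null_model_preferences(pellets, prof, n_iter=50, seed=0)

    def test_summary_and_plot(self):
        prof = self._profile({"M": 0.5, "N": 0.5})
        pellets = [make_pellet({"M": 400, "N": 100}, pid=str(i)) for i in range(10)]
        res = null_model_preferences(pellets, prof, seed=2)
        text = res.summary()
        assert "Availability-proportional null model" in text
        assert "M" in text and "classification" in text
        ax = res.plot()
        assert ax.get_ylabel() == ""
        assert len(ax.get_yticklabels()) == 2


class TestPooledProportions:
    def test_pools_across_pellets(self):
        pellets = [
            make_pellet({"A": 300, "B": 200}, pid="1"),
            make_pellet({"A": 100, "C": 400}, pid="2"),
        ]
        props = pooled_proportions(pellets)
        assert props == {"A": 0.4, "B": 0.2, "C": 0.4}

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            pooled_proportions([])


class TestClassifyOverlap:
    def test_set_partition(self):
        out = classify_overlap({"A", "B", "C"}, {"B", "C", "D"})
        assert out == {
            "A": "pollen_only",
            "B": "both",
            "C": "both",
            "D": "resource_only",
        }

    def test_equal_sets_all_both(self):
        out = classify_overlap({"A", "B"}, {"A", "B"})
        assert set(out.values()) == {"both"}
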