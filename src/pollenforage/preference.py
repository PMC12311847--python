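"""Preference and avoidance inference for bee-collected pollen.

Two complementary routes compare what bees collected with what the
landscape offered:

* **Proportion-preserving chi-square tables.**  Observed and expected
  proportion vectors are scaled to counts out of 500.  Categories present
  on both sides with scaled counts greater than 5 keep their own row at
  their *original* proportion; everything else — shared-but-small
  categories and categories present on one side only — is pooled into a
  terminal "other" row on each side.  Unlike the common practice of
  dropping unshared categories (which renormalises and distorts the
  remaining proportions), this keeps both columns summing to 500 while the
  retained rows reflect exactly the observed shares.  The same table
  construction backs both the goodness-of-fit test (collected vs resource
  availability) and the 2xk contingency test (honeybee vs bumble bee).

* **Availability-proportional null model.**  Treating each pellet
  (individual bee) as a replicate, each pellet's retained grain total is
  redrawn from a multinomial over the availability proportions; the
  species-level pooled proportion of each morphotype is compared with the
  95% percentile interval of that summary under the null.  Above the
  interval = preference, below = avoidance, inside = proportional;
  morphotypes collected but absent from the resource surveys cannot be
  assessed.

The null model follows the statsmodels idiom: build a
:class:`PreferenceModel` from pellets and an availability profile, call
``fit()``, and read estimates/intervals/classifications off the returned
:class:`PreferenceResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .availability import AvailabilityProfile
from .data_model import PollenPellet, ValidationError

__all__ = [
    "TestTable",
    "ChisqResult",
    "build_test_table",
    "gof_chisq",
    "contingency_chisq",
    "scale_to_counts",
    "PreferenceModel",
    "PreferenceResults",
    "PreferenceResult",
    "null_model_preferences",
    "classify_overlap",
    "pooled_proportions",
]

OTHER = "other"

#: Counts-out-of-500 scaling used for all chi-square tables.
DEFAULT_SCALE = 500

#: Chi-square cell requirement: retained categories need scaled counts
#: strictly greater than this on both sides.
MIN_COUNT = 5


# ---------------------------------------------------------------------------
# Proportion -> integer counts (largest-remainder rounding)
# ---------------------------------------------------------------------------


def scale_to_counts(props: Mapping[str, float], scale: int = DEFAULT_SCALE) -> dict[str, int]:
    """Round ``proportion x scale`` to integers summing exactly to ``scale``.

    Largest-remainder (Hamilton) rounding; ties broken by category name for
    determinism.
    """
    cats = sorted(props)
    raw = np.array([props[c] * scale for c in cats], dtype=float)
    base = np.floor(raw).astype(int)
    short = int(round(scale - base.sum()))
    remainders = raw - np.floor(raw)
    order = sorted(range(len(cats)), key=lambda i: (-remainders[i], cats[i]))
    counts = dict(zip(cats, base))
    for i in order[:short]:
        counts[cats[i]] += 1
    return counts


@dataclass
class TestTable:
    """An observed/expected count table scaled to a common total.

    ``categories`` lists the retained morphotypes in descending observed
    count (terminal ``"other"`` row last when present).  ``observed_props``
    and ``expected_props`` carry the *original* input proportions of the
    retained categories, untouched by the pooling.
    """

    categories: list[str]
    observed: dict[str, int]
    expected: dict[str, int]
    observed_props: dict[str, float] = field(default_factory=dict)
    expected_props: dict[str, float] = field(default_factory=dict)
    scale: int = DEFAULT_SCALE

    @property
    def df(self) -> int:
        return len(self.categories) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": self.categories,
                "observed": [self.observed[c] for c in self.categories],
                "expected": [self.expected[c] for c in self.categories],
            }
        )


def _check_props(name: str, props: Mapping[str, float]):
    s = sum(props.values())
    if abs(s - 1.0) > 1e-6:
        raise ValidationError(f"{name} proportions sum to {s}, not 1")
    if any(v < 0 for v in props.values()):
        raise ValidationError(f"{name} proportions must be non-negative")


def build_test_table(
    obs_props: Mapping[str, float],
    exp_props: Mapping[str, float],
    scale: int = DEFAULT_SCALE,
    min_count: int = MIN_COUNT,
) -> TestTable:
    """Build the proportion-preserving observed/expected table.

    Both proportion maps are scaled to counts out of ``scale``.  A category
    keeps its own row iff it appears on both sides with scaled counts
    strictly greater than ``min_count``; all remaining mass on each side is
    pooled into that side's "other" row, so both columns total ``scale``
    and the retained rows keep their original proportions exactly.
    """
    _check_props("observed", obs_props)
    _check_props("expected", exp_props)
    obs_counts = scale_to_counts(obs_props, scale)
    exp_counts = scale_to_counts(exp_props, scale)

    retained = [
        c
        for c in obs_counts
        if c in exp_counts and obs_counts[c] > min_count and exp_counts[c] > min_count
    ]
    retained.sort(key=lambda c: (-obs_counts[c], c))
    other_obs = scale - sum(obs_counts[c] for c in retained)
    other_exp = scale - sum(exp_counts[c] for c in retained)

    categories = list(retained)
    observed = {c: obs_counts[c] for c in retained}
    expected = {c: exp_counts[c] for c in retained}
    if other_obs > 0 or other_exp > 0:
        categories.append(OTHER)
        observed[OTHER] = other_obs
        expected[OTHER] = other_exp
    if len(categories) < 2:
        raise ValidationError(
            "fewer than 2 categories after pooling; the table is untestable"
        )
    return TestTable(
        categories=categories,
        observed=observed,
        expected=expected,
        observed_props={c: obs_props[c] for c in retained},
        expected_props={c: exp_props[c] for c in retained},
        scale=scale,
    )


@dataclass(frozen=True)
class ChisqResult:
    statistic: float
    df: int
    pvalue: float


def gof_chisq(table: TestTable) -> ChisqResult:
    """Goodness-of-fit chi-square of observed against expected counts.

    statistic = sum (O-E)^2 / E over the table's rows (including "other");
    df = number of rows - 1; upper-tail p from the chi-square distribution.
    """
    obs = np.array([table.observed[c] for c in table.categories], dtype=float)
    exp = np.array([table.expected[c] for c in table.categories], dtype=float)
    if np.any(exp <= 0):
        raise ValidationError("degenerate expectation: zero expected count")
    res = stats.chisquare(obs, exp)
    return ChisqResult(float(res.statistic), table.df, float(res.pvalue))


def contingency_chisq(
    counts_a: Mapping[str, float],
    counts_b: Mapping[str, float],
    min_count: int = MIN_COUNT,
) -> tuple[ChisqResult, pd.DataFrame]:
    """2xk contingency chi-square between two species' morphotype counts.

    Categories shared by both rows with counts strictly greater than
    ``min_count`` on both sides keep their own column; the rest of each
    row's mass is pooled into a per-row "other" column (columns with zero
    margin after pooling are dropped with a warning).  Expected counts come
    from the table margins; df = k - 1.
    """
    ta = sum(counts_a.values())
    tb = sum(counts_b.values())
    if ta <= 0 or tb <= 0:
        raise ValidationError("both rows need a positive total")
    retained = [
        c
        for c in counts_a
        if c in counts_b and counts_a[c] > min_count and counts_b[c] > min_count
    ]
    retained.sort(key=lambda c: (-(counts_a[c] + counts_b[c]), c))
    cols = list(retained)
    row_a = [float(counts_a[c]) for c in retained]
    row_b = [float(counts_b[c]) for c in retained]
    other_a = float(ta - sum(row_a))
    other_b = float(tb - sum(row_b))
    if other_a > 0 or other_b > 0:
        cols.append(OTHER)
        row_a.append(other_a)
        row_b.append(other_b)
    table = pd.DataFrame([row_a, row_b], index=["a", "b"], columns=cols)
    zero = table.columns[(table.sum(axis=0) == 0)]
    if len(zero):
        warnings.warn(f"dropping zero-margin column(s): {list(zero)}", stacklevel=2)
        table = table.drop(columns=zero)
    if table.shape[1] < 2:
        raise ValidationError("fewer than 2 columns; contingency test undefined")
    stat, p, dof, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return ChisqResult(float(stat), int(dof), float(p)), table


# ---------------------------------------------------------------------------
# Availability-proportional null model
# ---------------------------------------------------------------------------


def pooled_proportions(pellets: Sequence[PollenPellet]) -> dict[str, float]:
    """Species-level observed proportions: pooled grains / total grains."""
    pooled: dict[str, int] = {}
    for p in pellets:
        for m, c in p.counts.items():
            pooled[m] = pooled.get(m, 0) + c
    total = sum(pooled.values())
    if total <= 0:
        raise ValidationError("no grains in the pellet collection")
    return {m: c / total for m, c in pooled.items()}


@dataclass(frozen=True)
class PreferenceResult:
    """Observed vs null-expected proportion for one morphotype."""

    survey: str
    bee_species: str
    morphotype: str
    availability: float
    observed_prop: float
    null_mean: float
    ci_low: float
    ci_high: float
    classification: str
    n_iterations: int
    seed: int | None


class PreferenceModel:
    """Availability-proportional null model for one species in one survey.

    Parameters
    ----------
    pellets
        The survey's pellet collection for one bee species (counts as
        retained after any pre-processing; the model resamples the totals
        it is given).
    availability
        The survey's :class:`AvailabilityProfile`.
    bee_species, survey
        Labels carried into the results; inferred from the pellets /
        profile when omitted.
    """

    def __init__(
        self,
        pellets: Sequence[PollenPellet],
        availability: AvailabilityProfile,
        *,
        bee_species: str | None = None,
        survey: str | None = None,
    ):
        if not pellets:
            raise ValidationError("preference model needs at least one pellet")
        self.pellets = list(pellets)
        self.availability = availability
        self.bee_species = bee_species or self.pellets[0].bee_species
        self.survey = survey or availability.survey

        props = availability.proportions
        if sum(props.values()) <= 0:
            raise ValidationError("availability is zero everywhere")
        self.avail_morphs = sorted(m for m, v in props.items() if v > 0)
        self.avail_probs = np.array([props[m] for m in self.avail_morphs])
        self.avail_probs = self.avail_probs / self.avail_probs.sum()
        self.totals = np.array([p.total for p in self.pellets], dtype=np.int64)
        if np.any(self.totals <= 0):
            raise ValidationError("every pellet must carry grains")

    def _null_draws(self, n_iter: int, rng: np.random.Generator, how: str) -> np.ndarray:
        """(n_iter, k) null pooled proportions over ``avail_morphs``.

        "per_pellet" literally redraws every pellet's grain total from a
        multinomial over the availability proportions and pools; "pooled"
        draws the pooled counts directly from Multinomial(sum of totals,
        availability), which is the exact distribution of the per-pellet
        sum (independent multinomials sharing p add), just cheaper.
        """
        grand = int(self.totals.sum())
        if how == "pooled":
            counts = rng.multinomial(grand, self.avail_probs, size=n_iter)
        elif how == "per_pellet":
            n = np.broadcast_to(self.totals, (n_iter, len(self.totals)))
            counts = rng.multinomial(n, self.avail_probs).sum(axis=1)
        else:
            raise ValueError(f"unknown null draw mode {how!r}")
        return counts / grand

    def fit(
        self,
        n_iter: int = 1000,
        alpha: float = 0.05,
        seed: int | np.random.Generator | None = None,
        null: str = "pooled",
    ) -> "PreferenceResults":
        """Run the resampling null and classify every morphotype.

        Morphotypes above the [alpha/2, 1-alpha/2] percentile interval of
        the null pooled proportion are classified "preference", below it
        "avoidance", inside "proportional"; morphotypes with zero
        availability are "unassessable".  Identical seed, identical output.
        """
        if n_iter < 100:
            warnings.warn(
                f"n_iter={n_iter} gives unstable percentile intervals", stacklevel=2
            )
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        seed_label = seed if isinstance(seed, (int, np.integer)) else None

        observed = pooled_proportions(self.pellets)
        draws = self._null_draws(n_iter, rng, null)
        lo = np.percentile(draws, 100 * alpha / 2, axis=0)
        hi = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
        mean = draws.mean(axis=0)

        morphs = sorted(set(observed) | set(self.avail_morphs))
        idx = {m: i for i, m in enumerate(self.avail_morphs)}
        rows = []
        for m in morphs:
            obs = observed.get(m, 0.0)
            avail = self.availability.proportions.get(m, 0.0)
            if m not in idx:
                cls, nmean, cl, ch = "unassessable", np.nan, np.nan, np.nan
            else:
                i = idx[m]
                nmean, cl, ch = float(mean[i]), float(lo[i]), float(hi[i])
                if obs > ch:
                    cls = "preference"
                elif obs < cl:
                    cls = "avoidance"
                else:
                    cls = "proportional"
            rows.append(
                PreferenceResult(
                    survey=self.survey,
                    bee_species=self.bee_species,
                    morphotype=m,
                    availability=avail,
                    observed_prop=obs,
                    null_mean=nmean,
                    ci_low=cl,
                    ci_high=ch,
                    classification=cls,
                    n_iterations=n_iter,
                    seed=seed_label,
                )
            )
        return PreferenceResults(self, rows, alpha=alpha, n_iter=n_iter)


class PreferenceResults:
    """Fitted null-model results: estimates, intervals and classifications."""

    def __init__(
        self,
        model: PreferenceModel,
        preferences: list[PreferenceResult],
        *,
        alpha: float,
        n_iter: int,
    ):
        self.model = model
        self.preferences = preferences
        self.alpha = alpha
        self.n_iter = n_iter

    def __iter__(self):
        return iter(self.preferences)

    def __len__(self):
        return len(self.preferences)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.preferences])

    def classifications(self) -> dict[str, str]:
        return {r.morphotype: r.classification for r in self.preferences}

    def summary(self) -> str:
        """Plain-text summary table in the fitted-model idiom."""
        df = self.to_frame()
        head = (
            f"Availability-proportional null model\n"
            f"  species: {self.model.bee_species}   survey: {self.model.survey}\n"
            f"  pellets: {len(self.model.pellets)}   grains: "
            f"{int(self.model.totals.sum())}\n"
            f"  iterations: {self.n_iter}   interval: "
            f"{100 * (1 - self.alpha):.0f}% percentile\n"
        )
        cols = [
            "morphotype",
            "availability",
            "observed_prop",
            "null_mean",
            "ci_low",
            "ci_high",
            "classification",
        ]
        body = df[cols].to_string(
            index=False, float_format=lambda v: f"{v:.4f}", na_rep="--"
        )
        return head + body

    def plot(self, ax=None):
        """Dot-and-interval plot: observed proportion against the null CI."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * max(len(self.preferences), 4) + 1))
        colors = {
            "preference": "tab:green",
            "avoidance": "tab:red",
            "proportional": "tab:blue",
            "unassessable": "0.6",
        }
        assessable = [r for r in self.preferences if r.classification != "unassessable"]
        others = [r for r in self.preferences if r.classification == "unassessable"]
        ordered = assessable + others
        for y, r in enumerate(ordered):
            if not np.isnan(r.ci_low):
                ax.plot([r.ci_low, r.ci_high], [y, y], color="k", lw=1.5)
            ax.plot(
                r.observed_prop, y, "o", color=colors[r.classification], markersize=6
            )
        ax.set_yticks(range(len(ordered)))
        ax.set_yticklabels([r.morphotype for r in ordered])
        ax.set_xlabel("proportion of collected pollen")
        ax.set_title(
            f"{self.model.bee_species}, {self.model.survey} "
            f"(observed vs {100 * (1 - self.alpha):.0f}% null interval)"
        )
        return ax


def null_model_preferences(
    pellets: Sequence[PollenPellet],
    availability: AvailabilityProfile,
    n_iter: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    null: str = "pooled",
) -> PreferenceResults:
    """Functional wrapper: build the model and fit in one call."""
    return PreferenceModel(pellets, availability).fit(
        n_iter=n_iter, alpha=alpha, seed=seed, null=null
    )


# ---------------------------------------------------------------------------
# Morphotype overlap
# ---------------------------------------------------------------------------


def classify_overlap(
    pellet_morphotypes: Iterable[str], resource_morphotypes: Iterable[str]
) -> dict[str, str]:
    """Partition the morphotype union into both / pollen_only / resource_only."""
    pol = set(pellet_morphotypes)
    res = set(resource_morphotypes)
    out = {}
    for m in sorted(pol | res):
        if m in pol and m in res:
            out[m] = "both"
        elif m in pol:
            out[m] = "pollen_only"
        else:
            out[m] = "resource_only"
    return out
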