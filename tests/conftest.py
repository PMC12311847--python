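import numpy as np
import pytest

from pollenforage.data_model import PollenPellet, TaxonomyMap, default_design


def make_pellet(counts, *, bee="honeybee", site="site1", day="2016-06-15",
                period="P1", pid="X1", grains_total=None):
    total = sum(counts.values())
    return PollenPellet(
        bee_species=bee,
        site=site,
        day=day,
        period=period,
        pellet_id=pid,
        counts=dict(counts),
        grains_total=grains_total if grains_total is not None else max(total, 1),
    )


@pytest.fixture
def small_taxonomy():
    return TaxonomyMap(
        {
            "Fabaceae_Tricolporate": ("Fabaceae", ["Medicago_sativa", "Glycine_max"]),
            "Lotus_corniculatus": ("Fabaceae", ["Lotus_corniculatus"]),
            "Brassicaceae": ("Brassicaceae", []),
            "Asteraceae_Spines": ("Asteraceae", ["Cirsium_arvense"]),
            "Apiaceae": ("Apiaceae", ["Daucus_carota"]),
        }
    )


@pytest.fixture
def design():
    return default_design(["site1"])


def random_pellet(rng: np.random.Generator, morphotypes, grains=500):
    """A random pellet: Dirichlet composition over a random subset."""
    k = rng.integers(1, len(morphotypes) + 1)
    chosen = list(rng.choice(morphotypes, size=k, replace=False))
    probs = rng.dirichlet(np.ones(k))
    draw = rng.multinomial(grains, probs)
    counts = {m: int(c) for m, c in zip(chosen, draw) if c > 0}
    if not counts:
        counts = {chosen[0]: grains}
    return make_pellet(counts, pid=f"R{rng.integers(1e9)}")
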