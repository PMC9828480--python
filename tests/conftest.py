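import numpy as np
import pandas as pd
import pytest

from rstarcomp.growth_models import GrowthSeries
from rstarcomp.rct_simulator import (
    ResourceSupply,
    SimScenario,
    SpeciesParams,
    MESOCOSM_PULSE_FRACTION,
)
from rstarcomp.synthetic_data import StrainSpec


DAYS = np.arange(0.0, 15.0)  # daily fluorometer schedule over 2 weeks


def make_series(ln_rfu, times=DAYS, strain="S01", resource="N", level=5.0, rep="r1"):
    return GrowthSeries(strain, resource, level, rep,
                        np.asarray(times, float), np.exp(np.asarray(ln_rfu, float)))


@pytest.fixture
def days():
    return DAYS


@pytest.fixture
def exact_exp_series():
    """ln rfu = 2 + 0.4 t exactly."""
    return make_series(2.0 + 0.4 * DAYS)


@pytest.fixture
def monod_rates():
    """Noiseless replicate growth rates from (mu_max=0.8, Ks=5) at 10 levels."""
    levels = np.geomspace(0.25, 100.0, 10)
    mu = 0.8 * levels / (5.0 + levels)
    return pd.DataFrame({
        "strain": "S01", "resource": "N",
        "level": np.tile(levels, 3), "mu": np.tile(mu, 3),
        "replicate": np.repeat(["r1", "r2", "r3"], 10),
    })


def two_species_scenario(ks1=0.5, ks2=2.0, m=0.1, horizon=500.0, supply=10.0):
    """Single-resource chemostat-style competition; lower Ks wins."""
    sp1 = SpeciesParams("A", {"R": (1.0, ks1)}, {"R": 1.0}, b0=0.1)
    sp2 = SpeciesParams("B", {"R": (1.0, ks2)}, {"R": 1.0}, b0=0.1)
    return SimScenario(
        species=[sp1, sp2],
        resources=[ResourceSupply("R", supply, "chemostat", dilution=m)],
        m=m, horizon=horizon)


@pytest.fixture
def mesocosm_base():
    """Two-species base scenario with N, P (weekly pulse) and light (constant)."""
    species = [
        SpeciesParams("sp1", {"light": (1.0, 20.0), "N": (0.9, 0.5), "P": (0.8, 0.05)},
                      {"N": 1.0, "P": 0.0625}, b0=0.1),
        SpeciesParams("sp2", {"light": (0.8, 5.0), "N": (1.0, 2.0), "P": (0.9, 0.2)},
                      {"N": 1.0, "P": 0.0625}, b0=0.1),
    ]
    return SimScenario(
        species=species,
        resources=[
            ResourceSupply("N", 160.0, "pulse", pulse_fraction=MESOCOSM_PULSE_FRACTION),
            ResourceSupply("P", 10.0, "pulse", pulse_fraction=MESOCOSM_PULSE_FRACTION),
            ResourceSupply("light", 300.0, "constant"),
        ],
        m=0.013, horizon=70.0)


@pytest.fixture
def strain_spec():
    return StrainSpec("S01", "sp1", {"N": (0.8, 5.0), "P": (0.7, 0.1),
                                     "light": (1.0, 25.0)})


def community_fixture(seed=0, n_groups=2, n_per=3, n_taxa=5, scale=50):
    """Random count table: one week, `n_groups` treatments x `n_per` mesocosms."""
    rng = np.random.default_rng(seed)
    rows = []
    meso = 0
    for g in range(n_groups):
        for _ in range(n_per):
            meso += 1
            counts = rng.poisson(scale, n_taxa) + 1
            for t in range(n_taxa):
                rows.append({"week": 1, "mesocosm": f"M{meso:02d}",
                             "treatment": f"G{g + 1}", "taxon": f"t{t + 1}",
                             "count": int(counts[t])})
    return pd.DataFrame(rows)
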