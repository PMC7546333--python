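import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ssivarscape as sv

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def one_chrom_layout():
    """Single 1 Mb chromosome with a 100 cM map."""
    return sv.GenomeLayout.from_spec([("c1", 1_000_000, 100.0)])


def selfed_population(layout, config, seed):
    """Convenience wrapper: founders + selfed lines + truth from one seed."""
    rng = np.random.default_rng(seed)
    config.seed = seed
    founders, kinds = sv.simulate_founders(layout, config, rng)
    population, truth = sv.self_population(founders, layout, config, rng, kinds)
    return rng, founders, population, truth


def true_marker_codes(founders, population):
    """Lines x markers genotype codes (0/1/2 copies of the non-recipient
    allele) at the recipient-hom / variant-het marker sites — the error-free
    fully covered genotype matrix."""
    sites = founders.sites
    midx = np.flatnonzero(founders.marker_mask())
    rec = sites["rec1"].to_numpy()[midx]
    v1 = sites["var1"].to_numpy()[midx]
    v2 = sites["var2"].to_numpy()[midx]
    b = np.where(v1 == rec, v2, v1)
    return midx, b, population.genotype_codes(midx, b)
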