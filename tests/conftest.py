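import numpy as np
import pytest

import boundaryalt as ba


@pytest.fixture(scope="session")
def model():
    return ba.synthetic_ctcf_model()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across tests (seed 11)."""
    return ba.generate_cohort(ba.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def classified_sites(cohort, model):
    sites = ba.scan_genome(cohort.genome, model, 0.99)
    ba.classify_sites(sites, cohort.peaks, cohort.boundaries)
    return sites


@pytest.fixture(scope="session")
def catalog():
    return ba.make_synthetic_catalog()


def brute_force_overlaps(query, intervals):
    """Quadratic reference for half-open interval overlap."""
    return sorted(
        (iv for iv in intervals
         if iv.chrom == query.chrom and iv.start < query.end
         and query.start < iv.end),
        key=lambda iv: (iv.start, iv.end),
    )
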