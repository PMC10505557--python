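import numpy as np
import pytest

import lignoporo as lp

NINE_POINT_GRID = np.arange(1, 10) / 10.0

#: well-conditioned reference parameters used across fitting tests
REFERENCE_PARK = lp.ParkParameters(A_L=1.0, b_L=10.0, k_H=5.0, k_a=0.5, n=4.0)


@pytest.fixture(scope="session")
def reference_park():
    return REFERENCE_PARK


@pytest.fixture(scope="session")
def nine_point_grid():
    return NINE_POINT_GRID


@pytest.fixture(scope="session")
def noiseless_reference_fit():
    """Session-cached fit of a noiseless 9-point isotherm (fits are the
    slowest unit of work in the suite)."""
    iso = lp.gen_park_isotherm(REFERENCE_PARK, NINE_POINT_GRID, 0.0)
    return lp.fit_park(iso)


@pytest.fixture(scope="session")
def default_dvs_trace():
    """Zero-noise kinetic trace at the default study conditions."""
    return lp.gen_dvs_kinetics()


def five_bin_distribution(seed=7, free_pct=20.0, total_mg=3.0):
    """A 5-bin mesopore distribution spanning 4-32 nm with seeded fractions."""
    edges_m = np.geomspace(4e-9, 32e-9, 6)
    rng = np.random.default_rng(seed)
    fracs = rng.dirichlet(np.ones(5)) * (100.0 - free_pct)
    bins = [(edges_m[i], edges_m[i + 1], float(fracs[i])) for i in range(5)]
    return lp.PoreSizeDistribution(bins, free_pct, total_mg)


def matching_program(dist, bulk_hold_c=2.0, hold_s=600.0):
    """Step program whose hold temperatures realise the distribution's bin
    edges through the Gibbs-Thomson relation, plus a bulk-melt hold."""
    edges = [dist.bins[0][0]] + [b[1] for b in dist.bins]
    temps = [lp.melting_temperature_for_diameter(d) for d in edges]
    holds = [(t, hold_s) for t in temps] + [(273.15 + bulk_hold_c, hold_s)]
    return lp.StepProgram(holds)
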