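"""Shared fixtures.

The comparative scenario runs are expensive, so they are executed once per
session and shared between the structural tests and the acceptance suite.
"""

import numpy as np
import pytest

import gliosim as g

COMPARATIVE_SCENARIOS = (
    "no_adhesion",
    "reference",
    "bigel",
    "restricted_oxygen",
    "bigel_restricted",
)
SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def comparative_reports():
    """Scaled 7-day runs of the comparative scenarios, three seeds each."""
    return {
        name: [g.run_simulation(g.scaled_config(name, seed=s)) for s in SEEDS]
        for name in COMPARATIVE_SCENARIOS
    }


@pytest.fixture(scope="session")
def complex_matrix_report():
    """One scaled 7-day run of the heterogeneous-matrix scenario."""
    return g.run_simulation(g.scaled_config("complex_matrix", seed=1))


@pytest.fixture(scope="session")
def rescue_reports():
    """Scaled runs of the Warburg-rescue study (PDH inhibition gamma_kq=0.14
    plus oscillating oxygen), two seeds."""
    return [g.run_simulation(g.warburg_study_config(seed=s)) for s in (1, 2)]


@pytest.fixture(scope="session")
def reference_report(comparative_reports):
    return comparative_reports["reference"][0]


def median_total(reports):
    return float(np.median([r.counts["total"][-1] for r in reports]))
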