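"""Shared fixtures: benchmark parameter sets and small synthetic series.

Expensive multi-start fits are session-scoped so several tests can interrogate
the same solution pool.
"""

from __future__ import annotations

import numpy as np
import pytest

from cfkinetics import (
    FitProblem,
    HaldaneConfig,
    ThermoInfo,
    bdh_model,
    fdh_model,
    haldane_keq,
    multistart_fit,
)
from cfkinetics.synthetic import SynthDesign, gen_series

#: Published FDH benchmark parameters (kcat 1/s, constants mM, kdq 1/min).
BENCHMARK_FDH = {
    "kcat": 0.18,
    "KIA": 78.14,
    "KIQ": 0.118,
    "KMA": 0.0384,
    "KMB": 0.472,
    "kdq": 3.45e-2 / 60.0,
}

#: Five initial-condition designs spanning substrate, cofactor and enzyme
#: levels, the layout of a single-enzyme assay campaign.
FDH_DESIGNS = [
    ({"A": 1.0, "B": 100.0, "Q": 0.0}, {"E_fdh": 1.0e-3}),
    ({"A": 2.0, "B": 50.0, "Q": 0.0}, {"E_fdh": 2.0e-3}),
    ({"A": 0.5, "B": 150.0, "Q": 0.0}, {"E_fdh": 1.0e-3}),
    ({"A": 4.0, "B": 25.0, "Q": 0.1}, {"E_fdh": 1.5e-3}),
    ({"A": 1.5, "B": 75.0, "Q": 0.0}, {"E_fdh": 0.5e-3}),
]


@pytest.fixture(scope="session")
def fdh_truth() -> dict:
    return dict(BENCHMARK_FDH)


@pytest.fixture(scope="session")
def noiseless_fdh_series(fdh_truth):
    """Noiseless 5-dataset FDH series generated under the fitting
    discretization, so exact parameter recovery is the correct answer."""
    return gen_series(
        SynthDesign(
            model_tag="fdh",
            true_params=fdh_truth,
            designs=FDH_DESIGNS,
            sampling=(120.0, 4.0),
            noise_sd=0.0,
            seed=11,
            integrator="euler",
        )
    )


@pytest.fixture(scope="session")
def fdh_recovery_pool(noiseless_fdh_series):
    """Multi-start fit of the noiseless FDH series (shared across tests)."""
    problem = FitProblem(
        series=noiseless_fdh_series,
        model=fdh_model(),
        n_starts=4,
        seed=7,
    )
    return multistart_fit(problem)


#: Haldane-consistent BDH truth at dG0 = -22.5 kJ/mol, 310.15 K.
BDH_THERMO = ThermoInfo(dG0=-22.5, dG0_sd=4.1, T=310.15)
_KEQ = haldane_keq(BDH_THERMO)
BDH_TRUTH = {
    "kcatf": 50.0,
    "KMS": 1.0,
    "KMQ": 0.1,
    "KMP": 10.0,
    "KMA": 1.0,
    "kdq": 1.286e-3,
}
BDH_TRUTH["kcatr"] = (
    BDH_TRUTH["kcatf"] * BDH_TRUTH["KMP"] * BDH_TRUTH["KMA"]
    / (_KEQ * BDH_TRUTH["KMS"] * BDH_TRUTH["KMQ"])
)

BDH_DESIGNS = [
    ({"S": 20.0, "Q": 0.5, "P": 0.0, "A": 0.0}, {"E_bdh": 1.0e-3}),
    ({"S": 5.0, "Q": 0.3, "P": 1.0, "A": 0.1}, {"E_bdh": 2.0e-3}),
]


@pytest.fixture(scope="session")
def bdh_truth() -> dict:
    return dict(BDH_TRUTH)


@pytest.fixture(scope="session")
def bdh_haldane_pool(bdh_truth):
    """Small Haldane-constrained BDH multi-start fit (shared across tests)."""
    series = gen_series(
        SynthDesign(
            model_tag="bdh",
            true_params=bdh_truth,
            designs=BDH_DESIGNS,
            sampling=(30.0, 2.0),
            noise_sd=0.0,
            seed=5,
            integrator="euler",
        )
    )
    problem = FitProblem(
        series=series,
        model=bdh_model(),
        haldane=HaldaneConfig(BDH_THERMO, mode="equality"),
        n_starts=3,
        seed=2,
    )
    return multistart_fit(problem)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
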