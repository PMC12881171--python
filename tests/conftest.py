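import numpy as np
import pytest

from agelaw.data import AgeBin, IncidenceRecord, RegistrySeries
from agelaw.synth import (
    HeterogeneitySpec,
    SyntheticTruth,
    default_bins,
    expected_incidence,
    simulate_registry,
)

B_TRUE = 0.117
A_EXP = 0.032  # per 100,000; ~6,000 pooled cases for 5 registries x 2e6 py/bin
K_TRUE = 5
A_POW = 2.0e-6


@pytest.fixture(scope="session")
def bins7():
    """Dataset-1-like grid: [25,30) ... [55,60), midpoints 27.5 ... 57.5."""
    return default_bins()


@pytest.fixture(scope="session")
def exp_truth():
    return SyntheticTruth("exponential", a_e=A_EXP, b=B_TRUE)


@pytest.fixture(scope="session")
def pow_truth():
    return SyntheticTruth("power_law", a_m=A_POW, k=K_TRUE)


def noiseless_series(truth, bins, registry_id="noiseless"):
    recs = [
        IncidenceRecord(registry_id, b, float(expected_incidence(truth, b.midpoint)))
        for b in bins
    ]
    return RegistrySeries(registry_id, recs)


@pytest.fixture(scope="session")
def exp_series(exp_truth, bins7):
    """Noiseless exponential incidence on the 7-bin adult grid."""
    return noiseless_series(exp_truth, bins7)


@pytest.fixture(scope="session")
def pow_series(pow_truth, bins7):
    """Noiseless power-law incidence on the 7-bin adult grid."""
    return noiseless_series(pow_truth, bins7)


def jittered_registries(truth, bins, n_registries=5, noise_sd=0.01, seed=0):
    """Registries with tiny iid Gaussian jitter on ln(incidence).

    Near-noiseless stand-in for 'noiseless' multi-registry fixtures: exact
    curves have zero residual variance, which is outside Gaussian ML.
    """
    rng = np.random.default_rng(seed)
    out = []
    for j in range(n_registries):
        recs = [
            IncidenceRecord(
                f"r{j}",
                b,
                float(
                    expected_incidence(truth, b.midpoint)
                    * np.exp(rng.normal(0.0, noise_sd))
                ),
            )
            for b in bins
        ]
        out.append(RegistrySeries(f"r{j}", recs))
    return out


@pytest.fixture(scope="session")
def noisy_fixture_suite(exp_truth, pow_truth, bins7):
    """Seeded Poisson-sampled registries under both truths, for property checks."""
    suite = []
    for truth in (exp_truth, pow_truth):
        for seed in (1, 2, 3):
            suite.append(
                simulate_registry(truth, bins7, 1.0e7, seed=seed, registry_id=f"s{seed}")
            )
    return suite


@pytest.fixture(scope="session")
def het_registries(exp_truth, bins7):
    """Five Poisson-noise registries with mild between-registry heterogeneity."""
    het = HeterogeneitySpec(intercept_sd=0.2, slope_sd=0.005)
    return [
        simulate_registry(
            exp_truth, bins7, 2.0e6, heterogeneity=het, seed=100 + j, registry_id=f"h{j}"
        )
        for j in range(5)
    ]
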