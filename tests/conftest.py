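import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_cohort():
    """Cohort of 3,000 with one planted PRS effect, diagnoses for BPD/SZ."""
    from prsbrain import CohortConfig, generate_cohort, generate_diagnoses

    cfg = CohortConfig(
        n_participants=3000,
        prs_effect={("ADHD", "sa_cluster01"): -0.05},
        seed=11,
    )
    cohort = generate_cohort(cfg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort = generate_diagnoses(
            cohort, weights=(1.0, 0.5), threshold=2.5, seed=12,
            diseases=("BPD", "SZ"),
        )
    return cohort


@pytest.fixture
def gwas_pair_factory():
    """Factory for harmonizable exposure/outcome summary-stat pairs."""
    from prsbrain import GWASPairConfig, generate_gwas_pair

    def make(causal_effect=0.0, seed=0, n_instruments=50, n_snps=60, **kw):
        cfg = GWASPairConfig(
            n_snps=n_snps, n_instruments=n_instruments,
            causal_effect=causal_effect,
            n_exposure=100_000, n_outcome=100_000, seed=seed, **kw,
        )
        return generate_gwas_pair(cfg)

    return make
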