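import numpy as np
import pytest
from hypothesis import settings

import gctrial as g

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> g.CohortBundle:
    """A cohort at the default (trial-emulating) conditions."""
    return g.generate_cohort(g.CohortConfig(n_patients=62, seed=11, n_genes=400))


@pytest.fixture(scope="session")
def default_normalized(default_cohort) -> g.ExpressionMatrix:
    return g.normalize_expression(default_cohort.expression)


@pytest.fixture(scope="session")
def strong_cohort() -> g.CohortBundle:
    """Strong-effect conditions: large planted expression shifts, for
    recovery checks of the differential-expression stage."""
    return g.generate_cohort(
        g.CohortConfig(
            n_patients=62, seed=5, n_genes=400,
            resistant_shift=0.6, responder_shift=0.6,
        )
    )


@pytest.fixture(scope="session")
def tiny_cohort() -> g.CohortBundle:
    """A minimal cohort for format round-trips."""
    return g.generate_cohort(
        g.CohortConfig(n_patients=8, seed=3, n_genes=25,
                       n_mutation_genes=50, mutation_burden_mean=12.0)
    )


def responder_map(bundle: g.CohortBundle) -> dict[str, bool]:
    return {
        r.sample_id: r.response_category in ("CR", "PR")
        for r in bundle.clinical
        if r.response_category != "NE"
    }


@pytest.fixture(scope="session")
def planted_survival_cohort() -> g.CohortBundle:
    """n=1000, no censoring, hazard ratio 2.0 per SD of the resistant
    signature score — for hazard-recovery checks."""
    return g.generate_cohort(
        g.CohortConfig(
            n_patients=1000, seed=17, n_genes=100, n_mutation_genes=200,
            mutation_burden_mean=2.0, censoring_rate=0.0,
        )
    )
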