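import pytest

from stratify_kit import cohort_features, synthetic_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """A modest cohort shared by read-only tests (never mutate)."""
    params = synthetic_cohort.GenerativeParams(
        n_patients=500, n_physicians=15, n_years=4, seed=11
    )
    return synthetic_cohort.generate_cohort(params)


@pytest.fixture(scope="session")
def small_matrix(small_bundle):
    return cohort_features.build_feature_matrix(small_bundle)
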