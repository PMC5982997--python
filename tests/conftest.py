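import numpy as np
import pytest

import earlife


@pytest.fixture(scope="session")
def study():
    """One full synthetic cohort at the default study conditions."""
    clips, participants, truth = earlife.simulate_study(n_participants=91, seed=11)
    return clips, participants, truth


@pytest.fixture(scope="session")
def study_rows(study):
    """Aggregated, merged, cohort-filtered count rows for the cohort."""
    clips, participants, _ = study
    rows = earlife.aggregate_counts(clips, list(earlife.analyzed_behaviors()))
    rows = earlife.merge_religious_volunteer(rows, clips=clips)
    return earlife.apply_cohort_filters(rows, participants)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced sampler settings for unit tests."""
    return earlife.SamplerConfig(
        chains=2, draws=500, warmup=500, rhat_threshold=1.05, ess_threshold=100.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
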