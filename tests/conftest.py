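import numpy as np
import pytest

from metamem.datamodel import (
    CANONICAL_COLUMNS,
    MEASURE_RANGES,
    ParticipantRecord,
    age_targets,
    feature_matrix,
    zscore_normalize,
)
from metamem.perceptron import TrainingConfig
from metamem.synthetic import SyntheticConfig, generate


def make_record(pid="P001", age_group="young", condition="words", **overrides):
    """A valid record with mid-range values, overridable per column."""
    measures = {}
    for column in CANONICAL_COLUMNS:
        lo, hi = MEASURE_RANGES[column.rpartition("_")[0]]
        measures[column] = (lo + hi) / 2.0
    measures.update(overrides)
    return ParticipantRecord(
        id=pid, age_group=age_group, stimulus_condition=condition, measures=measures
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (57 young / 49 old, three latent clusters)."""
    return generate(seed=12345)


@pytest.fixture(scope="session")
def default_features(default_cohort):
    raw = feature_matrix(default_cohort.records)
    return raw, zscore_normalize(raw), age_targets(default_cohort.records)


@pytest.fixture(scope="session")
def small_separable():
    """A tiny cohort with a +/-3 z separation between age groups.

    Strong offsets on every measure make the classification problem
    linearly separable, giving fast, unambiguous training behaviour.
    """
    pattern = np.zeros((3, len(CANONICAL_COLUMNS)))
    pattern[0, :] = -1.5
    pattern[1, :] = 1.5
    pattern[2, :] = 1.5
    config = SyntheticConfig(
        n_young=12,
        n_old=12,
        old_cluster_sizes=(6, 6),
        crossover_young_into_cluster2=0,
        effect_pattern=pattern,
        residual_sd=0.3,
        seed=7,
    )
    return generate(config)


@pytest.fixture(scope="session")
def fast_training():
    """Training settings used for simulation studies in the tests.

    The learning dynamics are the default ones; only the epoch budget is
    sized for repeated retraining inside the suite.
    """
    return TrainingConfig(seed=0, learning_rate=0.5, max_epochs=3000, convergence_tol=1e-10)
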