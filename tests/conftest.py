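import numpy as np
import pytest

from exprqc import (
    DEFAULT_PANEL,
    ExpressionMatrix,
    SexAnnotation,
    SyntheticConfig,
    simulate_cohort,
)


def make_matrix(values, probe_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or tuple(f"p{i}" for i in range(values.shape[0]))
    sample_ids = sample_ids or tuple(f"s{j}" for j in range(values.shape[1]))
    return ExpressionMatrix(tuple(probe_ids), tuple(sample_ids), values)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    return make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture
def panel():
    return DEFAULT_PANEL


@pytest.fixture
def mixed_cohort():
    """Mixed-sex simulated cohort with one injected cross-sex mislabel."""
    config = SyntheticConfig(
        n_samples=200, mislabel_rate=1 / 200, n_background_probes=10, seed=42
    )
    return simulate_cohort(config)


@pytest.fixture
def clean_cohort():
    config = SyntheticConfig(n_samples=120, n_background_probes=10, seed=7)
    return simulate_cohort(config)


def annotation_from(labels: dict) -> SexAnnotation:
    return SexAnnotation(labels=labels)
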