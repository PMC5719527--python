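import itertools

import pytest

from taxconsensus import SimulationSpec, simulate_classifier_tables, simulate_truth

#: every (names, scores) configuration over {A, B, C, unassigned}^3 and a
#: small score grid — the exhaustive domain for rule-table checks
NAME_CHOICES = ("A", "B", "C", None)
SCORE_GRID = (0.8, 0.9, 1.0)


def all_rank_configs():
    for names in itertools.product(NAME_CHOICES, repeat=3):
        for scores in itertools.product(SCORE_GRID, repeat=3):
            yield tuple(
                None if n is None else (n, s)
                for n, s in zip(names, scores))


@pytest.fixture(scope="session")
def study_spec():
    """The study conditions: 500 OTUs, 10% error, 20% dropout."""
    return SimulationSpec(n_otus=500, error=0.1, dropout=0.2, seed=20260928)


@pytest.fixture(scope="session")
def study_truth(study_spec):
    return simulate_truth(study_spec)


@pytest.fixture(scope="session")
def study_tables(study_spec, study_truth):
    return simulate_classifier_tables(study_truth, study_spec)
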