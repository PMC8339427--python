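import numpy as np
import pytest

from icatk import simulate
from icatk.session import StimulusItem, TrialRecord


@pytest.fixture(scope="session")
def params():
    return simulate.default_params()


@pytest.fixture(scope="session")
def bank(params):
    return simulate.sample_item_bank(params, rng_seed=123)


@pytest.fixture(scope="session")
def big_bank():
    """Item bank with spare items for practice blocks."""
    items = [
        StimulusItem(item_id=f"a{k:03d}", category="animal", difficulty=0.0) for k in range(70)
    ]
    items += [
        StimulusItem(item_id=f"n{k:03d}", category="non_animal", difficulty=0.0) for k in range(70)
    ]
    return items


def make_main_records(n_correct, n_total, rt_ms=600.0, phase="main"):
    """Build a simple block of trial records with a given number correct."""
    records = []
    for i in range(n_total):
        cat = "animal" if i % 2 == 0 else "non_animal"
        correct = i < n_correct
        response = cat if correct else ("non_animal" if cat == "animal" else "animal")
        records.append(
            TrialRecord(
                item_id=f"it{i:03d}",
                category=cat,
                response=response,
                correct=correct,
                rt_ms=float(rt_ms),
                phase=phase,
                trial_index=i,
            )
        )
    return records


@pytest.fixture
def record_factory():
    return make_main_records


@pytest.fixture(scope="session")
def random_records():
    """A generator of random valid trial-record sessions."""

    def gen(seed, n=100, phase="main", timeout_rate=0.05):
        rng = np.random.default_rng(seed)
        records = []
        for i in range(n):
            cat = "animal" if rng.random() < 0.5 else "non_animal"
            if rng.random() < timeout_rate:
                records.append(
                    TrialRecord(item_id=f"it{i:03d}", category=cat, response="none",
                                correct=False, rt_ms=None, phase=phase, trial_index=i)
                )
                continue
            correct = rng.random() < 0.8
            response = cat if correct else ("non_animal" if cat == "animal" else "animal")
            records.append(
                TrialRecord(item_id=f"it{i:03d}", category=cat, response=response,
                            correct=correct, rt_ms=float(rng.uniform(250, 2500)),
                            phase=phase, trial_index=i)
            )
        return records

    return gen
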