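import numpy as np
import pytest

from numbersense.numerosity import TrialRecord
from numbersense.synthetic_data import TwinSimSpec, simulate_twin_dataset


def ae_spec(a2: float, n_mz: int, n_dz: int, seed: int = 0, **kw) -> TwinSimSpec:
    """AE generative spec (no shared environment), equal components per sex,
    pair counts split evenly over same-sex groups with DZos half of DZ."""
    e2 = 1.0 - a2
    return TwinSimSpec(
        a2_m=a2, c2_m=0.0, e2_m=e2, a2_f=a2, c2_f=0.0, e2_f=e2,
        n_pairs_by_group={
            "MZm": n_mz // 2, "MZf": n_mz - n_mz // 2,
            "DZm": n_dz // 4, "DZf": n_dz // 4,
            "DZos": n_dz - 2 * (n_dz // 4),
        },
        missing_rate=0.0, seed=seed, **kw,
    )


def make_trial(n_yellow, n_blue, correct, rt_ms=500.0, subject_id="S1"):
    """TrialRecord with a response consistent with the correctness flag."""
    if n_yellow == n_blue:
        response = "yellow"
    else:
        larger = "yellow" if n_yellow > n_blue else "blue"
        smaller = "blue" if larger == "yellow" else "yellow"
        response = larger if correct else smaller
    return TrialRecord(subject_id, n_yellow, n_blue, response, correct, rt_ms)


@pytest.fixture(scope="session")
def ae_dataset():
    """Moderate AE dataset (a2=.32) reused by read-only tests."""
    return simulate_twin_dataset(ae_spec(0.32, 700, 1140, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
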