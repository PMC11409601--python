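import numpy as np
import pytest

from ecgaf.synthetic import CLASS_SPECS, RhythmSpec, generate_records


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def clean_nsr():
    """A noiseless, perfectly regular sinus-rhythm record + truth peaks."""
    from ecgaf.synthetic import generate_rr_series, r_peak_times, synthesize_ecg

    spec = RhythmSpec(cls="NSR", duration_s=30.0, rr_mean_s=1.0, rr_cv=0.0,
                      noise_sigma=0.0)
    rng = np.random.default_rng(0)
    rr = generate_rr_series(spec, rng)
    rec = synthesize_ecg(rr, spec, rng, record_id="clean_nsr")
    return rec, r_peak_times(rr), spec


@pytest.fixture(scope="session")
def binary_records():
    """40 labeled NSR/AFib records (30 s, defaults) with truth peak times."""
    return generate_records({"NSR": 20, "AFib": 20}, seed=77)


@pytest.fixture(scope="session")
def four_class_records():
    return generate_records({c: 5 for c in CLASS_SPECS}, seed=78)
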