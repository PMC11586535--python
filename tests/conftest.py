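import numpy as np
import pytest

from caninepcg.synth import SynthesisConfig, synthesize_cohort, synthesize_pcg


@pytest.fixture(scope="session")
def small_cohort():
    """40 dogs with audio, default (published-table) marginals."""
    return synthesize_cohort(40, seed=42)


@pytest.fixture(scope="session")
def cohort_records_only():
    """400 dogs without audio, for splitting/staging/summary tests."""
    records, _ = synthesize_cohort(400, seed=1234, audio=False)
    return records


@pytest.fixture(scope="session")
def loud_recording():
    return synthesize_pcg(SynthesisConfig(murmur_grade="loud", seed=5))


@pytest.fixture(scope="session")
def silent_recording():
    return synthesize_pcg(SynthesisConfig(murmur_grade="none", seed=5))
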