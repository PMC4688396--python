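import pytest

from monotert import noiseless_reference_config, simulate_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """The deterministic 88-line reference cohort (19 mutant-mono / 20 wt-mono /
    49 biallelic, fixed depth 100, one anchor per line, seed 42) with truth."""
    return simulate_cohort(noiseless_reference_config())
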