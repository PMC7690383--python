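import pytest

from methpred import simcohort


@pytest.fixture(scope="session")
def default_cfg():
    return simcohort.SimConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_cfg):
    """One default synthetic cohort (5 NT / 11 pCR / 21 pIR, 20k probes), seed 1."""
    return simcohort.generate_cohort(default_cfg)


@pytest.fixture(scope="session")
def group_samples(cohort):
    _, _, sheet, _ = cohort
    return {g: sheet.samples_in_group(g) for g in ("NT", "pCR", "pIR")}
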