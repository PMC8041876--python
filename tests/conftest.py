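import pytest

from kirhla.hla_ligands import default_reference
from kirhla.synthetic_cohort import CohortSimParams, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def study_sized_cohort():
    """Ligand-mode cohort at the study's stratum sizes (278/70/44/48)."""
    params = CohortSimParams(seed=11)
    return simulate_cohort(params)


@pytest.fixture(scope="session")
def allele_mode_cohort():
    """Small allele-mode cohort to exercise the HLA pipeline end to end."""
    params = CohortSimParams(
        n_control=60, n_early=20, n_advanced=20, n_unknown_stage=0,
        seed=5, hla_mode="allele",
    )
    return simulate_cohort(params)
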