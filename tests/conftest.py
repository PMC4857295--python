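import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("repro", derandomize=True)
hypothesis_settings.load_profile("repro")

from nntplan import (
    BinomialOutcome,
    DiscomfortRange,
    NNTPair,
    Prevalence,
    ProspectiveDesign,
    RetrospectiveDesign,
)


@pytest.fixture
def ctcl_range() -> DiscomfortRange:
    """Elicited discomfort range of the CTCL planning example."""
    return DiscomfortRange(nnt_lower=2, nnt_upper=30)


@pytest.fixture
def ctcl_prevalence() -> Prevalence:
    """Incidence of rapid progression among early-stage CTCL patients."""
    return Prevalence(0.15)


@pytest.fixture
def ctcl_prospective() -> ProspectiveDesign:
    """40-patient prospective cohort, 25% anticipated test-positive."""
    return ProspectiveDesign(
        n_total=40, positive_fraction=0.25, target=NNTPair(2, 30),
        followup_note="accrual over 3 years, minimum 2 years follow-up",
    )


@pytest.fixture
def ctcl_retrospective(ctcl_prevalence) -> RetrospectiveDesign:
    """22 cases / 40 controls with anticipated SN = 18/22 and SP = 34/40."""
    return RetrospectiveDesign(
        n_cases=22, n_controls=40,
        anticipated_sn=BinomialOutcome(18, 22),
        anticipated_sp=BinomialOutcome(34, 40),
        prevalence=ctcl_prevalence,
    )
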