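import pytest
from hypothesis import settings

from nucsort.evidence import EvidenceConfig, LocalizationEvidence
from nucsort.model import Tool, UniProtState
from nucsort.simulate import CohortConfig, generate_cohort

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")

TOOL_ORDER = (Tool.LOCALIZER, Tool.NUCPRED, Tool.WEGOLOC, Tool.CELLO2GO)


def make_evidence(
    hit_count: int,
    horvu: UniProtState = UniProtState.ABSENT,
    arath: UniProtState = UniProtState.ABSENT,
    cytosolic: bool = False,
    protein_id: str = "P1",
) -> LocalizationEvidence:
    """Build an evidence vector with the first ``hit_count`` tools positive."""
    return LocalizationEvidence(
        protein_id=protein_id,
        tool_hits={t: i < hit_count for i, t in enumerate(TOOL_ORDER)},
        uniprot_horvu=horvu,
        uniprot_arath=arath,
        cytosolic_tagged=cytosolic,
    )


@pytest.fixture(scope="session")
def cfg() -> EvidenceConfig:
    return EvidenceConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-protein stochastic cohort shared across tests (seed fixed)."""
    return generate_cohort(CohortConfig(n_proteins=400, seed=7))
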