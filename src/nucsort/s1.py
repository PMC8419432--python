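"""Round-one (S1) categorization: predictor votes × UniProt record.

Six groups plus an explicit fall-through.  "More than two" of the four
predictors voting nuclear together with a nuclear-tagged UniProt record
makes a protein NUCLEAR; the remaining groups grade down the evidence or
flag disagreements between the predictors and the database.
"""

from __future__ import annotations

import enum

from .evidence import EvidenceConfig, LocalizationEvidence, combined_uniprot_state
from .model import UniProtState


class S1Category(str, enum.Enum):
    NUCLEAR = "NUCLEAR"
    PREDICTED_NUCLEAR = "PREDICTED_NUCLEAR"
    POSSIBLY_NUCLEAR = "POSSIBLY_NUCLEAR"
    DISCREPANCY_UNIPROT = "DISCREPANCY_UNIPROT"
    DISCREPANCY_PREDICTION = "DISCREPANCY_PREDICTION"
    CYTOSOLIC = "CYTOSOLIC"
    NON_CLASSIFIED = "NON_CLASSIFIED"


#: S1 groups treated as nuclear-side when merging the two rounds.
S1_NUCLEAR_SIDE = frozenset(
    {
        S1Category.NUCLEAR,
        S1Category.PREDICTED_NUCLEAR,
        S1Category.POSSIBLY_NUCLEAR,
        S1Category.DISCREPANCY_UNIPROT,
    }
)


def classify_s1(ev: LocalizationEvidence, cfg: EvidenceConfig) -> S1Category:
    """Assign the round-one category from an assembled evidence vector.

    Rules fire in precedence order; the function is total — every protein
    receives exactly one category, with NON_CLASSIFIED as the explicit
    fall-through (notably the hit_count == 2 / no-record cell, which the
    published scheme never assigns).
    """
    n = ev.hit_count
    uni = combined_uniprot_state(ev, cfg)
    nuclear = uni is UniProtState.NUCLEAR
    if cfg.possibly_requires_nuclear_record:
        possibly_record_ok = nuclear
    else:
        possibly_record_ok = uni is not UniProtState.ABSENT

    if n > 2 and nuclear:
        return S1Category.NUCLEAR
    if n > 2 and uni is UniProtState.ABSENT:
        return S1Category.PREDICTED_NUCLEAR
    if n > 2 and uni is UniProtState.NON_NUCLEAR:
        return S1Category.DISCREPANCY_UNIPROT
    if n == 2 and possibly_record_ok:
        return S1Category.POSSIBLY_NUCLEAR
    if n < 2 and nuclear:
        return S1Category.DISCREPANCY_PREDICTION
    if ev.cytosolic_tagged and n <= 1:
        return S1Category.CYTOSOLIC
    return S1Category.NON_CLASSIFIED
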