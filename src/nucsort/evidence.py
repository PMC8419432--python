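"""Assembly of the per-protein localization evidence vector.

Each identified protein gets a vote vector built from four predictor
outputs (Localizer, NucPred, WegoLoc, CELLO2GO), the UniProt
subcellular-location text of the barley accession, and — when a blastp
best hit passes the homology gate — the text of its Arabidopsis homolog.
Both classification rounds consume this vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .model import (
    AnnotationRecord,
    HomologyHit,
    PredictorOutput,
    ProteinIdentification,
    Tool,
    UniProtState,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvidenceConfig:
    """Thresholds and tag vocabularies of the evidence rules.

    Defaults implement the published criteria: NucPred calls nuclear at
    score ≥ 0.50; nuclear UniProt records are recognized by the substrings
    "chromos"/"chromat"/"nucl"; cytosolic-side records by
    "cytos"/"cytop"/"mitoch"/"memb"/"recept"; Arabidopsis annotation is
    consulted only when the best blastp hit reaches 70% homology.
    """

    nucpred_threshold: float = 0.50
    nuclear_tags: tuple[str, ...] = ("chromos", "chromat", "nucl")
    cytosolic_tags: tuple[str, ...] = ("cytos", "cytop", "mitoch", "memb", "recept")
    homology_gate_percent: float = 70.0
    homology_metric: str = "identity"  # or "similarity"
    #: an ARATH nuclear record substitutes for a missing HORVU record
    arath_substitutes: bool = True
    #: POSSIBLY NUCLEAR (S1) requires a nuclear-tagged record; relax to any record
    possibly_requires_nuclear_record: bool = True
    #: S2 "more than three nuclear prediction hits" on a four-tool panel
    s2_strong_hit_min: int = 4
    #: S2 "less than three nuclear prediction hits"
    s2_weak_hit_below: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.nucpred_threshold <= 1.0:
            raise ValueError("nucpred_threshold outside [0, 1]")
        if not 0.0 <= self.homology_gate_percent <= 100.0:
            raise ValueError("homology_gate_percent outside [0, 100]")
        if not self.nuclear_tags or not self.cytosolic_tags:
            raise ValueError("tag lists must be non-empty")
        if self.homology_metric not in ("identity", "similarity"):
            raise ValueError("homology_metric must be 'identity' or 'similarity'")


@dataclass(frozen=True)
class LocalizationEvidence:
    """The assembled vote vector for one protein."""

    protein_id: str
    tool_hits: dict[Tool, bool] = field(default_factory=dict)
    uniprot_horvu: UniProtState = UniProtState.ABSENT
    uniprot_arath: UniProtState = UniProtState.ABSENT
    cytosolic_tagged: bool = False
    homolog: HomologyHit | None = None

    @property
    def hit_count(self) -> int:
        return sum(self.tool_hits.values())


def _contains_any(text: str, tags: tuple[str, ...]) -> bool:
    low = text.lower()
    return any(t.lower() in low for t in tags)


def predictor_hit(tool: Tool, output: PredictorOutput, cfg: EvidenceConfig) -> bool:
    """Apply the per-tool positivity rule to one predictor output row.

    Localizer: predicted nuclear localization; NucPred: score ≥ threshold
    (boundary inclusive); WegoLoc: localization contains "nucl"; CELLO2GO:
    localization contains "nucl" or "chromo".  Text matching is
    case-insensitive substring containment.
    """
    if output.tool is not tool:
        raise ValueError(f"output is for {output.tool.value}, not {tool.value}")
    if tool is Tool.NUCPRED:
        if output.score is None:
            raise ValueError(f"{output.protein_id}: NucPred output lacks a score")
        return output.score >= cfg.nucpred_threshold
    text = output.localization_text or ""
    if tool is Tool.CELLO2GO:
        return _contains_any(text, ("nucl", "chromo"))
    if tool is Tool.WEGOLOC:
        return _contains_any(text, ("nucl",))
    # Localizer states the predicted compartment directly
    return _contains_any(text, ("nucl",))


def uniprot_state(
    record: AnnotationRecord | None, cfg: EvidenceConfig
) -> UniProtState:
    """Tri-state reading of a UniProt subcellular-location text."""
    if record is None or record.subcellular_location_text is None:
        return UniProtState.ABSENT
    if _contains_any(record.subcellular_location_text, cfg.nuclear_tags):
        return UniProtState.NUCLEAR
    return UniProtState.NON_NUCLEAR


def apply_homology_gate(hit: HomologyHit | None, cfg: EvidenceConfig) -> bool:
    """True iff a best hit exists and reaches the homology threshold."""
    return hit is not None and hit.homology_percent >= cfg.homology_gate_percent


def assemble_evidence(
    ident: ProteinIdentification,
    predictor_outputs: list[PredictorOutput],
    annotations: dict,
    homology: dict[str, HomologyHit],
    cfg: EvidenceConfig,
) -> LocalizationEvidence:
    """Build the evidence vector for one identified protein.

    A missing tool output counts as a negative hit (the panel is fixed at
    four tools).  The ARATH annotation is consulted only through the
    homology gate; the cytosolic flag looks at both the HORVU text and the
    gated ARATH text.
    """
    from .model import Organism  # local to avoid cycle in type-only use

    by_tool: dict[Tool, PredictorOutput] = {}
    for out in predictor_outputs:
        if out.protein_id != ident.protein_id:
            continue
        if out.tool in by_tool:
            raise ValueError(f"{ident.protein_id}: duplicate {out.tool.value} output")
        by_tool[out.tool] = out

    hits: dict[Tool, bool] = {}
    for tool in Tool:
        if tool in by_tool:
            hits[tool] = predictor_hit(tool, by_tool[tool], cfg)
        else:
            logger.debug("%s: no %s output, counted negative", ident.protein_id, tool.value)
            hits[tool] = False

    horvu_rec = annotations.get((ident.protein_id, Organism.HORVU))
    horvu = uniprot_state(horvu_rec, cfg)

    hit = homology.get(ident.protein_id)
    gated = apply_homology_gate(hit, cfg)
    arath_rec = None
    if gated:
        arath_rec = annotations.get((hit.subject_id, Organism.ARATH))
    arath = uniprot_state(arath_rec, cfg) if gated else UniProtState.ABSENT

    texts = []
    if horvu_rec is not None and horvu_rec.subcellular_location_text:
        texts.append(horvu_rec.subcellular_location_text)
    if arath_rec is not None and arath_rec.subcellular_location_text:
        texts.append(arath_rec.subcellular_location_text)
    cytosolic = any(_contains_any(t, cfg.cytosolic_tags) for t in texts)

    return LocalizationEvidence(
        protein_id=ident.protein_id,
        tool_hits=hits,
        uniprot_horvu=horvu,
        uniprot_arath=arath,
        cytosolic_tagged=cytosolic,
        homolog=hit if gated else None,
    )


def combined_uniprot_state(ev: LocalizationEvidence, cfg: EvidenceConfig) -> UniProtState:
    """Single UniProt state used by the first classification round.

    The barley record takes precedence; when it is absent, a gated
    Arabidopsis nuclear record substitutes (annotation transfer by
    homology) unless strict-HORVU mode is configured.
    """
    if ev.uniprot_horvu is not UniProtState.ABSENT:
        return ev.uniprot_horvu
    if cfg.arath_substitutes and ev.uniprot_arath is not UniProtState.ABSENT:
        return ev.uniprot_arath
    return UniProtState.ABSENT


def strict_horvu(cfg: EvidenceConfig) -> EvidenceConfig:
    """Variant config where only barley records count in round one."""
    return replace(cfg, arath_substitutes=False)
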