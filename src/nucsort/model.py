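"""Core data model for the chromosome-proteome triage pipeline.

The records here mirror the tables a gel-free chromosome proteomics
experiment produces after the database search: protein-group
identifications with spectral counts, BLAST best hits against a
well-annotated reference organism (Arabidopsis), subcellular-localization
predictor outputs, UniProt annotation rows, and conserved-domain hits.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field


class Tool(str, enum.Enum):
    """The four-member subcellular localization predictor panel."""

    LOCALIZER = "LOCALIZER"
    NUCPRED = "NUCPRED"
    WEGOLOC = "WEGOLOC"
    CELLO2GO = "CELLO2GO"


class Organism(str, enum.Enum):
    HORVU = "HORVU"  # Hordeum vulgare (barley)
    ARATH = "ARATH"  # Arabidopsis thaliana


class UniProtState(str, enum.Enum):
    """Tri-state outcome of tag-matching a UniProt subcellular-location text."""

    NUCLEAR = "nuclear"
    NON_NUCLEAR = "non_nuclear"
    ABSENT = "absent"


@dataclass(frozen=True)
class ProteinIdentification:
    """One protein-group representative from the search-engine output.

    ``neg_log_p`` is the PEAKS-style −logP confidence score (higher is more
    confident); ``spectral_counts`` maps run identifiers to
    peptide-spectrum-match counts.
    """

    protein_id: str
    description: str
    length: int
    neg_log_p: float
    unique_peptides: int
    total_peptides: int
    spectral_counts: dict[str, int] = field(default_factory=dict)
    group_id: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.protein_id}: length must be >= 1")
        if not 0 <= self.unique_peptides <= self.total_peptides:
            raise ValueError(
                f"{self.protein_id}: need 0 <= unique_peptides <= total_peptides"
            )
        if any(c < 0 for c in self.spectral_counts.values()):
            raise ValueError(f"{self.protein_id}: negative spectral count")


@dataclass(frozen=True)
class HomologyHit:
    """Best blastp hit of a barley query against an ARATH subject."""

    query_id: str
    subject_id: str
    homology_percent: float
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.homology_percent <= 100.0:
            raise ValueError(f"{self.query_id}: homology percent outside [0, 100]")
        if self.e_value < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


@dataclass(frozen=True)
class AnnotationRecord:
    """UniProt-style annotation row.

    ``subcellular_location_text`` of ``None`` means the field is absent from
    the entry, which is distinct from an empty string.
    """

    accession: str
    organism: Organism
    subcellular_location_text: str | None = None
    go_terms: tuple[str, ...] = ()
    protein_name: str = ""


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain (CD-Search style) hit on a protein sequence."""

    protein_id: str
    domain_accession: str
    e_value: float = 0.0
    start: int = 1
    end: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.protein_id}/{self.domain_accession}: bad interval "
                f"[{self.start}, {self.end}]"
            )


@dataclass(frozen=True)
class PredictorOutput:
    """One localization-predictor output row for one protein."""

    protein_id: str
    tool: Tool
    score: float | None = None
    localization_text: str | None = None

    def __post_init__(self) -> None:
        if self.tool is Tool.NUCPRED and self.score is None:
            raise ValueError(f"{self.protein_id}: NucPred row requires a numeric score")
        if self.tool is not Tool.NUCPRED and self.localization_text is None:
            raise ValueError(
                f"{self.protein_id}: {self.tool.value} row requires localization text"
            )
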