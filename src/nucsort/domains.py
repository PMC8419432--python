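"""Conserved-domain attribute database and per-protein domain scoring.

The second classification round asks whether a protein carries a domain
that, in this experiment, is characteristic of nuclear proteins.  The
attribute database is built from the round-one calls themselves: a domain
carried by NUCLEAR / PREDICTED_NUCLEAR / POSSIBLY_NUCLEAR proteins is
attributed *nuclear*, one carried by CYTOSOLIC proteins *false*; carriers
outside those groups contribute nothing, and conflicting carriers resolve
by majority of distinct carrier proteins with ties falling to *unknown*.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .model import DomainHit
from .s1 import S1Category

logger = logging.getLogger(__name__)

_NUCLEAR_SIDE = {
    S1Category.NUCLEAR,
    S1Category.PREDICTED_NUCLEAR,
    S1Category.POSSIBLY_NUCLEAR,
}


class DomainAttribute(str, enum.Enum):
    NUCLEAR = "nuclear"
    FALSE = "false"
    UNKNOWN = "unknown"


class ProteinDomainAttribute(str, enum.Enum):
    """Protein-level summary of its domains' attributes."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"
    NO_DOMAIN_INFO = "no_domain_info"


@dataclass(frozen=True)
class DomainEntry:
    attribute: DomainAttribute
    nuclear_support: int
    cytosolic_support: int


@dataclass(frozen=True)
class DomainAttributeDB:
    entries: dict[str, DomainEntry]

    def __len__(self) -> int:
        return len(self.entries)

    def attribute_of(self, domain_accession: str) -> DomainAttribute:
        entry = self.entries.get(domain_accession)
        return entry.attribute if entry is not None else DomainAttribute.UNKNOWN

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "domain_accession": acc,
                    "attribute": e.attribute.value,
                    "nuclear_support": e.nuclear_support,
                    "cytosolic_support": e.cytosolic_support,
                }
                for acc, e in sorted(self.entries.items())
            ],
            columns=["domain_accession", "attribute", "nuclear_support", "cytosolic_support"],
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "DomainAttributeDB":
        df = pd.read_csv(path, sep="\t", dtype={"domain_accession": str})
        return cls(
            {
                str(r.domain_accession): DomainEntry(
                    DomainAttribute(r.attribute),
                    int(r.nuclear_support),
                    int(r.cytosolic_support),
                )
                for r in df.itertuples(index=False)
            }
        )


def _resolve(nuclear_support: int, cytosolic_support: int) -> DomainAttribute:
    if nuclear_support > cytosolic_support:
        return DomainAttribute.NUCLEAR
    if cytosolic_support > nuclear_support:
        return DomainAttribute.FALSE
    return DomainAttribute.UNKNOWN


def build_domain_db(
    s1_calls: dict[str, S1Category], domain_hits: list[DomainHit]
) -> DomainAttributeDB:
    """Attribute every observed domain from the round-one calls of its carriers.

    Support counts are distinct carrier proteins, not hit rows, so a
    multi-hit protein cannot inflate its domains.  Hits on proteins absent
    from the call map are skipped with a warning.
    """
    nuclear_carriers: dict[str, set[str]] = defaultdict(set)
    cytosolic_carriers: dict[str, set[str]] = defaultdict(set)
    observed: set[str] = set()
    for hit in domain_hits:
        cat = s1_calls.get(hit.protein_id)
        if cat is None:
            logger.warning(
                "domain hit %s on unclassified protein %s skipped",
                hit.domain_accession,
                hit.protein_id,
            )
            continue
        observed.add(hit.domain_accession)
        if cat in _NUCLEAR_SIDE:
            nuclear_carriers[hit.domain_accession].add(hit.protein_id)
        elif cat is S1Category.CYTOSOLIC:
            cytosolic_carriers[hit.domain_accession].add(hit.protein_id)
    entries = {}
    for acc in observed:
        ns = len(nuclear_carriers.get(acc, ()))
        cs = len(cytosolic_carriers.get(acc, ()))
        entries[acc] = DomainEntry(_resolve(ns, cs), ns, cs)
    return DomainAttributeDB(entries)


def score_protein_domains(
    protein_id: str, hits: list[DomainHit], db: DomainAttributeDB
) -> ProteinDomainAttribute:
    """Summarize a protein's domain evidence against the attribute database.

    At least one nuclear domain and no false one scores *true*; at least
    one false and no nuclear scores *false*; mixed or all-unknown scores
    *unknown* (any false evidence vetoes true, keeping round two
    conservative).  A protein with no domain hits has no domain
    information at all.
    """
    own = [h for h in hits if h.protein_id == protein_id]
    if not own:
        return ProteinDomainAttribute.NO_DOMAIN_INFO
    attrs = {db.attribute_of(h.domain_accession) for h in own}
    has_nuclear = DomainAttribute.NUCLEAR in attrs
    has_false = DomainAttribute.FALSE in attrs
    if has_nuclear and not has_false:
        return ProteinDomainAttribute.TRUE
    if has_false and not has_nuclear:
        return ProteinDomainAttribute.FALSE
    return ProteinDomainAttribute.UNKNOWN
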