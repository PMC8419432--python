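"""Round-two (S2) categorization, the S1/S2 consensus merge, category
summaries, and the keyword census against a reference protein list.

Round two is stricter than round one: it demands a near-unanimous
predictor vote, distinguishes whether the nuclear UniProt record belongs
to the barley accession itself (NUCLEAR) or only to its Arabidopsis
homolog (NUCLEAR_BLAST), and requires a *true* domain attribute for either
of those top groups.  Proteins without any conserved-domain information
cannot be evaluated and form their own group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .domains import ProteinDomainAttribute
from .evidence import EvidenceConfig, LocalizationEvidence
from .model import UniProtState
from .s1 import S1Category, S1_NUCLEAR_SIDE


class S2Category(str, enum.Enum):
    NUCLEAR = "NUCLEAR"
    NUCLEAR_BLAST = "NUCLEAR_BLAST"
    POSSIBLY_NUCLEAR = "POSSIBLY_NUCLEAR"
    UNSUFFICIENT_CD_INFO = "UNSUFFICIENT_CD_INFO"
    DISCREPANCY_UNIPROT = "DISCREPANCY_UNIPROT"
    NON_NUCLEAR = "NON_NUCLEAR"


class FinalLabel(str, enum.Enum):
    NUCLEAR_S1_AND_S2 = "nuclear_s1_and_s2"
    NUCLEAR_S1_EXTRA = "nuclear_s1_extra"
    NON_NUCLEAR = "non_nuclear"


#: S2 groups counted as confirmed nuclear when merging the two rounds.
S2_NUCLEAR_SIDE = frozenset(
    {S2Category.NUCLEAR, S2Category.NUCLEAR_BLAST, S2Category.POSSIBLY_NUCLEAR}
)


@dataclass(frozen=True)
class ConsensusCall:
    protein_id: str
    s1: S1Category
    s2: S2Category
    final_label: FinalLabel


def classify_s2(
    ev: LocalizationEvidence, ds: ProteinDomainAttribute, cfg: EvidenceConfig
) -> S2Category:
    """Assign the round-two category; total function, precedence order.

    With the default four-tool panel, "more than three nuclear prediction
    hits" means a unanimous vote (``s2_strong_hit_min = 4``) and "less than
    three" means at most two (``s2_weak_hit_below = 3``); a vote of exactly
    three is covered by neither phrase and falls through to the discrepancy
    or non-nuclear rules.
    """
    n = ev.hit_count
    horvu_nuclear = ev.uniprot_horvu is UniProtState.NUCLEAR
    arath_nuclear = ev.uniprot_arath is UniProtState.NUCLEAR

    if ds is ProteinDomainAttribute.NO_DOMAIN_INFO:
        return S2Category.UNSUFFICIENT_CD_INFO
    if n >= cfg.s2_strong_hit_min and horvu_nuclear and ds is ProteinDomainAttribute.TRUE:
        return S2Category.NUCLEAR
    if (
        n >= cfg.s2_strong_hit_min
        and not horvu_nuclear
        and arath_nuclear
        and ds is ProteinDomainAttribute.TRUE
    ):
        return S2Category.NUCLEAR_BLAST
    if n < cfg.s2_weak_hit_below and (horvu_nuclear or arath_nuclear):
        return S2Category.POSSIBLY_NUCLEAR
    if not horvu_nuclear and not arath_nuclear and n >= 2:
        return S2Category.DISCREPANCY_UNIPROT
    return S2Category.NON_NUCLEAR


def merge_s1_s2(s1: S1Category, s2: S2Category) -> FinalLabel:
    """Consensus of the two rounds.

    A protein confirmed on both rounds is nuclear by consensus; one that
    only round one placed on the nuclear side is an extra, non-overlapping
    nuclear candidate; everything else is non-nuclear.
    """
    if s1 in S1_NUCLEAR_SIDE and s2 in S2_NUCLEAR_SIDE:
        return FinalLabel.NUCLEAR_S1_AND_S2
    if s1 in S1_NUCLEAR_SIDE:
        return FinalLabel.NUCLEAR_S1_EXTRA
    return FinalLabel.NON_NUCLEAR


def percent_one_decimal(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal, as printed in summaries."""
    if total <= 0:
        raise ValueError("total must be positive")
    return float(
        (Decimal(100) * Decimal(count) / Decimal(total)).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


def summarize_categories(
    calls: list[ConsensusCall],
    nsaf: pd.Series | None = None,
    by: str = "s2",
) -> pd.DataFrame:
    """Per-category ID counts, one-decimal percentages and NSAF shares.

    ``by`` selects the grouping level: ``"s1"``, ``"s2"`` or ``"final"``.
    ``nsaf`` is an optional per-protein NSAF series; category shares of its
    total are reported as fractions.
    """
    if not calls:
        raise ValueError("no calls to summarize")
    if by == "s1":
        keys = {c.protein_id: c.s1.value for c in calls}
        order = [c.value for c in S1Category]
    elif by == "s2":
        keys = {c.protein_id: c.s2.value for c in calls}
        order = [c.value for c in S2Category]
    elif by == "final":
        keys = {c.protein_id: c.final_label.value for c in calls}
        order = [c.value for c in FinalLabel]
    else:
        raise ValueError("by must be 's1', 's2' or 'final'")
    total = len(keys)
    counts = pd.Series(list(keys.values())).value_counts()
    rows = []
    nsaf_total = float(nsaf.sum()) if nsaf is not None else None
    for cat in order:
        k = int(counts.get(cat, 0))
        row = {"category": cat, "id_count": k, "id_percent": percent_one_decimal(k, total)}
        if nsaf is not None:
            members = [p for p, c in keys.items() if c == cat]
            share = float(nsaf.reindex(members).fillna(0.0).sum())
            row["nsaf_share"] = share / nsaf_total if nsaf_total else 0.0
        rows.append(row)
    row = {"category": "TOTAL", "id_count": total, "id_percent": 100.0}
    if nsaf is not None:
        row["nsaf_share"] = 1.0 if nsaf_total else 0.0
    rows.append(row)
    return pd.DataFrame(rows)


def keyword_census(
    names: dict[str, str],
    search_strings: list[str],
    reference_ids: set[str] | None = None,
) -> pd.DataFrame:
    """Count proteins whose name/description contains each search string.

    ``names`` maps protein id → name text (barley description, optionally
    concatenated with the homolog's name).  A protein found in
    ``reference_ids`` counts as *matched* (already present in the reference
    nuclear-protein list), otherwise as *novel*; with no reference list all
    proteins are novel.  A protein may count under several strings.
    """
    if not search_strings:
        raise ValueError("search strings must be non-empty")
    ref = reference_ids or set()
    rows = []
    for s in search_strings:
        low = s.lower()
        hits = [pid for pid, text in names.items() if low in text.lower()]
        novel = sum(1 for pid in hits if pid not in ref)
        rows.append(
            {
                "search_string": s,
                "novel": novel,
                "matched": len(hits) - novel,
                "total": len(hits),
            }
        )
    return pd.DataFrame(rows, columns=["search_string", "novel", "matched", "total"])
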