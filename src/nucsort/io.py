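"""Readers, writers and table-level filters for the external input formats.

All tabular inputs are plain TSV with headers; the proteome is standard
multi-record FASTA (Biopython), and homology comes as 12-column BLAST
tabular (``outfmt 6``; an optional 13th percent-positives column is
accepted).  Every reader returns the typed records in :mod:`nucsort.model`;
every writer emits a file the matching reader round-trips losslessly.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights

from .model import (
    AnnotationRecord,
    DomainHit,
    HomologyHit,
    Organism,
    PredictorOutput,
    ProteinIdentification,
    Tool,
)

logger = logging.getLogger(__name__)

#: Average mass of one water molecule, subtracted from free amino-acid
#: weights to obtain residue (monomer-in-chain) masses.
WATER_MASS = 18.0153

ID_TABLE_FIXED_COLUMNS = [
    "group_id",
    "protein_id",
    "description",
    "length",
    "neg_log_p",
    "unique_peptides",
    "total_peptides",
]


# ---------------------------------------------------------------------------
# identification table


def read_identifications(path: str | Path) -> list[ProteinIdentification]:
    """Read an identification TSV; columns after the fixed seven are run ids."""
    df = pd.read_csv(path, sep="\t", dtype={"group_id": str, "protein_id": str})
    missing = [c for c in ID_TABLE_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing identification columns {missing}")
    run_cols = [c for c in df.columns if c not in ID_TABLE_FIXED_COLUMNS]
    out = []
    for i, row in enumerate(df.to_dict("records")):
        if pd.isna(row["neg_log_p"]):
            raise ValueError(
                f"{path}: row {i + 2} ({row['protein_id']}) lacks neg_log_p"
            )
        counts = {c: 0 if pd.isna(row[c]) else int(row[c]) for c in run_cols}
        out.append(
            ProteinIdentification(
                protein_id=str(row["protein_id"]),
                description="" if pd.isna(row["description"]) else str(row["description"]),
                length=int(row["length"]),
                neg_log_p=float(row["neg_log_p"]),
                unique_peptides=int(row["unique_peptides"]),
                total_peptides=int(row["total_peptides"]),
                spectral_counts=counts,
                group_id=str(row["group_id"]),
            )
        )
    return out


def write_identifications(
    ids: Sequence[ProteinIdentification], path: str | Path
) -> None:
    run_cols = sorted({r for p in ids for r in p.spectral_counts})
    rows = []
    for p in ids:
        row = {
            "group_id": p.group_id if p.group_id is not None else p.protein_id,
            "protein_id": p.protein_id,
            "description": p.description,
            "length": p.length,
            "neg_log_p": p.neg_log_p,
            "unique_peptides": p.unique_peptides,
            "total_peptides": p.total_peptides,
        }
        for c in run_cols:
            row[c] = p.spectral_counts.get(c, 0)
        rows.append(row)
    pd.DataFrame(rows, columns=ID_TABLE_FIXED_COLUMNS + run_cols).to_csv(
        path, sep="\t", index=False
    )


def select_group_representatives(
    rows: Iterable[ProteinIdentification],
) -> list[ProteinIdentification]:
    """Keep one representative per protein group.

    Members without at least one unique peptide are not eligible; among the
    eligible members the one with the highest −logP score wins (ties broken
    by more unique peptides, then lexicographic protein id).  Groups with no
    eligible member are dropped and logged.
    """
    groups: dict[str, list[ProteinIdentification]] = defaultdict(list)
    for r in rows:
        groups[r.group_id if r.group_id is not None else r.protein_id].append(r)
    out = []
    for gid in sorted(groups):
        eligible = [m for m in groups[gid] if m.unique_peptides >= 1]
        if not eligible:
            logger.warning("group %s dropped: no member with a unique peptide", gid)
            continue
        out.append(
            max(eligible, key=lambda m: (m.neg_log_p, m.unique_peptides, m.protein_id))
        )
    seen: set[str] = set()
    for r in out:
        if r.protein_id in seen:
            raise ValueError(f"duplicate representative accession {r.protein_id}")
        seen.add(r.protein_id)
    return out


# ---------------------------------------------------------------------------
# BLAST tabular


def parse_blast_best_hits(
    stream: TextIO | str | Path, metric: str = "identity"
) -> dict[str, HomologyHit]:
    """Reduce BLAST outfmt-6 rows to one best hit per query.

    Best = highest bit score; ties broken by lowest e-value, then
    lexicographically smallest subject id.  ``metric`` selects which column
    fills ``homology_percent``: ``identity`` (column 3) or ``similarity``
    (optional column 13, percent positives).
    """
    if isinstance(stream, (str, Path)):
        with open(stream) as fh:
            return parse_blast_best_hits(fh, metric=metric)
    best: dict[str, HomologyHit] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) not in (12, 13):
            raise ValueError(
                f"BLAST tabular line {lineno}: expected 12 or 13 columns, "
                f"got {len(parts)}"
            )
        qseqid, sseqid = parts[0], parts[1]
        pident = float(parts[2])
        evalue = float(parts[10])
        bitscore = float(parts[11])
        if metric == "similarity":
            if len(parts) < 13:
                raise ValueError(
                    f"BLAST tabular line {lineno}: similarity metric requested "
                    "but no percent-positives column present"
                )
            percent = float(parts[12])
        else:
            percent = pident
        hit = HomologyHit(qseqid, sseqid, percent, bitscore, evalue)
        prev = best.get(qseqid)
        if prev is None or _blast_key(hit) < _blast_key(prev):
            best[qseqid] = hit
    return best


def _blast_key(h: HomologyHit) -> tuple[float, float, str]:
    return (-h.bit_score, h.e_value, h.subject_id)


# ---------------------------------------------------------------------------
# predictor, annotation and domain tables


def read_predictor_table(path: str | Path, tool: Tool) -> list[PredictorOutput]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        if tool is Tool.NUCPRED:
            out.append(PredictorOutput(str(row.protein_id), tool, score=float(row.score)))
        else:
            out.append(
                PredictorOutput(
                    str(row.protein_id), tool, localization_text=str(row.localization)
                )
            )
    return out


def write_predictor_table(
    outputs: Sequence[PredictorOutput], path: str | Path
) -> None:
    if outputs and outputs[0].tool is Tool.NUCPRED:
        df = pd.DataFrame(
            {"protein_id": [o.protein_id for o in outputs],
             "score": [o.score for o in outputs]}
        )
    else:
        df = pd.DataFrame(
            {"protein_id": [o.protein_id for o in outputs],
             "localization": [o.localization_text for o in outputs]}
        )
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[tuple[str, Organism], AnnotationRecord]:
    """Read the annotation TSV into a map keyed by (accession, organism).

    Duplicate keys: last-read wins with a warning.  An empty
    subcellular_location cell is read back as absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=[])
    out: dict[tuple[str, Organism], AnnotationRecord] = {}
    for row in df.itertuples(index=False):
        org = Organism(row.organism)
        key = (str(row.accession), org)
        if key in out:
            logger.warning("duplicate annotation for %s/%s: last wins", *key)
        loc = row.subcellular_location if row.subcellular_location != "" else None
        go = tuple(t for t in str(row.go_terms).split(";") if t)
        out[key] = AnnotationRecord(str(row.accession), org, loc, go, str(row.protein_name))
    return out


def write_annotations(
    records: Iterable[AnnotationRecord], path: str | Path
) -> None:
    rows = [
        {
            "accession": r.accession,
            "organism": r.organism.value,
            "subcellular_location": r.subcellular_location_text or "",
            "go_terms": ";".join(r.go_terms),
            "protein_name": r.protein_name,
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=["accession", "organism", "subcellular_location", "go_terms", "protein_name"],
    ).to_csv(path, sep="\t", index=False)


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_accession": str})
    return [
        DomainHit(
            str(r.protein_id), str(r.domain_accession),
            float(r.e_value), int(r.start), int(r.end),
        )
        for r in df.itertuples(index=False)
    ]


def write_domain_hits(hits: Sequence[DomainHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "protein_id": h.protein_id,
                "domain_accession": h.domain_accession,
                "e_value": h.e_value,
                "start": h.start,
                "end": h.end,
            }
            for h in hits
        ],
        columns=["protein_id", "domain_accession", "e_value", "start", "end"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# proteome FASTA and bulk amino-acid composition

#: Average residue masses (free amino acid minus one water), Da.
RESIDUE_MASSES = {aa: w - WATER_MASS for aa, w in protein_weights.items()}


def read_proteome(path: str | Path) -> dict[str, str]:
    """Read a FASTA proteome into an id → sequence map."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_proteome(sequences: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid, seq in sequences.items():
            fh.write(f">{pid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def compute_trp_mass_fraction(sequences: Iterable[str]) -> float:
    """Bulk tryptophan mass fraction of a proteome.

    Returns Σ mass(W residues) / Σ mass(all residues) over every sequence,
    using average residue masses.  Ambiguity codes (X, B, Z, ...) are
    skipped with a logged count.  This is the bulk-composition assumption
    behind converting a tryptophan-fluorescence reading into peptide mass.
    """
    trp_mass = 0.0
    total_mass = 0.0
    skipped = 0
    n_seq = 0
    w = RESIDUE_MASSES
    for seq in sequences:
        n_seq += 1
        for aa in seq.upper():
            m = w.get(aa)
            if m is None:
                skipped += 1
                continue
            total_mass += m
            if aa == "W":
                trp_mass += m
    if n_seq == 0 or total_mass == 0.0:
        raise ValueError("no sequences")
    if skipped:
        logger.info("skipped %d non-standard residues", skipped)
    frac = trp_mass / total_mass
    assert 0.0 <= frac <= 1.0 and math.isfinite(frac)
    return frac
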