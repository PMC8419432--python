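"""End-to-end driver: evidence bundle in, consensus calls out.

Chains the stages — group-representative selection, evidence assembly,
round-one categorization, domain-attribute database construction,
round-two categorization, and the consensus merge — over one coherent
bundle of input tables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as nio
from .domains import DomainAttributeDB, build_domain_db, score_protein_domains
from .evidence import EvidenceConfig, LocalizationEvidence, assemble_evidence
from .model import (
    AnnotationRecord,
    DomainHit,
    HomologyHit,
    Organism,
    PredictorOutput,
    ProteinIdentification,
    Tool,
)
from .s1 import S1Category, classify_s1
from .s2 import ConsensusCall, classify_s2, merge_s1_s2

PREDICTOR_FILES = {
    Tool.LOCALIZER: "predictor_localizer.tsv",
    Tool.NUCPRED: "predictor_nucpred.tsv",
    Tool.WEGOLOC: "predictor_wegoloc.tsv",
    Tool.CELLO2GO: "predictor_cello2go.tsv",
}


@dataclass
class EvidenceBundle:
    """Everything one analysis consumes, in memory."""

    identifications: list[ProteinIdentification]
    predictor_outputs: list[PredictorOutput]
    annotations: dict[tuple[str, Organism], AnnotationRecord]
    blast_best: dict[str, HomologyHit]
    domain_hits: list[DomainHit]
    proteome: dict[str, str] = field(default_factory=dict)
    truth: dict[str, str] | None = None

    def write(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        nio.write_identifications(self.identifications, d / "identifications.tsv")
        by_tool: dict[Tool, list[PredictorOutput]] = defaultdict(list)
        for out in self.predictor_outputs:
            by_tool[out.tool].append(out)
        for tool, fname in PREDICTOR_FILES.items():
            nio.write_predictor_table(by_tool.get(tool, []), d / fname)
        nio.write_annotations(self.annotations.values(), d / "annotations.tsv")
        with open(d / "blast.tsv", "w") as fh:
            for q in sorted(self.blast_best):
                h = self.blast_best[q]
                fh.write(
                    f"{h.query_id}\t{h.subject_id}\t{h.homology_percent:.1f}\t100\t0\t0\t"
                    f"1\t100\t1\t100\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
                )
        nio.write_domain_hits(self.domain_hits, d / "domains.tsv")
        if self.proteome:
            nio.write_proteome(self.proteome, d / "proteome.fasta")
        if self.truth is not None:
            pd.DataFrame(
                {"protein_id": list(self.truth), "true_class": list(self.truth.values())}
            ).to_csv(d / "truth.tsv", sep="\t", index=False)


def read_bundle(directory: str | Path) -> EvidenceBundle:
    d = Path(directory)
    predictor_outputs: list[PredictorOutput] = []
    for tool, fname in PREDICTOR_FILES.items():
        p = d / fname
        if p.exists():
            predictor_outputs.extend(nio.read_predictor_table(p, tool))
    truth = None
    if (d / "truth.tsv").exists():
        tdf = pd.read_csv(d / "truth.tsv", sep="\t", dtype=str)
        truth = dict(zip(tdf.protein_id, tdf.true_class))
    proteome = {}
    if (d / "proteome.fasta").exists():
        proteome = nio.read_proteome(d / "proteome.fasta")
    return EvidenceBundle(
        identifications=nio.read_identifications(d / "identifications.tsv"),
        predictor_outputs=predictor_outputs,
        annotations=nio.read_annotations(d / "annotations.tsv"),
        blast_best=nio.parse_blast_best_hits(d / "blast.tsv"),
        domain_hits=nio.read_domain_hits(d / "domains.tsv"),
        proteome=proteome,
        truth=truth,
    )


@dataclass
class PipelineResult:
    calls: list[ConsensusCall]
    evidence: dict[str, LocalizationEvidence]
    domain_db: DomainAttributeDB
    representatives: list[ProteinIdentification]

    @property
    def s1_calls(self) -> dict[str, S1Category]:
        return {c.protein_id: c.s1 for c in self.calls}

    @property
    def final_labels(self) -> dict[str, str]:
        return {c.protein_id: c.final_label.value for c in self.calls}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            ev = self.evidence[c.protein_id]
            rows.append(
                {
                    "protein_id": c.protein_id,
                    "s1": c.s1.value,
                    "s2": c.s2.value,
                    "final_label": c.final_label.value,
                    "hit_count": ev.hit_count,
                    "uniprot_horvu": ev.uniprot_horvu.value,
                    "uniprot_arath": ev.uniprot_arath.value,
                    "cytosolic_tagged": ev.cytosolic_tagged,
                }
            )
        return pd.DataFrame(rows)


def run_pipeline(
    bundle: EvidenceBundle,
    cfg: EvidenceConfig | None = None,
    domain_db: DomainAttributeDB | None = None,
) -> PipelineResult:
    """Run both classification rounds over a bundle.

    ``domain_db`` may carry a frozen attribute database built from an
    earlier experiment; by default the database is rebuilt from this
    bundle's own round-one calls.
    """
    cfg = cfg or EvidenceConfig()
    reps = nio.select_group_representatives(bundle.identifications)

    outputs_by_protein: dict[str, list[PredictorOutput]] = defaultdict(list)
    for out in bundle.predictor_outputs:
        outputs_by_protein[out.protein_id].append(out)
    hits_by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in bundle.domain_hits:
        hits_by_protein[h.protein_id].append(h)

    evidence: dict[str, LocalizationEvidence] = {}
    s1_calls: dict[str, S1Category] = {}
    for ident in reps:
        ev = assemble_evidence(
            ident,
            outputs_by_protein.get(ident.protein_id, []),
            bundle.annotations,
            bundle.blast_best,
            cfg,
        )
        evidence[ident.protein_id] = ev
        s1_calls[ident.protein_id] = classify_s1(ev, cfg)

    relevant_hits = [h for h in bundle.domain_hits if h.protein_id in s1_calls]
    if domain_db is None:
        domain_db = build_domain_db(s1_calls, relevant_hits)

    calls = []
    for ident in reps:
        pid = ident.protein_id
        ds = score_protein_domains(pid, hits_by_protein.get(pid, []), domain_db)
        s2 = classify_s2(evidence[pid], ds, cfg)
        calls.append(ConsensusCall(pid, s1_calls[pid], s2, merge_s1_s2(s1_calls[pid], s2)))
    return PipelineResult(calls, evidence, domain_db, reps)
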