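"""Synthetic evidence generator with known ground truth.

Emulates the statistical structure of a flow-sorted chromosome proteomics
experiment: a cohort of proteins split into nuclear/chromatin,
nucleolar/perichromosomal and cytosolic/other truth classes; four
localization predictors with class-dependent hit rates; patchy UniProt
annotation for the barley accessions and denser annotation for their
Arabidopsis homologs behind a homology gate; class-segregated
conserved-domain pools with cross-contamination; and spectral counts over
three sample types × three biological × two technical replicates, with
nuclear-side proteins enriched in sorted chromosomes and depleted in the
chromosome-depleted fraction.

Nucleolar/perichromosomal proteins are a distinct truth class that counts
as nuclear-positive in evaluation, reflecting that nucleolar proteins
(e.g. fibrillarin) coat mitotic chromosomes.

An exact-counts mode bypasses the stochastic models and writes evidence
rows that deterministically trigger a requested per-category outcome, for
worked-example checks against printed category tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AnnotationRecord,
    DomainHit,
    HomologyHit,
    Organism,
    PredictorOutput,
    ProteinIdentification,
    Tool,
)
from .pipeline import EvidenceBundle
from .quant import BIO_REPS, SAMPLE_TYPES, TECH_REPS, run_id

NUCLEAR_CLASSES = ("nuclear_chromatin", "nucleolar_perichromosomal")
ALL_CLASSES = NUCLEAR_CLASSES + ("cytosolic_other",)

#: Amino-acid frequencies approximating a plant proteome; the tryptophan
#: frequency puts the bulk Trp mass fraction near 1.95%.
AA_FREQUENCIES = {
    "A": 0.0770, "R": 0.0530, "N": 0.0430, "D": 0.0520, "C": 0.0180,
    "Q": 0.0360, "E": 0.0620, "G": 0.0670, "H": 0.0230, "I": 0.0530,
    "L": 0.0930, "K": 0.0600, "M": 0.0240, "F": 0.0400, "P": 0.0490,
    "S": 0.0820, "T": 0.0510, "W": 0.0115, "Y": 0.0290, "V": 0.0680,
}

_NUCLEAR_LOC_TEXTS = (
    "Nucleus",
    "Nucleus, nucleolus",
    "Nucleus, nucleoplasm",
    "Chromosome",
    "Chromosome, centromere",
    "Nucleus; Chromosome",
)
_CYTOSOLIC_LOC_TEXTS = (
    "Cytoplasm",
    "Cytoplasm, cytosol",
    "Mitochondrion",
    "Cell membrane",
    "Mitochondrion membrane",
)
_PREDICTOR_NUCLEAR_TEXTS = ("Nucleus", "nuclear", "Nucleus, chromosome")
_PREDICTOR_OTHER_TEXTS = ("Cytoplasm", "Plastid", "Extracellular", "Mitochondrion")

_NUCLEAR_NAMES = (
    "Histone H2A", "Histone H2B", "Histone H3.1", "Histone H1",
    "DNA replication licensing factor MCM2", "DNA helicase",
    "Chromatin remodeling ATPase", "Condensin complex subunit 1",
    "Cohesin subunit SCC3", "Kinesin-like protein", "Kinetochore protein NDC80",
    "Fibrillarin 1", "DNA topoisomerase 2", "Structural maintenance of chromosomes protein",
    "Nucleosome assembly protein 1", "DNA-directed RNA polymerase II subunit",
)
_OTHER_NAMES = (
    "ATP synthase subunit beta", "Ribulose bisphosphate carboxylase",
    "Actin-7", "Tubulin alpha chain", "Heat shock protein 70",
    "Glyceraldehyde-3-phosphate dehydrogenase", "Elongation factor 1-alpha",
    "V-type proton ATPase subunit", "40S ribosomal protein S3",
    "60S ribosomal protein L5",
)
_UNCHARACTERIZED = "Uncharacterized protein"


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of a simulated cohort.

    Defaults reflect the real experiment's design: three sample types in
    3 biological × 2 technical replicates; ~15% of the identifiable
    cohort nuclear-side; nuclear-side proteins ~3.5× more abundant on
    sorted chromosomes and slightly depleted in the chromosome-depleted
    fraction, while the cytosolic background is modestly more abundant
    everywhere; sparse barley annotation (half the accessions carry a
    subcellular-location text) against well-annotated Arabidopsis
    homologs.
    """

    n_proteins: int = 1000
    class_priors: dict[str, float] = field(
        default_factory=lambda: {
            "nuclear_chromatin": 0.10,
            "nucleolar_perichromosomal": 0.05,
            "cytosolic_other": 0.85,
        }
    )
    #: per-tool probability that a nuclear-side protein gets a nuclear call
    tool_sensitivity: dict[Tool, float] = field(
        default_factory=lambda: {t: 0.80 for t in Tool}
    )
    #: per-tool probability that a cytosolic protein gets a non-nuclear call
    tool_specificity: dict[Tool, float] = field(
        default_factory=lambda: {t: 0.92 for t in Tool}
    )
    annotation_coverage: float = 0.50
    annotation_accuracy: float = 0.90
    homolog_coverage: float = 0.85
    arath_annotation_coverage: float = 0.90
    arath_annotation_accuracy: float = 0.95
    #: beta(a, b) scaled to [low, high] percent identity of the best hit
    homology_identity_beta: tuple[float, float] = (5.0, 2.0)
    homology_identity_range: tuple[float, float] = (40.0, 100.0)
    n_nuclear_domains: int = 60
    n_cytosolic_domains: int = 120
    mean_domains_per_protein: float = 1.2
    domain_cross_contamination: float = 0.05
    #: expected spectral counts per technical run, per class and sample type
    abundance_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "nuclear_chromatin": {
                "sorted_chromosomes": 7.0, "homogenate": 2.0, "depleted_fraction": 1.6,
            },
            "nucleolar_perichromosomal": {
                "sorted_chromosomes": 7.0, "homogenate": 2.0, "depleted_fraction": 1.6,
            },
            "cytosolic_other": {
                "sorted_chromosomes": 2.6, "homogenate": 2.6, "depleted_fraction": 2.6,
            },
        }
    )
    detection_scale: float = 1.0
    protein_length_lognorm: tuple[float, float] = (5.8, 0.45)  # mean ~ 360 aa
    #: fraction of groups given an extra low-score member (exercises
    #: group-representative selection)
    decoy_group_member_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.class_priors.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class priors sum to {total}, not 1")
        if set(self.class_priors) != set(ALL_CLASSES):
            raise ValueError(f"class priors must cover exactly {ALL_CLASSES}")
        for d in (self.tool_sensitivity, self.tool_specificity):
            for v in d.values():
                if not 0.0 <= v <= 1.0:
                    raise ValueError("tool rates must lie in [0, 1]")
        for p in (
            self.annotation_coverage, self.annotation_accuracy,
            self.homolog_coverage, self.arath_annotation_coverage,
            self.arath_annotation_accuracy, self.domain_cross_contamination,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    classes: dict[str, str]  # protein_id -> truth class

    def is_nuclear(self, protein_id: str) -> bool:
        return self.classes[protein_id] in NUCLEAR_CLASSES


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    aas = list(AA_FREQUENCIES)
    probs = np.array(list(AA_FREQUENCIES.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(aas, size=length, p=probs))


def generate_cohort(cfg: CohortConfig) -> tuple[GroundTruth, EvidenceBundle]:
    """Draw a fully labeled cohort and every downstream evidence table.

    Deterministic given ``cfg.seed``: the same config yields a
    byte-identical bundle on disk.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_proteins
    classes = list(cfg.class_priors)
    truth_classes = rng.choice(
        classes, size=n, p=[cfg.class_priors[c] for c in classes]
    )
    ids = [f"HORVU.SIM.{i + 1:05d}" for i in range(n)]
    truth = GroundTruth(dict(zip(ids, truth_classes)))

    lengths = np.clip(
        rng.lognormal(*cfg.protein_length_lognorm, size=n).astype(int), 60, 5000
    )
    proteome = {pid: _random_sequence(rng, int(L)) for pid, L in zip(ids, lengths)}

    names = []
    for cls in truth_classes:
        if rng.random() < 0.35:
            names.append(_UNCHARACTERIZED)
        elif cls in NUCLEAR_CLASSES:
            names.append(str(rng.choice(_NUCLEAR_NAMES)))
        else:
            names.append(str(rng.choice(_OTHER_NAMES)))

    # predictor outputs -----------------------------------------------------
    predictor_outputs: list[PredictorOutput] = []
    for pid, cls in zip(ids, truth_classes):
        nuclear_true = cls in NUCLEAR_CLASSES
        for tool in Tool:
            p_hit = (
                cfg.tool_sensitivity[tool]
                if nuclear_true
                else 1.0 - cfg.tool_specificity[tool]
            )
            hit = rng.random() < p_hit
            if tool is Tool.NUCPRED:
                score = rng.uniform(0.5, 1.0) if hit else rng.uniform(0.0, 0.4999)
                predictor_outputs.append(PredictorOutput(pid, tool, score=round(score, 3)))
            else:
                pool = _PREDICTOR_NUCLEAR_TEXTS if hit else _PREDICTOR_OTHER_TEXTS
                predictor_outputs.append(
                    PredictorOutput(pid, tool, localization_text=str(rng.choice(pool)))
                )

    # annotations and homology ---------------------------------------------
    annotations: dict[tuple[str, Organism], AnnotationRecord] = {}
    blast_best: dict[str, HomologyHit] = {}
    a, b = cfg.homology_identity_beta
    lo, hi = cfg.homology_identity_range
    for i, (pid, cls, name) in enumerate(zip(ids, truth_classes, names)):
        nuclear_true = cls in NUCLEAR_CLASSES
        if rng.random() < cfg.annotation_coverage:
            accurate = rng.random() < cfg.annotation_accuracy
            pool = (
                _NUCLEAR_LOC_TEXTS
                if nuclear_true == accurate
                else _CYTOSOLIC_LOC_TEXTS
            )
            annotations[(pid, Organism.HORVU)] = AnnotationRecord(
                pid, Organism.HORVU, str(rng.choice(pool)), (), name
            )
        if rng.random() < cfg.homolog_coverage:
            subject = f"ARATH.SIM.{i + 1:05d}"
            ident = lo + (hi - lo) * rng.beta(a, b)
            blast_best[pid] = HomologyHit(
                pid, subject, round(float(ident), 1),
                bit_score=round(float(rng.uniform(80, 500)), 1),
                e_value=float(10 ** rng.uniform(-120, -10)),
            )
            if rng.random() < cfg.arath_annotation_coverage:
                accurate = rng.random() < cfg.arath_annotation_accuracy
                pool = (
                    _NUCLEAR_LOC_TEXTS
                    if nuclear_true == accurate
                    else _CYTOSOLIC_LOC_TEXTS
                )
                annotations[(subject, Organism.ARATH)] = AnnotationRecord(
                    subject, Organism.ARATH, str(rng.choice(pool)), (), name
                )

    # conserved-domain hits -------------------------------------------------
    nuclear_pool = [f"ND{i:04d}" for i in range(cfg.n_nuclear_domains)]
    cytosolic_pool = [f"CD{i:04d}" for i in range(cfg.n_cytosolic_domains)]
    domain_hits: list[DomainHit] = []
    for pid, cls, L in zip(ids, truth_classes, lengths):
        k = rng.poisson(cfg.mean_domains_per_protein)
        own, other = (
            (nuclear_pool, cytosolic_pool)
            if cls in NUCLEAR_CLASSES
            else (cytosolic_pool, nuclear_pool)
        )
        seen: set[str] = set()
        for _ in range(k):
            pool = other if rng.random() < cfg.domain_cross_contamination else own
            acc = str(rng.choice(pool))
            if acc in seen:
                continue
            seen.add(acc)
            start = int(rng.integers(1, max(2, L - 50)))
            end = min(int(L), start + int(rng.integers(30, 120)))
            domain_hits.append(
                DomainHit(pid, acc, float(10 ** rng.uniform(-40, -3)), start, end)
            )

    # spectral counts: 3 sample types x 3 bio x 2 tech ----------------------
    protein_effect = rng.lognormal(0.0, 0.8, size=n)
    counts: dict[str, np.ndarray] = {}
    for st in SAMPLE_TYPES:
        means = np.array(
            [cfg.abundance_means[c][st] for c in truth_classes]
        ) * protein_effect * cfg.detection_scale
        for b_rep in BIO_REPS:
            bio_effect = rng.lognormal(0.0, 0.25, size=n)
            for t_rep in TECH_REPS:
                lam = means * bio_effect * rng.lognormal(0.0, 0.1, size=n)
                counts[run_id(st, b_rep, t_rep)] = rng.poisson(lam)

    count_df = pd.DataFrame(counts, index=ids)
    detected = count_df.sum(axis=1) > 0

    identifications: list[ProteinIdentification] = []
    for pid, cls, name, L in zip(ids, truth_classes, names, lengths):
        if not detected[pid]:
            continue
        total_spc = int(count_df.loc[pid].sum())
        unique = max(1, int(rng.poisson(1 + total_spc / 8)))
        total_pep = unique + int(rng.poisson(total_spc / 4))
        neg_log_p = round(float(20 + rng.exponential(35)), 2)
        identifications.append(
            ProteinIdentification(
                protein_id=pid,
                description=name,
                length=int(L),
                neg_log_p=neg_log_p,
                unique_peptides=unique,
                total_peptides=total_pep,
                spectral_counts={c: int(v) for c, v in count_df.loc[pid].items()},
                group_id=pid,
            )
        )
        # occasionally add a weaker same-group member that must lose
        if rng.random() < cfg.decoy_group_member_rate:
            identifications.append(
                ProteinIdentification(
                    protein_id=pid + ".iso",
                    description=name,
                    length=int(L),
                    neg_log_p=round(neg_log_p - float(rng.uniform(1, 15)), 2),
                    unique_peptides=0,
                    total_peptides=int(rng.integers(0, 3)),
                    spectral_counts={},
                    group_id=pid,
                )
            )

    bundle = EvidenceBundle(
        identifications=identifications,
        predictor_outputs=[
            o for o in predictor_outputs if detected.get(o.protein_id, False)
        ],
        annotations=annotations,
        blast_best={q: h for q, h in blast_best.items() if detected.get(q, False)},
        domain_hits=[h for h in domain_hits if detected.get(h.protein_id, False)],
        proteome=proteome,
        truth={pid: cls for pid, cls in truth.classes.items() if detected[pid]},
    )
    detected_truth = GroundTruth(dict(bundle.truth))
    return detected_truth, bundle


# ---------------------------------------------------------------------------
# recovery evaluation


def evaluate_recovery(
    predicted_nuclear: set[str], truth: GroundTruth
) -> dict[str, float]:
    """Confusion-matrix metrics of a nuclear/chromosomal call set.

    Both nuclear truth classes count as positive.  Degenerate denominators
    yield NaN with a warning.
    """
    pos = {p for p in truth.classes if truth.is_nuclear(p)}
    neg = set(truth.classes) - pos
    tp = len(predicted_nuclear & pos)
    fp = len(predicted_nuclear & neg)
    fn = len(pos - predicted_nuclear)
    tn = len(neg - predicted_nuclear)

    def _ratio(num: int, den: int, what: str) -> float:
        if den == 0:
            warnings.warn(f"{what} undefined (empty denominator)")
            return float("nan")
        return num / den

    return {
        "sensitivity": _ratio(tp, tp + fn, "sensitivity"),
        "specificity": _ratio(tn, tn + fp, "specificity"),
        "precision": _ratio(tp, tp + fp, "precision"),
        "tp": float(tp), "fp": float(fp), "fn": float(fn), "tn": float(tn),
    }


# ---------------------------------------------------------------------------
# exact-counts mode

#: Evidence recipes that deterministically land a protein in one outcome of
#: the two-round scheme.  Each entry: (hit_count, horvu_text, arath_text,
#: shared_domain or None).  ``None`` text means no record.
EXACT_RECIPES: dict[str, tuple[int, str | None, str | None, str | None]] = {
    "nuclear": (4, "Nucleus", None, "EXN_NUC"),
    "nuclear_blast": (4, None, "Nucleus", "EXN_NB"),
    "possibly_nuclear": (2, "Nucleus", None, "EXN_POS"),
    "discrepancy_uniprot": (4, "Cytoplasm", None, "EXD_DU"),
    "unsufficient_cd": (4, "Nucleus", None, None),
    "s1_s2_inconsistent": (3, "Nucleus", None, "EXN_INC"),
    "non_nuclear": (0, "Cytoplasm", None, "EXC_CYT"),
}

_TOOL_ORDER = (Tool.LOCALIZER, Tool.NUCPRED, Tool.WEGOLOC, Tool.CELLO2GO)


def generate_exact_counts(requested: dict[str, int]) -> EvidenceBundle:
    """Build a deterministic cohort whose category tallies equal ``requested``.

    Keys are :data:`EXACT_RECIPES` outcome names; each protein's evidence is
    written so that exactly that outcome fires when the full pipeline runs
    (including the domain-attribute database built from the cohort's own
    round-one calls).  No randomness is involved.
    """
    unknown = set(requested) - set(EXACT_RECIPES)
    if unknown:
        raise ValueError(f"unknown exact-count outcomes: {sorted(unknown)}")
    identifications: list[ProteinIdentification] = []
    predictor_outputs: list[PredictorOutput] = []
    annotations: dict[tuple[str, Organism], AnnotationRecord] = {}
    blast_best: dict[str, HomologyHit] = {}
    domain_hits: list[DomainHit] = []

    for outcome, count in requested.items():
        hit_count, horvu_text, arath_text, domain = EXACT_RECIPES[outcome]
        for i in range(count):
            pid = f"EXC.{outcome.upper()}.{i + 1:05d}"
            identifications.append(
                ProteinIdentification(
                    protein_id=pid,
                    description=f"synthetic {outcome} protein",
                    length=300,
                    neg_log_p=50.0,
                    unique_peptides=3,
                    total_peptides=5,
                    spectral_counts={run_id("sorted_chromosomes", 1, 1): 5},
                    group_id=pid,
                )
            )
            for j, tool in enumerate(_TOOL_ORDER):
                hit = j < hit_count
                if tool is Tool.NUCPRED:
                    predictor_outputs.append(
                        PredictorOutput(pid, tool, score=0.95 if hit else 0.05)
                    )
                else:
                    predictor_outputs.append(
                        PredictorOutput(
                            pid, tool,
                            localization_text="Nucleus" if hit else "Cytoplasm",
                        )
                    )
            if horvu_text is not None:
                annotations[(pid, Organism.HORVU)] = AnnotationRecord(
                    pid, Organism.HORVU, horvu_text, (), f"synthetic {outcome} protein"
                )
            if arath_text is not None:
                subject = f"ARATH.{outcome.upper()}.{i + 1:05d}"
                blast_best[pid] = HomologyHit(pid, subject, 85.0, 300.0, 1e-80)
                annotations[(subject, Organism.ARATH)] = AnnotationRecord(
                    subject, Organism.ARATH, arath_text, (), f"synthetic {outcome} homolog"
                )
            if domain is not None:
                domain_hits.append(DomainHit(pid, domain, 1e-10, 10, 90))

    return EvidenceBundle(
        identifications=identifications,
        predictor_outputs=predictor_outputs,
        annotations=annotations,
        blast_best=blast_best,
        domain_hits=domain_hits,
    )
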