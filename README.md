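# nucsort

Rule-based triage of nuclear/chromosomal proteins identified on
flow-sorted mitotic chromosomes, with spectral-count quantification.

## The problem

Proteomic analysis of flow-sorted plant chromosomes (here: barley,
*Hordeum vulgare*) identifies thousands of proteins, but chromosome
preparations inevitably carry cytosolic contamination. Because the barley
proteome is sparsely annotated, no single resource can say which
identifications are genuinely nuclear/chromosomal. `nucsort` implements a
two-round, multi-classifier consensus that combines four subcellular
localization predictors (Localizer, NucPred, WegoLoc, CELLO2GO), UniProtKB
subcellular-location annotation for the barley accession and — through a
70 % homology gate on the best blastp hit — for its *Arabidopsis thaliana*
(ARATH) homolog, and an experiment-derived conserved-domain attribute
database. It is aimed at proteomics analysts who have search-engine output
(protein groups, spectral counts), predictor exports and annotation tables
in hand and need a reproducible, auditable classification plus an
enrichment comparison across sample types.

## The method

**Round one (S1).** Each protein gets a vote vector: the number of
predictor nuclear calls *n* ∈ {0..4} (NucPred positive at score ≥ 0.50,
the text tools by tag matching), a tri-state UniProt record
(nuclear / non-nuclear / absent, via the tags `chromos`, `chromat`,
`nucl`), and a cytosolic flag (`cytos`, `cytop`, `mitoch`, `memb`,
`recept`). Six groups are assigned by precedence: NUCLEAR (*n* > 2 and a
nuclear record), PREDICTED NUCLEAR (*n* > 2, no record), DISCREPANCY
UNIPROT (*n* > 2, non-nuclear record), POSSIBLY NUCLEAR (*n* = 2, nuclear
record), DISCREPANCY PREDICTION (*n* < 2, nuclear record), CYTOSOLIC
(cytosolic-tagged, at most one nuclear hit), plus an explicit
NON-CLASSIFIED fall-through.

**Domain attributes.** Conserved domains carried by round-one
NUCLEAR / PREDICTED NUCLEAR / POSSIBLY NUCLEAR proteins are attributed
*nuclear*; domains of CYTOSOLIC proteins are *false*; conflicts resolve by
majority of distinct carriers, ties and unobserved domains are *unknown*.

**Round two (S2)** re-evaluates with a stricter vote: NUCLEAR needs a
unanimous panel (*n* > 3), a nuclear barley record and a *true* domain
attribute; NUCLEAR (BLAST) is the same but with the nuclear record only on
the gated ARATH homolog; POSSIBLY NUCLEAR covers *n* < 3 with a nuclear
record; proteins without any domain information form UNSUFFICIENT CD INFO;
non-nuclear records with *n* ≥ 2 are DISCREPANCY UNIPROT. The final
consensus labels a protein `nuclear_s1_and_s2` (both rounds nuclear-side),
`nuclear_s1_extra` (round one only), or `non_nuclear`.

**Quantification.** Technical runs are summed, proteins must appear in
≥ 2 of 3 biological replicates, and abundance is the normalized spectral
abundance factor

    NSAF_i = (SpC_i / L_i) / Σ_k (SpC_k / L_k)

with SpC the spectral count and L the protein length. A
tryptophan-fluorescence assay converts measured Trp mass to peptide mass
assuming the proteome's bulk Trp content (1.95 % by mass for barley).

A seeded synthetic generator (`nucsort.simulate`) emulates the whole
evidence structure — compartment-dependent predictor hit rates, patchy
annotation, homology transfer, class-segregated domain pools, and
sample-type-dependent spectral abundance over 3 biological × 2 technical
replicates — so the pipeline is testable end to end without downloads.

## Worked example

```sh
$ nucsort simulate --n-proteins 300 --seed 4 --out demo
$ nucsort classify demo
            category  id_count  id_percent
             NUCLEAR         3         1.0
       NUCLEAR_BLAST         5         1.7
    POSSIBLY_NUCLEAR        26         8.7
UNSUFFICIENT_CD_INFO        79        26.3
 DISCREPANCY_UNIPROT        13         4.3
         NON_NUCLEAR       174        58.0
               TOTAL       300       100.0
recovery: sensitivity 1.000 specificity 1.000 precision 1.000
```

Of 300 simulated identifications, 34 end on the nuclear side of round two
(NUCLEAR + NUCLEAR (BLAST) + POSSIBLY NUCLEAR); because the bundle carries
ground truth, the consensus call is also scored against it — at this seed
every truly nuclear protein is recovered with no false positives.
`nucsort quantify demo` then prints per-sample-type ID and NSAF shares;
in the same simulation the nuclear NSAF share is ~21 % on sorted
chromosomes versus ~5–7 % in the homogenate and depleted fraction,
the enrichment signature the experiment is designed to detect.

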