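# Methods

## Scope and data model

`nucsort` operates downstream of the database search: its inputs are a
protein-group identification table (accession, −logP confidence,
unique/total peptide counts, per-run spectral counts, length), a proteome
FASTA, 12-column BLAST tabular best hits against Arabidopsis, one output
table per localization predictor, a UniProt-style annotation table and a
conserved-domain hit table. Raw spectra, the search itself, and the
predictors' internals are outside the boundary; their exported tables are
the interface.

Group filtering follows spectral-counting convention: a protein group is
represented by its highest-scoring member among those with at least one
unique peptide; groups with no such member are dropped. Exact −logP ties
are broken by more unique peptides, then lexicographic accession, so the
selection is deterministic. Missing spectral-count cells are zeros, not
missing values. An optional q-value column, when present, can be
filtered on; FDR control is otherwise assumed to have happened upstream
in the search engine.

## Evidence assembly

The vote vector per protein has three parts.

* **Predictor panel.** Four tools, fixed: a missing output row counts as
  a negative vote, because the group definitions are phrased over a fixed
  four-tool panel. NucPred is thresholded at 0.50 inclusive; the text
  tools match tags case-insensitively as substrings (`nucl` for WegoLoc
  and Localizer; `nucl`/`chromo` for CELLO2GO).
* **UniProt record.** Tri-state per organism: *nuclear* if the
  subcellular-location text contains `chromos`, `chromat` or `nucl`;
  *absent* if there is no record or no location text (distinct from an
  empty string); *non-nuclear* otherwise. The Arabidopsis record is
  consulted only when the best blastp hit reaches the 70 % homology gate
  (boundary inclusive). The gate metric is percent identity by default
  with a config switch to percent positives, since "homology" is used
  loosely across resources.
* **Cytosolic flag.** True if either the barley or the gated Arabidopsis
  location text contains any of `cytos`, `cytop`, `mitoch`, `memb`,
  `recept`.

For round one the two organisms collapse to a single record state: the
barley record wins; a gated Arabidopsis record substitutes only when the
barley record is absent (annotation transfer by homology). A barley
non-nuclear record is therefore not overridden by a nuclear homolog —
round two handles that disagreement explicitly via the NUCLEAR (BLAST)
group. A strict-barley mode disables substitution entirely.

## Classification rules and their edge cells

Both rounds are total functions applied in precedence order; the test
suite checks them exhaustively against independently coded rule tables
(90 evidence points for round one, 180 for round two).

Genuinely open cells were resolved as follows:

* Round one, *n* = 2 with no record: assigned NON-CLASSIFIED — no
  published group covers it.
* POSSIBLY NUCLEAR requires a nuclear-tagged record by default; a config
  flag relaxes this to "any record present".
* Round two, "more than three nuclear prediction hits" on a four-tool
  panel means a unanimous vote; `s2_strong_hit_min` exposes the threshold
  (the original tally may have counted the database record as a fifth
  classifier). A vote of exactly three is covered by neither "more than
  three" nor "less than three" and falls through to the discrepancy or
  non-nuclear rules; widening the strong rule to ≥ 3 is a config change.
* UNSUFFICIENT CD INFO is tested first in round two because it is defined
  by the absence of domain information regardless of other evidence.

## Domain-attribute database

Attributes are derived from the cohort's own round-one calls: a domain's
nuclear support is its number of distinct NUCLEAR / PREDICTED NUCLEAR /
POSSIBLY NUCLEAR carriers, its false support the distinct CYTOSOLIC
carriers; the attribute is the majority side, with ties (including 0–0)
*unknown*. Distinct carriers, not hit rows, prevent multi-hit inflation.
Protein-level scoring is conservative: any *false* domain vetoes *true*
and yields *unknown*. The database serializes to TSV and can be frozen
and reused across runs (`run_pipeline(..., domain_db=...)`), supporting
both build-and-freeze and per-run-rebuild workflows; which the original
study used is not documented, so both are first-class.

## Quantification

NSAF is computed per biological sample after technical-replicate pooling
(summation); the pooling level is a design choice here, as the source
protocol does not state it. Sample-type aggregates are the mean of the
three biological-replicate NSAF columns over the replicate-filtered
protein set, renormalized. Replicate presence means ≥ 1 pooled spectral
count; no minimum-count threshold is imposed. Protein length is the
residue count of the identified database sequence.

The tryptophan assay fits an ordinary least-squares line (scipy
`linregress`) through ≥ 3 standards spanning a nonzero range
(0.01–5.0 µg µL⁻¹ in the original protocol); inversion plus division by
the proteome bulk Trp mass fraction (default 0.0195) converts fluorescence
to peptide mass. Average residue masses (free amino acid minus one water,
Biopython's IUPAC table) are used for the bulk composition, matching the
bulk-mass character of the assay; ambiguity codes are skipped.
Extrapolation outside the calibrated response range and negative inferred
masses are warned (the latter clipped to zero).

## Synthetic cohorts

The generator emulates the experiment's statistical structure, not its
molecules: truth classes {nuclear_chromatin, nucleolar_perichromosomal,
cytosolic_other} with priors (0.10, 0.05, 0.85); per-tool sensitivity
0.80 and specificity 0.92; barley annotation coverage 0.50 with accuracy
0.90 against Arabidopsis homolog coverage 0.85, annotation coverage 0.90,
accuracy 0.95 and percent identity Beta(5, 2) scaled to [40, 100] (≈ 80 %
of homologs pass the 70 % gate); class-segregated domain pools (60
nuclear, 120 cytosolic accessions) with 5 % cross-contamination and a
Poisson(1.2) domain count, so a realistic fraction of proteins has no
domain information at all; and Poisson spectral counts over
3 sample types × 3 biological × 2 technical runs with lognormal protein,
replicate and run effects. The nucleolar/perichromosomal class counts as
nuclear-positive in evaluation, reflecting that nucleolar proteins coat
mitotic chromosomes.

Expected counts per technical run are 7.0 / 2.0 / 1.6 for nuclear-side
proteins on sorted chromosomes / homogenate / depleted fraction (a 3.5×
enrichment and a 0.8× depletion) against a flat 2.6 for the cytosolic
background; these were chosen once so the simulated nuclear NSAF share
lands near 30 % on sorted chromosomes and near 10 % elsewhere, the regime
the real experiment reports, while nuclear identifications stay below
20 % of IDs in every sample type. Detection is implicit in the Poisson
model: the probability of at least one count is 1 − exp(−λ), a saturating
function of abundance; `detection_scale` rescales λ. The amino-acid
frequency vector approximates a plant proteome with the tryptophan
frequency (1.15 mol %) placed so the bulk Trp mass fraction is ≈ 1.95 %.

What the generator does *not* emulate: peptide-level identification and
shared peptides (protein groups are trivial except for injected low-score
decoy members), correlated predictor errors (tools err independently,
which is optimistic — real predictors share training data), biased
annotation (coverage is independent of abundance), and compositional
count correlation beyond the NSAF closure itself. Passing recovery tests
therefore shows the rules and plumbing are correct under the stated error
model, not that the classifier achieves any particular accuracy on real
chromosomal preparations.

The exact-counts mode is deterministic: for each requested outcome it
writes evidence rows that provably trigger one rule path (including the
domain database the cohort itself induces), so published per-category
inventories can be replayed through the full pipeline and their printed
sums checked exactly. The "inconsistent between rounds" outcome is
realized as a unanimous-minus-one vote (3 of 4) with a nuclear record and
nuclear domain: round one calls it NUCLEAR, round two's threshold
structure leaves it NON-NUCLEAR — the cleanest cell that lands
round-one-nuclear / round-two-outside without touching the no-domain or
discrepancy tallies.

## Problem sizes and numerics

Default test and acceptance cohorts use 80–1000 proteins; exact-counts
replays run at the published inventory sizes (4139 and 2941). Percentages
are rendered by half-up rounding to one decimal (`decimal` module), which
reproduces every checked printed percentage; banker's rounding does not.
NSAF columns sum to 1 within 1e-9 and are invariant to count rescaling.
All randomness flows through one `numpy` `default_rng(seed)`; the same
config is byte-reproducible on disk.

## Known limitations

* The evidence model is rule-based by design; no probabilistic calibration
  of predictor votes is attempted.
* GO terms are carried through but never voted on.
* The homology gate consults only the single best blastp hit.
* The published combined inventories (837 nuclear/chromosomal proteins
  across both arms; 674 in the SCX arm) depend on the deposited
  supplementary identification lists and cannot be recomputed from
  printed category counts alone; the corresponding check runs only when
  those lists are provided locally.
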