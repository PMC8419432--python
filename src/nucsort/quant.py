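"""Spectral-count quantification and the tryptophan-fluorescence assay.

The quantitative arm of the workflow compares three sample types —
flow-sorted chromosomes, whole root-tip homogenate, and the
chromosome-depleted fraction — each measured in three biological
replicates with two technical runs apiece.  Technical runs are pooled by
summation, proteins must appear in at least two of the three biological
replicates to be considered, and abundance is expressed as the normalized
spectral abundance factor

    NSAF_i = (SpC_i / L_i) / Σ_k (SpC_k / L_k)

where SpC is a protein's spectral count and L its sequence length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SAMPLE_TYPES = ("sorted_chromosomes", "homogenate", "depleted_fraction")
BIO_REPS = (1, 2, 3)
TECH_REPS = (1, 2)

RUN_LEVELS = ("sample_type", "bio_rep", "tech_rep")


def run_id(sample_type: str, bio_rep: int, tech_rep: int) -> str:
    """Flat run identifier used as a spectral-count column name."""
    return f"{sample_type}.b{bio_rep}.t{tech_rep}"


def parse_run_id(run: str) -> tuple[str, int, int]:
    sample_type, b, t = run.rsplit(".", 2)
    return sample_type, int(b[1:]), int(t[1:])


def to_sample_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    """Lift a flat-run-column count table to (sample_type, bio_rep, tech_rep).

    Input columns are flat run ids (``sorted_chromosomes.b1.t2``); the
    output carries a three-level column MultiIndex.  Cells must be
    non-negative; missing cells are zero.
    """
    counts = counts.fillna(0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative spectral counts")
    tuples = [parse_run_id(c) for c in counts.columns]
    out = counts.copy()
    out.columns = pd.MultiIndex.from_tuples(tuples, names=RUN_LEVELS)
    return out.sort_index(axis=1)


def pool_technical_replicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over technical runs; presence is the union of runs."""
    return matrix.T.groupby(level=["sample_type", "bio_rep"]).sum().T


def filter_replicated(pooled: pd.DataFrame, min_reps: int = 2) -> dict[str, list[str]]:
    """Per sample type, keep proteins present in ≥ min_reps biological replicates.

    Presence means at least one pooled spectral count.  Returns a map
    sample_type → sorted list of kept protein ids.
    """
    kept: dict[str, list[str]] = {}
    for st in pooled.columns.get_level_values("sample_type").unique():
        block = pooled[st]
        n_reps = block.shape[1]
        if min_reps > n_reps:
            raise ValueError(
                f"min_reps={min_reps} exceeds the {n_reps} biological replicates of {st}"
            )
        present = (block > 0).sum(axis=1)
        kept[st] = sorted(block.index[present >= min_reps])
    return kept


def compute_nsaf(counts: pd.Series, lengths: pd.Series) -> pd.Series:
    """NSAF column for one biological sample.

    Zero-count proteins get NSAF 0; the nonzero entries sum to 1.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths < 1).any():
        raise ValueError("every protein needs a length >= 1")
    saf = counts / lengths
    total = saf.sum()
    if total == 0:
        raise ValueError("empty sample: all spectral counts are zero")
    return saf / total


def nsaf_table(pooled: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """NSAF per (sample_type, bio_rep) column of a pooled count matrix."""
    cols = {}
    for col in pooled.columns:
        cols[col] = compute_nsaf(pooled[col], lengths)
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["sample_type", "bio_rep"])
    return out


def category_share(
    pooled: pd.DataFrame,
    lengths: pd.Series,
    labels: dict[str, str],
    min_reps: int = 2,
) -> pd.DataFrame:
    """Per sample type and category: ID share and NSAF share.

    Shares are computed over the replicate-filtered protein set of each
    sample type; the NSAF of a sample type is the mean of its
    biological-replicate NSAF columns (restricted to kept proteins and
    renormalized).  Both measures are fractions summing to 1 within a
    sample type.
    """
    kept = filter_replicated(pooled, min_reps=min_reps)
    rows = []
    for st, proteins in kept.items():
        if not proteins:
            continue
        missing = [p for p in proteins if p not in labels]
        if missing:
            raise ValueError(f"{st}: {len(missing)} kept proteins lack a category call")
        block = pooled[st].loc[proteins]
        nsafs = []
        for rep in block.columns:
            if block[rep].sum() > 0:
                nsafs.append(compute_nsaf(block[rep], lengths))
        mean_nsaf = pd.concat(nsafs, axis=1).mean(axis=1)
        mean_nsaf = mean_nsaf / mean_nsaf.sum()
        cats = pd.Series({p: labels[p] for p in proteins})
        for cat in sorted(cats.unique()):
            members = cats.index[cats == cat]
            rows.append(
                {
                    "sample_type": st,
                    "category": cat,
                    "id_count": len(members),
                    "id_share": len(members) / len(proteins),
                    "nsaf_share": float(mean_nsaf.loc[members].sum()),
                }
            )
    return pd.DataFrame(
        rows, columns=["sample_type", "category", "id_count", "id_share", "nsaf_share"]
    )


# ---------------------------------------------------------------------------
# tryptophan-fluorescence peptide assay

#: Bulk tryptophan mass fraction of the barley proteome assumed when
#: converting measured tryptophan mass to total peptide mass.
DEFAULT_TRP_MASS_FRACTION = 0.0195


@dataclass(frozen=True)
class TrpCalibration:
    """Linear fluorescence-vs-tryptophan-mass calibration."""

    slope: float
    intercept: float
    residual_se: float
    valid_range: tuple[float, float]
    trp_mass_fraction: float = DEFAULT_TRP_MASS_FRACTION

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")


def fit_trp_calibration(
    standards: list[tuple[float, float]],
    trp_mass_fraction: float = DEFAULT_TRP_MASS_FRACTION,
) -> TrpCalibration:
    """Ordinary least-squares line through (trp_mass, fluorescence) standards.

    Requires at least three standards spanning a nonzero mass range; the
    standards' span becomes the calibration's valid range.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 calibration standards")
    x = np.array([s[0] for s in standards], dtype=float)
    y = np.array([s[1] for s in standards], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: standards span no mass range")
    fit = stats.linregress(x, y)
    resid = y - (fit.slope * x + fit.intercept)
    dof = max(len(x) - 2, 1)
    rse = float(np.sqrt(np.sum(resid**2) / dof))
    return TrpCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residual_se=rse,
        valid_range=(float(x.min()), float(x.max())),
        trp_mass_fraction=trp_mass_fraction,
    )


def trp_quantify(fluorescence: float, cal: TrpCalibration) -> float:
    """Convert a fluorescence reading to total peptide mass.

    Inverts the calibration line to tryptophan mass, then divides by the
    proteome's bulk tryptophan mass fraction.  Readings outside the
    calibrated response range are extrapolations (warned); a negative
    inferred tryptophan mass clips to zero with a warning.
    """
    trp_mass = (fluorescence - cal.intercept) / cal.slope
    lo, hi = cal.valid_range
    lo_resp = cal.slope * lo + cal.intercept
    hi_resp = cal.slope * hi + cal.intercept
    if not (min(lo_resp, hi_resp) <= fluorescence <= max(lo_resp, hi_resp)):
        warnings.warn("fluorescence outside calibrated response range; extrapolating")
    if trp_mass < 0:
        warnings.warn("negative inferred tryptophan mass clipped to 0")
        trp_mass = 0.0
    return trp_mass / cal.trp_mass_fraction
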