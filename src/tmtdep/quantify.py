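"""Peptide-to-protein relative quantification for TMT reporter intensities.

Three steps turn a peptide x sample reporter-intensity matrix I into
per-protein relative values R:

1. centralize:      U_ij = I_ij / mean_i(I_ij)   (per-peptide row mean)
2. median-correct:  NR_ij = U_ij / median_j(U_ij) (per-sample column median,
   removing channel loading bias)
3. rollup:          R_ik = median over protein k's *unique* observed
   peptides of NR_ij

All means and medians are over observed values only; missing cells stay
missing.  Shared peptides (more than one owner protein) never enter the
rollup.  The module also provides replicate-reproducibility QC (flagging
channels whose within-group correlation collapses) and MS/MS spectra
accounting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PeptideIntensityMatrix, ProteinQuantMatrix, RelativeQuantMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpectraAccounting:
    """MS/MS spectra and identification counts for a run."""

    total_spectra: int
    effective_spectra: int
    identified_peptides: int = 0
    specific_peptides: int = 0
    identified_proteins: int = 0
    quantifiable_proteins: int = 0

    def __post_init__(self) -> None:
        if self.effective_spectra > self.total_spectra:
            raise ValueError(
                f"effective spectra ({self.effective_spectra}) cannot exceed "
                f"total ({self.total_spectra})"
            )
        if self.specific_peptides > self.identified_peptides:
            raise ValueError("specific peptides cannot exceed identified peptides")
        if self.quantifiable_proteins > self.identified_proteins:
            raise ValueError("quantifiable proteins cannot exceed identified proteins")


def spectra_utilization(acc: SpectraAccounting) -> float:
    """Percent of acquired MS/MS spectra that were effective, to 1 decimal."""
    if acc.total_spectra <= 0:
        raise ValueError("total spectra must be positive")
    return round(100.0 * acc.effective_spectra / acc.total_spectra, 1)


def centralize(matrix: PeptideIntensityMatrix) -> RelativeQuantMatrix:
    """U_ij = I_ij / mean over samples of peptide j's observed intensities.

    Peptides with no observed value in any sample are dropped with a
    warning.  Fully observed rows end up with mean exactly 1.
    """
    vals = matrix.intensities
    all_missing = vals.isna().all(axis=1)
    if all_missing.any():
        dropped = list(vals.index[all_missing])
        logger.warning("dropping %d peptide(s) with no observed intensity: %s",
                       len(dropped), dropped[:5])
        vals = vals[~all_missing]
    row_mean = vals.mean(axis=1, skipna=True)
    u = vals.div(row_mean, axis=0)
    return RelativeQuantMatrix(u, matrix.groups.copy())


def median_correct(matrix: RelativeQuantMatrix) -> RelativeQuantMatrix:
    """NR_ij = U_ij / median over peptides of sample i's observed values.

    After correction every sample's observed median equals 1 exactly.
    """
    vals = matrix.values
    col_median = vals.median(axis=0, skipna=True)
    if col_median.isna().any():
        bad = list(col_median.index[col_median.isna()])
        raise ValueError(f"sample(s) with no observed value: {bad}")
    if (col_median == 0).any():
        bad = list(col_median.index[col_median == 0])
        raise ValueError(f"degenerate input: sample median is 0 for {bad}")
    nr = vals.div(col_median, axis=1)
    return RelativeQuantMatrix(nr, matrix.groups.copy())


def unique_peptides(peptide_map: Dict[str, Set[str]]) -> Dict[str, str]:
    """Peptides mapping to exactly one protein accession, as peptide->owner."""
    return {p: next(iter(owners)) for p, owners in peptide_map.items() if len(owners) == 1}


def rollup_protein(
    matrix: RelativeQuantMatrix,
    peptide_map: Dict[str, Set[str]],
    min_samples_per_group: int = 2,
) -> ProteinQuantMatrix:
    """R_ik = per-sample median of protein k's unique observed peptides.

    Shared peptides are excluded entirely.  A protein with no unique
    observed peptide in a sample is missing there; proteins whose unique
    peptides are observed in fewer than ``min_samples_per_group`` samples
    of any group are dropped as non-quantifiable.
    """
    unmapped = [p for p in matrix.values.index if p not in peptide_map]
    if unmapped:
        raise ValueError(f"peptide(s) absent from the peptide->protein map: {unmapped[:5]}")

    owner_of = unique_peptides(peptide_map)
    owners = pd.Series(
        [owner_of.get(p) for p in matrix.values.index], index=matrix.values.index
    ).dropna()
    sub = matrix.values.loc[owners.index]
    values = sub.groupby(owners).median()  # skips NaN; all-NaN slice -> NaN
    n_unique = sub.groupby(owners).size()

    groups = matrix.groups
    keep = pd.Series(True, index=values.index)
    for g in groups.unique():
        samples = list(groups.index[groups == g])
        keep &= values[samples].notna().sum(axis=1) >= min_samples_per_group
    values = values[keep].sort_index()
    n_unique = n_unique[keep].sort_index().astype(int)
    return ProteinQuantMatrix(values, matrix.groups.copy(), n_unique)


def protein_abundance(
    matrix: PeptideIntensityMatrix, peptide_map: Dict[str, Set[str]]
) -> ProteinQuantMatrix:
    """Per-sample raw protein abundance: median raw intensity of each
    protein's unique observed peptides (no normalization).

    This is the surface on which replicate reproducibility is judged:
    normalization deliberately removes the between-protein dynamic range,
    so sample-to-sample correlation must be measured before it.
    """
    owner_of = unique_peptides(peptide_map)
    vals = matrix.intensities
    owners = pd.Series([owner_of.get(p) for p in vals.index], index=vals.index).dropna()
    frame = vals.loc[owners.index].groupby(owners).median().sort_index()
    return ProteinQuantMatrix(frame, matrix.groups.copy())


def replicate_qc(
    matrix: ProteinQuantMatrix, floor: float = 0.8
) -> Tuple[List[str], pd.DataFrame]:
    """Flag within-group outlier channels by rank correlation.

    For every sample, the median Spearman correlation (on log-transformed,
    pairwise-complete protein values) against the other samples of its
    group is compared to ``floor``; samples below it are flagged for
    exclusion.  Pass a raw-abundance matrix (:func:`protein_abundance`),
    not a normalized one — normalization removes the shared structure the
    correlation measures.  Groups of fewer than 3 samples are skipped with
    a warning (a 2-sample group cannot isolate which member is the
    outlier).

    Returns (flagged sample IDs, full sample x sample Spearman matrix).
    """
    logged = np.log(matrix.values.where(matrix.values > 0))
    corr = logged.corr(method="spearman", min_periods=3)

    flagged: List[str] = []
    for g in matrix.groups.unique():
        samples = matrix.samples_of(g)
        if len(samples) < 3:
            logger.warning("group %s has %d samples; replicate QC skipped", g, len(samples))
            continue
        for s in samples:
            others = [t for t in samples if t != s]
            med = corr.loc[s, others].median()
            if med < floor:
                logger.warning(
                    "sample %s flagged: median within-group Spearman %.3f < floor %.3f",
                    s, med, floor,
                )
                flagged.append(s)
    return flagged, corr


def quantify(
    matrix: PeptideIntensityMatrix,
    peptide_map: Dict[str, Set[str]],
    min_samples_per_group: int = 2,
) -> ProteinQuantMatrix:
    """Full centralize -> median-correct -> unique-peptide rollup chain."""
    return rollup_protein(
        median_correct(centralize(matrix)), peptide_map, min_samples_per_group
    )
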