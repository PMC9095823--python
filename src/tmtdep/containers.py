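"""In-memory containers shared across the pipeline stages.

Both matrices are thin wrappers over a pandas DataFrame (rows = features,
columns = sample channels, NaN = missing) plus a per-sample group label
Series.  Intensities of exactly 0 are treated as missing on construction:
a reporter intensity of 0 means the ion was not observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_groups(values: pd.DataFrame, groups: pd.Series, min_per_group: int = 2) -> pd.Series:
    groups = groups.reindex(values.columns)
    if groups.isna().any():
        missing = list(groups.index[groups.isna()])
        raise ValueError(f"samples without a group label: {missing}")
    counts = groups.value_counts()
    small = counts[counts < min_per_group]
    if len(small):
        raise ValueError(
            f"each group needs >= {min_per_group} samples, got {counts.to_dict()}"
        )
    return groups.astype(str)


@dataclass
class PeptideIntensityMatrix:
    """Peptide x sample reporter intensities with group labels.

    ``intensities`` holds I (one row per peptide, one column per sample
    channel); missing observations are NaN.
    """

    intensities: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.intensities.index.duplicated().any():
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate peptide ID: {dup!r}")
        vals = self.intensities.astype(float)
        if (vals < 0).any().any():
            r, c = np.argwhere((vals < 0).to_numpy())[0]
            raise ValueError(
                f"negative intensity at peptide {vals.index[r]!r}, sample {vals.columns[c]!r}"
            )
        # reporter intensity 0 == not observed
        self.intensities = vals.mask(vals == 0)
        self.groups = _check_groups(self.intensities, self.groups)

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.columns)

    @property
    def peptide_ids(self) -> list:
        return list(self.intensities.index)

    def samples_of(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])

    def drop_samples(self, sample_ids) -> "PeptideIntensityMatrix":
        keep = [s for s in self.intensities.columns if s not in set(sample_ids)]
        return PeptideIntensityMatrix(self.intensities[keep].copy(), self.groups[keep].copy())

    def equals(self, other: "PeptideIntensityMatrix") -> bool:
        return (
            self.intensities.equals(other.intensities)
            and self.groups.equals(other.groups)
        )


@dataclass
class RelativeQuantMatrix:
    """Peptide x sample relative values (U after centralization, NR after
    median correction); same axes and missingness pattern as the source."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = _check_groups(self.values, self.groups)


@dataclass
class ProteinQuantMatrix:
    """Protein x sample relative quantitative values R.

    ``n_unique_peptides`` counts the unique (single-owner) peptides that
    contributed to each protein's rollup median.
    """

    values: pd.DataFrame
    groups: pd.Series
    n_unique_peptides: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        self.groups = _check_groups(self.values, self.groups)
        if self.n_unique_peptides is None:
            self.n_unique_peptides = pd.Series(np.nan, index=self.values.index)
        self.n_unique_peptides = self.n_unique_peptides.reindex(self.values.index)

    @property
    def protein_ids(self) -> list:
        return list(self.values.index)

    def samples_of(self, group: str) -> list:
        return list(self.groups.index[self.groups == group])

    def drop_samples(self, sample_ids) -> "ProteinQuantMatrix":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return ProteinQuantMatrix(
            self.values[keep].copy(), self.groups[keep].copy(), self.n_unique_peptides.copy()
        )
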