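"""Per-protein differential expression between two groups of channels.

Fold change is the ratio of group arithmetic means of the relative values
R (mutant over wild-type).  Significance is a two-sided two-sample t-test
on the per-channel R values.  Calls use strict thresholds — Up: FC > 1.30
and p < alpha; Down: FC < 0.77 and p < alpha — and differential proteins
are binned into severity categories Q1..Q4 by fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import ProteinQuantMatrix

logger = logging.getLogger(__name__)

NEGLOG10_P_CAP = 16.0  # ceiling for -log10(p) in the volcano table when p == 0


@dataclass
class DEPRecord:
    protein_id: str
    fold_change: float
    p_value: float
    regulation: str  # Up / Down / NS
    q_category: str  # Q1..Q4 / none


def fold_change(
    quant: ProteinQuantMatrix,
    numerator: str = "Hom",
    denominator: str = "Wt",
) -> pd.Series:
    """FC = mean R over numerator group / mean R over denominator group,
    arithmetic means of observed values.  Proteins whose denominator mean
    is 0 are excluded with a warning."""
    num = quant.values[quant.samples_of(numerator)].mean(axis=1, skipna=True)
    den = quant.values[quant.samples_of(denominator)].mean(axis=1, skipna=True)
    fc = num / den
    bad = den == 0
    if bad.any():
        logger.warning("excluding %d protein(s) with zero %s mean", int(bad.sum()), denominator)
        fc = fc[~bad]
    return fc.dropna()


def dep_test(
    quant: ProteinQuantMatrix,
    method: str = "student",
    log_transform: bool = False,
    group_a: str = "Wt",
    group_b: str = "Hom",
) -> pd.Series:
    """Two-sided two-sample t-test p-value per protein.

    ``method`` selects Student's equal-variance (default) or Welch's test.
    Degenerate rows (zero variance in both groups) get p = 1 when the
    means agree and p = 0 (flagged in the log) when they differ.
    """
    if method not in ("student", "welch"):
        raise ValueError(f"unknown test method {method!r}")
    a_cols = quant.samples_of(group_a)
    b_cols = quant.samples_of(group_b)
    vals = quant.values
    if log_transform:
        vals = np.log2(vals.where(vals > 0))
    a = vals[a_cols].to_numpy(dtype=float)
    b = vals[b_cols].to_numpy(dtype=float)
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    testable = (n_a >= 2) & (n_b >= 2)

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(
            a, b, axis=1, equal_var=(method == "student"), nan_policy="omit"
        )
        p = np.asarray(res.pvalue, dtype=float)

    # degenerate rows: zero variance in both groups
    sd_a = np.nanstd(a, axis=1, ddof=1)
    sd_b = np.nanstd(b, axis=1, ddof=1)
    flat = testable & (sd_a == 0) & (sd_b == 0)
    if flat.any():
        mean_eq = np.isclose(np.nanmean(a[flat], axis=1), np.nanmean(b[flat], axis=1))
        p[np.where(flat)[0][mean_eq]] = 1.0
        p[np.where(flat)[0][~mean_eq]] = 0.0
        if (~mean_eq).any():
            logger.warning(
                "%d protein(s) with zero variance and unequal means; p set to 0",
                int((~mean_eq).sum()),
            )
    p[~testable] = np.nan
    return pd.Series(p, index=vals.index, name="p_value").dropna()


def classify_dep(fc: float, p: float, config: PipelineConfig) -> str:
    """Strict-threshold call: Up / Down / NS."""
    if fc <= 0:
        raise ValueError(f"fold change must be positive, got {fc}")
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if fc > config.up_threshold and p < config.alpha:
        return "Up"
    if fc < config.down_threshold and p < config.alpha:
        return "Down"
    return "NS"


def assign_q(fc: float, regulation: str, config: PipelineConfig) -> str:
    """Severity bin for a differential call.

    Down calls split at the first edge (Q1: FC <= e0, else Q2); Up calls
    at the last (Q3: FC <= e3, else Q4).  The printed Q2 upper edge (0.769)
    sits just below the Down threshold (0.77); the sliver between them is
    assigned Q2 so the four bins partition the differential set.
    """
    e0, _, _, e3 = config.q_edges
    if regulation == "NS":
        return "none"
    if regulation == "Down":
        return "Q1" if fc <= e0 else "Q2"
    if regulation == "Up":
        return "Q3" if fc <= e3 else "Q4"
    raise ValueError(f"unknown regulation {regulation!r}")


def call_deps(
    quant: ProteinQuantMatrix,
    config: Optional[PipelineConfig] = None,
    numerator: str = "Hom",
    denominator: str = "Wt",
) -> List[DEPRecord]:
    """Fold change + t-test + threshold call + Q bin for every testable protein."""
    config = config or PipelineConfig()
    fc = fold_change(quant, numerator=numerator, denominator=denominator)
    p = dep_test(
        quant,
        method=config.test_method,
        log_transform=config.log_transform,
        group_a=denominator,
        group_b=numerator,
    )
    shared = fc.index.intersection(p.index)
    records = []
    for prot in shared:
        reg = classify_dep(float(fc[prot]), float(p[prot]), config)
        records.append(
            DEPRecord(
                protein_id=prot,
                fold_change=float(fc[prot]),
                p_value=float(p[prot]),
                regulation=reg,
                q_category=assign_q(float(fc[prot]), reg, config),
            )
        )
    return records


def dep_counts(records: Sequence[DEPRecord]) -> Dict[str, int]:
    """Up/Down/NS tallies plus the differential total (up + down)."""
    n_up = sum(1 for r in records if r.regulation == "Up")
    n_down = sum(1 for r in records if r.regulation == "Down")
    return {
        "n_tested": len(records),
        "n_up": n_up,
        "n_down": n_down,
        "n_dep": n_up + n_down,
        "n_ns": len(records) - n_up - n_down,
    }


def volcano_table(records: Sequence[DEPRecord]) -> pd.DataFrame:
    """Plot-ready volcano columns: log2 FC, -log10 p (capped), regulation."""
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "log2_fc": [np.log2(r.fold_change) for r in records],
            "neg_log10_p": [
                min(-np.log10(r.p_value), NEGLOG10_P_CAP) if r.p_value > 0 else NEGLOG10_P_CAP
                for r in records
            ],
            "regulation": [r.regulation for r in records],
        }
    )


def records_to_frame(records: Sequence[DEPRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in records],
            "fc": [r.fold_change for r in records],
            "log2fc": [np.log2(r.fold_change) for r in records],
            "p": [r.p_value for r in records],
            "regulation": [r.regulation for r in records],
            "q_category": [r.q_category for r in records],
        }
    )
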