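"""Targeted-versus-discovery concordance (PRM validation).

Parallel reaction monitoring (PRM) re-quantifies a handful of candidate
proteins with targeted high-resolution MS.  This module loads PRM/TMT
ratio tables, quantifies their agreement (sign concordance against 1.0,
rank correlation of log ratios, fold-change threshold pass count), and
provides per-group mean/SEM/t-test summaries for bar-plot style
comparisons.  The packaged fixture carries the 20 candidate proteins of
the Wt-vs-Hom mouse ileum study with their Hom/Wt ratios on both
platforms.
"""

from __future__ import annotations

import csv
import hashlib
import logging
from dataclasses import dataclass, asdict
from importlib import resources
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

_FIXTURE_NAME = "table1_prm.tsv"
_FIXTURE_SHA256 = "c370fcbcab37b4116bff34fcbaebe10862a4e44af93138f455d41bdf0c8de5da"

_PRM_COLUMNS = (
    "protein_id",
    "protein_name",
    "gene_name",
    "peptides",
    "prm_ratio",
    "tmt_ratio",
    "regulated_type",
)


@dataclass(frozen=True)
class PRMRecord:
    """One validated candidate: identifiers, monitored peptides, the
    Hom/Wt ratio from each platform, and the discovery-stage call."""

    protein_id: str
    protein_name: str
    gene_name: str
    peptides: Tuple[str, ...]
    prm_ratio: float
    tmt_ratio: float
    regulated_type: str

    def __post_init__(self) -> None:
        if self.prm_ratio <= 0 or self.tmt_ratio <= 0:
            raise ValueError(
                f"{self.protein_id}: ratios must be positive, "
                f"got prm={self.prm_ratio}, tmt={self.tmt_ratio}"
            )
        if self.regulated_type not in ("Up", "Down"):
            raise ValueError(
                f"{self.protein_id}: regulated_type must be Up or Down, "
                f"got {self.regulated_type!r}"
            )


@dataclass
class ConcordanceReport:
    n_records: int
    n_sign_concordant: int
    spearman_log_ratios: float
    n_passing_dep_thresholds: int
    calls_from_tmt: List[str]

    def to_dict(self) -> dict:
        return asdict(self)


def read_prm_table(path) -> List[PRMRecord]:
    """Read a PRM ratio TSV (columns: protein_id, protein_name, gene_name,
    peptides, prm_ratio, tmt_ratio, regulated_type)."""
    records: List[PRMRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_PRM_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"PRM table missing columns: {sorted(missing)}")
        for row in reader:
            records.append(
                PRMRecord(
                    protein_id=row["protein_id"],
                    protein_name=row["protein_name"],
                    gene_name=row["gene_name"],
                    peptides=tuple(row["peptides"].split()),
                    prm_ratio=float(row["prm_ratio"]),
                    tmt_ratio=float(row["tmt_ratio"]),
                    regulated_type=row["regulated_type"],
                )
            )
    return records


def load_table1_fixture() -> List[PRMRecord]:
    """Load the packaged 20-protein PRM/TMT ratio fixture.

    The file checksum is verified so a corrupted install fails loudly.
    """
    ref = resources.files("tmtdep").joinpath("data", _FIXTURE_NAME)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise RuntimeError(
            f"PRM fixture {_FIXTURE_NAME} is corrupted (sha256 {digest[:12]}...)"
        )
    with resources.as_file(ref) as path:
        return read_prm_table(path)


def concordance(
    records: Sequence[PRMRecord],
    up_threshold: float = 1.30,
    down_threshold: float = 0.77,
) -> ConcordanceReport:
    """Agreement between PRM and TMT ratios.

    Sign concordance counts records whose two ratios fall strictly on the
    same side of 1.0; a ratio of exactly 1.0 is logged and counted as
    non-concordant.  The rank correlation is Spearman's on log2 ratios
    (equivalently on the raw ratios).  The threshold pass count applies
    the discovery-stage fold-change bounds to the TMT ratio.
    """
    if not records:
        raise ValueError("need at least one PRM record")
    n_conc = 0
    calls = []
    n_pass = 0
    for r in records:
        if r.prm_ratio == 1.0 or r.tmt_ratio == 1.0:
            logger.warning("%s: ratio exactly 1.0, counted as non-concordant", r.protein_id)
        elif (r.prm_ratio > 1.0) == (r.tmt_ratio > 1.0):
            n_conc += 1
        if r.tmt_ratio > up_threshold:
            calls.append("Up")
            n_pass += 1
        elif r.tmt_ratio < down_threshold:
            calls.append("Down")
            n_pass += 1
        else:
            calls.append("NS")
    if len(records) > 1:
        rho = float(
            stats.spearmanr(
                np.log2([r.prm_ratio for r in records]),
                np.log2([r.tmt_ratio for r in records]),
            ).statistic
        )
    else:
        rho = np.nan
    return ConcordanceReport(
        n_records=len(records),
        n_sign_concordant=n_conc,
        spearman_log_ratios=rho,
        n_passing_dep_thresholds=n_pass,
        calls_from_tmt=calls,
    )


def group_stats(group_a: Sequence[float], group_b: Sequence[float]) -> dict:
    """Mean, SEM and two-sided equal-variance t-test for two groups of
    per-sample values, with the usual significance stars.

    Returns a dict with mean_a/sem_a, mean_b/sem_b, p_value and ``stars``
    ('' / '*' / '**' / '***' at 0.05 / 0.01 / 0.001).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if np.isnan(p):  # zero variance in both groups
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
    return {
        "mean_a": float(a.mean()),
        "sem_a": float(a.std(ddof=1) / np.sqrt(len(a))),
        "mean_b": float(b.mean()),
        "sem_b": float(b.std(ddof=1) / np.sqrt(len(b))),
        "p_value": p,
        "stars": stars,
    }
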