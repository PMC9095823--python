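"""Readers and writers for every file the pipeline touches.

Formats are deliberately plain:

* peptide / protein matrices — TSV with a header row of sample IDs and a
  second header line ``#group:`` carrying the per-sample group labels
  (a two-column sidecar TSV ``sample_id<TAB>group`` is accepted as an
  alternative); empty cells are missing, never 0;
* peptide->protein map — TSV with columns ``peptide_id``, ``protein_id``,
  one row per (peptide, owner) pair;
* annotations — standard GMT (term, description, members...), where the
  description field may carry an annotation category as ``CATEGORY|name``;
* PRM ratio tables — TSV (see :mod:`tmtdep.prm`).

Report tables (DEP, enrichment, Q matrix) write ratios with 4 decimals;
the matrix writers keep full float precision so write -> read round-trips
exactly.
"""

from __future__ import annotations

import csv
import logging
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd

from .containers import PeptideIntensityMatrix, ProteinQuantMatrix
from .enrichment import EnrichmentResult, TermAnnotation, results_to_frame
from .prm import PRMRecord, read_prm_table  # noqa: F401  (re-exported)

logger = logging.getLogger(__name__)

GROUP_LINE_PREFIX = "#group:"


def _read_matrix_tsv(path, groups_path=None):
    """Shared parser for the two-header-line matrix layout."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        sample_ids = header[1:]
        if len(sample_ids) < 2:
            raise ValueError(f"{path}: need at least 2 sample columns")
        groups = None
        rows, index = [], []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if row[0] == GROUP_LINE_PREFIX:
                groups = pd.Series(row[1:], index=sample_ids)
                continue
            if len(row) != len(sample_ids) + 1:
                raise ValueError(f"{path}:{lineno}: expected {len(sample_ids) + 1} fields")
            index.append(row[0])
            parsed = []
            for sample, cell in zip(sample_ids, row[1:]):
                if cell == "":
                    parsed.append(np.nan)
                    continue
                try:
                    parsed.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric intensity {cell!r} at row {row[0]!r}, "
                        f"column {sample!r}"
                    ) from None
            rows.append(parsed)
    if groups is None:
        if groups_path is None:
            raise ValueError(
                f"{path}: no '{GROUP_LINE_PREFIX}' line and no group sidecar given"
            )
        side = pd.read_csv(groups_path, sep="\t", header=None, names=["sample_id", "group"])
        groups = pd.Series(side["group"].values, index=side["sample_id"].values)
    frame = pd.DataFrame(rows, index=index, columns=sample_ids, dtype=float)
    return frame, groups


def read_peptide_table(path, groups_path=None) -> PeptideIntensityMatrix:
    """Read a peptide x sample reporter-intensity TSV."""
    frame, groups = _read_matrix_tsv(path, groups_path)
    return PeptideIntensityMatrix(frame, groups)


def write_peptide_table(matrix: PeptideIntensityMatrix, path) -> None:
    _write_matrix(matrix.intensities, matrix.groups, path, id_label="peptide_id")


def _write_matrix(frame: pd.DataFrame, groups: pd.Series, path, id_label: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow([id_label] + list(frame.columns))
        writer.writerow([GROUP_LINE_PREFIX] + [groups[s] for s in frame.columns])
        for pid, row in frame.iterrows():
            writer.writerow([pid] + ["" if pd.isna(v) else repr(float(v)) for v in row])


def read_peptide_map(path) -> Dict[str, Set[str]]:
    """Read peptide->protein ownership (one row per pair)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if not {"peptide_id", "protein_id"} <= set(frame.columns):
        raise ValueError(f"{path}: expected columns peptide_id, protein_id")
    out: Dict[str, Set[str]] = {}
    for pep, prot in zip(frame["peptide_id"], frame["protein_id"]):
        out.setdefault(pep, set()).add(prot)
    return out


def write_peptide_map(peptide_map: Dict[str, Set[str]], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["peptide_id", "protein_id"])
        for pep in sorted(peptide_map):
            for prot in sorted(peptide_map[pep]):
                writer.writerow([pep, prot])


def read_annotation_gmt(path) -> List[TermAnnotation]:
    """Read a GMT annotation file.

    Lines are ``term_id<TAB>description<TAB>member...``; member lists are
    de-duplicated, terms left empty after de-duplication are dropped with
    a warning, and a description of the form ``CATEGORY|name`` assigns the
    term to an annotation category (default ``"default"``).
    """
    terms: List[TermAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term_id, desc = fields[0], fields[1]
            members = {m for m in fields[2:] if m}
            if not members:
                logger.warning("%s:%d: term %s has no members; dropped", path, lineno, term_id)
                continue
            category, _, name = desc.partition("|")
            if not name:
                category, name = "default", desc
            terms.append(TermAnnotation(term_id=term_id, name=name, members=members, category=category))
    return terms


def write_annotation_gmt(terms: Sequence[TermAnnotation], path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            desc = f"{t.category}|{t.name}"
            fh.write("\t".join([t.term_id, desc] + sorted(t.members)) + "\n")


def read_protein_quant(path, groups_path=None) -> ProteinQuantMatrix:
    frame, groups = _read_matrix_tsv(path, groups_path)
    n_unique = None
    if "n_unique_peptides" in frame.columns:
        n_unique = frame.pop("n_unique_peptides").astype(int)
        groups = groups.drop("n_unique_peptides")
    return ProteinQuantMatrix(frame, groups, n_unique)


def write_protein_quant(quant: ProteinQuantMatrix, path) -> None:
    frame = quant.values.copy()
    frame.insert(0, "n_unique_peptides", quant.n_unique_peptides)
    groups = pd.concat([pd.Series({"n_unique_peptides": "-"}), quant.groups])
    _write_matrix(frame, groups, path, id_label="protein_id")


def write_dep_table(records, path) -> None:
    from .differential import records_to_frame

    frame = records_to_frame(records)
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def write_enrichment_table(results: Sequence[EnrichmentResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.4g")


def write_q_matrix(matrix: pd.DataFrame, path, row_order: Optional[Sequence[str]] = None) -> None:
    out = matrix.loc[list(row_order)] if row_order is not None else matrix
    out.to_csv(path, sep="\t", index_label="term", float_format="%.4f")
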