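"""End-to-end orchestration: quantify -> QC -> re-quantify -> differential
-> enrichment -> Q-group clustering -> PRM concordance -> run summary.

``run_pipeline`` is a pure function of (inputs, config): identical inputs
and configuration produce byte-identical artifacts.  Channels failing
replicate QC are excluded and the normalization is recomputed from the raw
intensities of the retained channels only.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set

from . import io as tio
from .config import PipelineConfig
from .containers import PeptideIntensityMatrix
from .differential import call_deps, dep_counts, records_to_frame, volcano_table
from .enrichment import TermAnnotation, cluster_rows, fisher_enrich, q_group_matrix, top_terms
from .prm import PRMRecord, concordance
from .quantify import protein_abundance, quantify, replicate_qc

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """An error raised by a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:  # re-raise with the stage name attached
        raise StageError(name, exc) from exc
    logger.info("stage %-12s %.2fs", name, time.perf_counter() - t0)
    return result


def run_pipeline(
    peptides: PeptideIntensityMatrix,
    peptide_map: Dict[str, Set[str]],
    out_dir,
    config: Optional[PipelineConfig] = None,
    terms: Optional[Sequence[TermAnnotation]] = None,
    prm_records: Optional[Sequence[PRMRecord]] = None,
) -> dict:
    """Run every stage and write the artifact set into ``out_dir``.

    Writes: ``quant.tsv``, ``dep.tsv``, ``volcano.tsv``, per-category
    ``enrichment_<cat>.tsv`` plus ``enrichment_top.tsv``, ``q_matrix.tsv``
    (cluster leaf order), ``prm_concordance.json`` and ``run_summary.json``.
    Returns the run summary dict.
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    abundance = _stage("qc_rollup", protein_abundance, peptides, peptide_map)
    flagged, _corr = _stage(
        "replicate_qc", replicate_qc, abundance, config.qc_correlation_floor
    )
    if flagged:
        remaining = peptides.groups.drop(flagged).value_counts()
        if (remaining < 2).any() or len(remaining) < len(peptides.groups.unique()):
            raise StageError(
                "replicate_qc",
                ValueError(f"QC flagged {flagged}; fewer than 2 samples would remain in a group"),
            )
        peptides = peptides.drop_samples(flagged)
    quant = _stage("quantify", quantify, peptides, peptide_map)
    tio.write_protein_quant(quant, out / "quant.tsv")

    records = _stage("differential", call_deps, quant, config)
    tio.write_dep_table(records, out / "dep.tsv")
    counts = dep_counts(records)
    vol = volcano_table(records)
    with open(out / "volcano.tsv", "w") as fh:
        fh.write(f"# up={counts['n_up']} down={counts['n_down']} ns={counts['n_ns']}\n")
        vol.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    summary = {
        "seed": config.seed,
        "config": config.to_dict(),
        "n_samples_in": int(len(peptides.sample_ids) + len(flagged)),
        "qc_flagged_samples": list(flagged),
        "n_peptides": int(len(peptides.peptide_ids)),
        "n_proteins_quantified": int(quant.values.shape[0]),
        **counts,
    }

    if terms:
        foreground = {r.protein_id for r in records if r.regulation != "NS"}
        background = set(quant.protein_ids)
        results = _stage("enrichment", fisher_enrich, foreground, background, terms)
        for cat in sorted({r.category for r in results}):
            tio.write_enrichment_table(
                [r for r in results if r.category == cat], out / f"enrichment_{cat}.tsv"
            )
        tio.write_enrichment_table(
            top_terms(results, config.enrichment_top_n), out / "enrichment_top.tsv"
        )
        q_assign = {r.protein_id: r.q_category for r in records if r.q_category != "none"}
        qmat = _stage("q_matrix", q_group_matrix, q_assign, background, terms, config.alpha)
        row_order = None
        if qmat.shape[0] >= 2:
            row_order, _link = _stage("cluster", cluster_rows, qmat)
        tio.write_q_matrix(qmat, out / "q_matrix.tsv", row_order)
        summary["n_terms_tested"] = len(results)
        summary["n_terms_significant"] = sum(
            1 for r in results if r.bh_adjusted_p < config.alpha
        )

    if prm_records:
        report = _stage(
            "prm", concordance, prm_records, config.up_threshold, config.down_threshold
        )
        with open(out / "prm_concordance.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        summary["prm"] = {
            "n_records": report.n_records,
            "n_sign_concordant": report.n_sign_concordant,
            "spearman_log_ratios": round(report.spearman_log_ratios, 4),
        }

    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary


def run_pipeline_from_paths(
    peptides_path,
    map_path,
    out_dir,
    config: Optional[PipelineConfig] = None,
    gmt_path=None,
    prm_path=None,
    groups_path=None,
) -> dict:
    """File-path front-end to :func:`run_pipeline` (the CLI entry)."""
    peptides = _stage("read_peptides", tio.read_peptide_table, peptides_path, groups_path)
    peptide_map = _stage("read_map", tio.read_peptide_map, map_path)
    terms = _stage("read_gmt", tio.read_annotation_gmt, gmt_path) if gmt_path else None
    prm_records = _stage("read_prm", tio.read_prm_table, prm_path) if prm_path else None
    return run_pipeline(peptides, peptide_map, out_dir, config, terms, prm_records)
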