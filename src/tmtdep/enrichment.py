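"""Term over-representation analysis for differential proteins.

One-sided Fisher's exact test per term (over-representation of the
foreground among the term's members), Benjamini-Hochberg correction within
each annotation category, fold-enrichment, top-N selection, the Q1..Q4
severity-bin enrichment matrix, and hierarchical clustering of its rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

NEGLOG10_CAP = 16.0  # keeps -log10(p) finite so z-scoring stays defined

Q_LABELS = ("Q1", "Q2", "Q3", "Q4")


@dataclass
class TermAnnotation:
    """One annotation term: an identifier, a display name, a category
    (e.g. BP/CC/MF/pathway/domain) and its member protein accessions."""

    term_id: str
    name: str
    members: Set[str]
    category: str = "default"


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    category: str
    k: int  # foreground proteins in term
    n: int  # foreground proteins with any annotation in category
    K: int  # background proteins in term
    N: int  # annotated background size
    p_value: float
    bh_adjusted_p: float = np.nan
    fold_enrichment: float = np.nan
    log2_fold_enrichment: float = np.nan


def fisher_pvalue(k: int, n: int, K: int, N: int) -> float:
    """One-sided (over-representation) Fisher exact p for the 2x2 table
    (k, n-k, K-k, N-K-n+k): the hypergeometric upper tail P(X >= k) when
    drawing n from a population of N containing K successes."""
    if not (0 <= k <= min(n, K) and max(n, K) <= N):
        raise ValueError(f"inconsistent 2x2 table: k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity from the
    largest rank down, cap at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def fisher_enrich(
    foreground: Iterable[str],
    background: Iterable[str],
    terms: Sequence[TermAnnotation],
) -> List[EnrichmentResult]:
    """Per-term one-sided Fisher enrichment of ``foreground`` within
    ``background``, BH-adjusted within each annotation category.

    The background of each category is restricted to proteins carrying at
    least one annotation in that category; terms are intersected with the
    background before counting.  Results are sorted by raw p (ties: larger
    fold enrichment, then term_id).
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    if not fg:
        logger.warning("empty foreground: no enrichment computed")
        return []

    by_cat: Dict[str, List[TermAnnotation]] = {}
    for t in terms:
        by_cat.setdefault(t.category, []).append(t)

    results: List[EnrichmentResult] = []
    for cat, cat_terms in sorted(by_cat.items()):
        annotated = set().union(*(t.members for t in cat_terms)) & bg
        N = len(annotated)
        n = len(fg & annotated)
        cat_results: List[EnrichmentResult] = []
        for t in sorted(cat_terms, key=lambda t: t.term_id):
            members = t.members & annotated
            K = len(members)
            if K == 0:
                continue
            k = len(fg & members)
            p = fisher_pvalue(k, n, K, N) if n > 0 else 1.0
            fe = (k / n) / (K / N) if n > 0 and k > 0 else (np.nan if n == 0 else 0.0)
            cat_results.append(
                EnrichmentResult(
                    term_id=t.term_id,
                    term_name=t.name,
                    category=cat,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    p_value=p,
                    fold_enrichment=fe,
                    log2_fold_enrichment=np.log2(fe) if fe and fe > 0 else -np.inf,
                )
            )
        adj = bh_adjust([r.p_value for r in cat_results])
        for r, a in zip(cat_results, adj):
            r.bh_adjusted_p = float(a)
        results.extend(cat_results)

    results.sort(key=lambda r: (r.p_value, -np.nan_to_num(r.fold_enrichment), r.term_id))
    return results


def top_terms(results: Sequence[EnrichmentResult], n: int) -> List[EnrichmentResult]:
    """First ``n`` results by raw p; ties broken by larger fold enrichment,
    then lexicographic term_id (deterministic)."""
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    ordered = sorted(
        results, key=lambda r: (r.p_value, -np.nan_to_num(r.fold_enrichment), r.term_id)
    )
    return ordered[:n]


def q_group_matrix(
    q_assignments: Dict[str, str],
    background: Iterable[str],
    terms: Sequence[TermAnnotation],
    bh_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-term -log10 Fisher p across the four fold-change severity bins.

    ``q_assignments`` maps protein_id -> Q1..Q4 for every differential
    protein.  Each bin is tested as foreground against the common
    background; terms are kept if BH-significant (< ``bh_alpha``) in at
    least one bin.  Returns a DataFrame with rows "category|term_id" and
    columns Q1..Q4, values capped at ``NEGLOG10_CAP``.
    """
    bg = set(background)
    per_q: Dict[str, Dict[str, EnrichmentResult]] = {}
    keep: Set[str] = set()
    for q in Q_LABELS:
        fg = {p for p, lab in q_assignments.items() if lab == q} & bg
        if not fg:
            logger.warning("Q group %s is empty; its column will be all zeros", q)
            per_q[q] = {}
            continue
        res = fisher_enrich(fg, bg, terms)
        per_q[q] = {f"{r.category}|{r.term_id}": r for r in res}
        keep |= {key for key, r in per_q[q].items() if r.bh_adjusted_p < bh_alpha}

    rows = sorted(keep)
    mat = pd.DataFrame(0.0, index=rows, columns=list(Q_LABELS))
    for q in Q_LABELS:
        for key in rows:
            r = per_q[q].get(key)
            if r is not None:
                mat.loc[key, q] = min(-np.log10(max(r.p_value, 10.0**-NEGLOG10_CAP)), NEGLOG10_CAP)
    return mat


def cluster_rows(matrix: pd.DataFrame):
    """Hierarchically cluster matrix rows: z-score each row, Euclidean
    distance, average linkage.  Returns (ordered row labels, linkage array).

    Constant rows (sd = 0) z-score to all-zeros, mirroring how heatmap-style
    tools keep degenerate rows plottable.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    vals = matrix.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d constant row(s) z-scored to zeros", int(flat.sum()))
    z = np.where(sd == 0, 0.0, (vals - mu) / np.where(sd == 0, 1.0, sd))
    link = average(pdist(z, metric="euclidean"))
    order = [matrix.index[i] for i in leaves_list(link)]
    return order, link


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Flatten enrichment results into a plot-ready table."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "category": r.category,
                "k": r.k,
                "n": r.n,
                "K": r.K,
                "N": r.N,
                "p_value": r.p_value,
                "bh_adjusted_p": r.bh_adjusted_p,
                "fold_enrichment": r.fold_enrichment,
                "log2_fold_enrichment": r.log2_fold_enrichment,
            }
            for r in results
        ]
    )
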