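"""Synthetic TMT experiments with known protein-level ground truth.

The generator emulates a two-group isobaric labelling design (default
4 wild-type vs 5 mutant channels): each protein gets a base abundance
drawn log-uniformly over three orders of magnitude; regulated proteins
multiply their mutant-group abundance by a planted ratio; each peptide
carries a lognormal ionization efficiency; every cell receives
multiplicative lognormal measurement noise; optionally a fraction of
peptides is shared between two owner proteins and a fraction of cells is
blanked with intensity-dependent (logistic in log intensity) missingness.

All randomness flows from a single numpy Generator in a fixed draw order:
abundances, regulation assignment, directions, magnitudes, peptide counts,
shared-peptide assignment, ionization efficiencies, noise, missingness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import PeptideIntensityMatrix
from .enrichment import TermAnnotation

ABUNDANCE_LOG10_RANGE = (4.0, 7.0)  # typical proteome dynamic range, 3 decades


@dataclass
class GroundTruth:
    """Planted truth of a simulated dataset."""

    true_ratio: Dict[str, float]  # protein -> Hom/Wt ratio (1.0 if unregulated)
    regulation: Dict[str, str]  # protein -> Up / Down / Unregulated
    peptide_owners: Dict[str, Tuple[str, ...]]  # peptide -> owner protein(s)

    def is_unique(self, peptide: str) -> bool:
        return len(self.peptide_owners[peptide]) == 1

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "true_ratio": self.true_ratio,
                    "regulation": self.regulation,
                    "peptide_owners": {k: list(v) for k, v in self.peptide_owners.items()},
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            true_ratio=raw["true_ratio"],
            regulation=raw["regulation"],
            peptide_owners={k: tuple(v) for k, v in raw["peptide_owners"].items()},
        )


def simulate_dataset(
    config: SimConfig,
) -> Tuple[PeptideIntensityMatrix, Dict[str, Set[str]], GroundTruth]:
    """Generate a reporter-intensity matrix, its peptide->protein map and
    the planted ground truth, reproducibly from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:05d}" for i in range(1, n + 1)]

    log10_abund = rng.uniform(*ABUNDANCE_LOG10_RANGE, size=n)
    abundance = 10.0 ** log10_abund

    n_reg = int(round(config.frac_regulated * n))
    reg_idx = rng.choice(n, size=n_reg, replace=False) if n_reg else np.array([], dtype=int)
    up = rng.random(n_reg) < 0.5
    mean_mag, sd_mag = config.log2fc_magnitude
    mags = np.abs(rng.normal(mean_mag, sd_mag, size=n_reg))
    ratio = np.ones(n)
    ratio[reg_idx] = 2.0 ** (np.where(up, mags, -mags))

    lo, hi = config.peptides_per_protein
    peps_per = rng.integers(lo, hi + 1, size=n)

    peptides: List[str] = []
    owner_idx: List[int] = []
    for i, cnt in enumerate(peps_per):
        for j in range(cnt):
            peptides.append(f"pep_{proteins[i]}_{j + 1}")
            owner_idx.append(i)
    n_pep = len(peptides)
    owner_idx = np.array(owner_idx)

    owners: Dict[str, Tuple[str, ...]] = {p: (proteins[i],) for p, i in zip(peptides, owner_idx)}
    n_shared = int(round(config.frac_shared_peptides * n_pep))
    if n_shared and n < 2:
        raise ValueError("shared peptides need at least 2 proteins")
    shared_sel = rng.choice(n_pep, size=n_shared, replace=False) if n_shared else []
    for pi in shared_sel:
        # second owner drawn uniformly among the other proteins
        other = int(rng.integers(n - 1))
        if other >= owner_idx[pi]:
            other += 1
        owners[peptides[pi]] = (proteins[owner_idx[pi]], proteins[other])

    efficiency = np.exp(rng.normal(0.0, config.ionization_sd, size=n_pep))

    sample_ids = [f"Wt{i + 1}" for i in range(config.n_wt)] + [
        f"Hom{i + 1}" for i in range(config.n_hom)
    ]
    group_labels = ["Wt"] * config.n_wt + ["Hom"] * config.n_hom
    is_hom = np.array([g == "Hom" for g in group_labels])

    # expected signal: owner abundance x planted ratio (Hom only) x efficiency
    base = abundance[owner_idx][:, None] * np.where(is_hom[None, :], ratio[owner_idx][:, None], 1.0)
    base = base * efficiency[:, None]

    sigma = np.sqrt(np.log1p(config.noise_cv**2))
    noise = np.exp(sigma * rng.standard_normal(size=(n_pep, len(sample_ids))))
    intensity = base * noise

    if config.missing_rate > 0:
        logi = np.log(intensity)
        scale = logi.std() or 1.0
        w = 1.0 / (1.0 + np.exp((logi - np.median(logi)) / scale))
        p_missing = np.minimum(w * config.missing_rate / w.mean(), 1.0)
        blank = rng.random(size=intensity.shape) < p_missing
        intensity = np.where(blank, np.nan, intensity)

    frame = pd.DataFrame(intensity, index=peptides, columns=sample_ids)
    groups = pd.Series(group_labels, index=sample_ids)
    matrix = PeptideIntensityMatrix(frame, groups)

    reg_label = np.full(n, "Unregulated", dtype=object)
    reg_label[reg_idx[up]] = "Up"
    reg_label[reg_idx[~up]] = "Down"
    truth = GroundTruth(
        true_ratio=dict(zip(proteins, ratio.tolist())),
        regulation=dict(zip(proteins, reg_label.tolist())),
        peptide_owners=owners,
    )
    peptide_map = {p: set(o) for p, o in owners.items()}
    return matrix, peptide_map, truth


def simulate_annotations(
    truth: GroundTruth,
    n_terms: int,
    term_size: Tuple[int, int] = (10, 40),
    enrichment_bias: float = 1.0,
    seed: int = 0,
    n_biased: int = 1,
    category: str = "pathway",
) -> List[TermAnnotation]:
    """Random GMT-writable term sets over the simulated proteins.

    When ``enrichment_bias`` > 1, the first ``n_biased`` terms (ids prefixed
    ``T_planted``) sample members with probability weight ``bias`` for
    regulated proteins and 1 otherwise; remaining terms sample uniformly,
    so under bias = 1 no term is enriched in expectation.
    """
    if enrichment_bias < 1:
        raise ValueError("enrichment_bias must be >= 1")
    proteins = sorted(truth.true_ratio)
    lo, hi = term_size
    if hi > len(proteins):
        raise ValueError(f"term_size upper bound {hi} exceeds protein count {len(proteins)}")
    rng = np.random.default_rng(seed)
    regulated = np.array([truth.regulation[p] != "Unregulated" for p in proteins])
    biased_w = np.where(regulated, enrichment_bias, 1.0)
    biased_w = biased_w / biased_w.sum()

    terms: List[TermAnnotation] = []
    n_planted = n_biased if enrichment_bias > 1 else 0
    for t in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        planted = t < n_planted
        p = biased_w if planted else None
        members = rng.choice(len(proteins), size=size, replace=False, p=p)
        prefix = "T_planted" if planted else "T"
        terms.append(
            TermAnnotation(
                term_id=f"{prefix}{t + 1:04d}",
                name=f"{'planted ' if planted else ''}term {t + 1}",
                members={proteins[i] for i in members},
                category=category,
            )
        )
    return terms


def degrade_sample(
    matrix: PeptideIntensityMatrix,
    sample_id: str,
    decorrelation: float,
    seed: int = 0,
) -> PeptideIntensityMatrix:
    """Destroy a channel's agreement with its replicates.

    A fraction ``decorrelation`` of the named sample's observed intensities
    is re-drawn independently from a lognormal fitted to that sample's own
    log-intensity distribution, severing the peptide-level correlation
    structure while preserving the marginal scale.
    """
    if sample_id not in matrix.intensities.columns:
        raise ValueError(f"unknown sample {sample_id!r}")
    if not 0 <= decorrelation <= 1:
        raise ValueError("decorrelation must be in [0, 1]")
    vals = matrix.intensities.copy()
    if decorrelation == 0:
        return PeptideIntensityMatrix(vals, matrix.groups.copy())
    rng = np.random.default_rng(seed)
    col = vals[sample_id]
    observed = col.dropna()
    n_redraw = int(round(decorrelation * len(observed)))
    chosen = rng.choice(observed.index.to_numpy(), size=n_redraw, replace=False)
    mu, sd = np.log(observed).mean(), np.log(observed).std() or 1.0
    vals.loc[chosen, sample_id] = np.exp(rng.normal(mu, sd, size=n_redraw))
    return PeptideIntensityMatrix(vals, matrix.groups.copy())
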