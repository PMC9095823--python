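"""Pipeline and simulation configuration objects.

Defaults encode the study design this package targets: a 4-channel
wild-type (Wt) versus 5-channel homozygous-mutant (Hom) TMT experiment,
differential calling at fold change > 1.30 or < 0.77 with raw p < 0.05,
and fold-change severity bins Q1..Q4 with edges 0.667 / 0.769 / 1.3 / 1.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import yaml

DEFAULT_Q_EDGES: Tuple[float, float, float, float] = (0.667, 0.769, 1.3, 1.5)


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds and knobs for the full quantify -> DEP -> enrich pipeline.

    Parameters
    ----------
    up_threshold, down_threshold
        Fold-change (Hom/Wt) bounds for calling a protein up- or
        down-regulated; comparisons are strict.
    alpha
        Raw p-value threshold for differential calls (no multiple-testing
        correction at this stage; BH is applied only in term enrichment).
    q_edges
        Fold-change edges for the severity bins Q1 (FC <= e0), Q2
        (e0 < FC < down_threshold), Q3 (up_threshold < FC <= e3) and
        Q4 (FC > e3).
    qc_correlation_floor
        Minimum median within-group Spearman correlation a channel must
        reach to survive replicate QC.
    enrichment_top_n
        Number of top terms reported per annotation category.
    test_method
        ``"student"`` (equal-variance) or ``"welch"`` two-sample t-test.
    log_transform
        If true, t-tests run on log2-transformed relative values.
    """

    up_threshold: float = 1.30
    down_threshold: float = 0.77
    alpha: float = 0.05
    q_edges: Tuple[float, float, float, float] = DEFAULT_Q_EDGES
    qc_correlation_floor: float = 0.8
    enrichment_top_n: int = 20
    test_method: str = "student"
    log_transform: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.down_threshold < 1 < self.up_threshold):
            raise ValueError(
                "thresholds must satisfy down_threshold < 1 < up_threshold, "
                f"got down={self.down_threshold}, up={self.up_threshold}"
            )
        if not 0 <= self.alpha < 1:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        edges = tuple(self.q_edges)
        if len(edges) != 4 or any(a >= b for a, b in zip(edges, edges[1:])):
            raise ValueError(f"q_edges must be 4 strictly increasing ratios, got {edges}")
        if self.test_method not in ("student", "welch"):
            raise ValueError(f"test_method must be 'student' or 'welch', got {self.test_method!r}")
        if self.enrichment_top_n < 1:
            raise ValueError("enrichment_top_n must be >= 1")
        object.__setattr__(self, "q_edges", edges)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "q_edges" in raw:
            raw["q_edges"] = tuple(raw["q_edges"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["q_edges"] = list(self.q_edges)
        return d


@dataclass(frozen=True)
class SimConfig:
    """Design of a synthetic TMT reporter-intensity experiment.

    The generator plants per-protein Hom/Wt ratios, per-peptide ionization
    efficiencies and multiplicative lognormal measurement noise, with an
    optional fraction of shared (two-owner) peptides and intensity-dependent
    missingness.  See :mod:`tmtdep.simulate`.
    """

    n_proteins: int = 500
    peptides_per_protein: Tuple[int, int] = (3, 8)
    n_wt: int = 4
    n_hom: int = 5
    frac_regulated: float = 0.2
    log2fc_magnitude: Tuple[float, float] = (1.0, 0.3)  # (mean, sd) of |log2 FC|
    ionization_sd: float = 1.0
    noise_cv: float = 0.1
    frac_shared_peptides: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError(
                f"peptides_per_protein must be a range with lower bound >= 1, got ({lo}, {hi})"
            )
        if self.n_proteins < 1 or self.n_wt < 2 or self.n_hom < 2:
            raise ValueError("need n_proteins >= 1 and at least 2 samples per group")
        for name in ("frac_regulated", "frac_shared_peptides", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_cv < 0 or self.ionization_sd < 0:
            raise ValueError("noise_cv and ionization_sd must be >= 0")
        object.__setattr__(self, "peptides_per_protein", (int(lo), int(hi)))
        object.__setattr__(self, "log2fc_magnitude", tuple(self.log2fc_magnitude))

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("peptides_per_protein", "log2fc_magnitude"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["peptides_per_protein"] = list(self.peptides_per_protein)
        d["log2fc_magnitude"] = list(self.log2fc_magnitude)
        return d
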