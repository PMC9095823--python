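# Methods

This note records the modelling and numerical choices behind `tmtdep`, in
the order the pipeline applies them, together with what the synthetic
benchmark does and does not establish.

## Quantification

The peptide-to-protein chain is centralization (`U_ij = I_ij / mean_i I_ij`),
median correction (`NR_ij = U_ij / median_j U_ij`) and a unique-peptide
median rollup (`R_ik = median_{j∈k} NR_ij`). Choices the formulas leave
open:

- **Missing data.** A reporter intensity of 0 means "not observed" and is
  treated as missing on ingest. All means and medians are taken over
  observed values only; a peptide with no observation anywhere is dropped
  with a warning. Consequences: fully observed peptide rows have mean
  exactly 1 after centralization, and every channel's observed median is
  exactly 1 after correction (both asserted to 1e-12 in tests).
- **Mean and median conventions.** The centralization mean is arithmetic
  (no log-space averaging); the median of an even count is the midpoint of
  the two central values.
- **Uniqueness.** A peptide is unique iff the supplied peptide→protein map
  assigns it exactly one accession. Shared peptides are excluded from the
  rollup entirely; adding arbitrarily many shared peptides can never
  change any `R` (property-tested).
- **Quantifiability.** A protein is reported iff it has ≥ 1 unique peptide
  observed in ≥ 2 channels of *each* group — the weakest rule that leaves
  both the fold change and the t-test defined.

The chain is invariant to global rescaling of the intensity matrix and
maps any rank-one input (`I_ij = a_i · b_j`) to all-ones, which is the
intended behaviour: only deviations from a common loading × efficiency
structure carry quantitative signal.

## Replicate QC

Reproducibility is judged per channel as the median Spearman correlation
against the other channels of its group, computed on log-transformed,
pairwise-complete **raw** protein abundances (the median raw intensity of
each protein's unique peptides). Raw, not normalized: centralization
deliberately removes the between-protein dynamic range, which is exactly
the shared structure that makes replicate correlations high (≈ 0.98 on
clean simulated data); on normalized values the same statistic hovers
near 0.6 and cannot separate good channels from bad ones. The default
floor of 0.8 sits between these regimes. Flagged channels are removed and
normalization is recomputed from the retained channels' raw intensities.
Groups of fewer than three channels are skipped with a warning — with two
members a low correlation cannot be attributed to either one. If flagging
would leave any group with fewer than two channels the QC stage raises
rather than silently continuing.

## Differential calling

- Fold change is the ratio of group arithmetic means of `R` (one number
  per protein), not a mean of pairwise ratios.
- p-values come from a two-sided Student's (equal-variance) t-test on the
  per-channel `R` values by default; Welch's test and a log2 transform are
  configuration flags. Degenerate rows (zero variance in both groups) get
  p = 1 when the means agree and p = 0, logged, when they do not.
- Thresholds are strict as printed: FC > 1.30, FC < 0.77, p < 0.05, with
  no multiple-testing correction at this stage (BH is applied only in
  enrichment). Under null simulations the raw p < 0.05 rate is consistent
  with its nominal level and the additional fold-change requirement pulls
  the realized false-call rate well below it.
- Severity bins: Down calls split at 0.667 (Q1 vs Q2), Up calls at 1.5
  (Q3 vs Q4). The conventional printed upper edge of Q2 (0.769) sits just
  below the Down threshold (0.77); the sliver in between is assigned Q2 so
  that the four bins exactly partition the differential set.
- The volcano table caps −log10 p at 16 (as does the Q-group matrix) so
  downstream z-scoring stays finite.

## Enrichment

One-sided (over-representation) Fisher exact p per term, computed as the
hypergeometric upper tail; tests cross-check this against an exhaustive
tail enumeration for every 2×2 table with N ≤ 60 and against an
independent Fisher implementation. The background is the set of
quantifiable proteins carrying at least one annotation in the tested
category — the least biased choice when the annotation source is supplied
as arbitrary GMT sets — and BH correction runs within each category
separately, since categories (GO namespaces, pathways, domains) are
reported separately. Top-N selection breaks p ties by larger fold
enrichment, then term id, so output order is deterministic. The Q-group
matrix tests each severity bin as its own foreground against the common
background and keeps terms BH-significant in at least one bin; rows are
z-scored (constant rows become zeros, logged) and clustered with Euclidean
distance and average linkage.

## PRM concordance

The packaged fixture carries 20 validated proteins with their Hom/Wt
ratios from both platforms; per-channel PRM signal values are not part of
the fixture, so `group_stats` (mean ± SEM, Student's t, significance
stars) is exercised on synthetic per-channel values only. Sign concordance
is strict against 1.0 — a ratio of exactly 1.0 is logged and counted for
neither side. The fixture file is checksummed at load so a corrupted
install fails loudly.

## Synthetic data

The generator emulates the study design: 4 Wt vs 5 Hom channels, protein
base abundances log-uniform over three decades (so the median-based steps
are exercised across scales), a planted Hom/Wt ratio per regulated protein
(direction 50/50, |log2 FC| normal with configurable mean and sd, default
1.0 ± 0.3 — within the span of the validated candidates, whose ratios run
from 0.25 to 4.74), per-peptide lognormal ionization efficiency,
multiplicative lognormal noise at a configurable CV (default 0.1),
optionally a fraction of two-owner shared peptides and
intensity-dependent missingness (logistic in log intensity, scaled to the
requested overall rate). One seed drives a single generator stream in a
documented draw order, so equal configurations give byte-identical data.

What the simulation does *not* model: isotopic impurity and co-isolation
interference (which compress real TMT ratios), retention-time effects,
peptide-specific digestion efficiency, and correlated (batch) noise.
Passing recovery tests therefore demonstrates correctness of the
computational chain, not the accuracy of TMT quantification on real
spectra.

Recovery benchmarks (problem sizes chosen to make the checks sharp while
keeping the suite quick): at 500 proteins, 5 peptides/protein, noise
CV 0.1, the mean log2 fold-change bias is below 0.05 and the rank
correlation between estimated and planted fold changes exceeds 0.9 over
the regulated proteins. The rank correlation is computed over the
regulated subset deliberately: unregulated proteins all share the exact
true ratio 1, and a rank statistic over a set that is 80% ties is bounded
near 0.7 for *any* estimator — the ties, not estimation error, dominate
it. Null datasets (no regulation) are required to yield a DEP rate of at
most 5%, and a term planted with 20× sampling bias for regulated proteins
must rank first by Fisher p among 40 terms.

## Known limitations

- Protein-group inference is out of scope: the peptide→protein map is
  taken as given, and "unique" is defined against accessions, not groups.
- No moderated-variance (empirical Bayes) test; at n = 4 vs 5 a moderated
  test would gain power, but the plain t keeps the discovery-stage
  behaviour transparent and matches the thresholds' intent.
- Enrichment operates on supplied GMT sets without ontology propagation;
  real GO/KEGG term counts depend on annotation versions and are not
  reproduced here.
- The spectra-accounting numbers (total/effective MS/MS counts) are
  inputs to an arithmetic check, not quantities the package can derive
  from intensity tables.
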