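# Methods

This note documents the models, defaults and numerical choices behind
`otoscreen`, and what the synthetic-data tests do and do not demonstrate.

## Differential expression

Per-gene statistics use a two-sample unequal-variance (Welch) t-test on log2
intensities, with logFC = mean(treated) − mean(control) and
Benjamini–Hochberg FDR over all genes. Published screens of this kind often
use moderated linear models (limma via GEO2R) for array data; this package
deliberately substitutes the plain Welch test. The acceptance surface here
is the threshold logic and planted-signal recovery, not replication of
variance moderation: at the effect sizes the thresholds are designed for
(|logFC| > 2), moderation changes nothing material, and the Welch test keeps
the module free of a heavy dependency. A gene with zero variance and equal
means in both groups is reported with p = 1 and logged. Precomputed DEG
tables (the single-cell path, where published per-cell-type DEG lists are
used as-is) bypass the t-test and enter directly at the threshold filter.

Two regimes, both exposed in `PipelineConfig`:

| parameter | default | units | role |
| --- | --- | --- | --- |
| `logfc_cut` | 2.0 | log2 | array regime: \|logFC\| > 2 |
| `p_cut` | 0.05 | probability | array regime: P < 0.05 |
| `fc_cut_linear` | 1.2 | linear ratio | single-cell regime: \|FC\| > 1.2 |
| `q_cut` | 0.05 | probability | single-cell regime: q < 0.05 |

Published descriptions of the array-path cutoff vary between |logFC| > 1 and
|logFC| > 2 in different passages; the cutoff is therefore configuration,
with 2 as the default, rather than a hard-coded constant. Records without a
q value are rejected (not imputed) under the single-cell regime. Report
ranking is p ascending, |logFC| descending, then gene ID — the tie-break is
ours, chosen for reproducibility.

Gene identifiers are whitespace-trimmed and upper-cased at every type
boundary, since mouse-convention symbols ("Egfr") and upper-case symbols
("EGFR") must compare equal across data sources.

## Pathway enrichment

One-sided over-representation: p = P[X ≥ k] for X hypergeometric over the
(N genes, K set members, n DEGs) counts, computed with `scipy.stats.
hypergeom.sf` and verified in the tests against exact rational enumeration
for all instances with N ≤ 12 (agreement to 12 significant digits). BH-FDR
is applied over the tested sets and records are sorted by (q, p, set ID).

Choices where the design was open:

- The universe defaults to all genes in the expression matrix (or the DEG
  table's gene column for precomputed input) and is configurable.
- Sets are intersected with the universe before testing; sets with fewer
  than two in-universe members are skipped with a log entry.
- Gene sets are flat; no GO-hierarchy propagation or redundancy reduction.
  The pipeline consumes flat ranked lists, so term-graph structure would add
  dependencies without changing eligibility decisions.
- Query eligibility counts **all** member DEGs of a pathway (the 3-up/3-down
  rule), not a "significant members" subset — the simplest reading that the
  eligibility rule supports, and the one implemented.

## Connectivity screen

The overlap score is a pure set statistic: in mimic mode, the count of query
up-genes in the signature's up set plus query down-genes in its down set,
divided by the total query size; reverse mode crosses the sets. Two
documented choices:

- The denominator is the full query size, not the query ∩ signature-space
  size; a query gene absent from a signature counts as discordant. This
  makes scores comparable across drugs with different gene coverage.
- Up/down concordance is pooled into a single fraction (not averaged as two
  per-direction fractions).

The production service this stage emulates ranks perturbations with a
characteristic-direction statistic over landmark genes; concordance with any
live service is explicitly out of scope — the set-based score above is the
module's definition. For signatures carrying a signed characteristic vector,
a cosine-similarity score over the shared gene space is provided (reverse
mode ranks by −cos). Ties are broken by drug ID so results are invariant to
compendium order; the top-K default is 50 and the hit cutoff is a strict
overlap score > 0.1.

## Consensus and bookkeeping

A *hit* is a drug surviving the score cutoff inside one pathway's top-K
list; the cutoff-then-count order is a configurable reading (counting could
equally be applied pre-cutoff, which the flagged `min_hits`/filter options
allow an analyst to emulate). Pathways with ≥ 3 distinct hit drugs are
retained; multi-pathway drugs are ranked by pathway count, best score, then
drug ID. Drug identity is the case-folded perturbation name — no
chemical-structure deduplication. Cross-arm consensus pools arms by drug
with arm membership, pooled pathways and best score; the table carries an
empty free-text annotation column for downstream mechanism-of-action
curation, which is intentionally manual and out of scope.

## Kinome analysis

Peptide activity is the OLS slope of fluorescence intensity vs camera
exposure time (≥ 3 exposures, default 5/25/100 ms); R² of a zero-variance
response is defined as 0. QC removes peptides with max signal ≤ 5 (inactive)
or R² < 0.90 (non-linear), both thresholds strict in the stated direction.
Fold change is the ratio of post-QC slopes averaged over replicate wells per
condition; calls are strict (FC = 1.15 exactly is not differential).

Kinase assignment uses random-sampling enrichment: per chip, the observed
count of differential peptides among a kinase's mapped on-chip peptides is
z-scored against `n_iter` uniform draws (without replacement) of equally
many peptides from the QC-passed chip; z is averaged across chips. Defaults
and numerical details:

- `n_iter` = 2000 (tests verify the sampled null against the closed-form
  hypergeometric moments at 10⁵ iterations within 3 Monte-Carlo SE).
- The null sd is floored at 10⁻¹²; a degenerate mapping (e.g. a kinase
  mapping the whole chip) reports z = 0 rather than dividing by zero.
- A peptide mapped by several kinases takes the **maximum** activity
  multiplier in the generator — documented because the composition rule for
  multi-kinase peptides is genuinely underdetermined.
- The curated kinase→peptide mapping is consumed as an input GMT file; the
  prediction-server curation that produces such maps is not reconstructed.
- Differential-peptide selection for KRSA uses the FC thresholds above; the
  exact advancement criteria of external implementations are not fully
  published, so the FC-threshold definition is the documented choice.

Family aggregation reports mean ± SD (ddof = 1; a single-peptide family
reports SD = 0) of peptide log2 fold changes per comparison. Cross-method
rank harmonization assigns quartile ⌈4r/n⌉ to rank r of n within each
method (quartile 1 = top); kinases absent from a method are left blank. The
routine two-way ANOVA that usually accompanies the family plot is not
reimplemented; the per-peptide values needed to run it externally are
emitted.

## Pharmacokinetics

The NCA stage is deliberately model-free. LLOQ censoring (default 5 ng/ml)
zeroes sub-LLOQ values; post-peak sub-LLOQ points are additionally excluded
from the λz fit but retained as zeros for the AUC. AUC uses the linear
trapezoid throughout (a linear-up/log-down variant was considered and left
out: on the dense or moderately sampled profiles this stage targets the
difference is far below the reported precision). The terminal window is
chosen by best adjusted R² over all contiguous windows of ≥ 3 quantifiable
points strictly after Tmax and ending at the last quantifiable point — a
standard automatic rule, stated here because published summaries rarely
state theirs. A non-positive fitted λz raises an explicit error rather than
returning silently unusable parameters. CL/F is derived from AUC(0–∞); note
that published summaries sometimes derive it from AUC(0–t) or report it on a
different convention, so both AUCs are always reported. The module defaults
to analyzing a single mean profile; per-animal analysis is supported by
simply running it per profile.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated:

- **Expression**: Gaussian noise on the log2 scale (sd 0.1 by default)
  around group means, with planted genes shifted by ±3 log2 units — an
  effect comfortably clearing the |logFC| > 2 filter, mirroring the
  large-effect DEGs such screens are built on; 5 samples per group;
  2000 genes at acceptance scale.
- **Compendium**: 200 drugs with 30-gene up/down sets; planted reversers
  place each query gene oppositely with probability 0.8 (background drugs
  0.1), by independent Bernoulli draws, so realized concordance varies and
  tests use seeds with verified realizations. Padding genes are drawn
  outside the query so they can never change a score.
- **Gene sets**: planted-enriched sets receive 3 planted up- and 3 planted
  down-regulated genes plus neutral padding; background sets draw uniformly
  from the universe.
- **Kinome**: intensity = base slope × activity multiplier × exposure +
  Gaussian noise, zero intercept; planted multiplier 1.3–1.5 on a
  10-peptide kinase.
- **PK**: one-compartment oral absorption (Bateman) with ka = 6.2 h⁻¹,
  ke = 0.33 h⁻¹, V/F = 127 L/kg, dose 15 mg/kg — chosen so the noise-free
  curve has Tmax ≈ 0.5 h, t½ ≈ 2.1 h and Cmax ≈ 100 ng/ml on the sparse
  0–6 h sampling design; noise is multiplicative lognormal with unit mean
  (concentrations stay positive, the standard bioanalytical assumption).

What the generators do **not** emulate — and hence what passing tests do not
show about real data: microarray probe-level artifacts, count-based
single-cell noise, batch effects, correlated genes, cell-line-specific drug
signature structure, chip washout kinetics, or between-animal PK
variability beyond a lognormal scatter. The synthetic study demonstrates
that the pipeline's logic is correct and its statistics calibrated
(null DEG rate ≈ 5%, KRSA null mean z ≈ 0), not that any particular
biological result would replicate.

## Problem sizes

Acceptance-scale runs use 2000-gene matrices, 200-drug compendia, 65 total
pathway queries across three arms, 3 chips × 80 peptides for the kinome
stage, and 10⁵ resampling iterations only in the oracle-equivalence check
(2000 elsewhere). These sizes make the full suite run in seconds while
keeping every statistic in the regime where its calibration is measurable.

## Known limitations

- The Welch substitution means per-gene p-values differ slightly from
  moderated-model pipelines near the significance boundary.
- The overlap score is a simplification of characteristic-direction ranking;
  rankings against a live signature service will differ.
- Quartile harmonization with fewer than 4 ranked kinases cannot populate
  quartile 1 (⌈4r/n⌉ ≥ 2 when n < 4); this is the documented ceiling rule.
- The NCA terminal-window search is O(points²) in the worst case — trivial
  at profile sizes this stage is meant for.
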