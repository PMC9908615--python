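# Methods

## The model

A bait-vs-control LFQ experiment is summarised per protein by log₂
intensity ratios between matched bait and control replicates. Two
hypotheses could explain a large ratio: a genuinely enriched protein, or
an ordinary protein at the tail of the measurement-noise distribution.
The workflow addresses this with two complementary statistics and a
nested classification.

**Significance A** treats the full set of per-protein summary ratios as
the empirical null. The 15.87th, 50th and 84.13th percentiles (for a
Gaussian: mean − SD, mean, mean + SD) anchor a robust z-score,
`z = (r − r₀)/(r₁ − r₀)` for ratios at or above the median, converted
to a one-sided normal upper-tail probability `p = ½·erfc(z/√2)`.
Because only the upper anchor enters, the statistic is insensitive to
the enriched minority inflating the variance, as long as that minority
stays below ~16% of proteins; beyond that the 84.13th percentile is
itself contaminated and power drops. Ratios strictly below the median
get p = 1 rather than a mirrored tail: depletion can never reach
significance, which is the intended one-sidedness of an enrichment
screen. At exactly the median p = 0.5, the value of the defining
formula at z = 0.

**Welch stage.** The phrase "one-sided paired Welch's t-test" is
internally contradictory (Welch's test is by construction unpaired);
the default here takes "paired" and "ratios" literally: a one-sided
one-sample t-test of the k per-replicate log₂ ratios against zero with
k − 1 degrees of freedom, which is algebraically a paired t-test on the
log intensities. The plausible alternative — a one-sided two-sample
Welch test on log₂ bait vs control with Welch–Satterthwaite df — is
exposed as `welch_mode="two_sample_welch"`. Zero-variance inputs are
resolved by the sign of the effect (positive mean → p = 0, otherwise
p = 1) instead of dividing by zero.

**Tiers.** Presence (≥ ⌈f·n⌉ of n bait replicates, f = 2/3 by default,
controls never counted) gates everything: proteins failing it get label
`none` and no q-values. Both p-vectors are BH-corrected *over the
presence-passing set only*, mirroring the sequential "from these"
construction of the classification; correcting over all detected
proteins instead would dilute m with proteins that can never be called.
Tier 3 = presence, Tier 2 = + SignA q ≤ α, Tier 1 = + Welch q ≤ α,
α = 0.05. Labels are exclusive, qualification sets nested.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `presence_fraction` | 2/3 | fraction of bait replicates | with 6 replicates resolves to ≥ 4 via ceiling |
| `alpha` | 0.05 | q-value threshold | applied to both BH-corrected stages |
| `pairing` | `by_index` | — | replicate ratio i = log₂ bait_i − log₂ control_i; `ratio_of_means` as alternative |
| `welch_mode` | `one_sample_on_ratios` | — | see above |
| `imputation` | `none` | — | ratios use present pairs only; `global_min_shift` deterministically fills missing cells with (per-sample minimum log₂ − 1) |

Percentiles use linear interpolation between closest ranks (the numpy
default). The anchors are interpolation-sensitive at small n, so the
convention is pinned and tested against an explicit uniform grid.

A constant ratio vector makes r₁ = r₀ and the z-score undefined; this
raises a dedicated degeneracy error rather than dividing by zero.
Significance A requires at least 3 finite summary ratios; the Welch
stage returns an undefined (NaN) p for proteins with fewer than 2
usable replicates, and undefined p-values are excluded from BH (m = the
number of defined tests) and can never qualify for a tier.

## GO over-representation

The "classic" algorithm: after closing annotations under ancestry
(is_a and part_of edges only, obsolete terms dropped), each term is
tested independently with the one-sided upper hypergeometric tail
P(X ≥ k), X ~ Hypergeom(N = |population|, K = term's population count,
n = |study|). Terms with K < 3 (`min_node_size`) are excluded before
testing; raw Fisher p ≤ 0.05 is the reported cut, with no
multiple-testing correction on terms — the screening convention this
pipeline reproduces. Unannotated population genes stay in N. Each
namespace (BP/MF/CC) is tested in its own run. Decorrelating algorithms
(elim/weight) that down-weight parents of significant children are
deliberately not implemented: classic is exactly specified and
oracle-checkable against integer-binomial enumeration, which the test
suite does exhaustively for N ≤ 40. The enrichment ratio
(k/n)/(K/N) accompanies each term for reporting.

## Dataset overlap

Candidates are matched against reference gene lists by exact
upper-cased gene symbol after optional homolog translation (an explicit
source→target symbol table; unmapped symbols pass through flagged, they
are not errors). The evidence count is the number of datasets
containing the symbol; the headline fraction is the share of candidates
with evidence ≥ 1, and all candidates tied at the maximum evidence
count are reported as "most frequent". No significance test is attached
to the overlap — none is defined for this comparison.

## The synthetic generator

`simulate_lfq` draws protein log₂ baselines from N(25, 2) — typical
MaxQuant LFQ magnitudes — adds N(0, 0.5) replicate noise, and an
additive +4 log₂ effect in the bait samples of a 5% enriched minority
(100 of 2000 by default), with one enriched protein spiked at twice the
effect to emulate the bait fusion protein dominating the ranking.
Dropout is missing-not-at-random: each cell is missing with probability
`logistic((21 − intensity) · 0.8)`. The midpoint sits two
between-protein SDs below the baseline and the slope is 0.8 per log₂
unit, giving ≈ 9% overall missingness concentrated in the low-intensity
tail — the dominant missingness mechanism of label-free MS at a
realistic rate. Intensities are exported on the linear scale with
missing cells written as 0, exactly the convention the reader reverses.
All randomness flows from one `numpy` Generator seed; identical seeds
give bit-identical output.

What the generator does *not* emulate: peptide-level structure and
shared peptides, ratio compression, batch effects, inter-sample
normalisation drift, and correlated missingness between replicates.
Passing the recovery tests therefore shows the statistical chain is
correct and calibrated under its own assumptions, not that those
assumptions hold for any particular instrument run.

`simulate_ontology` grows a random tree (each term's parent uniform
among earlier terms) in a single namespace and annotates genes to terms
at a background rate, elevating one designated term's rate within the
study set; with elevation 0 the study set is null by construction.

## Problem sizes and numerical checks

The recovery study runs 20 seeded simulations at 2000 proteins × 12
samples — large enough that the empirical Tier 1 recall (~95%) and
false-discovery proportion (<1%) are stable to a couple of percent
across seed sets, small enough to complete in seconds. Null calibration
uses 10 000 i.i.d. standard-normal ratios, where the SignA p ≤ 0.05
fraction lands at 0.05 by construction of the percentile anchors. BH is
verified against a direct step-up enumeration on random vectors, and
the hypergeometric tail against exact integer enumeration on the
exhaustive N ≤ 40 grid.

## Known limitations

- Significance A assumes a unimodal, roughly symmetric null ratio
  distribution; heavy contamination (> ~16% enriched) or bimodality
  biases the upper anchor.
- The per-protein summary ratio (mean of per-pair ratios) is one of
  several defensible constructions; `ratio_of_means` is offered but the
  two differ when missingness is unbalanced across pairs.
- No intensity normalisation across runs is performed; tables are
  assumed to be already normalised (as MaxQuant LFQ output is).
- The GO stage tests terms independently; parent terms of a truly
  enriched child will often co-appear significant.
- The gene universe for GO enrichment must be supplied explicitly;
  results are only interpretable relative to that choice.
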