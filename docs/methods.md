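# Methods

## Setting and rationale

`hpfscore` targets published population-health indicator collections of a
particular shape: each indicator is released as a single point estimate per
jurisdiction per report, rounded to one decimal place, without standard
errors, with small cells suppressed ("n.p."), and with at most eight
jurisdiction-level observations per indicator (fewer when small
jurisdictions are merged).  Variance-based inference is generally not
defensible on such material — the underlying samples, collection schedules
and suppression rules differ per source — so the package implements a
deliberately simple, magnitude-based heuristic that reduces every indicator
to an interpretable integer score and aggregates those scores over the
framework's own hierarchy.  It is an exploratory, omnibus-style summary:
its purpose is to surface global patterns worth a detailed study, not to
test hypotheses.

## The scoring model

For indicator *i* with values T1ᵢ, T2ᵢ in two consecutive reports:

| quantity | definition | degenerate cases |
|---|---|---|
| Δᵢ | T2ᵢ − T1ᵢ on the published (rounded) values | suppressed side → direction inferred, see below |
| U | sign(Δᵢ) ∈ {−1, 0, +1} | — |
| %Δᵢ | 100·(T2ᵢ − T1ᵢ)/T1ᵢ | T1ᵢ = 0 → UNDEFINED (never ±inf, never 0) |
| C1 | 1 if \|%Δᵢ\| ≥ τ else 0 | UNDEFINED %Δ propagates |
| LAD | maxⱼ \|Δᵢⱼ\| over the indicator's numerically complete jurisdictions | none complete → UNDEFINED |
| C2 | 1 if \|Δᵢ\| ≥ q·LAD, with LAD > 0 and Δᵢ ≠ 0 | LAD = 0 or Δ = 0 → 0; UNDEFINED LAD propagates |
| score | direction × U × (1 + C1 + C2), UNDEFINED indicators counting 0 | integer in [−3, 3] |

Both confidence indicators use non-strict thresholds ("met or exceeded")
and the *absolute* percentage change: a −4.6% change on a τ = 2% threshold
earns C1 just as +4.6% does; the direction is carried entirely by U and the
direction of effect.

### Parameters

- **τ (tau)**, default **2.0** percent: the relative-change threshold for
  C1.  Deliberately sensitive; raise it to demand larger relative movement.
- **q**, default **0.10**: the fraction of the LAD defining C2's absolute
  threshold.  The LAD acts as an empirical estimate of how much this
  indicator *can* move between reports, so C2 asks "was this jurisdiction's
  change non-trivial compared with the largest observed anywhere?".
- **direction of effect**, ±1 per indicator: a substantive judgement, not a
  statistical one.  The bundled registry encodes only the general rules
  (decreases in hospitalisation, mortality, smoking, alcohol/substance use
  and waiting times are improvements; increases in assessments, screening,
  healthy diet, physical activity, breastfeeding, community mental-health
  contacts and cultural identification are improvements); all other
  indicators require an explicit registry entry.

### Suppression and missingness rules

"n.p." marks a value too small to publish, and the suppression threshold is
assumed equal across the two reports (this assumption is logged).  Hence:
(n.p. → number) is inferred to be an increase (U = +1), (number → n.p.) a
decrease (U = −1), and (n.p. → n.p.) no change (U = 0).  Since no numeric
difference exists, both confidence indicators are precluded and the score
is bounded to ±1 — consistent with the motivation of the confidence
indicators: unpublished values cannot support confidence.  A row absent
from a report altogether is *not* inferable; indicators lacking any
jurisdiction with rows in both reports are excluded by the eligibility
filter.

### Zero baselines

Division by zero leaves %Δ UNDEFINED; the affected observation relies on C2
alone, bounding its score to ±2.  The alternative reading — an infinite
relative change always earns C1 — is available as
`zero_baseline_awards_c1=True` (CLI `--zero-baseline-awards-c1`) but is not
the default, because it awards maximal relative confidence precisely where
the relative measure is least meaningful.

### Known edge cases, by design

- **Trivial LADs**: C2 is always earned by the jurisdiction holding the
  LAD, even when that largest change is practically negligible; q guards
  only *relative* triviality.  A zero LAD (no jurisdiction moved) awards
  C2 to nobody.
- **LAD ties**: all jurisdictions at the maximum receive C2; there is no
  arbitrary single winner.
- **C2 comparator**: C2 compares the *absolute change* |Δ| with q·LAD (not
  the percentage change) — the comparative indicator is about magnitude on
  the indicator's own scale; the relative view is C1's job.
- **Rounding**: values are used exactly as published (1 dp); changes inside
  the rounding threshold are invisible, which is a property of the source
  data, not of this implementation.  Percentage changes are carried at full
  precision internally and rounded only for display — note that published
  %Δ columns derived from unrounded source values can differ by ±0.1 from
  what the rounded published inputs yield.
- **Category reduction**: ordinal indicators are collapsed to a
  rate-weighted mean Σ rate·weight / Σ rate (the raw weighted sum is
  available via `normalise=False`); a two-category indicator keeps only its
  favourable category; nested categories keep the broader one.  An ordinal
  cell with any suppressed category rate is treated as suppressed; an
  ordinal cell missing a registered category is an error — no imputation.

## Aggregation

Group and tier summaries are means of the viable indicator scores in the
cell, denominated by the number of indicators — tier means average over
indicators directly rather than over group means, so a group with more
indicators carries proportionally more weight.  The SEM uses the sample
(n − 1) standard deviation; with a single indicator it is undefined and no
interval is shown.  The 95% interval mean ± 1.96·SEM is display metadata
that conveys score spread; it is explicitly not a significance test (the
scores are bounded integers, not draws from a normal population).  Cells
with no viable indicators are omitted, never emitted as NaN.  Merged
jurisdictions ("Vic+Tas", "NSW+ACT", "Tas+ACT") and national-only rows are
scored normally but flagged non-allocatable and excluded from
state-partitioned averages.

## Dashboard

One panel per (jurisdiction, tier), one bar per group in framework
declaration order, y axis fixed to [−3, 3] everywhere for comparability.
Positive means are green, negative red; an exactly zero mean is drawn grey
(the green/red convention does not define it).  Error bars span the 95%
interval when the SEM is defined; since that interval can exceed the
logical score range, bars are clipped at ±3 with a small caret marking the
clipped end.  SVG output pins the hash salt and omits the timestamp, so
identical inputs render byte-identical files.

## Synthetic data generator

The generator emulates the *shape* of the published collections so the full
pipeline is testable offline: 289 indicators by default, allocated
round-robin across the bundled 68-measure hierarchy; eight jurisdictions
(or the merged panel with probability `merged_jurisdiction_prob`, default
0.05); values rounded to 1 dp; cells suppressed with probability
`suppression_prob` (default 0.03); baselines drawn uniformly from 5–95 to
cover rate-like magnitudes, with a small zero-baseline fraction (0.02)
exercising the division-by-zero path; roughly 10% ordinal indicators
(five-category rate tables summing to 100) and 5% binary-category
indicators, so every category-reduction path is exercised end-to-end.

Each indicator receives a latent truth: with probability
`true_improvement_prob` (default 0.6) it genuinely moves in its direction
of improvement, by `effect_size_scale` (default 0.08) of its baseline;
jurisdictions add Gaussian noise with sd `noise_scale` (default 0.02) of
the baseline.  The ground-truth table records the latent (noise-free)
change per jurisdiction, so recovery — the fraction of scoreable cells
whose score sign matches the latent direction — is exactly measurable.
With no noise, no suppression and rounding disabled, recovery is 100%;
it degrades monotonically as noise grows.  What the generator does *not*
emulate: the real collections' empirical marginal distributions,
cross-indicator correlation, overlapping observation periods and
source-specific biases — passing tests demonstrate the pipeline's
arithmetic and bookkeeping, not substantive conclusions about real data.

## Problem sizes and numerical choices

The test suite and the reproduction script run at desk scale: the
eight-jurisdiction worked examples, property checks over ~10⁴ randomly
generated panels, and synthetic runs of 120–289 indicators — sizes chosen
to match the published material's own scale (the full collection is ~2100
observations).  Scores within an aggregation cell are sorted before the
mean/SEM computation, making summaries exactly permutation invariant;
threshold comparisons are non-strict on full-precision values.  The
scale-invariance property (multiplying an indicator's values by k > 0
changes no score) holds exactly in real arithmetic; property tests exclude
inputs sitting exactly on a threshold, where floating-point rescaling can
legitimately flip a non-strict comparison.

## Limitations

Beyond the generator's idealisations: the scores carry no effect size —
a −3 says "a worsening, with confident direction", nothing about magnitude;
confidence here means "the change was comparatively large", not statistical
significance; two-timepoint differences on overlapping collection windows
can double-count events; and the framework hierarchy is taken as given, not
validated.  Duplicated measures must be allocated to exactly one tier in
the registry (the bundled default follows the convention of placing
hospitalisation-type duplicates with the other health-outcome measures in
Tier 1).
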