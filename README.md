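# hpfscore

Two-timepoint improvement scoring, hierarchical aggregation and dashboard
rendering for frameworks of published health indicators — built around the
Aboriginal and Torres Strait Islander Health Performance Framework (HPF),
whose 68 measures are organised into 15 groups within 3 tiers (health status
and outcomes; determinants of health; health system performance).

Published HPF data arrive as hundreds of separate tables of point estimates
rounded to one decimal place, with sporadic suppression of small cells
("n.p."), no measures of spread, and jurisdictions occasionally merged.
Formal statistical tests are rarely defensible on such material.  `hpfscore`
implements a transparent heuristic instead, for analysts who need a
whole-of-framework answer to two questions: *did each indicator change
between reports, and how much confidence does the data lend to that change?*

## The score

For indicator *i* in a jurisdiction, with published values T1ᵢ and T2ᵢ:

- Δᵢ = T2ᵢ − T1ᵢ, and the **unit change indicator** U = sign(Δᵢ) ∈ {−1, 0, +1};
- %Δᵢ = 100·(T2ᵢ − T1ᵢ)/T1ᵢ; **C1** = 1 when |%Δᵢ| ≥ τ (default τ = 2%);
- LAD = max over jurisdictions of |Δᵢ|; **C2** = 1 when |Δᵢ| ≥ q·LAD
  (default q = 0.10);
- **improvement score** = direction × U × (1 + C1 + C2) ∈ {−3, …, +3},

where *direction* ∈ {+1, −1} is the per-indicator direction of effect
(e.g. fewer hospitalisations is an improvement, more screening is an
improvement).  The sign of the score indicates movement towards (+) or away
from (−) improvement; the magnitude (1–3) indicates confidence.  Suppressed
values preclude both confidence indicators but still contribute a direction
("n.p." is inferred to lie below any published value), bounding those scores
to ±1; a zero baseline leaves %Δ undefined and bounds the score to ±2.

Scores are averaged per (jurisdiction, tier, group) cell, denominated by the
number of viable indicators, with SEM (sample sd/√n) and a descriptive 95%
interval (±1.96·SEM), and rendered as a green/red bar dashboard.

## Worked example

The self-assessed health status indicator (a weighted mean of five ordinal
response categories, higher = better) across the eight jurisdictions:

```python
import pandas as pd
from hpfscore import ImprovementScorer

X = pd.DataFrame(
    [("ACT", 63.7, 60.7), ("NSW", 63.4, 65.7), ("NT", 67.1, 69.1),
     ("Qld", 63.7, 65.8), ("SA", 63.3, 60.7), ("Tas", 61.4, 63.3),
     ("Vic", 62.7, 66.6), ("WA", 63.9, 65.1)],
    columns=["jurisdiction", "t1", "t2"],
).assign(indicator_id="self_assessed_health", direction=1)

scores = ImprovementScorer(tau=2.0, q=0.10).fit_transform(X)
print(scores[["jurisdiction", "delta", "lad", "unit_change", "c1", "c2", "score"]]
      .round(1).to_string(index=False))
```

```
jurisdiction  delta  lad  unit_change  c1  c2  score
         ACT   -3.0  3.9           -1   1   1     -3
         NSW    2.3  3.9            1   1   1      3
          NT    2.0  3.9            1   1   1      3
         Qld    2.1  3.9            1   1   1      3
          SA   -2.6  3.9           -1   1   1     -3
         Tas    1.9  3.9            1   1   1      3
         Vic    3.9  3.9            1   1   1      3
          WA    1.2  3.9            1   0   1      2
```

Every jurisdiction's change exceeded 2% relative and 10% of the LAD (3.9,
held by Vic) except WA, whose 1.9% relative change fell just below τ: its
score of +2 flags an improvement detected with less confidence.  ACT and SA
worsened with full confidence (−3).

`ImprovementScorer` and `ScoreAggregator` are scikit-learn transformers, so
scoring and group aggregation compose in a `Pipeline`; the same pipeline is
scriptable from the shell:

```sh
hpfscore run --seed 7 --out out/          # synthetic end-to-end run
hpfscore score --input obs.csv --registry registry.yaml --out scores.csv
hpfscore aggregate --scores scores.csv --level group --out groups.csv
hpfscore dashboard --summaries groups.csv --out out/ --format svg
```

The `synth` subcommand (and `hpfscore.generate`) produces framework-shaped
fixtures — long-format tables with 1-dp rounding, "n.p." suppression, merged
jurisdictions and known latent change directions — so the whole pipeline is
testable without any external data.

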