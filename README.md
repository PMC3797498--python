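# ecoassembly

Tools for asking a classic question in community ecology: when species
composition changes from plot to plot (beta diversity / species turnover), how
much of that change is driven by **habitat specialization** (species tracking
their environmental niches) and how much by **dispersal limitation** (species
simply failing to reach distant sites)? The package targets plot-based
vegetation surveys — plot × species abundance tables with accompanying
environmental measurements and plot coordinates — and implements the full
inference chain used in forest beta-diversity studies, together with a
synthetic-community generator so every stage can be validated against known
ground truth.

## What it computes

**Null-model turnover deviation.** Observed turnover is pairwise Bray–Curtis
dissimilarity, BC(j,k) = Σᵢ|xᵢⱼ − xᵢₖ| / Σᵢ(xᵢⱼ + xᵢₖ). A null model
reassembles each plot by randomly sampling individuals from the regional
species pool (preserving pool relative abundances and per-plot individual
totals, either exactly or in expectation). Over many iterations this yields a
per-pair standardized effect size, the *turnover deviation*

SES(j,k) = (BC_obs − mean BC_null) / sd BC_null,

positive when plots differ more than random assembly predicts. A one-sample
Student's *t*-test asks whether the mean deviation differs from zero.

**Mantel and partial Mantel tests** relate the deviation matrix to Euclidean
environmental distance (EnvD) and geographic distance (GeoD) by permutation,
including each controlling for the other; multiple regression on distance
matrices (MRM) is also provided.

**PCNM + RDA variation partitioning.** Spatial predictors are principal
coordinates of neighbor matrices (eigenvectors of the truncated geographic
distance matrix; truncation = longest minimum-spanning-tree edge). Community
abundances are Hellinger-transformed, environmental variables z-scored and
pruned of collinearity (|r| > 0.80). After permutation-based forward selection
(999 permutations, α = 0.05) in each predictor block, adjusted-R² variation
partitioning splits community variation into pure environment [E|S], spatially
structured environment [E∩S], pure space [S|E] and residual 1 − [E + S], with
reduced-model permutation tests for the conditional fractions.

**Synthetic surveys.** `ecoassembly.simulate` emulates a hierarchical design —
five sites along a ~30 km transect, five plots per site, spatially
autocorrelated environment (including a circular aspect variable), three
vegetation layers (herb/shrub/canopy, ≈80/102/34 species) — and assembles
communities with tunable niche strength ω and dispersal-limitation strength δ.
At ω = δ = 0 assembly reduces exactly to the null model, which is what makes
the whole pipeline testable.

## Worked example

```python
from ecoassembly import SimulationConfig, make_layer_bundle
from ecoassembly.pipeline import AnalysisSettings, run_all

bundle = make_layer_bundle(SimulationConfig(master_seed=99), 99)
reports, summary = run_all(bundle, AnalysisSettings(n_iter_null=1000, n_perm=999, seed=99))
print(summary.round(3).to_string(index=False))
```

prints

```
 layer  mean_deviation  deviation_p  mantel_R_EnvD  mantel_R_GeoD   E|S   E&S   S|E  residual
  herb          19.588          0.0          0.806          0.621 0.094 0.604 0.109     0.193
 shrub          18.097          0.0          0.827          0.678 0.075 0.678 0.073     0.174
canopy          13.450          0.0          0.609          0.916 0.013 0.795 0.085     0.108
```

Every layer shows strongly positive turnover deviation (non-random assembly).
The understory layers, simulated with strong niche filtering, couple most
tightly to environmental distance (Mantel R 0.81–0.83 vs 0.62–0.68 for
geography), while the dispersal-limited canopy layer flips the pattern
(geographic R = 0.92) and loses almost all pure-environment signal
([E|S] = 0.013). The large shared fraction [E∩S] reflects the spatially
structured environment along the transect. `examples/` contains one short
script per capability (null model, Mantel grid, PCNM construction,
variation partitioning, full pipeline).

A thin CLI mirrors the library for shell use:

```bash
ecoassembly simulate --seed 3 --out survey/
ecoassembly run --community herb survey/community_herb.csv \
    --env survey/environment.csv --coords survey/coordinates.csv \
    --seed 3 --out results/
```

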