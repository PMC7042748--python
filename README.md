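# asymflow

Telemetry + population-genetics analysis of asymmetric natal dispersal
between a lake's single inflow and single outflow spawning stream, built
for brown-trout-style systems where both streams drain into or out of a
shared lake-feeding habitat separated by under 100 m.

The package is aimed at fish ecologists and population geneticists who
hold three kinds of data for such a catchment — PIT-antenna detection
logs, codominant multilocus genotypes (microsatellites in Genepop
format), and tag/recapture length records with a water-temperature
series — and want to answer one question from all three at once: *do
spawners home to their natal stream, and if they stray, is the straying
symmetric?*

## What it computes

**Telemetry.** Mature fish detected during the spawning window
(1 November – 28 February) are classed as inflow-only (IO), outflow-only
(OO) or both-streams (B). Maturity at the window median date is imputed
with a growing-degree-day growth law

```
FL2 = FL1 + (a·ln FL1 + b) · DD_T0,     DD_T0 = Σ_d max(0, T_d − T0)
```

whose coefficients (a, b) and base temperature T0 are calibrated from
recaptured fish by weighted least squares with a 0–12 °C grid search on
T0. The maturity threshold is mean − 1 SD of visibly mature fish.

**Population genetics.** Per-group Ho, unbiased He, allelic richness by
rarefaction, private alleles, F_IS with a bootstrap CI; Monte-Carlo exact
Hardy–Weinberg tests; Weir–Cockerham θ (F_ST) with Slatkin linearization
θ/(1−θ), permutation significance and Holm sequential-Bonferroni
correction; Mantel tests and isolation-by-distance regression of
linearized F_ST on waterway distance; effective population size by the
linkage-disequilibrium (Burrows composite r²) method.

**Kinship.** Pairwise dyad classification (unrelated / half-sib /
full-sib / parent–offspring) under the k-coefficient mixture likelihood
P(pair) = k0·P0 + k1·P1 + k2·P2, a Yates-corrected two-proportion test
comparing mixed-site membership between half- and full-sib groups, and
full-sibling deduplication before structure analyses.

**Migration.** A two-deme Bayesian migrant-indicator MCMC ("BayesAss-
lite"): each sampled individual carries a latent origin (resident or
first-generation migrant), migration rates have Uniform[0, 1/3] priors,
allele frequencies Dirichlet(1) priors, and everything is Gibbs-sampled
with multi-chain R-hat and per-chain deviance diagnostics. The output is
the posterior for m(inflow→outflow) and m(outflow→inflow) — the
asymmetry is the headline result.

**Synthetic catchment.** `asymflow.synthcatch` generates complete linked
datasets (two stream demes under the F-model, polygamous families with
straying and both-stream-spawning parents, a lake pool, antenna
detections, temperatures, growth records) with every true parameter
recorded, so all of the above is validated against known truth without
any field data.

## Worked example

```python
from asymflow.synthcatch import SimulationConfig, simulate_dataset
from asymflow.asymigrate import MigrationConfig, run_migration_mcmc

ds = simulate_dataset(SimulationConfig(seed=1))   # 146 inflow + 124 outflow + 100 lake
juv = ds.genotypes.subset([i for i, g in enumerate(ds.genotypes.groups)
                           if g in ("inflow", "outflow")])
post = run_migration_mcmc(juv, ("inflow", "outflow"), MigrationConfig(seed=1))
print({k: round(v, 4) for k, v in post.means.items()})
```

prints

```
{'m_inflow_to_outflow': 0.2941, 'm_outflow_to_inflow': 0.0094}
```

— the sampler recovers the simulated asymmetry: roughly 29% of outflow
juveniles are estimated to be first-generation migrants from the inflow
(the dataset's realized fraction is 25.8%) against about 1% in the
reverse direction. On the packaged catchment distance matrices,

```
$ asymflow ibd mantel
Z = 523.51  p = 0.0114  (9999 permutations)
$ asymflow ibd regress
slope = 3.430e-06  intercept = 0.00193  R2 = 0.813  p = 4.374e-06
```

a positive Mantel association and an isolation-by-distance fit with
R² = 0.81: genetic distance grows with waterway distance across the six
sampling sites.

The full pipeline (simulate → QC → growth → telemetry → popgen → IBD →
Ne → kinship → migration) runs with

```
asymflow run --outdir out --seed 1
```

and writes per-stage CSV/JSON artifacts plus a consolidated
`report.json`.

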