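# Methods

This note documents the models behind each stage, the defaults and why
they are what they are, what the synthetic catchment does and does not
emulate, and the numerical choices a maintainer would want to know.

## Growth and maturity

Growth of lake-feeding fish between two captures is modelled as linear
in growing degree days: FL2 = FL1 + (a·ln FL1 + b)·DD_T0, with
DD_T0 = Σ max(0, T_d − T0) over daily mean temperatures in (date1,
date2]. The log transform of initial length encodes the
von-Bertalanffy-style decline of growth-per-degree-day with size.
Sub-daily temperature input is aggregated to daily arithmetic means;
internal gaps up to 5% of the queried window (configurable) are linearly
interpolated, larger gaps raise an error.

Calibration searches T0 over a 1 °C grid on 0–12 °C inclusive and, for
each candidate, fits (a, b) by least squares of observed growth on
(DD·ln FL1, DD) with no intercept — equivalently, a DD²-weighted
regression of growth-per-degree-day on ln FL1. The weighting matters:
measurement noise is additive on length (a few mm per capture pair), so
the per-degree-day response carries noise of σ/DD, and an unweighted fit
lets short or winter-heavy intervals dominate; in simulation the
unweighted variant selects a base temperature one degree below truth
almost systematically, while the weighted fit is centred. The winning T0
maximizes the growth-scale R²; ties break toward the lower T0 for
determinism. The reported `r_squared` is on the growth-per-degree-day
scale, the scale on which such calibrations are conventionally quoted
(≈0.7–0.8 on synthetic data at 3 mm noise).

A caveat worth stating plainly: with ~87 recapture pairs and 3 mm
measurement noise, adjacent base temperatures differ by under 1 mm of
predicted growth per observation, so the exact T0 is weakly identified —
simulations select the true 5 °C in roughly two-thirds of replicates and
a value within ±1 °C essentially always. Coefficients at the selected T0
are recovered tightly (|â − a| < 0.01 nearly always). Downstream use is
insensitive: predictions at T0 ± 1 with refitted coefficients differ by
a few mm at most.

The maturity threshold is round(mean − 1·SD) of visibly mature fish
(multiplier configurable); the conservative 1-SD margin aims to exclude
large immature fish from the spawning-behaviour analysis.

## Telemetry classification

A spawning window runs 1 November – 28 February inclusive (leap day
excluded). Per season, a fish's class is determined by the set of
streams with at least one in-window detection: inflow-only (IO),
upper-outflow-only (OO), or both (B). Only inflow and upper-outflow
antennae participate in classification; a lower-outflow antenna can be
registered for catchment-exchange reporting but is ignored here. Fish
detected only outside every window are excluded, as are fish whose
estimated fork length at the window median date (day 60 of the 120-day
window, 30 December) is below the maturity threshold in the season of
detection. The overall (multi-season) class uses the union of in-window
detections, so per-stream totals satisfy total = exclusive + both.
Nocturnality is the fraction of detections between the detection date's
sunset and the next sunrise, from a user-supplied solar table (default
17:00/08:00 winter values).

## Population-genetic statistics

Genotypes live in a `GenotypeTable` (individuals × loci × 2 integer
allele codes, 0 = missing) read from and written to Genepop files (2- or
3-digit codes). QC mirrors standard microsatellite practice: individuals
with fewer than 10 scored loci are dropped (strict less-than), and a
locus is flagged when its F_IS exceeds 0.15 in at least 6 sampling
groups — a heterozygote-deficit screen for null alleles.

Per group: Ho is the observed heterozygote fraction averaged over loci;
He is Nei's unbiased gene diversity (2n/(2n−1))(1 − Σp²) averaged over
loci; allelic richness is Hurlbert rarefaction Σ_a [1 − C(N−N_a, g)/
C(N, g)] at g gene copies (default: the group's smallest per-locus 2n;
cross-group comparisons should pass a common g); private alleles are
alleles absent from every other group; F_IS = 1 − Ho/He on the
locus-averaged values with a 1,000-rep bootstrap over loci for the CI.
The alternative Weir–Cockerham small-sample f is deliberately not the
default — the simple ratio is transparent and the bootstrap captures
locus sampling variance, which dominates here.

Hardy–Weinberg testing is a Monte-Carlo exact test: alleles at a locus
are permuted among the scored individuals and re-paired; the statistic
is the heterozygote count with two-sided extremeness measured from the
permutation mean, and p = (1 + #extreme)/(1 + n_mc). Differentiation
uses the Weir–Cockerham (1984) variance-components θ, accumulated over
alleles and loci with pairwise deletion of missing genotypes, and the
Slatkin linearization θ/(1−θ) as genetic distance (negative estimates
pass through the same formula). Significance comes from permuting
individuals between the two groups (p = (1 + #{θ_perm ≥ θ_obs})/
(1 + n_perm)); multiple comparisons use Holm's sequential Bonferroni.
Same-site temporal samples are pooled when no within-site between-year
comparison is significant at uncorrected α = 0.05.

## Isolation by distance

The Mantel statistic is the raw lower-triangle cross-product
Z = Σ_{i<j} X_ij·Y_ij, with the null built by jointly permuting the
row/column order of one matrix; the default test is one-sided for
positive association, as isolation by distance predicts. The IBD
regression is plain OLS of unfolded linearized F_ST on waterway metres.
The package ships the six-site catchment distance matrices (long-format
CSV) used by the worked example; recomputing Z from the 5-decimal
rounded genetic distances gives 523.51 against the published 525.47 —
the ~0.4% difference is input rounding, not method.

## Effective population size

The LD method: Burrows composite disequilibrium between two loci is the
covariance of per-individual allele dosages, and the r reported is
exactly the Pearson correlation of the dosage vectors (equivalently
Δ̂ normalized by dosage standard deviations). Per locus pair, allele
pairs above the minor-allele-frequency threshold (default 0.02)
contribute r² with the most common allele dropped (only k−1 dosages are
independent); pairs average unweighted. The drift signal is
r²' = mean r² − E[r²], with E[r²] the random-mating sampling expectation
(1/S + 3.19/S² for S ≥ 30, else 0.0018 + 0.907/S + 4.44/S²), and
Ne = (1/3 + √(1/9 − 2.76 r²'))/(2 r²'), infinite when r²' ≤ 0. The CI is
a delete-one jackknife over locus pairs mapped through the Ne transform.
Because the expectation formulas were calibrated for a slightly
different r² weighting, desk-scale simulations show a mild upward bias
(order tens of percent at 12 loci) and honest but under-covering
jackknife intervals; we document this rather than chase bit-level
compatibility with any particular reference implementation.

## Kinship

A dyad's per-locus likelihood under relationship k = (k0, k1, k2) —
the probabilities of sharing 0/1/2 alleles identical by descent — is
k0·P0 + k1·P1 + k2·P2, where P0 is the product of HWE genotype
probabilities, P1 conditions on exactly one shared IBD allele (a random
copy from the first genotype, the partner allele drawn from the
population), and P2 is the probability of the shared genotype. Presets:
U = (1,0,0), HS = (0.5,0.5,0), FS = (0.25,0.5,0.25), PO = (0,1,0), plus
a duplicate-sample check under (0,0,1). Loci multiply; allele
frequencies come from the pooled sample (justified by the weak
structure this package targets). Classification takes the
maximum-likelihood category; a dyad is *accepted* (reported) when its
posterior-style weight L_max/ΣL exceeds 0.9. For same-cohort juvenile
dyads the category set is (U, HS, FS): genotypes alone cannot separate
PO from FS — that distinction needs cohort or age information, which is
how candidate parents should be supplied. At 14 microsatellite loci the
mean FS-versus-HS log-likelihood ratio of a true full-sib pair is only
~1.5 nats, so demanding weight > 0.9 for recall would cap it near 55%;
the weight gate instead serves precision (unrelated pairs essentially
never pass it). Genotyping error is not modelled — loci are assumed
QC-filtered.

Mixed-site comparison: groups containing lake-sampled members are
excluded (the lake is feeding, not nursery, habitat), and the
proportion of groups containing both an inflow- and an outflow-sampled
member is compared between half- and full-sib groups with a Yates
continuity-corrected two-proportion chi-square (matching R's
`prop.test`). Full-sib deduplication collapses connected components of
accepted FS dyads to one representative: antenna-detected individuals
first, then most scored loci, then highest id.

## Migration MCMC

The "BayesAss-lite" model: two demes; each sampled individual carries a
latent origin z ∈ {resident, first-generation migrant from the other
deme}; P(z = migrant) = m_d for deme d with independent Uniform[0, 1/3]
priors on the two rates (the 1/3 bound is the identifiability constraint
of this model class); deme allele frequencies have Dirichlet(1) priors;
the genotype likelihood is the HWE probability under the origin deme's
frequencies. All updates are Gibbs: origins given frequencies and rates,
frequencies given origins (Dirichlet conjugacy on gene copies grouped by
origin), and each rate from its truncated-Beta full conditional (inverse
regularized-incomplete-beta sampling). Second-generation ancestry and
inbreeding are deliberately out of model.

Defaults are 2,000 burn-in + 10,000 sweeps (thin 5) and three chains;
the conjugate scheme mixes orders of magnitude faster than
Metropolis-based samplers of the same model, and these lengths give
Monte-Carlo error well below posterior width at the package's problem
sizes. Chains start overdispersed — one from the residents-only
configuration (with a short origin-clamped warm phase so frequencies
anchor on the empirical samples), the others from one-shot
empirical-frequency assignments at two prior strengths. At very weak
differentiation this posterior is genuinely multimodal: a
blended-frequency mode (both deme frequency vectors collapse toward each
other and the indicators decouple from the data) can trap chains even
though its data fit is clearly worse. Following established practice for
migrant-indicator models, each chain's posterior-mean data deviance is
recorded and chains more than 20 units above the best are excluded from
the combined posterior; exclusions and the between-chain R-hat are both
reported, and `converged` is true only when all chains agree. Reported
intervals are 95% highest-posterior-density intervals, not equal-tailed
quantiles: the parameter is truncated to [0, 1/3] and posterior mass
frequently piles against 0, where an equal-tailed interval can never
contain the boundary.

Leave-one-out assignment (`assign_loo`) complements the MCMC: each
individual is scored under every deme's allele frequencies
(re-estimated without the focal individual for its own deme, add-one
smoothing for unseen alleles) — the directional excess of
cross-assignments is a model-light check of the same asymmetry.

## The synthetic catchment

The generator produces the statistical structure the analysis assumes,
with every true parameter recorded for oracle comparisons.

* **Frequencies.** Per locus, ancestral frequencies are
  Dirichlet(concentration·1) over 10 alleles (the polymorphism of a
  well-chosen 14-locus microsatellite panel); each stream deme drifts as
  Dirichlet(ancestral·(1−F)/F) with F = 0.02, giving sampled pairwise θ
  of order 0.005–0.03 — the weak-differentiation regime. Realized He
  runs ≈0.78, a little above typical field values (a flat Dirichlet is
  more even than real microsatellite spectra); this makes genotypes
  slightly more informative per locus and is a known emulation gap.
* **Families and migration.** Each stream hosts 100 families whose sires
  and dams come from per-stream polygamy pools (pool size 0.7× the
  family count, so either sex can found several families — half-sib
  scenarios of both the two-males and two-females kind). Each offspring
  is, independently with probability m (0.30 into the outflow, 0.01 into
  the inflow), instead the product of a straying pair whose gametes come
  from the source deme, drawn from a small migrant-pair pool: such
  offspring are first-generation migrants in exactly the sense of the
  MCMC's model, and the realized migrant fraction among sampled fish is
  binomial around m and recorded in the truth record. Separately, with
  probability m·0.2 a family shares one parent with the source stream —
  a parent that spawns in both streams in one season — which is what
  creates mixed-site half-sibling dyads (and F1-hybrid offspring the
  first-generation model cannot represent; at these rates they are a
  small perturbation). With m = 0 both mechanisms vanish. The family
  count matters more than it looks: at 100 families per stream the
  sampled juveniles carry the low relatedness levels seen in real
  stream samples, whereas few-family configurations inject enough
  sibling pseudo-replication to tip the migration posterior into its
  blended mode.
* **Sampling.** 146 inflow + 124 outflow juveniles (matching the pooled
  juvenile groups of the motivating system) and a 100-fish lake pool
  drawn from both streams' unsampled offspring.
* **Telemetry.** Scripted IO/OO/B classes (default proportions
  39:107:62), one window per fish, Poisson(20) antenna passes per stream
  visit, per-pass Bernoulli detection (default 0.9 — antenna efficiency
  is a free parameter, not a field value), timestamps night-biased at
  0.95.
* **Temperatures and growth.** A sinusoidal annual cycle (mean 10.5 °C,
  amplitude 7.5 °C) floored at 4 °C — temperate lake surfaces plateau
  near the density maximum of water in winter rather than tracking a
  sinusoid minimum — plus N(0, 1 °C) daily noise. Recapture pairs have
  15–505-day intervals with both captures in the April–October field
  season, FL1 ~ U(90, 280) mm, and 3 mm Gaussian growth noise.

All randomness flows from a single seeded `numpy` generator; identical
seeds give byte-identical datasets. What passing tests on this generator
do **not** show: robustness to genotyping error or null alleles (not
simulated; the QC filters are tested on constructed cases instead),
lake spawning, tag loss, second-generation admixture, or temperature
regimes unlike a temperate maritime lake.

## Numerical choices and edge cases

* θ with a zero denominator (no variance at any locus) returns 0; a
  fixed difference returns exactly 1, where the linearization is
  undefined and raised/flagged rather than silently infinite.
* Monomorphic loci contribute He = Ho = 0 to averages, are skipped by
  the HWE test (p = 1) and carry no θ information.
* Permutation and Monte-Carlo p-values use the add-one form
  (1 + #extreme)/(1 + n), so p is never 0.
* Degree-day queries are additive over date partitions and
  non-increasing in T0; observations with zero degree-days at a
  candidate T0 are dropped for that candidate only.
* The dyad classifier precomputes per-locus genotype-pair kernels, so
  all-pairs scoring of a few hundred individuals takes under a second;
  results are identical to the per-pair likelihood path (tested).
* HPD intervals use the shortest-window order statistic; at 2,000+
  samples the discretization error is well below reporting precision.

## Known limitations

The migration model is first-generation-only and two-deme; hybrids bias
rates upward slightly and >2 demes are out of scope. The Ne module
documents (rather than removes) its small upward bias. The growth base
temperature is weakly identified at realistic noise; treat the selected
T0 as a calibration convenience, not a biological estimate. Sibship
power at 14 microsatellites supports dyad-level inference only — full
pedigree reconstruction needs either more markers or dedicated
software.
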