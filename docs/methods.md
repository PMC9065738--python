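# Methods

`pyuntb` asks one question of an OTU count table five different ways: can
stochastic neutral drift — equivalent per-capita birth, death and dispersal
across species — explain the observed community structure, or is
deterministic selection required?  This note records the models, the
conventions, and the design choices behind each analysis, and what the
synthetic-data generators do and do not emulate.

## Data model and filtering

The universal input is an OTU × sample matrix of non-negative integer read
counts.  Samples with fewer than 100 reads are excluded by default before
any neutrality test: below that depth a species-abundance distribution
(SAD) carries almost no information about assembly.  The filter is
idempotent and can be disabled.  No rarefaction is performed anywhere;
every likelihood used here conditions on the observed sample size J, which
makes rarefaction unnecessary for the tests themselves (it would only
discard reads).  Zero-count species are dropped from per-sample SADs
because all SAD likelihoods condition on observed species.

## Hubbell neutral model and the exact test

For one SAD D = (n_1, …, n_S) with J = Σ n_i, the neutral local community
coupled by immigration number I to a metacommunity with fundamental
biodiversity number θ assigns D the sampling-formula probability

    P(D | θ, I, J) = J! / (∏ n_i ∏_j Φ_j!) · θ^S / (I)_J
                     · Σ_{A=S}^{J} K(D, A) I^A / (θ)_A ,

where A counts immigrant ancestors, Φ_j is the number of species with
abundance j, (x)_N is the rising factorial, and K(D, A) is a convolution of
unsigned-Stirling-number coefficients.  Everything is computed in log
space; K(D, A) is independent of (θ, I) and cached per SAD, so likelihood
evaluation during optimization costs one log-sum-exp.  Correctness is
pinned by two independent oracles in the test suite: exhaustive
dynamic-programming enumeration of all assembly histories for J ≤ 8
(agreement to 1e-9 in log space) and the Ewens closed form in the
I → ∞ limit (relative error ≤ 1e-6 at I = 1e8, checked up to J = 2000).

Maximum-likelihood fitting runs bounded L-BFGS-B with the analytic gradient
over (log θ, logit m), θ ∈ [1e-3, 1e5], m ∈ [1e-6, 1−1e-6], from a
deterministic 3 × 3 start grid (θ ∈ {0.5, 20, 800} × m ∈ {0.1, 0.5, 0.9}).
Degenerate SADs (single species, or all singletons, where θ̂ diverges) are
returned as boundary fits with a warning, θ capped at 1e5.

**Weak identifiability.**  For a single SAD the profile likelihood in m is
a shallow double well: a low-m/high-θ mode and a high-m/low-θ mode
typically differ by under one log-unit, and the global optimum falls on
either side depending on sampling noise.  θ̂ is stable (median recovery
within a factor of two at J = 2000), but m̂ from one sample should not be
trusted — pooling sites (the multi-site model below) is the remedy.  This
is a property of the model, not of the optimizer; the package reports the
exact MLE rather than steering toward the generating values.

**Pseudo-P test.**  The exact neutrality test simulates n_sim SADs of the
same J from the fitted model (a two-stage urn drawing immigrant lineages at
rate I and assigning lineages to species by a Chinese-restaurant step at
rate θ — an exact draw from the sampling formula, verified by chi-square
against the enumerated distribution) and reports

    pseudo-P = (1 + #{simulated log-likelihood ≤ observed}) / (1 + n_sim).

Large pseudo-P means the observed likelihood is typical of neutral data;
neutrality is rejected when pseudo-P ≤ α (default 0.05).  Ties count
toward the numerator and the +1 smoothing forbids exactly zero — both
conservative toward neutrality.  By default each simulated replicate is
refitted before its likelihood is compared (full parametric bootstrap,
warm-started at the parent fit); measurement during development showed this
convention is almost exactly calibrated (type-I error 5.5% at nominal 5%
over 200 null datasets, Kolmogorov–Smirnov distance 0.04 from uniform),
whereas the faster `refit=False` mode, which evaluates replicates at the
parent parameters, is conservative (2% at nominal 5%, visibly non-uniform
pseudo-P).  The fast mode is kept, labeled approximate.  Samples above
30,000 reads are subsampled without replacement to 30,000 before testing
(flagged in the result): simulation cost grows with J while the abundance
information the test uses saturates far below that depth.  Defaults:
n_sim = 500 for analysis, 200 in the calibration suites.

Because the neutrality-test convention treats large P as "passes
neutrality", false-discovery-rate correction is inapplicable (it could
only raise P-values and thus loosen the test), so the package instead
provides a P-threshold sweep: the fraction of samples passing as the
threshold rises, a non-increasing curve.

## Multi-site neutral model (hierarchical Dirichlet process)

All samples of a treatment are modeled jointly: metacommunity relative
abundances β ~ stick-breaking(θ); each site i an independent Dirichlet
process around β with concentration I_i = m_i (N_i − 1)/(1 − m_i).  The
Gibbs sampler uses the direct-assignment representation: per site × species
ancestor-lineage ("table") counts a_ik ∝ s(n_ik, a)(I_i β_k)^a (sampled by
a vectorized Gumbel-max step grouped by n), β | tables ~ Dirichlet, θ by
the auxiliary-variable update for a Dirichlet-process concentration under a
Gamma(1, 0.1) prior, and each log I_i by shrinkage slice sampling under a
log-uniform prior on [1e-2, 1e6] (the model itself carries no natural
priors; these are deliberately vague).  The number-of-species distribution
P(S | θ, N) = s(N, S) θ^S Γ(θ)/Γ(θ + N) (unsigned Stirling numbers,
log-space recurrence) is exposed as `antoniak_pmf` and normalization-tested
to 1e-10 up to N = 50.  Defaults n_gibbs = 5000, burn-in = 2500; the
calibration suites use short chains (a few hundred iterations), which
recover θ within a factor of two at 10 sites × J = 2000.  Convergence is
monitored by split-chain potential scale reduction on log θ; values above
1.2 set a warning flag on the fit rather than raising.  The posterior-mean
metacommunity vector spreads its unobserved-species mass over a 200-class
stick-breaking tail at the posterior-mean θ.

**Test statistics.**  P_M and P_L are parametric-bootstrap pseudo-P values
with the same +1-smoothed convention as the single-site test.  Simulated
datasets come from the fitted model via a shared metacommunity
Chinese-restaurant process over immigrant lineages (so species identities
are shared across sites without explicit truncation).  The statistic must
be exchangeable over species labels, because simulated species carry no
correspondence to observed ones.  An earlier candidate — per-site
Dirichlet-multinomial likelihood given the posterior-mean β — fails
exactly where it matters: data engineered to be deterministically identical
across sites match the posterior mean almost perfectly and receive the
highest possible likelihood, so the most extreme violation of neutral
sampling noise would never be rejected.  The statistics used instead are
the Ewens log-likelihood of the pooled (all-sites) SAD at θ̂ for the
metacommunity level, and the per-site sampling-formula log-likelihood at
(θ̂, Î_i) for the local level.  Both are applied identically to observed
and simulated data, so the bootstrap remains internally calibrated;
self-generated neutral data give P_M well above 0.05 while the
identical-even-sites fixture gives P_M ≈ 0.01.

## Sloan near-neutral model

The Sloan model relaxes strict neutrality to a per-species test.  A local
community of N_T individuals exchanges individuals with a source community;
for species i with source frequency p_i the per-renewal transition
probabilities in local abundance N_i are

    P(N_i + 1 | N_i) = (1 − N_i/N_T) [m p_i + (1 − m) N_i/(N_T − 1)]
    P(N_i − 1 | N_i) = (N_i/N_T) [m(1 − p_i) + (1 − m)(N_T − N_i)/(N_T − 1)]

with the stay probability as the complement (normalization and the
absorbing-boundary identities are property-tested on a dense grid).  The
stationary distribution of x_i = N_i/N_T is approximated by the beta
diffusion limit Beta(N_T m p_i, N_T m (1 − p_i)).  m is fitted by least
squares between observed occurrence frequencies (fraction of destination
samples where a species exceeds the detection threshold d, default 1/N_T)
and the beta upper-tail prediction; R² can legitimately be negative and is
then reported as a failed fit, not an error.  N_T defaults to the rounded
mean destination sample total.  Species are classified against the central
95% beta interval of their mean local relative abundance (below / neutral /
above ⇒ negatively selected / drifting / positively selected); an
occurrence-frequency-interval mode is available as an alternative.  Species
with p_i ∈ {0, 1} have a degenerate beta and are excluded with a reason.
Source and destination may be the same sample set (the same-set scheme,
which raises apparent neutrality because the two sides share noise).
m is reported as a probability in (0, 1]; the unbounded product N_T·m is
reported alongside for comparison with parameterizations that quote
immigration rates rather than probabilities.

## Stochasticity ratio and its normalization

For each sample pair, the observed Ružička similarity (Σ min / Σ max over
relative abundances — the abundance-weighted Jaccard index) is compared
with its mean over n_null (default 1000) null-model randomizations.  Pairs
driven more similar than the null contribute Ē/C, pairs driven less
similar contribute (1 − Ē)/(1 − C); SR is the mean contribution.  Exact
ties are excluded from both counts (the defining inequalities are strict
and ties have measure zero for continuous abundances); the all-ties corner
case returns SR = 1 with a warning.  The normalized ratio NSR min–max
rescales SR so the fully deterministic extreme (C pushed to 1 for
more-similar pairs, 0 for less-similar pairs) maps to 0 and the
null-coincident configuration maps to 1; this realizes the intended
anchors with a simple closed form, and is the one statistic here whose
numeric values may differ from other published normalizations of the same
ratio.  Null algorithms are pluggable: `proportional_frequency` (default —
preserve each sample's richness, draw species with probability proportional
to regional occupancy, assign abundances proportional to regional means),
`richness_uniform`, and `identity` (degenerate, for tests).

The stochastic-limit calibration fixture draws every sample from the
proportional-frequency process itself over a 300-species pool with a
shallow power-law (Zipf exponent 0.5) abundance profile, occupancy ∝
abundance^0.25, and per-sample richness uniform on [100, 200].  The pool
shape matters: SR compares one observed draw per pair with the null mean,
so its self-null value is 1 minus a term proportional to the spread of the
pair-similarity distribution.  Under heavily dominated (e.g. steep
log-series) pools that spread is large relative to 1 − C and SR
under-shoots its limit even on genuinely null data; the shallow profile
keeps per-pair similarity concentrated, which is also the regime of the
high-similarity virome treatments this fixture stands in for.  Measured
mean SR over 50 replicate metacommunities is ≈ 0.95.

## Synthetic community generators

Local assembly is a sequential urn adding J individuals: the (n+1)-th is an
immigrant with probability I/(I+n) (I from m and J; I = ∞ at m = 1, where
the sample is exactly multinomial from the metacommunity — chi-square
checked), else a copy of a uniformly chosen resident.  Metacommunity
profiles: stick-breaking(θ) truncated at s_max and renormalized;
log-series (β_k ∝ x^k / k over ranks, x ∈ (0,1)); even.  Two non-neutral
urns perturb only the reproduction step, each governed by one scalar so
that zero is exactly neutral (bit-identical streams, enforced by splitting
the parameter and urn random streams):

* **IF** — per-species fecundities f_k ~ Gamma(mean 1, CV = effect), drawn
  once per dataset; parents chosen ∝ N_k f_k, immigrants ∝ β_k f_k.
  Raises dominance.
* **PC** — parents chosen ∝ N_k^(1−effect), a rare-species advantage.
  Raises evenness.

These are the simplest dynamics with the required reduction and direction
properties — stand-ins motivated by the competition/fitness-difference
dichotomy, not transcriptions of any published simulator.  The urn
formulation conserves J exactly and is static: no explicit birth–death
time series, no spatial structure, no local speciation.  Synthetic tables
therefore emulate the count structure, depth range (J ≈ 10²–10⁵), richness
range (tens to hundreds of OTUs) and assembly regime of real virome
treatments, but not sequencing artifacts (chimeras, contamination,
compositional biases) — passing calibration here says the statistics
behave correctly on ideal data, not that any particular real dataset is
neutral.

## Power analysis

Power against a non-neutral alternative is estimated by simulation:
datasets matched to a sample's J and fitted (θ, m) are generated by the IF
or PC urn around a log-series metacommunity, each tested for neutrality,
and power is the fraction with pseudo-P ≤ α.  The log-series shape
x = 0.99 (1000 ranks) is the calibration point at which the effect-0
generator — which is exactly neutral — yields near-uniform pseudo-P
(mean 0.55, rejection rate 2.5%), so power at effect 0 reduces to the
type-I error as it must; steeper or flatter profiles break this reduction
in opposite directions.  Two decision rules combine the observed pseudo-P
with the non-neutral average Ave.P: a non-neutral process is *detected*
iff P_observed < Ave.P (ties favor neutrality), and a *false negative* is
a detection in a sample that nevertheless passed the neutrality test
(P_observed > α).  Summaries report both fractions.

Measured behavior at the standard fixture (J = 1000, θ = 20, m = 0.3):
the PC alternative is detected with power ≈ 0.9–1.0 at effect 0.8, while
the IF alternative is essentially undetectable (power ≈ 0 at CV = 2–4,
with mean pseudo-P *rising* with CV).  The IF signature — a persistent
per-species fecundity tilt — is largely absorbed by refitting the neutral
model, since a tilted metacommunity is itself a legal neutral
configuration; only the reproduction-step tilt is in principle detectable
and it is weak at this J.  The package reports this honestly rather than
inflating IF power; single-sample neutrality "passes" are correspondingly
weak evidence against fitness differences of this kind.

## Pipeline

The orchestrator runs per-treatment HNM tests (with passing rate and
threshold sweep), SR/NSR, and the multi-site fit and tests; Sloan fits on
ordered treatment pairs (or same-set); optional per-sample power analysis.
All randomness derives from one configured seed through named substreams,
so reruns are byte-identical; stage failures are logged, marked in the
report, and do not halt other stages.

## Problem sizes in the shipped suites

The test and acceptance suites run the full analyses at reduced but
statistically meaningful sizes chosen once: 200 null datasets for type-I
calibration (J = 500, n_sim = 200), 50 metacommunities for the SR limit
(20 samples, 200 null draws), 20 replicates per parameter-recovery check,
short Gibbs chains (600/200) for the multi-site recovery, and 3 × 30
datasets per power arm (n_sim = 100).  Full-scale analysis defaults
(n_sim = 500, n_null = 1000, n_gibbs = 5000) remain the package defaults.

## Known limitations

* m from a single SAD is weakly identified (see above); report it with the
  multi-site fit when more than one sample exists.
* The Stirling-number table grows quadratically with the largest single
  OTU abundance after subsampling; extremely dominated multi-million-read
  samples rely on the 30,000-read subsampling path.
* The NSR normalization is one defensible choice among published variants;
  compare NSR values across tools only qualitatively.
* The IF/PC generators are minimal stand-ins; power numbers quantify
  detectability of *these* dynamics, not of every conceivable non-neutral
  process.
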