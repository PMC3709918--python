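# Methods

`aflpscan` analyses dominant biallelic markers (AFLP band
presence/absence) for signatures of divergent selection between
host-plant-affiliated insect populations, replicating a complete
genome-scan workflow: Bayesian allele-frequency estimation, multi-locus
FST and hierarchical AMOVA, a Bayesian FST-outlier scan with a
replicated-pair candidate rule, and an MCMC randomization test for
gametic disequilibrium between dominant loci.  This note records the
models, the numerical choices, and what the synthetic-data tests do and
do not establish.

## The dominant-marker observation model

A dominant locus exposes only the recessive homozygote: the band is
absent iff the genotype is "-/-".  Under Hardy-Weinberg equilibrium
(assumed throughout, as is standard for AFLP analysis) the band-absence
probability is u = q², with q the frequency of the non-amplifying
("null") allele.  All estimators in the package are built on counts
(m, N): band-absent individuals out of scored individuals, accumulated
per locus and population with missing phenotypes excluded pairwise.

### Bayesian frequency estimate (`dominant_freq`)

With a Beta(a, b) prior on u, the posterior is u ~ Beta(m+a, N-m+b) and

    q_hat = E[sqrt(u)] = B(m+a+1/2, N-m+b) / B(m+a, N-m+b),

evaluated through `scipy.special.betaln`.  The default prior is uniform
(a = b = 1); an "empirical" option fits (a, b) by method of moments to
the across-loci distribution of m/N.  Gene diversity is the plug-in
He = 2 q_hat (1 - q_hat), with no small-sample correction.  A unit test
verifies the closed form against numerical integration of the posterior
to 1e-8 over a grid of (m, N, a, b).

Two conventions deliberately bypass the Bayesian estimate:

* **Polymorphism / private-locus / MAF classification** uses the ML
  frequency p = 1 - sqrt(m/N).  Fixation thresholds (p > 0.99 or
  p < 0.01) are statements about the observed sample; posterior
  shrinkage keeps pooled estimates away from the bounds at any realistic
  sample size (m = 0 at N = 3000 still gives p = 0.984), which would
  make a 0.99 rule unsatisfiable.
* **FST** uses ML frequencies with an explicit sampling-variance
  correction (below); shrinkage of the Bayesian means compresses
  between-population contrasts roughly 2.5-fold at n = 24 and would
  bias FST down by a factor ~2.

### FST (`differentiation`)

The Lynch-Milligan variance-component construction: per locus with J
populations,

    among  = sum_j (q_hat_j - q_bar)² / (J-1)  -  mean_j Var(q_hat_j)
    within = mean_j q_hat_j (1 - q_hat_j)
    FST    = among / (among + within),

multi-locus FST as the ratio of sums over loci.  Negative per-locus
values are retained so that distribution summaries (mean, kurtosis, KS
comparisons between countries) remain unbiased; truncation is a display
decision only.

The correction term Var(q_hat) for q_hat = sqrt(m/N) is computed
**exactly under the binomial law** and averaged over the Jeffreys
posterior Beta(m+1/2, N-m+1/2) of u, cached per sample size.  The usual
first-order Taylor term (1-x)/4N overstates the estimate at true
FST 0.10 by ~0.015, and an exact plug-in at x = m/N collapses to zero at
fixed loci and overstates it by ~0.03; the Jeffreys-averaged variant
recovers simulated FST 0.10 as 0.10-0.11 and is within 0.01 of zero
under no differentiation (684 loci, n = 24).  Caveat: with literally
identical counts in both populations the observed among-locus variance
is exactly zero, so any sampling-corrected estimator returns a small
negative value; "no differentiation" means independent samples from
equal frequencies, and that is what the null tests simulate.

Permutation P-values for a population pair shuffle individuals between
the two samples (999 permutations, add-one rule).

### Hierarchical AMOVA (`differentiation.amova`)

The three-level decomposition (between host types / among populations
within host type / among individuals within populations) is computed on
**expected null-allele dosages**: band absent contributes dosage 2;
band present contributes the HWE conditional expectation
E[dosage | not -/-] = 2q/(1+q), with q the population's Bayesian
estimate.  Variance components come from unbalanced nested ANOVA mean
squares with the standard expected-mean-square coefficients; coancestry
coefficients are ratios of summed components (theta_CT, theta_SC,
theta_ST) with percentile bootstrap CIs over loci (1,000 resamples by
default).  This is a surrogate for a genotype-level AMOVA — dominant
data do not identify individual genotypes — and exactness is not
claimed; a brute-force mean-square oracle on small balanced designs
verifies the arithmetic, and planted host-level divergence is recovered
in ≥95 % of simulation seeds.

## FST-outlier scan (`outlier_scan`)

The scan re-implements the Multinomial-Dirichlet island model with the
locus/population decomposition of differentiation used by Bayesian
genome-scan software for dominant data.  For a pair of populations
j ∈ {1,2} and loci i:

    m_ij ~ Binomial(N_ij, q_ij²)
    q_ij ~ Beta(c_ij q̄_i, c_ij (1-q̄_i)),   c_ij = (1-F_ij)/F_ij
    logit(F_ij) = α_i δ_i + β_j
    q̄_i ~ Uniform(0,1),  α_i ~ N(0,1),  β_j ~ N(-1, 1.8²)
    δ_i ~ Bernoulli(1/11)        (prior odds 10 for the neutral model)

The dominant-data likelihood is the exact Binomial(N, q²) on
band-absence counts (HWE, no residual inbreeding term).  A
reversible-jump MCMC samples (q̄, q, α, β, δ) with random-walk updates
(reflection at [0,1] for frequencies), adaptive proposal scales tuned
during burn-in toward ~30 % acceptance, and a jump move that toggles
δ_i.  The jump proposes α from a normal centred on a pilot moment
estimate of logit FST_i given the current β (with the full Hastings
correction); proposing from the prior cannot reach large effects and
stalls mixing.  Desk-scale chain defaults are burn-in 5,000 and 20,000
kept iterations thinned by 10, all configurable; the test-suite and
acceptance runs use burn-in 1,500 / 4,500 kept / thin 3, which split-
chain diagnostics show is sufficient at these data sizes.

Outputs per locus: the posterior inclusion probability
PIP = E[δ_i] (positive posterior α indicating divergent selection,
negative balancing), the posterior mean of α given inclusion, posterior
mean F_ij per population, and the Bayesian q-value: with
PEP_i = 1 - PIP_i, q_i is the running mean of PEP over loci with
PEP ≤ PEP_i.  Loci failing a pooled MAF 0.05 filter (ML convention) are
excluded per comparison.  Correctness is checked against brute-force
numerical integration of the exact per-locus posterior on tiny instances
with the β prior made near-degenerate so loci decouple.

**Power at pairwise scale.**  A single two-population comparison of
dominant data at n ≈ 24 carries limited information: the Bayes factor
for the selection model exceeds ~90 (needed for q ≤ 0.10 under prior
odds 10) only for near-fixation contrasts such as m = (0, 22).  Under
Balding-Nichols planting at FST 0.5 over a 0.05 background, exact
posterior inclusion probabilities of planted loci average ~0.25, so
recovery at q ≤ 0.10 is a few percent even for a perfect sampler, while
the realized false-discovery proportion stays at zero.  The recovery
test in the acceptance suite runs exactly these conditions and documents
this ceiling; detecting a planted locus reliably requires either
near-fixed contrasts, larger samples, or more than two populations.

**Candidate rule.**  Per country, all within-country population pairs
are scanned; a locus is a candidate for host-plant adaptation when
flagged (q ≤ threshold; 0.05 and 0.10 both reported) in at least one
inter-host comparison and in none of the intra-host comparisons.  The
summary effect per candidate is the mean posterior α over flagged
comparisons, printed to two decimals with half-away-from-zero rounding.

## Gametic disequilibrium (`ld_test`)

For a locus pair only four joint phenotype classes are observable.
Under HWE and random gamete union the class probabilities are functions
of (q_A, q_B, g), g the double-null gamete frequency:
P(aa,bb) = g², P(absent at A) = q_A², P(absent at B) = q_B².  The ML
solution matches cell frequencies — q̂_A = sqrt((n_aP+n_aa)/N),
ĝ = sqrt(n_aa/N) — which is the global multinomial ML whenever ĝ lies in
the feasible gamete interval [max(0, q̂_A+q̂_B-1), min(q̂_A, q̂_B)].  When
the lower (Frechet) bound binds — possible when double-presence
phenotypes are nearly absent — the estimate is re-fit as the exact
constrained ML: an outer Nelder-Mead over the marginals with an inner
closed-form profile over g (the stationary points in g² are roots of a
cubic).  A coarse-to-fine grid-search oracle over 1,000 random tables
confirms agreement to |ΔD| < 1e-6.  D̂ = ĝ - q̂_A q̂_B and the gametic
correlation r = D̂ / sqrt(p_A(1-p_A) p_B(1-p_B)), p = 1 - q.  Note that
at small N the ML estimate is biased (concavity of sqrt at low
double-null counts shifts r by ≈ -0.1 at N = 24, q = 0.5); the MCMC
significance test below is conditioned on the same estimator and is
calibrated despite this bias.

**MCMC null test.**  Randomizing band phenotypes is not a valid null for
dominant markers, because band presence confounds two genotypes.  The
test instead randomizes the underlying genotype frequencies: a
Metropolis chain on (q_A, q_B) targets each locus's Zhivotovsky
posterior independently (uniform proposal of width 0.15 with reflection
at [0,1], initialised at the posterior means); at each of 10,000 default
steps, 2N pseudo allele copies per locus are drawn Binomial(2N, q),
randomly paired into N diploids, converted to band phenotypes, re-paired
across individuals, and one null r is computed.  The implementation
draws the double-absence count from the equivalent hypergeometric law
given the two margins, which is exact and vectorizes across steps.  The
one-sided P is (1 + #{r_null ≥ r_obs})/(steps + 1); undefined null
draws (monomorphic pseudo-samples) count as exceedances, keeping the
test conservative, and the add-one rule keeps P > 0 as the Z-transform
combination requires.  A two-sided |r| variant is provided; the
one-sided upper tail is the default.  Type-I error at α = 0.05 under
simulated linkage equilibrium (q = 0.5, n = 24, 500 replicates,
2,000-step chains) measures within (0.03, 0.07).

**Combination and FDR.**  P-values are combined per (country × host
type) category with Whitlock's weighted Z-transform (equal weights by
default, sqrt-n optional) and adjusted per category with
Benjamini-Hochberg step-up (statsmodels).

## Synthetic data (`synthetic`)

The generator emulates the study design the analysis assumes: 684 loci;
12 populations of 19-24 individuals nested in 2 host types nested in 2
countries; band phenotypes by random union of gametes under HWE.
Frequencies follow a hierarchical Balding-Nichols model — each level is
a Beta draw around its parent with shape (1-F)/F — which in the
biallelic case is exactly the scan's inference model, so generative
assumptions can be matched or violated deliberately.  Defaults,
calibrated once against the study's published summary tables:

| parameter | default | remark |
|---|---|---|
| ancestral prior on q | Beta(1.2, 0.5) | gives mean Bayesian He ≈ 0.25 per population |
| country-level FST | 0.07 | cross-country pairs land ≈ 0.12-0.16 |
| host-level FST | 0.035 (France), 0.065 (China) | inter-host pairs ≈ 0.04-0.10 |
| population-level FST | 0.015 | intra-host pairs ≈ 0.008-0.025 |
| selected loci | 2 + 9, α ∈ [1.14, 1.79] | host-level logit-FST effects, mirroring the published effect sizes |
| planted LD | none | D per pair is configurable, clamped to the feasible range |

Selection is encoded **only** as an elevated locus-specific host-level
FST (the same α the scan estimates); there is no explicit fitness model.
Selected loci draw their ancestral frequency inside [0.2, 0.8], since a
planted contrast at a nearly fixed locus is unobservable by any method.
Planted LD pairs draw gametes from the 2×2 gamete table with the target
D, identical across designated populations.

What the generator does **not** emulate: scoring error and size
homoplasy (fragment sizes are independent uniforms on [80, 450], so the
homoplasy check is calibrated under its null but never positive),
linkage beyond designated pairs, deviations from HWE, temporal drift,
and migration between countries.  Passing recovery tests therefore
demonstrates internal consistency of estimator and generator under the
assumed model, not robustness to real-data artefacts.

## Pipeline and reproducibility

`pipeline.run_pipeline` chains the stages (data → frequencies →
FST/AMOVA → scan → candidates → LD on candidate pairs → combined/
adjusted P → report) under one config and one global seed; per-stage
substream seeds are SHA-256 hashes of the stage name, so stage outputs
are pure functions of (inputs, config, seed) and reruns are
bit-identical.  The LD stage tests within-country candidate pairs in
that country's populations and cross-country pairs in every population,
then combines P per country × host category.  Reports are TSV tables
plus a plain-text summary; no figures are generated.

Scaled problem sizes used by the test suite and `scripts/acceptance.py`
(full-size settings remain the library defaults): scan chains burn-in
1,500 / 4,500 kept / thin 3; LD chains 2,000 steps; AMOVA bootstrap
200; the LD type-I calibration uses 300-500 replicates.

## Known limitations

* Pairwise outlier scans on dominant data at n ≈ 20-24 have very low
  per-locus power except at near-fixed contrasts (quantified above);
  the package reports honest posterior quantities rather than
  overstating certainty.
* The AMOVA is an expected-dosage surrogate, not a genotype AMOVA.
* He uses the plug-in estimator; no small-sample correction.
* The Hill ML D estimator is biased at small N (inherent to ML on
  sqrt-transformed counts); significance testing is calibrated by
  construction against the same estimator.
* No support for FIS ≠ 0, codominant markers, or hierarchical
  (more-than-two-level) island models in the scan.
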