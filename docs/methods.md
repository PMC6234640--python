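# Methods

`riskdrift` models how the machinery of genome-wide association studies
(GWAS) — who is studied, on what genotyping platform, with how many
samples, at what significance threshold — distorts the set of disease
loci that get discovered, and what that distortion does to risk-allele
frequency comparisons and genetic risk scores (GRS) across continental
populations. This note records the models, parameter choices, numerical
details, and the limits of what the synthetic experiments demonstrate.

## The discovery model

A simulated "GWAS catalog" is built by rejection sampling. A test SNP
is drawn uniformly (with replacement) from a platform-filtered pool of
variants; its risk-allele frequency in the study cohort is looked up
(the derived-allele frequency if the risk allele is derived, the
complement if ancestral; the MIX cohort uses the unweighted mean over
AFR, AMR, EAS, EUR, SAS); a genotype relative risk (GRR) is drawn from
the configured effect-size model; the analytic case-control power at
that frequency and GRR is computed; and the SNP is accepted with
probability equal to its power. Sampling continues until a target
number of *distinct* loci is accepted (default 3036, matching the size
of the curated disease-locus catalog the analysis mirrors; a SNP drawn
again after acceptance is skipped). Accepted loci carry their
frequencies in all five populations, so ascertainment bias can be
measured directly as Δ = mean risk-allele frequency in AFR minus the
pooled (unweighted mean) non-African frequency, reported separately
for ancestral-risk and derived-risk runs. Because frequencies in
non-study populations play no role in acceptance, any systematic Δ is
pure ascertainment artifact: the simulation assumes no true risk
difference between populations.

Default discovery scenario: EUR study cohort, 3500 cases and 3500
controls, additive inheritance, prevalence K = 0.1, significance
threshold α = 1e-5, fixed GRR 1.211, Affymetrix 6.0 platform flags.
A draw cap (default 1e8) turns pools with no attainable acceptances
(e.g. all monomorphic) into an informative error rather than a hang.

### Effect-size models

* `fixed` — GRR 1.211 in every population.
* `gamma` — one Gamma(shape 1.24, scale 0.85) draw per test SNP,
  shared by all populations.
* `gamma_pop_noise` — the gamma draw plus independent N(0, 0.5) noise
  per population (a crude genotype-by-environment surrogate).
* `gamma_shift_eur` / `gamma_shift_afr` — the gamma draw with +0.5
  added to the named population's GRR.

All models truncate GRR at 1 *after* noise/shift, so effects are
risk-increasing by construction. Power uses the study population's GRR
(the mean GRR for MIX); accepted loci record the full per-population
GRR vector. Replicate i of a run uses the deterministic child
generator seeded by (seed, i), so 1000-replicate experiments are
exactly reproducible.

## Case-control power

Penetrances f0, f1, f2 (disease probability given 0/1/2 risk alleles)
follow from prevalence K, GRR γ and the inheritance model — additive
(f1 = γ f0, f2 = (2γ−1) f0), dominant (f1 = f2 = γ f0), recessive
(f1 = f0, f2 = γ f0) — with f0 solved from
K = (1−p)² f0 + 2p(1−p) f1 + p² f2 under Hardy–Weinberg. Expected
case/control risk-allele frequencies are
p_case = [p² f2 + p(1−p) f1]/K and
p_control = [p² (1−f2) + p(1−p)(1−f1)]/(1−K).

Power is that of the two-sided 1-df allelic test on the 2×2 allele
table. The chi-square statistic normalises the case/control frequency
contrast by a null variance *estimated from the pooled sample
frequency*, so the closed form integrates the normal rejection
probability of the contrast over the (normal) sampling distribution of
that pooled frequency — a 41-node Gauss–Hermite quadrature, with the
exact covariance between contrast and pool, and pooled frequencies of
0 or 1 treated as untestable (power contribution 0). The plain
plug-in normal approximation was measured against a high-replicate
Monte-Carlo oracle and deviated by up to ~3×10⁻³ at high power with
skewed allele frequencies; the quadrature form tracks the oracle to
within Monte-Carlo error everywhere we checked, with the largest
residual (~3×10⁻³ near p = 0.5 at intermediate power) attributable to
the discreteness of the allele-count lattice, which no continuous
approximation removes. Monomorphic sites (p = 0 or 1) have power
exactly 0, which the rejection sampler relies on.

The Monte-Carlo oracle (`monte_carlo_power`) draws case/control
risk-allele counts binomially at (p_case, p_control) and applies the
Pearson chi-square allele test without continuity correction; it is
kept strictly independent of the analytic path and serves as the
authority in tests.

The scalar API raises on parameter combinations whose implied
penetrances leave [0, 1]; the vectorised sampler core instead
saturates penetrances at 1 and uses the prevalence implied by the
saturated values, because the heavy-tailed gamma effect models
occasionally produce draws (large γ, recessive, rare allele) for which
the stated prevalence is unattainable, and a hard error inside a
10⁶-draw batch would be useless. Saturation affects a vanishing
fraction of draws under the default models.

## The synthetic panel

Real multi-population frequency panels are large external resources;
the generator produces panels with the two structural features the
analysis depends on, and nothing else:

1. **SFS-shaped standing variation.** Ancestral derived-allele
   frequencies p₀ are drawn from the neutral spectrum ∝ 1/i on the
   grid {1/n_chrom, …, (n_chrom−1)/n_chrom} (n_chrom = 1000), so most
   derived alleles are rare and most ancestral alleles common.
2. **Asymmetric drift.** Population frequencies follow a hierarchical
   Balding–Nichols model: AFR ~ Beta with mean p₀ and variance
   f_afr·p₀(1−p₀); a shared out-of-Africa intermediate frequency is
   drawn with f_ooa from p₀; each of AMR/EAS/EUR/SAS drifts from the
   intermediate with f_pop. Defaults f_afr = 0.01, f_ooa = 0.10,
   f_pop = 0.02 — the simplest mean-preserving parameterisation in
   which bottlenecked non-African populations drift markedly more than
   the African population while remaining strongly correlated with one
   another. These are calibration knobs, not estimates of human
   history; the source analysis uses real panels and fits nothing.

Default panel size is 50,000 SNPs — a deliberate desk-scale stand-in
for a genome-wide site set, large enough that a 3036-locus catalog
samples it sparsely (tests use 30,000 with 300–2000-locus catalogs in
the same spirit).

Array content is emulated by small-discovery-panel ascertainment: a
SNP with frequency q in the discovery population (default EUR) is
retained with probability 1 − q^d − (1−q)^d, the chance of being
polymorphic in d = 4 sampled chromosomes. Small d maximises the
intermediate-frequency enrichment that commercial arrays exhibit.
Retained SNPs get a `SYNTH` platform flag; empirical Affymetrix 6.0 /
Illumina Omni 5M ID lists can be loaded onto real panels the same way.

Genotypes are Hardy–Weinberg draws, Binomial(2, daf), per individual
and locus. Disease-locus tables sample distinct panel variants with
risk alleles ancestral with probability 0.44 (the observed share of
ancestral risk alleles among curated disease associations) and one of
seven disease categories (gastrointestinal/liver, metabolic,
morphological, cancer, neurological, miscellaneous, cardiovascular)
assigned multinomially, uniform by default since the analysis does not
prescribe category sizes.

**What the generator does not emulate:** linkage disequilibrium (every
locus drifts independently), selection, admixture (AMR is modelled as
just another bottlenecked population, not an admixed one), finite-size
frequency noise in the "panel" itself, imputation error, and
fixed-catalog effects (each simulated catalog is freshly discovered).
Passing tests on this panel therefore demonstrate that the *discovery
mechanism alone* produces the continental biases — they do not
quantify the biases of any real catalog, whose magnitudes depend on
real demography and LD structure.

## Empirical statistics

Frequency contrasts join a disease-locus table to a panel and report
the mean AFR − pooled-non-AFR risk-allele frequency difference by risk
state, the fraction of loci with strictly higher African frequency
(ties count as not-higher and are reported), paired two-sided Wilcoxon
signed-rank tests (exact null for n ≤ 25, normal approximation above),
per-category summaries, and the squared Pearson correlation between
per-category Δ and the category's ancestral-risk proportion. The
overall Δ is the state-proportion-weighted mean
prop·Δ_anc + (1−prop)·Δ_der.

Loci are binned by their across-population mean DAF in width-0.2 bins;
the lowest bin is closed, [0, 0.2], and subsequent bins are
(0.2, 0.4], …, so a locus exactly at a boundary falls in the lower
bin (mean DAF ≤ 0.2 ⇒ lowest bin). Allele age defaults to
2·N·p/(1−p) generations (N = 10,000, 25 y/generation ⇒ 125,000 years
at p = 0.2); the formula is pluggable, with the Kimura–Ohta
−4N·p·ln(p)/(1−p) estimator provided as an alternative.

The joint site frequency spectrum assigns a record to cell
(⌊daf_x·bins⌋, ⌊daf_y·bins⌋), with frequency 1.0 in the top bin, so
marginals equal the 1-D spectra exactly.

## Genetic risk scores and the ancestral/derived correction

Raw GRS are unweighted sums of risk-allele counts over a category's
loci (derived count, or 2 − count for ancestral risk alleles); no
odds-ratio weighting, because the categories pool heterogeneous
phenotypes. Standardised GRS are Z-scores against the mean and
population SD (ddof = 0) over *all* individuals pooled across
populations.

The African correction replaces each locus count by an effective
count: count − 0.1902 at ancestral-risk loci and count + 0.1082 at
derived-risk loci, i.e. twice the mean African-vs-non-African
ancestral (9.51%) and derived (5.41%) risk-allele frequency
differences — so a homozygote carries −0.1902/0.8098/1.8098 effective
ancestral or 0.1082/1.1082/2.1082 effective derived risk alleles.
(The derived difference is printed once as 5.40% and once as 5.41% in
the source material; the constant uses 5.41%, and
`CorrectionConstants.from_panel` recomputes both shifts from any
panel's own frequency differences.) Corrected sums are mapped through
the *uncorrected* mean/SD, so corrected and uncorrected Z-scores live
on the same scale; algebraically, corrected raw = raw − L_anc·0.1902 +
L_der·0.1082 with L_anc, L_der the category's locus counts by state.
The correction is applied to AFR-labelled individuals by default
(configurable). Distribution comparisons use two-sided Mann–Whitney U
tests, exact in small samples without ties. Explicit per-population
mean-centering is deliberately not offered: it erases any real
between-population risk difference along with the artifact.

## Numerical and testing choices

* All randomness flows through `numpy.random.Generator`; every public
  generator accepts a seed or Generator, and replicate/child seeds are
  derived as `default_rng([seed, i])`.
* Panel TSVs round-trip frequencies bit-exactly (shortest-repr
  writing, `float_precision="round_trip"` parsing).
* Statistical assertions in the test suite use explicit oracles:
  normalised harmonic sums for the frequency spectrum, full
  enumeration for small-sample rank tests, binomial/geometric moment
  bounds (3 SE) for Monte-Carlo checks. The 36-point power-grid
  comparison re-estimates a point that misses its 3-SE band with one
  independent oracle draw before declaring disagreement, since 36
  simultaneous 3-SE comparisons against a noisy oracle stray outside
  the band by chance in roughly one run in ten.
* Monotonicity of |Δ| in sample size is asserted up to 3 SE of each
  paired difference of replicate means: on the array pool the bias
  saturates between n = 10⁵ and 10⁶, where raw means differ by less
  than Monte-Carlo noise.
* Test problem sizes (30,000-SNP panel, 300–2000-locus catalogs,
  50–100 replicates) were chosen once as desk-scale versions of the
  full experiments (3036 loci, 1000 replicates); the package runs the
  full sizes unchanged via configuration.

## Known limitations

* The allelic test is the only implemented association statistic
  (no trend test on genotypes, no logistic regression, no covariates);
  the choice is isolated in the power module should an alternative be
  needed.
* Penetrance saturation under extreme GRR draws slightly distorts the
  effective effect-size distribution in the far tail.
* The Balding–Nichols hierarchy has no LD and no admixture, so
  AMR-specific phenomena and clumping/thresholding questions are out
  of scope.
* Allele ages are point estimates from a frequency-only formula and
  inherit all of its assumptions (neutrality, constant N).
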