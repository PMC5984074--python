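# Methods

`pedigrowth` re-implements, as a tested library, the analytic chain that takes
longitudinal body measurements from a pedigreed primate colony to (i)
data-driven obesogenic-growth clusters, (ii) per-animal logistic growth
parameters, (iii) heritability and maternal-effect estimates with diet
covariates, and (iv) a variance-components linkage scan. A synthetic colony
generator supplies ground-truth data for every stage. This note records the
models, the defaults and why, the numerical choices, and the limits of what
the synthetic tests demonstrate.

## Pedigree and kinship

Kinship is computed by the standard recursive (tabular) method:
Φ_ii = ½(1 + Φ_sire,dam), Φ_ij = ½(Φ_j,sire(i) + Φ_j,dam(i)) for j earlier in
a topological order. Founders are assumed unrelated and non-inbred — the
usual convention when founder genotypes are unavailable; nothing in the
package depends on this beyond the kinship values themselves. Input row order
is never trusted: a topological sort (cycle detection included) runs on
load. The additive covariance kernel is 2Φ throughout. The maternal
"household" matrix H has h_ij = 1 iff i and j share a known dam; animals with
unknown dams are singleton households. Ages are decimal years,
(date − birth)/365.25; missing parents may be written `0` or left empty.

## Derived phenotypes

* BMI = BW kg / (CRL m)², computed per visit where BW and CRL co-occur and
  then averaged (a mean of ratios, deliberately not the ratio of means; a
  config switch restores the other convention).
* Obesity: waist circumference above the colony's empirical 80th percentile
  (type-7/linear-interpolation quantile) or the fixed 40.5 cm cut-off;
  comparison is strict (>). A warning fires when the empirical threshold
  strays >10% from 40.5 cm.
* Chronic obesity: ≥3 *consecutive* obese measures after deleting
  pregnant-flagged visits, so a pregnancy does not reset a run.
  Consecutiveness is defined on the retained measurement sequence, not on
  calendar gaps — the measurement calendar is irregular and no gap bound is
  imposed.
* Adult traits: means of all measures from age 5 (stable adult size) on.
  Pregnant visits are excluded from BW and WC averaging; CRL, a skeletal
  measure, is retained. This extends the pregnancy exclusion (stated for
  obesity classification and growth modelling) to adult averaging of the
  soft-tissue traits; the choice is configurable.
* Diet cohorts: an animal is "gestation-exposed" if the 165-day window before
  birth overlaps the intervention-diet era; otherwise the first of
  PN1 [birth, 2 y), PN2 [2, 5 y), adult [5 y, ∞) that overlaps the era; else
  "never". The era's calendar bounds come from the diet timeline config, not
  from code.
* Pre-transforms: rank-based inverse normal z_i = Probit((r_i − ½)/n) with
  average ranks on ties; age adjustment by OLS residuals on intercept + mean
  age.

## Trajectory clustering

Body-weight trajectories are binned to a common age grid (default 1 y; mean
within bin; pregnant visits excluded), rows with <6 observed bins dropped,
interior gaps linearly interpolated and edge gaps filled by nearest-value
copy. Lloyd k-means (Euclidean, best of `n_starts` seeded random
initialisations — scikit-learn's implementation behind this module's surface)
is scored by the Calinski–Harabasz ratio CH = [B/(k−1)]/[W/(n−k)], maximised
over k. Clusters are relabelled so cluster 1 is "heavy" (largest mean
terminal value). Sexes are clustered separately.

Only the birth-to-adulthood cohort (first measured ≤2 y old, observed to
≥4 y) enters clustering and growth modelling in the pipeline: trajectories of
animals first measured as adults are flat at their asymptote, and trajectories
of animals that left the colony as juveniles never express the dichotomy;
including them makes the edge-copy imputation dominate the partition.

## Logistic growth NLME

Size at age t is S(t) = θ₁/(1 + exp(−(θ₂ + θ₃ t))): θ₁ the adult asymptote,
θ₃ the rate constant (1/yr), and −θ₂/θ₃ the age at half adult size. This is
the unique standard three-parameter logistic consistent with that midpoint
relation. Each (sex × cluster) group is fitted independently with subject
random effects on all three parameters:

y_ij = S(t_ij; θ + b_i) + ε_ij, b_i ~ N(0, Σ_b), ε ~ N(0, σ²).

Estimation maximises the Laplace-approximated marginal likelihood: an inner
penalised Gauss–Newton solve (vectorised over subjects, Levenberg-damped,
warm-started across outer iterations) finds each subject's mode; the outer
Nelder–Mead search runs over (θ, log SD_b, log σ). Σ_b is diagonal by
default — robust at colony-scale group sizes; initialisation comes from a
two-stage fit (per-subject nonlinear least squares → medians and moment
estimates). Subject parameters are θ + b̂_i (empirical-Bayes modes). Fit
quality is the Pearson r between observed and subject-predicted values,
reported for the developmental window (ages ≤ midpoint + 2/θ₃) and the whole
life course. Near-zero random-effect SDs are flagged as boundary estimates.

## Variance decomposition

Continuous traits (inverse-normal transformed, age-adjusted) are modelled as
multivariate normal with Ω = 2Φσ²_g + Hσ²_c + Iσ²_e. Fixed effects are
profiled by GLS and σ²_e analytically, leaving an optimisation over
non-negative variance ratios: for a single kernel an eigen-rotation reduces
each likelihood evaluation to O(np²) and the ratio is found by grid +
bounded refinement (exact to ~1e−10); with several kernels, L-BFGS-B with
box constraints and multiple starts on Cholesky factorisations. ML (not
REML) is the default, matching the cited variance-decomposition convention.
h² = σ²_g/(σ²_g+σ²_c+σ²_e), c² = σ²_c/total; standard errors come from the
observed information (numerical Hessian in the variance parameters) with the
delta method. Tests of a single variance component use the boundary LRT,
p = ½P(χ²₁ ≥ Λ) — note the caveat under "Calibration" below.

Covariate screening is backward elimination under the polygenic model: drop
the least significant term with Wald p > α (default 0.05), keeping main
effects while any of their interactions survive; exact ties drop the
later-listed term.

Binary chronic obesity uses a probit liability model: l = Xβ + g + e,
g ~ N(0, 2Φσ²_g), e ~ N(0,1), y = 1 iff l > 0 (the intercept absorbs the
prevalence threshold); h² = σ²_g/(σ²_g+1) on the liability scale. The
marginal likelihood is approximated by a Laplace approximation over the
n-dimensional latent polygenic vector (Newton mode-finding), optimised by
Nelder–Mead over (β, log σ²_g). Laplace approximations for binary data
shrink variance components somewhat at moderate prevalence; at colony scale
this bias is well inside the sampling error, but the estimator should not be
used for n below ~100 or prevalence below ~5%.

## Linkage

At each grid position Ω gains a locus kernel: Π(pos)σ²_q + 2Φσ²_gr (+ Hσ²_c)
+ Iσ²_e. Π uses the proportion-of-alleles-IBD convention computed as the
sum over the four allele pairings divided by two, so E[Π] = 2Φ holds exactly
(including the 1+autozygosity diagonal) and σ²_q sits on the same covariance
scale as the polygenic term — one convention everywhere, avoiding the classic
factor-of-two ambiguity. LOD = (lnL_alt − lnL_null)/ln 10, clipped at 0;
the position-free null is fitted once per scan. Peaks are contiguous runs
above the suggestive threshold (1.9), classed significant when the maximum
reaches 3.3. Positions where a fit fails are reported as missing, never as
zero.

IBD sources: (a) the oracle — exact realized sharing read off gene-dropped
descent records (the primary path; an MCMC descent-graph sampler is out of
scope); (b) a windowed marker-based local-relationship estimate
(frequency-standardised dosage products, shrunk toward 2Φ with weight
m/(m+10), clipped to [0,2]) — a documented approximation validated against
the oracle on simulations, useful when only dense genotypes exist.
Genetic-map positions interpolate linearly in bp between anchors and clamp
beyond the ends.

The power simulator builds one colony pedigree, then per replicate
gene-drops the QTL chromosome, plants a biallelic QTL (frequency 0.5, effect
solved from the target locus heritability), simulates the trait, and records
the LOD at the true locus; it reports the fraction ≥ 3.3 with binomial SE.

## Synthetic colony

The generator emulates the study system rather than any particular dataset:

* Demography: ~28 founders from the mid-1970s; matrilineal breeding with
  female philopatry; up to 10 concurrent sires per season (harem-style but
  with realistic male turnover — ~110 lifetime sires); most colony-born males
  removed near maturity (rate 0.6 at age ~4); a soft carrying capacity of
  ~150 breeding residents; births through 2009. The defaults yield ~1000
  animals, ~600 with known parentage and attainable adult measures, a
  female:male adult ratio ≈ 2.5, and a maternal-sibship ratio of ≈ 2.3
  phenotyped offspring per dam.
* Measurement calendar: annual visits 2000–2007, thrice-yearly 2008–2015;
  7% missed visits; waist circumference recorded only from 2008 and only at
  ages ≥3; pregnancy flags for adult females at rate 0.18 per visit, with
  small BW/WC increments.
* Growth: each animal follows its (sex × heavy/light) group logistic curve
  plus subject deviations. Group means are anchored to typical colony adult
  sizes (asymptotes F 4.9/5.9 kg, M 6.8/8.1 kg) and encode bimaturism: heavy
  groups and males reach larger asymptotes via later midpoints and slower
  rates. Heavy/light membership is a heritable liability (h² = 0.5,
  prevalence 0.45). Subject SDs (0.25, 0.22, 0.10) on (θ₁, θ₂, θ₃) are
  chosen for testability — the planted dichotomy is separable (~4 SD gap in
  asymptote) so structure-recovery tests are meaningful; real within-cluster
  spread is wider, so recovery rates here say nothing about detectability in
  sparser data. Growth-parameter deviations are partly heritable (shares
  0.6/0.15/0.25) through a pedigree-simulated breeding value.
* Waist circumference is a sex-specific linear function of BW plus noise,
  so heavy-cluster adults are enriched for chronic obesity.
* Trait architecture: y = Xβ + q + g + c + e with q a biallelic QTL read
  off the gene-dropped descent, g an additive polygenic value simulated by
  pedigree recursion (exact 2Φ covariance), c shared within dam groups, e
  iid. Each component is standardised to its exact planted in-sample
  variance share; without this, genetic drift in a closed colony moves
  realized shares by tens of percent between seeds.
* Genome: 10 chromosomes × 100 cM by default (29 configurable), Haldane
  recombination (no interference), marker allele frequencies Beta(2,2)
  clipped to [0.05, 0.95].
* Determinism: a master seed spawns named sub-streams (pedigree, genetics,
  phenotypes, schedule); every output is a pure function of (config, seed).

What the synthetic data does **not** emulate: measurement error structure,
seasonal weight cycles, real litter/interbirth dynamics, linkage
disequilibrium beyond pedigree transmission, genotyping error or missing
genotypes, and any real effect of diet on growth (diet covariates are
generated as structure, not as causal effects — their effect sizes are
planted only where a test plants them). Passing tests therefore demonstrate
correctness of the estimators under their own assumptions, not field
performance.

## Calibration and problem sizes

The boundary LRT's asymptotic ½χ²₀+½χ²₁ reference is checked by simulation
in the regime where it applies — many independent sibships (150 quartets),
where the empirical 5% tail lands within binomial bounds. On a single deep
colony pedigree the same test is *conservative* (empirical tail ~0.01–0.03):
the score statistic is a weighted sum of few large eigen-contrasts and the
normal approximation overstates its tail. This is a property of the test on
such pedigrees, not of the optimiser (which matches dense grid search to
<1e−3); genome-wide conclusions on deep pedigrees should lean on the LOD
thresholds, which are calibrated at the null locus by simulation here.

Routine checks run at desk scale by design: colony pedigrees of ~250–650
phenotyped members, 200-replicate power runs, 500-replicate calibrations,
100-subject growth groups. Oracle equivalences (kinship vs gene-dropping,
ML vs dense grid, NLME vs per-subject least squares in the noise-free limit)
pin down exactness where exactness is the claim.

With exact locus IBD and complete two-parent pedigrees, the linkage power at
locus heritability 0.17 in a ~600-member colony computes to ~95–100%
(mean LOD ≈ 9). Marker-estimated IBD, incomplete parentage and genotyped
subsets — all realities of empirical colony data — can only reduce this;
the simulator's number is an upper envelope for a colony of this structure,
and the power stage exposes h²_q, h², replicate count and covariate/household
options so other operating points can be mapped.
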