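# Methods

This package re-creates, on synthetic data with recorded ground truth, the
statistical chain used to study the stability of grain-quality traits in
two-line hybrid rice bred from TGMS (thermo-sensitive genic male sterile)
females and restorer males: reaction-norm plasticity, combining ability of
plasticity, line-level genetic values, mixed-model association and LD-block
QTL calling. This note records the models, the defaults and why, the numerical
choices, and what the synthetic data does and does not emulate.

## Reaction-norm model and Finlay–Wilkinson regression

A record of hybrid *i* in environment *j* (a sowing stage within one trial
location) is modelled as

    y_ij = mu + g_i + h_j + b_i h_j + e_ij

equivalently `y_ij = mu + g_i + (1 + b_i) h_j + e_ij`. The slope `1 + b_i`
is the phenotype plasticity of hybrid *i*: slope 1 is average responsiveness
to the environmental gradient, slope < 1 a more stable hybrid. Environments
are the sowing stages of a single location, so plasticity is reported per
trait and location. Identifiability is fixed by the unweighted constraints
`sum_j h_j = 0` and `sum_i b_i = 0` (mean slope 1).

**ALS fitter.** Alternating least squares: the per-environment update
`(h | mu, g, b)` and the per-hybrid simple regressions `(mu, g, b | h)` are
each solved exactly, then the parameters are renormalised within the
invariance group of the model (rescale h vs slopes; shift h into g; shift g
into mu), which leaves fitted values unchanged. The objective is therefore
non-increasing; convergence is declared when it falls by less than `tol`
(default 1e-10, `max_iter` 500). Hybrids observed in fewer than three
sowings of a location are dropped with a log entry. If the environmental
effects have (numerically) zero spread, plasticity is undefined: the fit
returns b = 0 with an explicit `degenerate` flag rather than NaN.

**Gibbs fitter.** The hierarchical version places independent normal priors
on g, b and h with scaled-inverse-chi-square hyperpriors (df 5, scale = half
the data variance); defaults are 20 000 sweeps with 5 000 burn-in. Draws are
mapped to the ALS identifiability convention before averaging, so posterior
means are directly comparable with ALS estimates; with large fixed prior
variances the sampler reproduces the least-squares fit on balanced data.
Prior settings and chain lengths are this package's declared defaults; no
external convention is implied.

## Combining ability of plasticity

Per trait and location the hybrid plasticity is modelled additively,

    p_mf = mu + u_m + u_f + e,

with one parental random-effect vector u shared by the female and male side
and specific combining ability fixed at zero — without replicated crosses SCA
is not estimable, so it is not modelled. The overlay incidence (each hybrid
row carries +1 on both of its parents) gives a one-ratio mixed model; the
variance ratio is estimated by REML after one eigendecomposition of ZZ',
searched on a log10 grid over [1e-8, 1e8] and refined by bounded scalar
minimisation. GCA values are the BLUPs of u, re-centered to sum exactly to
zero. If the REML parental variance falls below 1e-8 x the sample variance
of p, the fit is declared null: all GCA values are reported as exactly 0
with the `zeroed` flag (the package's operational substitute for "no
significant additive effects detected"; no hypothesis test is attached).

"Stable parents" are those whose GCA is <= 0 for at least 5 of the 7 traits
in more than three of the five locations; both counts are configurable.

## Line-level genetic values (BLUP)

Per trait, records are decomposed as `Y = mu + (1|LINE) + (1|ENV) +
(1|LINE:ENV) + e`, with ENV the sowing stage (per-location scope) or the
location (cross-location scope; both scopes are exposed because either
grouping is defensible). With at most one record per LINE x ENV cell the
interaction variance is confounded with the residual and the term is dropped
automatically. REML uses 20 EM warm-start sweeps followed by Nelder-Mead on
log-variances (relative tolerance 1e-8); all linear algebra goes through the
Woodbury identity, so cost scales with the number of random-effect levels
rather than records. Variance components are floored at 1e-10 x var(Y).
An option to freeze the components enables the closed-form shrinkage oracle
used in tests. lme4 (via Rscript) serves as an independent cross-check of
the variance components in the test suite, never as the implementation.

## Mixed-model association

Kinship is the centered genomic relationship matrix K = WW'/m over
polymorphic SNPs (missing dosages mean-imputed for K only). Population
structure enters as fixed covariates: intercept plus the first three
genotype principal components (sign convention: largest-magnitude loading
positive). The per-SNP model

    y = Xc a + x beta + u + e,  u ~ N(0, s_g^2 K),  e ~ N(0, s_e^2 I)

is fit exactly: K is eigendecomposed once and the variance ratio
delta = s_e^2/s_g^2 is re-optimised per SNP by REML on the rotated data
(41-point log10 grid over [1e-5, 1e5], then bounded Brent refinement). The
reported test is the Wald ratio with a t reference on n − c degrees of
freedom, which reduces exactly to OLS when K = I. Samples missing a call at
a SNP are dropped for that SNP only (the eigendecomposition for each missing
pattern is cached); SNPs monomorphic in the analysed samples yield NaN
sentinels. The genome-wide threshold is Bonferroni: alpha divided by the
number of SNPs actually tested.

## LD blocks and QTL calling

Pairwise LD is the squared Pearson correlation of dosage columns
(composite-genotype r^2, pairwise-complete). Blocks are built by a
deterministic greedy adjacency rule: a SNP joins the current block when its
r^2 with at least one of the last `window` (default 20) block members
reaches the threshold (default 0.6); otherwise it starts a new block. This
is a deliberate, documented divergence from dedicated big-LD segmentation
algorithms: block topology only mediates QTL grouping here, and the greedy
rule is exactly checkable against an exhaustive segmentation oracle.

Blocks containing at least one SNP with p below the threshold are candidate
QTLs; significant blocks on a chromosome are merged when their gap is
strictly less than 1 Mb (a gap of exactly 1 Mb stays split). The lead SNP is
the member with the largest −log10 p, ties broken toward the smaller
coordinate. Percent variance explained by the lead SNP is
`2 af (1 − af) beta^2 / var(y) x 100`, capped at 100 — the formula is this
package's declared choice and is recorded in output metadata. Internally all
coordinates are 1-based inclusive; exported intervals are BED-style 0-based
half-open.

## Environment statistics and grading

Weather is summarised over the first 15 days after full heading: means of
daily minimum/maximum/average temperature, diurnal range and solar
radiation, total rainfall, and the number of rainy days, a rainy day having
strictly more than 1 mm of rain. Trait-factor association uses Spearman's
rho (mid-ranks for ties) with the two-sided t approximation on n − 2 df.
Quality grading is entirely rule-table-driven — per-trait graded thresholds
with a direction, overall grade = worst per-trait grade; the national
standard's numeric cut-offs are not public in a machine-readable form, so
the package ships only a clearly-labelled toy rule for tests and demos.

## Synthetic data: what it emulates, and what it does not

The default scenario mirrors the target study design: 32 inbred parents
(7 TGMS x 25 restorers), 141 F1 crosses drawn from the factorial with every
parent used, five locations with {3, 4, 4, 5, 4} sowings, seven quality
traits with plausible means (e.g. AC 16%, GC 60 mm, MRR 63%). Parents are
fully inbred (dosage 0/2); hybrid dosage is the parental mean, so F1
genotypes are implied rather than sequenced — a stray heterozygous parental
call is rounded up to the ALT homozygote with a warning. Phenotypes follow
the reaction-norm model exactly: per-trait genetic main effects carry
programmed causal SNPs plus a polygenic remainder (sd 0.5 trait units);
plasticity deviations b carry causal SNPs (default per-allele effect 0.35),
parental additive (GCA) contributions (sd 0.25 per parent) and a
non-additive remainder (sd 0.30), centered at generation so the truth obeys
the estimators' constraints; environment effects are drawn per location
(sd 1.0) and centered. These defaults put the plasticity spread near
sd(b) ≈ 0.5 — slopes mostly between 0.0 and 2.0, a wide but realistic range
for quality traits across staggered sowings.

Deliberately not emulated: recombination and linkage-map structure (SNPs are
exchangeable within a chromosome apart from position), population structure
beyond what the 32 founders induce, trait-specific biochemistry, and
phenology (heading dates are deterministic inputs). Consequently, passing
tests demonstrate the correctness and calibration of the estimators under
the stated generative model — not robustness to linkage disequilibrium decay
patterns, assay error structure, or unbalanced field designs beyond the
missingness the tests construct.

A consequence of the F1 design worth stating: all hybrid dosage vectors lie
in the (at most) 32-dimensional span of the founder genotypes, so any marker
can be strongly collinear with the structure covariates or with another
causal marker. The end-to-end QTL-recovery scenario therefore places its
programmed loci with `pick_unlinked_loci` — per chromosome, the marker least
explained by the leading principal components and the loci already chosen —
and gives the shared plasticity/main-effect locus a dominant effect
(2.0 trait units on g, 1.8 slope units on b; secondary loci 0.8/0.7). That
is the major-QTL regime this method is designed to detect; structure-aligned
signals are unidentifiable for any association method by construction, not a
weakness of this implementation.

## Problem sizes used in checks

The shipped checks run the full 141-hybrid design throughout; marker panels
are 200–400 SNPs for pipeline-level checks, 10 000 SNPs for the type-I
calibration of the association scan, and 50 samples x 20 SNPs where a
dense-grid REML oracle is recomputed per SNP. BLUP parameter recovery is
demonstrated at 50 lines x 4 environments x 2 replicates over 12 seeds;
the environment variance component, with only 3 degrees of freedom, is
checked for validity rather than accuracy — its sampling error is large at
any design size with few environments.

## Known limitations

* The greedy LD segmentation is not a clique- or CI-based block definition;
  block boundaries in low-LD regions are sensitive to the window parameter.
* Per-SNP REML assumes the kinship eigenbasis is shared across SNPs; SNPs
  with missing calls trigger a per-pattern re-decomposition, which is exact
  but slow if missingness patterns are many.
* The GCA "null" rule is a variance floor, not a significance test.
* Grading ships no national-standard thresholds; results depend entirely on
  the user's rule table.
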