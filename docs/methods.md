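# Methods

This note documents the models, rules, and numerical choices implemented in
`binqtl`, the defaults they carry, and what the synthetic-data experiments
do and do not demonstrate.

## Population and genotype model

The package targets a single F1 cross between two outbred diploid parents.
Each marker is a biallelic SNP; genotypes are held in AHB coding (A and B
the two homozygotes, H the heterozygote, `-1` missing).  Three marker
classes exist: heterozygous in parent 1 only, in parent 2 only, or in both.
The first two segregate 1:1 in the progeny and inform only the respective
parental map (backcross-like, "BC" design); the third segregates 1:2:1 and
informs the combined map ("F2" design).  This is the pseudo-testcross
strategy for outcrossing species.

### Synthetic populations

`simdata` draws marker positions per chromosome as Poisson(density ×
length) with distinct uniform positions, assigns marker classes with
probabilities `marker_class_probs`, and builds four parental haplotypes.
Meiosis is modelled without interference: per gamete and chromosome the
crossover count is Poisson(`map_length_morgans`) with uniform positions.
Genotyping noise is injected after the fact: each offspring call flips to a
uniformly chosen different state with probability `error_rate`, then goes
missing with probability `missing_rate`.  Parental calls are left clean by
default — the filter cascade treats them as ground truth, and the
generator's job is to stress offspring genotyping, not parental curation.

Defaults mirror the emulated study design: 235 progeny, eight chromosomes
at peach-like physical lengths (~226 Mb total), a marker density of the
order of the mapped resequencing SNP set (~580/Mb), 0.65 expected
crossovers per chromosome per meiosis, and marker-class proportions
(0.36/0.44/0.20) matching the relative sizes of the two parental and the
combined marker sets.  The true error rate of the emulated data is unknown;
the default ε = 0.01 sits in the middle of the plausible 0.005–0.02 band
and is a test condition, not an estimate.  Tests and the acceptance script
run scaled-down configurations (one or two chromosomes, 50–500 markers,
60–232 individuals) — chosen as the smallest sizes at which the statistical
behaviour under test is unambiguous.

QTL effects act through the true genotype of the marker nearest the QTL
position: +a for the A homozygote, d for the heterozygote, −a for the B
homozygote, plus one Gaussian residual per trait.  This avoids a separate
QTL-genotype bookkeeping layer; QTLs sharing a trait must therefore declare
the same residual sd.

Synthetic color data draw a latent integer grade (1–10 by default, the
color-card range), generate L ~ N(60, 5) and a* ~ N(5, 3) from typical
yellow-flesh colorimeter ranges, and solve b* so the specified linear
combination equals the latent grade exactly.  The *recorded* grade is the
latent grade plus Gaussian grading noise: the card assignment, not the
colorimeter, is the noisy measurement.  Putting the noise on the response
keeps OLS unbiased; perturbing the color channels instead would create an
errors-in-variables model that no linear fit recovers.

What the generator does not emulate: linked-read or depth-dependent error
structure (errors are i.i.d.), segregation distortion, interference
(crossovers are Poisson), polyploidy, or multi-generation pedigrees.
Passing tests therefore show the algorithms behave correctly under the
stated statistical model, not that they are robust to every artefact of
real resequencing data.

## Filter cascade

Order: biallelic (at VCF load) → informative (both parental calls present,
≥1 parent heterozygous) → AHB orientation → Mendelian masking → offspring
missingness → segregation.  The cascade is idempotent and never alters a
parental call.

Boundary semantics: a marker is dropped when offspring missingness
*exceeds* 0.20 (exactly 20% is kept); f(A) > 0.9, f(A) < 0.1 and
f(H) < 0.15 are strict.  Frequencies are computed among non-missing
offspring, which keeps them unbiased under missingness.

AHB orientation: raw VCF coding labels the reference homozygote A, so a
het × alt-hom marker has f(A) = 0 among offspring and the f(A) bounds, read
literally, would discard every such marker.  The cascade therefore orients
each single-het-parent marker so the homozygous parent carries A before the
segregation rules run; both-het markers keep reference orientation (their
offspring f(A) ≈ 0.25 passes the bounds either way).  With orientation the
literal bounds act as intended: they remove severely distorted markers and
essentially nothing on clean data.

Mendelian masking derives the allowed offspring states from gamete
transmission (e.g. A × H allows {A, H}; A × B allows only H); inconsistent
calls become missing and are counted.  The 20% missingness rule runs after
masking — masked calls count as missing, the natural reading of the rule's
position in the cascade.

## Binning and the DR rule

Phasing (1:1 sets only): a greedy pass in physical order flips a marker's
0/1 coding iff more than half of co-called individuals disagree with the
previous phased marker; ties keep the current phase.  The result labels the
two transmitted parental haplotypes consistently along each chromosome, up
to one global inversion per chromosome (which is immaterial downstream).
The manual curation step of discarding visibly divergent markers is
automated as: drop a marker whose calls disagree with the per-individual
majority of a ±5-marker phased window in more than 20% of co-called
individuals (`max_divergence`, exposed as a flag).  Repositioning of
markers is not attempted — reproducibility over curator judgment.

Breakpoint detection runs per individual and chromosome on the ordered,
non-missing state sequence.  A maximal run deviating from the current
accepted state and reverting to it is a double-recombination candidate,
accepted only if it has ≥ 2 contiguous markers *and* spans ≥ 100 kb;
rejected candidates are flagged as genotyping errors.  A deviation followed
by a third state (possible in 1:2:1 data, e.g. A→B with the H unobserved)
is a genuine transition.  Terminal runs — including the leading one — carry
no span evidence, so only the marker-count half of the rule applies to
them: a terminal run shorter than 2 markers is flagged as an error.  This
uniform "two witnesses" principle is a deliberate choice: accepting
single-marker terminal runs would mint a spurious bin for every error
landing on a chromosome-end marker, defeating the purpose of binning.  Its
cost is that a real crossover witnessed by only the outermost marker is
lost, shortening maps by a few percent at low marker density (measured
≈ 5% at 4 markers/Mb; negligible at resequencing densities).

Bins are the segments between the pooled (union over individuals) accepted
breakpoints.  Each individual's bin consensus is the majority of its
non-error, non-missing member calls; ties and empty sets give missing.
The one-bin matrix keeps one row per bin named by the first (topmost)
member SNP; the consensus construction subsumes the representative
imputation rules (missing or contradictory representative calls are
replaced by the bin majority; a single-marker bin call flagged as a
rejected DR has no remaining support and comes out missing).

## Genetic maps

Two-point linkage: for 1:1 data, r̂ is the recombinant fraction among
co-called pairs and LOD = n_R·log10(2r̂) + n_NR·log10(2(1−r̂)); for 1:2:1
data, r̂ comes from an EM over the standard intercross likelihood (the
double-heterozygote class is a phase-unknown mixture contributing
2r²/(r² + (1−r)²) expected recombinant gametes) and the LOD is the log10
likelihood ratio against r = 0.5.  The EM is validated against a
brute-force grid search of the same likelihood.

Linkage groups are single-linkage components at LOD ≥ 19 (the default
grouping stringency for dense data; note the two-point LOD is bounded by
n·log10 2, so small populations need a lower threshold).  Within groups,
bins are ordered by physical position — order estimation by regression
mapping is intentionally not re-implemented, since bins are physically
anchored; this is a documented limitation, not an omission.  Cumulative
positions sum Kosambi-transformed consecutive-pair r̂; an undefined pair
imputes 0 cM with a warning and r̂ ≥ 0.5 caps the segment at 49.9 cM.

IBD detection reports maximal marker-free gaps ≥ 2.5 Mb, including
telomeric gaps (a chromosome whose markers stop 9 Mb short of the end has a
9 Mb possibly-IBD tail); percentages are gap length over declared
chromosome length.  Physical coverage is the first-to-last mapped marker
span as a percentage of chromosome length.

## QTL scanning

Interval mapping is implemented as Haley–Knott regression rather than a
full EM mixture model: at each scan position (1 cM grid plus every bin
position) the phenotype is regressed on expected genotype scores computed
from the flanking bins through Kosambi-inverted recombination fractions.
At a marker position this reduces exactly to regression on class
indicators, which is the oracle check in the test suite.  A missing flank
contributes its design prior; contradictory flanking calls at ~0 cM
separation (possible after consensus errors) are handled by flooring the
flank recombination fractions at 1e-9.

LOD = (n/2)·log10(RSS0/RSS1); %EV = 100·(1 − RSS1/RSS0) — an R²-style
definition, which need not coincide with other software's variance
decomposition.  Effects come from the fitted class means: for 1:2:1 data
a = (A−B)/2 and d = H−(A+B)/2 (the regression coefficients on
P(A)−P(B) and P(H)); for 1:1 data a = A−H.  Gene action is classified by
|d/a|: ≤ 0.25 additive, ≤ 0.75 partly dominant, ≤ 1.25 dominant, beyond
that overdominant (the band the source classification leaves open);
band-edge ties fall to the lower-dominance class, and a = 0 is
unclassifiable.

Permutation thresholds permute the phenotype vector jointly against the
whole genome and take the empirical (1−α) quantile of the per-permutation
maximum LOD.  The implementation is vectorized: per scan position a QR
factorization of [1, X] turns the RSS of thousands of permuted phenotypes
into one matrix product, making 10 000 permutations cheap.  Support
intervals are the nearest scan positions where LOD falls one unit below
the peak, mapped to flanking-bin physical positions and truncated at the
nearest IBD boundary when they would extend into a marker-free gap.

Reporting across the three maps follows the map-choice rules: a QTL
significant in a parental map (possibly also the combined map) is reported
from whichever map gives the highest LOD; a QTL significant only in the
combined map is not reported.  Major Mendelian traits can instead be
co-segregated directly: the trait is coded as a pseudo-marker and placed in
the bin minimizing the mismatch fraction (allowing a global label swap).

## Color scoring

FCS = b0 + b1·L + b2·a* + b3·b*, ordinary least squares.  The protocol is a
uniform random 70/30 train/test split (stratified-by-grade splitting is
offered since grades are banded), 5-fold CV on the training subset
reporting mean ± sd of R², MAE and RMSE, refit on the full training subset,
and held-out evaluation.  R² is 1 − SSres/SStot on the evaluation set; a
rank-deficient design (constant color channel) is an explicit error;
predictions outside the training grade range are allowed but flagged.
On the default synthetic conditions (grades uniform on 1–10, grading noise
sd 0.25) CV gives R² ≈ 0.99 with MAE ≈ 0.21 and RMSE ≈ 0.25: the absolute
errors are set by the grading noise, while R² also reflects the grade
variance of the sample, so narrower real-world grade distributions yield
lower R² at the same noise.

## Phenotype statistics

Shapiro–Wilk for normality (≥ 3 values; constant traits flagged
undefined); Pearson correlations with two-sided p on pairwise-complete
observations (point-biserial for binary-vs-quantitative arises as a special
case).  Broad-sense heritability uses a one-way random-effects
decomposition — individuals as the genotype effect, yearly values as
replicates: H² = σ²G/(σ²G + σ²E) from the ANOVA mean squares with the
standard unbalanced-design effective replicate number, clamped to [0, 1].
This is one of several defensible H² definitions; agreement with any
particular published H² value is not claimed.  Early/late maturity
comparisons use Welch's one-tailed t-test (early darker).  The expression
screen removes genes whose summed stage × parent mean FPKM is ≤ 10
("combined" read literally as a sum; a mean option is exposed), then flags
genes with any per-stage Welch t-test p < 0.05 between parents; stages with
fewer than two replicates in either parent are skipped with a warning.

## Validation experiments and their scope

- **Error robustness** (the method's motivating property): on a simulated
  50 cM chromosome (N = 100, ~500 markers, ε = 0.01, 5% missing) the
  one-bin map stays within 20% of the truth while the naive per-marker map
  inflates ~10-fold.  A single population's realized crossover count is
  Poisson (sd ≈ 11% here), so the acceptance script averages five
  replicates.
- **Recovery power**: a QTL of one phenotypic-sd additive effect (n = 232)
  is located within 10 cM with LOD above a 1000-permutation threshold in
  ≥ 90% of replicates.
- **Type-I control**: fresh Gaussian null phenotypes exceed the α = 0.05
  genome-wide threshold at the nominal rate within binomial error.

These demonstrate correctness under the generator's assumptions at desk
scale; they are not a benchmark on real resequencing data.
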