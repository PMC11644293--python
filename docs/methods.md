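# Methods

## Composite tolerance index

The index chain is defined on replicate-averaged trait values. DC = X/CK
requires CK > 0; a zero control value is an error rather than DC = 0,
because control germination in a viable panel is near-saturated (the
generator respects this: control GP is drawn in the 90–100% range) and a
zero control measurement signals a failed assay, not tolerance. DI = DC ·
X/X̄ additionally requires a positive panel mean under stress — a trait
with zero panel-wide stressed performance carries no ranking information
and is rejected with an explicit message.

Factor extraction is the principal-component style used by mainstream
statistics packages: eigen-decomposition of the Pearson correlation matrix
of the DI columns. Loadings are eigenvectors scaled by √λ; factor-score
coefficients follow the regression method (R⁻¹·loadings); factor scores
are standardised DI times the coefficients. Both matrices are reported
because the two are easy to confuse in published tables — score
coefficients are not bounded by 1, loadings from a correlation matrix are.
Eigenvectors are sign-ambiguous, so signs are fixed to make the GP loading
positive; factor scores are then comparable across runs.

Retention defaults to the Kaiser rule (λ > 1.0). On a four-trait
germination panel the first factor typically explains ~80% of variance and
is the only one retained, in which case ω = (1) and D equals the
membership-normalised F1 score, so D can genuinely reach 0 and 1. When no
eigenvalue exceeds 1 (an essentially uncorrelated panel) the first factor
is retained with a warning rather than failing, since downstream weights
cannot be computed from an empty set. A `retain_rule="all"` or integer
top-k override is available; with all factors retained ω ∝ P.

The membership function is applied to retained factor scores (not to the
raw DI columns): min–max normalisation per factor, so the extreme
accessions map to exactly 0 and 1. Classification bands are
lower-inclusive/upper-exclusive with the top band closed —
[0.7, 1.0], [0.4, 0.7), [0.1, 0.4), [0.04, 0.1), [0, 0.04) — a convention
that makes the five bands a partition of [0, 1]; the boundaries are
configurable.

WPGMA clustering runs on |D_i − D_j| (Euclidean distance in one
dimension) via scipy's weighted linkage, cut into four groups by default;
the module tests pin the merge heights to a naive O(n³) re-implementation
on all small instances.

## Mixed-model association

The scan is the EMMAX approximation: variance components of
y = Xβ + u + ε, u ~ N(0, σ²_g K), are estimated once under the null by
REML, profiled to a one-dimensional search over δ = σ²_e/σ²_g (Brent on
log δ ∈ [−10, 10], tolerance 1e−6) after a spectral decomposition of K;
each marker is then a generalized least-squares test on the rotated,
whitened data with a two-sided p from t on n − rank(X) − 1 degrees of
freedom. With K = I the procedure reduces exactly to per-marker OLS,
which the tests exploit as an oracle. p-values are carried in log space so
−log10(p) survives below 1e−300.

K defaults to the VanRaden centered genomic relationship matrix,
Z Zᵀ / (2Σp(1−p)) with mean-imputed missing dosages; an IBS similarity
alternative is available. No structure covariates are fitted by default —
the kinship absorbs subpopulation stratification, which a dedicated test
verifies on a 5-subpopulation null (naive OLS inflated, mixed-model
type-I error within [0.005, 0.02] at nominal 0.01). QC keeps SNPs with
MAF strictly above 0.05 and missing rate strictly below 0.5; the
significance threshold −log10(p) > 5.75 is strict and exposed as a
parameter (it is a convention inherited from prior panel studies, not
derived here). λ_GC uses the exact χ²₁ median (≈0.4549) as the null
reference.

## Candidate mapping

Coordinates are 1-based inclusive throughout (GFF3 convention). Windows
are [pos − 75000, pos + 75000] clipped at 1, and a gene is reported on ≥1
bp intersection — the permissive standard, since "within the region" does
not imply full containment. SNP–gene distance is 0 inside the gene and
otherwise plain coordinate subtraction to the nearer gene end; on the
published coordinates this reproduces the 508 bp / 19.9 kb values (one
figure caption prints 506 bp for the same pair; simple subtraction gives
508 and that is what the implementation reports). Allele percentages are
computed over non-missing allele counts. LD r² is the squared Pearson
correlation of 0/1/2 dosages over pairwise-complete accessions.

CAPS screening builds both allele versions of the sequence and counts
IUPAC-aware recognition-site matches in the ±(site length − 1) bp
neighbourhood of the SNP; a site count differing between alleles flags the
enzyme as a CAPS candidate. The default catalogue (SalI GTCGAC, BclI
TGATCA, SspI AATATT) is palindromic, so forward-strand scanning is
complete; non-palindromic sites in an extended catalogue are additionally
matched via their reverse complement.

## Expression statistics

Technical replicates are averaged on the Ct scale before differencing
(standard Livak practice). ΔCt = Ct_target − Ct_reference,
ΔΔCt = ΔCt_sample − ΔCt_calibrator with the control condition of the same
accession as calibrator, so the calibrator's relative expression is
exactly 1 by construction. Duncan's multiple range test computes critical
ranges from the studentized range distribution at protection levels
α_p = 1 − (1−α)^(p−1) with the harmonic mean group size, applies the
containment rule (a range nested in a non-significant wider range is
non-significant), and emits a compact letter display. At two groups the
protection level collapses to α and the decision coincides with the
pooled t-test, which the tests verify. Group contrasts treat accessions
within a tolerance group as biological replicates; per-accession
technical-replicate pooling is available through the same function by
passing different groupings.

## Synthetic panel generator

The generator's defaults are the study conditions: 196 accessions, 3
replicates of 50 seeds, control means GP 97.2%, FW 29.3 mg, SL 10.9 mm,
RL 33.3 mm, stress reductions 72.09/71.88/83.62/83.86%, control/drought
CVs and the published 4×4 DI correlation structure, genotypes in 5
subpopulations (Balding–Nichols with Fst 0.1), MAF drawn in (0.05, 0.5],
2% missing calls completely at random.

One latent tolerance value per accession drives everything: T =
subpopulation shift + additive causal-SNP effects + unit noise,
standardised. Per-trait latents U carry the configured correlation matrix
exactly (U = ρT + E with ρ the first eigen-component and cov(E) = R −
ρρᵀ). The stressed trait value is control mean × (1 − reduction) × m,
where the link satisfies m² = max(0, 1 + 2cU)/norm — chosen so that the
DI, which is quadratic in the trait value, is linear in U and inherits the
correlation structure instead of attenuating it. The censoring at zero
(accessions that fail to germinate at all under stress, as real panels
show) still attenuates correlations slightly, so the latent correlations
are pre-compensated by numerically inverting the censored-link correlation
map; the resulting DI correlations land within a few hundredths of the
target. The dispersion parameter c scales with the configured reduction
relative to its calibrated default: no stress means nothing for tolerance
to modulate, which also makes the zero-reduction case mean-preserving for
the bounded GP trait.

Constitutive size: control FW/SL/RL are lognormal with a shared size
factor (half the log-variance); the stressed value carries size with
exponent 1/2, which makes the DI ratio cancel constitutive-size noise
exactly — in this model stressed performance is driven by tolerance, not
by unstressed vigor. GP is binomial: 50 seeds per replicate at the
accession's germination probability, giving realistic integer counts and
exact zeros.

What the generator does not emulate: linkage disequilibrium decay along
the chromosome (SNPs are drawn independently given subpopulation
frequencies), genotype–environment interaction across replicates, batch
effects, and informative missingness. Passing tests therefore demonstrate
that the pipeline's statistics behave as designed under the stated
generative assumptions, not that the biological effect sizes of any real
panel are recoverable.

## Problem sizes and numerics

Test simulations use panels of 50–250 accessions and 500–5,000 SNPs, and
100 replicates for the power check (n = 200, m = 2,000, one causal SNP at
~30% explained variance) — sizes at which the checked contrasts (EMMAX vs
OLS to 1e−6 on −log10 p; KS uniformity of 5,000 null p-values; top-hit
power ≥ 95/100) are sharp while the whole suite stays fast. Degenerate
inputs fail loudly: non-positive-definite correlation inputs, constant
phenotypes or factor scores, monomorphic panels, windows on unknown
chromosomes, and reference-allele/sequence disagreements all raise typed
errors naming the offender. All tabular output uses 6 significant digits
(p-values in scientific notation) with '.' for missing, so reruns are
byte-identical and diffable.
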