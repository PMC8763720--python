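# Methods

This note documents the statistical models behind each module, the defaults
that matter, what the synthetic-data generator does and does not emulate, and
the numerical choices made where the design was genuinely open.

## Record model and harmonization

A study is a set of per-SNP association records in a fixed column layout
(`SNP CHR POS EA OA EAF BETA SE P Z N`), 1-based VCF-style coordinates,
alleles restricted to {A,C,G,T}. The genome build is metadata only; no
liftover is attempted. Missing values are `NA` on disk and NaN in memory;
reals are serialized with 12 significant digits so a read/write round trip is
exact to ~1e-12 relative.

Harmonization orients every record so the effect allele is the reference
panel's ALT allele. The record is matched on SNP id, with chromosome/position
agreement required (an id match at a different position is treated as absent
from the reference — retained but excluded from frequency checks). Allele
comparison distinguishes: exact match; swap (effect/other reversed → β, Z
negated, eaf complemented); strand flip (base complement); strand+swap; and
mismatch (dropped). Palindromic pairs (A/T, C/G) are strand-ambiguous by
construction: they are resolved by choosing the orientation whose frequency
is closer to the reference ALT frequency, and only when both study and
reference MAF are below the ambiguity threshold (default **0.4**); otherwise
the record is dropped. This is the standard guard against silent strand
errors at intermediate frequencies.

Field reconstruction: a missing SE is recovered as `|β|/Φ⁻¹(1−p/2)`
(impossible when β = 0 or p = 1, counted as unrecoverable); a missing Z is
filled from β/SE, or from p with β's sign; a missing p from the two-sided
normal tail of Z; a missing frequency from the reference. P-values below the
smallest positive normal double are clamped before quantile inversion, with a
warning.

One floating-point caveat: the frequency complement `1−(1−x)` is not
bit-exact in IEEE doubles, so the harmonize→swap→harmonize involution is
exact on every column except EAF, which can differ by one ulp.

## Quality control

Four checks, two per-SNP and two study-level:

| check | statistic | flag / verdict rule | default |
|---|---|---|---|
| frequency concordance | \|eaf − ref_af\| | flag if > af_delta | 0.2 |
| p/Z consistency | \|log₁₀p_rep − log₁₀p(β/se)\| | flag if > logp_delta | 1.0 decade |
| effect symmetry | skewness g₁ = m₃/m₂^{3/2} | asymmetric if \|g₁\| > skewness_max | 0.5 |
| inflation | λGC = median(z²)/0.4549 | reported, not gated | — |

The implied phenotypic variance, `median_j(se_j²·n_j·2p_j(1−p_j))`, is
reported as a sanity check (≈1 for a standardized trait); the median makes it
robust to top hits, at the cost of ignoring the O(h²/M) per-SNP β² term.

A SNP is an **outlier** if any per-SNP flag is set; SNPs that no check could
evaluate (missing fields, absent from reference) are excluded from the
denominator. The study verdict is *not recommended* iff the outlier fraction
strictly exceeds **5 %** or the effect distribution is asymmetric. The
verdict is advisory: registration proceeds with an explicit override. The
cutoffs for the per-SNP deltas and the skewness statistic are this package's
choices (robust to rounding in published files); the 5 % outlier rule and the
symmetry requirement define the upload policy itself. The p/Z check compares
against the normal tail; scans generated by the simulator carry t-based
p-values (n−2 df), whose disagreement with the normal is orders of magnitude
below the one-decade flag threshold at any realistic n.

## Meta-analysis

Fixed-effect IVW per SNP: wᵢ = 1/seᵢ², β̂ = Σwᵢβᵢ/Σwᵢ, se = (Σwᵢ)^{−1/2},
Q = Σwᵢ(βᵢ−β̂)², I² = max(0, 1−(k−1)/Q). The Z-score method is Stouffer's
with √n weights: ẑ = Σ√nᵢzᵢ/√Σnᵢ; it yields direction and significance only,
so the pooled β/se are left missing. SNPs absent from some studies are
combined over the studies that have them (k recorded; `complete_cases`
restricts to full overlap). Output frequency is the n-weighted mean. No
random-effects model and no λGC correction of inputs — λGC is reported by the
compatibility check instead, leaving the decision with the analyst.

## LD-score regression

LD scores use a SNP-count window (default 100; the synthetic panel has no
genetic map to define cM windows): ℓⱼ = 1 + Σ_{0<|k−j|≤w} r̃²ⱼₖ within the
chromosome, with r̃² = r² − (1−r²)/(n−2), which is unbiased for zero under
independence, so ℓ is not inflated by panel sampling noise. Monomorphic SNPs
get ℓ = 1 and a flag.

Heritability is the slope of the weighted regression of χ²ⱼ = zⱼ² on
N·ℓⱼ/M (intercept free, or constrained to 1 with `intercept_one`). Weighting
is two-step: 1/max(ℓ,1) first, then heteroskedasticity weights
1/(2(N·ℓ·ĥ²/M + intercept)²·max(ℓ,1)). The step-1 estimates that enter the
step-2 weights are **cross-fitted by block** — each block's weights come from
a fit excluding that block — because in-sample weights correlate with each
SNP's own χ² noise and measurably attenuate the slope at desk-scale SNP
counts (~9 % at M = 2000). Standard errors are leave-one-block-out jackknife
over contiguous position-sorted blocks (default 20; the simulation benches
use 40).

Genetic covariance ρ_g is the analogous slope of z₁z₂ on √(n₁n₂)·ℓ/M; the
free intercept absorbs sample overlap. r_g = ρ_g/√(ĥ²₁ĥ²₂), with the
jackknife applied to r_g itself (all three regressions re-fit per deleted
block); r_g is undefined (NaN, flagged) when either heritability estimate is
non-positive. All heteroskedasticity weights are built from step-1 estimates,
with a sign-symmetric cross term, which gives two exact identities: a study
regressed on itself returns r_g = 1 bit-for-bit, and negating one trait's
effects negates r_g exactly.

Desk-scale caveat: the regression has leverage only if ℓ varies. A
constant-LD panel gives nearly constant ℓ and a hopelessly ill-conditioned
fit; the packaged benches therefore interleave many small LD blocks of
varying strength (`simulate.concat_panels`), which also keeps the jackknife
blocks exchangeable.

## Colocalization (SMR / HEIDI / θ)

The SMR statistic at the instrument (top exposure SNP) is
T = z₁²z₂²/(z₁²+z₂²), referred to the 1-df χ² upper tail; T ≤ min(z₁²,z₂²),
approaching the smaller χ² as the other grows.

HEIDI asks whether the ratio bᵢ = z₁ᵢ/z₂ᵢ is constant across SNPs in LD with
the instrument, as it must be under a single shared causal variant.
SNP selection: trait-2 p < 1.6e-4 (|z| ≳ 3.78), r² to the top SNP within
[0.05, 0.9], mutual-redundancy pruning at r² > 0.9 keeping the smaller p, at
most 20 SNPs; the top SNP is always included. The covariance of
dᵢ = bᵢ − b_top comes from the delta method on z-ratios with
cov(z·ᵢ, z·ⱼ) = rᵢⱼ from the panel and cov(z₁, z₂) = 0 — i.e. the two traits
are assumed measured in non-overlapping cohorts. The statistic
T = Σ(dᵢ/sd(dᵢ))² is a weighted sum of 1-df χ² variables; its tail is
evaluated by seeded Monte Carlo (default 100 000 draws) from the
eigenvalues of the correlation matrix of the standardized d, with the +1
continuity correction, so repeated calls under one seed are bit-identical
and p has negligible MC error above ~1e-4. A singular covariance is
ridge-regularized (1e-8 on the diagonal) with a warning. Ratios use
z-scores rather than effect sizes, avoiding unit dependence.

θ is the cosine similarity of the two orientation-harmonized z profiles over
the region: θ = Σz₁ᵢz₂ᵢ/√(Σz₁ᵢ²·Σz₂ᵢ²) ∈ [−1,1]. The raw (un-whitened)
cosine is used; an LD-whitened variant (z → L⁻¹z) would discount redundant
SNPs in strong LD and may be preferable when regions are dominated by one
large LD block. θ is invariant to positive rescaling of either profile and to
jointly flipping any SNP's orientation.

Default region: ±500 kb around the top trait-2 SNP.

## Mendelian randomization

Instruments are exposure SNPs with p < 5e-8, greedily LD-clumped (ascending
p; discard at r² > 0.01 with a retained SNP within 500 kb), joined to the
outcome on SNP id. Three estimators over the Wald ratios wⱼ = β_yⱼ/β_xⱼ with
first-order delta SEs se_yⱼ/|β_xⱼ| (the se_x term is ignored — valid for
strong instruments; instruments with β_x = 0 are dropped with a warning):

* **IVW**: precision-weighted mean of ratios.
* **Egger**: WLS of β_y on β_x with free intercept, weights 1/se_y²,
  instruments pre-oriented to β_x ≥ 0 so the intercept is interpretable as
  directional pleiotropy. SEs use a multiplicative random-effects scale
  floored at 1: with ~10 instruments the freely estimated residual scale
  often drops below the sampling floor and understates the SEs.
* **Weighted median**: interpolated weighted median of ratios, SE by seeded
  parametric bootstrap (default 1000 draws of β_x, β_y from their sampling
  normals); consistent when up to half the weight lies on invalid
  instruments.

All three coincide when every ratio is identical; estimates are invariant to
instrument order and to re-coding any SNP's effect allele.

## Synthetic-data generator

Haplotypes follow a first-order Markov copy chain: SNP j copies SNP j−1's
allele on the same haplotype with probability `ld_rho`, else draws fresh from
Bernoulli(maf_j) with maf_j ~ U(maf_range) (default (0.05, 0.5)). Copying
makes realized frequencies drift smoothly, so adjacent Pearson correlation ≈
ld_rho and r² decays geometrically with distance (audited: mean adjacent |r|
= 0.026 at ρ = 0, mean r² = 0.81 at ρ = 0.9). Panel AF is defined as the
realized haplotype column mean, so study EAF and reference AF agree exactly
when the same individuals are scanned. `concat_panels` stacks blocks with
different ρ as successive chromosomes over the same individuals.

Phenotypes are additive: a uniformly drawn causal set with effects
N(0, h²/n_causal) on standardized dosages, Gaussian noise scaled to the
target h², and the final phenotype centered and scaled to sample variance
exactly 1 (so the QC trait-variance estimator has a known target). The
realized h² is reported alongside. The association scan is exact per-SNP
simple linear regression (closed-form normal equations, verified against an
explicit least-squares oracle to 1e-10), with t-based p-values (n−2 df),
Z = β/se, and ALT-allele dosage as the effect allele.

Corruptions alter exactly round(fraction·m) seeded-randomly chosen records:
frequency flips (eaf → 1−eaf), p-value scrambling among victims, ten-fold
effect inflation with untouched SEs, and strand errors (complemented alleles
without re-orientation). An optional candidate mask restricts the victim
pool, e.g. to low-frequency SNPs where a frequency flip is guaranteed to
breach the concordance threshold.

What the generator does **not** emulate: realistic demography or coalescent
genealogies (no allele-frequency spectrum shape, no long-range LD), genotype
imputation uncertainty, case-control liability traits, cryptic relatedness or
population stratification (the LDSC intercept is therefore ≈1 by
construction), and multi-allelic or indel variation. Passing tests show the
methods are implemented correctly under their own model assumptions, not that
they are robust to the artefacts of real cohort data.

## Simulation scales used in the test suite

Study sizes were chosen so every regime of interest is exercised while the
whole suite stays interactive: QC boundary experiments use 1 000 SNPs ×
1 000 individuals; LDSC benches 2 000 SNPs × 2 000 individuals in 80 LD
blocks with 100 phenotype replicates; HEIDI error rates 200 replicate loci of
50 SNPs × 2 000 individuals; MR recovery 100 replicates of 300 SNPs × 5 000
individuals. Statistical acceptance bands follow the estimators' own
uncertainty (±2 jackknife/bootstrap SEs, binomial tolerance on rates).

## Known limitations

* λGC conflates polygenicity with confounding at desk scale; on strongly
  polygenic simulations λGC ≫ 1 is expected and correct.
* The LDSC slope is approximately unbiased only when causal effects are
  spread over the scored SNPs (the M in N·ℓ/M must match the effect
  support); heritability concentrated on few SNPs inflates the variance of
  the fit far beyond the jackknife's view of it.
* HEIDI's cohort-independence assumption (cov(z₁,z₂) = 0) is wrong for
  overlapping samples; the cross term would need the phenotypic correlation,
  which summary statistics alone do not provide.
* The MR instrument SEs ignore exposure-side noise; weak instruments violate
  this and bias ratios toward zero (no Steiger filtering, no second-order
  correction by default).
* The registry is a single-directory flat-file store; concurrent writers are
  not protected.
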