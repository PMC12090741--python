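# Methods

This note documents the statistical models implemented in `lifehist`,
the defaults and why they were chosen, what the synthetic generators do
and do not emulate, and the numerical conventions that matter for
reproducing results.

## Community-weighted rrn copy number

Each ASV receives the operon count of the most taxonomically resolved
reference match, searching genus → family → order → class → phylum down
to a configurable fallback rank (default: phylum). When several
reference lineages match at the deciding rank, their mean copy number is
used — a deterministic, order-independent tie-break. The community
statistic is the abundance-weighted mean

    avg_rrn = Σᵢ Rᵢ Wᵢ / Σᵢ Rᵢ

over ASVs with an assigned Wᵢ. Reads of unassigned ASVs are excluded
from numerator and denominator rather than imputed with a global mean:
imputation would pull every sample toward the reference average and mask
real contrasts. The matched read fraction is always reported and samples
below `min_matched` (default 0.5) are flagged, not dropped. Because the
statistic is scale-invariant in the counts, rarefaction barely affects
it; it is computed on unrarefied counts by default with rarefaction
available upstream.

## Genomic traits from metagenomes

**GC.** Per-read GC = (G+C)/(A+C+G+T), with N excluded from the
denominator and reads shorter than `min_len` excluded from the moments.
The variance is the unbiased sample variance across reads; the default
reporting unit is percent (variance in %²), where between-ecosystem
differences of a few units are interpretable; a fraction² option exists.

**Genome equivalents and AGS.** Universal single-copy marker families
occur once per genome, so the pooled coverage of a family
(aligned bp / family length) counts genomes observed at sequencing
depth. The aggregator across families defaults to the median for
robustness to a single mis-mapped family (mean available). Average
genome size is total read bp divided by genome equivalents. The marker
family list and hit table are inputs; read mapping itself is out of
scope.

**Codon usage bias.** The CUB statistic is a MILC-type
log-likelihood-ratio. For each multi-codon synonymous family *a* of the
bacterial genetic code (table 11; stops and Met/Trp excluded) with
observed counts O_c, n_a = Σ O_c, and background within-family
frequencies e_c,

    M_a = 2 Σ_c O_c ln((O_c/n_a) / e_c),   0·ln 0 := 0,

and the raw statistic is (Σ_a M_a)/L with L = Σ_a n_a. The corrected
statistic subtracts the *exact* null expectation of each M_a under
Multinomial(n_a, e), computed from the binomial marginals (each family
term is additive over codons, so the expectation is a finite sum of
binomial pmf terms, cached by (family frequencies, n_a)). The usual
χ² degrees-of-freedom count k_a − 1 is the asymptotic limit of this
quantity but under-corrects by O(1/n_a) at real ribosomal-protein gene
lengths (~200 codons), leaving a visible positive bias; the exact form
centres background-sampled genes at zero at any length. The background
distribution pools codon counts over all background genes
(count-weighted, not gene-averaged); families unobserved in the
background are flagged and skipped in scoring. The community CUB is the
codon-count-weighted mean of corrected per-gene statistics over
ribosomal genes. The statistic sits behind a small interface so an
alternative (e.g. an ENC difference) could be plugged in.

**Growth prediction.** Minimum generation time follows
ln d = β₀ + β₁·CUB (β₁ expected negative: stronger ribosomal codon bias,
faster growth); maximum growth rate is 1/d. The calibration is an OLS
fit of ln(doubling time) on CUB; the shipped defaults (β₀ = 1, β₁ = −2,
giving d between ~0.4 h at strong bias and ~2.7 h at none) are fitted on
synthetic pairs — fitting on real doubling-time compendia would require
external data and is out of scope, and all comparisons made with the
package are of relative trait differences, which are insensitive to the
calibration anchor. Temperature adjustment of the prediction is not
implemented (pluggable extension).

## qPCR chip

QC is applied per well: a well is retained iff efficiency ∈
[1.8, 2.2] (inclusive), its negative control did not amplify, and
CT ≤ 31 (an undetected CT fails this rule). The exclusion log records
the first rule that fired in the order efficiency → negative control →
CT, so exclusion counts partition the excluded wells. Quantification
uses the single-curve model copies = 10^((CT − intercept)/slope) per
replicate with geometric-mean pooling — the arithmetic mean on the CT
(log) scale — and a sample×gene value is reported if at least one
replicate survives. Relative abundance divides by the 16S rRNA copies of
the same sample; samples without a positive 16S value are dropped with a
warning. The packaged 66-gene map labels the 48 genes of the
well-established carbon-hydrolysis, inorganic-nitrogen-transformation
and phosphorus-solubilization pathways; remaining chip targets are
"other" and excluded from the C+N+P total.

## Community ecology

Rarefaction draws a multivariate hypergeometric sample (exact uniform
subsampling without replacement) to a fixed depth, default 33,018 reads;
shallower samples are dropped with a warning. Shannon uses natural log;
Chao1 defaults to the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)),
defined even without doubletons (classic form via flag).

Weighted UniFrac is the normalized variant,
d(A,B) = Σ_b ℓ_b·|p_A(b) − p_B(b)| / Σ_b ℓ_b·(p_A(b)+p_B(b)), bounded in
[0, 1] so values are comparable across pairs; computation is delegated
to scikit-bio and cross-checked in the tests against an exhaustive
branch-enumeration oracle. Bray–Curtis (on proportions) is provided as a
non-phylogenetic fallback.

NMDS minimises Kruskal stress-1 by SMACOF majorization with isotonic
(pool-adjacent-violators) regression of configuration distances on the
dissimilarity order. The update path depends on the input only through
ranks, so stress is exactly invariant under strictly monotone transforms
of the dissimilarities — the defining property of nonmetric scaling.
Defaults: k = 2, 20 random restarts, 500 iterations, tolerance 1e-6 on
the relative stress decrease; coincident points during iteration are
held apart by 1e-8. The best configuration is centred, rotated to
principal axes, and sign-fixed so every axis has a non-negative
coordinate for the first sample: axis signs are intrinsically arbitrary,
and this convention makes NMDS1/NMDS2 reproducible as downstream
predictors (signs need not match any particular published ordination).

**Differential genus abundance** is a deliberately simple, fully
self-contained negative-binomial Wald procedure; numerical agreement
with heavier shrinkage machinery is a non-goal, calibration on the
synthetic null is the goal. Steps: (1) ASV counts are summed per genus,
with unresolved genera grouped per family as `unclassified_<family>`;
(2) median-of-ratios size factors (median taken in linear space over
genera with a finite geometric mean); (3) per-genus method-of-moments
dispersion from pooled within-group moments of normalized counts,
clipped to [1e-8, 10] and shrunk halfway on the log scale toward a
log-linear mean–dispersion trend fitted across genera; (4)
log₂FC = log₂((μ̂₂+½)/(μ̂₁+½)) with a delta-method SE from the NB variance
μ + αμ²; (5) a Wald test against a t reference with n₁+n₂−2 degrees of
freedom — the moment dispersion estimate is noisy at realistic group
sizes and a normal reference is measurably anticonservative (empirical
type-I ≈ 0.07 at 10+10 samples vs ≈ 0.045 with the t) — then
Benjamini–Hochberg adjustment; (6) a genus is *responsive* when
|log₂FC| > 1 and adjusted P < 0.05.

## Driver attribution

All predictors and responses are z-scored (sample SD). Composite
nutrient parameters are PC1 scores of the standardized member variables,
sign-fixed so the first listed variable loads positively; the "N + P"
composite pools the N- and P-related variables into one PCA (a single
principled composite) rather than averaging two separate PC1s — the
averaging alternative is available via a flag since either convention is
defensible.

Group contrasts use a random-intercept model
y = β₀ + β₁·ecosystem + u_site + ε fitted by REML (statsmodels MixedLM),
with Wald-z inference on β₁ — anti-conservative at very small site
counts, documented as such. Near-singular fits (site variance below
1e-3 of the residual variance) are returned as the OLS contrast, which
is exactly what the mixed model degenerates to at the boundary; with
fewer than two sites OLS is used with a warning.

All-subsets selection fits OLS for every predictor subset (k ≤ 12
enforced; 2^k fits) and ranks by the Gaussian profile AIC
n·ln(RSS/n) + 2(k+2), counting slopes, intercept and error variance;
ties break toward the smaller model, then lexicographically. AICc is
available via flag. Note a fixed penalty of 2 admits a given spurious
predictor with probability ≈ P(χ²₁ > 2) ≈ 0.16, so the best model is
expected to contain occasional extras; recovery claims should be read as
"the true drivers are in the best model", not "the best model is exactly
the true set". Hierarchical partitioning computes each selected
predictor's independent effect as its average R² increment over all
entry orders via the 2^k subset-R² table with Shapley weights
s!(k−s−1)!/k! (k ≤ 10); the effects sum to the full-model R² by
construction, and reduce to marginal R² for orthogonal predictors.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of its arguments including the seed
(single RNG stream per call) and returns a truth record.

- **Communities**: one ASV per reference taxon; base log-abundances
  Normal(0, 1) (log-normal rank-abundance with a heavy tail); the
  cropland effect and a Normal(0, site_sd²) site intercept shift the
  log-abundance of *high-copy* taxa (reference copy number strictly
  above the median — a parameter-free copiotroph proxy); multinomial
  sampling at the requested depth (scalar or per-sample vector). Truth
  stores the exact pre-sampling expected community rrn per sample. A
  bisection helper sizes the effect to a target relative rrn difference
  (e.g. 20%) on the generator's own expectation curve.
- **Metagenomes**: reads uniform along genomes (genome chosen by
  length), each genome carrying one interior copy of every marker
  family; aligned bp are the exact read–marker overlaps. Per-read GC is
  truncated-Normal, and each read carries exactly round(gc·L) G+C bases
  so the planted GC distribution is reproduced without base-sampling
  noise (gc_sd = 0 gives exactly zero variance). Defaults: 150 bp
  reads, GC 0.55 ± 0.05.
- **Coding genes**: amino-acid families used uniformly; background genes
  sample codons from the background frequencies, ribosomal genes from
  frequencies exponentially tilted toward each family's preferred
  (modal) codon with strength `bias`. Truth CUB is the asymptotic
  expectation (mean within-family 2·KL of tilted vs background);
  default gene length 200 codons, typical of ribosomal proteins.
- **qPCR plates**: CT from the standard curve plus optional Normal
  noise; each well independently gets an out-of-spec efficiency
  (uniform on [1.5, 1.79] ∪ [2.21, 2.5]) with probability
  `frac_bad_eff` and a negative-control flag with `frac_neg_amp`;
  triplicates per sample×gene.
- **Drivers**: multivariate-Normal predictors with a given correlation
  matrix (positive-definiteness enforced) and a linear response.

Not emulated: sequencer error profiles, chimeras, amplification bias,
phylogenetically realistic trees (the random tree utility exists only to
exercise UniFrac), spatial autocorrelation among sites, or compositional
coupling between traits. Passing the recovery benchmarks therefore
demonstrates the correctness and calibration of the estimators under
the stated generative assumptions — not robustness to real-data
artefacts such as primer bias or taxonomy misassignment.

## Numerical conventions and scales

- Copy numbers in the synthetic reference lie on a 0.5 grid in [1, 15].
- Rarefaction, NMDS restarts, and every generator take explicit seeds;
  the pipeline writes per-output SHA-256 checksums in its manifest and
  reruns byte-identically under a fixed seed.
- The acceptance script uses, per seed: 1,000 random tables for the
  weighted-mean oracle; 100 replicates of 20 sites × 3 samples at depth
  3·10⁴ for effect recovery; 20 metagenomes of 10 genomes (4 Mbp mean)
  with 30 × 6 kb marker families at 300k reads (median-coverage SD ≈ 1%,
  comfortably inside the 5% recovery band); 500 + 4×200 genes for CUB;
  5 × 200 genera for the null type-I rate and 100 replicates for power;
  100 replicates of n = 150 for driver selection. These sizes keep every
  quantity's Monte-Carlo error well below the band it is checked
  against.

## Known limitations

- The rrn reference is a packaged fixture standing in for a live operon
  database; real analyses should regenerate it from a current release.
- Wald-z (LMM) and t (NB test) references are approximations; neither
  implements Satterthwaite/Kenward–Roger degrees of freedom.
- The NB test's dispersion shrinkage is intentionally lighter than
  full empirical-Bayes machinery; borderline genera near the |log₂FC|=1
  threshold are the first place results will differ from heavier tools.
- Structural equation modeling and spatial interpolation are out of
  scope; driver claims rest on the regression/partition stack.
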