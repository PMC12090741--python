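# lifehist

Microbial life-history trait inference for soil communities.

Soil microbial communities can be placed on a copiotroph–oligotroph
(r–K) axis from molecular data alone: fast-growing copiotrophs carry
many rRNA operons (*rrn*) per genome, strong codon-usage bias in
ribosomal genes, and variable GC content, while oligotrophs carry few
operons and grow slowly. `lifehist` implements the statistical pipeline
needed to contrast these strategies between land uses (e.g. cropland vs
pristine soils) from standard molecular inputs:

- **Community-weighted rrn copy number** — per-ASV copy numbers assigned
  from a taxon→operon-count reference by closest taxonomic match
  (genus → phylum fallback), then averaged per sample as
  `avg_rrn = Σᵢ Rᵢ·Wᵢ / Σᵢ Rᵢ`, where `Rᵢ` is the read count of ASVᵢ and
  `Wᵢ` its copy number; unmatched reads are excluded and the matched
  fraction reported.
- **Metagenome-derived genomic traits** — per-read GC mean/variance,
  genome equivalents from the median coverage of universal single-copy
  marker families, average genome size `AGS = total bp / genome
  equivalents`, codon-usage bias (a MILC-type log-likelihood-ratio
  statistic of ribosomal genes against the bulk coding background, with
  an exact small-sample null correction), and predicted minimum
  generation time `d = exp(β₀ + β₁·CUB)` with maximum growth rate `1/d`.
- **qPCR functional-gene chip** — per-well QC (efficiency ∈ [1.8, 2.2],
  clean negative control, CT ≤ 31), standard-curve inversion
  `copies = 10^((CT−intercept)/slope)` with geometric-mean replicate
  pooling, normalisation to gene copies per 16S copy, and C/N/P pathway
  sums over the packaged 66-gene chip map.
- **Community ecology** — rarefaction, Shannon and (bias-corrected)
  Chao1, Bray–Curtis and normalized weighted UniFrac distances,
  nonmetric multidimensional scaling (rank-invariant SMACOF, Kruskal
  stress-1), and a self-contained negative-binomial Wald test flagging
  responsive genera (|log₂FC| > 1, BH-adjusted P < 0.05).
- **Driver attribution** — z-scoring, PC1 composite nutrient parameters,
  random-intercept mixed-model contrasts (ecosystem fixed, site random,
  REML), Spearman correlation, all-subsets OLS ranked by AIC, and
  hierarchical (Shapley) partitioning of explained variance.
- **Synthetic data with recorded truth** — every input above can be
  generated with planted effects (copiotroph enrichment, genome sizes,
  codon bias tied to a known generation time, out-of-spec qPCR wells,
  known driver coefficients), so each stage is testable end to end
  without downloads.

## Worked example

Plant a ~20% community-rrn difference between cropland and pristine
soils (10 sites per arm, 3 samples per site, 30,000 reads per sample)
and recover it with the mixed model:

```python
import lifehist as lh
from lifehist import synthetic
from lifehist.drivers import lmm_group_effect

ref = synthetic.gen_reference(150, (1, 15), seed=100)
effect = synthetic.calibrate_effect(ref, 0.20, seed=7)
table, meta, truth = synthetic.gen_communities(
    ref, n_sites=20, samples_per_site=3, effect=effect,
    site_sd=0.1, depth=30_000, seed=7,
)
copies = lh.assign_rrn_copies(table, ref)
res = lh.community_avg_rrn(table, copies)
fit = lmm_group_effect(res["avg_rrn"], meta["ecosystem"], meta["site_id"])
print(f"true cropland-pristine rrn difference: {truth.true_effect_rrn:.3f}")
print(f"estimated difference: {fit.fixed_effect_estimate:.3f} +/- {fit.se:.3f} (p = {fit.p:.2e})")
```

prints

```
true cropland-pristine rrn difference: 1.647
estimated difference: 1.641 +/- 0.064 (p = 2.61e-145)
```

i.e. the REML contrast recovers the planted difference in community
operon count (here ~1.6 operons, a ~20% relative enrichment of
high-copy taxa in cropland) well within one standard error, with the
site-level variance absorbed by the random intercept.

The same stages are available from the shell:

```bash
lifehist simulate --seed 7 --out-dir sim
lifehist rrn --counts sim/counts.tsv --taxonomy sim/taxonomy.tsv \
             --reference sim/reference.tsv --out rrn.csv
lifehist run --seed 7 --out-dir full_run   # full pipeline + manifest
```

## Layout

```
src/lifehist/
  rrn.py         # reference matching + community-weighted rrn
  metagenome.py  # GC, genome equivalents/AGS, MILC CUB, growth prediction
  qpcr.py        # chip QC, standard-curve inversion, 16S normalisation
  ecology.py     # rarefaction, diversity, distances, NMDS, NB Wald test
  drivers.py     # z-scores, PC1, LMM, Spearman, AIC, partitioning
  synthetic.py   # generators with recorded ground truth
  config.py, pipeline.py, cli.py   # orchestration (`lifehist` CLI)
docs/methods.md  # model and design notes
```

See `docs/methods.md` for the statistical details, parameter defaults,
and the limits of what the synthetic benchmarks demonstrate.
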