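# Methods

This note records the models, defaults and numerical choices behind
`bulkscan`, and what the simulation-backed tests do and do not establish.

## 1. The simulated experiment

`bulkscan.simdata` generates every input the pipeline consumes, emulating an
F2 bulked-segregant design for an ordinal color trait:

* **Genome and markers.** `n_chromosomes` chromosomes of `chrom_length_bp`
  (default one 100-Mb chromosome, the geometry of the real mapping target).
  Markers are near-evenly spaced with uniform jitter; a fraction
  (`indel_fraction`, default 0.11, the approximate genome-wide InDel/SNP
  ratio in resequencing data of this kind) is labelled InDel and flows
  through the identical statistic path, distinguished only by type.
* **Meiosis.** Gametes follow a Haldane (no-interference) map at
  `cm_per_mb` (default 1 cM/Mb, a typical plant genome-wide average);
  genotypes are coded 0/1/2 = GP05 homozygote / heterozygote / PP05
  homozygote, and the two parents are fixed opposite homozygotes
  everywhere.
* **Phenotype.** A latent liability `a·(g−1) + d·[g=1] + N(0, σ²)` at a
  single QTL (default a=3, d=0, σ=0.5 — a nearly Mendelianised major gene,
  the regime in which extreme-class bulking is used; a second QTL is
  available via `qtl2`). The five ordinal classes cut the liability at the
  quintiles of the *no-QTL* distribution N(0, σ²); under a strong QTL the
  two extreme classes then coincide with the homozygote clusters, which is
  exactly what the bulking design assumes. The default QTL position,
  78 Mb, mirrors the position of the real chromosome-10 locus; it was fixed
  a priori and is configurable.
* **Bulks.** The `n_bulk` (default 30) most extreme class-1 and class-5
  plants, ties broken by liability then individual id, so bulk membership
  is a pure function of the seed.
* **Pooled reads.** Equal-weight allele pooling (equal-amount DNA mixing):
  the true PP05-allele frequency of a bulk is the mean genotype dosage of
  its members; parents are fixed at 0/1. Depths are Poisson(`mean_depth`,
  default 30); reads are Binomial(depth, p(1−e)+(1−p)e) with per-read
  error e = 0.001 (~Q30). No pipetting-noise term is modelled.
* **RNA-seq.** Negative-binomial counts, 3 vs 3 replicates, dispersion
  0.05, base means log-normal(ln 100, 1.3). `n_de` genes (default 100, 80%
  of them placed in the candidate region) receive |log2FC| = 2 with random
  sign; a designated causal gene receives log2FC = 3.5, the near on/off
  contrast expected of a major pigment-pathway regulator. Ground-truth
  labels are returned for recovery tests.

Every stage draws from a generator seeded by (config seed, stage tag), so
any stage re-run with the same config is byte-identical.

What the generator does **not** emulate: read-level errors beyond a
symmetric per-read flip, mapping artefacts, depth–GC covariation, pipetting
noise in pool construction, polygenic background beyond the Gaussian
residual, and genotyping error in the marker tables. A green recovery test
therefore establishes that the statistics behave as designed under clean
Mendelian sampling — not that they are robust to artefacts of real pooled
sequencing.

## 2. Association scan

* **Orientation and filtering.** A site is informative when each parent's
  minor-allele read fraction is ≤ 0.1 (calling it homozygous) and the
  parents disagree; the PP05 allele is then known per site. Bulk depths
  must lie in [10, 3× mean] by default — bounds are declared in the run
  log, not derived from data.
* **Δ(SNP-index).** Purple-bulk minus green-bulk PP05-allele read fraction;
  zero-depth pools yield flagged missing records excluded from smoothing.
* **Smoother.** "Distance" fitting is tricube-kernel local regression on
  physical distance, local-constant by default (local-linear available),
  bandwidth 2 Mb, never across chromosome boundaries; positions with no
  in-window support fall back to the nearest supported marker.
* **Null thresholds for Δ.** Monte-Carlo (default 10,000 reps): per
  replicate, each bulk's n_bulk genotypes from (¼,½,¼) with no selection,
  bulk frequency = mean dosage, reads Binomial(depth, freq); the threshold
  at level L is the L-quantile of |Δ|. Thresholds are tabulated at every
  observed depth and linearly interpolated; a site's lookup depth is
  min(bulk depths), slightly conservative when depths are asymmetric.
  Genotype draws are shared across the depth grid — depth only enters the
  read-sampling stage.
* **ED.** `√(Σ_alleles (f_green − f_purple)²)` = √2·|Δf| at biallelic
  sites; "multiplication" de-noising is a power transform ED^k, default
  k=5 (self-multiplication, the standard choice in ED-based BSA). The
  association threshold is median + 3·sample SD (n−1) of the smoothed
  ED^k values, computed genome-wide but separately per marker type, since
  the InDel scan is the same method run in parallel and a pooled threshold
  mis-calibrates the sparser track.
* **Regions.** Maximal runs of consecutive markers with smoothed statistic
  above threshold (|fitted| for Δ, two-sided, since the confidence bands
  are symmetric; one-sided mode available); runs < 1 Mb apart merged;
  runs with < 10 markers dropped; endpoints are marker positions, not
  window edges. SNP and InDel regions are union-merged within each method,
  then the two methods' region sets are intersected (1-based inclusive
  interval arithmetic; lengths reported in Mb at two decimals).

## 3. Fine mapping

Co-segregation scoring is strict: a marker co-segregates iff zero scored
bulk plants violate the expected genotype (green extremes 0; purple
extremes 2 under the additive model, {1,2} under the dominant model).
Missing calls are excluded from the denominator rather than imputed, and a
marker with < 80% of plants scored is flagged low-confidence. The refined
interval is [min, max] position of all co-segregating markers on the
region's chromosome; one marker gives a zero-length interval and no
co-segregating marker inside the region is an error (the orchestrator
catches it and falls back to the unrefined scan region, noting the
fallback). Co-segregation through 2×60 gametes requires a marker within
roughly 0.8 cM, so the default simulated panel places 100 markers across
the candidate interval.

## 4. Expression stage

FPKM = counts·10⁹/(length·library size); genes below 1 FPKM in *all*
samples are excluded (the boundary value is kept). The DEG caller is a
deliberately lightweight stand-in for DESeq2: median-of-ratios size factors
(total-count fallback), log2 fold change of normalised group means with
pseudocount 0.5, a per-gene NB Wald test whose variance uses the
delta-method `(1/μ + α)/n` with a pooled within-group method-of-moments
dispersion floored at 1e-8, and Benjamini–Hochberg correction. Its
acceptance surface is parameter recovery on simulated ground truth
(sensitivity ≥ 0.8, empirical FDR ≤ 0.1 at the standard FDR < 0.01,
|log2FC| > 1 rule), not DESeq2-identical numbers; one test cross-checks
fold-change estimates against pyDESeq2 as an independent implementation.
Replicate QC is Pearson r on log2(FPKM+1). Term enrichment is the
hypergeometric upper tail with BH Q values, significance flagged at
p ≤ 1e-4 (GO convention) and Q ≤ 0.05 (KEGG convention); the background
defaults to the FPKM-filtered gene set.

## 5. Candidate report

Region genes are selected by ≥ 1 bp overlap (containment available).
Ranking is deterministic: significant DEGs first (|log2FC| descending, FDR
ascending), then annotation-keyword matches (anthocyanin-pathway
vocabulary: MYB/bHLH/WD, chalcone, flavonoid, vacuolar transport — an
explicitly heuristic stand-in for manual curation), then position.

## 6. Known limitations

* **The median+3SD ED threshold assumes a background-dominated genome.**
  On a single 100-Mb, 1-Morgan chromosome carrying a strong QTL, more than
  half the loci are in linkage with it, so the threshold is computed from a
  distribution dominated by the signal; in roughly 10–20% of simulated runs
  it exceeds the attainable maximum (√2)^k and the ED method calls nothing,
  emptying the two-method intersection. Under a no-QTL genome the smoothed
  ED^k track is right-skewed and long-range autocorrelated (bulk genotype
  sampling wander), so its rare median+3SD exceedances arrive in runs far
  longer than the 10-marker minimum and spurious regions appear on ~40% of
  null chromosomes even in a 12-chromosome genome. Two acceptance tests
  assert the stricter behaviour (≥95% intersection recovery on one
  chromosome; ≤25% null chromosomes with an ED region) and are expected to
  fail; the Δ(SNP-index) arm alone recovers the QTL in 20/20 runs and its
  null exceedance rate calibrates at ~0.9% against the nominal 1%. On
  multi-chromosome genomes where background dominates — the setting the
  rule comes from — the ED caller behaves as intended (see the worked
  example's two-chromosome test worlds).
* The null-calibration worlds use n_f2 = 360: with 240 plants and no QTL
  the 30-plant extreme classes are occasionally unfilled; the null Δ
  distribution depends only on n_bulk and depth, not n_f2.
* Zero-tolerance co-segregation is sensitive to genotyping error, which the
  simulator does not model; real screens would tolerate a small recombinant
  count or re-genotype.
* The Wald test is anticonservative for very low counts at n=3; extreme
  fold-change estimates for near-zero genes occasionally outrank truly
  stronger effects (no shrinkage is applied).
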