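# Methods

This note documents the models and procedures snppanel implements, the
parameter defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical and design choices
made where the problem left room.

## Genotype model and QC

Genotypes are stored as alt-allele dosage codes {0, 1, 2} with −1 for
missing; half-called diploid genotypes (`0/.`) count as missing, and phased
and unphased calls are treated identically. Coordinates are 1-based
inclusive (VCF convention) everywhere inside the package; BED files are
converted to/from 0-based half-open only at the I/O boundary. Chromosome
order follows first appearance in the VCF header.

The QC filter retains sites with missingness **< 0.1** and MAF **≥ 0.05**.
The MAF boundary is inclusive: "remove MAF < 0.05" is the removal condition,
so a site at exactly 0.05 stays. Sites where every call is missing are
flagged undefined rather than silently reported as monomorphic, and fail the
missingness filter. The filter is idempotent by construction.

## Breed-informative scoring

For each breed pair, three per-site statistics:

* **Wright's Fst** in the two-population heterozygosity form
  (H_T − H_S)/H_T with H_T = 2p̄(1−p̄), p̄ the mean of the two frequencies,
  defined as 0 when both populations are fixed for the same allele. No
  sample-size correction is applied — the plain parametric form is the
  intended statistic here, and candidate ranking only needs relative order.
  Algebraically this estimator equals (p₁−p₂)² / (4 p̄(1−p̄)).
* **delta** = |p₁ − p₂|.
* **Rosenberg's I_n** over both alleles with natural log and 0·ln 0 = 0.
  For two populations it is 0 iff p₁ = p₂ and reaches its maximum ln 2 at a
  fixed difference (verified against a grid-search oracle).

Which breed comparisons feed the ranking is a genuine design choice: the
package scores **every unordered breed pair with all three statistics** and
takes the union of per-(statistic, comparison) top-N lists. The union
preserves markers informative for any single contrast; a marker that is
uninformative for every pair is never carried. Ties at the top-N boundary
break on genome-order site index, so ranking is deterministic.

Subset size among {1000, …, 5000} is picked by a plateau rule: the smallest
N whose breed-label silhouette (computed in PC1–PC2 space of a PCA
restricted to the subset) is within 0.02 of the maximum across the tested
sizes. A quantitative surrogate is needed because "pick the best-looking
PCA" is not reproducible; 0.02 is small against the silhouette's own
replicate-to-replicate spread.

When averaging Fst across many loci (the simulator calibration), the
package uses the heterozygosity-weighted ratio-of-sums
Σ(H_T − H_S)/ΣH_T rather than the mean of per-locus ratios; the unweighted
mean is biased low by Jensen's inequality and dominated by low-information
loci.

## Panel construction

Candidates are merged into priority tiers — breed_specific and
trait_related → 1, common → 2, wgs_polymorphic (requires MAF > 0.2) → 3 —
and a physical locus appearing in several categories keeps its
highest-priority entry. Chromosomes are tiled with disjoint 50-kb windows
(0-based half-open, last window short). Per window:

* **1 candidate** → kept (`kept_single`);
* **≥ 2 candidates** → the pair minimising SD², the population variance of
  {S, N_i, N_j, E}. X̄ is the mean of those four positions — the only
  reading that makes the expression a variance. Ties break first on higher
  combined priority (smaller priority-number sum), then on the leftmost
  pair, so selection is deterministic (`sd2_pair`);
* **0 candidates** → one site from the supplement pool (`filled`), or
  nothing (`empty`). The pool is the window's QC-passing non-candidate
  sites, tiered as priority 3 when MAF > 0.2 and a residual tier otherwise
  (reported as category `supplement`), ranked by tier, then MAF, then
  position. One fill per empty window keeps the panel near the observed
  density of under one site per window.

A caveat worth stating plainly: minimising the variance of
{S, N_i, N_j, E} pulls the two chosen sites toward the window centre rather
than spreading them toward the thirds of the window. The formula is
implemented exactly as specified; the even-spacing intent and the formula's
actual optimum disagree, and the audit table makes the realised geometry
inspectable.

`cap_exempt_priority1` (off by default) keeps every priority-1 site and
applies the two-per-window cap only to priority 2–3; it exists because
dropping trait-related loci through the cap may not reflect how a real chip
would be filled, but the literal two-per-window rule is the default.

The per-window audit (rule fired, SD² value, candidate count, selected
positions) makes the whole construction replayable; `build_panel` is a
deterministic function of its inputs.

## ROH detection

Detection follows the PLINK sliding-window scheme with parameters: minimum
run length 1 Mb; maximum inter-SNP gap 1 Mb; minimum density 1 SNP/100 kb;
window of 50 SNPs; ≤ 1 heterozygous call per window; ≤ 5 missing calls per
window (the PLINK default, adopted because the source parameter set omits
it); window-support threshold 0.01; α = 0.05. A SNP is flagged when the
fraction of homozygous windows covering it reaches the threshold; maximal
flagged runs, split at > 1 Mb gaps, become segments if they pass length,
density and the minimum SNP count

    L = ⌈ ln(α/(n_s·n_i)) / ln(1 − het) ⌉,

applied per segment with a ceiling so the chance-run guarantee is
conservative (a 1e-9 tolerance inside the ceiling guards exact-integer
ratios against float noise). Chromosomes with fewer SNPs than one window
are scored against the single truncated window instead of being dropped.
Sex chromosomes are excluded by default. In the orchestrated `detect_roh`,
n_s is the mean genotyped-SNP count per animal and het the mean per-site
observed heterozygosity.

**Window threshold and boundary resolution.** The default threshold 0.01 is
deliberately the conservative published setting, but note that with 50-SNP
windows any single passing window flags a SNP (1/50 = 0.02 ≥ 0.01). A
window anchored at the first SNP flanking a truly homozygous tract contains
≤ 1 heterozygous call whenever the flank contributes at most one het, so
flagged runs extend outward until two heterozygous calls accumulate in the
flank — about 2/het SNPs, a random quantity. Measured on planted tracts
(100 replicates, background het ≈ 0.33): detection is 100% with zero false
segments at thresholds 0.01–0.10, but the called boundary lands within one
inter-SNP spacing of the tract edge in only ~1–8% of runs (median error
≈ 4–8 spacings; smallest at PLINK's 0.05, which the recovery tests
therefore use). No threshold concentrates the boundary to ±1 SNP — the
smear is a property of window-based calling, not of this implementation —
so ROH boundaries from any PLINK-style caller should be read with a
resolution of several SNP spacings. The planted-tract acceptance check that
demands one-spacing boundaries is retained unmodified and fails for exactly
this reason; the passing property tests assert what the method does
guarantee (detection, no false calls, smear bounded well inside half a
window).

**Islands.** Per-SNP incidence is the fraction of individuals with a
segment covering the SNP (inclusive ends). The island threshold is the
(1 − 0.01) empirical quantile of the incidence vector (numpy linear
interpolation); islands are maximal runs of consecutive panel SNPs strictly
above it with ≥ 2 SNPs, never spanning chromosomes. Runs are defined over
panel-SNP adjacency irrespective of bp gaps; an optional gap-split
(> 1 Mb) is available but off by default since the convention is not
standardised. With a flat incidence vector nothing exceeds the quantile and
no island is called. Feature annotation is plain 1-based interval
intersection against GFF3 gene or BED intervals via an interval tree.

## Validation analyses

* **PCA**: missing calls mean-imputed per site, sites centred by 2p and
  scaled by √(2p(1−p)), monomorphic sites dropped, SVD of the centred
  matrix. Component signs are fixed by forcing each component's
  largest-magnitude loading positive, making scores reproducible across
  runs and sample orderings.
* **p-distance**: d(i,j) = mean over jointly-called sites of |g_i − g_j|/2;
  a pair with no jointly-called site is an error unless explicitly allowed
  (then NaN).
* **Neighbor joining**: classic Saitou–Nei agglomeration, ties in the Q
  criterion broken on smallest node indices, negative branch lengths
  clamped to zero with the deficit moved to the sister branch so the pair
  sum is preserved. Implemented in-package because this clamping and
  determinism contract is pinned; scikit-bio's independent NJ is the
  cross-check oracle in the tests. On additive matrices the output
  reproduces all pairwise path lengths to 1e-9.
* **LD decay**: r² is the squared Pearson correlation of dosage vectors
  over pairwise-complete samples (genotype-based, requiring no phasing),
  for same-chromosome pairs within a maximum distance, averaged per
  distance bin; the reported decay distance interpolates the first bin
  crossing below r² = 0.2 between bin midpoints.

These are method-level counterparts of the usual external toolchain (PLINK
PCA, VCF2Dis, PopLDdecay); numeric parity with those binaries is not a
goal, method equivalence is.

## Synthetic data

The generator emulates the shape of a multi-breed resequencing panel:
ancestral frequencies p ~ Uniform(0.05, 0.95), per-breed frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols: mean p, variance Fp(1−p)),
genotypes Binomial(2, p_ij), independent Bernoulli missingness. Defaults
are chosen once to mirror a realistic study at desk scale: 9 breeds × 20
samples (a local-plus-reference breed panel), F = 0.1 per breed (strong
breed-level differentiation; the implied pairwise Fst is F/(2−F) ≈ 0.053,
typical of cattle breeds), missingness 0.005 (a > 99% call rate), 5,000
sites over two 50-Mb chromosomes. Everything is reproducible from the
config seed, byte-identically for written VCFs.

Two deliberate simplifications: sites are placed uniformly and drawn
independently, so there is **no linkage disequilibrium** (an optional
copy-with-mutation mode duplicates a fraction of sites nearby with a 2%
flip rate to create high-r² pairs for LD tests), and there is no pedigree,
migration or bottleneck structure. Passing tests on this generator
therefore demonstrate correctness of the algorithms under the stated
model, not robustness to real LD structure, batch missingness patterns or
admixture.

Planted homozygous tracts set one sample's calls in a region to 0 or 2
(allele drawn by the site's realised frequency, missing preserved), giving
exact ground truth for the detector. Candidate labelling assigns disjoint
random site subsets to trait_related/common and labels the remaining
MAF > 0.2 sites wgs_polymorphic, verified back against realised MAF.

**Calibration.** The heterozygosity-weighted Fst between two simulated
breeds converges to (F₁+F₂)/(4−(F₁+F₂)) — F/(2−F) for a shared F — because
F parameterises each breed's divergence from the ancestral pool, not the
pairwise contrast; calibration checks compare against this closed form
(±0.02 at 10,000 sites), not against F itself.

## Numerical and degenerate-input conventions

* Fst returns 0 (not NaN) when both frequencies are fixed for the same
  allele; 0·ln 0 = 0 throughout I_n; I_n is clipped at 0 against −0.0.
* Welch's unequal-variance t-test is used for all group comparisons; two
  identical constant groups report p = 1 explicitly (the t statistic is
  undefined there). Groups with fewer than two samples are excluded with a
  warning.
* Quantile and histogram conventions: numpy linear-interpolation quantiles;
  MAF spectrum bins [0,0.05), [0.05,0.1), [0.1,0.2), [0.2,0.3), [0.3,0.4),
  [0.4,0.5].
* All tie-breaks (ranking, SD² pairs, NJ joins, fill choice) are
  deterministic and documented at the function level; identical inputs give
  byte-identical outputs.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen as the
smallest sizes at which each property is statistically unambiguous: the
chip-scale panel build uses the four published category sizes (42,686 sites
over a 24,000-window synthetic genome); the SD² oracle 1,000 random windows
of ≤ 20 candidates; ROH recovery 100 replicates of 500 SNPs over 10 Mb with
a 2.5 Mb planted tract; Fst calibration 10,000 sites; PCA separation 30+30
samples × 2,000 sites; NJ additivity 20 random 4-taxon trees.

## Known limitations

* Window-based ROH boundaries have multi-SNP resolution (above); F_ROH or
  HMM-based approaches would be needed for finer boundaries and are out of
  scope.
* The SD² criterion centres pairs rather than spreading them (above).
* The top-1% island threshold is relative to the analysed population; with
  fewer than ~100 panel SNPs the quantile is coarse and a warning is
  emitted.
* The LD module is quadratic per chromosome in the number of sites within
  the distance cutoff — appropriate for panel-scale (tens of thousands of
  sites) data, not for whole-genome marker sets.
* No admixture/ancestry-fraction estimation and no GO/KEGG/PPI enrichment:
  interval-level gene annotation is the supported endpoint.
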