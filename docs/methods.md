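# Methods

`sweepscan` detects and dates selective sweeps from SNP genotype panels of
divergently selected populations, and ships a forward Wright–Fisher
simulator of the underlying breeding design so that every stage of the
analysis can be exercised against known truth.

## Windowed heterozygosity scan

Within-population variability is measured per biallelic marker as the
expected heterozygosity

    Hz = 1 − (m² + (1−m)²) = 2m(1−m),

where `m` is the major allele frequency (maximum 0.5 at m = 0.5, zero at
fixation).  Per-marker values are averaged in a sliding window of `W`
consecutive markers (default `W = 100`, step 1), per chromosome; windows
never span a chromosome boundary, and markers with no successful calls are
dropped from a window's mean with the divisor reduced accordingly.
Averaging suppresses single-marker noise: an isolated fixed marker can
reflect uneven founder haplotype frequencies rather than selection, whereas
a sweep spans a region with a consistent signal.

Two populations' profiles are compared by their per-window difference, and
selection during an interval is read from the *change* of that difference
between two sampling generations.  The significance threshold is empirical:
most of the genome is assumed to drift, so a normal distribution with the
mean and SD of the observed genome-wide change distribution serves as the
null.  The two-sided family-wise level `alpha` (default 0.05) is Bonferroni
corrected for `ceil(n_markers / W)` non-overlapping windows — the number of
independent windows needed to cover the genome — giving a per-tail quantile
`(alpha/2) / ceil(n_markers/W)`.  For a 55,983-marker genome and W = 100
this is 0.025/560 ≈ 4.46×10⁻⁵, i.e. cuts at ±3.92 SD.  Because true sweeps
inflate the fitted SD, the null is conservative where selection exists.
Windows strictly beyond a cut are flagged (ties at the cut are not flagged,
for determinism); adjacent flagged windows of equal sign merge into regions,
as do flagged runs whose sliding-window marker spans overlap.

## Dating sweeps on the sampling grid

The design sampled eight subgroups: high- and low-selected lines at
generations 40, 50 and 53, plus relaxed lines split from each at generation
45 and sampled nine generations later.  For a sweep region, each subgroup is
classified `fixed` / `reduced` / `polymorphic` and the pattern is matched
against a rule table (onset before 40; onset in (40,45] with fixation before
or after the split; fixation only by 53; or not fixed).

The state statistic is the region's **minimum** windowed Hz — the depth of
the profile dip — not the region mean.  Merged significant regions include
partially swept flank windows; their residual heterozygosity would dilute a
mean and turn fixation calls into artifacts of region extent, while the
fixation pattern itself is carried by the deepest part of the dip (a region
is "fixed" in a subgroup exactly when its profile touches zero there).
`fixed` means dip Hz below `fixation_threshold` (default 0.01 rather than
exactly zero, since n = 20 samples can miss rare alleles); `reduced` means
below `reduced_fraction` (default 0.5) times that subgroup's genome-wide
median windowed Hz; anything else is `polymorphic`.

## Allele-frequency divergence

Per marker, a 2×2 table of allele counts from two populations is tested with
the two-sided Fisher exact test (sum of hypergeometric probabilities of all
tables at most as probable; scipy's implementation, matching R's
`fisher.test`).  The threshold is `alpha` Bonferroni-corrected for the
number of markers actually tested — 0.05/55,983 ≈ 8.9×10⁻⁷ at the real
panel's size; this is conservative because LD reduces the effective number
of tests.  Markers monomorphic in both populations give p = 1 and stay in
the denominator.  To compare the *global* divergence of two pairs, each
scan's −log₁₀ p-values are sorted descending and paired rank-for-rank, and
the slope of an OLS fit (with intercept by default; both the pair order and
the intercept are options) measures the excess divergence of one pair over
the other — slope > 1 means the y-pair's p-values are globally smaller.

## Heterozygosity loss and haplotype blocks

Genome-wide mean Hz change between two samples (later minus earlier,
negative = loss) is computed over markers (default) or windows, with markers
uncalled in either sample excluded pairwise.  Because linked markers are
correlated, the uncertainty attached is the SE of the mean over
non-overlapping `W`-marker windows, not over markers.

Haplotype blocks follow the Gabriel confidence-interval definition.
Two-locus haplotype frequencies are estimated from unphased genotypes by EM
over the double-heterozygote phase (tolerance 10⁻⁸, max 1,000 iterations);
|D′| gets a CI from the likelihood of the genotype counts profiled over a
101-point |D′| grid with allele frequencies held at their sample values
(5th/95th percentiles of the normalised profile).  A pair is strong-LD when
ci_low ≥ 0.70 and ci_high ≥ 0.98, shows historical recombination when
ci_high < 0.90, and is otherwise uninformative; pairs with minor allele
frequency < 0.05, or fewer than two double-called individuals, are
uninformative.  Blocks are marker intervals whose outermost pair is
strong-LD with ≥ 95% of informative internal pairs strong-LD; pairs farther
apart than 10 Mb are never evaluated; overlaps resolve longest-first.
Reported "large" blocks are those strictly over 5 Mb.

## The synthetic-data generator

The simulator emulates a bidirectional truncation-selection experiment on a
polygenic trait.  Key elements, with defaults chosen to mirror the study
system rather than to be convenient:

* **Founder pool.** Per-marker base frequencies are drawn U(0.2, 0.8) —
  SNP arrays are ascertained toward common variants — and per-founder-line
  frequencies around them from a Beta with concentration 8 (seven partially
  differentiated founder sub-lines), giving structured standing variation.
  Founder haplotypes are drawn marker-independently within a sub-line, so
  founder LD is weaker than in real data; LD in later generations arises
  from drift and selection.
* **Trait and selection.** Strictly additive trait over `n_causal` loci
  (effects N(0, 1)) plus N(0, env_sd²) environmental noise; scenario
  defaults (40 loci, env_sd 8) give h² ≈ 0.2, typical of juvenile body
  weight.  Each generation the top (high line) or bottom (low line)
  `truncation` fraction by phenotype become parents.  Two mating schemes:
  `random_union` (default; each offspring draws two distinct parents
  uniformly, no selfing) and `sire_dam` (the `n_sires` most extreme selected
  individuals contribute one gamete per offspring, the remaining selected
  the other — the hierarchical structure of poultry breeding, with
  Ne ≈ 4SD/(S+D)).  The selection scenarios use `sire_dam` because random
  union ties a rare beneficial allele's spread rate (≤ N/K per generation)
  to the parent count that also sets drift, which cannot reproduce a fast
  sweep in a line with realistic heterozygosity-loss rates.  Relaxed lines
  draw parents at random, optionally downweighted by
  `exp(−cost · direction · trait)` to model purging of previously favoured
  alleles.
* **Recombination.** Switch events between adjacent markers are independent
  Bernoulli with probability from the inverse Haldane map of the cM spacing
  — exactly a Poisson crossover process without interference.
* **Scale.** Selection scenarios use N = 1000 hatched per line, truncation
  0.15 (150 selected: 30 sires + 120 dams, Ne ≈ 96 — matching the
  sub-percent per-generation heterozygosity-loss rate the real lines show),
  5 chromosomes × 200 cM, and relaxed flocks of 25–50 (the relaxed groups
  were small).  A small census with proportionally stronger truncation does
  not reproduce the study system: the genome is mostly fixed by generation
  40 and the drift null is so wide that no sweep can cross it.  The
  drift-only scenario uses N = 50 flocks and 10⁴ markers.
* **Novel mutation.** The injection replaces one allele copy in one random
  selected parent at the configured generation; the injected site is forced
  monomorphic-reference in founders and excluded from the causal set, so the
  allele is genuinely novel.  With an effect that dominates the trait
  distribution, carriers are always selected and the allele fixes within
  5–10 generations.

Scenario analyses use `window_size = 50` (10 cM at the synthetic 0.1–0.2
cM/marker spacing), matching the geometric role of the real analysis's
100-marker ≈ 7 cM windows; `W = 100` stays the default for chip-density
data.

What passing synthetic tests do **not** show: robustness to genotyping
error, array ascertainment against one discovery panel, founder LD
structure, overlapping generations, or family-structured matings.  The
synthetic acceptance rates characterise the method under this generator's
assumptions, at desk scale.

## Numerical choices

* Window means use cumulative sums; NaN markers renormalise the divisor.
* The empirical null uses the sample SD (ddof = 1); a zero-SD change vector
  is a hard error.
* Fisher p-values are memoised on row/column-swap canonicalised tables
  (p is invariant to both swaps), which collapses genome scans onto a few
  thousand distinct tables.
* EM haplotype frequencies start at 0.25 each; only the double-heterozygote
  count is latent, so convergence is fast and monotone.
* All simulator randomness flows from one `numpy` Generator seeded by
  `SimConfig.seed`; identical configs are bit-reproducible.

## Known limitations

* The empirical null is anticonservative in two ways that the acceptance
  script quantifies under pure drift at desk scale.  Scanning *sliding*
  windows while Bonferroni-correcting only for the non-overlapping window
  count — the published construction — inflates the family-wise flag rate
  several-fold; this buys localization of region boundaries at the cost of
  formal FWER control.  And even on the non-overlapping grid the drift
  change distribution is a variance mixture across windows (window
  heterozygosity varies), hence leptokurtic; at small Ne and only ~100
  independent windows the realized family-wise rate exceeds the nominal
  0.05 severalfold.  Both effects shrink with more windows and larger Ne.
* Timeline dating of a *novel* mutation is sharpest when the mutation
  predates the relaxed-line split by at least four generations: from a
  single copy, the allele frequency at a split three generations later is
  capped near 0.5 in any discrete-generation mating scheme, so the relaxed
  line rarely shows the halved heterozygosity that pins fixation into the
  split-to-next-sample interval; such sweeps are instead dated by their
  completion between the later samples.
* Timeline rules are written for the eight-subgroup design; other designs
  need their own rule table.
* The block caller is the published confidence-interval definition, not a
  byte-level reimplementation of any particular GUI tool; block boundaries
  on real data may differ in detail.
* `two_locus_em` assumes Hardy–Weinberg within population when splitting
  double heterozygotes, as the standard method does; strong inbreeding
  violates this.
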