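# Methods

This note documents the models implemented in `chromreprog`, the synthetic
data they are validated against, and the numerical and design choices made
where the underlying procedures are commonly described only loosely.

## Pathway activity

Expression is library-normalized (median-of-ratios by default) before any
ratio is formed; otherwise the relative-expression ratio is confounded by
sequencing depth. For gene *g* and condition *c* with per-condition means
m_gc, the relative expression is r_gc = m_gc / mean_c(m_gc), so each gene's
ratios average to 1 across conditions by construction and genes with zero
expression everywhere are excluded (and listed). Pathway activity is the
weighted mean of r_gc over the pathway's measured genes. The weighting
follows the convention of pathway-activity scoring from relative expression:
w_g = 1 / (number of pathways containing g), damping promiscuous housekeeping
genes; a uniform-weight option exists. Outlier trimming and permutation
significance — present in some formulations — are deliberately not applied;
the divergence filter is the plain |Δactivity| > 0.1 rule with a strict
inequality. Pathways whose gene sets miss the expression table entirely are
dropped and reported rather than silently scored as empty means.

## Differential statistics

The pipeline needs only (log₂FC, padj) semantics downstream, so the
differential engine is deliberately simple and fully specified:

- log₂FC = log₂((m₂+1)/(m₁+1)) on normalized means; the pseudocount of 1
  avoids −∞ and is standard.
- `welch_log`: Welch's unequal-variance t-test on log₂(x+1), vectorized over
  features. Genes whose values are identical in both groups produce an
  undefined statistic and are assigned p = 1 (no evidence of change).
- `exact_permutation`: the absolute difference of group means of log₂(x+1)
  against its full label-permutation null (all C(n₁+n₂, n₁) splits; refused
  above 200 splits). At 3 vs 3 this enumerates all 20 splits, so the smallest
  attainable p is 1/20.
- Benjamini–Hochberg step-up, implemented directly (p·m/rank with a reverse
  cumulative minimum, capped at 1); adjusted values never fall below raw ones.
- Significance: padj ≤ 0.05 and |log₂FC| ≥ 0.5, both boundaries inclusive.

Shrinkage-based count models (dispersion sharing across genes) are out of
scope; consequently this engine has less power at small n than those models,
which matters for how the synthetic data are calibrated (below). Peak-level
differential analysis reuses the same machinery on per-peak summed track
coverage scaled by spike-in factors; spike-in factors are
geomean(spike counts)/count_i, which is invariant to rescaling all counts.

## Chromatin landscape

All intervals are 0-based half-open; the promoter window is TSS ± 2.5 kb
everywhere (the single promoter width used consistently across modules), and
the TSS of a minus-strand gene is its interval's last base. Peak dynamics
between conditions are presence/absence by ≥ 1 bp interval overlap (the
overlap threshold is a parameter); the three categories partition the inputs
and swapping conditions swaps lost↔gained exactly. Region annotation assigns
one category per peak by its midpoint with fixed precedence
promoter > exon > intron > distal ("intron" = in a gene body without hitting
an exon); the precedence is a declared convention, chosen for deterministic
single-category counts. Promoter states come from the 2×2 overlap truth
table of the active (H3K4me3) and repressive (H3K27me3) marks; "lost K4/K27
at a bivalent promoter" means the promoter window's overlap status changed
between conditions, not that a genome-wide peak identity disappeared. If
both marks vanish simultaneously (possible, though not generated by the
simulator), the transition is attributed to the loss consistent with the
expression direction. Active enhancers are the enhancer-mark peaks with zero
promoter-window overlap; their dynamics reuse the peak-overlap rule.

## ABC and ABC-P² scoring

Candidate enhancers for a gene are those whose midpoint lies in
[TSS − 1 Mb, TSS + 1 Mb). Choices made where the quantities are commonly
underspecified, all exposed as parameters:

- A is the **sum** of per-bp enhancer-mark signal over the enhancer interval
  (so bigger enhancers score higher); P is the **mean** per-bp promoter-mark
  signal over the promoter window (so P is width-independent).
- "Calibrated" signal means multiplied by the sample's normalization factor
  (spike-in derived when available).
- C is the raw contact count between the TSS bin and the enhancer-midpoint
  bin at 5 kb resolution, divided by (chromosome cis total / 10⁶) —
  contacts-per-million, the simplest normalization that makes C invariant to
  sequencing depth. No matrix balancing is applied by default.
- ABC is the plain sum Σ A_e·C_e with no denominator over candidate
  elements, and ABC-P² = ABC·P² exactly.

ABC is additive over disjoint enhancer subsets and invariant to enhancer
ordering and to global contact-map scaling.

## 3D genome analytics

**Expected/observed.** expected[d] is the mean count at diagonal offset d;
O/E divides by it and masks offsets with zero expectation. No balancing is
applied by default — O/E already removes the dominant distance effect at the
scales this package targets.

**Compartment PC1** is computed per chromosome (the standard practice for
eigenvector compartment analysis): bins with zero coverage are masked, O/E is
smoothed with a centered running-mean window of 100 kb (at 25 kb bins the
window is widened to the next odd count, 5 bins — an even window shifts the
signal half a bin and systematically mislabels compartment-block edges), the
bin-by-bin Pearson correlation matrix is eigendecomposed, and the leading
eigenvector is sign-anchored so that its correlation with the GC track is
non-negative, then scaled to unit variance so thresholds are comparable
across chromosomes. "No compartment signal" is reported when the correlation
matrix is essentially constant or the leading eigenvalue explains under 5% of
total |eigenvalue| mass; pure-noise maps sit near 4% while genuine
checkerboards score far higher, and exact constancy never occurs in sampled
data, which is why an explained-variance floor is used.

**Compartment changes** use the published 7-way rule set with t = 0.2 on PC1
(A→stronger A, B→A, B→weaker B, B→stronger B, A→B, A→weaker A, stable). The
category definitions overlap (e.g. PC1 0.3 → −0.3 satisfies both A→B and
A→weaker A); the first matching rule in the order listed wins, which is the
documented precedence.

**Saddle plots** trim the top and bottom 2.5% of the genome-wide eigenvector,
rank-split the surviving bins into 50 equal groups (ascending PC1), and
average cis O/E within group pairs; corner summaries are means over the 5×5
extreme blocks, with strength AA·BB/AB². Rank-splitting makes the saddle
invariant to any consistent permutation of bins.

**P(s)** sums counts per diagonal offset across chromosomes, normalizes per
contributing bin-pair and per total cis count (hence depth invariance), and
aggregates into log-spaced distance bins. The log₂ ratio of two curves is
interpolated linearly in log₁₀(s) to locate sign-change crossing points, as
one reads intersections off a log-x plot; ratios within 10⁻⁹ of zero are
treated as exactly zero so float round-off cannot fabricate crossings.

**Interaction fold changes** compare class sums (per-chromosome cis, per-pair
trans) each divided by its map's total contacts; classes empty in either map
are masked. Top trans region pairs aggregate bin pairs to 2 Mb, rank by
signed log₂FC (pseudocounted with half a read in map-total units), take the
stated fraction with coordinate-order tie-breaking, and merge contiguous
selections into rectangles.

**Insulation** at bin i is log₂ of the mean of the w×w diamond (rows
[i−w, i), columns (i, i+w]) over the chromosome's mean diamond; w = 10 bins
by default. Boundaries are local minima below −0.1, collected deepest-first
with a 3-bin exclusion zone; domains are the inter-boundary intervals
(including chromosome ends), standing in for TAD calls; boundary sets of two
conditions are merged with a 1-bin tolerance for paired score comparison.
Loop calling is out of scope.

## Synthetic data: what it emulates and what it does not

Every generator stream is derived from the master seed via independent
spawned substreams, so adding a modality never perturbs another, and all
planted quantities are emitted in a truth sidecar for exact scoring.

- **Expression**: negative-binomial counts, 2 conditions × 3 replicates,
  planted DE genes (half up, half down) at log₂FC 2. Defaults emulate deeply
  sequenced replicate cultures of a clonal cell line: median per-gene count
  500 (a 20–40 M read bulk library) and dispersion 0.01, the textbook figure
  for cell-line replicates. This low-variance regime is what makes the
  per-gene Welch test adequate at n = 3; with tissue-level dispersion
  (≈ 0.1) no per-gene test without information sharing has useful power
  there, which is a property of the statistics, not a bug.
- **Marks**: plateau peaks (height = snr × noise_sd) at planted promoter
  and enhancer sites on a background of truncated Gaussian noise; peaks are
  then *re-called* from the noisy track by thresholding (background + 3 sd,
  minimum run of 4 bins at 500 bp), so finite snr genuinely loses and
  invents peaks rather than degrading cosmetically. noise_sd = 0 gives an
  exact noise-free dataset.
- **Contacts**: cis expectation (|i−j| in bins)^α with the diagonal pinned
  at the s = 1 level, times (1 + δ) for same-compartment bin pairs, Poisson
  sampled on the upper triangle and mirrored; trans is uniform plus planted
  enriched blocks. Compartment flips between conditions relabel whole blocks
  rather than redrawing the genome, isolating the classifier's signal. A
  warning is recorded when the near-diagonal expectation falls below 10
  counts.

Not emulated: read-level artifacts (mappability, GC amplification bias,
duplicates), replicate-level contact maps, trans-compartment structure,
peak-width variation, and correlated noise between marks. Passing tests on
this generator therefore demonstrate algorithmic correctness and planted-
signal recovery, not robustness to the full noise structure of real
sequencing data.

## Problem sizes and defaults

The demo/acceptance dataset uses 2 chromosomes × 10 Mb at 25 kb bins
(800 bins), 1200 genes, 200 DE, 10-bin compartment blocks with 4 flipped
blocks per chromosome, δ = 1, decay exponent −1, 5×10⁶ cis-weighted reads,
and a 5 kb map (1.5×10⁶ reads, first chromosome) for ABC scoring — sizes
chosen so a complete run takes well under a minute on a laptop while every
statistic (eigenvectors, saddles, insulation minima) is comfortably
populated. All thresholds (padj 0.05, |log₂FC| 0.5, pathway diff 0.1,
classifier t 0.2, saddle 50 bins / 2.5% trim, promoter ± 2.5 kb, ABC ± 1 Mb
at 5 kb) are carried in a single config object and echoed into the run
report.

## Known limitations

- The differential engine is a transparent stand-in; effect-size estimates
  are not shrunk, and power at n = 2–3 with high dispersion is poor.
- PC1 is per chromosome; no genome-wide eigenvector option is offered.
- O/E is not balanced; heavily uneven coverage would bias compartment and
  saddle estimates.
- `top_trans_regions` ranks by signed log₂FC of pseudocounted normalized
  counts; it is a ranking, not a significance test.
- GC "correction" of compartments is orientation only; per-bin GC covariate
  regression of O/E is not applied.
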