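# Methods

## Per-sample super-enhancer calling

The caller follows the ROSE lineage of SE identification from called
enhancer peaks and a signal track; it does not call peaks or process
reads.

**TSS exclusion.** Peaks fully contained in the half-open zone
`[tss − w, tss + w)` of any annotated gene are removed before stitching
(default `w = 2500` bp). This suppresses promoter-proximal signal that
would otherwise be stitched into enhancer clusters. Partial overlaps are
kept: a peak that merely touches a promoter zone still carries enhancer
evidence. With `w = 0` the zone is empty and nothing is excluded. The
split is returned as (kept, excluded) so callers can verify
`|kept| + |excluded| = |input|`.

**Stitching.** Sorted peaks merge transitively when the gap
`next.start − prev.end` is ≤ the stitching distance (default 12,500 bp —
the canonical "within ~12.5 kb" enhancer-cluster definition). Regions on
different chromosomes never merge. Stitching is idempotent and the gap
between consecutive output regions is by construction strictly greater
than the distance.

**Quantification.** Region signal is the integral of per-base density
`chip(b) − control(b)` (control term 0 when absent) over the union of
constituent peaks (default) or the whole stitched span
(`quantify_mode = "full_region"`, closer to implementations that
integrate the stitched interval; the default treats inter-constituent
gaps as background). Negative net signal is clamped to 0 before ranking
(`clamp_negative`, default on) because the cutoff geometry assumes
non-negative ordinates. The caller assumes densities are already
depth-normalized; no library-size correction is applied (the consensus
stage's intensity normalization absorbs scale differences).

**Tangent-line cutoff.** Sort the n region signals ascending into
`v(1..n)` and set `s = (max v − min v)/n`, the mean slope of the
rank-signal curve. For each candidate index x,
`f(x) = #{i : v(i) ≤ v(x) + s·(i − x)}` counts points on or below the
slope-`s` line through `(x, v(x))`. On a convex hockey-stick curve this
line lies below the curve only near the tangent point where the local
slope reaches `s`, so `f` is minimized there. The cutoff index `x*` is
the argmin (ties to the smallest x, for determinism); super-enhancers are
the regions with signal strictly greater than `v(x*)`. Consequences worth
noting: a constant vector gives `s = 0`, `f ≡ n`, `x* = 1` and an empty
SE set (strict inequality); the partition, `x*` and all ranks are
invariant under multiplying all signals by any c > 0. Fewer than two
regions is an error. The implementation evaluates f for all x by one
vectorized comparison matrix; the test suite pins it exactly (index and
value) to two independent brute-force searches.

**Ranking.** Ranks are 1-based with rank 1 the strongest region, ties
broken by (chromosome, start) so reruns are byte-identical. Regions, not
peaks, are the unit of ranking and of all downstream aggregation.

## Consensus and the TF screen

**Intensity normalization.** Within each sample, every region's signal is
divided by the sample's maximum region signal, giving intensities in
(0, 1]. This cancels multiplicative depth/efficiency differences between
samples exactly (a property the simulator's per-sample jitter is used to
test). A sample whose maximum signal is 0 is degenerate and rejected.

**Clustering.** Per-sample SEs merge by single-linkage with any ≥ 1 bp
overlap of their half-open intervals; abutting SEs do not merge. The
criterion is deliberately loose because stitched boundaries are coarse;
no reciprocal-overlap rule is imposed. A configurable
`min_overlap_frac` tightens linkage to a fraction of the shorter of the
incoming interval and the current cluster span — an approximation of
pairwise single linkage that is exact at the default 0. Presence counts
distinct samples; a sample contributing two SEs to one cluster counts
once for presence while both members enter the averages.

**Reliability filter.** Clusters present in fewer than `min_presence`
samples are dropped (default 6 — "more than 5" of a 9-sample cohort).
The filter is monotone: raising the threshold never increases the kept
count.

**Prioritization.** `avg_rank` is the arithmetic mean of member ranks and
`avg_intensity` of member intensities. The order is lexicographic
(avg_rank ascending, avg_intensity descending, then coordinates): rank
and intensity are combined without inventing a weighting formula, and
both values are emitted for plotting. Raw ranks (not percentiles) are
averaged because region counts are comparable across samples of one
cohort; cohorts with very different region counts should compare
intensities, which are already normalized.

**Gene assignment.** Every gene whose TSS lies within
`[start − window, end + window)` of the cluster span is assigned (default
window 50 kb), with signed distance from the nearest SE edge (0 when the
TSS is inside the span, negative upstream of the span start) and a
nearest-gene flag. Window-based assignment rather than nearest-gene-only
lets one SE nominate several TFs, which is what a screening application
wants; both the window and the rule are configurable and recorded in the
run manifest. The TF table reports, per TF, the best (lowest) avg_rank
among its clusters.

## Downstream gene-centric summaries

The proximal promoter defaults to TSS ± 2 kb, strand-aware: for a −
strand gene the window is mirrored so "upstream" extends toward larger
coordinates. A gene's "genomic region" is its annotated body with no
flank. Both windows are configurable because no single convention is
universal; the promoter window is echoed in the output header. Gene-body
and promoter flags are computed independently (a promoter peak upstream
of the body sets only the promoter flag). The DE filter keeps
|log2 fold change| > 1 and FDR < 0.05 — the fold-change > 2 rule on the
log2 scale (asserted as an equivalence in tests). Disease-list overlap
emits one record per (gene, list) membership with direction and log2FC,
per-list counts, and the union count of DE genes hitting any list.

## Synthetic cohort

The generator emulates a tissue cohort profiled for an active-enhancer
mark, at the scale of a desk-size test: N = 9 samples on a 2 × 10 Mb
genome, ~500 background enhancer peaks per sample (uniform positions,
widths 500–2000 bp, pairwise disjoint), background signal areas drawn
gamma(shape 1.5, scale 100) — right-skewed and heavy-tailed, which the
hockey-stick geometry requires — and a per-sample multiplicative
log-normal depth factor (sd 0.2) applied to every density, which the
consensus intensity normalization must cancel.

Planted SEs are clusters of ≥ 3 evenly spaced constituents whose gaps are
well under the stitching distance; their aggregate signal is `fold` times
the sample's median background peak signal, split evenly across
constituents. The default layout plants three loci: fold 30 in all 9
samples anchored at TF gene `SETF01` (a strongest-locus discovery
analogue that should take consensus priority 1), fold 20 in 7 samples at
TF `SETF02`, and fold 20 in 6 samples at a non-TF gene. Anchor genes get
their TSS 3 kb past the locus end — near enough for the 50-kb assignment
window, far enough that TSS exclusion cannot swallow planted
constituents. Background peaks are rejection-sampled to stay a stitching
distance away from planted loci, and background gene TSSs 60 kb away, so
the planted stitched regions contain exactly the planted constituents and
ground truth stays unambiguous. All randomness flows from one seed;
identical configs give byte-identical files.

What the simulator does **not** emulate: read-level noise, peak-calling
artefacts, copy-number or mappability biases, correlated enhancer
domains, or biologically realistic background sharing between samples
(background SEs recur across samples only by chance, which makes the
presence filter nearly perfectly precise here). Recovery results on this
cohort therefore demonstrate the pipeline's logic — stitching, cutoff,
presence and prioritization arithmetic — not expected sensitivity on real
tissue panels, where shared biology and technical covariance will lower
precision.

**Recovery scoring.** A planted SE is recovered when a kept consensus SE
overlaps ≥ 50% of its locus; eligibility requires the locus to be planted
in at least `min_presence` samples. Precision counts kept consensus SEs
overlapping any planted locus. With no eligible loci sensitivity is
undefined (reported as NA/None, not an error).

## Problem sizes and determinism

Default test and acceptance runs use the sizes above (9 samples × ~500
peaks, 20 seeds for recovery scoring, 200 random vectors up to n = 2000
for the cutoff cross-check); a full run of everything completes in well
under a minute on one core. End-to-end outputs are byte-identical for a
fixed config and seed, and consensus outputs are invariant to the order
samples are listed in — member lists are sorted by sample id before
averaging, so floating-point summation order is fixed.

## Known limitations

- The consensus `min_overlap_frac` mode links against the growing cluster
  span, not all pairs; at fractions near 1 it can split chains that true
  single linkage would keep together.
- Chromosomes sort lexicographically (chr1 < chr10 < chr2) everywhere;
  nothing downstream depends on karyotype order.
- The caller trusts input densities; no depth normalization or input-track
  scaling beyond subtraction is performed.
- Gene assignment is TSS-window-based; it does not use chromatin contact
  or expression data to pick SE targets, and the window default (50 kb) is
  a convention, not an inference.
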