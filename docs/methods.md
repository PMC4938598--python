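# Methods

## Data model and coordinates

All stages operate on a shared probe map: ordered probes on the 22 human
autosomes with 1-based base-pair positions (hg19-style printed
coordinates). Internal coordinates are 1-based inclusive so that segment
and BPR endpoints equal printed probe positions; BED export converts to
0-based half-open. Non-autosomal records are dropped on ingest with a
logged count rather than raised as errors, since the analysis is defined
on autosomes only. Chromosome labels are normalised by stripping a
leading `chr`.

A signal matrix carries an explicit scale flag — raw intensities or log2
ratios — and mixing scales is an error. When allele-level columns are
supplied, the per-SNP intensity is the sum of the two allele intensities.

## Reference and log2 ratios

The pooled reference is the per-probe arithmetic mean of the reference
samples' intensities, computed on the intensity scale (averaging before
the log transform). No trimming, median, GC or wave correction is
applied. A sample's copy-number track is `log2(sample/reference)` per
probe. Ratio-scale input (e.g. from the simulator) bypasses this stage;
the run manifest records which path produced the ratios.

## Circular binary segmentation

Segmentation is a from-scratch CBS implementation. For a stretch of
n markers, every circular arc with at least `min_width` markers on both
sides of the split is scored with the pooled-variance two-sample t form

    Z(arc) = (mean_arc − mean_comp) / (s · sqrt(1/k + 1/(n−k))),

and the stretch splits at the maximising arc if the permutation p-value
of `T = max |Z|` is ≤ `alpha`; the procedure recurses on the pieces.
Defaults: `alpha = 0.001`, `min_width = 4`, `undo_sd = 0.5` — the
segmentation settings of the analysis this package operationalises —
with `n_perm = 10,000` permutations (the tests use 1,000). The hybrid
tail approximations and variance-trimming options of the classical
reference implementation are deliberately not reproduced: the permutation
route is exact, seedable and testable against enumeration at desk scale.

Numerical and design choices:

* **Scan form.** `Z` is maximised through the equivalent between-split
  sum of squares `B = k(n−k)/n · (mean_arc − mean_comp)²`, because
  `Z² = (n−2)B/(SS_tot − B)` with `SS_tot` permutation-invariant. The
  scan maximises `|S[j] − S[i]|/sqrt(k(n−k))` over cumulative sums of the
  centred data, which vectorises per arc length; permutation batches
  reuse the same kernel.
* **Ties** on equal statistic values resolve to the smallest arc start
  index, then the smallest end index — deterministic across platforms.
* **Degeneracy.** A perfect split (zero within-split variance, distinct
  means) scores `T = inf` and participates in comparisons through the
  B-scale, where it is finite. A stretch whose centred sum of squares is
  at float-residue level (≤ 1e-20 · Σx²) is treated as constant: `T = 0`,
  `p = 1`.
* **Permutation p-values.** When `n! ≤ n_perm` the reference distribution
  is enumerated exhaustively and `p = #{T_perm ≥ T_obs}/n!` — exact and
  deterministic, which is what makes the full-enumeration test for small
  stretches meaningful. Otherwise `n_perm` uniform permutations are drawn
  from the seeded generator and `p = (1 + #{T ≥ T_obs})/(1 + n_perm)`;
  sampling stops early once `p` can no longer fall to `alpha`. A
  consequence of the add-one convention worth knowing: `alpha` is only
  reachable when `1/(1+n_perm) ≤ alpha` (e.g. `n_perm ≥ 999` for
  `alpha = 0.001`); the parameter object logs a warning otherwise.
* **Split boundaries.** An arc interior to the stretch yields two
  change-points, an arc touching an end one. Candidate arcs are
  constrained by arc and complement size only; a boundary that would
  strand an edge piece shorter than `min_width` is dropped at recursion
  level, so every completed segment holds at least `min_width` markers
  (unless a whole chromosome is shorter, which is kept whole and logged).
* **Noise sd** is estimated robustly as
  `median(|x_{i+1} − x_i|)/(0.6745·√2)` — true change-points contaminate
  only a handful of lag-1 differences — and floored at 1e-8 so noise-free
  fixtures keep well-defined sd-unit thresholds.
* **Outlier smoothing** precedes segmentation: a marker whose distance to
  its nearest neighbour value within ±`smooth_region` (10) markers
  exceeds `outlier_sd` (4) noise-sds is pulled to that neighbour value
  offset by `shrink_sd` (2) noise-sds toward the original. Adjacent equal
  spikes are each other's near neighbours and survive as genuine short
  levels.
* **sd-undo** removes, weakest first, change-points whose adjacent mean
  difference is below `undo_sd` noise-sds, recomputing merged means from
  the data, until all remaining gaps pass. It never increases the
  segment count and guarantees the output gap property.
* **Seeding.** Every stochastic call draws from a generator derived from
  one run seed; in cohort runs each sample's stream is spawned from
  (seed, sample index), so results are independent of processing order
  and reruns are byte-identical.

## Copy-number-altered regions

"Segments exhibiting a difference" is operationalised on the
entity-averaged profile: each probe first takes its sample's segment
mean, samples of an entity are averaged probe-wise, a chromosomal mean is
computed from those averaged values, and maximal runs of probes deviating
by ≥ +0.1 (gain) or ≤ −0.1 (loss) are reported. The cross-sample average
has no single segmentation of its own, so maximal probe runs are the only
well-defined reading; where an original segment passes the cut wholly the
two coincide. Both cuts are inclusive. `min_markers_per_region`
(default 1) optionally drops very short runs. Calling is invariant to
adding a constant per chromosome (mean-centering removes it).

## Breakpoint regions and recurrence classes

A BPR is the interval from the last probe of a segment to the first probe
of its successor when the two segment means differ by **strictly more
than** 0.6 log2 units (about one copy). BPRs are matched across samples
by exact (chromosome, start, end) identity: all samples share one array
layout, so recurrent breakpoints land on identical probe pairs, and
per-position counting presupposes exactness. Overlap-tolerant matching is
deliberately not the default. A sample carries a given interval at most
once.

Frequencies are `100·count/group_size`, kept unrounded internally;
display rounds half away from zero to two decimals. Classification uses
the unrounded values to avoid knife-edge flips at the 1.00%/0.50% cuts.
With `k` = number of entities at or above 1%:

| k | normal | class |
|---|--------|-------|
| 0 | —      | 4 (none) |
| 1 | —      | 1 (entity-specific; the normal frequency is irrelevant) |
| k/n ≥ 0.25 | < 0.5% | 2 (cancer-specific) |
| k/n ≥ 0.25 | ≥ 0.5% | 3 (common) |

The published wording gives "more than 25%" for class 2 but "≥ 25%" for
class 3; both are implemented as ≥ 0.25, which reproduces every row of
the published class column (including a row with exactly 2 of 8 entities
printed as class 2). The remaining cell — `k ≥ 2` below the fraction,
impossible with eight entities — falls back to class 4 with a warning.
The NOF flag is inclusive: ≥ 10% in at least one tumor entity or the
normal group. The entity-frequency, entity-fraction, normal and NOF cuts
are all configurable.

Hotspots are described only qualitatively in the source analysis
(adjacently clustered BPRs over overlapping altered segments); the
implementation here is the package's own: catalog intervals whose gaps
are ≤ `hotspot_gap` (100 kb) merge into clusters, and clusters with
≥ `hotspot_min_members` (2) distinct BPRs are reported with span, member
count and total carriers.

## Colocalization

Overlap is computed on 1-based inclusive spans via interval trees; one
shared base pair counts and no minimum overlap fraction is imposed. Every
interval receives exactly one location category: intragenic (entirely
inside ≥ 1 gene span), intergenic (no overlap), otherwise overlapping.
Gene spans are taken as given by the annotation (GFF3 gene features or
BED4+); isoform structure is ignored. Tumor-associated status comes
solely from a user-supplied id list — no cancer-gene catalog is bundled,
and the annotation's provenance string is recorded as supplied because
annotation versioning is otherwise unreproducible.

## Synthetic cohorts

The generator emulates what the analysis assumes: piecewise-constant
log2-ratio tracks around a zero baseline, planted jumps at fixed
inter-probe boundaries shared by all samples, and i.i.d. Gaussian probe
noise (default sd 0.15 — well below the 0.6 BPR cut; the source analysis
specifies no noise model). Each planted event is a shifted segment, so a
carrier exhibits two BPR boundaries. Per-group presence probabilities
express entity-private, shared and normal-tissue events, so all four
recurrence classes arise by construction. `study_cohort_spec` mirrors the
study's group sizes (377/189/340/291/1104/207/120/109 tumors + 432
normals), scalable for fast tests; the default probe layout is 2,000
probes per chromosome at 1 kb spacing on 4 chromosomes.

Not emulated: raw allele intensities, genotyping error, GC waviness,
aneuploidy-wide baseline shifts, and the empirical BPR size distribution
(only boundary placement). Passing recovery tests therefore demonstrates
correctness of the chain detection → aggregation → classification under
the model's assumptions, not robustness to real-array artifacts.

## Problem sizes used in the tests

The suite verifies the arc statistic against an exhaustive O(n²) oracle
for n ≤ 30, permutation p-values against full enumeration for n ≤ 7, and
boundary recovery on 500-marker tracks with three jumps ≥ 4 noise-sd
(n_perm 1,000). End-to-end recovery runs a 4-entity cohort of 50 samples
per group (250 total) on 2 × 250 probes with planted class-1/2/3 events;
with jumps ≥ 6 noise-sd, detection is essentially certain and realized
frequencies are recovered exactly. These sizes keep the whole suite under
a minute on one CPU while still exercising every code path at cohort
scale.

## Known limitations

* Exact-boundary BPR matching is blind to recurrent breakpoints that
  drift by a probe between samples (a config extension point).
* The permutation test, while exact, is slower than closed-form tail
  approximations at very long chromosomes; genome-scale runs should lower
  `n_perm` or parallelise over samples.
* Entity-level CNA calling on averaged profiles dilutes rare events by
  design; it characterises cohorts, not individual genomes.
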