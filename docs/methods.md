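# Methods

This note records the models, conventions and numerical choices behind
`lsgkit`, and what the synthetic-data tests do and do not demonstrate.

## Expression model and filters

Two array designs are supported. The tissue panel carries raw fluorescence
intensities (arbitrary units), one sample per tissue; the time series
carries log₂ expression ratios versus a reference pool with time points in
days relative to parturition, two diet groups, and replicate animals, plus
companion raw intensities and per-spot significance p-values.

Detection filtering keeps a gene when at least one sample simultaneously
(i) is flagged present, (ii) lies **strictly** above that sample's
negative-control median (a value equal to the median fails "above"), and
(iii) meets the intensity floor **inclusively** (exactly 250/150 passes).
For the time series the additional requirement — per-spot p < 0.05 in at
least one sample — is evaluated independently of the intensity rule: the
two "at least one sample-point" conditions need not hold at the same
sample. Filtering is idempotent by construction.

### Diet-within-time contrasts

The reference analysis used a mixed model with an unstated random-effect
structure; `lsgkit` deliberately fits fixed-effects OLS on (time, diet)
cell means per gene. Every cell mean is a free parameter, the residual
variance is pooled across cells, and for each time point the contrast
mean(diet_b) − mean(diet_a) (diets in sorted label order) is tested
two-sided against t with n_obs − n_cells degrees of freedom. An empty cell
makes that contrast non-estimable (NaN), never an exception. BH adjustment
runs jointly over all gene × time tests; this is a simplification of the
original mixed model and is stated as such. With zero replicate noise the
estimate equals the planted effect exactly.

`mean_cluster_fold` reports 2^(mean log₂ diet difference) over named time
points across a gene set; the caller fixes the diet order, so a 1.8-fold
under-expression on the restricted diet is reported as 1.8 when the
difference is taken ad-libitum minus restricted.

## Seed-based clustering

Pearson correlations are pairwise-complete with a minimum overlap of 3;
fewer complete pairs, or zero variance, make the correlation undefined
(NaN), and items whose correlation is undefined against everything are
excluded from trees with a warning.

Unstated mechanisms were fixed as follows and are configurable:

* **Seed grouping** uses single linkage (connected components of the
  r ≥ 0.90 graph); the representative is the medoid (highest mean r to its
  group), ties to the lexicographically smallest id.
* **Cluster adjustment** greedily removes the non-seed member with the
  lowest mean correlation to the rest until the average pairwise r reaches
  0.75. Seeds are never removed; if the threshold is unreachable the
  seeds-only cluster is returned with a warning flag. Removal order is
  deterministic (ties resolved lexicographically), so membership is
  invariant to input row order.
* **Overlapping clusters** are resolved by keeping the largest
  (`keep-largest`), the only supported mode.

Tissue preferentiality is inclusive: intensity(target) ≥ fold × max(other
tissues), fold = 2 by default. Hierarchical gene-condition trees are
average linkage on 1 − r; the branch correlation reported per merge is
1 − merge height.

## Promoter windows

The proximal promoter is [−1000, +100] around the TSS under the biological
convention without a position 0, hence 1100 nt. On the + strand this is
genomic [TSS−1000, TSS+99] (1-based inclusive); on the − strand,
[TSS−99, TSS+1000] reverse-complemented. BED6 input is 0-based half-open;
the TSS is chromStart+1 (+) or chromEnd (−). Windows running past a contig
end are clipped and flagged, never padded. Repeat masking travels as
lowercase (soft mask); hard-masking to N happens only in `masked_view`, so
one genome file serves both the masked and unmasked analyses. Cluster genes
stay in the enrichment background by default; they are subtracted only for
de novo discovery backgrounds.

## Match-style scanning

For a count matrix with per-position frequencies f(i,b), the information
vector is I(i) = Σ_b f(i,b)·ln(4·f(i,b)) with 0·ln 0 = 0, and a word w
scores

    MSS = (Current − Min) / (Max − Min),
    Current = Σ_i I(i)·f(i, w_i),  Min/Max = Σ_i I(i)·min_b/max_b f(i,b).

Natural log is used; any base cancels in the ratio. The core is the
5-consecutive-position window maximizing Σ I(i) (leftmost on ties; full
width, with a warning, for matrices narrower than 5), and core similarity
applies the same formula restricted to those positions. The core is a
property of the matrix: when scanning the reverse strand the forward core
window is mirrored onto the reverse-complemented matrix, so tie-breaking
cannot pick strand-inconsistent cores. Windows touching any non-ACGT base
are skipped entirely rather than partially scored. Hit coordinates are
1-based on the promoter's own forward (TSS-oriented) axis regardless of
match strand. Presence is per promoter — a single occurrence counts —
while full hit lists feed the composite analysis. No pseudocounts are used
in MSS (zeros are covered by the 0·ln 0 convention); pseudocounts appear
only in the discovery log-odds.

## Composite enrichment

Two or three sites co-occur when their matrices are distinct, their
intervals do not overlap, and every consecutive gap — nearest-edge
distance, start_next − end_prev − 1 (a `start`-to-`start` mode is also
available) — lies in [d_min, d_max]. The three minimum distances 20/50/100
are three separate analyses with d_max = 250; for triplets the gap rule
binds each consecutive pair in positional order. Ordered keys follow
positional order relative to the TSS (A\*B ≠ B\*A); unordered keys are
canonicalized by sorting (A,B,C). Each key counts at most once per
promoter, and contingency tables count promoters, not occurrences.

Enrichment is the one-sided Fisher exact (hypergeometric upper tail)
P(X ≥ k) with population n+N, successes k+K, draws n; two-sided is
available by flag. BH runs within each (arity, order-mode, distance-class)
family. The minimum-cell rule defaults to k + K ≥ 5 — the composite must
be observed at least five times overall — because reported composites can
occur in fewer than five cluster genes; `cluster` and `all` placements are
configurable. A key is significant when adjusted p ≤ 0.1, the minimum-cell
rule passed, and (when an unmasked analysis is supplied) the key is also
predicted in the unmasked cluster promoters — the guard that keeps
significant predictions out of repeats.

## De novo discovery

Discovery is a plain discriminative Gibbs sampler, replacing the original
perceptron-weighted sampler that was used as a black box: one candidate
site per foreground sequence with an explicit no-site option (ZOOPS), PWM
re-estimation with background-proportional pseudocounts (0.5 by default),
and window scores that are log-odds against a 0-order background model
estimated from the background promoters (N excluded). Restarts are
seed-driven: each restart picks one random foreground window and starts
every sequence at its best match to that word, which locates sparse planted
sites in 1100-nt promoters far more reliably than uniform random starts.
The best of `restarts` independent restarts per width is reported, making
results deterministic given the seed; widths 6–16 are run separately and
ranked.

The objective is the mean foreground best-site log-odds minus the mean
background best-site log-odds, in nats, with foreground sites scored
**leave-one-out** (each sequence's own site is removed from the counts
before scoring that sequence). LOO removes the per-sequence optimism, but a
max-over-windows discriminative search still retains roughly one nat of
selection optimism at typical sizes (dozens of sequences, 4^w candidate
patterns, best of many restarts), so the null objective is small-positive
rather than zero; planted signals score several nats higher, and the
downstream decision — matching against a known library at p < 0.01 — is
unaffected. Tests assert this honest behaviour.

PWM matching scores the best alignment over all offsets (minimum overlap 4
columns) and both orientations; the aligned-column Pearson correlations are
summed and divided by the **query width**, so unaligned query columns
contribute zero — without this penalty a chance 4-column overlap between
same-consensus-base columns outscores a genuine full-width match and the
shuffle null has no power. The empirical p-value is
(1 + #{column-shuffled targets scoring ≥ observed})/(n_shuffles + 1),
n_shuffles = 1000 by default, significance at p < 0.01. Column-shuffle
nulls are intrinsically weak for low-complexity motifs (many permutations
preserve a repetitive consensus); that is a property of the statistic and
is visible in the tests.

## Weighted network

Unsigned power adjacency a_ij = |cor(x_i, x_j)|^β with diagonal 1 excluded
from connectivity k_i = Σ_{j≠i} a_ij. β defaults to 8; grid selection
(1–20) takes the smallest β whose connectivity distribution is
approximately scale-free: R² ≥ 0.8 for the regression of log₁₀ p(k) on
log₁₀ k over 10 equal-occupancy bins. Because equal-occupancy bins have
constant counts by construction, p(k) is the empirical density
count/(total × bin width); when no β reaches the target the best-R² β is
returned with a warning. Topological overlap is

    TOM_ij = (Σ_u a_iu·a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),  TOM_ii = 1.

Modules are a **static** cut of the average-linkage tree on 1 − TOM at
height 0.95 (the dynamic tree cut of the reference implementation is not
reproducible from "default parameters"; a static cut is deterministic),
with clusters below 30 genes left unassigned. Gene significance is the
maximum over conditions of −log₁₀ raw p from the diet contrasts (mean is
available), so the 1.2 cutoff corresponds to p ≤ ~0.063; hub genes are the
top-5 connectivity genes within their module passing GS ≥ 1.2 and
k/k_max ≥ 0.95, where k_max is intramodular (global when there is one
module).

## Synthetic data: what it emulates, and what it does not

All generator output is a pure function of one integer seed (byte-identical
files on re-run). Conditions emulated:

* **Panel**: 18 tissues; log-normal intensities (median ≈ 512 units,
  spread 1.5 log₂ units) with a configurable floor so the 250-unit filter
  bites; present flags and a negative-control median (50 units) per sample.
  Planted clusters follow a latent-factor model
  x_g = √ρ·z + √(1−ρ)·ε on the log₂ scale, giving expected pairwise
  r = ρ exactly; tissue-preferential genes have the target tissue set to
  exactly fold × the maximum of the others, so the inclusive ≥ 2-fold rule
  passes by construction.
* **Time series**: 7 time points (−65…+49 days), 2 diets, 5 replicate
  animals. Non-cluster genes follow diet-independent temporal profiles;
  cluster genes share a latent factor drawn per (time, replicate) and
  identical across diets. Planted diet effects (log₂ fold on the second
  diet at named times) are therefore the **only** systematic diet signal,
  and shared latent draws cancel exactly from every diet-within-time
  estimate — contrasts are unbiased with replicate noise (σ = 0.3 log₂
  units by default) as the only error term. Per-spot p-values come from
  the replicate-noise model.
* **Promoters**: 1100 nt, GC 0.5, ~10% soft-masked in contiguous blocks;
  planted instances are exact consensus words of named PWMs inserted
  uppercase on the forward strand with gaps drawn uniformly from the
  spec'd range; collisions are retried a bounded number of times, then
  reported with the promoter id.
* **PWM library**: constant per-position depth (20) with consensus counts
  at 90–100% of depth. The sharpness emulates a minimized-false-positive
  matrix profile: measured chance hits are ≈0.1 per 1100-nt promoter over
  both strands at the default thresholds, so planted composites dominate
  and the order-reversed key of a planted pair behaves as a negative
  control. Softer matrices make chance upstream hits pair with planted
  downstream sites, and the reversed key becomes genuinely (if weakly)
  enriched — a real effect, but not the regime the enrichment analysis is
  meant for.
* **Genome/TSS**: a single contig with evenly slotted, jittered TSSs on
  both strands, clamped so every promoter window fits; words can be
  planted at known promoter offsets for coordinate round-trips.

Not emulated: hybridization physics, dye effects, array normalization,
cross-hybridizing probes, real repeat structure or promoter composition
biases, and correlated TFBS co-occurrence beyond what is planted. Passing
tests demonstrate that the algorithms recover known truth under the stated
noise models at the stated sizes — not that the biological conclusions of
any particular dataset are correct.

## Problem sizes used in tests and the acceptance script

Simulations are scaled to desk size while keeping the stated operating
conditions: cluster recovery uses 50 planted among 1000 noise genes over
20 seeds; composite enrichment 100 cluster vs 1000 background promoters
(plant rates 0.4/0.05) over 20 seeds; null calibration 50 random splits of
an 1100-promoter pool; discovery 50 foreground vs 100 background 1100-nt
promoters with 40 restarts × 30 sweeps per width (the package default is
100 restarts); networks 212 genes for module detection and 200 for hub
recovery over 10 seeds. The Fisher oracle check is exhaustive over all
tables with n+N ≤ 60.

## Known limitations

* The diet model is fixed-effects OLS, not the original mixed model; with
  strong animal-level covariance the standard errors differ even though
  the estimates agree.
* Static module cuts at height 0.95 can split very weakly attached genes
  off a module that a dynamic cut would keep.
* The column-shuffle matching null loses power on low-complexity motifs.
* One-sided enrichment only reports over-representation;
  under-representation needs the two-sided flag.
* The filter counts of any real dataset depend on curation choices
  (duplicate probe handling) that are outside this package's scope.
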