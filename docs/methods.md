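# Methods

## The three-component model

`threeca` targets paired longitudinal designs: the same subject measured
at an early and a late time point. For one feature (gene, transcript, or
binned genomic window), the subject pairs are points
$p_i = (x_i, y_i)$ in the (early, late) plane. All geometry is computed
on a log2 working scale — linear-scale inputs (RPKM-like) are
transformed as $\log_2(x + \text{pseudocount})$ with pseudocount 1 by
default; binned array log2 ratios are used as-is. A raw-scale analysis
is available by flag (`log_transform=False`).

With centroid $c = (\bar x, \bar y)$:

| component | definition | role |
|---|---|---|
| $t$ | $(\bar y - \bar x)/\sqrt 2$ | signed temporal change; perpendicular distance of $c$ from the identity line |
| $s$ | $\sqrt{\bar x^2 + \bar y^2}$ | absolute signal strength; distance of $c$ from the origin |
| $v$ | $\sqrt{\tfrac 1n \sum_i \lVert p_i - c\rVert^2}$ | variance radius; RMS dispersion of pair-points around $c$ |

$|t| \le s$ always (a perpendicular distance to a line through the
origin cannot exceed the distance to the origin), and $v = 0$ iff all
pair-points coincide. Swapping early and late negates $t$ exactly and
leaves $v$ and $s$ untouched; multiplying all intensities by $k > 0$
(raw scale) scales all three components by $k$ and therefore changes no
rank.

**Variance radius choice.** "A centroid with a radius approximating the
variance" admits several estimators; this package uses the RMS distance
of pair-points from the centroid (the 2-D standard-deviation radius).
It is smooth, easy to verify against a brute-force loop, and degenerates
sensibly (0 only for coincident points). The nearest-point distance was
rejected as an estimator because it is frequently 0. The combination
and radius computations sit behind small, single-purpose functions so
an alternative estimator can be substituted without touching the rest
of the chain.

## Rank combination and selection

Each component is ranked over all features: smallest $v$, largest $s$
and largest $|t|$ receive rank 1; ties get average ranks. The 3CA score
is the weighted mean of the three ranks with **equal weights by
default** — the deliberately agnostic choice: if two features tie on
temporal change and signal, the one with lower inter-individual variance
ranks better. Weights are exposed for knowledge-driven reweighting.
Rank aggregation makes the score scale-free, which is what allows
expression matrices and array ratio tracks to be treated identically.

Selection transforms scores to SD distances:
$z = (\text{score} - \min \text{score})/\text{SD}$ using the **sample**
SD ($n-1$ denominator), and keeps features with $z \le k$, default
$k = 1$. The minimum-score feature is always selected. Two diagnostics
are attached to every selection: the fraction selected, and whether the
best-2%-of-scores set lies entirely inside the selection (it does in
all reference runs; the "top 2 %" property is reported, not used as a
second rule). If all scores are identical (SD = 0) every feature is
selected and a warning is emitted.

**Contribution diagnostic.** For feature ranks $r_v, r_s, r_t$ over $N$
features, the inverse ranks $N + 1 - r_k$ are normalised to percentages.
A feature ranking identically on all three components gets exactly
(1/3, 1/3, 1/3) — this identity is exact in floating point and is
asserted in the tests. Group labels (`top`, `random`, `shuffled`)
support the standard comparison of the top-scored list against random
features and against a pairing-destroying shuffled control (all
2·n_pairs sample columns permuted jointly with a seeded RNG).

**Gene collapse.** Transcript-level tables collapse to gene symbols
either by minimal score (for score-based selection) or by largest $|t|$
(for GSEA ranking); ties break lexicographically by transcript id so
results are platform-independent.

## Pre-ranked GSEA

The signed $t$ of the selected features (or of all features, by flag)
is the ranking metric, sorted descending with lexicographic tie-breaks.
Enrichment is the weighted KS running sum: hits step up by
$|m_i|^p / N_R$ (default exponent $p = 1$, $N_R$ the in-set weight sum),
misses step down by $1/(N - N_\text{hits})$; ES is the signed maximum
deviation. On an exact tie between the positive and negative extreme
magnitudes the positive extreme is reported (a measure-zero case that
must nonetheless be fixed for determinism). If every in-set metric is 0,
hit increments fall back to $1/N_\text{hits}$.

The null is gene-label permutation: for each set size, `n_perm` random
same-size sets from the ranked universe (default 1000, seeded). NES
divides ES by the mean magnitude of same-sign permutation ES; the
nominal p is the same-sign tail frequency with a +1 correction, so it is
never exactly 0 and is floored at $1/(n_\text{perm}+1)$. FDR q follows
the NES-pooling procedure of the reference GSEA tool (Benjamini–Hochberg
across sets available by flag). Size filters default to 15–500 and are
flags; analyses with large curated sets need `max_size` raised, and the
planted-set checks in this package run with `min_size=2` because the
pre-filtered universe can carry only a handful of set members.

The Wilcoxon set-shift test (set scores vs background scores) uses the
exact rank-sum null for combined $n \le 25$ without ties, otherwise the
normal approximation with tie correction; identical value multisets
yield p = 1.

## Paired baseline statistics

The baseline comparison forms intra-individual changes (late − early
per subject, log scale) and an inter-individual background: all
unordered subject pairs whose ages at the chosen time point differ by at
most 2 years (default), oriented older-minus-younger with lexicographic
subject-id tie-breaks. The background uses **early** samples by default
— a cross-sectional contrast uncontaminated by the second sampling —
with `late` and `both` available. Per feature, a two-sample test
(Wilcoxon rank-sum by default; Welch's t by flag) compares the two
change sets; q-values are Benjamini–Hochberg; constant features are
flagged with p = 1.

A caveat the tests make explicit: when subjects carry gene-specific
baseline offsets, the inter-individual change set has strictly larger
variance than the intra set even for unchanged genes — the two groups
are then *not* exchangeable and the test rejects above nominal. That
asymmetry is precisely the inter-individual variation the paired design
removes. Type-I calibration is therefore verified under the
exchangeable null (no subject-level heterogeneity), where the empirical
rejection rate is compared against the exact attainable level of the
discrete rank-sum null (α\* = 0.0433 at 10 vs 10) computed by an
independent enumeration oracle.

## Tiling-array preprocessing

Coordinates are 0-based half-open throughout (BED convention);
TSV dialects with 1-based starts must be converted on read. Probe log2
ratios are averaged in 500 bp windows on a 250 bp step grid anchored at
position 0 of each chromosome; a probe belongs to a window when its
**midpoint** lies in `[start, end)` (midpoint membership avoids
double-counting long probes). Windows with fewer than 4 probes are
emitted but flagged `kept = False`. A step larger than the window is
rejected (the grid would leave gaps).

The quantile floor is computed **track-wide** (per sample contrast):
the 50 % quantile of all probe ratios in the original track. Member
ratios below the floor are reset to it before window means are
recomputed, and windows with none or one probe **strictly above** the
floor are discarded (ties at the floor count as not-above, which is what
makes fully-floored windows discardable). The original probe ratios are
retained inside the window track, so applying the floor twice is
exactly idempotent.

For shore analysis, every window is assigned the minimal gap between
its edges and any CpG island (merged, optionally length-filtered ≥
500 bp) on its chromosome — the window edge closer to the nearest
island decides, so a window 400 bp from its left island and 300 bp from
its right one sits at distance 300. Overlap gives distance 0. Distances
are cut into 250 bp shore bins starting at the island boundary; windows
beyond `max_dist` or on island-free chromosomes are excluded with
counts reported. Per-bin summaries (n, mean, median) are produced for
whichever component columns are present.

Quantile normalization across arrays is provided only as a plumbing
utility; inputs are assumed normalized upstream.

## Synthetic data

The generator emulates the reference study design. Per gene $g$ and
subject $i$, on the log2 scale:

```
b_gi  = baseline_g + u_gi          u_gi ~ N(0, inter_sd_g)
early = b_gi + e1                  e ~ N(0, noise_sd)
late  = b_gi + effect_g + e2
```

with `baseline_g ~ N(6, 2)` (lognormal intensities on the linear
scale), `inter_sd_g ~ |N(0, 0.5)|` (gene-specific inter-individual
variability), `noise_sd = 0.25` per time point, 10 subjects with
sampling gaps uniform on [12, 19] years and early ages uniform on
[35, 75 − gap]. The default planted structure is one 100-gene
coordinately down-regulated set at log2 effect −1 among 5,000 genes.
Values are emitted on the linear scale as $2^{\text{log2 value}}$, with
a truth table aligned to the matrix. All draws hang off a single seed.

Two structural properties of this model matter for interpreting test
results:

1. The subject effect $u_{gi}$ is shared by both time points and
   cancels exactly in the intra-subject change, so each gene's temporal
   estimate has the same precision (`noise_sd`/√n_pairs) regardless of
   its inter-individual variance. Consequently $v$ and $s$ carry no
   information about planted status under the default configuration,
   and the equal-weight rank mean dilutes the (perfect) temporal ranks
   of planted genes with two independent rank lotteries: the measured
   precision of the 1-SD selection at the pinned reference run is
   5/162 ≈ 3 %, with planted genes occupying exactly the top-100 $|t|$
   ranks. Real data, where variance and intensity predict the
   reliability of the temporal estimate, is the regime the method is
   designed for; this generator default is the harder, least-favourable
   case and the tests pin its measured behaviour rather than an
   aspirational recovery rate.
2. The `intensity_variance_coupling` flag creates that realistic
   regime: per-gene noise grows as baseline intensity drops
   (multiplier $(1 + e^{-(b_g - \mu)/2})/2$), so dim genes produce
   large spurious $|t|$ values that contaminate the edges of an
   unfiltered ranked list. Under the coupled high-variability
   configuration (`inter_sd_scale = 1.5`, `noise_sd = 0.6`, coupling
   on), pre-filtering by 3CA score strengthens planted-set enrichment
   (|ES| ≈ 1.00 vs ≈ 0.93 unfiltered, smaller nominal p) — the
   pre-filtering rationale the package exists to support. Coupling is
   off by default.

The probe-track simulator places probes uniformly at random, with early
ratios equal to a regional base level plus noise and late ratios
additionally carrying the planted regional effect; it exists to
exercise the binning → scoring path end to end.

What the synthetic data does **not** emulate: read-level sequencing
noise and library-size effects, probe sequence biases, correlated gene
modules beyond the planted sets, non-Gaussian heavy tails, and real
genome coordinates. Passing tests demonstrate correctness of the
machinery and the qualitative behaviour of the method under a known
generative model, not performance on any particular real data set.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run entirely on simulated
data at these sizes, chosen as the package's reference conditions:
5,000 genes × 10 pairs for recovery runs (1,000 GSEA permutations);
1,500 genes for the paired-test null calibration on a cohort whose age
draw yields the design's 10 inter-individual background pairs; 500
replicate random sets (universe 800, 99 permutations each) for GSEA
nominal-p calibration; exhaustive small instances (≤ 10 features ×
≤ 4 pairs, all subsets ≤ 4 of a 10-gene list) for brute-force oracle
equivalence at 1e-12 relative tolerance; and 1,000 random instances for
the symmetry suite.

## Numerical conventions and degenerate inputs

- Sample SD ($n-1$) everywhere a score SD is needed.
- Average ranks on ties; lexicographic feature/transcript/subject id
  tie-breaks for every argmin/argmax decision.
- `direction` is `flat` only at $t$ exactly 0; no epsilon band.
- TSV output at 6 significant digits (full precision by flag).
- Degenerate cases: single feature → contribution (1/3, 1/3, 1/3);
  SD = 0 → select all with warning; a gene set spanning the whole
  ranked universe → error (the miss decrement is undefined); empty
  set ∩ universe → skipped and logged.

## Known limitations

- The equal-weight rank combination is one defensible reading of the
  published description; the exact combination formula used upstream is
  not public, so the implementation isolates it for substitution.
- Gene-label permutation is the only GSEA null (no phenotype
  permutation); with few selected set members the permutation p is
  floor-limited.
- The paired test's rank-sum p-values are discrete at n = 10; users
  comparing rejection rates to nominal levels should expect the exact
  attainable level, not α itself.
- No annotation-service integration: over-representation is a generic
  one-sided Fisher test against user-supplied GMT collections.
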