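# Methods

## Statistics and the permutation null

Tests operate on a nonnegative feature × sample matrix and a binary group
labeling. Each feature row is rank-transformed across samples with
midranks for ties; zeros — the bulk of a sparse table — tie with each
other and enter symmetrically. Two statistics are offered, `meanrank`
(difference of group mean ranks) and `mannwhitney` (Mann-Whitney U
centered at its null mean n1·n2/2). Both are affine functions of the
group-1 rank sum, so they order features identically by |T|; `meanrank`
is the default used throughout the benchmarks.

The null distribution is built by permuting the label vector B times
(default 1000), sampling uniformly with replacement from the n!
arrangements, and recomputing all m statistics against each shuffle.
Sharing one shuffle across features preserves the cross-feature
dependence of the table, which the data-driven protocols rely on.
Randomness comes from `numpy.random.default_rng` seeded with a single
integer; `exhaustive_null` enumerates all C(n, n1) distinct arrangements
instead, for exact small-sample work.

Numerical backbone: both statistics are computed as a fixed positive
multiple of U2 = 2·S1 − n1(n+1), where S1 is the group-1 sum of doubled
midranks. Doubled midranks are integers, so U2 is an exact integer
carried in float64 (all intermediate values are far below 2^53), and the
inclusive `≥` tie comparisons in the FDR estimator are exact — no
epsilon tolerances anywhere. Permutation p-values use the add-one rule
p = (1 + #{b: |T*_jb| ≥ |T_j|})/(B+1), valid by construction with floor
1/(B+1).

Inputs are used as given: rank statistics are invariant to per-feature
monotone transformations, but no cross-sample depth normalization is
performed; if library sizes differ systematically between groups that
signal will be detected, so normalization (or the `--min-sample-reads`
filter) is the caller's responsibility.

## The three procedures

**BH.** Adjusted values min_{i≥j} (m/i)·p_(i), capped at 1; reject at
adjusted ≤ q. Implemented directly; tests cross-check against
statsmodels.

**Filtered BH.** For each feature compute the minimal achievable
p-value: put the largest observations of the row into one group
(whichever direction is more extreme) and evaluate the probability that
a random relabeling matches that extreme — exactly by enumeration when
C(n, n1) ≤ 20,000, otherwise from the same B permutations with the
add-one rule. Features whose minimal p exceeds q can never be rejected
and are removed; BH then runs on the survivors with m equal to the kept
count. Filtering is what rescues BH from rare taxa, but it is binary: a
taxon with minimal p just below q survives and pays full multiplicity.

**Discrete FDR (primary).** The plug-in cut-point procedure described in
the README. Candidate cut-points are the distinct observed |T_j| — the
estimate V̂/R̂ only changes there, so finer grids cannot change the
rejection set. Conventions for corner cases: FDR̂ is defined as 0 when
R̂ = 0 (nothing rejected, vacuously controlled); Ĉ is the *smallest*
qualifying candidate even though FDR̂ need not be monotone in C
(maximizing discoveries subject to the constraint); ties |T*| = C count
as exceedances.

**Adjusted values for the discrete procedure** are defined as the
smallest nominal level at which the feature is rejected: the running
minimum of FDR̂ over cut-points at or below |T_j|. Thresholding them at q
therefore reproduces the cut-point procedure identically, for every q,
and for m = 1 the adjusted value equals the raw permutation p-value.

## Relationships between the procedures, exactly and approximately

Two identities often quoted for these procedures hold in the idealized
(infinite-permutation) limit but only approximately for the finite-B
estimators, and the package's tests assert them at their true strength:

* *Collapse to BH under identical nulls.* When every feature has the
  same permutation null, the discrete procedure's advantage vanishes.
  With the finite-B estimators the adjusted values match BH's from below
  within (m−1)/(B+1): V̂ adds the observed indicator only for features
  above the cut, while the add-one p-value adds one for every feature.
  At B = 1000 the discrepancy is at most a few thousandths; the test
  suite asserts the two-sided bound and rejection equality at levels not
  straddled by this granularity.
* *Dominance over BH.* The discrete procedure rejects everything BH
  rejects at the q levels used in practice (asserted across inputs at
  q ≤ 0.4, and exactly under identical nulls). It is not a pointwise
  theorem for the common-cut-point form: a feature whose null piles mass
  above another feature's observed statistic can, at levels near 1, make
  the |T|-threshold and per-feature-p orderings disagree in either
  direction. These regimes are far above any level used for inference.

## The community simulator

`simulate_community` draws a two-group survey from a block model:

| parameter | default | meaning |
|---|---|---|
| `n_differential` / `n_null` / `n_rare` | 100 / 100 / 800 | taxon block sizes |
| `effect_size` | 2.5 | frequency multiplier on the shifted halves of the differential block |
| `reads_per_sample` | 400 | multinomial depth per sample |
| `rare_presence` | 5 | max samples in which a rare taxon is nonzero |
| baseline frequencies | log-uniform 10⁻³–10⁻²·⁵ | abundance skew of the non-rare blocks |

Baseline frequencies for the differential and null blocks are drawn
log-uniformly over half a decade — skewed, but keeping the rank
statistics of different taxa on comparable scales, which a common
statistic cut-point requires to be competitive with per-feature p-value
methods. Group difference: a random half of the differential block is
multiplied by `effect_size`, the other half divided by it, and the block
rescaled to its original total mass. Rescaling within the block only is
deliberate: it guarantees null and rare taxa have *exactly* the same
frequencies in both groups, so the truth vector is clean — renormalizing
the whole vector would shift every null taxon through compositional
spillover and corrupt the FDR ground truth. Each sample is one
multinomial draw at the given depth (column sums equal the depth before
rare injection); rare taxa are then zeroed and given 1–3 reads in 1–5
randomly chosen samples each, identically in both groups.

The defaults put the non-rare blocks at roughly 0.5–3 reads per sample —
the low-count regime where rank statistics are strongly discrete — and
make rare taxa present in 4–5 samples pass the FBH filter while those in
1–3 samples fail it, so the benchmark exercises both the filter's help
and its limits. On this preset the three procedures reproduce the
expected pattern: BH's FDR ≈ 1%, FBH ≈ 2%, discrete ≈ 5% (all below
q = 10%), with the discrete procedure finding on average ≥ 15 more of the
100 true taxa than BH and ≥ 6 more than FBH across group sizes 10–100,
margins widening as samples shrink; in the sparsity sweep its discovery
count stays flat from 500 to 10,000 rare taxa while BH's collapses.

What the generator does **not** emulate: overdispersion beyond
multinomial noise, phylogenetic or ecological correlation between taxa
(each sample is a single multinomial draw), sequencing error, variable
library sizes, or compositional effects of very dominant taxa. Passing
benchmarks on it therefore demonstrates correct FDR mechanics under
sparsity and discreteness, not robustness to every property of real
surveys; the resample-split and spiking protocols exist precisely to
re-run the null and power checks on arbitrary (including real) tables
with their dependence intact.

## Data-driven protocols and evaluation

`resample_split_null` draws 2N distinct columns from a source table and
splits them into pseudo-groups at random — a global null with the source
table's cross-taxon dependence, under which FDR equals the family-wise
error rate. `spike_signals` multiplies k randomly chosen taxa's counts
(preferring non-empty rows) by an effect factor in the pseudo-sick group,
rounding half-up with a one-read floor where counts were positive.

`run_replicates` averages per-replicate false-discovery proportions
V/max(R,1) and true-discovery counts over independently seeded
replicates; all methods in a replicate share one permutation profile, so
comparisons are paired. Per-replicate seeds derive from
`SeedSequence(seed, spawn_key=(i,))`, making any replicate reproducible
in isolation. Early stopping at a target FDP standard error (the
headline runs use 0.001 in spirit but fixed replicate counts in
practice) engages only after 10 replicates, since FDP variance estimates
from a handful of replicates are unreliable. Power is reported as the
mean *count* of true discoveries, with the proportion alongside.

Benchmark problem sizes (desk scale, a few minutes on one CPU): the
sample-size sweep uses group sizes {10, 20, 35, 60, 100} × 50
replicates; the sparsity sweep rare-taxon counts {500, 2000, 5000,
10000} × 30 replicates; the global-null check 200 resample-splits at 20
samples per group. B = 1000 throughout.

## Input handling

TSV tables (feature IDs first column, sample IDs header) and BIOM 2.1
via biom-format; QIIME-style mapping files with `#SampleID`. Readers
reject rather than coerce: duplicate IDs, negative values and missing
entries fail with the offending identifier named. Abundance filtering
keeps features with row sum ≥ the threshold (inclusive); the per-sample
read filter `--min-sample-reads` (off by default) drops samples below a
total-read threshold. The CLI echoes its invocation to standard error
and uses exit codes 0 / 2 / 3 for success / invalid input / internal
error.

## Known limitations

The plug-in FDR estimate is slightly anticonservative in principle (it
estimates the null exceedance mass among all features, not only true
nulls, which partially offsets this); observed FDR on all shipped presets
stays near q/2. A common statistic cut-point presumes |T| is comparable
across features — with wildly heterogeneous per-feature sparsity the
adjusted-p comparators can be preferable, which is why the simulator
keeps block scales comparable. Only two-group designs are supported; no
paired, longitudinal, multi-group or covariate-adjusted tests, and no
compositional (log-ratio) modeling.
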