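"""Sparse multinomial community simulators and data-driven null/spike protocols.

The generative model emulates a two-group (healthy vs. sick) 16S-style
survey. A community holds three blocks of taxa:

* a *differential* block whose relative frequencies genuinely differ
  between the groups,
* a *null* block with identical frequencies in both groups, and
* a large *rare* block — taxa observed in only a handful of samples, with
  identical (negligible) frequency in both groups. Rare taxa carry no
  signal; they exist to inflate the multiplicity burden and the
  discreteness of the rank statistics, which is the regime the discrete
  FDR procedure targets.

Baseline frequencies for the differential and null blocks are drawn
log-uniformly, mimicking the abundance skew of real communities while
keeping the rank statistics of different taxa on comparable scales. Group differences are created by multiplying a
random half of the differential block by ``effect_size`` and the other
half by ``1/effect_size``, then rescaling the block to its original total
mass — so null and rare taxa keep *exactly* the same frequency in both
groups and only the differential block differs. Each sample is a single
multinomial draw of ``reads_per_sample`` reads; rare-taxon counts are then
injected post hoc into a few randomly chosen samples.

Two data-driven protocols operate on an existing table instead of a
parametric model: ``resample_split_null`` builds a global-null dataset by
randomly splitting samples of one table into two pseudo-groups (preserving
cross-taxon dependence), and ``spike_signals`` plants known signals by
multiplying chosen taxa's counts in the sick pseudo-group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .stats_core import AbundanceMatrix, GroupAssignment

__all__ = [
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_community",
    "resample_split_null",
    "spike_signals",
    "sim1_spec",
    "sim2_spec",
    "null_spec",
]

#: Baseline per-taxon frequencies are drawn log-uniformly from this range
#: (before block normalization). Half a decade of spread keeps the
#: abundance distribution skewed while leaving the block's statistic
#: scales comparable across taxa.
_LOG10_FREQ_RANGE = (-3.0, -2.5)

#: Injected rare-taxon counts are uniform on 1..3 reads.
_RARE_COUNT_MAX = 3


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated community.

    ``effect_size`` is the frequency multiplier applied to the up-shifted
    half of the differential block (the down-shifted half is divided by
    it); ``rare_presence`` caps the number of samples in which any rare
    taxon is nonzero; ``reads_per_sample`` is the multinomial depth.
    """

    n_per_group: int
    n_differential: int = 100
    n_null: int = 100
    n_rare: int = 800
    effect_size: float = 2.5
    rare_presence: int = 5
    reads_per_sample: int = 400
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValidationError("n_per_group must be positive")
        for name in ("n_differential", "n_null", "n_rare"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.n_differential + self.n_null + self.n_rare < 1:
            raise ValidationError("at least one taxon is required")
        if self.n_differential + self.n_null < 1:
            raise ValidationError(
                "at least one non-rare taxon is needed to carry multinomial mass"
            )
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        if self.n_differential > 0 and self.effect_size == 1.0:
            raise ValidationError(
                "effect_size must differ from 1 when differential taxa are requested"
            )
        if self.rare_presence < 1:
            raise ValidationError("rare_presence must be positive")
        if self.reads_per_sample < 1:
            raise ValidationError("reads_per_sample must be positive")

    @property
    def n_taxa(self) -> int:
        return self.n_differential + self.n_null + self.n_rare


@dataclass(frozen=True)
class SimulatedDataset:
    """A community table, its two-group labeling, and the ground truth."""

    matrix: AbundanceMatrix
    groups: GroupAssignment
    truth: np.ndarray

    def __post_init__(self) -> None:
        truth = np.asarray(self.truth, dtype=bool)
        object.__setattr__(self, "truth", truth)
        if truth.size != self.matrix.n_features:
            raise ValidationError("truth vector length must equal the taxon count")


def _group_frequencies(
    spec: SimulationSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Healthy and sick frequency vectors over all taxa (rare block = 0)."""
    nd, nn = spec.n_differential, spec.n_null
    base = 10.0 ** rng.uniform(*_LOG10_FREQ_RANGE, nd + nn)
    base /= base.sum()
    healthy = np.concatenate([base, np.zeros(spec.n_rare)])
    sick_block = base.copy()
    if nd > 0:
        n_up = (nd + 1) // 2
        up = rng.permutation(nd)[:n_up]
        direction = np.full(nd, 1.0 / spec.effect_size)
        direction[up] = spec.effect_size
        sick_block[:nd] = base[:nd] * direction
        # rescale the differential block only: null taxa keep identical
        # frequencies in both groups, so only the marked taxa truly differ
        sick_block[:nd] *= base[:nd].sum() / sick_block[:nd].sum()
    sick = np.concatenate([sick_block, np.zeros(spec.n_rare)])
    return healthy, sick


def simulate_community(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one two-group community table from the block model.

    Columns are ordered healthy (label 0) then sick (label 1); each column
    is one multinomial draw of ``reads_per_sample`` reads from its group's
    frequency vector. Rare taxa are then made nonzero in 1..``rare_presence``
    randomly chosen samples each (uniform 1..3 reads), identically
    distributed in both groups. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    healthy, sick = _group_frequencies(spec, rng)
    N = spec.n_per_group
    counts_h = rng.multinomial(spec.reads_per_sample, healthy, size=N)
    counts_s = rng.multinomial(spec.reads_per_sample, sick, size=N)
    values = np.vstack([counts_h, counts_s]).T.astype(float)  # taxa × samples

    n_samples = 2 * N
    nd, nn, nr = spec.n_differential, spec.n_null, spec.n_rare
    for r in range(nr):
        row = nd + nn + r
        k = int(rng.integers(1, spec.rare_presence + 1))
        pos = rng.choice(n_samples, size=k, replace=False)
        values[row, :] = 0.0
        values[row, pos] = rng.integers(1, _RARE_COUNT_MAX + 1, size=k)

    feature_ids = (
        [f"diff{j:05d}" for j in range(nd)]
        + [f"null{j:05d}" for j in range(nn)]
        + [f"rare{j:05d}" for j in range(nr)]
    )
    sample_ids = [f"H{j:04d}" for j in range(N)] + [f"S{j:04d}" for j in range(N)]
    matrix = AbundanceMatrix(values, tuple(feature_ids), tuple(sample_ids))
    groups = GroupAssignment(
        np.r_[np.zeros(N, dtype=int), np.ones(N, dtype=int)], ("healthy", "sick")
    )
    truth = np.r_[np.ones(nd, dtype=bool), np.zeros(nn + nr, dtype=bool)]
    return SimulatedDataset(matrix=matrix, groups=groups, truth=truth)


def resample_split_null(
    matrix: AbundanceMatrix, n_per_group: int, seed: int | None = None
) -> SimulatedDataset:
    """Global-null dataset: random samples of one table split into pseudo-groups.

    Selects ``2 * n_per_group`` distinct columns uniformly at random and
    assigns half to each pseudo-group at random. No taxon truly differs, so
    every rejection is a false positive, while the cross-taxon dependence of
    the source table is carried over unchanged.
    """
    if n_per_group < 1:
        raise ValidationError("n_per_group must be positive")
    if matrix.n_samples < 2 * n_per_group:
        raise ValidationError(
            f"need at least {2 * n_per_group} samples, table has {matrix.n_samples}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(matrix.n_samples, size=2 * n_per_group, replace=False)
    sub = matrix.select_samples(chosen)
    labels = np.r_[
        np.zeros(n_per_group, dtype=int), np.ones(n_per_group, dtype=int)
    ]
    labels = labels[rng.permutation(2 * n_per_group)]
    groups = GroupAssignment(labels, ("pseudo_healthy", "pseudo_sick"))
    truth = np.zeros(sub.n_features, dtype=bool)
    return SimulatedDataset(matrix=sub, groups=groups, truth=truth)


def spike_signals(
    dataset: SimulatedDataset,
    k: int,
    effect_size: float,
    seed: int | None = None,
) -> SimulatedDataset:
    """Plant ``k`` true signals by scaling taxa's counts in the sick group.

    Taxa are chosen uniformly at random, preferring taxa nonzero in at
    least one sample (a spike on an all-zero row would be invisible). The
    chosen taxa's counts in label-1 samples are multiplied by
    ``effect_size`` and rounded half-up, with a floor of one read wherever
    the pre-spike count was positive; the truth vector marks them true.
    """
    m = dataset.matrix.n_features
    if k < 0 or k > m:
        raise ValidationError(f"k must lie in [0, {m}], got {k}")
    if effect_size <= 0 or effect_size == 1.0:
        raise ValidationError("effect_size must be positive and different from 1")
    if k == 0:
        return dataset
    rng = np.random.default_rng(seed)
    nonzero = np.flatnonzero(dataset.matrix.values.any(axis=1))
    zero = np.flatnonzero(~dataset.matrix.values.any(axis=1))
    if nonzero.size >= k:
        spiked = rng.choice(nonzero, size=k, replace=False)
    else:
        extra = rng.choice(zero, size=k - nonzero.size, replace=False)
        spiked = np.concatenate([nonzero, extra])
    values = dataset.matrix.values.copy()
    sick = dataset.groups.labels == 1
    block = values[np.ix_(spiked, np.flatnonzero(sick))]
    scaled = np.floor(block * effect_size + 0.5)  # round half up
    scaled[(block > 0) & (scaled < 1)] = 1.0
    values[np.ix_(spiked, np.flatnonzero(sick))] = scaled
    truth = dataset.truth.copy()
    truth[spiked] = True
    matrix = AbundanceMatrix(
        values, dataset.matrix.feature_ids, dataset.matrix.sample_ids
    )
    return SimulatedDataset(matrix=matrix, groups=dataset.groups, truth=truth)


def sim1_spec(n_per_group: int, seed: int | None = None, **overrides) -> SimulationSpec:
    """Community preset sweeping sample size: 100 differential, 100 null, 800 rare."""
    overrides.setdefault("n_differential", 100)
    overrides.setdefault("n_null", 100)
    overrides.setdefault("n_rare", 800)
    return SimulationSpec(n_per_group=n_per_group, seed=seed, **overrides)


def sim2_spec(n_rare: int, seed: int | None = None, **overrides) -> SimulationSpec:
    """Sparsity-sweep preset: 50 samples per group, rare-taxon count varies."""
    overrides.setdefault("n_per_group", 50)
    overrides.setdefault("n_differential", 100)
    overrides.setdefault("n_null", 100)
    return SimulationSpec(n_rare=n_rare, seed=seed, **overrides)


def null_spec(n_per_group: int, seed: int | None = None, **overrides) -> SimulationSpec:
    """Global-null preset: no differential block at all."""
    overrides.setdefault("n_null", 200)
    overrides.setdefault("n_rare", 800)
    return SimulationSpec(
        n_per_group=n_per_group, n_differential=0, seed=seed, **overrides
    )
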