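"""Rank-based two-sample statistics and their label-permutation null.

The testing problem: a feature (taxon) × sample count table and a two-group
labeling of the samples. For every feature we compute a rank statistic
comparing the groups — either the difference of group mean ranks
(``meanrank``) or the Mann-Whitney U statistic centered at its null mean
``n1*n2/2`` (``mannwhitney``); the two are affine functions of the group-1
rank sum and therefore order features identically by ``|T|``.

The null distribution is built by permuting the sample labels: each
permutation shuffles the label vector once and applies it to *all* features
simultaneously, which preserves the cross-feature dependence structure of
the table. Statistics are evaluated internally on *doubled* midranks, which
are integers, so observed and permuted statistics live on an exact lattice
and tie comparisons (``>=``) are free of floating-point fuzz.

Depth normalization across samples is deliberately not performed here:
rank statistics are invariant to per-feature monotone transformations, but
cross-sample library-size normalization, if desired, is the caller's
responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

from .exceptions import ValidationError

STATISTICS = ("meanrank", "mannwhitney")

__all__ = [
    "AbundanceMatrix",
    "GroupAssignment",
    "StatisticProfile",
    "rank_transform",
    "compute_statistics",
    "build_null",
    "exhaustive_null",
    "permutation_pvalues",
    "STATISTICS",
]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Nonnegative feature × sample table with unique string identifiers.

    ``values`` holds counts or relative abundances; rows are features
    (taxa/OTUs), columns are samples. An empty feature axis is permitted
    (it can arise from aggressive abundance filtering); an empty sample
    axis is not.
    """

    values: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "feature_ids", tuple(str(f) for f in self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        if values.ndim != 2:
            raise ValidationError("abundance values must form a 2-D matrix")
        m, n = values.shape
        if n == 0:
            raise ValidationError("abundance matrix must contain at least one sample")
        if len(self.feature_ids) != m:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {m} matrix rows"
            )
        if len(self.sample_ids) != n:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n} matrix columns"
            )
        if len(set(self.feature_ids)) != m:
            raise ValidationError("duplicate feature ids")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample ids")
        if not np.all(np.isfinite(values)):
            bad = np.where(~np.isfinite(values).all(axis=1))[0][0]
            raise ValidationError(
                f"non-finite value in feature {self.feature_ids[bad]!r}"
            )
        if np.any(values < 0):
            bad = np.where((values < 0).any(axis=1))[0][0]
            raise ValidationError(
                f"negative value in feature {self.feature_ids[bad]!r}"
            )

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_features(self, mask: np.ndarray) -> "AbundanceMatrix":
        mask = np.asarray(mask)
        ids = tuple(np.asarray(self.feature_ids, dtype=object)[mask])
        return AbundanceMatrix(self.values[mask], ids, self.sample_ids)

    def select_samples(self, index: np.ndarray) -> "AbundanceMatrix":
        index = np.asarray(index)
        ids = tuple(np.asarray(self.sample_ids, dtype=object)[index])
        return AbundanceMatrix(self.values[:, index], self.feature_ids, ids)


@dataclass(frozen=True)
class GroupAssignment:
    """Binary labeling of samples; label 1 is the 'case'/'sick' group."""

    labels: np.ndarray
    group_names: tuple[str, str] = ("group0", "group1")

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "group_names", tuple(self.group_names))
        if labels.ndim != 1:
            raise ValidationError("labels must be a 1-D vector")
        if not np.isin(labels, (0, 1)).all():
            raise ValidationError("labels must be 0 or 1")
        if labels.sum() == 0 or labels.sum() == labels.size:
            raise ValidationError("both groups must be nonempty")
        if len(self.group_names) != 2:
            raise ValidationError("exactly two group names are required")

    @property
    def n_samples(self) -> int:
        return self.labels.size

    @property
    def group_sizes(self) -> tuple[int, int]:
        n1 = int(self.labels.sum())
        return self.labels.size - n1, n1

    def flipped(self) -> "GroupAssignment":
        return GroupAssignment(1 - self.labels, (self.group_names[1], self.group_names[0]))


@dataclass(frozen=True)
class StatisticProfile:
    """Observed statistics ``T_j`` plus an m × B matrix of permuted ``T*_jb``."""

    observed: np.ndarray
    permuted: np.ndarray
    statistic_name: str
    seed: int | None = None
    group_sizes: tuple[int, int] | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        observed = np.asarray(self.observed, dtype=float)
        permuted = np.asarray(self.permuted, dtype=float)
        object.__setattr__(self, "observed", observed)
        object.__setattr__(self, "permuted", permuted)
        if permuted.ndim != 2 or permuted.shape[0] != observed.size:
            raise ValidationError("permuted matrix must be m × B")
        if permuted.shape[1] < 1:
            raise ValidationError("at least one permutation is required")
        if not (np.all(np.isfinite(observed)) and np.all(np.isfinite(permuted))):
            raise ValidationError("statistics must be finite")

    @property
    def n_features(self) -> int:
        return self.observed.size

    @property
    def B(self) -> int:
        return self.permuted.shape[1]


def rank_transform(matrix: AbundanceMatrix) -> np.ndarray:
    """Rank each feature's values across samples, ties getting midranks.

    Every row of the result sums to ``n(n+1)/2``. Zeros — the dominant
    value in sparse tables — tie with each other and receive a common
    midrank, so presence/absence structure enters the statistic
    symmetrically.
    """
    if matrix.n_features == 0:
        raise ValidationError("cannot rank an empty matrix")
    return rankdata(matrix.values, axis=1)


def _doubled_ranks(values: np.ndarray) -> np.ndarray:
    # Doubled midranks are integers; stored as float64 they are exact and
    # matrix products against 0/1 label columns stay exact (all integers
    # well below 2**53), so statistic ties compare exactly.
    return np.rint(2.0 * rankdata(values, axis=1))


def _statistic_scale(statistic_name: str, n0: int, n1: int) -> float:
    # Both statistics are `scale * U2` with U2 = 2*S1 - n1*(n+1) the doubled,
    # centered group-1 rank sum (an exact integer).
    n = n0 + n1
    if statistic_name == "meanrank":
        return n / (2.0 * n0 * n1)
    if statistic_name == "mannwhitney":
        return 0.5
    raise ValidationError(
        f"unknown statistic {statistic_name!r}; expected one of {STATISTICS}"
    )


def _check_alignment(matrix: AbundanceMatrix, groups: GroupAssignment) -> None:
    if groups.n_samples != matrix.n_samples:
        raise ValidationError(
            f"{groups.n_samples} labels for {matrix.n_samples} samples"
        )


def compute_statistics(
    matrix: AbundanceMatrix,
    groups: GroupAssignment,
    statistic_name: str = "meanrank",
) -> np.ndarray:
    """Per-feature two-sample rank statistic on the observed labeling.

    ``meanrank``: mean rank of group-1 samples minus mean rank of group-0
    samples. ``mannwhitney``: Mann-Whitney U for group 1, centered at
    ``n1*n2/2`` so that large ``|T|`` is extreme in either direction.
    """
    _check_alignment(matrix, groups)
    if matrix.n_features == 0:
        return np.empty(0)
    n0, n1 = groups.group_sizes
    n = n0 + n1
    scale = _statistic_scale(statistic_name, n0, n1)
    dr = _doubled_ranks(matrix.values)
    u2 = dr @ groups.labels.astype(float) - n1 * (n + 1)
    return scale * u2


def _label_columns(labels: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """n × B matrix whose columns are independent uniform shuffles of ``labels``."""
    n = labels.size
    keys = rng.random((B, n))
    perms = np.argsort(keys, axis=1)
    return labels[perms].T.astype(float)


def build_null(
    matrix: AbundanceMatrix,
    groups: GroupAssignment,
    statistic_name: str = "meanrank",
    B: int = 1000,
    seed: int | None = None,
) -> StatisticProfile:
    """Joint-label permutation null: B shuffles shared by every feature.

    Each of the B draws permutes the label vector once and recomputes all m
    statistics against that single shuffled labeling, so the permuted
    statistics retain whatever dependence the features have across samples.
    Permutations are sampled uniformly with replacement from the n!
    arrangements (the identity may recur).
    """
    _check_alignment(matrix, groups)
    if B < 1:
        raise ValidationError("B must be a positive integer")
    if matrix.n_features == 0:
        raise ValidationError("cannot build a null for an empty matrix")
    n0, n1 = groups.group_sizes
    n = n0 + n1
    scale = _statistic_scale(statistic_name, n0, n1)
    dr = _doubled_ranks(matrix.values)
    rng = np.random.default_rng(seed)
    L = _label_columns(groups.labels, B, rng)
    center = n1 * (n + 1)
    observed = scale * (dr @ groups.labels.astype(float) - center)
    permuted = scale * (dr @ L - center)
    return StatisticProfile(
        observed=observed,
        permuted=permuted,
        statistic_name=statistic_name,
        seed=seed,
        group_sizes=(n0, n1),
    )


def exhaustive_null(
    matrix: AbundanceMatrix,
    groups: GroupAssignment,
    statistic_name: str = "meanrank",
    max_arrangements: int = 100_000,
) -> StatisticProfile:
    """Exact null over all C(n, n1) distinct label arrangements.

    Intended for small problems (tests, exact minimal p-values); the
    observed labeling occurs among the B = C(n, n1) permuted columns.
    """
    _check_alignment(matrix, groups)
    n0, n1 = groups.group_sizes
    n = n0 + n1
    K = comb(n, n1)
    if K > max_arrangements:
        raise ValidationError(
            f"{K} label arrangements exceed the cap of {max_arrangements}"
        )
    L = np.zeros((n, K))
    for b, ones in enumerate(combinations(range(n), n1)):
        L[list(ones), b] = 1.0
    scale = _statistic_scale(statistic_name, n0, n1)
    dr = _doubled_ranks(matrix.values)
    center = n1 * (n + 1)
    observed = scale * (dr @ groups.labels.astype(float) - center)
    permuted = scale * (dr @ L - center)
    return StatisticProfile(
        observed=observed,
        permuted=permuted,
        statistic_name=statistic_name,
        seed=None,
        group_sizes=(n0, n1),
    )


def permutation_pvalues(profile: StatisticProfile) -> np.ndarray:
    """Two-sided permutation p-values with the add-one convention.

    ``p_j = (1 + #{b : |T*_jb| >= |T_j|}) / (B + 1)`` — valid p-values whose
    smallest achievable value is ``1/(B+1)``.
    """
    exceed = (np.abs(profile.permuted) >= np.abs(profile.observed)[:, None]).sum(axis=1)
    return (1.0 + exceed) / (profile.B + 1.0)
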