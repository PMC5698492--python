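"""Replicate-based FDR/power estimation and the sweep harnesses.

``run_replicates`` is the workhorse: generate datasets with a known truth,
apply each procedure at level ``q``, and average the per-replicate false
discovery proportion (FDP) and true-discovery count. All procedures in one
replicate share a single permutation profile, so method comparisons are
paired. Replication stops when every method's FDP standard error drops
below ``se_target`` (after a minimum number of replicates) or at
``max_replicates``.

``filter_sweep`` and ``subsample_power_curve`` rerun the procedures across
abundance-filter levels and per-group subsample sizes, mirroring how a
practitioner probes sensitivity to filtering and to cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .fdr_procedures import (
    bh_adjust,
    dsfdr_threshold,
    fbh_from_profile,
    permutation_pvalues,
)
from .io import filter_taxa
from .stats_core import AbundanceMatrix, GroupAssignment, StatisticProfile, build_null
from .synthetic_data import SimulatedDataset

METHODS = ("dsfdr", "fbh", "bh")

__all__ = [
    "EvaluationSummary",
    "METHODS",
    "apply_method",
    "false_discovery_proportion",
    "run_replicates",
    "filter_sweep",
    "subsample_power_curve",
    "replicate_seeds",
]


@dataclass(frozen=True)
class EvaluationSummary:
    """Averaged outcome of one method over simulation replicates."""

    method: str
    mean_fdr: float
    mean_true_discoveries: float
    mean_true_proportion: float
    replicates: int
    se_fdr: float
    m0: int
    q: float


def false_discovery_proportion(rejected: np.ndarray, truth: np.ndarray) -> float:
    """Realized FDP: false rejections over ``max(R, 1)``."""
    rejected = np.asarray(rejected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if rejected.shape != truth.shape:
        raise ValidationError("rejection and truth vectors must have equal length")
    r = int(rejected.sum())
    v = int((rejected & ~truth).sum())
    return v / max(r, 1)


def apply_method(
    method: str,
    dataset: SimulatedDataset,
    profile: StatisticProfile,
    q: float,
) -> np.ndarray:
    """Rejection mask of one procedure on a shared permutation profile."""
    if method == "dsfdr":
        return dsfdr_threshold(profile, q).rejected
    if method == "bh":
        return bh_adjust(permutation_pvalues(profile)).values <= q
    if method == "fbh":
        return fbh_from_profile(dataset.matrix, dataset.groups, profile, q).rejected
    raise ValidationError(f"unknown method {method!r}; expected one of {METHODS}")


def replicate_seeds(seed: int | None, index: int) -> tuple[int, int]:
    """Deterministic (data_seed, permutation_seed) for replicate ``index``.

    Children are spawned from ``SeedSequence(seed)`` with spawn key
    ``(index,)``, so replicate streams are mutually independent and any
    replicate can be regenerated in isolation. Seeds are reduced below
    2**31 for portability.
    """
    child = np.random.SeedSequence(entropy=seed, spawn_key=(index,))
    a, b = child.generate_state(2)
    return int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF


def run_replicates(
    generator: Callable[[int], SimulatedDataset],
    methods: Sequence[str] = METHODS,
    q: float = 0.1,
    B: int = 1000,
    max_replicates: int = 100,
    se_target: float = 0.001,
    seed: int | None = None,
    statistic_name: str = "meanrank",
    min_replicates: int = 10,
) -> list[EvaluationSummary]:
    """Estimate each method's FDR and power over simulated replicates.

    ``generator`` maps an integer seed to a :class:`SimulatedDataset`;
    it is called once per replicate with an independent derived seed.
    Replication stops at ``max_replicates``, or earlier once at least
    ``min_replicates`` have run and every method's FDP standard error is
    below ``se_target``.
    """
    if max_replicates < 2:
        raise ValidationError("at least two replicates are required")
    for method in methods:
        if method not in METHODS:
            raise ValidationError(f"unknown method {method!r}")
    fdp: dict[str, list[float]] = {m: [] for m in methods}
    td: dict[str, list[int]] = {m: [] for m in methods}
    m0 = 0
    n_truth = 0
    done = 0
    for i in range(max_replicates):
        data_seed, perm_seed = replicate_seeds(seed, i)
        dataset = generator(data_seed)
        profile = build_null(
            dataset.matrix, dataset.groups, statistic_name, B, perm_seed
        )
        m0 = int((~dataset.truth).sum())
        n_truth = int(dataset.truth.sum())
        for method in methods:
            rejected = apply_method(method, dataset, profile, q)
            fdp[method].append(false_discovery_proportion(rejected, dataset.truth))
            td[method].append(int((rejected & dataset.truth).sum()))
        done = i + 1
        if done >= max(min_replicates, 2):
            ses = [
                np.std(fdp[m], ddof=1) / np.sqrt(done) for m in methods
            ]
            if all(se < se_target for se in ses):
                break
    summaries = []
    for method in methods:
        f = np.asarray(fdp[method])
        t = np.asarray(td[method], dtype=float)
        summaries.append(
            EvaluationSummary(
                method=method,
                mean_fdr=float(f.mean()),
                mean_true_discoveries=float(t.mean()),
                mean_true_proportion=float(t.mean() / n_truth) if n_truth else 0.0,
                replicates=done,
                se_fdr=float(np.std(f, ddof=1) / np.sqrt(done)),
                m0=m0,
                q=q,
            )
        )
    return summaries


def summaries_frame(summaries: Sequence[EvaluationSummary], preset: str, B: int) -> pd.DataFrame:
    """Tabular form of :func:`run_replicates` output."""
    return pd.DataFrame(
        {
            "preset": preset,
            "method": [s.method for s in summaries],
            "q": [s.q for s in summaries],
            "B": B,
            "replicates": [s.replicates for s in summaries],
            "mean_fdr": [s.mean_fdr for s in summaries],
            "se_fdr": [s.se_fdr for s in summaries],
            "mean_true_discoveries": [s.mean_true_discoveries for s in summaries],
            "mean_true_proportion": [s.mean_true_proportion for s in summaries],
        }
    )


def filter_sweep(
    matrix: AbundanceMatrix,
    groups: GroupAssignment,
    filter_levels: Sequence[float],
    methods: Sequence[str] = METHODS,
    q: float = 0.1,
    B: int = 1000,
    seed: int | None = None,
    statistic_name: str = "meanrank",
) -> pd.DataFrame:
    """Discovery counts as a function of the total-abundance filter level.

    For each level, taxa with row sum below the level are removed and each
    procedure reruns on the reduced table (fresh permutations per level,
    derived deterministically from ``seed``).
    """
    levels = list(filter_levels)
    if any(lv < 0 for lv in levels):
        raise ValidationError("filter levels must be nonnegative")
    if sorted(levels) != levels:
        raise ValidationError("filter levels must be ascending")
    rows = []
    for i, level in enumerate(levels):
        filtered = filter_taxa(matrix, level)
        _, perm_seed = replicate_seeds(seed, i)
        if filtered.n_features == 0:
            for method in methods:
                rows.append((level, method, 0, 0))
            continue
        profile = build_null(filtered, groups, statistic_name, B, perm_seed)
        dataset = SimulatedDataset(
            matrix=filtered,
            groups=groups,
            truth=np.zeros(filtered.n_features, dtype=bool),
        )
        for method in methods:
            rejected = apply_method(method, dataset, profile, q)
            rows.append((level, method, int(rejected.sum()), filtered.n_features))
    return pd.DataFrame(
        rows, columns=["filter_level", "method", "discoveries", "n_features"]
    )


def subsample_power_curve(
    matrix: AbundanceMatrix,
    groups: GroupAssignment,
    sizes: Sequence[int],
    methods: Sequence[str] = METHODS,
    q: float = 0.1,
    B: int = 1000,
    replicates: int = 10,
    seed: int | None = None,
    statistic_name: str = "meanrank",
) -> pd.DataFrame:
    """Mean discovery counts as a function of per-group subsample size.

    For each size, samples are drawn without replacement within each group,
    each procedure reruns, and discovery counts are averaged over
    ``replicates`` draws.
    """
    n0, n1 = groups.group_sizes
    for size in sizes:
        if size < 1 or size > min(n0, n1):
            raise ValidationError(
                f"subsample size {size} exceeds the smaller group ({min(n0, n1)})"
            )
    idx0 = np.flatnonzero(groups.labels == 0)
    idx1 = np.flatnonzero(groups.labels == 1)
    rows = []
    counter = 0
    for size in sizes:
        counts: dict[str, list[int]] = {m: [] for m in methods}
        for _ in range(replicates):
            data_seed, perm_seed = replicate_seeds(seed, counter)
            counter += 1
            rng = np.random.default_rng(data_seed)
            # sorted draws preserve column order, so a full-size subsample
            # reproduces the original design exactly
            take0 = np.sort(rng.choice(idx0, size=size, replace=False))
            take1 = np.sort(rng.choice(idx1, size=size, replace=False))
            index = np.concatenate([take0, take1])
            sub = matrix.select_samples(index)
            sub_groups = GroupAssignment(
                np.r_[np.zeros(size, dtype=int), np.ones(size, dtype=int)],
                groups.group_names,
            )
            profile = build_null(sub, sub_groups, statistic_name, B, perm_seed)
            dataset = SimulatedDataset(
                matrix=sub,
                groups=sub_groups,
                truth=np.zeros(sub.n_features, dtype=bool),
            )
            for method in methods:
                rejected = apply_method(method, dataset, profile, q)
                counts[method].append(int(rejected.sum()))
        for method in methods:
            rows.append((size, method, float(np.mean(counts[method]))))
    return pd.DataFrame(rows, columns=["size", "method", "mean_discoveries"])
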