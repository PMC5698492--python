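"""Feature-table and metadata I/O, abundance filtering, result serialization.

Supported formats: tab-separated feature tables (feature IDs in the first
column, sample IDs in the header) and BIOM 2.1 (HDF5) via the
``biom-format`` library; QIIME-style mapping files (tab-separated,
``#SampleID`` first column) for sample metadata. Readers validate rather
than coerce: duplicate IDs, negative entries and missing values are
rejected with the offending identifier in the message.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError
from .stats_core import AbundanceMatrix, GroupAssignment

logger = logging.getLogger("dsfdr")

__all__ = [
    "MetadataTable",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "align_and_label",
    "filter_taxa",
    "write_results",
]


@dataclass(frozen=True)
class MetadataTable:
    """Per-sample string-valued metadata keyed by unique sample IDs."""

    frame: pd.DataFrame  # index = sample ids, columns = metadata fields

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r} in metadata")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(str(s) for s in self.frame.index)


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        return format
    return "biom" if str(path).endswith(".biom") else "tsv"


def _matrix_from_frame(frame: pd.DataFrame, source: str) -> AbundanceMatrix:
    if frame.index.has_duplicates:
        dup = frame.index[frame.index.duplicated()][0]
        raise FormatError(f"duplicate feature id {dup!r} in {source}")
    if frame.columns.has_duplicates:
        dup = frame.columns[frame.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r} in {source}")
    values = frame.to_numpy(dtype=float)
    if np.isnan(values).any():
        bad = frame.index[np.isnan(values).any(axis=1)][0]
        raise FormatError(f"missing value in feature {bad!r} in {source}")
    if (values < 0).any():
        bad = frame.index[(values < 0).any(axis=1)][0]
        raise FormatError(f"negative value in feature {bad!r} in {source}")
    return AbundanceMatrix(
        values,
        tuple(str(f) for f in frame.index),
        tuple(str(s) for s in frame.columns),
    )


def read_feature_table(path: str | Path, format: str | None = None) -> AbundanceMatrix:
    """Load a feature × sample table from TSV or BIOM 2.1.

    TSV: first column feature IDs, header row sample IDs, numeric body
    (integers, decimals or scientific notation; dot decimal separator).
    A leading ``# Constructed from biom file``-style comment line is
    tolerated. BIOM: observations are features, columns are samples.
    """
    fmt = _infer_format(path, format)
    if fmt == "biom":
        import biom

        table = biom.load_table(str(path))
        frame = pd.DataFrame(
            table.matrix_data.toarray(),
            index=table.ids("observation"),
            columns=table.ids("sample"),
        )
        return _matrix_from_frame(frame, str(path))
    if fmt != "tsv":
        raise ValidationError(f"unknown table format {fmt!r}")
    try:
        with open(path) as fh:
            first = fh.readline()
            skip = 1 if first.startswith("# ") else 0
        frame = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse {path} as a TSV feature table: {e}") from e
    non_numeric = frame.columns[
        [not np.issubdtype(d, np.number) for d in frame.dtypes]
    ]
    if len(non_numeric):
        raise FormatError(
            f"non-numeric column {non_numeric[0]!r} in {path}"
        )
    return _matrix_from_frame(frame, str(path))


def write_feature_table(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (feature IDs first column, sample IDs header)."""
    frame = pd.DataFrame(
        matrix.values, index=list(matrix.feature_ids), columns=list(matrix.sample_ids)
    )
    frame.index.name = "#FeatureID"
    frame.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> MetadataTable:
    """Load a QIIME-style mapping file (tab-separated, ``#SampleID`` first)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse {path} as a mapping file: {e}") from e
    frame.index = frame.index.astype(str)
    return MetadataTable(frame=frame)


def align_and_label(
    matrix: AbundanceMatrix,
    metadata: MetadataTable,
    group_column: str,
    group_values: tuple[str, str] | None = None,
) -> tuple[AbundanceMatrix, GroupAssignment]:
    """Intersect table and metadata samples and build the two-group labeling.

    Samples absent from either side, or carrying a value outside
    ``group_values``, are dropped (counts are logged). Label 0/1 assignment
    follows ``group_values`` when given, else lexicographic order of the
    two observed values.
    """
    if group_column not in metadata.frame.columns:
        raise ValidationError(
            f"metadata has no column {group_column!r}; "
            f"available: {list(metadata.frame.columns)}"
        )
    column = metadata.frame[group_column]
    shared = [s for s in matrix.sample_ids if s in column.index]
    dropped = matrix.n_samples - len(shared)
    if dropped:
        logger.info("dropped %d samples absent from the metadata", dropped)
    if not shared:
        raise ValidationError("no sample ids shared between table and metadata")
    values = column.loc[shared]
    if group_values is None:
        observed = sorted(set(values.dropna()))
        if len(observed) != 2:
            raise ValidationError(
                f"column {group_column!r} has {len(observed)} distinct values "
                f"among shared samples ({observed}); specify group_values "
                "to select exactly two"
            )
        group_values = (observed[0], observed[1])
    g0, g1 = (str(v) for v in group_values)
    keep = [s for s in shared if str(values.loc[s]) in (g0, g1)]
    if len(keep) < len(shared):
        logger.info(
            "dropped %d samples outside groups (%s, %s)",
            len(shared) - len(keep),
            g0,
            g1,
        )
    labels = np.array([1 if str(values.loc[s]) == g1 else 0 for s in keep], dtype=int)
    if labels.sum() == 0 or labels.sum() == labels.size:
        raise ValidationError(
            f"need samples from both groups ({g0!r}, {g1!r}) after alignment"
        )
    index = [matrix.sample_ids.index(s) for s in keep]
    return matrix.select_samples(np.asarray(index)), GroupAssignment(labels, (g0, g1))


def filter_taxa(matrix: AbundanceMatrix, min_total_abundance: float) -> AbundanceMatrix:
    """Keep features whose total abundance is at least the threshold.

    The comparison is inclusive (``>=``); order is preserved. Removing every
    feature yields an empty matrix with a warning rather than an error.
    """
    if min_total_abundance < 0:
        raise ValidationError("the abundance threshold must be nonnegative")
    keep = matrix.values.sum(axis=1) >= min_total_abundance
    if not keep.any():
        warnings.warn(
            f"abundance filter at {min_total_abundance} removed every feature",
            stacklevel=2,
        )
    return matrix.select_features(keep)


def filter_samples(matrix: AbundanceMatrix, min_sample_reads: float) -> AbundanceMatrix:
    """Drop samples whose total reads fall below the threshold (inclusive keep)."""
    if min_sample_reads < 0:
        raise ValidationError("the sample-read threshold must be nonnegative")
    keep = np.flatnonzero(matrix.values.sum(axis=0) >= min_sample_reads)
    if keep.size == 0:
        raise ValidationError(
            f"sample-read filter at {min_sample_reads} removed every sample"
        )
    return matrix.select_samples(keep)


def write_results(
    path: str | Path,
    matrix: AbundanceMatrix,
    statistics: np.ndarray,
    raw_p: np.ndarray | None,
    adjusted_p: np.ndarray | None,
    rejected: np.ndarray,
    method: str,
    q: float,
    B: int,
    seed: int | None,
) -> None:
    """Serialize a test run as a TSV with one row per feature."""
    frame = pd.DataFrame(
        {
            "feature_id": list(matrix.feature_ids),
            "statistic": statistics,
            "raw_p": raw_p if raw_p is not None else np.nan,
            "adjusted_p": adjusted_p if adjusted_p is not None else np.nan,
            "rejected": np.where(np.asarray(rejected, dtype=bool), "true", "false"),
            "method": method,
            "q": q,
            "B": B,
            "seed": seed if seed is not None else "",
        }
    )
    frame.to_csv(path, sep="\t", index=False)
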