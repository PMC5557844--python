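"""Expression-matrix I/O, log2 normalization, and stress/MOCK fold changes.

The central container is :class:`ExpressionMatrix`, a genes x samples
table of hybridization intensities carried either on the linear scale
(raw, strictly positive) or on the log2 scale.  Downstream statistics
(fold changes, clustering, correlation) always operate on log2 values,
so the first pipeline stage is :func:`log2_normalize`.

Fold changes are computed per replicate pair: each stressed sample is
matched to the MOCK (untreated control) sample of the same series,
stress type, and replicate index, and log2FC = log2(stress) - log2(mock).
Condition means average the pairs of each stress type.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError, PairingError, ValidationError

STRESS_TYPES = ("drought", "cold", "heat", "submergence", "none")
CONDITIONS = ("stress", "mock")

METADATA_COLUMNS = [
    "sample_id",
    "series_id",
    "stress_type",
    "condition",
    "replicate",
    "stage",
    "day",
    "hour",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  Missing
        measurements are NaN, never zero.
    scale
        ``"linear"`` (strictly positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise FormatError(f"duplicate sample ids: {list(dups)[:5]}")
        if self.scale == "linear":
            self._check_positive()

    def _check_positive(self) -> None:
        bad = self.values.to_numpy() <= 0
        bad &= ~np.isnan(self.values.to_numpy())
        if bad.any():
            rows, cols = np.nonzero(bad)
            cells = [
                f"({self.values.index[r]}, {self.values.columns[c]})"
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(
                f"nonpositive intensities on the linear scale at {cells}"
                + (" ..." if len(rows) > 5 else "")
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def read_expression_matrix(
    path: str | Path | _io.TextIOBase, scale_hint: str = "linear"
) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene ids, header row).

    Empty cells and ``NA`` become NaN (absent), not zero.  Duplicate gene
    or sample ids and ragged rows raise :class:`FormatError`; nonpositive
    values under ``scale_hint="linear"`` raise :class:`ValidationError`.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA", ""],
            keep_default_na=True,
        )
        df = df.apply(pd.to_numeric)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise FormatError(f"malformed expression TSV: {exc}") from exc
    except ValueError as exc:
        raise FormatError(f"non-numeric expression values: {exc}") from exc
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(values=df, scale=scale_hint)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; NaN cells are written as ``NA``."""
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV and validate the coded fields."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "series_id": str})
    missing = set(["sample_id", "series_id", "stress_type", "condition"]) - set(meta.columns)
    if missing:
        raise FormatError(f"metadata lacks required columns: {sorted(missing)}")
    bad_st = set(meta["stress_type"].dropna()) - set(STRESS_TYPES)
    if bad_st:
        raise FormatError(f"unknown stress_type values: {sorted(bad_st)}")
    bad_cond = set(meta["condition"].dropna()) - set(CONDITIONS)
    if bad_cond:
        raise FormatError(f"unknown condition values: {sorted(bad_cond)}")
    if "hour" in meta.columns:
        hours = meta["hour"].dropna()
        if ((hours % 2 != 0) | (hours < 0) | (hours > 22)).any():
            raise ValidationError("hour must be even and within [0, 22]")
    return meta


def write_sample_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False, na_rep="NA")


def log2_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert linear intensities to the log2 scale.

    Raises :class:`ValidationError` on an already-log2 input (applying
    log2 twice would silently corrupt fold changes) and on nonpositive
    values.  Absent (NaN) cells stay absent.
    """
    if matrix.scale != "linear":
        raise ValidationError("matrix is already log2-scaled")
    return ExpressionMatrix(values=np.log2(matrix.values), scale="log2")


@dataclass
class FoldChangeProfile:
    """Per-gene log2(stress/MOCK) values per replicate pair.

    ``log2fc`` is genes x pairs; ``pair_meta`` records series, stress type
    and replicate of each pair; ``condition_means`` averages a gene's
    pairs within each stress type.
    """

    log2fc: pd.DataFrame
    pair_meta: pd.DataFrame
    condition_means: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        means = {}
        for stype, grp in self.pair_meta.groupby("stress_type", sort=True):
            means[stype] = self.log2fc[grp["pair_id"]].mean(axis=1)
        self.condition_means = pd.DataFrame(means, index=self.log2fc.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.log2fc.index

    @property
    def pair_ids(self) -> pd.Index:
        return self.log2fc.columns


def fold_change(
    matrix: ExpressionMatrix,
    metadata: pd.DataFrame,
    stress_types: Iterable[str] | None = None,
) -> FoldChangeProfile:
    """Per-replicate log2 fold changes of stressed over MOCK samples.

    Stress and MOCK samples are matched within a series by stress type
    and replicate index.  A stressed sample without its control raises
    :class:`PairingError` naming the sample.
    """
    if matrix.scale != "log2":
        raise ValidationError("fold_change requires a log2-scaled matrix")
    meta = metadata[metadata["sample_id"].isin(matrix.sample_ids)].copy()
    if stress_types is not None:
        keep = set(stress_types)
        meta = meta[meta["stress_type"].isin(keep) | (meta["condition"] == "mock")]

    mock_lookup: dict[tuple, str] = {}
    for row in meta[meta["condition"] == "mock"].itertuples():
        mock_lookup[(row.series_id, row.stress_type, row.replicate)] = row.sample_id

    pair_ids, pair_rows, cols = [], [], []
    stressed = meta[meta["condition"] == "stress"].sort_values("sample_id")
    for row in stressed.itertuples():
        key = (row.series_id, row.stress_type, row.replicate)
        if key not in mock_lookup:
            raise PairingError(
                f"stressed sample {row.sample_id!r} has no matched MOCK "
                f"(series={row.series_id}, stress={row.stress_type}, "
                f"replicate={row.replicate})"
            )
        pair_id = f"{row.series_id}:{row.stress_type}:r{row.replicate}"
        pair_ids.append(pair_id)
        pair_rows.append(
            {
                "pair_id": pair_id,
                "series_id": row.series_id,
                "stress_type": row.stress_type,
                "replicate": row.replicate,
                "stress_sample": row.sample_id,
                "mock_sample": mock_lookup[key],
            }
        )
        cols.append(
            matrix.values[row.sample_id] - matrix.values[mock_lookup[key]]
        )
    if not pair_ids:
        raise PairingError("no stress/MOCK pairs found")
    log2fc = pd.concat(cols, axis=1)
    log2fc.columns = pair_ids
    return FoldChangeProfile(log2fc=log2fc, pair_meta=pd.DataFrame(pair_rows))


def filter_missing(
    log2fc: pd.DataFrame, max_missing_frac: float = 0.2
) -> pd.DataFrame:
    """Drop genes whose fraction of absent fold-change entries exceeds the cap."""
    frac = log2fc.isna().mean(axis=1)
    return log2fc.loc[frac <= max_missing_frac]
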