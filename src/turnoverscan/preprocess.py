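"""Expression-matrix IO, normalization, replicate QC and tissue collapsing.

The unit of all downstream comparative analysis is the per-tissue mean
expression profile on a log2 scale; this module gets a raw or
pre-normalized gene x sample matrix to that point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .errors import FormatError

__all__ = [
    "RAW_COUNTS",
    "LOG_NORMALIZED",
    "ExpressionMatrix",
    "TurnoverTable",
    "read_expression",
    "read_turnover_table",
    "turnover_fixture_path",
    "normalize",
    "qc_replicate_correlation",
    "filter_genes",
    "collapse_to_tissues",
]

RAW_COUNTS = "RAW_COUNTS"
LOG_NORMALIZED = "LOG_NORMALIZED"
GERM_LAYERS = ("ectoderm", "mesoderm", "endoderm")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values plus sample -> tissue metadata.

    ``values``: DataFrame with gene IDs as index and sample IDs as columns.
    ``metadata``: Series mapping sample ID -> tissue label.
    ``scale``: RAW_COUNTS or LOG_NORMALIZED.
    """

    values: pd.DataFrame
    metadata: pd.Series
    scale: str = LOG_NORMALIZED

    def __post_init__(self):
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError("duplicate gene IDs: " + ", ".join(map(str, dups[:5])))
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample IDs")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise FormatError(
                "samples missing from metadata: " + ", ".join(map(str, missing[:5]))
            )
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("expression values must be finite")
        if self.scale == RAW_COUNTS and (vals < 0).any():
            raise FormatError("raw counts must be non-negative")
        if self.scale not in (RAW_COUNTS, LOG_NORMALIZED):
            raise FormatError(f"unknown scale {self.scale!r}")
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def gene_ids(self) -> list:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list:
        return list(self.values.columns)

    @property
    def tissues(self) -> list:
        seen: dict = {}
        for t in self.metadata:
            seen.setdefault(t, None)
        return list(seen)

    def write(self, expression_path, metadata_path) -> None:
        # %.17g guarantees bit-exact float round-trip through text
        self.values.to_csv(
            expression_path, sep="\t", index_label="gene", float_format="%.17g"
        )
        self.metadata.rename("tissue").to_csv(
            metadata_path, sep="\t", index_label="sample_id"
        )


@dataclass
class TurnoverTable:
    """Tissue -> (germ layer, turnover in days)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        need = {"tissue", "germ_layer", "turnover_days"}
        if not need.issubset(self.table.columns):
            raise FormatError(f"turnover table needs columns {sorted(need)}")
        if self.table["tissue"].duplicated().any():
            raise FormatError("duplicate tissue labels in turnover table")
        self.table = self.table.copy()
        self.table["germ_layer"] = self.table["germ_layer"].str.lower()
        bad_layer = ~self.table["germ_layer"].isin(GERM_LAYERS)
        if bad_layer.any():
            raise FormatError(
                "unknown germ layer(s): "
                + ", ".join(self.table.loc[bad_layer, "germ_layer"].unique())
            )
        days = pd.to_numeric(self.table["turnover_days"], errors="raise")
        if (days <= 0).any():
            bad = self.table.loc[days <= 0, "tissue"].tolist()
            raise FormatError("non-positive turnover for: " + ", ".join(bad))
        self.table["turnover_days"] = days.astype(float)
        self.table = self.table.set_index("tissue", drop=False)

    @property
    def tissues(self) -> list:
        return list(self.table.index)

    @property
    def turnover_days(self) -> pd.Series:
        return self.table["turnover_days"]

    @property
    def germ_layer(self) -> pd.Series:
        return self.table["germ_layer"]

    @classmethod
    def from_trait(cls, log10_turnover: dict, germ_layer: str = "mesoderm"):
        """Build a table from a log10-days trait map (synthetic runs)."""
        rows = pd.DataFrame(
            {
                "tissue": list(log10_turnover),
                "germ_layer": germ_layer,
                "turnover_days": [10.0 ** v for v in log10_turnover.values()],
            }
        )
        return cls(rows)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_expression(path, metadata_path, scale: str = LOG_NORMALIZED) -> ExpressionMatrix:
    """Read a tab-separated gene x sample matrix and its sample metadata."""
    values = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    meta = pd.read_csv(metadata_path, sep="\t")
    if not {"sample_id", "tissue"}.issubset(meta.columns):
        raise FormatError("metadata needs columns sample_id and tissue")
    metadata = meta.set_index("sample_id")["tissue"]
    return ExpressionMatrix(values=values, metadata=metadata, scale=scale)


def read_turnover_table(path) -> TurnoverTable:
    """Read a tab-separated (tissue, germ_layer, turnover_days) table."""
    return TurnoverTable(pd.read_csv(path, sep="\t"))


def turnover_fixture_path():
    """Path to the packaged 21-tissue human turnover table."""
    return resources.files("turnoverscan.data") / "turnover_table.tsv"


def normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million scaling followed by log2(x + 1).

    A no-op (with a warning) if the matrix is already log-normalized.
    """
    if matrix.scale == LOG_NORMALIZED:
        warnings.warn("matrix already log-normalized; normalize() is a no-op")
        return matrix
    libsize = matrix.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise FormatError(
            "zero total counts in sample(s): " + ", ".join(map(str, zero.index))
        )
    cpm = matrix.values * (1e6 / libsize)
    return ExpressionMatrix(
        values=np.log2(cpm + 1.0), metadata=matrix.metadata, scale=LOG_NORMALIZED
    )


def qc_replicate_correlation(
    matrix: ExpressionMatrix, threshold: float = 0.90
) -> pd.DataFrame:
    """Minimum within-tissue pairwise Pearson correlation, per tissue.

    Tissues with a single sample are reported with min 1.0 and flagged.
    """
    if matrix.scale != LOG_NORMALIZED:
        raise FormatError("replicate QC expects log-normalized values")
    rows = []
    for tissue in matrix.tissues:
        samples = matrix.metadata.index[matrix.metadata == tissue]
        if len(samples) < 2:
            rows.append((tissue, len(samples), 1.0, True, True))
            continue
        corr = np.corrcoef(matrix.values[samples].to_numpy().T)
        iu = np.triu_indices(len(samples), k=1)
        mn = float(corr[iu].min())
        rows.append((tissue, len(samples), mn, mn >= threshold, False))
    return pd.DataFrame(
        rows,
        columns=["tissue", "n_samples", "min_pairwise_pearson", "pass", "single_sample"],
    )


def filter_genes(
    matrix: ExpressionMatrix, min_expr: float = 0.0, min_frac_tissues: float = 0.5
) -> ExpressionMatrix:
    """Keep genes with expression strictly above ``min_expr`` in at least
    ``min_frac_tissues`` of tissues, judged on per-tissue mean profiles."""
    if matrix.scale != LOG_NORMALIZED:
        raise FormatError("gene filtering expects log-normalized values")
    profiles = collapse_to_tissues(matrix)
    frac = (profiles > min_expr).mean(axis=1)
    keep = frac >= min_frac_tissues
    if not keep.any():
        raise FormatError(
            "gene filter removed every gene; lower min_expr or min_frac_tissues"
        )
    return ExpressionMatrix(
        values=matrix.values.loc[keep[keep].index],
        metadata=matrix.metadata,
        scale=matrix.scale,
    )


def collapse_to_tissues(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-tissue arithmetic mean profiles (genes x tissues DataFrame)."""
    if matrix.scale != LOG_NORMALIZED:
        raise FormatError("collapse expects log-normalized values")
    grouped = matrix.values.T.groupby(matrix.metadata).mean().T
    return grouped[matrix.tissues]
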