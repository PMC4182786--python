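"""Condition-labelled, subject-paired expression matrix container and TSV IO.

The on-disk format is two UTF-8 tab-separated files with mandatory header
rows and no quoting: the expression table (rows = genes, columns = samples,
log2 values) and a sample sidecar (sample_id, subject_id, condition).
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "read_expression", "write_expression"]

CONDITIONS = ("normal", "tumor")


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample condition and subject.

    ``values``: DataFrame indexed by gene id with sample-id columns.
    ``samples``: DataFrame indexed by sample id with ``subject_id`` and
    ``condition`` columns.  Each subject may contribute at most one sample
    per condition.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample columns and sample metadata rows disagree")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        dup = self.samples.groupby(["subject_id", "condition"]).size()
        if (dup > 1).any():
            raise ValueError("a subject has more than one sample in a condition")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def condition(self, condition: str) -> pd.DataFrame:
        """Expression sub-matrix of one condition."""
        keep = self.samples.index[self.samples["condition"] == condition]
        return self.values[list(keep)]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples)

    @staticmethod
    def concat(parts: list["ExpressionMatrix"]) -> "ExpressionMatrix":
        """Column-wise concatenation (e.g. normal + tumor of one cohort)."""
        genes = parts[0].gene_ids
        for p in parts[1:]:
            if p.gene_ids != genes:
                raise ValueError("gene sets differ between matrices")
        return ExpressionMatrix(
            pd.concat([p.values for p in parts], axis=1),
            pd.concat([p.samples for p in parts], axis=0),
        )


def write_expression(expr: ExpressionMatrix, values_path, samples_path) -> None:
    expr.values.to_csv(values_path, sep="\t", index_label="gene_id", float_format="%.10g")
    expr.samples.to_csv(samples_path, sep="\t")


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed TSV {path}: {err}") from err


def read_expression(values_path, samples_path) -> ExpressionMatrix:
    values = _read_tsv(values_path, index_col=0)
    samples = _read_tsv(samples_path, index_col=0)
    missing = [c for c in ("subject_id", "condition") if c not in samples.columns]
    if missing:
        raise ValueError(f"{samples_path}: missing columns {missing}")
    extra = set(values.columns) ^ set(samples.index)
    if extra:
        raise ValueError(
            f"sample identifiers disagree between {Path(values_path).name} and "
            f"{Path(samples_path).name}: {sorted(extra)}"
        )
    return ExpressionMatrix(values, samples.loc[list(values.columns)])
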