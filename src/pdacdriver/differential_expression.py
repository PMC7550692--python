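"""Thresholded differential-expression calling between TP53 groups.

The DEG arm: keep genes expressed (value > 0) in strictly more than 20% of
samples, exclude genes whose mean level is below 5 in both groups, then
call differential genes with a classical two-sample Student t-test on
log2(x+1) values and a raw-scale log2 fold change, flagging genes with
P <= 0.05 and |log2FC| >= 1.  Externally produced DEG lists (e.g. from a
rank-based caller) are accepted as plain gene-list files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEG_P_THRESHOLD = 0.05
DEG_ABS_LOG2FC_THRESHOLD = 1.0
EXPRESSED_FRACTION = 0.20
MIN_LEVEL = 5.0


@dataclass(frozen=True)
class ExpressionMatrix:
    """Normalized genes × samples expression values with sample group labels.

    ``values`` is a nonnegative DataFrame indexed by gene with one column
    per sample; ``groups`` maps every sample to its group label.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene identifiers in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers in expression matrix")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing[:5]}")
        aligned = self.groups.loc[self.values.columns]
        if aligned.nunique() < 2:
            raise ValueError("expression matrix must contain at least two sample groups")
        object.__setattr__(self, "groups", aligned)

    @property
    def group_labels(self) -> list:
        return sorted(self.groups.unique())

    def group_columns(self, label: str) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == label].index]

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.groups)


def filter_expressed(matrix: ExpressionMatrix, fraction: float = EXPRESSED_FRACTION) -> ExpressionMatrix:
    """Keep genes with value > 0 in strictly more than ``fraction`` of samples."""
    if matrix.values.empty:
        raise ValueError("expression matrix is empty")
    positive_frac = (matrix.values > 0).mean(axis=1)
    return matrix.with_values(matrix.values.loc[positive_frac > fraction])


def filter_min_level(matrix: ExpressionMatrix, min_level: float = MIN_LEVEL) -> ExpressionMatrix:
    """Drop genes whose group-mean expression is below ``min_level`` in both groups."""
    labels = matrix.group_labels
    if len(labels) != 2:
        raise ValueError(f"minimum-level filter requires exactly 2 groups, got {labels}")
    mean_a = matrix.group_columns(labels[0]).mean(axis=1)
    mean_b = matrix.group_columns(labels[1]).mean(axis=1)
    keep = ~((mean_a < min_level) & (mean_b < min_level))
    return matrix.with_values(matrix.values.loc[keep])


def call_degs(
    matrix: ExpressionMatrix,
    group_a: str | None = None,
    group_b: str | None = None,
    p_threshold: float = DEG_P_THRESHOLD,
    abs_log2fc_threshold: float = DEG_ABS_LOG2FC_THRESHOLD,
) -> pd.DataFrame:
    """Per-gene t-test and fold change; returns a table sorted by P.

    The t-test is the classical equal-variance two-sample test on
    log2(value+1); the fold change is log2((mean_A+1)/(mean_B+1)) on the
    raw scale (pseudocount 1, stable at zeros).  ``passed`` is true iff
    P <= ``p_threshold`` and |log2FC| >= ``abs_log2fc_threshold``;
    ``direction`` is "up" when group A exceeds group B.
    """
    labels = matrix.group_labels
    if group_a is None or group_b is None:
        if len(labels) != 2:
            raise ValueError(f"call_degs requires exactly 2 groups, got {labels}")
        # by convention the mutant/treated group (sorts first here) is A
        group_a, group_b = labels
    a = matrix.group_columns(group_a)
    b = matrix.group_columns(group_b)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples for the t-test")

    log_a = np.log2(a.to_numpy() + 1.0)
    log_b = np.log2(b.to_numpy() + 1.0)
    _, p_values = stats.ttest_ind(log_a, log_b, axis=1, equal_var=True)
    log2fc = np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0))

    table = pd.DataFrame(
        {
            "gene": matrix.values.index,
            "log2fc": log2fc.to_numpy(),
            "p_value": p_values,
        }
    )
    table["direction"] = np.where(table["log2fc"] >= 0, "up", "down")
    table["passed"] = (table["p_value"] <= p_threshold) & (
        table["log2fc"].abs() >= abs_log2fc_threshold
    )
    return table.sort_values("p_value", kind="stable").reset_index(drop=True)


def read_deg_list(path: str | Path) -> list[str]:
    """Read an externally produced DEG list (one gene per line, or TSV
    whose first column is the gene); returns a de-duplicated ordered list."""
    path = Path(path)
    genes: list[str] = []
    seen: set[str] = set()
    n_lines = 0
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene = line.split("\t")[0].strip()
            if not gene:
                continue
            n_lines += 1
            if gene not in seen:
                seen.add(gene)
                genes.append(gene)
    if not genes:
        raise ValueError(f"DEG list {path} contains no genes")
    if n_lines != len(genes):
        logger.warning(
            "%s: %d duplicate gene entrie(s) collapsed (%d lines, %d unique)",
            path, n_lines - len(genes), n_lines, len(genes),
        )
    return genes
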