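"""Differential-expression stand-in stage.

This module turns raw count matrices into :class:`~vascrisk.data.ContrastResult`
tables with a deliberately simple, fully specified recipe:

* CPM normalization (each library scaled to one million),
* log2 fold change ``log2((meanCPM_a + 0.5) / (meanCPM_b + 0.5))``,
* Welch's two-sample t-test on ``log2(CPM + 0.5)`` per gene,
* Benjamini-Hochberg FDR across genes,
* ``mean_expr`` = overall mean CPM.

It is NOT an attempt to reproduce a negative-binomial GLM pipeline (edgeR-style
dispersion modelling, TMM normalization); it is a transparent replacement that
honours the same output contract, so every downstream stage (pathway
similarity, risk association, classification) can be exercised and validated
end to end.  The 0.5 prior count avoids infinite fold changes and log(0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import CellType, ContrastResult, DataError, ValidationError

__all__ = [
    "CountMatrix",
    "NormalizationError",
    "InsufficientReplicationError",
    "read_counts_tsv",
    "write_counts_tsv",
    "compute_cpm",
    "welch_ttest",
    "bh_adjust",
    "de_contrast",
    "count_degs",
]

PRIOR_COUNT = 0.5


class NormalizationError(DataError):
    """A sample cannot be CPM-normalized (zero total count)."""


class InsufficientReplicationError(DataError):
    """A condition has fewer than two replicates."""


@dataclass
class CountMatrix:
    """Integer gene x sample count matrix with per-sample condition labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    conditions: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x samples array")
        n_genes, n_samples = self.counts.shape
        if n_genes != len(self.gene_ids) or n_samples != len(self.sample_ids):
            raise ValidationError("counts shape does not match gene/sample id lists")
        if len(self.conditions) != n_samples:
            raise ValidationError("one condition label required per sample")
        if len(set(self.gene_ids)) != n_genes:
            raise ValidationError("gene_ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("sample_ids must be unique")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")

    def condition_columns(self, condition: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.conditions) == condition)


def read_counts_tsv(path: str | Path, conditions: Mapping[str, str] | None = None) -> CountMatrix:
    """Read a genes x samples counts TSV (first column = gene id).

    If ``conditions`` is not given, each sample's condition is inferred as the
    sample name up to the last underscore (``treated_1`` -> ``treated``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [str(s) for s in df.columns]
    if conditions is None:
        cond = [s.rsplit("_", 1)[0] for s in sample_ids]
    else:
        cond = [conditions[s] for s in sample_ids]
    return CountMatrix(
        gene_ids=[str(g) for g in df.index],
        sample_ids=sample_ids,
        conditions=cond,
        counts=df.to_numpy(),
    )


def write_counts_tsv(cm: CountMatrix, path: str | Path) -> None:
    pd.DataFrame(cm.counts, index=pd.Index(cm.gene_ids, name="gene_id"),
                 columns=cm.sample_ids).to_csv(path, sep="\t")


def compute_cpm(cm: CountMatrix) -> np.ndarray:
    """Counts-per-million: every library column scaled to sum to 1e6."""
    totals = cm.counts.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise NormalizationError(f"sample {cm.sample_ids[zero[0]]!r} has zero total count")
    return cm.counts / totals * 1e6


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t-test along the last axis; returns (t, p).

    Rows with zero variance in both groups get t = 0, p = 1 when the group
    means agree and p = 0 otherwise (the limit of an infinite t statistic).
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-identical groups
        res = stats.ttest_ind(a, b, axis=-1, equal_var=False)
        t = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
    var_a = a.var(axis=-1, ddof=1)
    var_b = b.var(axis=-1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    if np.any(degenerate):
        equal_means = np.isclose(a.mean(axis=-1), b.mean(axis=-1))
        t = np.where(degenerate, 0.0, t)
        p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    return np.squeeze(t), np.squeeze(p)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def de_contrast(
    cm: CountMatrix,
    condition_a: str,
    condition_b: str,
    treatment: str | None = None,
    cell_type: CellType | str = CellType.SMC,
) -> ContrastResult:
    """Contrast ``condition_a`` vs ``condition_b`` (positive log_fc = higher in a)."""
    cols_a = cm.condition_columns(condition_a)
    cols_b = cm.condition_columns(condition_b)
    for cond, cols in ((condition_a, cols_a), (condition_b, cols_b)):
        if cols.size < 2:
            raise InsufficientReplicationError(
                f"condition {cond!r} has {cols.size} sample(s); need >= 2"
            )
    cpm = compute_cpm(cm)
    cpm_a, cpm_b = cpm[:, cols_a], cpm[:, cols_b]
    log_fc = np.log2((cpm_a.mean(axis=1) + PRIOR_COUNT) / (cpm_b.mean(axis=1) + PRIOR_COUNT))
    _, p = welch_ttest(np.log2(cpm_a + PRIOR_COUNT), np.log2(cpm_b + PRIOR_COUNT))
    p = np.atleast_1d(p)
    fdr = bh_adjust(p)
    mean_expr = cpm[:, np.concatenate([cols_a, cols_b])].mean(axis=1)
    if treatment is None:
        treatment = f"{condition_a}_vs_{condition_b}"
    df = pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "log_fc": log_fc,
            "p_value": p,
            "fdr": fdr,
            "mean_expr": mean_expr,
        }
    )
    return ContrastResult(treatment_id=treatment, cell_type=cell_type, data=df)


def count_degs(contrast: ContrastResult, fdr_threshold: float = 0.10) -> int:
    """Number of genes with fdr <= threshold (the DEG-count rule)."""
    if not (0 < fdr_threshold <= 1):
        raise ValidationError(f"fdr_threshold must be in (0, 1], got {fdr_threshold}")
    return int((contrast.data["fdr"] <= fdr_threshold).sum())
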