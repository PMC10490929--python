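"""Pathway-level Spearman similarity between a query and reference treatments.

For a query contrast, a reference contrast and one pathway, the similarity is
the Spearman rank correlation (average ranks for ties) of log2 fold changes
over the pathway genes that (a) are present in both contrasts and (b) have a
treatment p-value below ``alpha`` in *either* contrast.  The full engine
evaluates the Cartesian product of queries x reference compounds x pathways
per cell type, keeping undefined correlations (too few genes, or zero rank
variance) as explicit records so the bookkeeping never loses a cell of the
product.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    CellType,
    ContrastResult,
    Database,
    PathwayCollection,
    ValidationError,
)

__all__ = [
    "SimilarityRecord",
    "filter_genes",
    "pathway_spearman",
    "similarity_matrix",
    "records_to_frame",
    "write_similarity",
    "read_similarity",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_GENES",
]

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_GENES = 5
MIN_GENES_FLOOR = 3


@dataclass(frozen=True)
class SimilarityRecord:
    """Spearman rho for one (query, reference, pathway, cell type) cell.

    ``rho`` is ``None`` when fewer than ``min_genes`` genes survive the filter
    or either side has zero rank variance; ``n_genes`` is the post-filter
    gene count either way.
    """

    query_id: str
    reference_id: str
    pathway_id: str
    cell_type: str
    rho: float | None
    n_genes: int


def _check_min_genes(min_genes: int) -> int:
    if min_genes < MIN_GENES_FLOOR:
        raise ValidationError(f"min_genes must be >= {MIN_GENES_FLOOR}, got {min_genes}")
    return min_genes


def _avg_ranks(a: np.ndarray) -> tuple[np.ndarray, bool]:
    """(average 1-based ranks, has_ties) — a light-weight equivalent of
    scipy.stats.rankdata(method="average") for the hot loop."""
    n = a.size
    order = np.argsort(a, kind="stable")
    sa = a[order]
    ranks = np.empty(n)
    if n == 0 or np.all(sa[1:] != sa[:-1]):
        ranks[order] = np.arange(1, n + 1)
        return ranks, False
    boundary = np.empty(n, dtype=bool)
    boundary[0] = True
    np.not_equal(sa[1:], sa[:-1], out=boundary[1:])
    grp = np.cumsum(boundary) - 1
    counts = np.bincount(grp)
    starts = np.concatenate(([0], np.cumsum(counts)[:-1]))
    avg = starts + (counts + 1) / 2.0
    ranks[order] = avg[grp]
    return ranks, True


def _spearman(x: np.ndarray, y: np.ndarray) -> float | None:
    """Spearman rho with average ranks for ties; None on zero rank variance.

    Tie-free pairs use the closed form 1 - 6*sum(d^2)/(n(n^2-1)); otherwise
    the Pearson correlation of the rank vectors (the general definition).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rx, tx = _avg_ranks(x)
    ry, ty = _avg_ranks(y)
    if not tx and not ty:
        d = rx - ry
        rho = 1.0 - 6.0 * (d @ d) / (n * (n * n - 1))
    else:
        if np.all(rx == rx[0]) or np.all(ry == ry[0]):
            return None
        rx = rx - rx.sum() / n
        ry = ry - ry.sum() / n
        denom = np.sqrt((rx @ rx) * (ry @ ry))
        if denom == 0:
            return None
        rho = (rx @ ry) / denom
    return float(min(1.0, max(-1.0, rho)))


def filter_genes(
    query: ContrastResult,
    reference: ContrastResult,
    pathway_genes: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
) -> list[str]:
    """Pathway genes present in both contrasts with p < alpha in either,
    in stable lexicographic order."""
    q = query.indexed()
    r = reference.indexed()
    genes = sorted(set(pathway_genes) & set(q.index) & set(r.index))
    if not genes:
        return []
    qp = q.loc[genes, "p_value"].to_numpy()
    rp = r.loc[genes, "p_value"].to_numpy()
    keep = (qp < alpha) | (rp < alpha)
    return [g for g, k in zip(genes, keep) if k]


def pathway_spearman(
    query: ContrastResult,
    reference: ContrastResult,
    pathway_genes: Iterable[str],
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = DEFAULT_MIN_GENES,
    pathway_id: str = "",
) -> SimilarityRecord:
    """Similarity record for one query/reference/pathway combination."""
    _check_min_genes(min_genes)
    genes = filter_genes(query, reference, pathway_genes, alpha)
    rho: float | None = None
    if len(genes) >= min_genes:
        x = query.indexed().loc[genes, "log_fc"].to_numpy()
        y = reference.indexed().loc[genes, "log_fc"].to_numpy()
        rho = _spearman(x, y)
    return SimilarityRecord(
        query_id=query.treatment_id,
        reference_id=reference.treatment_id,
        pathway_id=pathway_id,
        cell_type=query.cell_type.value,
        rho=rho,
        n_genes=len(genes),
    )


def _aligned(
    contrast: ContrastResult, all_genes: pd.Index, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(log_fc, present, significant) arrays aligned to ``all_genes``."""
    df = contrast.indexed().reindex(all_genes)
    lfc = df["log_fc"].to_numpy()
    p = df["p_value"].to_numpy()
    present = ~np.isnan(p)
    with np.errstate(invalid="ignore"):
        sig = present & (p < alpha)
    return lfc, present, sig


def similarity_matrix(
    queries: Sequence[ContrastResult],
    database: Database,
    pathways: PathwayCollection,
    cell_type: CellType | str,
    alpha: float = DEFAULT_ALPHA,
    min_genes: int = DEFAULT_MIN_GENES,
) -> list[SimilarityRecord]:
    """Evaluate the full queries x reference-compounds x pathways product.

    References are the designated (highest-concentration) treatment per
    database compound for the requested cell type.  Output order is
    deterministic: queries in the given order, then sorted pathway id, then
    sorted reference compound id.  Exactly
    ``len(queries) * n_references * n_pathways`` records are returned;
    undefined correlations are kept with ``rho=None``.
    """
    _check_min_genes(min_genes)
    ct = CellType(cell_type) if not isinstance(cell_type, CellType) else cell_type
    refs = database.references(ct)
    if not refs:
        raise ValidationError(f"database has no reference contrasts for cell type {ct.value}")
    if len(pathways) == 0:
        raise ValidationError("pathway collection is empty")
    if not queries:
        raise ValidationError("no query contrasts supplied")

    pw_ids = pathways.sorted_ids()
    pw_genes = {pw: sorted(pathways[pw].genes) for pw in pw_ids}
    all_genes = pd.Index([g for pw in pw_ids for g in pw_genes[pw]])
    slices: dict[str, slice] = {}
    start = 0
    for pw in pw_ids:
        stop = start + len(pw_genes[pw])
        slices[pw] = slice(start, stop)
        start = stop

    ref_ids = sorted(refs)
    ref_aligned = {rid: _aligned(refs[rid], all_genes, alpha) for rid in ref_ids}

    records: list[SimilarityRecord] = []
    for query in queries:
        if query.cell_type != ct:
            raise ValidationError(
                f"query {query.treatment_id!r} is {query.cell_type.value}, expected {ct.value}"
            )
        q_lfc, q_present, q_sig = _aligned(query, all_genes, alpha)
        for pw in pw_ids:
            sl = slices[pw]
            ql, qp_sig, qpres = q_lfc[sl], q_sig[sl], q_present[sl]
            for rid in ref_ids:
                r_lfc, r_present, r_sig = ref_aligned[rid]
                rl, rpres = r_lfc[sl], r_present[sl]
                mask = qpres & rpres & (qp_sig | r_sig[sl])
                n = int(mask.sum())
                rho = _spearman(ql[mask], rl[mask]) if n >= min_genes else None
                records.append(
                    SimilarityRecord(
                        query_id=query.treatment_id,
                        reference_id=rid,
                        pathway_id=pw,
                        cell_type=ct.value,
                        rho=rho,
                        n_genes=n,
                    )
                )
    return records


def records_to_frame(records: Iterable[SimilarityRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "query_id": r.query_id,
                "reference_id": r.reference_id,
                "pathway_id": r.pathway_id,
                "cell_type": r.cell_type,
                "rho": np.nan if r.rho is None else r.rho,
                "n_genes": r.n_genes,
            }
            for r in records
        ]
    )
    return df


def write_similarity(records: Iterable[SimilarityRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep=".")


def read_similarity(path: str | Path) -> list[SimilarityRecord]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    return [
        SimilarityRecord(
            query_id=str(row.query_id),
            reference_id=str(row.reference_id),
            pathway_id=str(row.pathway_id),
            cell_type=str(row.cell_type),
            rho=None if pd.isna(row.rho) else float(row.rho),
            n_genes=int(row.n_genes),
        )
        for row in df.itertuples()
    ]
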