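"""Per-pathway cardiovascular-risk association statistics.

Given the pathway-level similarity table and per-compound risk flags, this
module asks, for each (query, pathway, cell type): do risk-flagged reference
drugs correlate *more strongly* with the query than unflagged drugs?

Two one-sided tests are computed per pathway:

* **Mann-Whitney U** — are the risk group's rho values stochastically
  greater?  Exact null distribution when the combined sample is small
  (<= ``EXACT_MAX_N``) and tie-free, normal approximation with tie
  correction otherwise.
* **Fisher's exact test** — are risk drugs enriched among drugs with a
  positive pathway correlation (rho > ``rho_threshold``)?  One-sided
  hypergeometric tail; odds ratio carries an infinity marker on a zero
  denominator.

A pathway is called *shared* with the risk class when the configured
decision rule holds (default: Mann-Whitney p < alpha).  The shared-pathway
count per query is the headline summary; a gene-name randomization control
(`randomize_query`) provides the matching null.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import ContrastResult, DataError, ValidationError
from .de import bh_adjust
from .similarity import SimilarityRecord

__all__ = [
    "PathwayRiskResult",
    "DECISION_RULES",
    "EXACT_MAX_N",
    "mann_whitney_risk",
    "fisher_positive_enrichment",
    "risk_association",
    "count_shared_pathways",
    "randomize_query",
    "null_band",
    "results_to_frame",
]

EXACT_MAX_N = 20
DECISION_RULES = ("mann_whitney", "fisher", "both")


class RuleError(DataError):
    """Unknown shared-pathway decision rule."""


@dataclass(frozen=True)
class PathwayRiskResult:
    """Risk-association statistics for one (query, pathway, cell type).

    ``u_stat``/``p_mw`` or ``odds_ratio``/``p_fisher`` are NaN when the
    corresponding test is undefined (an empty label group after dropping
    undefined correlations).
    """

    query_id: str
    pathway_id: str
    cell_type: str
    n_risk: int
    n_nonrisk: int
    u_stat: float
    p_mw: float
    odds_ratio: float
    p_fisher: float
    shared: bool


def mann_whitney_risk(
    risk_rhos: Sequence[float],
    nonrisk_rhos: Sequence[float],
    exact_max_n: int = EXACT_MAX_N,
) -> tuple[float, float] | None:
    """One-sided Mann-Whitney U (alternative: risk rhos greater).

    Returns ``(U, p)`` or ``None`` when either group is empty.  The exact
    null distribution is used for tie-free samples with combined size
    <= ``exact_max_n``; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(risk_rhos, dtype=float)
    y = np.asarray(nonrisk_rhos, dtype=float)
    if x.size == 0 or y.size == 0:
        return None
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (not has_ties and combined.size <= exact_max_n) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_positive_enrichment(
    risk_rhos: Sequence[float],
    nonrisk_rhos: Sequence[float],
    rho_threshold: float = 0.0,
) -> tuple[float, float] | None:
    """One-sided Fisher's exact test for enrichment of risk drugs among
    drugs with rho > ``rho_threshold``.

    Returns ``(odds_ratio, p)`` or ``None`` on an all-empty table.  The odds
    ratio is ``(a*d)/(b*c)`` with ``inf`` on a zero denominator (and NaN for
    the indeterminate 0/0 case).
    """
    x = np.asarray(risk_rhos, dtype=float)
    y = np.asarray(nonrisk_rhos, dtype=float)
    a = int((x > rho_threshold).sum())
    b = x.size - a
    c = int((y > rho_threshold).sum())
    d = y.size - c
    if a + b + c + d == 0:
        return None
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    num, den = a * d, b * c
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan
    return odds, float(p)


def _shared_call(p_mw: float, p_fisher: float, rule: str, alpha: float) -> bool:
    if rule == "mann_whitney":
        return bool(p_mw < alpha) if not math.isnan(p_mw) else False
    if rule == "fisher":
        return bool(p_fisher < alpha) if not math.isnan(p_fisher) else False
    if rule == "both":
        return (
            not math.isnan(p_mw) and not math.isnan(p_fisher)
            and p_mw < alpha and p_fisher < alpha
        )
    raise RuleError(f"unknown decision rule {rule!r}; expected one of {DECISION_RULES}")


def _query_compound(query_id: str) -> str:
    return query_id.rpartition("@")[0] or query_id


def risk_association(
    records: Iterable[SimilarityRecord],
    risk_labels: Mapping[str, bool],
    decision_rule: str = "mann_whitney",
    alpha: float = 0.05,
    rho_threshold: float = 0.0,
    exclude_self: bool = True,
    correction: str | None = None,
) -> list[PathwayRiskResult]:
    """Group similarity records by (query, pathway, cell type) and test each.

    Undefined correlations are dropped before testing; a reference matching
    the query's own compound id is excluded when ``exclude_self``.  With
    ``correction="bh"`` the decision rule is applied to Benjamini-Hochberg
    adjusted p-values across the pathways of each (query, cell type).
    """
    if decision_rule not in DECISION_RULES:
        raise RuleError(f"unknown decision rule {decision_rule!r}; expected one of {DECISION_RULES}")
    if correction not in (None, "bh"):
        raise RuleError(f"unknown correction {correction!r}; expected None or 'bh'")
    if not (0 < alpha < 1):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")

    groups: dict[tuple[str, str, str], list[SimilarityRecord]] = defaultdict(list)
    for rec in records:
        groups[(rec.query_id, rec.pathway_id, rec.cell_type)].append(rec)

    results: list[PathwayRiskResult] = []
    for (query_id, pathway_id, cell_type), recs in sorted(groups.items()):
        self_id = _query_compound(query_id)
        risk_vals: list[float] = []
        nonrisk_vals: list[float] = []
        for rec in recs:
            if rec.rho is None:
                continue
            if exclude_self and rec.reference_id == self_id:
                continue
            if rec.reference_id not in risk_labels:
                raise ValidationError(f"no risk label for reference {rec.reference_id!r}")
            (risk_vals if risk_labels[rec.reference_id] else nonrisk_vals).append(rec.rho)
        mw = mann_whitney_risk(risk_vals, nonrisk_vals)
        fisher = fisher_positive_enrichment(risk_vals, nonrisk_vals, rho_threshold)
        u_stat, p_mw = mw if mw is not None else (math.nan, math.nan)
        odds, p_fisher = fisher if fisher is not None else (math.nan, math.nan)
        results.append(
            PathwayRiskResult(
                query_id=query_id,
                pathway_id=pathway_id,
                cell_type=cell_type,
                n_risk=len(risk_vals),
                n_nonrisk=len(nonrisk_vals),
                u_stat=u_stat,
                p_mw=p_mw,
                odds_ratio=odds,
                p_fisher=p_fisher,
                shared=False,  # filled below (possibly after correction)
            )
        )

    # apply the decision rule, optionally on BH-adjusted p per (query, cell type)
    by_group: dict[tuple[str, str], list[int]] = defaultdict(list)
    for i, res in enumerate(results):
        by_group[(res.query_id, res.cell_type)].append(i)
    for idxs in by_group.values():
        p_mw = np.array([results[i].p_mw for i in idxs])
        p_f = np.array([results[i].p_fisher for i in idxs])
        if correction == "bh":
            p_mw = _bh_with_nan(p_mw)
            p_f = _bh_with_nan(p_f)
        for j, i in enumerate(idxs):
            results[i] = replace(
                results[i], shared=_shared_call(p_mw[j], p_f[j], decision_rule, alpha)
            )
    return results


def _bh_with_nan(p: np.ndarray) -> np.ndarray:
    out = np.full_like(p, np.nan)
    mask = ~np.isnan(p)
    if mask.any():
        out[mask] = bh_adjust(p[mask])
    return out


def count_shared_pathways(
    results: Iterable[PathwayRiskResult],
    query_id: str,
    cell_type: str,
    decision_rule: str = "mann_whitney",
    alpha: float = 0.05,
) -> int:
    """Number of pathways called shared for one query and cell type."""
    if decision_rule not in DECISION_RULES:
        raise RuleError(f"unknown decision rule {decision_rule!r}; expected one of {DECISION_RULES}")
    count = 0
    for res in results:
        if res.query_id == query_id and res.cell_type == cell_type:
            count += _shared_call(res.p_mw, res.p_fisher, decision_rule, alpha)
    return count


def randomize_query(query: ContrastResult, seed: int) -> ContrastResult:
    """Gene-name randomization control: permute the gene_id column uniformly
    at random against the statistics rows, leaving the multiset of
    (log_fc, p, fdr, mean_expr) untouched."""
    rng = np.random.default_rng(seed)
    df = query.data.copy()
    perm = rng.permutation(len(df))
    df["gene_id"] = df["gene_id"].to_numpy()[perm]
    return ContrastResult(
        treatment_id=f"{query.treatment_id}#rand{seed}",
        cell_type=query.cell_type,
        data=df,
    )


def null_band(n_pathways: int, alpha: float = 0.05, level: float = 0.99) -> tuple[int, int]:
    """Central ``level`` interval of Binomial(n_pathways, alpha): the range of
    shared-pathway counts compatible with no risk association."""
    lo = int(stats.binom.ppf((1 - level) / 2, n_pathways, alpha))
    hi = int(stats.binom.ppf(1 - (1 - level) / 2, n_pathways, alpha))
    return lo, hi


def results_to_frame(results: Iterable[PathwayRiskResult]) -> pd.DataFrame:
    df = pd.DataFrame([res.__dict__ for res in results])
    if not df.empty:
        df["neg_log10_p_mw"] = -np.log10(df["p_mw"].clip(lower=1e-300))
    return df
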