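"""Reference-based per-cell stemness scoring and its group comparisons.

The score compares each cell against a stem-vs-fibroblast differential
expression reference (fibroblasts vs fibroblast-derived iPS cells): the
top ``k`` up-regulated genes (up in stem cells) and top ``k`` down-
regulated genes among the significant rows define a stem list and a
fibroblast list. For each cell and each list,

    identity = n + sum(logTPM)

where ``n`` is the number of list genes with a raw count > 0 and the sum
runs over the log-normalized values (ln(1 + counts-per-scale)) of all list
genes present in the matrix. The per-cell score is

    stemness = (stem identity + 1) / (fibroblast identity + 1)

which is 1 for a cell expressing none of the listed genes. An alternative
summation mode restricted to expressed genes only (ln of raw
counts-per-scale, no pseudocount) is available via ``expressed_only``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import CountMatrix, NormalizedMatrix
from .markers import rank_sum_test

__all__ = [
    "select_signature_genes",
    "stemness_score",
    "compare_stemness",
    "highest_among_groups",
    "StemnessResult",
]


@dataclass
class StemnessResult:
    """Per-cell stemness table plus the gene lists actually used."""

    table: pd.DataFrame  # cell_id, n_up_expressed, sum_log_up, stem_identity,
    #                      n_down_expressed, sum_log_down, fib_identity, score
    up_used: list[str]
    down_used: list[str]
    up_missing: list[str]
    down_missing: list[str]
    mode: str = "all-listed ln(1+CP)"


def select_signature_genes(
    ref: pd.DataFrame,
    k: int = 250,
    alpha: float = 0.05,
) -> tuple[list[str], list[str]]:
    """Top-k up- and down-regulated significant genes from a DE reference.

    Rows with p_adj < ``alpha`` are eligible; the up list is the first k by
    effect descending, the down list the first k by effect ascending. Ties
    at the boundary break by (p_adj ascending, symbol lexicographic). If a
    direction has fewer than k significant genes all of them are returned
    with a warning.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if ref.empty:
        raise ValueError("reference DE table is empty")
    for col in ("symbol", "effect", "p_adj"):
        if col not in ref.columns:
            raise ValueError(f"reference table lacks column {col!r}")
    sig = ref[ref["p_adj"] < alpha]
    up_pool = sig[sig["effect"] > 0].sort_values(
        ["effect", "p_adj", "symbol"], ascending=[False, True, True]
    )
    down_pool = sig[sig["effect"] < 0].sort_values(
        ["effect", "p_adj", "symbol"], ascending=[True, True, True]
    )
    for name, pool in (("up", up_pool), ("down", down_pool)):
        if len(pool) < k:
            warnings.warn(
                f"only {len(pool)} significant {name}-regulated genes available "
                f"(requested {k})",
                stacklevel=2,
            )
    return list(up_pool["symbol"].head(k)), list(down_pool["symbol"].head(k))


def _list_stats(
    norm: NormalizedMatrix, raw: CountMatrix, genes: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    symbols = pd.Index(norm.gene_symbols)
    present = [g for g in genes if g in symbols]
    missing = [g for g in genes if g not in symbols]
    if not present:
        raise ValueError("no listed gene present in the matrix")
    cols = symbols.get_indexer(present)
    n_expr = np.asarray((raw.counts[:, cols] > 0).sum(axis=1)).ravel()
    sum_log = np.asarray(norm.values[:, cols].sum(axis=1)).ravel()
    return n_expr.astype(int), sum_log, present, missing


def _list_stats_expressed_only(
    norm: NormalizedMatrix, raw: CountMatrix, genes: list[str]
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Alternative mode: sum ln(counts-per-scale) over expressed list genes."""
    symbols = pd.Index(norm.gene_symbols)
    present = [g for g in genes if g in symbols]
    missing = [g for g in genes if g not in symbols]
    if not present:
        raise ValueError("no listed gene present in the matrix")
    cols = symbols.get_indexer(present)
    sub = raw.counts[:, cols].tocoo().astype(np.float64)
    totals = raw.cell_totals()
    logs = np.log(sub.data / totals[sub.row] * norm.scale)
    n_expr = np.zeros(raw.n_cells, dtype=int)
    sum_log = np.zeros(raw.n_cells)
    np.add.at(n_expr, sub.row, 1)
    np.add.at(sum_log, sub.row, logs)
    return n_expr, sum_log, present, missing


def stemness_score(
    norm: NormalizedMatrix,
    raw: CountMatrix,
    up: list[str],
    down: list[str],
    expressed_only: bool = False,
) -> StemnessResult:
    """Per-cell stem/fibroblast identities and the stemness score.

    ``up`` are genes up-regulated in stem cells (the stem list), ``down``
    the fibroblast list. Matrices must share axes. Genes absent from the
    matrix contribute nothing and are reported in the result.
    """
    if norm.n_cells != raw.n_cells or norm.n_genes != raw.n_genes:
        raise ValueError("normalized and raw matrices must share axes")
    if not up or not down:
        raise ValueError("both gene lists must be non-empty")
    stat = _list_stats_expressed_only if expressed_only else _list_stats
    n_up, s_up, up_used, up_missing = stat(norm, raw, up)
    n_down, s_down, down_used, down_missing = stat(norm, raw, down)
    stem_identity = n_up + s_up
    fib_identity = n_down + s_down
    score = (stem_identity + 1.0) / (fib_identity + 1.0)
    table = pd.DataFrame(
        {
            "cell_id": norm.cell_ids,
            "n_up_expressed": n_up,
            "sum_log_up": s_up,
            "stem_identity": stem_identity,
            "n_down_expressed": n_down,
            "sum_log_down": s_down,
            "fib_identity": fib_identity,
            "score": score,
        }
    )
    return StemnessResult(
        table=table,
        up_used=up_used,
        down_used=down_used,
        up_missing=up_missing,
        down_missing=down_missing,
        mode="expressed-only ln(CP)" if expressed_only else "all-listed ln(1+CP)",
    )


def compare_stemness(
    scores: np.ndarray,
    grouping: np.ndarray | pd.Series,
    group_a: str,
    group_b: str,
    sided: str = "two-sided",
) -> tuple[float, float]:
    """Unpaired Wilcoxon rank-sum comparison of scores between two groups.

    ``sided`` is "two-sided" or "one-sided-greater" (alternative: group_a
    stochastically greater than group_b). Returns (U statistic, p).
    """
    scores = np.asarray(scores, dtype=float)
    grouping = np.asarray(grouping)
    a = scores[grouping == group_a]
    b = scores[grouping == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    alternative = {"two-sided": "two-sided", "one-sided-greater": "greater"}[sided]
    return rank_sum_test(a, b, alternative=alternative)


def highest_among_groups(
    scores: np.ndarray,
    grouping: np.ndarray | pd.Series,
    focal: str,
) -> pd.DataFrame:
    """One-vs-rest-of-groups one-sided comparisons: is ``focal`` highest?

    For each other group, tests focal > that group (one-sided rank-sum).
    Returns a table (other, median_focal, median_other, U, p).
    """
    grouping = np.asarray(grouping)
    scores = np.asarray(scores, dtype=float)
    others = [g for g in pd.unique(grouping) if g != focal]
    if not others:
        raise ValueError("no other groups to compare against")
    rows = []
    focal_scores = scores[grouping == focal]
    for g in others:
        other_scores = scores[grouping == g]
        u, p = rank_sum_test(focal_scores, other_scores, alternative="greater")
        rows.append(
            {
                "other": g,
                "median_focal": float(np.median(focal_scores)),
                "median_other": float(np.median(other_scores)),
                "U": u,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
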