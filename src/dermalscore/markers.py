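"""One-vs-rest marker statistics, signature scores and over-representation.

Marker detection follows the convention of one-vs-rest Wilcoxon rank-sum
testing on log-normalized expression: for every gene expressed in at least
``min_pct`` of either group, a two-sided rank-sum p-value (normal
approximation with midrank tie correction and continuity correction; exact
distribution for small tie-free groups), a log fold-change on de-logged
means with pseudocount 1, and a Bonferroni adjustment over the tested
genes. Signature scores are per-cell means of normalized expression over a
gene list; dot-plot summaries report percent-expressed and average
expression per cluster; over-representation of a query gene set in a term
is a hypergeometric upper-tail test with BH adjustment across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .io_qc import NormalizedMatrix

__all__ = [
    "GeneSignature",
    "rank_sum_test",
    "find_markers",
    "signature_score",
    "dotplot_summary",
    "enrichment_test",
    "enrichment_table",
    "bh_adjust",
]


@dataclass
class GeneSignature:
    name: str
    genes: list[str]
    direction: str = "up"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")

    @staticmethod
    def read_tsv(path) -> list["GeneSignature"]:
        """Two-column TSV (name, gene), one row per signature member."""
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "gene"], dtype=str)
        return [
            GeneSignature(name=str(name), genes=list(grp["gene"]))
            for name, grp in df.groupby("name", sort=False)
        ]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def rank_sum_test(
    x: np.ndarray,
    y: np.ndarray,
    alternative: str = "two-sided",
    exact_max_n: int = 25,
) -> tuple[float, float]:
    """Unpaired Wilcoxon rank-sum (Mann-Whitney) test of x vs y.

    Uses the exact null distribution when both groups are small
    (combined n <= ``exact_max_n``) and the data are tie-free, so small-
    sample p-values coincide with full enumeration over group assignments;
    otherwise the normal approximation with midrank tie correction and
    continuity correction. Returns (U statistic of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return float(len(x) * len(y) / 2), 1.0
    tie_free = len(np.unique(combined)) == len(combined)
    if tie_free and len(combined) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _expm1_means(values: sp.csr_matrix, mask: np.ndarray) -> np.ndarray:
    """Per-gene mean of (e^value - 1) over the masked cells."""
    sub = values[mask]
    e = sub.copy()
    e.data = np.expm1(e.data)
    return np.asarray(e.mean(axis=0)).ravel()


def find_markers(
    norm: NormalizedMatrix,
    labels: np.ndarray | pd.Series,
    cluster: str,
    min_pct: float = 0.1,
) -> pd.DataFrame:
    """One-vs-rest marker statistics for ``cluster``.

    Genes expressed in >= ``min_pct`` of either the cluster or the rest are
    tested. Columns: gene, log_fc (natural log of de-logged means with
    pseudocount 1), p, p_adj (Bonferroni over tested genes), pct_in,
    pct_out. Sorted by p then descending log_fc.
    """
    labels = np.asarray(labels)
    if len(labels) != norm.n_cells:
        raise ValueError("labels length must match the number of cells")
    in_mask = labels == cluster
    if not in_mask.any():
        raise ValueError(f"cluster {cluster!r} not present in labels")
    n_in, n_out = int(in_mask.sum()), int((~in_mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError("need at least 2 cells in and out of the cluster")

    values = norm.values.tocsc()
    pct_in = np.asarray((values[in_mask] > 0).mean(axis=0)).ravel()
    pct_out = np.asarray((values[~in_mask] > 0).mean(axis=0)).ravel()
    tested = (pct_in >= min_pct) | (pct_out >= min_pct)
    idx = np.flatnonzero(tested)
    if len(idx) == 0:
        return pd.DataFrame(
            columns=["gene", "log_fc", "p", "p_adj", "pct_in", "pct_out"]
        )

    mean_in = _expm1_means(values[:, idx], in_mask)
    mean_out = _expm1_means(values[:, idx], ~in_mask)
    log_fc = np.log((mean_in + 1) / (mean_out + 1))

    n_total = n_in + n_out
    if n_total <= 25:
        dense = np.asarray(values[:, idx].todense())
        pvals = np.array(
            [
                rank_sum_test(dense[in_mask, j], dense[~in_mask, j])[1]
                for j in range(dense.shape[1])
            ]
        )
    else:
        dense = np.asarray(values[:, idx].todense())
        res = stats.mannwhitneyu(
            dense[in_mask],
            dense[~in_mask],
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
            axis=0,
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        # all-tied genes: zero rank variance, define p = 1
        allsame = np.array(
            [len(np.unique(dense[:, j])) == 1 for j in range(dense.shape[1])]
        )
        pvals = np.where(allsame | ~np.isfinite(pvals), 1.0, pvals)

    out = pd.DataFrame(
        {
            "gene": np.asarray(norm.gene_symbols)[idx],
            "log_fc": log_fc,
            "p": pvals,
            "p_adj": np.minimum(pvals * len(idx), 1.0),
            "pct_in": pct_in[idx],
            "pct_out": pct_out[idx],
        }
    )
    return out.sort_values(["p", "log_fc"], ascending=[True, False], ignore_index=True)


def signature_score(
    norm: NormalizedMatrix, sig: GeneSignature
) -> tuple[np.ndarray, list[str]]:
    """Per-cell mean normalized expression over the signature's present genes.

    Returns (scores, missing genes). Raises if no signature gene is in the
    matrix namespace.
    """
    symbols = pd.Index(norm.gene_symbols)
    present = [g for g in sig.genes if g in symbols]
    missing = [g for g in sig.genes if g not in symbols]
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} present in the matrix")
    cols = symbols.get_indexer(present)
    scores = np.asarray(norm.values[:, cols].mean(axis=1)).ravel()
    return scores, missing


def dotplot_summary(
    norm: NormalizedMatrix,
    labels: np.ndarray | pd.Series,
    genes: list[str] | None = None,
    signatures: list[GeneSignature] | None = None,
) -> pd.DataFrame:
    """Percent-expressed and average-expression per (cluster, feature).

    For genes, percent expressed counts cells with count > 0 and average
    expression is the mean normalized value in the cluster; for signatures
    the score replaces the value (percent counts score > 0).
    """
    labels = np.asarray(labels)
    if len(labels) != norm.n_cells:
        raise ValueError("labels must cover all cells")
    clusters = pd.unique(labels)
    feats: list[tuple[str, np.ndarray]] = []
    if genes:
        symbols = pd.Index(norm.gene_symbols)
        for g in genes:
            if g in symbols:
                col = np.asarray(
                    norm.values[:, symbols.get_loc(g)].todense()
                ).ravel()
            else:
                col = np.zeros(norm.n_cells)
            feats.append((g, col))
    for sig in signatures or []:
        scores, _ = signature_score(norm, sig)
        feats.append((sig.name, scores))
    if not feats:
        raise ValueError("provide genes and/or signatures")

    rows = []
    for cl in clusters:
        mask = labels == cl
        if not mask.any():
            raise ValueError(f"empty cluster {cl!r}")
        for name, col in feats:
            v = col[mask]
            rows.append(
                {
                    "cluster": cl,
                    "feature": name,
                    "pct_expressed": 100.0 * float((v > 0).mean()),
                    "avg_expression": float(v.mean()),
                }
            )
    return pd.DataFrame(rows)


def enrichment_test(
    query: set[str] | list[str],
    term: set[str] | list[str],
    universe: set[str] | list[str],
) -> tuple[float, float]:
    """Hypergeometric over-representation of ``term`` genes in ``query``.

    p = P(overlap >= observed) drawing |query| genes from the universe;
    fold enrichment = (overlap/|query|) / (|term|/|universe|).
    """
    query, term, universe = set(query), set(term), set(universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= universe:
        raise ValueError("query is not contained in the universe")
    if not term <= universe:
        raise ValueError("term is not contained in the universe")
    M, n, N = len(universe), len(term), len(query)
    k = len(query & term)
    p = float(stats.hypergeom.sf(k - 1, M, n, N))
    if n == 0:
        return min(p, 1.0), np.nan
    fold = (k / N) / (n / M)
    return min(p, 1.0), fold


def enrichment_table(
    query: set[str] | list[str],
    terms: dict[str, set[str] | list[str]],
    universe: set[str] | list[str],
) -> pd.DataFrame:
    """enrichment_test over many terms with BH adjustment across terms."""
    rows = []
    for name, term in terms.items():
        p, fold = enrichment_test(query, term, universe)
        rows.append(
            {
                "term": name,
                "overlap": len(set(query) & set(term)),
                "term_size": len(set(term)),
                "p": p,
                "fold_enrichment": fold,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    return df.sort_values("p", ignore_index=True)
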