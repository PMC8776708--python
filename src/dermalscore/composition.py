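"""Age-related cluster-composition statistics.

Each cluster is tested one-vs-rest: does a cell's odds of belonging to the
cluster differ between old and young donors? The 2x2 table (old in / old
out / young in / young out) feeds a two-sided Fisher's exact test (the
point-probability scan rule) and a cross-product odds ratio reported in an
explicit orientation — old-enriched (odds(old)/odds(young)) when the
cluster grows with age, young-enriched (the reciprocal) when it shrinks —
with a Woolf logit 95% CI (Haldane 0.5 correction when any cell is zero).
Donor-level analyses compare per-donor cluster fractions between age
groups by an unpaired two-tailed t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "composition_table",
    "fisher_or",
    "composition_analysis",
    "fraction_test",
    "donor_fractions",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 age x cluster-membership table.

    a: old cells in cluster, b: old cells outside, c: young cells in
    cluster, d: young cells outside.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def composition_table(
    meta: pd.DataFrame,
    cluster: str,
    cluster_col: str = "cluster",
    group_col: str = "age_group",
    old_label: str = "old",
    young_label: str = "young",
) -> ContingencyTable:
    """Cross-tabulate age group x membership of ``cluster``."""
    groups = meta[group_col].to_numpy()
    clusters = meta[cluster_col].to_numpy()
    if cluster not in clusters:
        raise ValueError(f"cluster {cluster!r} absent from {cluster_col!r}")
    is_old = groups == old_label
    is_young = groups == young_label
    if not is_old.any() or not is_young.any():
        raise ValueError("need at least one cell in each age group")
    in_cl = clusters == cluster
    return ContingencyTable(
        a=int((is_old & in_cl).sum()),
        b=int((is_old & ~in_cl).sum()),
        c=int((is_young & in_cl).sum()),
        d=int((is_young & ~in_cl).sum()),
    )


def fisher_or(
    t: ContingencyTable,
    orientation: str = "old-enriched",
    z: float = 1.959963984540054,
) -> dict:
    """Two-sided Fisher's exact p and oriented cross-product odds ratio.

    orientation "old-enriched" reports odds(old in cluster)/odds(young in
    cluster) = (a d)/(b c); "young-enriched" the reciprocal, so OR > 1
    reads "young-enriched". The 95% CI is Woolf's logit interval
    ln OR +/- z sqrt(1/a+1/b+1/c+1/d); when any cell is zero the Haldane
    0.5 correction is applied to all four cells (for both OR and CI, which
    keeps the estimate finite and inside its interval).
    """
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        raise ValueError("empty row or column margin")
    if orientation not in ("old-enriched", "young-enriched"):
        raise ValueError(f"unknown orientation {orientation!r}")

    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")

    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    haldane = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_old = (a * d) / (b * c)
    if orientation == "young-enriched":
        or_old = 1.0 / or_old
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = float(np.exp(np.log(or_old) - z * se))
    ci_high = float(np.exp(np.log(or_old) + z * se))
    return {
        "a": t.a,
        "b": t.b,
        "c": t.c,
        "d": t.d,
        "orientation": orientation,
        "OR": float(or_old),
        "ci_low": ci_low,
        "ci_high": ci_high,
        "p": float(p),
        "haldane": haldane,
    }


def composition_analysis(
    meta: pd.DataFrame,
    orientations: dict[str, str] | None = None,
    cluster_col: str = "cluster",
    group_col: str = "age_group",
) -> pd.DataFrame:
    """One-vs-rest Fisher OR analysis for every cluster.

    ``orientations`` maps cluster -> orientation; unspecified clusters are
    auto-oriented so OR >= 1 (old-enriched if the old odds are larger).
    """
    orientations = orientations or {}
    rows = []
    for cl in pd.unique(meta[cluster_col]):
        t = composition_table(meta, cl, cluster_col=cluster_col, group_col=group_col)
        ori = orientations.get(cl)
        if ori is None:
            odds_old = (t.a + 0.5) * (t.d + 0.5) / ((t.b + 0.5) * (t.c + 0.5))
            ori = "old-enriched" if odds_old >= 1 else "young-enriched"
        row = fisher_or(t, orientation=ori)
        row["cluster"] = cl
        rows.append(row)
    cols = ["cluster", "a", "b", "c", "d", "orientation", "OR", "ci_low", "ci_high", "p"]
    return pd.DataFrame(rows)[cols]


def donor_fractions(
    meta: pd.DataFrame,
    cluster: str,
    cluster_col: str = "cluster",
    donor_col: str = "donor",
    group_col: str = "age_group",
) -> pd.DataFrame:
    """Per-donor fraction of cells belonging to ``cluster``."""
    in_cl = (meta[cluster_col] == cluster).groupby(meta[donor_col]).mean()
    grp = meta.groupby(donor_col)[group_col].first()
    return pd.DataFrame({"fraction": in_cl, "age_group": grp}).rename_axis("donor")


def fraction_test(
    fractions: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
    group_a: str = "young",
    group_b: str = "old",
    welch: bool = False,
) -> dict:
    """Two-tailed unpaired t-test on per-donor cluster fractions.

    Equal-variance (Student) by default, Welch behind the flag. Also
    reports each group's mean +/- SEM.
    """
    fractions = np.asarray(fractions, dtype=float)
    groups = np.asarray(groups)
    x = fractions[groups == group_a]
    y = fractions[groups == group_b]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 donors per group")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    if np.allclose(x, x[0]) and np.allclose(y, y[0]) and np.isclose(x[0], y[0]):
        return {
            "t": 0.0, "p": 1.0,
            "mean_a": float(x.mean()), "sem_a": float(stats.sem(x)),
            "mean_b": float(y.mean()), "sem_b": float(stats.sem(y)),
        }
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_a": float(x.mean()),
        "sem_a": float(stats.sem(x)),
        "mean_b": float(y.mean()),
        "sem_b": float(stats.sem(y)),
    }
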