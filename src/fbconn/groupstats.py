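"""Two-group comparison of state fraction rates with FDR control.

For each connectivity state the per-subject fraction rates of the two
groups are compared with a two-sample test (Welch's unequal-variance
t-test by default; Mann-Whitney U as a distribution-free option).  Raw
p-values are corrected with the Benjamini-Hochberg step-up procedure,
with the family being the set of states (per band, when comparing
band-resolved fraction rates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .states import FractionRateTable

__all__ = ["GroupComparisonResult", "fdr_correct", "compare_fraction_rates"]


@dataclass
class GroupComparisonResult:
    """Tidy per-state (x band) comparison table plus family metadata."""

    table: pd.DataFrame     # state, [band,] mean_<a>, mean_<b>, statistic, raw_p, adjusted_p, significant
    group_labels: tuple[str, str]
    q_level: float
    n_comparisons: int
    test: str


def fdr_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    Adjusted values are monotone in the p-value ranking and capped at 1;
    a comparison is significant when its adjusted p-value is below ``q``.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a non-empty 1-D sequence")
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return adjusted, reject


def _two_sample(a: np.ndarray, b: np.ndarray, test: str) -> tuple[float, float]:
    if np.array_equal(np.sort(a), np.sort(b)) and np.ptp(a) == 0 and np.ptp(b) == 0:
        return 0.0, 1.0     # both groups constant and equal: no evidence by definition
    if test == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
    elif test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}; use 'welch' or 'mannwhitney'")
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(p):    # zero variance in both groups with equal means
        stat, p = 0.0, 1.0
    return stat, p


def compare_fraction_rates(
    table: FractionRateTable,
    groups: dict[str, str],
    scope: str = "overall",
    test: str = "welch",
    q: float = 0.05,
) -> GroupComparisonResult:
    """Compare per-state fraction rates between exactly two subject groups.

    ``scope='overall'`` compares the band-pooled fractions with the FDR
    family spanning all states; ``scope='per_band'`` compares within each
    band, correcting across states separately per band.
    """
    if scope not in ("overall", "per_band"):
        raise ValueError("scope must be 'overall' or 'per_band'")
    df = (table.overall if scope == "overall" else table.per_band).copy()
    df["group"] = df["subject"].map(groups)
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "subject"].unique())
        raise ValueError(f"subjects without a group label: {missing}")
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two group labels, got {labels}")
    la, lb = labels
    for lab in labels:
        n = df.loc[df["group"] == lab, "subject"].nunique()
        if n < 2:
            raise ValueError(f"group {lab!r} has {n} subject(s); need at least 2")

    family_cols = ["band"] if scope == "per_band" else []
    rows = []
    for keys, sub in df.groupby(family_cols + ["state"]) if family_cols else (
        ((s,), g) for s, g in df.groupby("state")
    ):
        a = sub.loc[sub["group"] == la, "fraction"].to_numpy()
        b = sub.loc[sub["group"] == lb, "fraction"].to_numpy()
        stat, p = _two_sample(a, b, test)
        row = {"state": keys[-1], f"mean_{la}": a.mean(), f"mean_{lb}": b.mean(),
               "statistic": stat, "raw_p": p}
        if family_cols:
            row["band"] = keys[0]
        rows.append(row)
    out = pd.DataFrame(rows)

    # BH per family: across states (within band for per_band scope)
    out["adjusted_p"] = np.nan
    out["significant"] = False
    families = out.groupby("band") if family_cols else [(None, out)]
    for _, fam in families:
        adj, rej = fdr_correct(fam["raw_p"].to_numpy(), q=q)
        out.loc[fam.index, "adjusted_p"] = adj
        out.loc[fam.index, "significant"] = rej

    n_states = out["state"].nunique()
    order = (family_cols + ["state"]) if family_cols else ["state"]
    out = out.sort_values(order).reset_index(drop=True)
    front = order + [f"mean_{la}", f"mean_{lb}", "statistic", "raw_p", "adjusted_p", "significant"]
    return GroupComparisonResult(
        table=out[front],
        group_labels=(la, lb),
        q_level=q,
        n_comparisons=n_states,
        test=test,
    )
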