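"""Normality assessment and rank-based between-partition comparisons.

Most CBC analytes are non-normally distributed, so between-group
comparisons are rank-based throughout: Mann-Whitney U for two groups
(pregnant vs non-pregnant, and each trimester pair) and Kruskal-Wallis
for the three-way trimester comparison, with Kolmogorov-Smirnov
normality checks as a descriptive preliminary.  Decisions are two-sided
at alpha = 0.05 by default and no multiplicity adjustment is applied to
the pairwise trimester tests (a Bonferroni option exists, off by
default).

The KS test is run against a normal with mean/SD estimated from the data
itself, which makes the asymptotic p-value conservative; the
small-sample corrected (Lilliefors) variant is available behind
``corrected=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "comparison_table",
    "kruskal_wallis",
    "ks_normality",
    "mann_whitney_u",
]

PREGNANT = ("T1", "T2", "T3")


@dataclass(frozen=True)
class ComparisonResult:
    analyte_name: str | None
    label: str
    test: str  # "KS-normality" | "Mann-Whitney U" | "Kruskal-Wallis"
    statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def p_display(self) -> str:
        """p to 4 decimals with a display floor of "<0.0001"."""
        return "<0.0001" if self.p_value < 0.0001 else f"{self.p_value:.4f}"


def ks_normality(
    values: np.ndarray,
    *,
    corrected: bool = False,
    alpha: float = 0.05,
    analyte_name: str | None = None,
) -> ComparisonResult:
    """Kolmogorov-Smirnov test against a fitted normal.

    The statistic is ``sup |ECDF - Phi((x - mean)/sd)|``.  A
    zero-variance vector is degenerate and reported as maximally
    non-normal (statistic 1, p = 0).  ``corrected=True`` uses the
    Lilliefors small-sample distribution for the p-value.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values for a normality check")
    sd = np.std(values, ddof=1)
    if sd < 1e-12 * max(1.0, abs(float(np.mean(values)))):
        return ComparisonResult(
            analyte_name=analyte_name, label="normality",
            test="KS-normality", statistic=1.0, p_value=0.0, alpha=alpha,
        )
    if corrected:
        from statsmodels.stats.diagnostic import lilliefors

        stat, p = lilliefors(values, dist="norm")
    else:
        stat, p = stats.kstest(values, "norm", args=(np.mean(values), sd))
    return ComparisonResult(
        analyte_name=analyte_name, label="normality", test="KS-normality",
        statistic=float(stat), p_value=float(p), alpha=alpha,
    )


def mann_whitney_u(
    x: np.ndarray,
    y: np.ndarray,
    *,
    use_continuity: bool = True,
    method: str = "auto",
    alpha: float = 0.05,
    label: str = "",
    analyte_name: str | None = None,
) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    ``method="auto"`` computes the exact null distribution when the
    pooled sample is small (<= 14) and tie-free, and otherwise uses the
    normal approximation with tie-corrected variance and (by default) a
    continuity correction.  Two samples with no rank separation at all
    (every value identical) return ``U = n_x n_y / 2`` and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return ComparisonResult(
            analyte_name=analyte_name, label=label, test="Mann-Whitney U",
            statistic=x.size * y.size / 2.0, p_value=1.0, alpha=alpha,
        )
    if method == "auto":
        ties = np.unique(pooled).size < pooled.size
        method = "exact" if (pooled.size <= 14 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method,
        use_continuity=use_continuity,
    )
    return ComparisonResult(
        analyte_name=analyte_name, label=label, test="Mann-Whitney U",
        statistic=float(res.statistic), p_value=float(res.pvalue), alpha=alpha,
    )


def kruskal_wallis(
    groups: Sequence[np.ndarray],
    *,
    alpha: float = 0.05,
    label: str = "",
    analyte_name: str | None = None,
) -> ComparisonResult:
    """Kruskal-Wallis H test (tie-corrected, chi-square approximation)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # no rank separation at all
        return ComparisonResult(
            analyte_name=analyte_name, label=label, test="Kruskal-Wallis",
            statistic=0.0, p_value=1.0, alpha=alpha,
        )
    stat, p = stats.kruskal(*arrays)
    return ComparisonResult(
        analyte_name=analyte_name, label=label, test="Kruskal-Wallis",
        statistic=float(stat), p_value=float(p), alpha=alpha,
    )


def comparison_table(
    dataset: pd.DataFrame,
    analytes: Sequence[str],
    *,
    partitions: Sequence[str] = ("T1", "T2", "T3", "NP"),
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-analyte comparison panel.

    One row per analyte: pooled pregnant vs non-pregnant (Mann-Whitney),
    the three trimester pairs (Mann-Whitney), and the three-way trimester
    comparison (Kruskal-Wallis).  A comparison whose group is empty for
    an analyte is marked unavailable (NaN).  ``bonferroni=True`` scales
    the pairwise trimester p-values by 3 (capped at 1).
    """
    comparisons = [
        ("pregnant_vs_np", ("pooled", "NP")),
        ("T1_vs_T2", ("T1", "T2")),
        ("T1_vs_T3", ("T1", "T3")),
        ("T2_vs_T3", ("T2", "T3")),
    ]
    pairwise = {"T1_vs_T2", "T1_vs_T3", "T2_vs_T3"}
    rows = []
    for analyte in analytes:
        groups = {
            part: dataset.loc[dataset["partition"] == part, analyte].dropna().to_numpy()
            for part in partitions
        }
        groups["pooled"] = np.concatenate(
            [groups[p] for p in PREGNANT if p in groups] or [np.array([])]
        )
        row: dict[str, object] = {"analyte": analyte}
        for name, (ga, gb) in comparisons:
            if groups.get(ga, np.array([])).size and groups.get(gb, np.array([])).size:
                res = mann_whitney_u(
                    groups[ga], groups[gb], alpha=alpha, label=name,
                    analyte_name=analyte,
                )
                p = res.p_value
                if bonferroni and name in pairwise:
                    p = min(1.0, 3.0 * p)
                row[f"{name}_U"] = res.statistic
                row[f"{name}_p"] = p
            else:
                row[f"{name}_U"] = np.nan
                row[f"{name}_p"] = np.nan
        if all(groups.get(p, np.array([])).size for p in PREGNANT):
            res = kruskal_wallis(
                [groups[p] for p in PREGNANT], alpha=alpha,
                label="trimesters", analyte_name=analyte,
            )
            row["trimesters_H"] = res.statistic
            row["trimesters_p"] = res.p_value
        else:
            row["trimesters_H"] = np.nan
            row["trimesters_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
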