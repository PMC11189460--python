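"""Univariate biomarker statistics.

Group comparisons use Mann–Whitney's two-sided U test (exact enumeration
for small tie-free samples, tie/continuity-corrected normal approximation
otherwise) with Benjamini–Hochberg control of the false-discovery rate at
5%.  Fold changes are ratios of group means (affected / control).
Clinical-score associations use Spearman rank correlation with BH
adjustment within each clinical variable's family.  Distribution utilities
(D'Agostino–Pearson normality, Box–Cox, Student's t) support the
parametric side analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .qc import FeatureTable

__all__ = [
    "GroupComparison",
    "mann_whitney_u",
    "benjamini_hochberg",
    "fold_change",
    "compare_groups",
    "spearman_matrix",
    "dagostino_pearson",
    "boxcox_transform",
    "student_t",
]

#: largest min(n, m) for which the exact Mann–Whitney branch is used
EXACT_MW_MAX_N = 8
#: largest n for which Spearman p comes from exact permutation
EXACT_SPEARMAN_MAX_N = 9


@dataclass
class GroupComparison:
    """One protein's two-group comparison (affected vs control)."""

    protein_id: str
    group_a: str  # affected
    group_b: str  # control
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    p_adjusted: float
    fold_change: float

    @property
    def direction(self) -> str:
        return "up_in_affected" if self.fold_change >= 1 else "up_in_control"


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[np.isfinite(x)]

def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of x, p).

    Exact null enumeration when ``min(n, m) <= 8`` and the pooled sample is
    tie-free; otherwise the normal approximation with continuity and tie
    correction.  Missing values are dropped.
    """
    x, y = _clean(x), _clean(y)
    if x.size == 0 or y.size == 0:
        raise ValueError("each group needs at least one non-missing value")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= EXACT_MW_MAX_N and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up FDR control; returns (rejected flags, adjusted p)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([], bool), np.array([], float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, p_adj


def fold_change(affected, control) -> float:
    """mean(affected) / mean(control); NaN (reported) when the control mean is 0."""
    a, c = _clean(affected), _clean(control)
    if a.size == 0 or c.size == 0:
        raise ValueError("empty group in fold_change")
    cm = float(np.mean(c))
    if cm == 0:
        return float("nan")
    return float(np.mean(a)) / cm


def compare_groups(
    table: FeatureTable,
    affected: str,
    control: str = "HC",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Protein-wise Mann–Whitney comparisons of two groups with BH control.

    Returns one row per protein: U, raw p, BH-adjusted p, fold change
    (affected/control mean ratio), direction, and the signed log10 p used
    for lollipop-style displays (negative when the protein is down in the
    affected group).
    """
    rows = []
    skipped = []
    for prot in table.proteins:
        a = table.group_values(prot, affected)
        c = table.group_values(prot, control)
        if a.size == 0 or c.size == 0:
            skipped.append(prot)
            continue
        u, p = mann_whitney_u(a, c)
        rows.append(
            {
                "protein_id": prot,
                "group_a": affected,
                "group_b": control,
                "n_a": a.size,
                "n_b": c.size,
                "u_statistic": u,
                "p_value": p,
                "fold_change": fold_change(a, c),
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    rejected, p_adj = benjamini_hochberg(df["p_value"].to_numpy(), alpha)
    df["p_adjusted"] = p_adj
    df["significant"] = rejected
    df["direction"] = np.where(df["fold_change"] >= 1, "up_in_affected", "up_in_control")
    df["signed_log10_p"] = -np.log10(df["p_value"]) * np.sign(np.log2(df["fold_change"]))
    df.attrs["skipped"] = skipped
    return df


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Exact two-sided permutation p for Spearman rho (small n)."""
    from itertools import permutations

    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    n = len(rx)
    count = 0
    total = 0
    target = abs(rho) - 1e-12
    for perm in permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_matrix(
    table: FeatureTable,
    clinical: list[str],
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Spearman correlations between proteins and clinical variables.

    Pairwise-complete observations; average ranks on ties.  For fewer than
    10 pairs the p-value is an exact permutation p, otherwise the
    t-approximation.  BH adjustment is applied variable-wise: the family
    for each clinical variable is its correlations across all proteins.
    Returns long format: protein_id, variable, n, rho, p_value, p_adjusted.
    """
    rows = []
    for var in clinical:
        if var not in table.metadata.columns:
            raise KeyError(f"clinical variable {var!r} not in metadata")
        cv = pd.to_numeric(table.metadata[var], errors="coerce")
        for prot in table.proteins:
            pv = table.values[prot]
            ok = pv.notna() & cv.notna()
            n = int(ok.sum())
            if n < min_pairs:
                rows.append(
                    {"protein_id": prot, "variable": var, "n": n,
                     "rho": np.nan, "p_value": np.nan}
                )
                continue
            x, y = pv[ok].to_numpy(), cv[ok].to_numpy()
            rho, p = sps.spearmanr(x, y)
            if n < EXACT_SPEARMAN_MAX_N + 1 and np.isfinite(rho):
                p = _spearman_exact_p(x, y, rho)
            rows.append(
                {"protein_id": prot, "variable": var, "n": n,
                 "rho": float(rho), "p_value": float(p)}
            )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = np.nan
    df["significant"] = False
    for var in clinical:
        sel = (df["variable"] == var) & df["p_value"].notna()
        if sel.any():
            rej, adj = benjamini_hochberg(df.loc[sel, "p_value"].to_numpy(), alpha)
            df.loc[sel, "p_adjusted"] = adj
            df.loc[sel, "significant"] = rej
    return df


def dagostino_pearson(x) -> tuple[float, float]:
    """D'Agostino–Pearson K² omnibus normality test (skewness + kurtosis).

    Requires n ≥ 20; the chi-square approximation for the combined
    statistic is unreliable below that.
    """
    x = _clean(x)
    if x.size < 20:
        raise ValueError(f"D'Agostino–Pearson requires n >= 20, got {x.size}")
    stat, p = sps.normaltest(x)
    return float(stat), float(p)


def boxcox_transform(x, lmbda: float | None = None) -> tuple[np.ndarray, float]:
    """Box–Cox power transform toward normality.

    λ is chosen by profile maximum likelihood unless forced; the transform
    is (x^λ − 1)/λ, with log x at λ = 0.  All inputs must be positive.
    """
    x = np.asarray(x, dtype=float)
    bad = np.flatnonzero(~(x > 0))
    if bad.size:
        raise ValueError(f"Box–Cox requires positive values; offending indices: {bad[:10].tolist()}")
    if lmbda is not None:
        return sps.boxcox(x, lmbda=lmbda), float(lmbda)
    transformed, lam = sps.boxcox(x)
    return transformed, float(lam)


def student_t(x, y) -> tuple[float, float]:
    """Two-sample pooled-variance Student t test (two-tailed).

    Degenerate zero-variance inputs: equal means → p = 1; unequal means →
    p reported as below 1e-6 (the statistic diverges).
    """
    x, y = _clean(x), _clean(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    sx, sy = np.var(x, ddof=1), np.var(y, ddof=1)
    if sx == 0 and sy == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float("inf") if np.mean(x) > np.mean(y) else float("-inf"), 1e-7
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)
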