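"""Rank-based statistics, expression normalization and grouped comparisons.

All group contrasts use the two-sided Wilcoxon rank-sum test and report
medians. Partial rank correlations control a covariate by the first-order
partial-correlation formula on mid-ranks, with the binary COG/SOG type
entering as mid-ranks of a dichotomy. Raw p-values are reported (no
multiple-testing correction by default, Benjamini–Hochberg optional) with
significance stars at 0.05 / 0.01 / 0.0001.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger("ctoevol")

STAR_THRESHOLDS = ((0.0001, "***"), (0.01, "**"), (0.05, "*"))


def stars(p: float | None) -> str:
    """Significance stars: p<0.05 -> *, p<0.01 -> **, p<0.0001 -> ***."""
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    for threshold, label in STAR_THRESHOLDS:
        if p < threshold:
            return label
    return "-"


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (statistic, p).

    Exact enumeration when n+m <= 12 with no ties; otherwise the normal
    approximation with tie and continuity correction. Two identical
    constant samples give p = 1 by convention (flagged in the log).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.info("wilcoxon: all values identical; p = 1 by convention")
        return float(x.size * y.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation of mid-ranks with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("zero variance in ranks; correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling z.

    All three variables are rank-transformed (mid-ranks; a binary variable
    becomes the mid-ranks of its two groups); the first-order partial
    correlation formula is applied to the pairwise Pearson correlations of
    the ranks, with a t test on n-3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = x.size
    if not (y.size == n and z.size == n) or n < 4:
        raise ValueError("need complete triples with n >= 4")
    rx, ry, rz = (sps.rankdata(v) for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 1e-12:
        raise ValueError("covariate perfectly correlated with a variable; partial undefined")
    rho = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    rho = min(1.0, max(-1.0, rho))
    df = n - 3
    if abs(rho) >= 1.0:
        return float(rho), 0.0
    t = rho * math.sqrt(df / (1.0 - rho**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(rho), float(p)


def quantile_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Classic quantile normalization across columns.

    Each column is replaced by the mean of the column-wise sorted values
    (the reference distribution) at its rank; tied values receive the mean
    of their reference slots. Missing values are an error — filter first.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if table.isna().any().any():
        raise ValueError("missing values not allowed; pre-filter the table")
    values = table.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # tied input values share the mean of their reference slots
        sorted_col = col[order]
        tie_starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        tie_ends = np.r_[tie_starts[1:], sorted_col.size]
        for s, e in zip(tie_starts, tie_ends):
            if e - s > 1:
                assigned[order[s:e]] = reference[s:e].mean()
        out[:, j] = assigned
    return pd.DataFrame(out, index=table.index, columns=table.columns)


def standardize_expression(values) -> np.ndarray:
    """Center to median 0, scale to variance 1 (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need n >= 2")
    centered = v - np.median(v)
    sd = centered.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; cannot standardize")
    return centered / sd


def stratify_top_quantile(
    values: pd.Series, top_fraction: float = 0.2
) -> tuple[set[str], set[str]]:
    """Split genes into highly (top fraction) and non-highly expressed.

    The cutoff is the (1 - top_fraction) quantile; genes at or above it are
    'highly', so boundary ties all land in the highly set. Applied per
    condition (growth phase) by the caller — phases are never pooled.
    """
    if values.empty:
        raise ValueError("no expression values")
    cutoff = values.quantile(1.0 - top_fraction)
    highly = set(values.index[values >= cutoff])
    non_highly = set(values.index) - highly
    if not non_highly:
        logger.warning("expression stratification: all values tied; everything 'highly'")
    return highly, non_highly


@dataclass(frozen=True)
class ComparisonReport:
    """One Table-style row: COG vs SOG medians and p-values in a stratum."""

    stratum: str
    n_cog: int
    n_sog: int
    median_dn_cog: float
    median_dn_sog: float
    p_dn: float | None
    median_ds_cog: float
    median_ds_sog: float
    p_ds: float | None
    median_omega_cog: float
    median_omega_sog: float
    p_omega: float | None

    def to_row(self) -> dict:
        return {
            "stratum": self.stratum,
            "#gene (COG/SOG)": f"{self.n_cog}/{self.n_sog}",
            "dN_COG": self.median_dn_cog,
            "dN_SOG": self.median_dn_sog,
            "p_dN": self.p_dn,
            "stars_dN": stars(self.p_dn),
            "dS_COG": self.median_ds_cog,
            "dS_SOG": self.median_ds_sog,
            "p_dS": self.p_ds,
            "stars_dS": stars(self.p_ds),
            "omega_COG": self.median_omega_cog,
            "omega_SOG": self.median_omega_sog,
            "p_omega": self.p_omega,
            "stars_omega": stars(self.p_omega),
        }


def grouped_rate_comparison(
    rates: pd.DataFrame,
    strata: pd.Series | None = None,
    call_column: str = "orientation_call",
    bh_correct: bool = False,
) -> list[ComparisonReport]:
    """COG vs SOG medians and Wilcoxon p-values per stratum.

    ``rates`` needs columns ``dN``, ``dS``, ``omega`` and ``call_column``
    (values 'COG'/'SOG'), indexed by group id. ``strata`` maps group id to
    a stratum label (None = single overall stratum). Strata with fewer
    than 2 genes in either group get a row with non-computable p-values.
    With ``bh_correct`` the p-values are Benjamini–Hochberg adjusted across
    all emitted tests.
    """
    df = rates.copy()
    df["_stratum"] = "all" if strata is None else strata.reindex(df.index)
    df = df[df["_stratum"].notna()]
    reports: list[ComparisonReport] = []
    for label, sub in df.groupby("_stratum", sort=True):
        cog = sub[sub[call_column] == "COG"]
        sog = sub[sub[call_column] == "SOG"]
        row: dict = {"stratum": str(label), "n_cog": len(cog), "n_sog": len(sog)}
        for metric, key in (("dN", "dn"), ("dS", "ds"), ("omega", "omega")):
            xc = cog[metric].dropna()
            xs = sog[metric].dropna()
            row[f"median_{key}_cog"] = float(xc.median()) if len(xc) else float("nan")
            row[f"median_{key}_sog"] = float(xs.median()) if len(xs) else float("nan")
            if len(xc) >= 2 and len(xs) >= 2:
                _, p = wilcoxon_rank_sum(xc, xs)
            else:
                p = None
            row[f"p_{key}"] = p
        reports.append(ComparisonReport(**row))
    if bh_correct:
        reports = _bh_adjust(reports)
    return reports


def _bh_adjust(reports: list[ComparisonReport]) -> list[ComparisonReport]:
    from dataclasses import replace

    keys = ["p_dn", "p_ds", "p_omega"]
    flat = [
        (i, k, getattr(r, k))
        for i, r in enumerate(reports)
        for k in keys
        if getattr(r, k) is not None
    ]
    if not flat:
        return reports
    pvals = np.array([p for _, _, p in flat])
    m = pvals.size
    order = np.argsort(pvals)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        idx = order[rank_pos]
        running = min(running, pvals[idx] * m / (rank_pos + 1))
        adj[idx] = running
    updated = list(reports)
    for (i, k, _), a in zip(flat, adj):
        updated[i] = replace(updated[i], **{k: float(a)})
    return updated


def report_frame(reports: list[ComparisonReport]) -> pd.DataFrame:
    """Reports as a table mirroring the grouped-comparison layout."""
    return pd.DataFrame([r.to_row() for r in reports])
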