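"""Dosage-balance statistics for gene-family copy-number tables.

Implements the statistical core of the copy-number analysis: OLS regressions
of subfamily counts on the family total (whose slopes sum to one by algebra,
since ASMT + COMT = total), the slope ratio contrasting subfamily growth
rates, proportion-vs-total correlation trends, a deterministic 1-D k-means
split into high- and low-copy species groups with Welch t and Mann–Whitney U
group tests, the receptor-vs-enzyme copy-number correlation, cross-ploidy
comparisons, and the subfamily expression contrast on FPKM matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DosageRegression:
    slope_asmt: float
    slope_comt: float
    intercept_asmt: float
    intercept_comt: float
    slope_ratio: float | None  # None when slope_comt == 0
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def subfamily_regression(table: pd.DataFrame) -> DosageRegression:
    """OLS of each subfamily count on the family total, plus proportion trends.

    Pearson and Spearman statistics relate the ASMT proportion (asmt/total)
    to the total copy number; zero-total rows are dropped from the proportion
    trend only.
    """
    if len(table) < 3:
        raise ValueError("need >= 3 species")
    total = table["total"].to_numpy(float)
    if np.ptp(total) == 0:
        raise ValueError("totals are all equal; regression undefined")
    asmt = table["asmt"].to_numpy(float)
    comt = table["comt"].to_numpy(float)

    fit_a = stats.linregress(total, asmt)
    fit_c = stats.linregress(total, comt)
    ratio = fit_a.slope / fit_c.slope if fit_c.slope != 0 else None

    nz = total > 0
    share = asmt[nz] / total[nz]
    if nz.sum() >= 3 and np.ptp(total[nz]) > 0 and np.ptp(share) > 0:
        pear = stats.pearsonr(total[nz], share)
        spear = stats.spearmanr(total[nz], share)
    else:  # proportion trend undefined on constant input
        nan = type("r", (), {"statistic": float("nan"), "pvalue": float("nan")})
        pear = spear = nan
    return DosageRegression(
        slope_asmt=float(fit_a.slope),
        slope_comt=float(fit_c.slope),
        intercept_asmt=float(fit_a.intercept),
        intercept_comt=float(fit_c.intercept),
        slope_ratio=None if ratio is None else float(ratio),
        pearson_r=float(pear.statistic),
        pearson_p=float(pear.pvalue),
        spearman_rho=float(spear.statistic),
        spearman_p=float(spear.pvalue),
    )


@dataclass(frozen=True)
class GroupSplit:
    """High/low-copy species split from 1-D k-means (k = 2)."""

    labels: np.ndarray  # "high" / "low" per species
    boundary_low: float  # largest total in the low group
    boundary_high: float  # smallest total in the high group
    t_stat: float | None = None
    t_p: float | None = None
    u_stat: float | None = None
    u_p: float | None = None


def split_high_low(
    totals: np.ndarray | pd.Series,
    statistic: np.ndarray | pd.Series | None = None,
) -> GroupSplit:
    """Split species into high/low copy groups by 1-D k-means (k = 2).

    Centers initialize at the extreme values and Lloyd iterations run to
    convergence — deterministic, and for k = 2 in one dimension the result is
    a single threshold cut on the sorted totals.  When `statistic` is given
    (one value per species, e.g. a subfamily proportion), a two-sided Welch
    t-test and Mann–Whitney U test compare it between the groups.
    """
    x = np.asarray(totals, float)
    if len(x) < 4:
        raise ValueError("need >= 4 species")
    if np.ptp(x) == 0:
        raise ValueError("totals are all equal; split undefined")

    lo, hi = float(x.min()), float(x.max())
    for _ in range(1000):
        high = np.abs(x - hi) < np.abs(x - lo)  # ties go to the low group
        new_lo, new_hi = x[~high].mean(), x[high].mean()
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    labels = np.where(high, "high", "low")

    t_stat = t_p = u_stat = u_p = None
    if statistic is not None:
        s = np.asarray(statistic, float)
        if len(s) != len(x):
            raise ValueError("statistic must have one value per species")
        t = stats.ttest_ind(s[high], s[~high], equal_var=False)
        u = stats.mannwhitneyu(s[high], s[~high], alternative="two-sided")
        t_stat, t_p = float(t.statistic), float(t.pvalue)
        u_stat, u_p = float(u.statistic), float(u.pvalue)
    return GroupSplit(
        labels=labels,
        boundary_low=float(x[~high].max()),
        boundary_high=float(x[high].min()),
        t_stat=t_stat,
        t_p=t_p,
        u_stat=u_stat,
        u_p=u_p,
    )


@dataclass(frozen=True)
class ReceptorCorrelation:
    rho: float | None
    p: float | None
    undefined_reason: str | None = None


def receptor_correlation(table: pd.DataFrame) -> ReceptorCorrelation:
    """Spearman rank correlation of receptor count vs ASMT/COMT total."""
    if "receptor" not in table.columns:
        raise ValueError("table has no receptor column")
    if len(table) < 10:
        raise ValueError("need >= 10 species")
    receptor = table["receptor"].to_numpy(float)
    total = table["total"].to_numpy(float)
    if np.ptp(receptor) == 0:
        return ReceptorCorrelation(None, None, "constant_receptor_counts")
    res = stats.spearmanr(receptor, total)
    return ReceptorCorrelation(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class PloidyComparison:
    mean_total_a: float
    mean_total_b: float
    fold_change: float
    t_total: float
    t_total_p: float
    u_total: float
    u_total_p: float
    mean_share_a: float
    mean_share_b: float
    t_share: float
    t_share_p: float
    u_share: float
    u_share_p: float

    @property
    def fold_change_2dp(self) -> float:
        return round(self.fold_change, 2)


def ploidy_comparison(
    table_a: pd.DataFrame, table_b: pd.DataFrame, share: str = "asmt"
) -> PloidyComparison:
    """Contrast total copy numbers and a subfamily share across two groups.

    Fold change is mean(total_a)/mean(total_b); Welch t and Mann–Whitney U
    tests run on both the totals and the chosen subfamily share.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both tables must be nonempty")
    if share not in ("asmt", "comt"):
        raise ValueError("share must be 'asmt' or 'comt'")
    tot_a = table_a["total"].to_numpy(float)
    tot_b = table_b["total"].to_numpy(float)
    if tot_b.mean() == 0:
        raise ValueError("zero mean total in the denominator group")
    share_a = table_a[share].to_numpy(float) / tot_a
    share_b = table_b[share].to_numpy(float) / tot_b

    t_tot = stats.ttest_ind(tot_a, tot_b, equal_var=False)
    u_tot = stats.mannwhitneyu(tot_a, tot_b, alternative="two-sided")
    t_sh = stats.ttest_ind(share_a, share_b, equal_var=False)
    u_sh = stats.mannwhitneyu(share_a, share_b, alternative="two-sided")
    return PloidyComparison(
        mean_total_a=float(tot_a.mean()),
        mean_total_b=float(tot_b.mean()),
        fold_change=float(tot_a.mean() / tot_b.mean()),
        t_total=float(t_tot.statistic),
        t_total_p=float(t_tot.pvalue),
        u_total=float(u_tot.statistic),
        u_total_p=float(u_tot.pvalue),
        mean_share_a=float(share_a.mean()),
        mean_share_b=float(share_b.mean()),
        t_share=float(t_sh.statistic),
        t_share_p=float(t_sh.pvalue),
        u_share=float(u_sh.statistic),
        u_share_p=float(u_sh.pvalue),
    )


@dataclass(frozen=True)
class ExpressionComparison:
    median_asmt: float
    median_comt: float
    q1_asmt: float
    q3_asmt: float
    q1_comt: float
    q3_comt: float
    n_asmt: int
    n_comt: int
    u_stat: float
    p: float
    comt_higher: bool


def _tukey_keep(values: np.ndarray) -> np.ndarray:
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return values[(values >= q1 - 1.5 * iqr) & (values <= q3 + 1.5 * iqr)]


def expression_compare(
    fpkm: pd.DataFrame,
    labels: pd.Series,
    fpkm_min: float = 1.0,
    outlier_rule: str = "tukey",
) -> ExpressionComparison:
    """Pool per-subfamily FPKM values and contrast the subfamilies.

    Values below `fpkm_min` are excluded; remaining values are cleaned by
    Tukey 1.5×IQR fences per subfamily (`outlier_rule="none"` disables), then
    medians/quartiles and a two-sided Mann–Whitney U test are reported, with
    a direction flag for COMT > ASMT (by median).
    """
    if outlier_rule not in ("tukey", "none"):
        raise ValueError(f"unknown outlier_rule {outlier_rule!r}")
    pools = {}
    for sub in ("ASMT", "COMT"):
        gene_ids = labels.index[labels == sub]
        if len(gene_ids) == 0:
            raise ValueError(f"no genes labeled {sub}")
        values = fpkm.loc[gene_ids].to_numpy(float).ravel()
        values = values[values >= fpkm_min]
        if outlier_rule == "tukey" and len(values):
            values = _tukey_keep(values)
        if len(values) == 0:
            raise ValueError(f"subfamily {sub} is empty after FPKM filtering")
        pools[sub] = values

    u = stats.mannwhitneyu(pools["COMT"], pools["ASMT"], alternative="two-sided")
    qa = np.percentile(pools["ASMT"], [25, 50, 75])
    qc = np.percentile(pools["COMT"], [25, 50, 75])
    return ExpressionComparison(
        median_asmt=float(qa[1]),
        median_comt=float(qc[1]),
        q1_asmt=float(qa[0]),
        q3_asmt=float(qa[2]),
        q1_comt=float(qc[0]),
        q3_comt=float(qc[2]),
        n_asmt=int(len(pools["ASMT"])),
        n_comt=int(len(pools["COMT"])),
        u_stat=float(u.statistic),
        p=float(u.pvalue),
        comt_higher=bool(qc[1] > qa[1]),
    )
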