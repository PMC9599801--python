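"""Between-group and correlation statistics for the cohort analysis.

Conventions chosen to match the clinical-table statistics exactly:
Student's pooled-variance t (df = n1 + n2 - 2), Pearson chi-square without
continuity correction (df = 1), Wilcoxon rank-sum with tie-corrected normal
approximation and continuity correction (exact enumeration for small
tie-free samples), Shapiro-Wilk normality screen at alpha = 0.05, and
Pearson correlation with the t-transform p-value (df = n - 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class TestResult:
    statistic_name: str  # one of: t, chi_square, rank_sum_z, pearson_r, shapiro_w
    statistic: float
    p_value: float
    df: float | None = None
    n: int | None = None
    group_summaries: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p-value outside [0, 1]")


def independent_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Student's pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(
        "t", float(t), float(p), df=n1 + n2 - 2, n=n1 + n2,
        group_summaries={"group1": (mean1, sd1), "group2": (mean2, sd2)},
    )


def independent_t_test_from_samples(x, y) -> TestResult:
    """Same test from raw samples; agrees with the summary entry point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return independent_t_test(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("a zero marginal makes the chi-square undefined")
    chi2, p, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult("chi_square", float(chi2), float(p), df=dof, n=int(table.sum()))


def _rank_sum_z(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected normal-approximation z with continuity correction,
    based on the rank sum of the first sample."""
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = ranks[:n1].sum()
    mu = n1 * (n2 + n1 + 1) / 2.0
    _, counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / ((n1 + n2) * (n1 + n2 - 1))
    sigma2 = n1 * n2 / 12.0 * (n1 + n2 + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0
    correction = 0.5 * np.sign(w - mu)
    return float((w - mu - correction) / np.sqrt(sigma2))


def rank_sum_test(x, y, method: str = "auto") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) two-sided test.

    ``method``: "asymptotic" = tie-corrected normal approximation with
    continuity correction; "exact" = full enumeration (small tie-free
    samples); "auto" = exact when both n <= 10 and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if method == "auto":
        method = "exact" if (len(x) <= 10 and len(y) <= 10 and not has_ties) else "asymptotic"
    if method not in ("exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        "rank_sum_z", _rank_sum_z(x, y), float(res.pvalue), n=len(x) + len(y),
        group_summaries={
            "group1": (float(np.median(x)), float(sps.iqr(x))),
            "group2": (float(np.median(y)), float(sps.iqr(y))),
        },
    )


def normality_check(x, alpha: float = 0.05) -> tuple[bool, TestResult]:
    """Shapiro-Wilk normality screen; True = consistent with normality.

    Routes the automatic choice between the t-test and the rank-sum test.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("normality undefined for a constant sample")
    w, p = sps.shapiro(x)
    return bool(p >= alpha), TestResult("shapiro_w", float(w), float(p), n=len(x))


def pearson_correlation(x, y) -> TestResult:
    """Pearson r with two-tailed p from the t-transform (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson_r", float(r), float(p), df=len(x) - 2, n=len(x))


def pairwise_band_comparison(
    matrices: list,
    groups: list[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """Rank-sum test of every channel pair's PLI between the two groups.

    ``matrices`` is one :class:`~plimci.pli.ConnectivityMatrix` per subject
    (same band, same montage), ``groups`` the per-subject group labels.
    Returns one row per unordered pair with the group medians, z and raw p;
    with ``adjust`` a Benjamini-Hochberg column is appended (off by default:
    the primary analysis reports raw p-values).
    """
    if len(matrices) != len(groups):
        raise ValueError("matrices and groups length mismatch")
    labels = matrices[0].channel_labels
    band = matrices[0].band
    for cm in matrices:
        if cm.channel_labels != labels:
            raise ValueError("all subjects must share one channel set")
        if cm.band != band:
            raise ValueError("all matrices must be from the same band")
    group_names = sorted(set(groups))
    if len(group_names) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = group_names
    n_ch = len(labels)
    iu, ju = np.triu_indices(n_ch, k=1)
    stacked = np.stack([cm.values[iu, ju] for cm in matrices])  # subject x pair
    mask1 = np.array([g == g1 for g in groups])
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")

    rows = []
    for p_idx in range(len(iu)):
        res = rank_sum_test(stacked[mask1, p_idx], stacked[~mask1, p_idx],
                            method="asymptotic")
        rows.append({
            "band": band.name,
            "channel_a": labels[iu[p_idx]],
            "channel_b": labels[ju[p_idx]],
            f"median_{g1}": float(np.median(stacked[mask1, p_idx])),
            f"median_{g2}": float(np.median(stacked[~mask1, p_idx])),
            "z": res.statistic,
            "p": res.p_value,
        })
    out = pd.DataFrame(rows)
    if adjust:
        out["p_bh"] = false_discovery_adjust(out["p"].to_numpy())
    return out


def false_discovery_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# Printed clinical-table summaries, used as fixture inputs by the
# reproduction check (validate_table1).
# ---------------------------------------------------------------------------

PRINTED_TABLE1: dict[str, dict] = {
    "gender_mf": {"MCI": (13, 17), "NC": (16, 14), "chi2": 0.601, "p": 0.438},
    "age_years": {"MCI": (67.17, 4.12), "NC": (67.73, 4.40), "t": -0.515, "p": 0.609},
    "education_years": {"MCI": (10.63, 3.75), "NC": (10.23, 3.23), "t": 0.443, "p": 0.660},
    "moca_score": {"MCI": (22.08, 2.24), "NC": (28.08, 1.41), "t": -11.350},
    "t2dm_duration_years": {"MCI": (14.23, 7.80), "NC": (15.43, 8.34), "t": -0.576, "p": 0.567},
    "n_per_group": 30,
}
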