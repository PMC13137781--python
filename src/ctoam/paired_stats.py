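"""Paired nonparametric statistics for cohort HDA tables.

The inferential battery mirrors a paired cross-sectional design: per-region
operated vs. contralateral Wilcoxon signed-rank tests with Holm correction
and matched-pairs rank-biserial effect sizes; and an interregional Friedman
test on per-patient fractions averaged across both knees, followed by
Bonferroni-corrected pairwise Wilcoxon post-hoc comparisons.  A Shapiro--Wilk
screen is reported but never switches the pipeline to parametric tests.

The Wilcoxon signed-rank p value is exact for small samples: all ``2**n``
sign assignments over the midranks of the absolute nonzero differences are
enumerated (two-sided, by distance of the positive-rank sum W from its null
mean).  This keeps exactness under ties, which off-the-shelf exact modes do
not provide.  Beyond ``n = 12`` a normal approximation with tie and
continuity corrections is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .region_hda import REGION_LABELS

__all__ = [
    "PairedTestResult",
    "FriedmanResult",
    "DegenerateDataWarning",
    "EXACT_ENUMERATION_MAX_N",
    "shapiro_wilk_screen",
    "wilcoxon_signed_rank",
    "rank_biserial",
    "holm_adjust",
    "bonferroni_adjust",
    "side_comparison",
    "average_across_knees",
    "friedman_test",
    "posthoc_pairwise",
]

#: Largest n for which the exact 2**n sign-assignment enumeration is used.
EXACT_ENUMERATION_MAX_N = 12

REGION_PAIRS = tuple(
    (REGION_LABELS[i], REGION_LABELS[j])
    for i in range(4) for j in range(i + 1, 4))


class DegenerateDataWarning(UserWarning):
    """Emitted when all paired differences are zero (no information)."""


@dataclass
class PairedTestResult:
    region: str
    w_statistic: float
    p_raw: float
    p_adjusted: float
    effect_r: float  # signed matched-pairs rank-biserial; nan when degenerate
    n_effective: int
    median_operated: float
    iqr_operated: tuple[float, float]
    median_nonoperated: float
    iqr_nonoperated: tuple[float, float]
    median_combined: float
    iqr_combined: tuple[float, float]


@dataclass
class FriedmanResult:
    chi2: float
    df: int
    p: float
    posthoc: list[tuple[str, str, float, float]]  # (region_a, region_b, p_raw, p_adj)


def shapiro_wilk_screen(values) -> tuple[float, float]:
    """Shapiro--Wilk normality screen (reporting only; the analysis path is
    always nonparametric)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3 or x.size > 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for constant input")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def _signed_midranks(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zero differences (classic Wilcoxon convention); midranks of |d|."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    return d, ranks


def _exact_two_sided_p(w: float, ranks: np.ndarray) -> float:
    """P(|W' - S/2| >= |W - S/2|) over all 2**n equiprobable sign assignments,
    where S is the total rank sum; the null distribution of W is symmetric
    about S/2 even under midranks."""
    n = len(ranks)
    # subset-sum distribution built iteratively over scaled integer ranks
    scaled = np.round(ranks * 2).astype(int)  # midranks are multiples of 1/2
    totals = np.zeros(1, dtype=np.int64)
    for r in scaled:
        totals = np.concatenate([totals, totals + r])
    center = scaled.sum() / 2.0
    dist = abs(w * 2 - center)
    return float(np.count_nonzero(np.abs(totals - center) >= dist - 1e-9) / 2 ** n)


def wilcoxon_signed_rank(x, y) -> tuple[float, float, int]:
    """Two-sided paired Wilcoxon signed-rank test.

    Returns ``(W, p, n_effective)`` with ``W`` the positive-rank sum over
    nonzero differences.  All-zero differences yield ``(0, 1.0, 0)`` with a
    :class:`DegenerateDataWarning`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("x and y must be equal-length 1D arrays, length >= 1")
    d, ranks = _signed_midranks(x - y)
    n = len(d)
    if n == 0:
        warnings.warn("all paired differences are zero", DegenerateDataWarning,
                      stacklevel=2)
        return 0.0, 1.0, 0
    w = float(ranks[d > 0].sum())
    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(w, ranks)
    else:
        s = ranks.sum()
        mean = s / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        num = abs(w - mean) - 0.5  # continuity correction
        z = max(num, 0.0) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    return w, p, n


def rank_biserial(x, y) -> float:
    """Matched-pairs rank-biserial correlation r = (R+ - R-)/(R+ + R-) over
    nonzero differences; NaN (flagged) when every difference is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d, ranks = _signed_midranks(x - y)
    if len(d) == 0:
        warnings.warn("all paired differences are zero: effect size undefined",
                      DegenerateDataWarning, stacklevel=2)
        return float("nan")
    r_pos = ranks[d > 0].sum()
    r_neg = ranks[d < 0].sum()
    return float((r_pos - r_neg) / (r_pos + r_neg))


def holm_adjust(p_values) -> list[float]:
    """Step-down Holm adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, min(1.0, (m - i) * p[idx]))
        adjusted[idx] = running
    return adjusted.tolist()


def bonferroni_adjust(p_values) -> list[float]:
    """Bonferroni adjustment: min(1, m*p) per value."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size).tolist()


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])  # linear interpolation
    return float(q1), float(med), float(q3)


def _cohort_wide(cohort: pd.DataFrame, threshold_hu: float) -> pd.DataFrame:
    required = {"patient_id", "region", "threshold_hu",
                "fraction_operated", "fraction_nonoperated"}
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    sub = cohort[cohort["threshold_hu"] == threshold_hu]
    if sub.empty:
        raise ValueError(f"no cohort rows at threshold {threshold_hu} HU")
    return sub


def side_comparison(cohort: pd.DataFrame, threshold_hu: float = 1000.0,
                    ) -> list[PairedTestResult]:
    """Per-region operated vs. contralateral comparison at one threshold.

    One Wilcoxon signed-rank test per region, Holm-adjusted across the four
    regions, with rank-biserial effect sizes and median [IQR] summaries for
    the operated, non-operated and combined fractions.  Regions with fewer
    than two complete pairs are skipped with a warning.
    """
    sub = _cohort_wide(cohort, threshold_hu)
    per_region: dict[str, tuple] = {}
    for region in REGION_LABELS:
        rows = sub[sub["region"] == region].dropna(
            subset=["fraction_operated", "fraction_nonoperated"])
        if len(rows) < 2:
            warnings.warn(f"region {region}: fewer than 2 complete pairs, skipped",
                          UserWarning, stacklevel=2)
            continue
        op = rows["fraction_operated"].to_numpy(float)
        nop = rows["fraction_nonoperated"].to_numpy(float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            w, p, n_eff = wilcoxon_signed_rank(op, nop)
            r = rank_biserial(op, nop)
        per_region[region] = (w, p, n_eff, r, op, nop)

    if not per_region:
        raise ValueError("no region has enough complete pairs")
    adjusted = holm_adjust([v[1] for v in per_region.values()])
    results: list[PairedTestResult] = []
    for (region, (w, p, n_eff, r, op, nop)), p_adj in zip(per_region.items(), adjusted):
        q1o, medo, q3o = _quartiles(op)
        q1n, medn, q3n = _quartiles(nop)
        q1c, medc, q3c = _quartiles(np.concatenate([op, nop]))
        results.append(PairedTestResult(
            region=region, w_statistic=w, p_raw=p, p_adjusted=p_adj,
            effect_r=r, n_effective=n_eff,
            median_operated=medo, iqr_operated=(q1o, q3o),
            median_nonoperated=medn, iqr_nonoperated=(q1n, q3n),
            median_combined=medc, iqr_combined=(q1c, q3c)))
    return results


def average_across_knees(cohort: pd.DataFrame, threshold_hu: float = 1000.0,
                         ) -> pd.DataFrame:
    """Per-patient regional fractions averaged over both knees.

    Returns a patients x regions (MF, CR, MLF, LLF) DataFrame; patients with
    any incomplete pair are excluded with a warning.  Row sums remain 1 by
    linearity of the within-knee normalization.
    """
    sub = _cohort_wide(cohort, threshold_hu)
    wide = sub.pivot_table(index="patient_id", columns="region",
                           values=["fraction_operated", "fraction_nonoperated"],
                           aggfunc="first")
    avg = (wide["fraction_operated"] + wide["fraction_nonoperated"]) / 2.0
    avg = avg.reindex(columns=list(REGION_LABELS))
    incomplete = avg.index[avg.isna().any(axis=1)]
    if len(incomplete) > 0:
        warnings.warn(f"patients excluded for incomplete pairs: {list(incomplete)}",
                      UserWarning, stacklevel=2)
        avg = avg.drop(index=incomplete)
    return avg


def friedman_test(matrix, run_posthoc: bool = True) -> FriedmanResult:
    """Friedman repeated-measures rank test across the four regions.

    Rows are patients, columns the k = 4 regions.  Uses within-row midranks
    and the tie-corrected statistic
    ``chi2 = (k-1) * sum_j (R_j - n(k+1)/2)^2 / (sum_ij r_ij^2 - n k (k+1)^2 / 4)``,
    which reduces to the classic ``12/(n k (k+1)) * sum R_j^2 - 3n(k+1)``
    without ties; fully tied data yield chi2 = 0.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("matrix must be n_patients x 4")
    n, k = m.shape
    if n < 2:
        raise ValueError("Friedman test requires at least 2 patients")
    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    num = (k - 1) * ((col_sums - n * (k + 1) / 2.0) ** 2).sum()
    den = (ranks**2).sum() - n * k * (k + 1) ** 2 / 4.0
    chi2 = 0.0 if den == 0 else float(num / den)
    p = float(stats.chi2.sf(chi2, k - 1))
    posthoc = posthoc_pairwise(m) if run_posthoc else []
    return FriedmanResult(chi2=chi2, df=k - 1, p=p, posthoc=posthoc)


def posthoc_pairwise(matrix) -> list[tuple[str, str, float, float]]:
    """Pairwise Wilcoxon signed-rank tests over the six region pairs with
    Bonferroni correction (adjusted p = min(1, 6 * raw p))."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("matrix must be n_patients x 4")
    raw = []
    for a, b in REGION_PAIRS:
        ia, ib = REGION_LABELS.index(a), REGION_LABELS.index(b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateDataWarning)
            _, p, _ = wilcoxon_signed_rank(m[:, ia], m[:, ib])
        raw.append(p)
    adjusted = bonferroni_adjust(raw)
    return [(a, b, p, p_adj)
            for (a, b), p, p_adj in zip(REGION_PAIRS, raw, adjusted)]
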