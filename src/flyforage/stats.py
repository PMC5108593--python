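"""Group-comparison procedures: Wilcoxon rank-sum with Bonferroni
correction, Fisher's exact test with modified-Wald proportion CIs, and
bootstrap difference-of-medians confidence intervals."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ComparisonResult:
    pair: tuple
    statistic: float
    p_raw: float
    p_adjusted: float  # min(1, m * p_raw)
    stars: str


@dataclass
class BootstrapCI:
    estimate: float  # difference of group medians (a - b)
    lower: float  # 5th percentile
    upper: float  # 95th percentile
    n_boot: int
    seed: int


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def ranksum_bonferroni(
    groups: dict | list,
    comparisons: list[tuple] | None = None,
) -> list[ComparisonResult]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) per comparison pair,
    Bonferroni-adjusted by the family size (number of comparisons passed).

    ``groups`` maps labels to samples (a list is keyed by index).  Uses the
    exact null distribution for small untied samples, normal approximation
    otherwise (scipy's default policy).  NaNs are dropped pairwise.
    """
    if isinstance(groups, list):
        groups = dict(enumerate(groups))
    if comparisons is None:
        keys = list(groups)
        comparisons = [
            (keys[i], keys[j])
            for i in range(len(keys))
            for j in range(i + 1, len(keys))
        ]
    m = len(comparisons)
    out = []
    for a_key, b_key in comparisons:
        a = np.asarray(groups[a_key], float)
        b = np.asarray(groups[b_key], float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) == 0 or len(b) == 0:
            raise ValueError(f"empty sample in comparison {(a_key, b_key)}")
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        p_adj = min(1.0, m * res.pvalue)
        out.append(
            ComparisonResult(
                pair=(a_key, b_key),
                statistic=float(res.statistic),
                p_raw=float(res.pvalue),
                p_adjusted=float(p_adj),
                stars=significance_stars(p_adj),
            )
        )
    return out


def modified_wald_ci(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Agresti-Coull 'modified Wald' CI for a proportion: add 2 successes
    and 2 failures, then apply the Wald formula, clipping into [0, 1]."""
    if n <= 0:
        raise ValueError("n must be positive")
    z = sps.norm.ppf(0.5 + conf / 2.0)
    p = (successes + 2.0) / (n + 4.0)
    half = z * np.sqrt(p * (1.0 - p) / (n + 4.0))
    return max(0.0, p - half), min(1.0, p + half)


def fisher_modified_wald(counts) -> dict:
    """Two-sided Fisher exact p for a 2x2 table plus per-row modified-Wald
    proportion CIs.

    ``counts`` is [[a, b], [c, d]]: rows are groups, columns are
    success/failure.  The exact p and the CI method are reported side by
    side (the CI is for each row's success proportion).
    """
    table = np.asarray(counts, dtype=int)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("counts must be a nonnegative 2x2 table")
    if table.sum() == 0:
        raise ValueError("all-zero table")
    _, p = sps.fisher_exact(table, alternative="two-sided")
    cis = [
        modified_wald_ci(int(r[0]), int(r.sum())) if r.sum() else (np.nan, np.nan)
        for r in table
    ]
    props = [r[0] / r.sum() if r.sum() else np.nan for r in table]
    return {
        "p": float(p),
        "proportions": props,
        "proportion_cis": cis,
    }


def bootstrap_median_diff(
    a, b, n_boot: int = 10_000, seed: int = 0
) -> BootstrapCI:
    """Bootstrap CI for median(a) - median(b): resample within each group
    with replacement, take the 5% / 95% percentiles of the replicate
    differences.  Non-overlap of two such CIs is the significance criterion
    used for group contrasts."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, len(a), size=(n_boot, len(a)))
    ib = rng.integers(0, len(b), size=(n_boot, len(b)))
    diffs = np.median(a[ia], axis=1) - np.median(b[ib], axis=1)
    lo, hi = np.percentile(diffs, [5.0, 95.0])
    return BootstrapCI(
        estimate=float(np.median(a) - np.median(b)),
        lower=float(lo),
        upper=float(hi),
        n_boot=n_boot,
        seed=seed,
    )
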