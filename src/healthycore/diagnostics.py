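"""Cohort-discrepancy diagnostics between two sites.

Implements the battery used to establish that two healthy-control cohorts
differ: per-feature mean tests (Welch t, two-sample Kolmogorov-Smirnov)
and scale tests (variance-ratio F, Ansari-Bradley) with Benjamini-
Hochberg FDR control; covariate-balanced repeated subsampling to rule a
covariate (sex) in or out as the driver of the discrepancy; and the
within/between-site average-mean-difference summary computed on repeated
disjoint subsamples, optionally after per-cohort mean/variance
adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import ConfigurationError, DataError, FeatureTable, MEASURES

DEFAULT_FDR_Q = 0.05


@dataclass
class TestPanelResult:
    """Per-feature statistics for one two-cohort comparison.

    ``table`` has one row per feature with columns
    ``feature, t_stat, t_p, ks_stat, ks_p, f_stat, f_p, ab_stat, ab_p``
    (mean tests and/or variance tests depending on which battery ran) and
    a ``degenerate`` flag for features constant in both cohorts.
    """

    table: pd.DataFrame
    q: float = DEFAULT_FDR_Q
    rejections: dict[str, dict[str, int]] = field(default_factory=dict)

    def summarize(self) -> pd.DataFrame:
        """Rejection counts before/after FDR, one row per test."""
        rows = [
            {"test": name, "before_fdr": c["before"], "after_fdr": c["after"]}
            for name, c in self.rejections.items()
        ]
        return pd.DataFrame(rows)


def _check_features(A: FeatureTable, B: FeatureTable) -> None:
    if A.feature_names != B.feature_names:
        raise DataError("cohorts have different feature sets")


def fdr_adjust(pvalues: np.ndarray, q: float = DEFAULT_FDR_Q) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    reject, adjusted, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject, adjusted


def _f_test_two_sided(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided variance-ratio F test (sample variances, ddof=1)."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0, 1.0
    if vb == 0:
        return np.inf, 0.0
    F = va / vb
    dfa, dfb = len(a) - 1, len(b) - 1
    cdf = stats.f.cdf(F, dfa, dfb)
    p = 2.0 * min(cdf, 1.0 - cdf)
    return float(F), float(min(p, 1.0))


def mean_difference_tests(
    A: FeatureTable, B: FeatureTable, q: float = DEFAULT_FDR_Q
) -> TestPanelResult:
    """Per-feature Welch t and two-sample KS tests with FDR summary."""
    _check_features(A, B)
    rows = []
    for j, name in enumerate(A.feature_names):
        a, b = A.values[:, j], B.values[:, j]
        degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
        if degenerate:
            t_stat, t_p, ks_stat, ks_p = 0.0, 1.0, 0.0, 1.0
        else:
            t_stat, t_p = stats.ttest_ind(a, b, equal_var=False)
            ks_stat, ks_p = stats.ks_2samp(a, b)
        rows.append(
            {
                "feature": name,
                "t_stat": float(t_stat),
                "t_p": float(t_p),
                "ks_stat": float(ks_stat),
                "ks_p": float(ks_p),
                "degenerate": bool(degenerate),
            }
        )
    table = pd.DataFrame(rows)
    result = TestPanelResult(table=table, q=q)
    for test in ("t", "ks"):
        reject, adj = fdr_adjust(table[f"{test}_p"].to_numpy(), q)
        table[f"{test}_p_adj"] = adj
        table[f"{test}_reject_fdr"] = reject
        result.rejections[test] = {
            "before": int((table[f"{test}_p"] < q).sum()),
            "after": int(reject.sum()),
        }
    return result


def variance_difference_tests(
    A: FeatureTable, B: FeatureTable, q: float = DEFAULT_FDR_Q
) -> TestPanelResult:
    """Per-feature variance-ratio F and Ansari-Bradley tests with FDR."""
    _check_features(A, B)
    rows = []
    for j, name in enumerate(A.feature_names):
        a, b = A.values[:, j], B.values[:, j]
        degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
        if degenerate:
            f_stat, f_p, ab_stat, ab_p = 1.0, 1.0, 0.0, 1.0
        else:
            f_stat, f_p = _f_test_two_sided(a, b)
            # exact Ansari-Bradley null for small combined samples,
            # normal approximation otherwise
            ab = stats.ansari(a, b, alternative="two-sided")
            ab_stat, ab_p = ab.statistic, min(ab.pvalue, 1.0)
        rows.append(
            {
                "feature": name,
                "f_stat": float(f_stat),
                "f_p": float(f_p),
                "ab_stat": float(ab_stat),
                "ab_p": float(ab_p),
                "degenerate": bool(degenerate),
            }
        )
    table = pd.DataFrame(rows)
    result = TestPanelResult(table=table, q=q)
    for test in ("f", "ab"):
        reject, adj = fdr_adjust(table[f"{test}_p"].to_numpy(), q)
        table[f"{test}_p_adj"] = adj
        table[f"{test}_reject_fdr"] = reject
        result.rejections[test] = {
            "before": int((table[f"{test}_p"] < q).sum()),
            "after": int(reject.sum()),
        }
    return result


@dataclass
class BalancedSubsampleResult:
    """Rejection-rate summary over covariate-balanced replicates."""

    #: test name -> fraction of replicates with >= 1 FDR rejection
    any_rejection_rate: dict[str, float]
    #: test name -> mean per-feature raw rejection fraction at level q
    mean_rejection_fraction: dict[str, float]
    reps: int
    subsample_per_level: dict[str, int]
    q: float

    def verdict(self, threshold: float = 0.5) -> dict[str, bool]:
        """Whether each test still flags a cohort difference after balancing."""
        return {k: v >= threshold for k, v in self.any_rejection_rate.items()}


def balanced_subsample_test(
    A: FeatureTable,
    B: FeatureTable,
    balance_on: str = "sex",
    reps: int = 10_000,
    seed: int = 0,
    q: float = DEFAULT_FDR_Q,
) -> BalancedSubsampleResult:
    """Repeat the four-test panel on covariate-balanced subsamples.

    Each replicate draws, for every covariate level, the same number of
    subjects from both cohorts (the largest size common to both), then
    runs the mean and variance batteries with FDR.  Repeating the
    procedure many times removes the dependence of the conclusion on any
    single random subsample.
    """
    _check_features(A, B)
    rng = np.random.default_rng(seed)

    def levels(t: FeatureTable) -> dict[str, np.ndarray]:
        vals = np.array([getattr(s, "sex" if balance_on == "sex" else balance_on) or "" for s in t.subjects])
        return {lv: np.nonzero(vals == lv)[0] for lv in np.unique(vals)}

    lev_A, lev_B = levels(A), levels(B)
    common = sorted(set(lev_A) & set(lev_B))
    missing = (set(lev_A) | set(lev_B)) - set(common)
    if missing:
        raise DataError(f"covariate level(s) {sorted(missing)} absent in one cohort")
    sizes = {lv: min(len(lev_A[lv]), len(lev_B[lv])) for lv in common}
    if all(v == 0 for v in sizes.values()):
        raise DataError("no common covariate levels with subjects in both cohorts")

    tests = ("t", "ks", "f", "ab")
    any_reject = {t: 0 for t in tests}
    frac_reject = {t: 0.0 for t in tests}
    for _ in range(reps):
        idx_A = np.concatenate(
            [rng.choice(lev_A[lv], size=sizes[lv], replace=False) for lv in common]
        )
        idx_B = np.concatenate(
            [rng.choice(lev_B[lv], size=sizes[lv], replace=False) for lv in common]
        )
        sub_A, sub_B = A.take(idx_A), B.take(idx_B)
        mean_res = mean_difference_tests(sub_A, sub_B, q)
        var_res = variance_difference_tests(sub_A, sub_B, q)
        for t in ("t", "ks"):
            any_reject[t] += int(mean_res.rejections[t]["after"] > 0)
            frac_reject[t] += (mean_res.table[f"{t}_p"] < q).mean()
        for t in ("f", "ab"):
            any_reject[t] += int(var_res.rejections[t]["after"] > 0)
            frac_reject[t] += (var_res.table[f"{t}_p"] < q).mean()

    return BalancedSubsampleResult(
        any_rejection_rate={t: any_reject[t] / reps for t in tests},
        mean_rejection_fraction={t: frac_reject[t] / reps for t in tests},
        reps=reps,
        subsample_per_level=sizes,
        q=q,
    )


SCENARIOS = ("A_vs_A", "B_vs_B", "random_splits", "A_vs_B")


@dataclass
class MeanDiffSummary:
    """Average |mean difference| per measure family and scenario.

    ``table``: rows = measure families (area/thickness/volume), columns =
    the four scenarios (within-A, within-B, random splits of the pool,
    cross-site).  Units follow the measure unless adjustment standardized
    the features.
    """

    table: pd.DataFrame
    n_sub: int
    reps: int
    adjustment: str

    def cross_exceeds_within(self) -> dict[str, bool]:
        """Per measure: is the cross-site value the maximum of the four?"""
        out = {}
        for measure, row in self.table.iterrows():
            out[measure] = bool(row["A_vs_B"] >= row[list(SCENARIOS[:3])].max())
        return out


def average_mean_difference(
    A: FeatureTable,
    B: FeatureTable,
    n_sub: int = 21,
    reps: int = 100,
    seed: int = 0,
    adjustment: str = "none",
) -> MeanDiffSummary:
    """Within/between-cohort average absolute mean difference.

    Four scenarios per replicate, each comparing two disjoint subsets of
    ``n_sub`` subjects: two subsets of A; two subsets of B; two subsets of
    the pooled A+B; one subset of A versus one of B.  For each scenario
    the per-feature |mean1 - mean2| is averaged over the features of each
    measure family, then over replicates.  ``adjustment="mean_variance"``
    first standardizes every feature by the pooled A+B mean and SD, which
    puts the three measure families on one dimensionless scale; a
    cross-site value that stays above the within-site values after this
    adjustment indicates a persistent site effect.  (Per-cohort
    standardization would instead zero out every cross-site mean
    difference by construction and can show no residual gap.)
    """
    _check_features(A, B)
    if n_sub < 2:
        raise ConfigurationError("n_sub must be >= 2")
    if adjustment not in ("none", "mean_variance"):
        raise ConfigurationError(f"unknown adjustment {adjustment!r}")
    n_sub_eff = min(n_sub, A.n_subjects // 2, B.n_subjects // 2)
    if n_sub_eff < n_sub:
        import logging

        logging.getLogger(__name__).warning(
            "n_sub lowered from %d to %d to fit the smaller cohort", n_sub, n_sub_eff
        )
    n_sub = n_sub_eff
    if n_sub < 2:
        raise ConfigurationError("cohorts too small for disjoint subsets")

    XA, XB = A.values, B.values
    if adjustment == "mean_variance":
        pooled = np.vstack([XA, XB])
        mu, sd = pooled.mean(axis=0), pooled.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)
        XA, XB = (XA - mu) / sd, (XB - mu) / sd
    pool = np.vstack([XA, XB])

    measure_cols: dict[str, list[int]] = {
        m: A.measure_columns(m) for m in MEASURES if A.measure_columns(m)
    }
    rng = np.random.default_rng(seed)
    acc = {m: {s: 0.0 for s in SCENARIOS} for m in measure_cols}

    def pair_diff(X: np.ndarray) -> np.ndarray:
        idx = rng.permutation(X.shape[0])[: 2 * n_sub]
        m1 = X[idx[:n_sub]].mean(axis=0)
        m2 = X[idx[n_sub:]].mean(axis=0)
        return np.abs(m1 - m2)

    def cross_diff() -> np.ndarray:
        ia = rng.permutation(XA.shape[0])[:n_sub]
        ib = rng.permutation(XB.shape[0])[:n_sub]
        return np.abs(XA[ia].mean(axis=0) - XB[ib].mean(axis=0))

    for _ in range(reps):
        diffs = {
            "A_vs_A": pair_diff(XA),
            "B_vs_B": pair_diff(XB),
            "random_splits": pair_diff(pool),
            "A_vs_B": cross_diff(),
        }
        for m, cols in measure_cols.items():
            for s in SCENARIOS:
                acc[m][s] += diffs[s][cols].mean()

    table = pd.DataFrame(
        {s: [acc[m][s] / reps for m in measure_cols] for s in SCENARIOS},
        index=list(measure_cols),
    )
    return MeanDiffSummary(table=table, n_sub=n_sub, reps=reps, adjustment=adjustment)


def mean_diff_markdown(summaries: Mapping[str, MeanDiffSummary]) -> str:
    """Markdown report of one or more MeanDiffSummary objects."""
    lines = []
    for title, s in summaries.items():
        lines.append(f"### {title} (n_sub={s.n_sub}, reps={s.reps}, adjustment={s.adjustment})")
        lines.append("")
        lines.append(s.table.to_markdown(floatfmt=".4f"))
        lines.append("")
    return "\n".join(lines)
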