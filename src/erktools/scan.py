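"""Negative-feedback-regulator expression scan and RPPA association tests.

Given a tumor cohort split by mutation status in RTK-RAS pathway drivers,
the scan asks which of a small panel of ERK negative-feedback regulators
(DUSP, SPRY and SPRED family genes) is differentially expressed: a Welch
two-sample t-test per panel gene, Bonferroni correction across the panel,
and a −log2(p) significance score against an alpha of 0.01.

The companion RPPA analyses relate phospho-protein levels (P-ERK, P-p38,
P-JNK) to mutation status or to expression quartiles of a single gene via
Mann-Whitney U tests, and quantify the expression/phospho-ERK association
with a Pearson correlation (one-tailed where the direction is predicted).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionTable, SampleAnnotation, logger


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of two sample groups."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    U_stat: float
    p: float
    tail: str


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    p: float
    tail: str


def welch_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = False
) -> tuple[float, float, float]:
    """Two-tailed two-sample t-test, Welch's correction by default.

    Returns (t, df, p) with t = (mean x − mean y) / sqrt(sx²/nx + sy²/ny)
    and df by Welch–Satterthwaite. If both groups are constant with equal
    means, p = 1 is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            logger.warning("both groups constant with equal means; p = 1")
            return 0.0, float(len(x) + len(y) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(min(res.pvalue, 1.0))


def scan_regulators(
    expr: ExpressionTable,
    annot: SampleAnnotation,
    panel: Sequence[str],
    grouping: str | Callable[[SampleAnnotation], pd.Series],
    alpha: float = 0.01,
    equal_var: bool = False,
    score_on: str = "adjusted",
) -> pd.DataFrame:
    """Per-gene differential-expression scan with Bonferroni correction.

    ``grouping`` is either a ``|``-separated mutation predicate (e.g.
    ``"EGFR|KRAS"``) or a callable producing a boolean mask over annotated
    samples. One row per panel gene: raw p from a two-tailed t-test (Welch
    by default), p_adj = min(1, p × |panel|), the −log2 significance score
    (on the adjusted p by default, ``score_on="raw"`` for the raw p),
    the direction of change in the mutant group, and a significance call
    p_adj < alpha.
    """
    if score_on not in ("adjusted", "raw"):
        raise ValueError(f"unknown score_on {score_on!r}")
    missing = [g for g in panel if g not in expr.gene_ids]
    if missing:
        raise ValueError(f"panel genes absent from expression table: {missing}")

    mask = annot.mutation_mask(grouping) if isinstance(grouping, str) else grouping(annot)
    mask = mask.reindex(expr.sample_ids)
    if mask.isna().any():
        raise ValueError("annotation missing for some expression samples")
    mutant_ids = expr.sample_ids[mask.to_numpy(dtype=bool)]
    wt_ids = expr.sample_ids[~mask.to_numpy(dtype=bool)]
    if len(mutant_ids) == 0 or len(wt_ids) == 0:
        raise ValueError("grouping must yield two non-empty sample sets")

    n_tested = len(panel)
    rows = []
    for gene in panel:
        x = expr.values.loc[gene, mutant_ids].to_numpy(dtype=float)
        y = expr.values.loc[gene, wt_ids].to_numpy(dtype=float)
        t, df, p = welch_t_test(x, y, equal_var=equal_var)
        p_adj = min(1.0, p * n_tested)
        score = -np.log2(p_adj if score_on == "adjusted" else p) + 0.0  # avoid -0.0
        rows.append(
            (
                gene, float(x.mean()), float(y.mean()), t, df, p, p_adj, score,
                "up" if x.mean() >= y.mean() else "down",
                p_adj < alpha,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "mean_mutant", "mean_wildtype", "t_stat", "df",
            "p_raw", "p_adj", "neg_log2_p", "direction", "significant",
        ],
    )


def normalize_rows_for_heatmap(values: pd.DataFrame | ExpressionTable) -> pd.DataFrame:
    """Row-wise robust standardization: (value − row median) / row MAD.

    MAD is the unscaled median absolute deviation from the row median. Rows
    with MAD = 0 become missing values, with a warning.
    """
    frame = values.values if isinstance(values, ExpressionTable) else values
    arr = frame.to_numpy(dtype=float)
    med = np.median(arr, axis=1, keepdims=True)
    mad = np.median(np.abs(arr - med), axis=1, keepdims=True)
    degenerate = mad[:, 0] == 0
    if degenerate.any():
        logger.warning(
            "heatmap normalization: %d constant row(s) set to missing", degenerate.sum()
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (arr - med) / mad
    out[degenerate, :] = np.nan
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    tail: str = "two",
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Mann-Whitney U test; one-tailed direction tests "x greater".

    Exact enumeration when nx + ny <= 16 with no ties in the pooled data,
    otherwise normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs at least 1 observation")
    alternative = {"two": "two-sided", "one": "greater"}[tail]
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):  # tie-corrected variance would vanish
        return GroupComparison(
            label_a, label_b, len(x), len(y), len(x) * len(y) / 2.0, 1.0, tail
        )
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 16 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return GroupComparison(
        label_a, label_b, len(x), len(y),
        float(res.statistic), float(min(res.pvalue, 1.0)), tail,
    )


def quartile_groups(values: pd.Series) -> tuple[set, set]:
    """Split samples into top and bottom expression quartiles.

    With k = ceil(n/4), the high group contains samples whose value is at
    least the k-th largest, the low group those at most the k-th smallest;
    ties expand groups by >=/<= inclusion. All-equal input returns both
    groups as all samples, with a warning.
    """
    values = pd.Series(values).astype(float)
    n = len(values)
    if n < 4:
        raise ValueError("need at least 4 samples to form quartiles")
    srt = np.sort(values.to_numpy())
    if srt[0] == srt[-1]:
        logger.warning("quartile split on constant values: groups equal all samples")
        return set(values.index), set(values.index)
    k = ceil(n / 4)
    low_cut, high_cut = srt[k - 1], srt[n - k]
    high = set(values.index[values >= high_cut])
    low = set(values.index[values <= low_cut])
    logger.info("quartile groups: |high| = %d, |low| = %d of n = %d", len(high), len(low), n)
    return high, low


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], tail: str = "two"
) -> CorrelationResult:
    """Pearson product-moment correlation; one-tailed tests positive association.

    p comes from t = r sqrt((n−2)/(1−r²)) against the t(n−2) distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need paired vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    alternative = {"two": "two-sided", "one": "greater"}[tail]
    res = stats.pearsonr(x, y, alternative=alternative)
    return CorrelationResult(len(x), float(res.statistic), float(min(res.pvalue, 1.0)), tail)
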