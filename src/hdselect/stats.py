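"""Per-species differential-abundance statistics for case/control profiles.

For each species the module reports the prevalence (percent of samples in a
class with RA > 0), the log2 fold change of class-mean abundances
(log2(mean_case / mean_control), left as an explicit +/-inf or NaN sentinel
when a class mean is zero -- no silent pseudocount), a two-sided Wilcoxon
rank-sum (Mann-Whitney) test, and Benjamini-Hochberg adjusted q-values.  A
species is flagged significant when p <= 0.05 and q <= 0.2 (the defaults).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "prevalence",
    "log2fc",
    "bh_adjust",
    "rank_sum_bh",
]


def _class_columns(labels: pd.Series | dict, samples, cls) -> list:
    lab = pd.Series(labels)
    cols = [s for s in samples if str(lab.get(s)) == str(cls)]
    if not cols:
        raise ValueError(f"class {cls!r} has no samples")
    return cols


def prevalence(matrix: pd.DataFrame, labels, cls) -> pd.Series:
    """Percent of ``cls`` samples in which each species is detected (value > 0)."""
    cols = _class_columns(labels, matrix.columns, cls)
    return 100.0 * (matrix[cols] > 0).sum(axis=1) / len(cols)


def log2fc(ra: pd.DataFrame, labels, case, control) -> pd.Series:
    """log2 of the ratio of class-mean abundances (case over control).

    Zero means yield sentinels: +inf (control mean 0, case mean > 0),
    -inf (case mean 0, control mean > 0), NaN (both 0); callers should treat
    non-finite values as "undefined" rather than as magnitudes.
    """
    case_cols = _class_columns(labels, ra.columns, case)
    ctrl_cols = _class_columns(labels, ra.columns, control)
    mean_case = ra[case_cols].mean(axis=1)
    mean_ctrl = ra[ctrl_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log2(mean_case.values / mean_ctrl.values)
    return pd.Series(out, index=ra.index, name="log2fc")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: q_i = min_{j>=i} (p_j * m / j).

    Input order is preserved; q-values are clipped at 1 and are monotone
    non-decreasing in the p-sorted order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.shape[0]
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def rank_sum_bh(
    ra: pd.DataFrame,
    labels,
    case,
    control,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.2,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Per-species rank-sum tests with BH correction and significance calls.

    ``method`` selects the Mann-Whitney p-value computation: "asymptotic"
    (normal approximation with tie correction, the default) or "exact".
    Returns one row per species: prevalence in both classes, log2FC, p, q,
    and ``significant`` (p <= p_threshold and q <= fdr_threshold).
    """
    if method not in {"asymptotic", "exact"}:
        raise ValueError("method must be 'asymptotic' or 'exact'")
    case_cols = _class_columns(labels, ra.columns, case)
    ctrl_cols = _class_columns(labels, ra.columns, control)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("need at least 2 samples per class for the rank-sum test")
    case_values = ra[case_cols].to_numpy(dtype=np.float64)
    ctrl_values = ra[ctrl_cols].to_numpy(dtype=np.float64)
    p_values = np.empty(ra.shape[0])
    for i in range(ra.shape[0]):
        x, y = case_values[i], ctrl_values[i]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p_values[i] = 1.0  # constant species: no evidence either way
            continue
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
        p_values[i] = res.pvalue
    q_values = bh_adjust(p_values)
    out = pd.DataFrame(
        {
            "species": ra.index,
            "prevalence_case": prevalence(ra, labels, case).values,
            "prevalence_control": prevalence(ra, labels, control).values,
            "log2fc": log2fc(ra, labels, case, control).values,
            "p_value": p_values,
            "q_value": q_values,
        }
    ).set_index("species")
    out["significant"] = (out["p_value"] <= p_threshold) & (
        out["q_value"] <= fdr_threshold
    )
    return out
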