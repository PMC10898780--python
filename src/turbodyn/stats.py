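"""Group-level comparison statistics.

Kolmogorov-Smirnov distance between node-level metastability
distributions, Benjamini-Hochberg FDR, Pearson brain-behaviour
correlations, Wilcoxon rank tests, the top-quantile node tally per
resting-state network, and a thin adapter for ANOVA / ANCOVA through
statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ks_distance",
    "bh_fdr",
    "pearson_with_p",
    "rank_tests",
    "top_quantile_nodes",
    "anova_adapter",
]


@dataclass
class StatResult:
    statistic: float
    p_value: float | None
    n: tuple[int, ...]
    method: str
    p_adjusted: float | None = None


def ks_distance(sample_a, sample_b) -> float:
    """Kolmogorov-Smirnov distance: sup_x |ECDF_a(x) - ECDF_b(x)|."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be nonempty")
    grid = np.concatenate([a, b])
    ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / a.size
    ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(ecdf_a - ecdf_b).max())


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]  # enforce monotonicity
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def pearson_with_p(x, y) -> StatResult:
    """Pearson r with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must be equal-length with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero-variance input")
    res = sps.pearsonr(x, y)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(x.size,),
        method="pearson",
    )


def rank_tests(sample_a, sample_b, paired: bool = False) -> StatResult:
    """Wilcoxon signed-rank (paired) or rank-sum (unpaired) test."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired and a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if min(a.size, b.size) < 5:
        warnings.warn("n < 5: asymptotic p-value unreliable")
    if paired:
        d = a - b
        if np.all(d == 0):
            return StatResult(0.0, None, (a.size, b.size), "wilcoxon-signed-rank")
        res = sps.wilcoxon(a, b)
        method = "wilcoxon-signed-rank"
    else:
        res = sps.ranksums(a, b)
        method = "wilcoxon-rank-sum"
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(a.size, b.size),
        method=method,
    )


def top_quantile_nodes(differences, rsn_labels, q: float = 0.15) -> dict[str, int]:
    """Count per network the nodes in the top-q quantile of |difference|.

    The threshold is the empirical (1 - q) quantile (linear
    interpolation); membership is strictly greater than the threshold,
    so under massive ties the selected set may be empty.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    d = np.abs(np.asarray(differences, dtype=float))
    labels = np.asarray(rsn_labels)
    if labels.shape[0] != d.shape[0]:
        raise ValueError("labels must cover all nodes")
    thr = np.quantile(d, 1 - q)
    sel = d > thr
    return {str(name): int(np.sum(sel & (labels == name))) for name in np.unique(labels)}


def anova_adapter(
    data: pd.DataFrame,
    formula: str,
    covariates: list[str] | None = None,
    typ: int = 2,
) -> pd.DataFrame:
    """OLS ANOVA/ANCOVA through statsmodels; records the design used.

    ``formula`` is a patsy formula (e.g. ``"value ~ C(group) * C(lam)"``);
    covariates already present in the formula are simply logged.  Returns
    the ANOVA table with the formula and covariates attached in
    ``DataFrame.attrs``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols(formula, data=data).fit()
    table = sm.stats.anova_lm(model, typ=typ)
    table.attrs["formula"] = formula
    table.attrs["covariates"] = covariates or []
    table.attrs["n_obs"] = int(model.nobs)
    return table
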