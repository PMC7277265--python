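"""Shared statistics: t-tests, one-way ANOVA, BH-FDR and bootstrap intervals.

All group-level inference in the package funnels through these wrappers so
that degenerate inputs (zero-variance samples) and FDR family definitions are
handled in one place.  Tests are two-sided throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "fdr_bh",
    "one_sample_t",
    "paired_t",
    "one_way_anova",
    "bootstrap_ci_mean",
    "attach_fdr",
]


@dataclass
class StatResult:
    """One hypothesis test: statistic, dof, raw p and (optionally) FDR q."""

    name: str
    statistic: float
    df: float
    p: float
    q: float = float("nan")
    reject: bool = False
    effect_direction: int = 0
    note: str = field(default="")

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "q": self.q,
            "reject": self.reject,
            "effect_direction": self.effect_direction,
            "note": self.note,
        }


def fdr_bh(p_values, alpha: float = 0.05, method: str = "bh"):
    """Benjamini–Hochberg (or -Yekutieli) step-up correction.

    Parameters
    ----------
    p_values : array-like of raw p-values in [0, 1]; the caller defines the family.
    alpha : rejection threshold on the adjusted values.
    method : ``"bh"`` (independent/PRDS) or ``"by"`` (arbitrary dependence).

    Returns
    -------
    q : ndarray of adjusted p-values (monotone step-up).
    reject : boolean ndarray, ``q <= alpha`` per the step-up rule.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("fdr_bh requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must be finite and within [0, 1]")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    reject, q, _, _ = multipletests(p, alpha=alpha, method=sm_method)
    return q, reject


def _degenerate_t(mean_diff: float, n: int, name: str) -> StatResult:
    # Zero-variance sample: t is 0 (on-null) or +/-inf (off-null, p -> 0).
    if mean_diff == 0:
        return StatResult(name, 0.0, n - 1, 1.0, note="zero variance, on null")
    stat = np.inf if mean_diff > 0 else -np.inf
    return StatResult(
        name, float(stat), n - 1, 0.0,
        effect_direction=int(np.sign(mean_diff)),
        note="zero variance, off null",
    )


def one_sample_t(values, mu: float = 0.0, name: str = "one_sample_t") -> StatResult:
    """Two-sided one-sample t-test of ``mean(values) == mu`` (df = n - 1)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("one_sample_t requires a 1-D sample with n >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("non-finite values in sample")
    if np.std(x) == 0:
        return _degenerate_t(float(x.mean() - mu), x.size, name)
    t, p = sps.ttest_1samp(x, mu)
    return StatResult(name, float(t), x.size - 1, float(p),
                      effect_direction=int(np.sign(x.mean() - mu)))


def paired_t(a, b, name: str = "paired_t") -> StatResult:
    """Two-sided paired t-test on ``a - b`` (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-D samples")
    return one_sample_t(a - b, 0.0, name=name)


def one_way_anova(*groups, name: str = "one_way_anova") -> StatResult:
    """One-way fixed-effects ANOVA; df = (k - 1, N - k)."""
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.size < 2 or np.any(~np.isfinite(g)):
            raise ValueError("each group needs n >= 2 finite values")
    k = len(arrs)
    n_total = sum(g.size for g in arrs)
    if np.std(np.concatenate(arrs)) == 0:
        # All observations identical: F is 0 by convention.
        return StatResult(name, 0.0, k - 1, 1.0, note="zero variance")
    f, p = sps.f_oneway(*arrs)
    res = StatResult(name, float(f), k - 1, float(p))
    res.note = f"df_between={k - 1}, df_within={n_total - k}"
    return res


def bootstrap_ci_mean(values, n_iter: int = 1000, level: float = 0.95,
                      seed: int | None = None):
    """Percentile bootstrap CI of the mean (default 1,000 resamples, 95%)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("bootstrap requires n >= 2")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_iter, x.size))
    means = x[idx].mean(axis=1)
    lo = (1.0 - level) / 2.0
    return float(np.quantile(means, lo)), float(np.quantile(means, 1.0 - lo))


def attach_fdr(results: list[StatResult], alpha: float = 0.05,
               method: str = "bh") -> list[StatResult]:
    """Correct a family of StatResults in place and return it."""
    if not results:
        return results
    q, reject = fdr_bh([r.p for r in results], alpha=alpha, method=method)
    for r, qi, ri in zip(results, q, reject):
        r.q = float(qi)
        r.reject = bool(ri)
    return results
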