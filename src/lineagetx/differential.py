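"""Negative-binomial differential expression between stages.

The test is the exact conditional NB test: under the null hypothesis the
two group sums K_A and K_B are negative-binomial with means proportional
to the summed size factors and a shared per-unit mean; conditioning on the
observed total K_A + K_B = S, the two-sided p-value is the probability of
all splits (a, S-a) at most as probable as the observed one.

Dispersion is estimated per gene by within-condition method of moments,
then regularized by taking the maximum of the gene-wise estimate and a
fitted mean-dispersion trend (conservative sharing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import normalized_counts, size_factors as _size_factors

DISPERSION_FLOOR = 1e-8
# relative slack when comparing split probabilities to the observed one, so
# ties are included regardless of floating-point noise
_P_TIE_RTOL = 1e-8


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------

def _genewise_dispersion(norm: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Pooled within-condition method-of-moments dispersion per gene."""
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = len(idx) - 1
        num += w * (v - m)
        den += w * m**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return alpha


def _fit_trend(mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha ~ a0 + a1/mean with non-negative coefficients."""
    ok = mean > 0
    if ok.sum() < 2:
        return np.full_like(mean, DISPERSION_FLOOR)
    design = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    from scipy.optimize import nnls

    coef, _ = nnls(design, np.clip(alpha[ok], 0.0, None))
    trend = np.full_like(mean, DISPERSION_FLOOR)
    trend[ok] = coef[0] + coef[1] / mean[ok]
    return trend


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: pd.Series,
) -> pd.Series:
    """Per-gene NB dispersion alpha_i >= 0.

    Within-condition method-of-moments estimates pooled across conditions,
    regularized as max(gene-wise, fitted a0 + a1/mean trend) and floored at
    1e-8.  Requires at least one condition with >= 2 replicates.
    """
    conditions = conditions.reindex(counts.columns)
    groups = [
        np.flatnonzero((conditions == c).to_numpy())
        for c in conditions.unique()
    ]
    if not any(len(g) >= 2 for g in groups):
        raise ValueError(
            "no condition has replication; supply a dispersion value explicitly"
        )
    norm = normalized_counts(counts, factors).to_numpy()
    alpha = _genewise_dispersion(norm, groups)
    mean = norm.mean(axis=1)
    trend = _fit_trend(mean, alpha)
    final = np.maximum(np.maximum(alpha, trend), DISPERSION_FLOOR)
    return pd.Series(final, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# exact conditional NB test
# ---------------------------------------------------------------------------

def _group_sum_pmf(total: int, mean: float, var: float) -> np.ndarray:
    """pmf of a group-sum on 0..total under NB(mean, var) (Poisson if var<=mean)."""
    ks = np.arange(total + 1)
    if mean <= 0:
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        return pmf
    if var <= mean * (1 + 1e-12):
        return stats.poisson.pmf(ks, mean)
    size = mean**2 / (var - mean)
    p = size / (size + mean)
    return stats.nbinom.pmf(ks, size, p)


def nb_exact_pvalue(
    k_a: int,
    k_b: int,
    sf_a: np.ndarray,
    sf_b: np.ndarray,
    alpha: float,
) -> float:
    """Two-sided conditional p-value for the split (k_a, k_b).

    Both group sums are modelled as NB with common per-size-factor mean
    q = (k_a + k_b) / (sum of all size factors); the variance of a group
    sum is sum_j (q s_j + alpha q^2 s_j^2).  Conditional on the total, the
    p-value sums the probabilities of every split at most as probable as
    the observed one.
    """
    sf_a = np.asarray(sf_a, dtype=float)
    sf_b = np.asarray(sf_b, dtype=float)
    total = int(k_a + k_b)
    if total == 0:
        return 1.0
    q = total / (sf_a.sum() + sf_b.sum())
    mean_a = q * sf_a.sum()
    mean_b = q * sf_b.sum()
    var_a = mean_a + alpha * q**2 * np.sum(sf_a**2)
    var_b = mean_b + alpha * q**2 * np.sum(sf_b**2)
    pmf_a = _group_sum_pmf(total, mean_a, var_a)
    pmf_b = _group_sum_pmf(total, mean_b, var_b)
    joint = pmf_a * pmf_b[::-1]  # joint[a] = P(K_A = a) P(K_B = total - a)
    denom = joint.sum()
    if denom <= 0:
        return 1.0
    observed = joint[k_a]
    p = joint[joint <= observed * (1 + _P_TIE_RTOL)].sum() / denom
    return float(min(p, 1.0))


@dataclass
class Contrast:
    stage_a: str
    stage_b: str


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    dispersion: pd.Series | float,
    conditions: pd.Series,
    contrast: tuple[str, str],
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Exact conditional NB test for one stage pair.

    Returns a DataFrame indexed by gene with columns ``baseMeanA``,
    ``baseMeanB`` (size-factor-normalized group means), ``log2FC``
    (with pseudocount), ``pval`` and ``padj`` (Benjamini-Hochberg).
    """
    stage_a, stage_b = contrast
    conditions = conditions.reindex(counts.columns)
    for label in (stage_a, stage_b):
        if not (conditions == label).any():
            raise ValueError(f"unknown or empty stage label in contrast: {label!r}")
    idx_a = np.flatnonzero((conditions == stage_a).to_numpy())
    idx_b = np.flatnonzero((conditions == stage_b).to_numpy())
    sf = factors.reindex(counts.columns).to_numpy(dtype=float)
    sf_a, sf_b = sf[idx_a], sf[idx_b]
    raw = counts.to_numpy()
    if np.isscalar(dispersion):
        alphas = np.full(counts.shape[0], float(dispersion))
    else:
        alphas = dispersion.reindex(counts.index).to_numpy(dtype=float)

    k_a = raw[:, idx_a].sum(axis=1).astype(int)
    k_b = raw[:, idx_b].sum(axis=1).astype(int)
    pvals = np.ones(counts.shape[0])
    for i in range(counts.shape[0]):
        if k_a[i] + k_b[i] > 0:
            pvals[i] = nb_exact_pvalue(k_a[i], k_b[i], sf_a, sf_b, alphas[i])

    mean_a = (raw[:, idx_a] / sf_a).mean(axis=1)
    mean_b = (raw[:, idx_b] / sf_b).mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    log2fc[(k_a + k_b) == 0] = 0.0
    return pd.DataFrame(
        {
            "baseMeanA": mean_a,
            "baseMeanB": mean_b,
            "log2FC": log2fc,
            "pval": pvals,
            "padj": bh_adjust(pvals),
        },
        index=counts.index,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_all_pairs(
    counts: pd.DataFrame,
    conditions: pd.Series,
    factors: pd.Series | None = None,
    dispersion: pd.Series | float | None = None,
    stages: list[str] | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Exact NB test for every ordered pair of stages (a before b in `stages`)."""
    conditions = conditions.reindex(counts.columns)
    if stages is None:
        stages = list(dict.fromkeys(conditions))
    if factors is None:
        factors = _size_factors(counts)
    if dispersion is None:
        dispersion = estimate_dispersion(counts, factors, conditions)
    results: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(stages):
        for b in stages[i + 1 :]:
            results[(a, b)] = nb_test(counts, factors, dispersion, conditions, (a, b))
    return results
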