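"""Expression quantification: size factors, FPKM, variance stabilization,
detection rates and mean-relative (stage-scaled) expression.

Conventions
-----------
* Size factors are the median-of-ratios estimator (count over per-gene
  geometric mean, median across genes expressed in every sample), rescaled
  to geometric mean 1.
* The variance-stabilizing transform assumes negative-binomial counts with
  variance mu + alpha * mu**2 (common dispersion alpha) and is the closed
  form of the stabilizing integral: vst(x) = (2/sqrt(alpha)) *
  asinh(sqrt(alpha * x)), with the alpha -> 0 limit 2*sqrt(x).
* Relative (mean-scaled) expression is computed on log2(stage mean + 1)
  and centered per gene across stages, so every row sums to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

VST_ALPHA_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame | ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample, geometric mean 1.

    Genes with a zero count in any sample are excluded from the reference
    (their geometric mean would be zero).  Raises ``ValueError`` when no
    gene is expressed in all samples.
    """
    if isinstance(counts, ExpressionMatrix):
        counts = counts.counts
    values = counts.to_numpy(dtype=float)
    expressed_everywhere = (values > 0).all(axis=1)
    if not expressed_everywhere.any():
        raise ValueError(
            "size factor estimation requires at least one gene with nonzero "
            "counts in every sample"
        )
    ref = values[expressed_everywhere]
    log_geo_mean = np.log(ref).mean(axis=1)
    log_ratios = np.log(ref) - log_geo_mean[:, None]
    factors = np.exp(np.median(log_ratios, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalized_counts(counts: pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    return counts / factors.reindex(counts.columns).to_numpy()


# ---------------------------------------------------------------------------
# FPKM
# ---------------------------------------------------------------------------

def fpkm(
    counts: pd.DataFrame | ExpressionMatrix,
    gene_lengths: pd.Series | None = None,
    total_fragments: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase of exon per million mapped fragments.

    FPKM_ij = count_ij / ((length_i / 1e3) * (total_j / 1e6)).  The
    per-sample total defaults to the column sum of the analyzed matrix.
    """
    if isinstance(counts, ExpressionMatrix):
        if gene_lengths is None:
            gene_lengths = counts.gene_lengths
        if total_fragments is None:
            total_fragments = counts.total_fragments
        counts = counts.counts
    if gene_lengths is None:
        raise ValueError("gene lengths are required to compute FPKM")
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()[:5]
        raise ValueError(f"missing gene lengths, e.g. {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    if total_fragments is None:
        total_fragments = counts.sum(axis=0)
    totals = total_fragments.reindex(counts.columns).astype(float)
    if (totals <= 0).any():
        raise ValueError("per-sample fragment totals must be positive")
    denom = np.outer(lengths.to_numpy(dtype=float) / 1e3, totals.to_numpy() / 1e6)
    return pd.DataFrame(
        counts.to_numpy(dtype=float) / denom, index=counts.index, columns=counts.columns
    )


# ---------------------------------------------------------------------------
# variance-stabilizing transform
# ---------------------------------------------------------------------------

def vst_transform(x, alpha: float):
    """Closed-form VST of normalized counts ``x`` at common dispersion alpha.

    Antiderivative of 1/sqrt(mu + alpha*mu^2): (2/sqrt(alpha)) *
    asinh(sqrt(alpha*x)); monotone, vst(0) = 0, limit 2*sqrt(x) as
    alpha -> 0.
    """
    if alpha < 0:
        raise ValueError("dispersion alpha must be non-negative")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("normalized counts must be non-negative")
    if alpha == 0:
        return 2.0 * np.sqrt(x)
    return (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * x))


def estimate_common_dispersion(counts: pd.DataFrame, factors: pd.Series) -> float:
    """Pooled method-of-moments common dispersion for the VST.

    For each gene, alpha_g = (var - mean)/mean^2 on size-factor-normalized
    counts; the estimate is the median over genes with positive mean,
    floored at 1e-8.
    """
    norm = normalized_counts(counts, factors).to_numpy()
    mean = norm.mean(axis=1)
    var = norm.var(axis=1, ddof=1) if norm.shape[1] > 1 else np.zeros_like(mean)
    ok = mean > 0
    if not ok.any():
        return VST_ALPHA_FLOOR
    alpha = (var[ok] - mean[ok]) / mean[ok] ** 2
    return float(max(np.median(alpha), VST_ALPHA_FLOOR))


def vst(
    counts: pd.DataFrame | ExpressionMatrix,
    factors: pd.Series | None = None,
    alpha: float | None = None,
) -> pd.DataFrame:
    """Variance-stabilized layer from raw counts.

    ``alpha=None`` estimates a common dispersion by pooled method of
    moments (floored at 1e-8).
    """
    if isinstance(counts, ExpressionMatrix):
        counts = counts.counts
    if factors is None:
        factors = size_factors(counts)
    if alpha is None:
        alpha = estimate_common_dispersion(counts, factors)
    if alpha < 0:
        raise ValueError("dispersion alpha must be non-negative")
    norm = normalized_counts(counts, factors)
    return pd.DataFrame(
        vst_transform(norm.to_numpy(), alpha), index=counts.index, columns=counts.columns
    )


# ---------------------------------------------------------------------------
# detection rate
# ---------------------------------------------------------------------------

def detection_rate(
    expr: ExpressionMatrix, layer: str = "counts", threshold: float = 0.0
) -> pd.Series:
    """Per-sample fraction of annotated genes with value > threshold."""
    values = expr.layer(layer)
    return (values > threshold).mean(axis=0).rename("detection_rate")


# ---------------------------------------------------------------------------
# stage means and mean-relative expression
# ---------------------------------------------------------------------------

def stage_means(values: pd.DataFrame, stages: pd.Series) -> pd.DataFrame:
    """Average replicates within stage; columns ordered by first appearance."""
    stages = stages.reindex(values.columns)
    if stages.isna().any():
        raise ValueError("stage labels missing for some samples")
    order = list(dict.fromkeys(stages))
    grouped = values.T.groupby(stages, sort=False).mean().T
    return grouped[order]


def scale_to_stage_mean(
    values: pd.DataFrame,
    stages: pd.Series | None = None,
    log_base: float = 2.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Relative expression: log stage means centered on the per-gene mean.

    rel_is = log(mean_is + pc) - mean_s' log(mean_is' + pc); each row sums
    to zero across stages, so positive entries mark stages where the gene
    is preferentially active.  ``stages`` maps sample ids to stage labels;
    pass ``None`` when ``values`` already holds one column per stage.
    """
    means = stage_means(values, stages) if stages is not None else values
    if means.shape[1] < 2:
        raise ValueError("mean-relative expression needs at least two stages")
    logged = np.log(means.to_numpy(dtype=float) + pseudocount) / np.log(log_base)
    centered = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(centered, index=means.index, columns=means.columns)
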