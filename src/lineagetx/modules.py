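"""Dynamic-gene selection and expression-module discovery.

A gene is *dynamic* when it is differentially expressed between at least
two stages (significant in >= ``min_contrasts`` pairwise contrasts) and
robustly detected in at least one stage (stage-mean FPKM above a floor,
default 10).  Dynamic genes are grouped into expression modules by
agglomerative clustering of their mean-relative stage profiles with
correlation distance and average linkage, cut into exactly k clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from .containers import ModuleAssignment
from .quantify import stage_means


def select_dynamic_genes(
    de_results: dict[tuple[str, str], pd.DataFrame],
    fpkm: pd.DataFrame,
    stages: pd.Series,
    alpha: float = 0.05,
    fpkm_min: float = 10.0,
    p_col: str = "padj",
    min_contrasts: int = 1,
    expected_stages: list[str] | None = None,
) -> pd.Index:
    """Dynamic gene set at the default thresholds (p < 0.05, FPKM > 10).

    ``de_results`` must cover every unordered stage pair of the design
    (pass ``expected_stages`` to override the stage list inferred from the
    metadata); missing contrasts raise with the absent pairs listed.
    """
    if expected_stages is None:
        expected_stages = list(dict.fromkeys(stages.dropna()))
    wanted = {
        frozenset((a, b))
        for i, a in enumerate(expected_stages)
        for b in expected_stages[i + 1 :]
    }
    have = {frozenset(pair) for pair in de_results}
    missing = wanted - have
    if missing:
        pretty = sorted(tuple(sorted(m)) for m in missing)
        raise ValueError(f"DE results missing for stage pairs: {pretty}")

    sig_counts = None
    for table in de_results.values():
        sig = (table[p_col] < alpha).astype(int)
        sig_counts = sig if sig_counts is None else sig_counts.add(sig, fill_value=0)
    significant = sig_counts >= min_contrasts

    means = stage_means(fpkm, stages)
    detected = (means > fpkm_min).any(axis=1)
    keep = significant.reindex(fpkm.index, fill_value=False) & detected
    return fpkm.index[keep]


def cluster_modules(
    rel_expr: pd.DataFrame,
    k: int = 10,
    linkage: str = "average",
    distance: str = "correlation",
    height: float | None = None,
    min_module_size: int = 5,
) -> ModuleAssignment:
    """Agglomerative clustering of mean-relative profiles into k modules.

    Distance is 1 - Pearson correlation between profiles by default
    (shape-based grouping); constant rows, which have undefined
    correlation, are assigned distance 0 to each other and the maximum
    distance 2 to varying rows.  The tree is cut into exactly ``k``
    clusters (or at ``height`` when given); labels are renumbered 1..k in
    dendrogram leaf order so the assignment is deterministic.

    ``min_module_size`` makes the cut robust to stray genes: when the
    plain k-cut yields clusters below the floor, the tree is over-cut to
    the smallest k' >= k giving at least k clusters of adequate size, the
    k largest are kept as modules, and the remaining genes are assigned to
    the module with the nearest mean profile.  When no such k' exists
    (tiny inputs, k close to the gene count) the plain cut is used, so
    boundary behaviour such as k = n_genes (one gene per module) is
    preserved.  Set ``min_module_size=0`` to disable.
    """
    genes = list(rel_expr.index)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds the number of dynamic genes ({len(genes)})")
    x = rel_expr.to_numpy(dtype=float)
    if distance == "correlation":
        dmat = _correlation_distance(x)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        dmat = squareform(pdist(x, metric="euclidean"))
    else:
        raise ValueError(f"unsupported distance {distance!r}")
    z = hierarchy.linkage(squareform(dmat, checks=False), method=linkage)
    if height is not None:
        raw = hierarchy.fcluster(z, t=height, criterion="distance")
        k = int(raw.max())
    else:
        raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
        if min_module_size > 1:
            raw = _robust_cut(z, x, k, min_module_size, raw)
    leaves = hierarchy.leaves_list(z)
    labels = _relabel_by_leaf_order(raw, leaves)
    return ModuleAssignment(
        genes=genes,
        labels=labels,
        leaf_order=leaves,
        k=k,
        linkage_method=linkage,
        distance_metric=distance,
    )


def _robust_cut(
    z: np.ndarray, x: np.ndarray, k: int, min_size: int, plain: np.ndarray
) -> np.ndarray:
    """Over-cut until k clusters reach ``min_size``; absorb the rest.

    Keeps the k largest clusters (ties broken by cluster id) and assigns
    every remaining gene to the kept cluster whose mean profile is nearest
    in correlation.  Falls back to the plain k-cut when no k' <= n yields
    k sufficiently large clusters.
    """
    n = x.shape[0]
    if np.bincount(plain)[1:].min() >= min_size:
        return plain
    for k_prime in range(k, n + 1):
        raw = hierarchy.fcluster(z, t=k_prime, criterion="maxclust")
        sizes = np.bincount(raw)[1:]
        big = np.flatnonzero(sizes >= min_size) + 1
        if len(big) >= k:
            order = sorted(big, key=lambda c: (-sizes[c - 1], c))
            kept = order[:k]
            centroids = np.vstack([x[raw == c].mean(axis=0) for c in kept])
            out = np.zeros(n, dtype=int)
            for new, c in enumerate(kept, start=1):
                out[raw == c] = new
            stray = np.flatnonzero(out == 0)
            if stray.size:
                sim = _profile_correlation(x[stray], centroids)
                out[stray] = sim.argmax(axis=1) + 1
            return out
    return plain


def _profile_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows of a and rows of b (constant rows -> 0)."""

    def unitize(m: np.ndarray) -> np.ndarray:
        c = m - m.mean(axis=1, keepdims=True)
        norm = np.sqrt((c**2).sum(axis=1, keepdims=True))
        return np.divide(c, norm, out=np.zeros_like(c), where=norm > 0)

    return unitize(a) @ unitize(b).T


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation with a defined value for constant rows."""
    sd = x.std(axis=1)
    constant = sd == 0
    centered = x - x.mean(axis=1, keepdims=True)
    norm = np.where(constant, 1.0, np.sqrt((centered**2).sum(axis=1)))
    unit = centered / norm[:, None]
    corr = np.clip(unit @ unit.T, -1.0, 1.0)
    d = 1.0 - corr
    if constant.any():
        d[np.ix_(constant, ~constant)] = 2.0
        d[np.ix_(~constant, constant)] = 2.0
        d[np.ix_(constant, constant)] = 0.0
    np.fill_diagonal(d, 0.0)
    return d


def _relabel_by_leaf_order(raw: np.ndarray, leaves: np.ndarray) -> np.ndarray:
    """Renumber cluster labels 1..k by first appearance in leaf order."""
    mapping: dict[int, int] = {}
    for leaf in leaves:
        lab = int(raw[leaf])
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    return np.array([mapping[int(l)] for l in raw])


def module_recovery_score(
    assignment: ModuleAssignment, truth: pd.Series
) -> float:
    """Adjusted Rand index between inferred and planted module labels.

    ``truth`` maps gene ids to planted module labels; scored over the genes
    present in both (raises if the sets are disjoint).
    """
    inferred = assignment.as_series()
    common = inferred.index.intersection(truth.index)
    if len(common) == 0:
        raise ValueError("assignment and ground truth share no genes")
    return float(adjusted_rand_score(truth.loc[common], inferred.loc[common]))


def module_profiles(
    assignment: ModuleAssignment, rel_expr: pd.DataFrame
) -> pd.DataFrame:
    """Mean relative-expression profile per module (module x stage)."""
    labels = assignment.as_series()
    return rel_expr.loc[labels.index].groupby(labels).mean()
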