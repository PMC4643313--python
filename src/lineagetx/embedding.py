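"""Diffusion-map embedding of samples for developmental staging.

A Gaussian kernel on Euclidean distances between sample expression
profiles is density-normalized (anisotropy exponent 1), row-normalized to
a stochastic transition matrix, and eigendecomposed.  The diffusion
components (DCs) are the non-trivial eigenvectors ordered by decreasing
eigenvalue; on stage-structured data the leading component captures
developmental progression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .containers import DiffusionEmbedding


def diffusion_map(
    expr: pd.DataFrame,
    n_components: int = 3,
    bandwidth: float | str = "auto",
    stage_order: pd.Series | None = None,
) -> DiffusionEmbedding:
    """Diffusion map of ``expr`` (samples x genes).

    Parameters
    ----------
    expr:
        Sample-by-feature matrix (e.g. VST values of dynamic genes); no NaN.
    n_components:
        Number of diffusion components to return; must be < n_samples.
    bandwidth:
        Gaussian kernel sigma.  ``"auto"`` uses the median of the nonzero
        pairwise Euclidean distances.
    stage_order:
        Optional numeric stage rank per sample.  When given, each component
        is sign-oriented so its Spearman correlation with the stage order is
        non-negative; otherwise the first nonzero loading is made positive.

    Notes
    -----
    Kernel: K_ij = exp(-d_ij^2 / (2 sigma^2)); density normalization
    divides by the product of row and column kernel sums (anisotropy
    exponent 1); the final matrix is row-normalized to be stochastic.
    Components are deterministic up to sign.
    """
    x = expr.to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("expression matrix contains NaN")
    n = x.shape[0]
    if n < 3:
        raise ValueError("diffusion map needs at least 3 samples")
    if n_components >= n:
        raise ValueError("n_components must be smaller than the number of samples")

    d = squareform(pdist(x, metric="euclidean"))
    if bandwidth == "auto":
        nonzero = d[np.triu_indices(n, k=1)]
        nonzero = nonzero[nonzero > 0]
        if nonzero.size == 0:
            raise ValueError("all samples are identical; bandwidth undefined")
        sigma = float(np.median(nonzero))
    else:
        sigma = float(bandwidth)
        if sigma <= 0:
            raise ValueError("bandwidth must be positive")

    k = np.exp(-(d**2) / (2.0 * sigma**2))
    # density normalization, anisotropy exponent 1
    q = k.sum(axis=1)
    k_tilde = k / np.outer(q, q)
    # symmetric conjugate of the stochastic matrix for a stable eigensolve
    row = k_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(row)
    sym = k_tilde * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # map back to right eigenvectors of the stochastic matrix; drop the
    # trivial constant component (eigenvalue 1)
    psi = evecs * inv_sqrt[:, None]
    comps = psi[:, 1 : n_components + 1]
    lams = evals[1 : n_components + 1]
    comps = comps / np.linalg.norm(comps, axis=0)

    comps = _orient(comps, stage_order, expr.index)
    coords = pd.DataFrame(
        comps,
        index=expr.index,
        columns=[f"DC{i + 1}" for i in range(comps.shape[1])],
    )
    return DiffusionEmbedding(coords=coords, eigenvalues=lams, bandwidth=sigma)


def transition_matrix(expr: pd.DataFrame, bandwidth: float | str = "auto") -> np.ndarray:
    """Row-stochastic diffusion operator used by :func:`diffusion_map`."""
    x = expr.to_numpy(dtype=float)
    n = x.shape[0]
    d = squareform(pdist(x, metric="euclidean"))
    if bandwidth == "auto":
        nz = d[np.triu_indices(n, k=1)]
        nz = nz[nz > 0]
        sigma = float(np.median(nz))
    else:
        sigma = float(bandwidth)
    k = np.exp(-(d**2) / (2.0 * sigma**2))
    q = k.sum(axis=1)
    k_tilde = k / np.outer(q, q)
    return k_tilde / k_tilde.sum(axis=1, keepdims=True)


def _orient(
    comps: np.ndarray, stage_order: pd.Series | None, sample_ids: pd.Index
) -> np.ndarray:
    comps = comps.copy()
    if stage_order is not None:
        ranks = rankdata(stage_order.reindex(sample_ids).to_numpy(dtype=float))
        for j in range(comps.shape[1]):
            rho = np.corrcoef(rankdata(comps[:, j]), ranks)[0, 1]
            if rho < 0:
                comps[:, j] *= -1
    else:
        for j in range(comps.shape[1]):
            nz = np.flatnonzero(np.abs(comps[:, j]) > 1e-12)
            if nz.size and comps[nz[0], j] < 0:
                comps[:, j] *= -1
    return comps
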