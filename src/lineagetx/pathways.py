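"""Pathway expression scores and hypergeometric gene-set enrichment.

Pathway expression is summarized as the sum of member FPKM values divided
by the pathway size (i.e. the mean over members), per condition; scores can
be scaled to the cross-condition mean for comparison between conditions.
Over-representation is the hypergeometric upper-tail test with
Benjamini-Hochberg correction across the collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .differential import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Named gene sets (GMT semantics): unique names, nonempty sets."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"pathway {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def pathway_score(
    condition_fpkm: pd.DataFrame,
    members: set[str],
    count_missing: bool = False,
) -> pd.Series:
    """Size-normalized summed FPKM of pathway members, per condition.

    score_c = sum(member FPKM at c) / n, where n is the number of members
    present in the matrix (``count_missing=True`` divides by the full
    pathway size instead, counting absentees at 0).  Raises when no member
    is present; absent members are reported via logging.
    """
    present = [g for g in members if g in condition_fpkm.index]
    absent = sorted(set(members) - set(present))
    if not present:
        raise ValueError("no pathway member present in the expression matrix")
    if absent:
        logger.warning("pathway members absent from matrix (counted as 0): %s", absent[:10])
    denom = len(members) if count_missing else len(present)
    return condition_fpkm.loc[present].sum(axis=0) / denom


def score_collection(
    condition_fpkm: pd.DataFrame,
    collection: PathwayCollection,
    count_missing: bool = False,
) -> pd.DataFrame:
    """Pathway x condition score matrix (pathways with no member present dropped)."""
    rows = {}
    for name, members in collection:
        try:
            rows[name] = pathway_score(condition_fpkm, members, count_missing)
        except ValueError:
            logger.warning("pathway %r has no member in the matrix; skipped", name)
    return pd.DataFrame(rows).T


def scale_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Divide each pathway row by its cross-condition mean.

    Scaled rows have mean 1; all-zero rows stay 0 and are flagged in the
    log.  Requires >= 2 conditions.
    """
    if scores.shape[1] < 2:
        raise ValueError("scaling requires at least two conditions")
    means = scores.mean(axis=1)
    zero = means == 0
    if zero.any():
        logger.warning("pathways with zero mean score left at 0: %s", list(scores.index[zero])[:10])
    safe = means.replace(0, np.nan)
    out = scores.div(safe, axis=0).fillna(0.0)
    return out


def hypergeom_enrichment(
    query: set[str],
    collection: PathwayCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each pathway.

    p = P(X >= k) with X ~ Hypergeom(N=|universe|, K=|pathway & universe|,
    n=|query & universe|) and k the observed overlap.  Query genes outside
    the universe are dropped with a warning; pathways are intersected with
    the universe.  Returns a DataFrame with columns k, K, n, N, pval, padj
    (BH across the collection).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    stray = query - universe
    if stray:
        logger.warning("query genes outside universe dropped: %s", sorted(stray)[:10])
    q = query & universe
    if not q:
        raise ValueError("query and universe are disjoint")
    n_univ = len(universe)
    rows = []
    for name, members in collection:
        in_univ = members & universe
        k = len(q & in_univ)
        big_k = len(in_univ)
        # upper tail: P(X >= k) = sf(k - 1)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, len(q))) if big_k else 1.0
        rows.append((name, k, big_k, len(q), n_univ, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["pathway", "k", "K", "n", "N", "pval"]).set_index("pathway")
    out["padj"] = bh_adjust(out["pval"].to_numpy())
    return out
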