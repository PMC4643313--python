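"""Quantitative immunofluorescence lineage analysis.

Per-cell marker intensities (NANOG, GATA6, CDX2, DAPI) are DAPI-normalized,
thresholded into positive/negative calls (Otsu on log intensities by
default), and combined into mutually exclusive lineage classes:
NANOG-only (epiblast), GATA6-only (primitive endoderm), coexpressing and
double-negative.  NANOG-high cells carry at least 1.5x the average
normalized NANOG intensity of their embryo.  Per-embryo class proportions
are compared across treatments with one-way ANOVA and Tukey HSD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu

logger = logging.getLogger(__name__)

CHANNELS = ("nanog", "gata6", "cdx2", "dapi")
LINEAGE_CLASSES = ("NANOG-only", "GATA6-only", "coexpressing", "double-negative")
NANOG_HIGH_FACTOR = 1.5


# ---------------------------------------------------------------------------
# normalization and positivity calls
# ---------------------------------------------------------------------------

def normalize_cells(cells: pd.DataFrame) -> pd.DataFrame:
    """DAPI-normalize marker channels; cells without valid DAPI are dropped.

    Adds ``<channel>_norm`` columns (channel / DAPI of the same cell);
    original values are retained.  The number of dropped cells is logged
    and stored in ``result.attrs['n_dropped']``.
    """
    required = {"cell_id", "embryo_id", "treatment", *CHANNELS}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    valid = cells["dapi"].notna() & (cells["dapi"] > 0)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropped %d cells with zero/missing DAPI", n_dropped)
    out = cells.loc[valid].copy()
    for ch in ("nanog", "gata6", "cdx2"):
        out[f"{ch}_norm"] = out[ch] / out["dapi"]
    out.attrs["n_dropped"] = n_dropped
    return out


@dataclass
class ThresholdRule:
    """Positivity rule: 'otsu' (per embryo, on log10 values), 'fixed'
    (absolute threshold) or 'quantile' (per-embryo quantile)."""

    method: str = "otsu"
    threshold: float | None = None  # for 'fixed'
    q: float = 0.5  # for 'quantile'


def call_positive(
    cells: pd.DataFrame, channel: str, rule: ThresholdRule | None = None
) -> pd.Series:
    """Per-cell positivity for a normalized channel.

    Default rule is Otsu's threshold on the log10 distribution of the
    embryo's normalized intensities (log-normal intensity modes are
    symmetric in log space).  Embryos with fewer than 3 cells fall back to
    the global Otsu threshold, with a warning.  The thresholds actually
    applied are logged.
    """
    rule = rule or ThresholdRule()
    col = f"{channel}_norm"
    if col not in cells.columns:
        raise ValueError(f"channel column {col!r} not present; run normalize_cells first")
    values = cells[col].to_numpy(dtype=float)
    if rule.method == "fixed":
        if rule.threshold is None:
            raise ValueError("fixed rule requires a threshold")
        return pd.Series(values > rule.threshold, index=cells.index, name=f"{channel}_pos")
    if rule.method == "quantile":
        thr = cells.groupby("embryo_id")[col].transform(lambda v: v.quantile(rule.q))
        return pd.Series(values > thr.to_numpy(), index=cells.index, name=f"{channel}_pos")
    if rule.method != "otsu":
        raise ValueError(f"unknown threshold method {rule.method!r}")

    logv = np.log10(values + 1e-12)
    global_thr = _otsu_or_none(logv)
    calls = np.zeros(len(cells), dtype=bool)
    for embryo, idx in cells.groupby("embryo_id").indices.items():
        sub = logv[idx]
        if len(sub) < 3 or np.ptp(sub) == 0:
            thr = global_thr
            logger.warning(
                "embryo %s has <3 cells or constant %s; using global threshold", embryo, channel
            )
        else:
            thr = threshold_otsu(sub)
        if thr is None:  # fully degenerate input: everything negative
            continue
        calls[idx] = sub > thr
        logger.debug("embryo %s %s threshold (log10): %.4f", embryo, channel, thr)
    return pd.Series(calls, index=cells.index, name=f"{channel}_pos")


def _otsu_or_none(logv: np.ndarray) -> float | None:
    if len(logv) < 2 or np.ptp(logv) == 0:
        return None
    return float(threshold_otsu(logv))


# ---------------------------------------------------------------------------
# lineage classification
# ---------------------------------------------------------------------------

def classify_lineage(
    cells: pd.DataFrame,
    nanog_pos: pd.Series | None = None,
    gata6_pos: pd.Series | None = None,
    nanog_high_factor: float = NANOG_HIGH_FACTOR,
    high_scope: str = "embryo",
    high_ref: str = "positive",
) -> pd.DataFrame:
    """Assign each cell a lineage class and a NANOG-high flag.

    Classes: N+/G- -> NANOG-only, G+/N- -> GATA6-only, N+/G+ ->
    coexpressing, otherwise double-negative.  ``nanog_high`` is True when
    the cell is NANOG-positive and its normalized NANOG intensity is at
    least ``nanog_high_factor`` times the reference average (inclusive
    comparison).  The reference is the mean normalized NANOG over the
    NANOG-positive cells of the same embryo (``high_ref='positive'``,
    default): a NANOG-high cell is one that is unusually bright among the
    NANOG-expressing cells.  ``high_ref='all'`` averages over every cell
    instead; with dim negative-cell backgrounds that reference sits far
    below the positive population, so most positive cells clear 1.5x it
    and the flag loses discriminatory power.  ``high_scope='treatment'``
    pools the reference across the treatment arm rather than per embryo.
    """
    out = cells.copy()
    if nanog_pos is None:
        nanog_pos = call_positive(out, "nanog")
    if gata6_pos is None:
        gata6_pos = call_positive(out, "gata6")
    out["nanog_pos"] = nanog_pos.to_numpy()
    out["gata6_pos"] = gata6_pos.to_numpy()
    n, g = out["nanog_pos"], out["gata6_pos"]
    out["lineage_class"] = np.select(
        [n & ~g, g & ~n, n & g],
        ["NANOG-only", "GATA6-only", "coexpressing"],
        default="double-negative",
    )
    scope = "embryo_id" if high_scope == "embryo" else "treatment"
    if high_ref == "positive":
        pos_vals = out["nanog_norm"].where(out["nanog_pos"])
        ref = pos_vals.groupby(out[scope]).transform("mean")
    elif high_ref == "all":
        ref = out.groupby(scope)["nanog_norm"].transform("mean")
    else:
        raise ValueError(f"high_ref must be 'positive' or 'all', got {high_ref!r}")
    out["nanog_high"] = (
        (out["nanog_norm"] >= nanog_high_factor * ref).fillna(False) & out["nanog_pos"]
    )
    return out


def embryo_proportions(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-embryo class fractions, counts, and NANOG-high fraction.

    One row per embryo with its treatment, total cell count, the fraction
    of each lineage class (summing to 1) and ``frac_nanog_high``.
    """
    rows = []
    for embryo, sub in calls.groupby("embryo_id"):
        counts = sub["lineage_class"].value_counts()
        total = len(sub)
        row = {
            "embryo_id": embryo,
            "treatment": sub["treatment"].iloc[0],
            "n_cells": total,
        }
        for cls in LINEAGE_CLASSES:
            row[f"n_{cls}"] = int(counts.get(cls, 0))
            row[f"frac_{cls}"] = counts.get(cls, 0) / total
        row["frac_nanog_high"] = float(sub["nanog_high"].mean())
        rows.append(row)
    return pd.DataFrame(rows).set_index("embryo_id")


def treatment_summary(props: pd.DataFrame, stat: str) -> pd.DataFrame:
    """Mean +/- SD of a per-embryo statistic per treatment."""
    g = props.groupby("treatment")[stat]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n_embryos": g.size()})


# ---------------------------------------------------------------------------
# one-way ANOVA with Tukey HSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, q, p_adj


P_FLOOR = 1e-15


def anova_tukey(values: pd.Series, groups: pd.Series) -> AnovaTukeyResult:
    """One-way fixed-effects ANOVA with Tukey HSD post-hoc comparisons.

    ``values`` holds one observation per experimental unit (embryo) and
    ``groups`` the treatment label.  Pairwise p-values come from the
    studentized-range distribution with the within-group degrees of
    freedom (Tukey-Kramer for unequal group sizes).  With zero
    within-group variance and unequal means, p-values are floored at
    1e-15.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [values[labels == g] for g in names]
    ns = np.array([len(s) for s in samples])
    if (ns < 2).any():
        bad = [g for g, n in zip(names, ns) if n < 2]
        raise ValueError(f"groups with fewer than 2 observations: {bad}")
    k = len(names)
    n_total = ns.sum()
    means = np.array([s.mean() for s in samples])
    grand = values.mean()
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(((s - s.mean()) ** 2).sum() for s in samples))
    df_b, df_w = k - 1, int(n_total - k)
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w

    if ms_within == 0:
        if ss_between == 0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, P_FLOOR
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_b, df_w))
        p = max(p, P_FLOOR) if ss_between > 0 else p

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[j] - means[i]
            se = np.sqrt(ms_within / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
                p_adj = 1.0 if diff == 0 else P_FLOOR
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, df_w))
                p_adj = float(np.clip(p_adj, P_FLOOR if q > 0 else 0.0, 1.0))
                if q == 0:
                    p_adj = 1.0
            rows.append((names[i], names[j], diff, q, p_adj))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "q", "p_adj"])
    return AnovaTukeyResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        df_between=df_b,
        df_within=df_w,
        pairwise=pairwise,
    )


def quantify_if(
    cells: pd.DataFrame,
    stat: str = "frac_NANOG-only",
    rule: ThresholdRule | None = None,
) -> tuple[pd.DataFrame, AnovaTukeyResult]:
    """End-to-end IF quantification: normalize, call, classify, test.

    Returns (per-embryo proportion table, ANOVA/Tukey result for ``stat``).
    """
    norm = normalize_cells(cells)
    calls = classify_lineage(
        norm,
        call_positive(norm, "nanog", rule),
        call_positive(norm, "gata6", rule),
    )
    props = embryo_proportions(calls)
    result = anova_tukey(props[stat], props["treatment"])
    return props, result
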