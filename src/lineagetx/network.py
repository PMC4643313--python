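"""Interaction-network reduction and per-stage activity projection.

A curated directed signed network (e.g. a pluripotency interaction
network) is reduced to the dynamically expressed genes plus a fixed set of
anchor regulators (default Pou5f1, Nanog, Sox2).  A node is *active* at a
stage when its mean-relative (stage-scaled log) expression is strictly
positive there; an edge is active only when both endpoints are active.
Gene-symbol matching is case-insensitive with an optional synonym map.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ActivityState, Edge, InteractionNetwork

logger = logging.getLogger(__name__)

DEFAULT_ANCHORS = frozenset({"Pou5f1", "Nanog", "Sox2"})


def _canon(symbol: str, synonyms: dict[str, str] | None = None) -> str:
    s = symbol.strip()
    if synonyms:
        lowered = {k.casefold(): v for k, v in synonyms.items()}
        s = lowered.get(s.casefold(), s)
    return s.casefold()


def reduce_network(
    net: InteractionNetwork,
    dynamic_genes: set[str],
    anchors: set[str] = DEFAULT_ANCHORS,
    keep_isolated: bool = False,
    synonyms: dict[str, str] | None = None,
) -> InteractionNetwork:
    """Induced subgraph on (dynamic genes | anchors) & network nodes.

    Anchor nodes are retained even when isolated; other isolated nodes are
    dropped unless ``keep_isolated``.  Raises when the intersection is
    empty; warns when anchors are absent from the network.
    """
    canon_nodes = {_canon(n, synonyms): n for n in net.nodes}
    keep_keys = {_canon(g, synonyms) for g in dynamic_genes} | {
        _canon(a, synonyms) for a in anchors
    }
    anchor_keys = {_canon(a, synonyms) for a in anchors}
    missing_anchors = anchor_keys - set(canon_nodes)
    if missing_anchors:
        logger.warning("anchors absent from network: %s", sorted(missing_anchors))
    selected = {canon_nodes[k] for k in keep_keys & set(canon_nodes)}
    if not selected:
        raise ValueError("no network node matches the dynamic genes or anchors")
    edges = frozenset(
        e for e in net.edges if e.source in selected and e.target in selected
    )
    if not keep_isolated:
        touched = {e.source for e in edges} | {e.target for e in edges}
        is_anchor = {n for n in selected if _canon(n, synonyms) in anchor_keys}
        selected = touched | is_anchor
        if not selected:
            raise ValueError("reduction left no nodes (all isolated, no anchors)")
    return InteractionNetwork(nodes=frozenset(selected), edges=edges)


def node_activity(
    rel_expr: pd.DataFrame,
    stage: str,
    net: InteractionNetwork,
    synonyms: dict[str, str] | None = None,
) -> frozenset[str]:
    """Nodes with strictly positive mean-relative expression at ``stage``.

    Genes absent from ``rel_expr`` are inactive everywhere (warned).  Ties
    at exactly 0 (flat genes) are inactive, so no gene appears
    preferentially active at every stage.
    """
    if stage not in rel_expr.columns:
        raise ValueError(f"unknown stage {stage!r}; have {list(rel_expr.columns)}")
    expr_by_key = {_canon(g, synonyms): v for g, v in rel_expr[stage].items()}
    active = set()
    missing = []
    for node in net.nodes:
        key = _canon(node, synonyms)
        if key not in expr_by_key:
            missing.append(node)
            continue
        if expr_by_key[key] > 0:
            active.add(node)
    if missing:
        logger.warning(
            "%d network nodes missing from expression, treated inactive: %s",
            len(missing),
            sorted(missing)[:10],
        )
    return frozenset(active)


def active_edges(
    net: InteractionNetwork, active_nodes: frozenset[str] | set[str]
) -> frozenset[Edge]:
    """Edges whose source AND target are both active; sign preserved."""
    return frozenset(
        e for e in net.edges if e.source in active_nodes and e.target in active_nodes
    )


def activity_state(
    rel_expr: pd.DataFrame,
    stage: str,
    net: InteractionNetwork,
    synonyms: dict[str, str] | None = None,
) -> ActivityState:
    nodes = node_activity(rel_expr, stage, net, synonyms)
    return ActivityState(stage=stage, active_nodes=nodes, active_edges=active_edges(net, nodes))


def connectivity_profile(
    net: InteractionNetwork,
    rel_expr: pd.DataFrame,
    stages: list[str] | None = None,
    synonyms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Active node/edge counts per stage, with the peak stage flagged.

    Returns a DataFrame indexed by stage with columns ``n_active_nodes``,
    ``n_active_edges`` and ``is_peak`` (True for the stage of maximal edge
    count; first such stage in order on ties).
    """
    if stages is None:
        stages = list(rel_expr.columns)
    unknown = [s for s in stages if s not in rel_expr.columns]
    if unknown:
        raise ValueError(f"stages not present in relative expression: {unknown}")
    rows = []
    for s in stages:
        st = activity_state(rel_expr, s, net, synonyms)
        rows.append((s, st.n_active_nodes, st.n_active_edges))
    out = pd.DataFrame(rows, columns=["stage", "n_active_nodes", "n_active_edges"])
    out = out.set_index("stage")
    peak = out["n_active_edges"].to_numpy().argmax()
    out["is_peak"] = False
    out.iloc[peak, out.columns.get_loc("is_peak")] = True
    return out


def core_coexpression_stages(
    stage_fpkm: pd.DataFrame,
    core_genes: list[str],
    floor: float = 10.0,
    synonyms: dict[str, str] | None = None,
) -> set[str]:
    """Stages at which ALL core genes exceed the expression floor.

    Mirrors the check of whether one developmental stage coexpresses every
    component of a minimal self-renewal circuit.  ``stage_fpkm`` is a
    gene x stage matrix of stage-mean FPKM.  Missing core genes raise with
    the absentees listed.
    """
    if not core_genes:
        raise ValueError("core gene list is empty")
    by_key = {_canon(g, synonyms): g for g in stage_fpkm.index}
    rows = []
    absent = []
    for g in core_genes:
        key = _canon(g, synonyms)
        if key in by_key:
            rows.append(by_key[key])
        else:
            absent.append(g)
    if absent:
        raise ValueError(f"core genes absent from expression matrix: {absent}")
    sub = stage_fpkm.loc[rows]
    ok = (sub > floor).all(axis=0)
    return set(ok.index[ok])


# ---------------------------------------------------------------------------
# construction helpers
# ---------------------------------------------------------------------------

def network_from_edges(edges: list[tuple[str, str, str]], extra_nodes=()) -> InteractionNetwork:
    """Build an InteractionNetwork from (source, sign, target)-free triples.

    ``edges`` are (source, target, sign) triples with sign in
    {"activates", "inhibits"}; duplicates collapse.
    """
    edge_set = frozenset(Edge(s, t, sign) for s, t, sign in edges)
    nodes = {e.source for e in edge_set} | {e.target for e in edge_set} | set(extra_nodes)
    return InteractionNetwork(nodes=frozenset(nodes), edges=edge_set)
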