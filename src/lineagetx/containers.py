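"""Core data containers shared across the analysis stages.

The central object is :class:`ExpressionMatrix`, a genes-by-samples count
matrix with optional derived layers (FPKM, variance-stabilized values) and
per-sample metadata.  Everything is backed by pandas so gene and sample
identifiers travel with the values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METADATA_COLUMNS = ("stage", "lineage", "condition", "replicate")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression container.

    Parameters
    ----------
    counts:
        Raw fragment counts, genes in rows, samples in columns.  Values must
        be non-negative integers.
    samples:
        Per-sample metadata indexed by sample id with at least a ``stage``
        column; ``lineage``, ``condition`` and ``replicate`` are filled with
        defaults if absent.
    gene_lengths:
        Exonic length in bp per gene (required for FPKM).
    fpkm, vst:
        Optional derived layers with the same shape as ``counts``.
    total_fragments:
        Per-sample total mapped fragments used as the FPKM denominator.
        Defaults to the column sums of ``counts`` when absent.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_lengths: pd.Series | None = None
    fpkm: pd.DataFrame | None = None
    vst: pd.DataFrame | None = None
    total_fragments: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.copy()
        for col in METADATA_COLUMNS:
            if col not in self.samples.columns:
                if col == "replicate":
                    self.samples[col] = np.arange(1, len(self.samples) + 1)
                elif col == "stage":
                    raise ValueError("sample metadata must contain a 'stage' column")
                else:
                    self.samples[col] = self.samples["stage"]
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        counts = self.counts
        if not counts.index.is_unique or not counts.columns.is_unique:
            raise ValueError("gene and sample identifiers must be unique")
        values = counts.to_numpy()
        if values.size == 0:
            raise ValueError("empty count matrix")
        if np.any(values < 0):
            raise ValueError("counts must be non-negative")
        if not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integers")
        missing = set(counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"sample metadata missing for: {sorted(missing)}")
        for name, layer in (("fpkm", self.fpkm), ("vst", self.vst)):
            if layer is not None and layer.shape != counts.shape:
                raise ValueError(f"{name} layer shape does not match counts")
        if self.fpkm is not None and (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.reindex(counts.index)
            if lengths.isna().any():
                absent = lengths.index[lengths.isna()].tolist()[:5]
                raise ValueError(f"gene lengths missing for genes such as {absent}")
            if (lengths <= 0).any():
                raise ValueError("gene lengths must be strictly positive")

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def stage_of(self) -> pd.Series:
        """Stage label per sample, aligned to the count columns."""
        return self.samples.loc[self.sample_ids, "stage"]

    def layer(self, name: str) -> pd.DataFrame:
        """Return a layer by name ('counts', 'fpkm' or 'vst')."""
        table = {"counts": self.counts, "fpkm": self.fpkm, "vst": self.vst}
        if name not in table:
            raise KeyError(f"unknown layer {name!r}; expected one of {sorted(table)}")
        layer = table[name]
        if layer is None:
            raise KeyError(f"layer {name!r} has not been computed")
        return layer


@dataclass
class DiffusionEmbedding:
    """Samples embedded into diffusion components (DCs).

    ``coords`` holds one column per component, ordered by decreasing
    eigenvalue of the diffusion operator; the trivial unit eigenvalue and
    its constant eigenvector are excluded.  Component signs follow the
    convention documented in :func:`lineagetx.embedding.diffusion_map`.
    """

    coords: pd.DataFrame  # samples x components, columns DC1..DCn
    eigenvalues: np.ndarray
    bandwidth: float

    @property
    def sample_ids(self) -> pd.Index:
        return self.coords.index


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # "activates" | "inhibits"


@dataclass
class InteractionNetwork:
    """Directed signed interaction network over gene symbols."""

    nodes: frozenset[str]
    edges: frozenset[Edge]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.source not in self.nodes or e.target not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: {e}")
            if e.sign not in ("activates", "inhibits"):
                raise ValueError(f"edge sign must be activates/inhibits, got {e.sign!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, sign=e.sign)
        return g


@dataclass
class ActivityState:
    """Active subnetwork of an :class:`InteractionNetwork` at one stage."""

    stage: str
    active_nodes: frozenset[str]
    active_edges: frozenset[Edge]

    @property
    def n_active_nodes(self) -> int:
        return len(self.active_nodes)

    @property
    def n_active_edges(self) -> int:
        return len(self.active_edges)


@dataclass
class ModuleAssignment:
    """Partition of the dynamic gene set into expression modules."""

    genes: list[str]
    labels: np.ndarray  # module label per gene, contiguous 1..k
    leaf_order: np.ndarray  # dendrogram leaf order (indices into genes)
    k: int
    linkage_method: str
    distance_metric: str

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if len(labels) != len(self.genes):
            raise ValueError("one module label per gene required")
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError("module labels must be contiguous 1..k")

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=pd.Index(self.genes, name="gene_id"), name="module")
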