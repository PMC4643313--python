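"""Readers and writers for the tabular formats used across the pipeline.

All tabular outputs are UTF-8, tab-separated, and may carry ``#``-prefixed
metadata header lines with the parameters of the producing run; readers
skip such lines.  Counts round-trip losslessly as TSV or MatrixMarket MTX
with row/column name sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

from .containers import ExpressionMatrix, InteractionNetwork, Edge
from .pathways import PathwayCollection
from .synthetic import GroundTruth


def _write_header(handle, metadata: dict | None) -> None:
    if metadata:
        for key, value in metadata.items():
            handle.write(f"# {key}={value}\n")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def write_counts_tsv(counts: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, metadata)
        counts.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_counts_tsv(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    _validate_counts(counts, path)
    return counts


def _validate_counts(counts: pd.DataFrame, path) -> None:
    values = counts.to_numpy()
    bad = np.argwhere(values < 0)
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"{path}: negative count at gene {counts.index[r]!r} "
            f"(data row {r + 1}), sample {counts.columns[c]!r}"
        )
    if not np.allclose(values, np.round(values)):
        raise ValueError(f"{path}: counts must be integers")


def write_counts_mtx(counts: pd.DataFrame, prefix) -> None:
    """Write MatrixMarket ``<prefix>.mtx`` plus ``.rows``/``.cols`` sidecars."""
    prefix = Path(prefix)
    sio.mmwrite(str(prefix.with_suffix(".mtx")), sparse.csr_matrix(counts.to_numpy()))
    prefix.with_suffix(".rows").write_text("\n".join(map(str, counts.index)) + "\n")
    prefix.with_suffix(".cols").write_text("\n".join(map(str, counts.columns)) + "\n")


def read_counts_mtx(prefix) -> pd.DataFrame:
    prefix = Path(prefix)
    matrix = sio.mmread(str(prefix.with_suffix(".mtx")))
    matrix = np.asarray(matrix.todense()) if sparse.issparse(matrix) else np.asarray(matrix)
    rows = prefix.with_suffix(".rows").read_text().splitlines()
    cols = prefix.with_suffix(".cols").read_text().splitlines()
    if matrix.shape != (len(rows), len(cols)):
        raise ValueError(
            f"{prefix}: MTX dimensions {matrix.shape} do not match sidecars "
            f"({len(rows)} row names, {len(cols)} column names)"
        )
    counts = pd.DataFrame(matrix, index=pd.Index(rows, name="gene_id"), columns=cols)
    _validate_counts(counts, prefix)
    return counts


# ---------------------------------------------------------------------------
# sample metadata / annotation / layers
# ---------------------------------------------------------------------------

def write_sample_metadata(samples: pd.DataFrame, path) -> None:
    samples.rename_axis("sample_id").to_csv(path, sep="\t")


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if "stage" not in meta.columns:
        raise ValueError(f"{path}: sample metadata must contain a 'stage' column")
    return meta


def write_gene_annotation(lengths: pd.Series, path) -> None:
    lengths.rename("length_bp").rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_annotation(path) -> pd.Series:
    annot = pd.read_csv(path, sep="\t", index_col=0, comment="#")["length_bp"]
    if (annot <= 0).any():
        bad = annot.index[annot <= 0][0]
        raise ValueError(f"{path}: non-positive gene length for {bad!r}")
    return annot


def write_layer(layer: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a real-valued expression layer (FPKM, VST, relative expression)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, metadata)
        layer.rename_axis("gene_id").to_csv(fh, sep="\t")


def read_layer(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_expression_matrix(counts_path, metadata_path, annotation_path=None) -> ExpressionMatrix:
    counts = read_counts_tsv(counts_path)
    samples = read_sample_metadata(metadata_path)
    lengths = read_gene_annotation(annotation_path) if annotation_path else None
    return ExpressionMatrix(counts=counts, samples=samples, gene_lengths=lengths)


# ---------------------------------------------------------------------------
# gene sets (GMT) and networks (SIF / edge list)
# ---------------------------------------------------------------------------

def read_gmt(path) -> PathwayCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, desc, *genes = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            sets[name] = {g for g in genes if g}
            descriptions[name] = desc
    return PathwayCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: PathwayCollection, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_sif(path) -> InteractionNetwork:
    """Simple interaction format: ``source<TAB>interaction<TAB>target``."""
    edges = []
    nodes = set()
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # isolated node
                nodes.add(fields[0])
                continue
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 'source<TAB>interaction<TAB>target'")
            src, sign, tgt = fields
            if sign not in ("activates", "inhibits"):
                raise ValueError(f"{path}:{lineno}: interaction must be activates/inhibits, got {sign!r}")
            edges.append(Edge(src, tgt, sign))
            nodes.update((src, tgt))
    return InteractionNetwork(nodes=frozenset(nodes), edges=frozenset(edges))


def write_sif(net: InteractionNetwork, path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        touched = set()
        for e in sorted(net.edges, key=lambda e: (e.source, e.target, e.sign)):
            fh.write(f"{e.source}\t{e.sign}\t{e.target}\n")
            touched.update((e.source, e.target))
        for node in sorted(net.nodes - touched):
            fh.write(f"{node}\n")


def read_edge_list(path) -> InteractionNetwork:
    """3-column TSV with header: source, target, sign."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"source", "target", "sign"}
    if not required <= set(table.columns):
        raise ValueError(f"{path}: edge list needs columns {sorted(required)}")
    edges = frozenset(Edge(r.source, r.target, r.sign) for r in table.itertuples())
    nodes = frozenset({e.source for e in edges} | {e.target for e in edges})
    return InteractionNetwork(nodes=nodes, edges=edges)


def write_edge_list(net: InteractionNetwork, path) -> None:
    rows = sorted((e.source, e.target, e.sign) for e in net.edges)
    pd.DataFrame(rows, columns=["source", "target", "sign"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell tables and ground truth
# ---------------------------------------------------------------------------

CELL_COLUMNS = ["cell_id", "embryo_id", "treatment", "nanog", "gata6", "cdx2", "dapi"]


def write_cells_csv(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def read_cells_csv(path) -> pd.DataFrame:
    cells = pd.read_csv(path, comment="#")
    missing = set(CELL_COLUMNS) - set(cells.columns)
    if missing:
        raise ValueError(f"{path}: cell table missing columns {sorted(missing)}")
    return cells


def write_ground_truth(truth: GroundTruth, path) -> None:
    payload = {
        "dynamic_flag": truth.dynamic_flag.astype(bool).to_dict(),
        "expressed_flag": truth.expressed_flag.astype(bool).to_dict(),
        "module_label": truth.module_label.astype(int).to_dict(),
        "stage_mean": {
            "genes": list(truth.stage_mean.index),
            "stages": list(truth.stage_mean.columns),
            "values": truth.stage_mean.to_numpy().tolist(),
        },
        "lib_factors": truth.lib_factors.to_dict(),
        "pseudotime": truth.pseudotime.astype(int).to_dict(),
        "peak_stage": truth.peak_stage,
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    sm = payload["stage_mean"]
    return GroundTruth(
        dynamic_flag=pd.Series(payload["dynamic_flag"], name="dynamic").rename_axis("gene_id"),
        expressed_flag=pd.Series(payload["expressed_flag"], name="expressed").rename_axis("gene_id"),
        module_label=pd.Series(payload["module_label"], name="module", dtype=int).rename_axis("gene_id"),
        stage_mean=pd.DataFrame(
            sm["values"], index=pd.Index(sm["genes"], name="gene_id"), columns=sm["stages"]
        ),
        lib_factors=pd.Series(payload["lib_factors"], name="lib_factor"),
        pseudotime=pd.Series(payload["pseudotime"], name="pseudotime", dtype=int),
        peak_stage=payload["peak_stage"],
    )


def write_de_table(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        _write_header(fh, metadata)
        table.rename_axis("gene_id").to_csv(fh, sep="\t")
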