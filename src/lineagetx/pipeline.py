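"""End-to-end transcriptome pipeline: quantify -> differential ->
modules -> embedding -> [network] -> [pathways].

``run_pipeline`` reads the configured inputs, executes the stages in
order, writes every intermediate table and a JSON manifest (files,
parameters, thresholds, seed, version) sufficient to reproduce the run.
Any stage failure raises :class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import differential, embedding, io, modules, network, pathways, quantify

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    counts_path: str
    metadata_path: str
    annotation_path: str
    out_dir: str
    gmt_path: str | None = None
    sif_path: str | None = None
    run_pathways: bool = False
    alpha: float = 0.05
    fpkm_min: float = 10.0
    k: int = 10
    n_components: int = 3
    nanog_high_factor: float = 1.5
    anchors: tuple[str, ...] = ("Pou5f1", "Nanog", "Sox2")
    vst_alpha: float | None = None
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        for label, value in (
            ("alpha", self.alpha),
            ("fpkm_min", self.fpkm_min),
            ("k", self.k),
            ("nanog_high_factor", self.nanog_high_factor),
        ):
            if value <= 0:
                raise ValueError(f"threshold {label} must be positive")
        required = [self.counts_path, self.metadata_path, self.annotation_path]
        if self.run_pathways:
            if self.gmt_path is None:
                raise ValueError("pathway scoring requested but no GMT path configured")
            required.append(self.gmt_path)
        if self.sif_path is not None:
            required.append(self.sif_path)
        missing = [p for p in required if not Path(p).is_file()]
        if missing:
            raise FileNotFoundError(f"input files not found: {missing}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full transcriptome pipeline and return the manifest."""
    logging.basicConfig(level=config.log_level)
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(config).items() if k != "log_level"},
        "outputs": {},
    }

    def _record(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    # -- quantify ----------------------------------------------------------
    try:
        em = io.read_expression_matrix(
            config.counts_path, config.metadata_path, config.annotation_path
        )
        factors = quantify.size_factors(em.counts)
        em.fpkm = quantify.fpkm(em.counts, em.gene_lengths)
        vst_alpha = (
            config.vst_alpha
            if config.vst_alpha is not None
            else quantify.estimate_common_dispersion(em.counts, factors)
        )
        em.vst = quantify.vst(em.counts, factors, vst_alpha)
        stages = em.stage_of()
        rel = quantify.scale_to_stage_mean(em.fpkm, stages)
        logger.info("quantify: vst alpha=%.4g, size factors in [%.3f, %.3f]",
                    vst_alpha, factors.min(), factors.max())
        io.write_layer(em.fpkm, out / "fpkm.tsv", {"stage": "quantify"})
        io.write_layer(em.vst, out / "vst.tsv", {"stage": "quantify", "alpha": vst_alpha})
        io.write_layer(rel, out / "relative_expression.tsv", {"stage": "quantify"})
        factors.to_csv(out / "size_factors.tsv", sep="\t")
        for name in ("fpkm.tsv", "vst.tsv", "relative_expression.tsv", "size_factors.tsv"):
            _record(name.split(".")[0], out / name)
        manifest["parameters"]["vst_alpha_used"] = float(vst_alpha)
    except Exception as exc:  # noqa: BLE001 - halt with stage name
        raise PipelineError("quantify", exc) from exc

    # -- differential ------------------------------------------------------
    try:
        de = differential.de_all_pairs(em.counts, stages, factors=factors)
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        for (a, b), table in de.items():
            path = de_dir / f"de_{a}_vs_{b}.tsv"
            io.write_de_table(table, path, {"contrast": f"{a} vs {b}", "alpha": config.alpha})
            _record(f"de_{a}_vs_{b}", path)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("differential", exc) from exc

    # -- dynamic modules ---------------------------------------------------
    try:
        dynamic = modules.select_dynamic_genes(
            de, em.fpkm, stages, alpha=config.alpha, fpkm_min=config.fpkm_min
        )
        logger.info("modules: %d dynamic genes at padj<%.3g, FPKM>%.3g",
                    len(dynamic), config.alpha, config.fpkm_min)
        assignment = modules.cluster_modules(rel.loc[dynamic], k=config.k)
        table = assignment.as_series().to_frame()
        table["leaf_rank"] = pd.Series(
            {assignment.genes[i]: rank for rank, i in enumerate(assignment.leaf_order)}
        )
        table.to_csv(out / "modules.tsv", sep="\t")
        modules.module_profiles(assignment, rel.loc[dynamic]).to_csv(
            out / "module_profiles.tsv", sep="\t"
        )
        _record("modules", out / "modules.tsv")
        _record("module_profiles", out / "module_profiles.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dynamic_modules", exc) from exc

    # -- embedding ---------------------------------------------------------
    try:
        stage_order = pd.Series(
            {s: i for i, s in enumerate(dict.fromkeys(stages))}
        ).reindex(stages.values)
        stage_order.index = stages.index
        emb = embedding.diffusion_map(
            em.vst.loc[dynamic].T if len(dynamic) else em.vst.T,
            n_components=config.n_components,
            stage_order=stage_order,
        )
        emb.coords.rename_axis("sample_id").to_csv(out / "diffusion_map.tsv", sep="\t")
        pd.Series(emb.eigenvalues, name="eigenvalue").to_csv(out / "eigenvalues.tsv", sep="\t")
        _record("diffusion_map", out / "diffusion_map.tsv")
        _record("eigenvalues", out / "eigenvalues.tsv")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("embedding", exc) from exc

    # -- network (optional) ------------------------------------------------
    if config.sif_path is not None:
        try:
            net = io.read_sif(config.sif_path)
            reduced = network.reduce_network(net, set(dynamic), set(config.anchors))
            profile = network.connectivity_profile(reduced, rel)
            profile.to_csv(out / "network_activity.tsv", sep="\t")
            io.write_sif(reduced, out / "network_reduced.sif")
            _record("network_activity", out / "network_activity.tsv")
            _record("network_reduced", out / "network_reduced.sif")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("network", exc) from exc

    # -- pathways (optional) -----------------------------------------------
    if config.run_pathways:
        try:
            collection = io.read_gmt(config.gmt_path)
            stage_fpkm = quantify.stage_means(em.fpkm, stages)
            scores = pathways.score_collection(stage_fpkm, collection)
            scaled = pathways.scale_scores(scores)
            scores.to_csv(out / "pathway_scores.tsv", sep="\t")
            scaled.to_csv(out / "pathway_scores_scaled.tsv", sep="\t")
            enrich = pathways.hypergeom_enrichment(
                set(dynamic), collection, set(em.gene_ids)
            )
            enrich.to_csv(out / "pathway_enrichment.tsv", sep="\t")
            for name in ("pathway_scores", "pathway_scores_scaled", "pathway_enrichment"):
                _record(name, out / f"{name}.tsv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("pathways", exc) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
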