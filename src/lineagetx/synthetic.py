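"""Synthetic data with recorded ground truth.

The generator emulates the statistical structure of lineage-resolved
embryo RNA-seq: a minority of dynamic genes organized in stage-specific
expression modules, negative-binomial counts (variance mu + alpha*mu^2)
with log-normal library-size variation, a planted interaction network
whose nodes all peak at one stage, and per-cell immunofluorescence
intensity tables with planted treatment effects on lineage proportions.

Every random quantity is drawn from a seeded generator, so identical
configurations yield identical outputs, and the planted truth is returned
alongside the data for downstream recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, InteractionNetwork, Edge
from .lineage_if import LINEAGE_CLASSES

#: the study's full design: four embryonic stages from morula to
#: postimplantation epiblast, the E4.5 primitive endoderm, cultured ESCs
#: and the diapaused epiblast
FULL_STAGES = ("E2.5", "E3.5", "E4.5-EPI", "E4.5-PrE", "E5.5", "ESC", "diapause")
#: the four embryonic stages the dynamic-gene criterion is defined over
DEFAULT_STAGES = ("E2.5", "E3.5", "E4.5-EPI", "E5.5")

BASELINE_LOG_SD = 0.5  # per-gene baseline spread (log-normal, mean-preserving)


def default_module_profiles(
    n_stages: int, n_modules: int, fold: float = 4.0
) -> list[list[float]]:
    """Distinct stage-activity profiles: ``fold`` on active stages, 1 elsewhere.

    Modules are the non-empty proper subsets of stages ordered by subset
    size then lexicographically (single-stage peaks first, then
    two-stage blocks, ...), so any two module profiles differ in shape.
    """
    if n_modules > 2**n_stages - 2:
        raise ValueError(
            f"cannot build {n_modules} distinct profiles over {n_stages} stages"
        )
    profiles = []
    for size in range(1, n_stages):
        for active in combinations(range(n_stages), size):
            prof = [fold if s in active else 1.0 for s in range(n_stages)]
            profiles.append(prof)
            if len(profiles) == n_modules:
                return profiles
    return profiles


def smooth_module_profiles(
    n_stages: int, n_modules: int, fold: float = 4.0, width: float = 1.5
) -> list[list[float]]:
    """Gaussian-bump profiles along the stage axis (trajectory structure).

    Module m peaks at an evenly spaced center c_m in [0, n_stages - 1]:
    profile(s) = 1 + (fold - 1) * exp(-(s - c_m)^2 / (2 width^2)).
    Neighbouring stages share module activity, so stage-to-stage
    similarity decays with developmental distance — the geometry a
    diffusion map needs to order samples along a developmental axis.
    """
    centers = np.linspace(0.0, n_stages - 1.0, n_modules)
    grid = np.arange(n_stages)
    return [
        (1.0 + (fold - 1.0) * np.exp(-((grid - c) ** 2) / (2.0 * width**2))).tolist()
        for c in centers
    ]


@dataclass
class SimConfig:
    """Configuration of the count simulator.

    Defaults reflect the study design being emulated: four ordered
    embryonic stages, 4 replicates per stage, ~10% dynamic genes in ten
    modules with 4-fold stage effects, NB dispersion 0.1, ~20% library-size
    variation (log scale) and 65% of genes expressed (matching the 60%-70%
    detection rates of small-cell-number RNA-seq).
    """

    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 4
    frac_dynamic: float = 0.1
    n_modules: int = 10
    module_profiles: list[list[float]] | None = None
    baseline_mean: float = 50.0
    dispersion: float = 0.1
    libsize_log_sd: float = 0.2
    gene_length_range: tuple[int, int] = (500, 5000)
    frac_expressed: float = 0.65
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.stages) < 2:
            raise ValueError("at least two stages required")
        if self.replicates_per_stage <= 0:
            raise ValueError("replicates_per_stage must be positive")
        if not 0 <= self.frac_dynamic <= 1:
            raise ValueError("frac_dynamic must lie in [0, 1]")
        if not 0 < self.frac_expressed <= 1:
            raise ValueError("frac_expressed must lie in (0, 1]")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be non-negative")
        if self.libsize_log_sd < 0:
            raise ValueError("libsize_log_sd must be non-negative")
        lo, hi = self.gene_length_range
        if lo <= 0 or hi < lo:
            raise ValueError("gene_length_range must be positive and ordered")
        if self.module_profiles is None:
            self.module_profiles = default_module_profiles(len(self.stages), self.n_modules)
        if len(self.module_profiles) != self.n_modules:
            raise ValueError("number of module_profiles must equal n_modules")
        for prof in self.module_profiles:
            if len(prof) != len(self.stages):
                raise ValueError("each module profile needs one entry per stage")
            if any(v <= 0 for v in prof):
                raise ValueError("module profile multipliers must be positive")
        if self.n_dynamic < self.n_modules and self.frac_dynamic > 0:
            raise ValueError("frac_dynamic * n_genes must be >= n_modules")

    @property
    def n_dynamic(self) -> int:
        return int(round(self.frac_dynamic * self.n_genes))

    @property
    def n_samples(self) -> int:
        return len(self.stages) * self.replicates_per_stage


@dataclass
class GroundTruth:
    """Planted truth recorded by :func:`simulate_counts`."""

    dynamic_flag: pd.Series  # bool per gene
    expressed_flag: pd.Series  # bool per gene
    module_label: pd.Series  # module 1..k per dynamic gene
    stage_mean: pd.DataFrame  # true NB mean, gene x stage (before lib factors)
    lib_factors: pd.Series  # true library-size factor per sample
    pseudotime: pd.Series  # planted rank per sample (nondecreasing in stage order)
    peak_stage: str  # stage of maximal planted module coexpression


def simulate_counts(config: SimConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw a stage-structured NB count matrix with recorded ground truth.

    Non-dynamic genes have flat stage profiles; unexpressed genes have mean
    zero everywhere.  Counts are NB with mean
    ``baseline * profile * lib_factor`` and variance ``mu + alpha mu^2``
    (Poisson at alpha = 0).  Library-size factors are log-normal and
    mean-centered in log space, so their geometric mean is exactly 1.
    """
    rng = np.random.default_rng(config.seed)
    n, stages = config.n_genes, list(config.stages)
    genes = pd.Index([f"gene{i:05d}" for i in range(n)], name="gene_id")

    n_dyn = config.n_dynamic
    n_unexpr = int(round((1.0 - config.frac_expressed) * n))
    if n_dyn + n_unexpr > n:
        raise ValueError("frac_dynamic + (1 - frac_expressed) exceeds 1")
    perm = rng.permutation(n)
    dyn_idx = perm[:n_dyn]
    unexpr_idx = perm[n_dyn : n_dyn + n_unexpr]

    dynamic = np.zeros(n, dtype=bool)
    dynamic[dyn_idx] = True
    expressed = np.ones(n, dtype=bool)
    expressed[unexpr_idx] = False

    modules = np.zeros(n, dtype=int)
    if n_dyn:
        modules[dyn_idx] = np.arange(n_dyn) % config.n_modules + 1

    baseline = config.baseline_mean * np.exp(
        rng.normal(-(BASELINE_LOG_SD**2) / 2.0, BASELINE_LOG_SD, size=n)
    )
    profiles = np.asarray(config.module_profiles, dtype=float)
    stage_mean = np.tile(baseline[:, None], (1, len(stages)))
    if n_dyn:
        stage_mean[dyn_idx] = baseline[dyn_idx, None] * profiles[modules[dyn_idx] - 1]
    stage_mean[~expressed] = 0.0

    sample_ids, sample_stage, sample_rep = [], [], []
    for s in stages:
        for r in range(1, config.replicates_per_stage + 1):
            sample_ids.append(f"{s}_r{r}")
            sample_stage.append(s)
            sample_rep.append(r)
    m = len(sample_ids)
    log_factors = rng.normal(0.0, config.libsize_log_sd, size=m)
    log_factors -= log_factors.mean()
    lib = np.exp(log_factors)

    stage_idx = np.array([stages.index(s) for s in sample_stage])
    mu = stage_mean[:, stage_idx] * lib[None, :]
    counts = _nb_draw(rng, mu, config.dispersion)

    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=n
    )
    samples_meta = pd.DataFrame(
        {
            "stage": sample_stage,
            "lineage": sample_stage,
            "condition": sample_stage,
            "replicate": sample_rep,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    em = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        samples=samples_meta,
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
    )
    truth = GroundTruth(
        dynamic_flag=pd.Series(dynamic, index=genes, name="dynamic"),
        expressed_flag=pd.Series(expressed, index=genes, name="expressed"),
        module_label=pd.Series(modules[dyn_idx], index=genes[dyn_idx], name="module"),
        stage_mean=pd.DataFrame(stage_mean, index=genes, columns=stages),
        lib_factors=pd.Series(lib, index=sample_ids, name="lib_factor"),
        pseudotime=pd.Series(stage_idx, index=sample_ids, name="pseudotime"),
        peak_stage=_peak_stage(profiles, stages),
    )
    return em, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB(mean mu, variance mu + alpha mu^2); Poisson when alpha == 0."""
    if alpha == 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def _peak_stage(profiles: np.ndarray, stages: list[str]) -> str:
    """Stage where the most module profiles exceed their cross-stage mean."""
    above = profiles > profiles.mean(axis=1, keepdims=True)
    return stages[int(above.sum(axis=0).argmax())]


# ---------------------------------------------------------------------------
# planted interaction network
# ---------------------------------------------------------------------------

def simulate_network(
    config: SimConfig,
    truth: GroundTruth,
    n_nodes: int,
    edge_density: float,
    seed: int | None = None,
) -> InteractionNetwork:
    """Directed signed network over dynamic genes peaking at ``truth.peak_stage``.

    Nodes are sampled from dynamic genes whose planted profile exceeds its
    cross-stage mean at the peak stage, so node activity (and hence edge
    connectivity) is maximal there.  The edge count is deterministic:
    ``round(edge_density * n_nodes * (n_nodes - 1))`` ordered pairs sampled
    without replacement, random signs.
    """
    if not 0 < edge_density <= 1:
        raise ValueError("edge_density must lie in (0, 1]")
    dyn_genes = truth.dynamic_flag.index[truth.dynamic_flag]
    if n_nodes > len(dyn_genes):
        raise ValueError("n_nodes exceeds the number of dynamic genes")
    rng = np.random.default_rng(config.seed + 7919 if seed is None else seed)
    peak = truth.peak_stage
    prof = truth.stage_mean.loc[dyn_genes]
    peaked = prof.index[prof[peak] > prof.mean(axis=1)]
    if n_nodes > len(peaked):
        raise ValueError(
            f"only {len(peaked)} dynamic genes peak at {peak!r}; requested {n_nodes}"
        )
    nodes = sorted(rng.choice(peaked, size=n_nodes, replace=False))
    pairs = [(a, b) for a in nodes for b in nodes if a != b]
    n_edges = int(round(edge_density * len(pairs)))
    chosen = rng.choice(len(pairs), size=n_edges, replace=False)
    signs = rng.choice(["activates", "inhibits"], size=n_edges)
    edges = frozenset(
        Edge(pairs[i][0], pairs[i][1], sign) for i, sign in zip(chosen, signs)
    )
    return InteractionNetwork(nodes=frozenset(nodes), edges=edges)


# ---------------------------------------------------------------------------
# immunofluorescence cell tables
# ---------------------------------------------------------------------------

#: control-arm lineage class probabilities (late blastocyst ICM-like mix)
BASE_CLASS_PROBS = {
    "NANOG-only": 0.25,
    "GATA6-only": 0.35,
    "coexpressing": 0.10,
    "double-negative": 0.30,
}
#: log-normal intensity model (arbitrary fluorescence units)
CHANNEL_PARAMS = {
    "dapi": {"mean": 1000.0, "sigma": 0.30},
    "positive": {"mean": 600.0, "sigma": 0.35},
    "negative": {"mean": 60.0, "sigma": 0.35},
}
CDX2_POSITIVE_PROB = 0.3  # trophectoderm-like fraction, class-independent
VALID_CHANNELS = frozenset({"NANOG", "GATA6", "CDX2", "DAPI"})


@dataclass
class TreatmentEffect:
    """Planted effect of one treatment arm.

    class_weight:
        Multiplicative factors on the base class probabilities
        (renormalized), e.g. ``{"NANOG-only": 2.0, "GATA6-only": 0.3}``
        for an ERK-inhibition-like shift.
    channel_scale:
        Multiplicative shift of a channel's mean intensity in every cell,
        e.g. ``{"NANOG": 2.0}``.
    nanog_boost_frac / nanog_boost_scale:
        Fraction of NANOG-positive cells whose NANOG intensity is further
        multiplied by ``nanog_boost_scale`` — plants an excess of
        NANOG-high cells (WNT-inhibition-like effect).
    """

    class_weight: dict[str, float] = field(default_factory=dict)
    channel_scale: dict[str, float] = field(default_factory=dict)
    nanog_boost_frac: float = 0.0
    nanog_boost_scale: float = 1.0

    def __post_init__(self) -> None:
        for cls in self.class_weight:
            if cls not in LINEAGE_CLASSES:
                raise ValueError(f"unknown lineage class {cls!r}")
        for ch in self.channel_scale:
            if ch.upper() not in VALID_CHANNELS:
                raise ValueError(f"unknown channel name {ch!r}")
        if not 0 <= self.nanog_boost_frac <= 1:
            raise ValueError("nanog_boost_frac must lie in [0, 1]")


def simulate_if_cells(
    n_embryos_per_treatment: int,
    cells_per_embryo: int,
    treatments: list[str],
    effects: dict[str, TreatmentEffect] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell fluorescence intensity table with planted lineage classes.

    Intensities are log-normal around class-specific channel means;
    treatment effects shift class proportions and/or channel means as
    configured.  Returns ``(cells, truth)`` where ``truth`` records the
    planted lineage class per cell.
    """
    if n_embryos_per_treatment <= 0 or cells_per_embryo <= 0:
        raise ValueError("embryo and cell counts must be positive")
    effects = effects or {}
    for t in effects:
        if t not in treatments:
            raise ValueError(f"effect given for unknown treatment {t!r}")
    rng = np.random.default_rng(seed)
    classes = list(BASE_CLASS_PROBS)
    rows, truth_rows = [], []
    cell_counter = 0
    for treatment in treatments:
        eff = effects.get(treatment, TreatmentEffect())
        probs = np.array(
            [BASE_CLASS_PROBS[c] * eff.class_weight.get(c, 1.0) for c in classes]
        )
        probs /= probs.sum()
        scale = {ch.upper(): v for ch, v in eff.channel_scale.items()}
        for e in range(n_embryos_per_treatment):
            embryo_id = f"{treatment}_e{e + 1}"
            for _ in range(cells_per_embryo):
                cell_id = f"cell{cell_counter:06d}"
                cell_counter += 1
                cls = classes[rng.choice(len(classes), p=probs)]
                nanog_pos = cls in ("NANOG-only", "coexpressing")
                gata6_pos = cls in ("GATA6-only", "coexpressing")
                cdx2_pos = rng.random() < CDX2_POSITIVE_PROB
                dapi = _lognormal(rng, CHANNEL_PARAMS["dapi"]["mean"], CHANNEL_PARAMS["dapi"]["sigma"])
                nanog = _marker(rng, nanog_pos) * scale.get("NANOG", 1.0)
                gata6 = _marker(rng, gata6_pos) * scale.get("GATA6", 1.0)
                cdx2 = _marker(rng, cdx2_pos) * scale.get("CDX2", 1.0)
                dapi *= scale.get("DAPI", 1.0)
                if nanog_pos and eff.nanog_boost_frac > 0 and rng.random() < eff.nanog_boost_frac:
                    nanog *= eff.nanog_boost_scale
                rows.append(
                    (cell_id, embryo_id, treatment, nanog, gata6, cdx2, dapi)
                )
                truth_rows.append((cell_id, cls))
    cells = pd.DataFrame(
        rows, columns=["cell_id", "embryo_id", "treatment", "nanog", "gata6", "cdx2", "dapi"]
    )
    truth = pd.DataFrame(truth_rows, columns=["cell_id", "true_class"]).set_index("cell_id")
    return cells, truth


def _lognormal(rng: np.random.Generator, mean: float, sigma: float) -> float:
    """Log-normal draw with expected value ``mean``."""
    return float(np.exp(rng.normal(np.log(mean) - sigma**2 / 2.0, sigma)))


def _marker(rng: np.random.Generator, positive: bool) -> float:
    params = CHANNEL_PARAMS["positive" if positive else "negative"]
    return _lognormal(rng, params["mean"], params["sigma"])
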