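"""End-to-end orchestration: network -> vectors -> clusters -> enrichment -> effects.

All intermediates are plain TSV so stage-wise CLI runs and a single
:func:`run_pipeline` call produce byte-identical artifacts, and a JSON
manifest (config, seed, row counts, package version) records provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import clustering, diffusion, enrichment, evaluation, phenonet

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Pipeline inputs and tuning parameters.

    Defaults follow the reference analysis: restart probability 0.7,
    steady-state tolerance 1e-8, 1000 bootstrap resamples, AU threshold 0.95,
    Fisher alpha 0.001, effect-score cutoff 0.20.
    """

    relations: str = ""
    universe: str = ""
    efficacy: str = ""
    compounds: str = ""
    gold_standard: str | None = None
    r: float = 0.7
    tol: float = 1.0e-8
    n_boot: int = 1000
    au_threshold: float = 0.95
    fisher_alpha: float = 0.001
    effect_cutoff: float = 0.20
    linkage: str = "average"
    scales: list[float] = field(default_factory=lambda: list(clustering.DEFAULT_SCALES))
    fisher_sidedness: str = "greater"
    multi_cluster_combine: str = "max"
    rb_second_is_broader: bool = True
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.r < 1:
            raise ValueError("r must lie in (0, 1)")
        for name in ("au_threshold", "fisher_alpha", "effect_cutoff"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_boot < 1 or self.tol <= 0:
            raise ValueError("n_boot must be >= 1 and tol > 0")
        for key in ("relations", "universe", "efficacy", "compounds"):
            path = getattr(self, key)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{key} input missing: {path!r}")
        if self.gold_standard and not Path(self.gold_standard).exists():
            raise FileNotFoundError(f"gold_standard input missing: {self.gold_standard!r}")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing intermediates plus a manifest to ``outdir``."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    edges = phenonet.read_relations(config.relations, rb_second_is_broader=config.rb_second_is_broader)
    network = phenonet.weight_edges(phenonet.build_network(edges))
    phenonet.write_network(network, outdir / "network.tsv")
    universe = phenonet.read_universe(config.universe)
    counts["concepts"] = len(network.concepts)
    counts["universe"] = len(universe)
    logger.info("network: %d concepts, %d universe phenotypes", counts["concepts"], counts["universe"])

    profiles = diffusion.read_annotations(config.efficacy)
    matrix = diffusion.plant_vectors(network, profiles, universe, r=config.r, tol=config.tol)
    diffusion.write_matrix(matrix, outdir / "phenotype_matrix.tsv")
    counts["plants"] = matrix.shape[0]
    logger.info("vectors: %d plants mapped", counts["plants"])

    dend, support = clustering.assess_support(
        matrix,
        n_boot=config.n_boot,
        scales=tuple(config.scales),
        seed=config.seed,
        method=config.linkage,
    )
    clusters = clustering.pick_clusters(dend, support, threshold=config.au_threshold)
    clustering.write_clusters(clusters, outdir / "clusters.tsv")
    (outdir / "dendrogram.nwk").write_text(dend.to_newick() + "\n")
    support.table().to_csv(outdir / "cluster_support.tsv", sep="\t", index=False)
    counts["clusters"] = len(clusters)
    logger.info("clustering: %d supported clusters (AU >= %g)", len(clusters), config.au_threshold)

    catalog = enrichment.read_catalog(config.compounds)
    all_plants = frozenset(matrix.index)
    enriched = enrichment.enriched_compounds(
        clusters, catalog, all_plants, alpha=config.fisher_alpha, alternative=config.fisher_sidedness
    )
    enrichment.write_enrichment(enriched, outdir / "enrichment.tsv")
    counts["enriched"] = len(enriched)

    predictions = enrichment.predict_effects(enriched, matrix, clusters, combine=config.multi_cluster_combine)
    associations = enrichment.filter_effects(predictions, cutoff=config.effect_cutoff)
    enrichment.write_predictions(associations, outdir / "predictions.tsv")
    counts["associations"] = len(associations)
    logger.info("effects: %d compounds enriched, %d associations kept", len(enriched), len(associations))

    report = None
    if config.gold_standard:
        gold = evaluation.read_gold_standard(config.gold_standard)
        scored = {p.compound_id: p.scores for p in predictions}
        report = {
            axis: evaluation.averaged_metrics(scored, gold, axis=axis)
            for axis in ("compound", "phenotype")
        }
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")

    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "herbnet_version": __version__,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"counts": counts, "clusters": clusters, "predictions": predictions, "report": report}
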