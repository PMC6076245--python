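"""Synthetic worlds with planted pharmacological structure.

The generator emulates the statistical shape of a herbal-medicine knowledge
base: a rooted phenotype tree (standing in for a CUI hierarchy), latent
"efficacy themes" (disjoint phenotype subtrees two levels below the root),
plants annotated mostly from their theme's subtree with a tunable noise rate,
theme compounds present preferentially in theme plants (p_in vs p_out), and
background compounds sprinkled uniformly.  The planted truth maps every theme
compound to its theme's phenotype set, giving the whole pipeline a recoverable
ground truth without any external database.

All randomness flows from one integer seed through named substreams so each
stage regenerates independently.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .diffusion import PlantProfile
from .phenonet import HierarchyEdge, PhenotypeNetwork, build_network, weight_edges

_STREAM_THEMES = 1
_STREAM_PLANTS = 2
_STREAM_COMPOUNDS = 3

__all__ = ["SynthParams", "SyntheticWorld", "make_ontology", "plant_themes",
           "make_plants", "make_compounds", "make_world", "write_world"]


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic world; defaults give a strongly recoverable signal.

    tree_depth/branching: complete phenotype tree shape (depth 4, branching 3
    gives 40 concepts).  n_themes disjoint subtrees rooted two levels below
    the root act as efficacy themes; plants_per_theme plants each draw
    annotations_per_plant annotations from their theme subtree, replacing each
    with a uniform universe draw with probability annotation_noise.  Theme
    compounds appear in theme plants with probability p_in and elsewhere with
    p_out; n_background_compounds appear anywhere with probability
    background_presence.
    """

    tree_depth: int = 4
    branching: int = 3
    n_themes: int = 5
    plants_per_theme: int = 8
    annotations_per_plant: int = 4
    annotation_noise: float = 0.1
    compounds_per_theme: int = 3
    p_in: float = 0.9
    p_out: float = 0.05
    n_background_compounds: int = 30
    background_presence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tree_depth < 3 or self.branching < 2:
            raise ValueError("need tree_depth >= 3 and branching >= 2")
        for name in ("n_themes", "plants_per_theme", "annotations_per_plant",
                     "compounds_per_theme"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("annotation_noise", "p_in", "p_out", "background_presence"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class SyntheticWorld:
    params: SynthParams
    network: PhenotypeNetwork
    universe: list[str]
    themes: dict[str, frozenset[str]]  # theme root concept -> theme phenotype set
    plant_theme: dict[str, str]  # plant_id -> theme root
    profiles: list[PlantProfile]
    catalog: dict[str, set[str]] = field(default_factory=dict)
    truth: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def plants(self) -> frozenset[str]:
        return frozenset(p.plant_id for p in self.profiles)


def make_ontology(params: SynthParams) -> tuple[PhenotypeNetwork, list[str]]:
    """Complete rooted tree; universe = all non-root concepts (BFS order).

    Concept IDs are zero-padded BFS indices ("C000" is the root), so
    lexicographic tie-breaks coincide with generation order.
    """
    n_total = sum(params.branching**k for k in range(params.tree_depth))
    width = max(3, len(str(n_total - 1)))
    ids = [f"C{i:0{width}d}" for i in range(n_total)]
    edges = []
    for i in range(1, n_total):
        parent = (i - 1) // params.branching
        edges.append(HierarchyEdge(parent=ids[parent], child=ids[i]))
    network = weight_edges(build_network(edges))
    return network, ids[1:]


def _subtree(network: PhenotypeNetwork, root: str) -> frozenset[str]:
    import networkx as nx

    return frozenset(nx.descendants(network.graph, root) | {root})


def plant_themes(network: PhenotypeNetwork, params: SynthParams) -> dict[str, frozenset[str]]:
    """Choose n_themes disjoint subtrees rooted two levels below the root."""
    candidates = sorted(c for c in network.concepts if network.depth(c) == 3)
    if params.n_themes > len(candidates):
        raise ValueError(
            f"{params.n_themes} themes requested but only {len(candidates)} "
            "subtrees exist two levels below the root"
        )
    rng = np.random.default_rng([params.seed, _STREAM_THEMES])
    roots = sorted(str(r) for r in rng.choice(candidates, size=params.n_themes, replace=False))
    return {r: _subtree(network, r) for r in roots}


def make_plants(
    themes: dict[str, frozenset[str]], universe: list[str], params: SynthParams
) -> tuple[list[PlantProfile], dict[str, str]]:
    """Plants annotated from their theme subtree with per-annotation noise."""
    rng = np.random.default_rng([params.seed, _STREAM_PLANTS])
    profiles: list[PlantProfile] = []
    plant_theme: dict[str, str] = {}
    for t_idx, (root, phenos) in enumerate(sorted(themes.items())):
        pool = sorted(phenos)
        for j in range(params.plants_per_theme):
            a = params.annotations_per_plant
            picks = [str(p) for p in rng.choice(pool, size=min(a, len(pool)), replace=a > len(pool))]
            annotations = [
                universe[rng.integers(len(universe))] if rng.random() < params.annotation_noise else p
                for p in picks
            ]
            pid = f"plant_T{t_idx}_{j:02d}"
            profiles.append(PlantProfile(plant_id=pid, efficacy=frozenset(annotations)))
            plant_theme[pid] = root
    return profiles, plant_theme


def make_compounds(
    themes: dict[str, frozenset[str]],
    plant_theme: dict[str, str],
    params: SynthParams,
) -> tuple[dict[str, set[str]], dict[str, frozenset[str]]]:
    """Theme compounds (p_in/p_out presence) plus uniform background compounds."""
    rng = np.random.default_rng([params.seed, _STREAM_COMPOUNDS])
    plants = sorted(plant_theme)
    catalog: dict[str, set[str]] = {p: set() for p in plants}
    truth: dict[str, frozenset[str]] = {}
    for t_idx, (root, phenos) in enumerate(sorted(themes.items())):
        for j in range(params.compounds_per_theme):
            comp = f"cmpd_T{t_idx}_{j:02d}"
            truth[comp] = phenos
            for p in plants:
                prob = params.p_in if plant_theme[p] == root else params.p_out
                if rng.random() < prob:
                    catalog[p].add(comp)
    for j in range(params.n_background_compounds):
        comp = f"cmpd_BG_{j:02d}"
        for p in plants:
            if rng.random() < params.background_presence:
                catalog[p].add(comp)
    return catalog, truth


def make_world(params: SynthParams | None = None) -> SyntheticWorld:
    """Generate the full synthetic world from a single parameter set."""
    params = params or SynthParams()
    network, universe = make_ontology(params)
    themes = plant_themes(network, params)
    profiles, plant_theme = make_plants(themes, universe, params)
    catalog, truth = make_compounds(themes, plant_theme, params)
    return SyntheticWorld(
        params=params,
        network=network,
        universe=universe,
        themes=themes,
        plant_theme=plant_theme,
        profiles=profiles,
        catalog=catalog,
        truth=truth,
    )


def write_world(world: SyntheticWorld, outdir: str | Path) -> None:
    """Emit the TSV dialects the pipeline reads, plus a provenance JSON.

    relations.tsv rows state "concept2 is broader than concept1" (RB), the
    same orientation the parser assumes by default.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "relations.tsv", "w") as fh:
        for u, v in sorted(world.network.graph.edges):
            fh.write(f"{v}\tRB\t{u}\n")
    with open(outdir / "universe.txt", "w") as fh:
        fh.writelines(f"{c}\n" for c in world.universe)
    with open(outdir / "efficacy.tsv", "w") as fh:
        for prof in world.profiles:
            for c in sorted(prof.efficacy):
                fh.write(f"{prof.plant_id}\t{c}\n")
    with open(outdir / "compounds.tsv", "w") as fh:
        for plant in sorted(world.catalog):
            for comp in sorted(world.catalog[plant]):
                fh.write(f"{plant}\t{comp}\n")
    with open(outdir / "gold.tsv", "w") as fh:
        for comp in sorted(world.truth):
            for c in sorted(world.truth[comp]):
                fh.write(f"{comp}\t{c}\ttherapeutic\n")
    with open(outdir / "params.json", "w") as fh:
        json.dump(asdict(world.params), fh, indent=2, sort_keys=True)
        fh.write("\n")
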