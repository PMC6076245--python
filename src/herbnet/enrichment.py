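"""Compound enrichment in plant clusters and effect-vector mapping.

For each supported plant cluster, every compound found in at least one member
is tested for over-representation with a one-sided Fisher's exact test on the
2x2 table (in-cluster/has-compound).  Compounds below the p-value threshold
(default 0.001, no multiplicity correction) inherit the cluster's averaged
phenotype vector as their predicted pharmacological effects; a compound
enriched in several clusters combines the cluster means element-wise
(maximum by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .clustering import PlantCluster

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.001
DEFAULT_EFFECT_CUTOFF = 0.20

__all__ = [
    "ContingencyTable",
    "EnrichedCompound",
    "EffectPrediction",
    "read_catalog",
    "contingency",
    "fisher_exact",
    "enriched_compounds",
    "predict_effects",
    "filter_effects",
    "write_enrichment",
    "write_predictions",
]


def read_catalog(path) -> dict[str, set[str]]:
    """Read a (plant_id, compound_id) TSV into a plant -> compounds map."""
    table = pd.read_csv(path, sep="\t", header=None, names=["plant_id", "compound_id"], dtype=str)
    return {pid: set(grp["compound_id"]) for pid, grp in table.groupby("plant_id", sort=True)}


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: cluster membership x compound presence.

    a: in-cluster plants containing the compound, b: in-cluster lacking it,
    c: out-of-cluster containing it, d: out-of-cluster lacking it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(
    cluster: PlantCluster,
    compound_id: str,
    catalog: dict[str, set[str]],
    all_plants: set[str] | frozenset[str],
) -> ContingencyTable:
    if not set(cluster.members) <= set(all_plants):
        raise ValueError(f"cluster {cluster.cluster_id} members not all in the plant set")
    carriers = {p for p in all_plants if compound_id in catalog.get(p, ())}
    if not carriers:
        raise ValueError(f"compound {compound_id!r} absent from every plant")
    a = len(cluster.members & carriers)
    b = len(cluster.members) - a
    c = len(carriers) - a
    d = len(all_plants) - len(cluster.members) - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact p-value via the hypergeometric distribution.

    One-sided "greater" (the default) gives the enrichment tail
    P(X >= a) for X ~ Hypergeom(N, K = a + c, n = a + b); "two-sided" sums
    all tables with probability <= the observed one.
    """
    N, K, n = table.n, table.a + table.c, table.a + table.b
    if alternative == "greater":
        return float(hypergeom.sf(table.a - 1, N, K, n))
    if alternative == "two-sided":
        support = np.arange(max(0, n + K - N), min(n, K) + 1)
        pmf = hypergeom.pmf(support, N, K, n)
        p_obs = hypergeom.pmf(table.a, N, K, n)
        return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))
    raise ValueError(f"unknown alternative {alternative!r}")


@dataclass(frozen=True)
class EnrichedCompound:
    compound_id: str
    cluster_id: str
    p_value: float
    table: ContingencyTable


def enriched_compounds(
    clusters: list[PlantCluster],
    catalog: dict[str, set[str]],
    all_plants: set[str] | frozenset[str],
    alpha: float = DEFAULT_ALPHA,
    alternative: str = "greater",
) -> list[EnrichedCompound]:
    """Test every compound present in >= 1 cluster member; keep p < alpha.

    Raw p-values are thresholded directly (no multiple-testing correction);
    the threshold itself is the tuning knob.
    """
    results: list[EnrichedCompound] = []
    n_tested = 0
    for cluster in clusters:
        present = sorted(set().union(*(catalog.get(p, set()) for p in cluster.members)))
        for compound in present:
            tab = contingency(cluster, compound, catalog, all_plants)
            p = fisher_exact(tab, alternative=alternative)
            n_tested += 1
            if p < alpha:
                results.append(
                    EnrichedCompound(compound_id=compound, cluster_id=cluster.cluster_id, p_value=p, table=tab)
                )
    logger.info(
        "enriched_compounds: %d of %d (cluster, compound) tests below alpha=%g",
        len(results),
        n_tested,
        alpha,
    )
    return results


@dataclass
class EffectPrediction:
    compound_id: str
    scores: pd.Series  # indexed by universe concept IDs, values in [0, 1]
    clusters: tuple[str, ...]


def predict_effects(
    enriched: list[EnrichedCompound],
    matrix: pd.DataFrame,
    clusters: list[PlantCluster],
    combine: str = "max",
) -> list[EffectPrediction]:
    """Map averaged cluster phenotype vectors onto their enriched compounds.

    The effect vector of a (compound, cluster) pair is the arithmetic mean of
    the member plants' phenotype vectors.  A compound enriched in several
    clusters combines the cluster means element-wise ("max" keeps every
    cluster's signal undiluted; "mean" averages them).
    """
    if combine not in {"max", "mean"}:
        raise ValueError(f"unknown combine rule {combine!r}")
    by_id = {cl.cluster_id: cl for cl in clusters}
    cluster_mean: dict[str, pd.Series] = {}
    for cid, cl in by_id.items():
        missing = cl.members - set(matrix.index)
        if missing:
            raise ValueError(f"cluster {cid} members missing from the phenotype matrix: {sorted(missing)}")
        cluster_mean[cid] = matrix.loc[sorted(cl.members)].mean(axis=0)
    grouped: dict[str, list[str]] = {}
    for e in enriched:
        grouped.setdefault(e.compound_id, []).append(e.cluster_id)
    predictions: list[EffectPrediction] = []
    for compound in sorted(grouped):
        cids = tuple(sorted(set(grouped[compound])))
        stack = pd.concat([cluster_mean[c] for c in cids], axis=1)
        scores = stack.max(axis=1) if combine == "max" else stack.mean(axis=1)
        predictions.append(EffectPrediction(compound_id=compound, scores=scores, clusters=cids))
    return predictions


def filter_effects(
    predictions: list[EffectPrediction], cutoff: float = DEFAULT_EFFECT_CUTOFF
) -> list[tuple[str, str, float]]:
    """(compound, phenotype, score) pairs with score >= cutoff.

    Sorted by score descending, ties by (compound_id, concept_id).
    """
    out = [
        (pred.compound_id, concept, float(score))
        for pred in predictions
        for concept, score in pred.scores.items()
        if score >= cutoff
    ]
    out.sort(key=lambda t: (-t[2], t[0], t[1]))
    return out


def write_enrichment(enriched: list[EnrichedCompound], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tcompound_id\ta\tb\tc\td\tp_value\n")
        for e in enriched:
            t = e.table
            fh.write(f"{e.cluster_id}\t{e.compound_id}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\t{e.p_value:.6g}\n")


def write_predictions(associations: list[tuple[str, str, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("compound_id\tconcept_id\tscore\n")
        for compound, concept, score in associations:
            fh.write(f"{compound}\t{concept}\t{score:.6g}\n")
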