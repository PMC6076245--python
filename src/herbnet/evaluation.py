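"""Ranked-prediction evaluation against gold-standard associations.

Predicted compound-phenotype scores are evaluated as rankings: AUROC (area
under the ROC curve, equal to the tie-corrected Mann-Whitney statistic) and
AUPR (non-interpolated step-rule area under the precision-recall curve),
averaged either per compound (ranking phenotypes within each compound) or per
phenotype (ranking compounds within each phenotype).  Negatives are all
universe items not labelled positive for the unit being ranked.  Also
provided: the F1 threshold scan used to pick a score cutoff, rank-correlation
and top-fraction Tanimoto overlap between two methods, and the
network-proximity ("target-closeness") baseline that scores a
compound-phenotype pair by the average shortest-path distance between the
compound's targets and the phenotype's genes on a protein-interaction
network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "UndefinedMetricError",
    "read_gold_standard",
    "precision_recall",
    "auroc",
    "aupr",
    "averaged_metrics",
    "f1_scan",
    "rank_correlation",
    "top_fraction_tanimoto",
    "target_closeness",
]


class UndefinedMetricError(ValueError):
    pass


@dataclass(frozen=True)
class GoldStandard:
    """Known (compound, phenotype) associations with a provenance label."""

    pairs: frozenset[tuple[str, str, str]]  # (compound_id, concept_id, label)

    def positives(self, label: str | None = None) -> set[tuple[str, str]]:
        return {(c, p) for c, p, lab in self.pairs if label is None or lab == label}


def read_gold_standard(path) -> GoldStandard:
    table = pd.read_csv(
        path, sep="\t", header=None, names=["compound_id", "concept_id", "label"], dtype=str
    )
    bad = set(table["label"]) - {"therapeutic", "candidate"}
    if bad:
        raise ValueError(f"unknown gold-standard labels {sorted(bad)}")
    return GoldStandard(pairs=frozenset(map(tuple, table.itertuples(index=False))))


def precision_recall(
    predicted: set, positives: set, universe: set
) -> tuple[float, float]:
    """Precision TP/(TP+FP) and recall TP/(TP+FN); 0 when a denominator is 0."""
    if not predicted <= universe or not positives <= universe:
        raise ValueError("predicted and positive sets must lie inside the universe")
    tp = len(predicted & positives)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(positives) if positives else 0.0
    if not predicted:
        logger.debug("precision undefined (no predictions); reported as 0")
    return precision, recall


def _scores_labels(scores: dict[str, float], positives: set[str]) -> tuple[np.ndarray, np.ndarray]:
    items = sorted(scores)
    y = np.array([it in positives for it in items], dtype=bool)
    s = np.array([scores[it] for it in items], dtype=float)
    return s, y


def auroc(scores: dict[str, float], positives: set[str]) -> float:
    """AUROC as the normalized Mann-Whitney U with midrank tie correction."""
    s, y = _scores_labels(scores, positives)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUROC needs at least one positive and one negative")
    ranks = rankdata(s)  # midranks
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr(scores: dict[str, float], positives: set[str]) -> float:
    """Step-rule AUPR: mean over positives of precision at that positive's rank.

    Items are ranked by descending score with a deterministic lexicographic
    tie-break on the item ID.
    """
    if not positives & set(scores):
        raise UndefinedMetricError("AUPR needs at least one ranked positive")
    order = sorted(scores, key=lambda it: (-scores[it], it))
    n_pos = len(positives & set(scores))
    tp = 0
    area = 0.0
    for rank, item in enumerate(order, start=1):
        if item in positives:
            tp += 1
            area += tp / rank
    return area / n_pos


def averaged_metrics(
    predictions: dict[str, pd.Series],
    gold: GoldStandard,
    axis: str = "compound",
    label: str | None = None,
) -> dict:
    """Mean and sd of per-unit AUROC/AUPR over compounds or phenotypes.

    axis="compound": each compound's phenotypes are ranked by its effect
    vector.  axis="phenotype": each phenotype ranks the compounds by that
    phenotype's score.  Units without both a positive and a negative are
    skipped with a log entry.
    """
    positives = gold.positives(label)
    if axis == "compound":
        units = {c: dict(v.items()) for c, v in predictions.items()}
        unit_pos = {c: {p for cc, p in positives if cc == c} for c in units}
    elif axis == "phenotype":
        frame = pd.DataFrame(predictions)  # rows: phenotypes, cols: compounds
        units = {ph: dict(frame.loc[ph].items()) for ph in frame.index}
        unit_pos = {ph: {c for c, pp in positives if pp == ph} for ph in units}
    else:
        raise ValueError(f"unknown axis {axis!r}")
    rocs, prs, skipped = [], [], []
    for unit, scored in sorted(units.items()):
        pos = unit_pos[unit] & set(scored)
        if not pos or len(pos) == len(scored):
            skipped.append(unit)
            continue
        rocs.append(auroc(scored, pos))
        prs.append(aupr(scored, pos))
    if skipped:
        logger.info("averaged_metrics: skipped %d %s units without both classes", len(skipped), axis)
    if not rocs:
        raise UndefinedMetricError(f"no evaluable {axis} units")
    return {
        "axis": axis,
        "n_units": len(rocs),
        "n_skipped": len(skipped),
        "auroc_mean": float(np.mean(rocs)),
        "auroc_sd": float(np.std(rocs, ddof=1)) if len(rocs) > 1 else 0.0,
        "aupr_mean": float(np.mean(prs)),
        "aupr_sd": float(np.std(prs, ddof=1)) if len(prs) > 1 else 0.0,
    }


def f1_scan(
    scored_pairs: dict[tuple[str, str], float],
    positives: set[tuple[str, str]],
    thresholds: np.ndarray | None = None,
) -> tuple[float, dict[float, float]]:
    """F1 at each score threshold; returns (best threshold, full curve).

    Ties in the maximum go to the smaller threshold.
    """
    if thresholds is None:
        thresholds = np.arange(0.0, 0.9501, 0.05)
    universe = set(scored_pairs)
    pos = positives & universe
    curve: dict[float, float] = {}
    for t in thresholds:
        t = round(float(t), 10)
        predicted = {pair for pair, s in scored_pairs.items() if s >= t}
        p, r = precision_recall(predicted, pos, universe)
        curve[t] = 2 * p * r / (p + r) if (p + r) > 0 else 0.0
    best = max(sorted(curve), key=lambda t: curve[t])  # ties -> smallest threshold
    return best, curve


def rank_correlation(scores_a: dict[str, float], scores_b: dict[str, float]) -> float:
    """Spearman rank correlation over the shared item universe (midranked ties)."""
    shared = sorted(set(scores_a) & set(scores_b))
    if len(shared) < 2:
        raise UndefinedMetricError("rank correlation needs >= 2 shared items")
    rho = spearmanr([scores_a[i] for i in shared], [scores_b[i] for i in shared]).statistic
    return float(rho)


def top_fraction_tanimoto(
    scores_a: dict[str, float], scores_b: dict[str, float], fraction: float = 0.10
) -> float:
    """Tanimoto overlap |A&B|/|A|B| of the two top-fraction item sets."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    shared = sorted(set(scores_a) & set(scores_b))
    k = max(1, int(round(fraction * len(shared))))
    if not shared:
        raise UndefinedMetricError("empty item universe")
    top_a = set(sorted(shared, key=lambda i: (-scores_a[i], i))[:k])
    top_b = set(sorted(shared, key=lambda i: (-scores_b[i], i))[:k])
    return len(top_a & top_b) / len(top_a | top_b)


def target_closeness(
    compound_genes: set[str],
    phenotype_genes: set[str],
    ppi: nx.Graph,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Network-proximity baseline on a protein-interaction graph.

    Score: mean over the compound's target genes of the shortest-path
    distance to the nearest phenotype gene, computed on the PPI's largest
    connected component.  The permutation p-value is the fraction of
    ``n_perm`` uniformly drawn same-size gene sets with distance <= observed.
    """
    component = max(nx.connected_components(ppi), key=len)
    sub = ppi.subgraph(component)
    targets = sorted(compound_genes & component)
    disease = sorted(phenotype_genes & component)
    if not targets or not disease:
        raise ValueError("gene sets do not map onto the network's largest component")

    def mean_min_dist(src: list[str], dst: list[str]) -> float:
        dst_set = set(dst)
        total = 0.0
        for g in src:
            dists = nx.single_source_shortest_path_length(sub, g)
            total += min(dists[t] for t in dst_set if t in dists)
        return total / len(src)

    observed = mean_min_dist(targets, disease)
    rng = np.random.default_rng(seed)
    nodes = sorted(component)
    hits = 0
    for _ in range(n_perm):
        rt = list(rng.choice(nodes, size=len(targets), replace=False))
        rd = list(rng.choice(nodes, size=len(disease), replace=False))
        if mean_min_dist(rt, rd) <= observed:
            hits += 1
    return observed, hits / n_perm
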