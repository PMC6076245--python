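"""Hierarchical clustering of plant phenotype vectors with bootstrap support.

Plants are clustered by average-linkage agglomeration on cosine distances
between their phenotype vectors.  Cluster credibility follows the multiscale
bootstrap: phenotype columns are resampled with replacement at several sample
sizes (scale factors s of the column count), the fraction of resampled
dendrograms reproducing a node's exact member set gives its bootstrap
probability bp(s), and the approximately unbiased (AU) p-value is obtained by
fitting

    z(s) = Phi^{-1}(1 - bp(s)) = v * sqrt(s) + c / sqrt(s)

by weighted least squares and extrapolating: AU = 1 - Phi(v - c).  Clusters
whose AU reaches a threshold (default 0.95) are considered supported; nested
significant nodes are absorbed by their maximal significant ancestor so the
reported clusters are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm

logger = logging.getLogger(__name__)

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4
DEFAULT_N_BOOT = 1000
DEFAULT_AU_THRESHOLD = 0.95

__all__ = [
    "Dendrogram",
    "ClusterSupport",
    "PlantCluster",
    "cosine_distance",
    "hclust",
    "multiscale_bootstrap",
    "au_fit",
    "assess_support",
    "pick_clusters",
    "write_clusters",
]


class DegenerateInputError(ValueError):
    pass


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); 0 iff the vectors are positive scalar multiples."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise DegenerateInputError("cosine distance is undefined for a zero vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


@dataclass
class Dendrogram:
    """Average-linkage merge tree over named leaves.

    ``members[i]`` is the leaf-id set of internal node ``i`` (scipy order:
    node i merges at row i of the linkage matrix); ``heights`` are the merge
    distances, non-decreasing along root paths under average linkage.
    """

    leaves: list[str]
    Z: np.ndarray
    members: list[frozenset[str]] = field(init=False)
    heights: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.members = _member_sets(self.Z, self.leaves)
        self.heights = self.Z[:, 2].copy()

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def to_newick(self) -> str:
        n = self.n_leaves
        reps: dict[int, str] = {i: lbl for i, lbl in enumerate(self.leaves)}
        for i, (a, b, h, _) in enumerate(self.Z):
            reps[n + i] = f"({reps[int(a)]},{reps[int(b)]}):{h:.6g}"
        top = reps[2 * n - 2]
        return top.rsplit(":", 1)[0] + ";"


def _member_sets(Z: np.ndarray, leaves: list[str]) -> list[frozenset[str]]:
    n = len(leaves)
    sets: list[frozenset[str]] = [frozenset({l}) for l in leaves]
    for a, b, _, _ in Z:
        sets.append(sets[int(a)] | sets[int(b)])
    return sets[n:]


def _cosine_condensed(X: np.ndarray) -> np.ndarray:
    d = pdist(X, metric="cosine")
    # column resampling can zero out a row; treat such pairs as maximally distant
    bad = ~np.isfinite(d)
    if bad.any():
        d = d.copy()
        d[bad] = 1.0
    return d


def hclust(matrix: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of matrix rows on cosine distance."""
    if matrix.shape[0] < 2:
        raise ValueError("clustering needs at least two rows")
    X = matrix.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        zero = list(matrix.index[norms == 0])
        raise DegenerateInputError(f"zero phenotype vectors for plants {zero}")
    Z = linkage(_cosine_condensed(X), method=method)
    return Dendrogram(leaves=list(matrix.index), Z=Z)


@dataclass
class ClusterSupport:
    """Per internal node: bp across scales, fitted AU p-value and fit quality."""

    node_members: list[frozenset[str]]
    bp: list[dict[float, float]]
    au: list[float]
    fit_error: list[float]
    n_boot: int

    def table(self) -> pd.DataFrame:
        rows = []
        for i, mem in enumerate(self.node_members):
            row = {"node": i, "size": len(mem), "au": self.au[i], "fit_error": self.fit_error[i]}
            row.update({f"bp_{s:g}": p for s, p in self.bp[i].items()})
            rows.append(row)
        return pd.DataFrame(rows)


def multiscale_bootstrap(
    matrix: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    method: str = "average",
) -> tuple[Dendrogram, list[dict[float, float]]]:
    """Bootstrap probabilities of every dendrogram node across sample scales.

    For each scale ``s``, ``round(s * P)`` phenotype columns are drawn with
    replacement ``n_boot`` times; bp(node, s) is the fraction of resampled
    dendrograms containing an internal node with the identical member set.
    Per-scale RNG streams are derived from the single ``seed``.
    """
    dend = hclust(matrix, method=method)
    X = matrix.to_numpy(dtype=float)
    n, P = X.shape
    targets = {mem: i for i, mem in enumerate(dend.members)}
    counts = np.zeros((len(dend.members), len(scales)), dtype=np.int64)
    used_scales: list[float] = []
    for si, s in enumerate(scales):
        m = int(round(s * P))
        if m < 2:
            logger.info("multiscale_bootstrap: scale %g gives %d columns, skipped", s, m)
            continue
        used_scales.append(s)
        rng = np.random.default_rng([seed, si])
        for _ in range(n_boot):
            cols = rng.integers(0, P, size=m)
            Z = linkage(_cosine_condensed(X[:, cols]), method=method)
            for mem in _member_sets(Z, dend.leaves):
                j = targets.get(mem)
                if j is not None:
                    counts[j, si] += 1
    bp = [
        {s: counts[i, scales.index(s)] / n_boot for s in used_scales}
        for i in range(len(dend.members))
    ]
    return dend, bp


def au_fit(bp: dict[float, float], n_boot: int) -> tuple[float, float]:
    """Fit the two-parameter normal-quantile model and extrapolate the AU p-value.

    bp values are clamped into [1/(B+1), B/(B+1)] so the probit is finite;
    scales whose bp sits at a clamp bound contribute no quantile information
    (a cluster found in every resample, or never) and are excluded from the
    fit.  Weights come from the binomial variance of bp propagated through
    the probit transform.  Returns ``(au, fit_error)`` where fit_error is the
    weighted mean squared residual.  With fewer than two informative scales
    the fit is degenerate and the majority-side limit (0 or 1) is returned
    with fit_error = inf.
    """
    if len(bp) < 2:
        raise ValueError("AU fit needs bootstrap probabilities at >= 2 scales")
    lo, hi = 1.0 / (n_boot + 1), n_boot / (n_boot + 1.0)
    all_scales = np.array(sorted(bp))
    p_all = np.clip(np.array([bp[s] for s in all_scales]), lo, hi)
    informative = (p_all > lo) & (p_all < hi)
    if informative.sum() < 2:
        return (1.0 if p_all.mean() >= 0.5 else 0.0), float("inf")
    scales = all_scales[informative]
    p = p_all[informative]
    z = norm.ppf(1.0 - p)
    # var(z) = var(bp) / phi(z)^2, binomial var(bp) = p(1-p)/B
    var_z = p * (1.0 - p) / (n_boot * norm.pdf(z) ** 2)
    w = 1.0 / var_z
    X = np.column_stack([np.sqrt(scales), 1.0 / np.sqrt(scales)])
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(X.T @ WX, X.T @ (w * z), rcond=None)
    v, c = beta
    resid = z - X @ beta
    fit_error = float(np.average(resid**2, weights=w))
    au = float(1.0 - norm.cdf(v - c))
    return min(max(au, 0.0), 1.0), fit_error


def assess_support(
    matrix: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
    method: str = "average",
) -> tuple[Dendrogram, ClusterSupport]:
    """Run the multiscale bootstrap and fit AU p-values for every node."""
    dend, bp = multiscale_bootstrap(matrix, n_boot=n_boot, scales=scales, seed=seed, method=method)
    au: list[float] = []
    errs: list[float] = []
    for node_bp in bp:
        a, e = au_fit(node_bp, n_boot)
        au.append(a)
        errs.append(e)
    support = ClusterSupport(node_members=dend.members, bp=bp, au=au, fit_error=errs, n_boot=n_boot)
    return dend, support


@dataclass(frozen=True)
class PlantCluster:
    cluster_id: str
    members: frozenset[str]
    au: float


def pick_clusters(
    dend: Dendrogram,
    support: ClusterSupport,
    threshold: float = DEFAULT_AU_THRESHOLD,
) -> list[PlantCluster]:
    """Maximal non-root nodes with AU >= threshold; nested ones absorbed.

    The root (all leaves) is excluded, nested significant nodes are replaced
    by their outermost significant ancestor, and the returned clusters are
    mutually disjoint, ordered by decreasing size then member ids.
    """
    n_nodes = len(dend.members)
    candidates = [
        (i, dend.members[i])
        for i in range(n_nodes - 1)  # last node is the root
        if support.au[i] >= threshold and len(dend.members[i]) >= 2
    ]
    candidates.sort(key=lambda t: (-len(t[1]), sorted(t[1])))
    chosen: list[tuple[int, frozenset[str]]] = []
    for i, mem in candidates:
        if not any(mem <= kept for _, kept in chosen):
            chosen.append((i, mem))
    return [
        PlantCluster(cluster_id=f"cluster_{k + 1}", members=mem, au=support.au[i])
        for k, (i, mem) in enumerate(chosen)
    ]


def write_clusters(clusters: list[PlantCluster], path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tau\tmembers\n")
        for cl in clusters:
            fh.write(f"{cl.cluster_id}\t{cl.au:.6g}\t{','.join(sorted(cl.members))}\n")
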