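"""Random walk with restart over the weighted phenotype network.

A plant's known efficacy concepts seed a random walker that diffuses through
the hierarchy (treated as undirected, with Wu-Palmer edge weights as
transition affinities) and restarts at the seeds with probability ``r`` each
step:

    p_{t+1} = (1 - r) W p_t + r p_0

with ``W`` the column-normalized weighted adjacency matrix.  The steady state,
restricted to a fixed ordered phenotype universe, is the plant's phenotype
vector.  ``r = 0.7`` keeps diffusion local; iteration stops when the L1 change
drops below 1e-8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .phenonet import PhenotypeNetwork

logger = logging.getLogger(__name__)

DEFAULT_RESTART = 0.7
DEFAULT_TOL = 1e-8
MAX_ITERATIONS = 10_000

__all__ = [
    "PlantProfile",
    "TransitionMatrix",
    "ConvergenceError",
    "UnmappablePlantError",
    "read_annotations",
    "column_normalize",
    "make_seed",
    "rwr",
    "rwr_closed_form",
    "plant_vector",
    "plant_vectors",
    "ablation_vectors",
    "write_matrix",
    "read_matrix",
]


class ConvergenceError(RuntimeError):
    pass


class UnmappablePlantError(ValueError):
    """No efficacy concept of a plant maps into the network."""


@dataclass(frozen=True)
class PlantProfile:
    plant_id: str
    efficacy: frozenset[str]


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over an ordered concept list."""

    W: sp.csr_matrix
    concepts: list[str]
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.index = {c: i for i, c in enumerate(self.concepts)}
        cols = np.asarray(self.W.sum(axis=0)).ravel()
        if not np.allclose(cols, 1.0, atol=1e-9):
            raise ValueError("transition matrix columns must sum to 1")


def read_annotations(path) -> list[PlantProfile]:
    """Read a (plant_id, concept_id) TSV into per-plant efficacy profiles."""
    table = pd.read_csv(path, sep="\t", header=None, names=["plant_id", "concept_id"], dtype=str)
    profiles = [
        PlantProfile(plant_id=pid, efficacy=frozenset(grp["concept_id"]))
        for pid, grp in table.groupby("plant_id", sort=True)
    ]
    if not profiles:
        raise ValueError(f"no plant annotations in {path}")
    return profiles


def column_normalize(network: PhenotypeNetwork) -> TransitionMatrix:
    """Column-normalize the symmetric weighted adjacency of the network.

    Hierarchy edges are traversable in both directions.  A concept with no
    edges keeps all its mass via a unit self-loop.
    """
    if not network.weights:
        raise ValueError("network has no edge weights; call weight_edges first")
    concepts = network.concepts
    index = {c: i for i, c in enumerate(concepts)}
    n = len(concepts)
    rows, cols, vals = [], [], []
    for (u, v), w in network.weights.items():
        rows.append(index[u])
        cols.append(index[v])
        vals.append(w)
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    colsum = np.asarray(A.sum(axis=0)).ravel()
    isolated = np.where(colsum == 0)[0]
    if isolated.size:
        A = A + sp.coo_matrix(
            (np.ones(isolated.size), (isolated, isolated)), shape=(n, n)
        )
        colsum[isolated] = 1.0
    W = (A @ sp.diags(1.0 / colsum)).tocsr()
    return TransitionMatrix(W=W, concepts=concepts)


def make_seed(profile: PlantProfile, transition: TransitionMatrix) -> np.ndarray:
    """Uniform seed distribution over the plant's mapped efficacy concepts."""
    mapped = sorted(c for c in profile.efficacy if c in transition.index)
    missing = len(profile.efficacy) - len(mapped)
    if missing:
        logger.info(
            "make_seed: plant %s has %d efficacy concepts outside the network",
            profile.plant_id,
            missing,
        )
    if not mapped:
        raise UnmappablePlantError(
            f"plant {profile.plant_id} has no efficacy concept in the network"
        )
    p0 = np.zeros(len(transition.concepts))
    p0[[transition.index[c] for c in mapped]] = 1.0 / len(mapped)
    return p0


def rwr(
    transition: TransitionMatrix,
    p0: np.ndarray,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITERATIONS,
) -> np.ndarray:
    """Iterate the restart recursion to the steady state.

    Convergence is declared when the L1 norm of the update falls below
    ``tol``; exceeding ``max_iter`` raises :class:`ConvergenceError`.  The
    column-stochastic operator acts on the probability vector directly, so
    the walker's mass is conserved and the result sums to 1.
    """
    if not 0 < r < 1:
        raise ValueError(f"restart probability must lie in (0, 1), got {r}")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError("seed vector must sum to 1")
    W = transition.W
    p = p0.copy()
    for _ in range(max_iter):
        p_next = (1.0 - r) * (W @ p) + r * p0
        if np.abs(p_next - p).sum() < tol:
            return p_next
        p = p_next
    raise ConvergenceError(f"RWR did not converge within {max_iter} iterations")


def rwr_closed_form(
    transition: TransitionMatrix, p0: np.ndarray, r: float = DEFAULT_RESTART
) -> np.ndarray:
    """Direct linear solve of the steady state: p = r (I - (1-r) W)^{-1} p0."""
    n = len(transition.concepts)
    A = np.eye(n) - (1.0 - r) * transition.W.toarray()
    return r * np.linalg.solve(A, p0)


def steady_state(
    transition: TransitionMatrix,
    p0: np.ndarray,
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
    dense_cutoff: int = 2000,
) -> np.ndarray:
    """Dense closed-form solve for small networks, sparse iteration otherwise."""
    if len(transition.concepts) <= dense_cutoff:
        return rwr_closed_form(transition, p0, r)
    return rwr(transition, p0, r=r, tol=tol)


def plant_vector(
    steady: np.ndarray, transition: TransitionMatrix, universe: list[str]
) -> np.ndarray:
    """Project a steady state onto the universe order; no renormalization.

    Raw projection keeps values comparable across plants: each entry is the
    walker's stationary probability of that phenotype.
    """
    try:
        idx = [transition.index[c] for c in universe]
    except KeyError as exc:
        raise ValueError(f"universe concept {exc.args[0]!r} absent from the network") from exc
    return steady[idx]


def plant_vectors(
    network: PhenotypeNetwork,
    profiles: list[PlantProfile],
    universe: list[str],
    r: float = DEFAULT_RESTART,
    tol: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """RWR phenotype matrix: one row per mappable plant, universe columns.

    Plants with no mappable efficacy concept are skipped with a log entry.
    """
    transition = column_normalize(network)
    rows: dict[str, np.ndarray] = {}
    for profile in profiles:
        try:
            p0 = make_seed(profile, transition)
        except UnmappablePlantError:
            logger.warning("plant_vectors: excluding unmappable plant %s", profile.plant_id)
            continue
        steady = steady_state(transition, p0, r=r, tol=tol)
        rows[profile.plant_id] = plant_vector(steady, transition, universe)
    if not rows:
        raise UnmappablePlantError("no plant could be mapped onto the network")
    return pd.DataFrame.from_dict(rows, orient="index", columns=universe)


def ablation_vectors(profiles: list[PlantProfile], universe: list[str]) -> pd.DataFrame:
    """Hierarchy-free control: binary indicators of direct annotations.

    Each plant's vector is 1 on its annotated universe phenotypes and 0
    elsewhere; no diffusion, so hierarchy relations play no role.
    """
    col = {c: i for i, c in enumerate(universe)}
    rows: dict[str, np.ndarray] = {}
    for profile in profiles:
        vec = np.zeros(len(universe))
        hits = [col[c] for c in profile.efficacy if c in col]
        vec[hits] = 1.0
        if not hits:
            logger.warning(
                "ablation_vectors: plant %s has no annotation inside the universe",
                profile.plant_id,
            )
        rows[profile.plant_id] = vec
    return pd.DataFrame.from_dict(rows, orient="index", columns=universe)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="plant_id", float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="plant_id")
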