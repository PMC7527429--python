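"""Random-walk-with-restart (RWR) gene prioritization on a weighted network.

Candidate genes are scored by their diffusion proximity to a set of seed
genes with prior disease evidence.  The walk iterates

    P(l+1) = (1 - b) * Y @ P(l) + b * P0

where ``Y`` is the column-normalised connection matrix of the network,
``b`` is the restart probability and ``P0`` puts mass 1/T on each of the
T seed nodes.  The stationary distribution ranks non-seed genes; the top-k
become candidates for downstream prognostic modelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "RWRConfig",
    "TransitionMatrix",
    "build_transition_matrix",
    "rwr",
    "rwr_closed_form",
    "rank_top_k",
]

#: Seed genes used by default: ovarian-cancer pathway genes with prior evidence.
DEFAULT_SEEDS = ("ACOT7", "CERK", "EHMT2", "MTAP", "PDE8A")


@dataclass(frozen=True)
class RWRConfig:
    """Parameters of the restart walk.

    b
        Restart probability in (0, 1].  Higher values keep the walker near
        the seeds; 0.7 is the conventional choice for gene prioritization.
    max_iter
        Iteration cap.  With the default L1 tolerance the walk converges in
        far fewer steps; the cap is a safety net.
    tol
        L1 convergence threshold on successive iterates.
    k
        Number of top-ranked non-seed genes to report.
    """

    b: float = 0.7
    max_iter: int = 100_000
    tol: float = 1e-10
    k: int = 200

    def __post_init__(self) -> None:
        if not 0.0 < self.b <= 1.0:
            raise ValueError(f"restart probability b must be in (0, 1], got {self.b}")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic operator ``Y`` over an ordered node list.

    Columns of isolated (degree-zero) nodes are all-zero; the walk routine
    compensates by teleporting the escaping mass back to the restart
    distribution so that total probability is conserved.
    """

    nodes: tuple[str, ...]
    Y: np.ndarray = field(repr=False)

    @property
    def dangling(self) -> np.ndarray:
        """Boolean mask of zero-column (isolated) nodes."""
        return self.Y.sum(axis=0) == 0

    def index_of(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.nodes)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in network: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)


def build_transition_matrix(net: nx.Graph) -> TransitionMatrix:
    """Column-normalise the weighted adjacency matrix of ``net``.

    ``Y[i, j] = w(i, j) / sum_i w(i, j)`` so that a walker at node ``j``
    moves to neighbour ``i`` with probability proportional to the edge
    weight.  Node order is sorted lexicographically for determinism.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = tuple(sorted(net.nodes()))
    W = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    if (W < 0).any():
        raise ValueError("negative edge weight in network")
    if np.diag(W).any():
        raise ValueError("self-loop in network")
    colsum = W.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        Y = np.where(colsum > 0, W / colsum, 0.0)
    return TransitionMatrix(nodes=nodes, Y=Y)


def _initial_vector(tm: TransitionMatrix, seeds) -> np.ndarray:
    seeds = list(seeds)
    if not seeds:
        raise ValueError("need at least one seed gene")
    idx = tm.index_of(seeds)
    p0 = np.zeros(len(tm.nodes))
    p0[idx] = 1.0 / len(seeds)  # 1/T on each of the T seeds
    return p0


def rwr(
    tm: TransitionMatrix, seeds, cfg: RWRConfig = RWRConfig()
) -> tuple[np.ndarray, int]:
    """Iterate the restart walk to its fixed point.

    Returns the stationary probability vector (aligned with ``tm.nodes``)
    and the number of iterations performed.  Mass that would leak through
    zero columns (isolated nodes) is teleported back to the restart
    distribution, so the vector sums to 1 at every iterate.
    """
    p0 = _initial_vector(tm, seeds)
    dangling = tm.dangling
    p = p0.copy()
    for it in range(1, cfg.max_iter + 1):
        moved = (1.0 - cfg.b) * (tm.Y @ p)
        leaked = (1.0 - cfg.b) * p[dangling].sum()
        p_next = moved + (cfg.b + leaked) * p0
        resid = np.abs(p_next - p).sum()
        p = p_next
        if resid < cfg.tol:
            return p, it
    warnings.warn(
        f"RWR did not converge in {cfg.max_iter} iterations "
        f"(final L1 residual {resid:.3e})",
        RuntimeWarning,
        stacklevel=2,
    )
    return p, cfg.max_iter


def rwr_closed_form(tm: TransitionMatrix, seeds, b: float) -> np.ndarray:
    """Exact stationary solution ``b (I - (1-b) Y~)^-1 P0``.

    ``Y~`` is ``Y`` with dangling columns replaced by the restart
    distribution, matching the teleport convention of :func:`rwr`.  Used as
    the independent linear-algebra oracle for the iterative solver.
    """
    if not 0.0 < b <= 1.0:
        raise ValueError("b must be in (0, 1]")
    p0 = _initial_vector(tm, seeds)
    Y = tm.Y.copy()
    dangling = tm.dangling
    if dangling.any():
        Y[:, dangling] = p0[:, None]
    n = len(tm.nodes)
    A = np.eye(n) - (1.0 - b) * Y
    return b * np.linalg.solve(A, p0)


def rank_top_k(
    p: np.ndarray, tm: TransitionMatrix, seeds, cfg: RWRConfig = RWRConfig()
) -> list[tuple[str, float]]:
    """Top-k non-seed genes by stationary probability.

    Seeds are the query, not candidates, and are excluded.  Ties are broken
    lexicographically by gene id so the ranking is deterministic.
    """
    seed_set = set(seeds)
    candidates = [
        (gene, float(p[i])) for i, gene in enumerate(tm.nodes) if gene not in seed_set
    ]
    candidates.sort(key=lambda gp: (-gp[1], gp[0]))
    if cfg.k > len(candidates):
        warnings.warn(
            f"requested top {cfg.k} but only {len(candidates)} candidates; "
            "returning all",
            RuntimeWarning,
            stacklevel=2,
        )
        return candidates
    return candidates[: cfg.k]
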