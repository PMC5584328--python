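"""In-silico prediction of expression-invariant (reference) genes.

Genes are ranked ``i = 1..n`` by their expression averaged over all samples
(ascending; identically-zero genes are dropped). The ranked genes form the
nodes of a directed acyclic graph in which every gene is connected to every
higher-ranked gene, and the invariant set is the cheapest path from the most
lowly expressed non-zero gene (source, rank 1) to the most highly expressed
gene (target, rank n). The cost of the edge (i, j), j > i, is

    c_ij = d_ij + (j - i - 1) * m + k_ij * h

where ``d_ij`` is a normalised Euclidean distance between the two genes'
centered log2 expression profiles, the flat penalty ``m`` is paid once for
every gene skipped between i and j, and ``k_ij`` counts the samples in which
the higher-ranked gene j is expressed *below* the lower-ranked gene i — an
expression-order inversion, evidence that the two genes are not jointly
stable — each inversion costing ``h``. Known reference genes act as reward
sinks: visiting one subtracts ``r`` from the objective, so sufficiently
large ``r`` guarantees their inclusion while still allowing a reference
whose detour is costlier than ``r`` to be rejected.

The minimization is an instance of a minimum-cost flow / shortest-path
linear program, solved here exactly by dynamic programming in
``O(n^2 * n_s)`` with edge costs computed on the fly.

Normalised distance
-------------------
``d_ij`` is computed on log2(expression + pseudocount) profiles, each gene's
profile centered by its own cross-sample mean, with the squared distance
divided by the number of samples before the square root:

    d_ij = sqrt( sum_s ((p_i[s] - mean(p_i)) - (p_j[s] - mean(p_j)))^2 / n_s )

Centering makes two genes at different absolute levels but with the same
profile *shape* mutually reachable at near-zero cost (the invariant path
must span the whole dynamic range); the 1/n_s scaling keeps d comparable to
the flat penalties m and h across designs with different sample counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix, log_transform

__all__ = [
    "SelectorConfig",
    "RankedGeneIndex",
    "EdgeCost",
    "PathSolution",
    "rank_genes",
    "normalized_distance",
    "inversion_count",
    "edge_cost",
    "solve_cheapest_path",
    "select_invariant_genes",
]


@dataclass(frozen=True)
class SelectorConfig:
    """Tuning constants of the cheapest-path selector.

    ``m`` (flat skip penalty, default 4.0) and ``h`` (per-inversion penalty,
    default 5.0) control how many genes end up on the path; ``r`` (default
    800.0) is the reward for visiting a known reference gene — roughly the
    number of genes divided by the number of reference genes, and large
    enough that known references are normally kept on the path.
    """

    m: float = 4.0
    h: float = 5.0
    r: float = 800.0
    pseudocount: float = 1.0
    known_reference_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.m < 0 or self.h < 0 or self.r < 0:
            raise ValueError("penalties m, h and reward r must be non-negative")
        if not self.pseudocount > 0:
            raise ValueError("pseudocount must be positive")
        object.__setattr__(
            self, "known_reference_ids", frozenset(self.known_reference_ids)
        )


@dataclass
class RankedGeneIndex:
    """Genes ranked ascending by mean expression; the DP's node set.

    Ranks are 1-based: ``gene_ids[0]`` has rank 1 (lowest mean, the path
    source) and ``gene_ids[-1]`` rank n (highest mean, the target). Ties in
    mean expression are broken by lexicographic gene ID so the ranking is
    deterministic.
    """

    gene_ids: list
    mean_expression: np.ndarray
    is_known_reference: np.ndarray
    excluded_zero_genes: list

    @property
    def n(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class EdgeCost:
    """Cost breakdown of a single DAG edge between ranks i < j (1-based)."""

    i: int
    j: int
    d: float
    k: int
    cost: float


@dataclass
class PathSolution:
    """The optimal source-to-target path and its objective.

    ``objective`` is the raw sum of edge costs z = sum c_ij; since reward
    sinks subtract r per known reference visited, ``reward_adjusted`` =
    z + sum b over visited nodes is also reported (it may be negative).
    """

    ranks: list[int]
    gene_ids: list
    objective: float
    reward_adjusted: float
    edges: list[EdgeCost]
    rejected_references: list

    @property
    def n_selected(self) -> int:
        return len(self.ranks)

    @property
    def total_inversions(self) -> int:
        return int(sum(e.k for e in self.edges))


def rank_genes(matrix: ExpressionMatrix, config: SelectorConfig) -> RankedGeneIndex:
    """Rank genes ascending by mean expression, dropping all-zero genes.

    Requires an rpkm/fpkm-scale matrix (convert counts first) and at least
    two genes with non-zero expression. Known reference IDs missing from
    the matrix, or identically zero, are dropped with a warning.
    """
    if matrix.kind == "counts":
        raise ValueError(
            "rank_genes requires rpkm/fpkm-scale values; convert counts with "
            "compute_rpkm first"
        )
    values = matrix.data.to_numpy(dtype=float)
    nonzero = values.any(axis=1)
    excluded = [g for g, keep in zip(matrix.gene_ids, nonzero) if not keep]
    if int(nonzero.sum()) < 2:
        raise ValueError(
            f"need at least 2 genes with non-zero expression, got {int(nonzero.sum())}"
        )
    kept_ids = np.asarray(matrix.gene_ids, dtype=object)[nonzero]
    means = values[nonzero].mean(axis=1)
    # stable sort on (mean, gene_id): lexicographic ID breaks mean ties
    order = np.lexsort((kept_ids.astype(str), means))
    ranked_ids = list(kept_ids[order])

    refs = set(config.known_reference_ids)
    present = refs & set(ranked_ids)
    for ref in sorted(refs - present, key=str):
        if ref in excluded:
            warnings.warn(
                f"known reference gene {ref!r} has identically zero expression; dropped"
            )
        else:
            warnings.warn(f"known reference gene {ref!r} not found in matrix; dropped")
    flags = np.array([g in present for g in ranked_ids], dtype=bool)
    return RankedGeneIndex(ranked_ids, means[order], flags, excluded)


def normalized_distance(profile_i: np.ndarray, profile_j: np.ndarray) -> float:
    """Normalised Euclidean distance between two centered log profiles.

    Both inputs are per-sample log2(expression + pseudocount) vectors; each
    is centered by its own mean, so a constant log offset (a pure scaling
    difference) contributes nothing.
    """
    pi = np.asarray(profile_i, dtype=float)
    pj = np.asarray(profile_j, dtype=float)
    if pi.shape != pj.shape:
        raise ValueError("profiles must have equal length")
    diff = (pi - pi.mean()) - (pj - pj.mean())
    return float(np.sqrt((diff**2).mean()))


def inversion_count(expr_i: np.ndarray, expr_j: np.ndarray) -> int:
    """Number of samples where the higher-ranked gene j is below gene i.

    Strict inequality on the raw (linear RPKM) scale; ties do not count.
    """
    return int(np.sum(np.asarray(expr_j) < np.asarray(expr_i)))


def edge_cost(
    i: int,
    j: int,
    index: RankedGeneIndex,
    log_values: np.ndarray,
    raw_values: np.ndarray,
    config: SelectorConfig,
) -> EdgeCost:
    """Total cost c_ij = d_ij + (j - i - 1) m + k_ij h for ranks i < j (1-based).

    ``log_values``/``raw_values`` are (n x n_s) arrays in rank order.
    """
    if j <= i:
        raise ValueError(f"edge requires j > i, got i={i}, j={j}")
    d = normalized_distance(log_values[i - 1], log_values[j - 1])
    k = inversion_count(raw_values[i - 1], raw_values[j - 1])
    cost = d + (j - i - 1) * config.m + k * config.h
    return EdgeCost(i, j, d, k, cost)


def _rank_ordered_values(
    matrix: ExpressionMatrix, index: RankedGeneIndex, config: SelectorConfig
):
    raw = matrix.data.loc[index.gene_ids].to_numpy(dtype=float)
    logm = log_transform(matrix, config.pseudocount).data
    logv = logm.loc[index.gene_ids].to_numpy(dtype=float)
    return logv, raw


def solve_cheapest_path(
    index: RankedGeneIndex,
    log_values: np.ndarray,
    raw_values: np.ndarray,
    config: SelectorConfig,
) -> PathSolution:
    """Exact DP solution of the cheapest-path program.

    Recurrence: best(j) = min_{i<j} [best(i) + c_ij] + b_j with
    best(1) = b_1, where b = -r at known-reference nodes and 0 elsewhere
    (endpoints included — they are forced onto the path anyway). Edge costs
    are vectorised per target node and never materialised as a full matrix.
    Ties between equal-cost predecessors are broken toward the largest i
    (denser, adjacent-step paths), so the result is deterministic.
    """
    n = index.n
    if n < 2:
        raise ValueError("cheapest path needs at least 2 ranked genes")
    n_s = log_values.shape[1]
    centered = log_values - log_values.mean(axis=1, keepdims=True)
    b = np.where(index.is_known_reference, -config.r, 0.0)

    best = np.empty(n)
    pred = np.full(n, -1, dtype=int)
    best[0] = b[0]
    ranks_before = np.arange(n)
    for j in range(1, n):
        diff = centered[:j] - centered[j]
        d = np.sqrt((diff * diff).sum(axis=1) / n_s)
        k = (raw_values[j] < raw_values[:j]).sum(axis=1)
        skip = (j - ranks_before[:j] - 1) * config.m
        total = best[:j] + d + skip + k * config.h
        tmin = total.min()
        i = int(np.flatnonzero(total == tmin)[-1])
        best[j] = tmin + b[j]
        pred[j] = i

    ranks0 = []
    node = n - 1
    while node >= 0:
        ranks0.append(node)
        node = pred[node]
    ranks0.reverse()

    edges = [
        edge_cost(i + 1, j + 1, index, log_values, raw_values, config)
        for i, j in zip(ranks0[:-1], ranks0[1:])
    ]
    z = float(sum(e.cost for e in edges))
    on_path = set(ranks0)
    rejected = [
        index.gene_ids[i]
        for i in range(n)
        if index.is_known_reference[i] and i not in on_path
    ]
    return PathSolution(
        ranks=[i + 1 for i in ranks0],
        gene_ids=[index.gene_ids[i] for i in ranks0],
        objective=z,
        reward_adjusted=float(best[n - 1]),
        edges=edges,
        rejected_references=rejected,
    )


def select_invariant_genes(
    matrix: ExpressionMatrix, config: SelectorConfig = SelectorConfig()
) -> tuple[PathSolution, list]:
    """Full selector pipeline: rank genes, solve the DP, return path genes.

    With an empty reference list the identical DP runs with all node
    rewards zero — the unrewarded optimum is then the best estimate of the
    invariant set from the data alone. Supplied references that the path
    rejects (detour costlier than r) are reported on the solution.
    """
    index = rank_genes(matrix, config)
    logv, raw = _rank_ordered_values(matrix, index, config)
    solution = solve_cheapest_path(index, logv, raw, config)
    if solution.rejected_references:
        warnings.warn(
            "reference gene(s) rejected as too costly to keep on the path: "
            f"{solution.rejected_references}"
        )
    return solution, list(solution.gene_ids)
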