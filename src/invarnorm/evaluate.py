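"""Normalization diagnostics.

Relative log expression (RLE) box statistics, cross-condition log2-ratio
distributions, Euclidean sample-distance matrices with Ward ("ward.D2")
hierarchical clustering, and pairwise gene-correlation matrices. These are
the quantities by which a between-sample normalization is judged: RLE boxes
should sit on zero with small spread, and replicates should cluster
together once sample-specific distortions are removed.

All statistics are invariant to gene-row and sample-column order (up to
relabeling). Quartiles use linear interpolation (the type-7 convention) for
cross-language reproducibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix

__all__ = [
    "RLEStats",
    "Dendrogram",
    "rle_stats",
    "log2_ratio_distribution",
    "ratio_summary",
    "sample_distance_matrix",
    "ward_cluster",
    "gene_correlation_matrix",
    "monophyletic_conditions",
]


def _as_df(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, ExpressionMatrix) else matrix


# ---------------------------------------------------------------- RLE


@dataclass
class RLEStats:
    """Per-sample box statistics of relative log expression.

    The reference value per gene is the median across samples of
    log2(value + pseudocount); ratios are each sample's log value minus the
    reference. Whiskers follow the 1.5*IQR rule.
    """

    table: pd.DataFrame  # index: sample; columns: median, q1, q3, iqr, ...
    pseudocount: float

    def __getitem__(self, sample):
        return self.table.loc[sample]


def rle_stats(matrix, pseudocount: float = 1.0) -> RLEStats:
    """RLE box statistics per sample (median, quartiles, whiskers, outliers)."""
    df = _as_df(matrix)
    if df.shape[1] < 2:
        raise ValueError("RLE needs at least 2 samples")
    logv = np.log2(df.to_numpy(dtype=float) + pseudocount)
    reference = np.median(logv, axis=1, keepdims=True)
    ratios = logv - reference

    q1, med, q3 = np.percentile(ratios, [25, 50, 75], axis=0)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    n_out = ((ratios < lo[None, :]) | (ratios > hi[None, :])).sum(axis=0)
    table = pd.DataFrame(
        {
            "median": med,
            "q1": q1,
            "q3": q3,
            "iqr": iqr,
            "whisker_low": lo,
            "whisker_high": hi,
            "n_outliers": n_out.astype(int),
        },
        index=df.columns,
    )
    return RLEStats(table, pseudocount)


def rle_ratios(matrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """The full per-gene RLE ratio matrix underlying :func:`rle_stats`."""
    df = _as_df(matrix)
    logv = np.log2(df.to_numpy(dtype=float) + pseudocount)
    ratios = logv - np.median(logv, axis=1, keepdims=True)
    return pd.DataFrame(ratios, index=df.index, columns=df.columns)


# ------------------------------------------------- cross-condition ratios


def log2_ratio_distribution(
    matrix,
    condition_of_sample: dict,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-gene log2 ratio of condition a over condition b.

    Replicates are combined as the within-condition mean of
    (value + pseudocount) before the log:
    ratio[g] = log2(mean_a(v + pc)) - log2(mean_b(v + pc)).
    """
    df = _as_df(matrix)
    known = set(condition_of_sample.values())
    for cond in (cond_a, cond_b):
        if cond not in known:
            raise ValueError(f"unknown condition label {cond!r}")
    cols_a = [s for s in df.columns if condition_of_sample.get(s) == cond_a]
    cols_b = [s for s in df.columns if condition_of_sample.get(s) == cond_b]
    if not cols_a or not cols_b:
        raise ValueError("both conditions need at least one sample in the matrix")
    mean_a = (df[cols_a] + pseudocount).mean(axis=1)
    mean_b = (df[cols_b] + pseudocount).mean(axis=1)
    return np.log2(mean_a) - np.log2(mean_b)


def ratio_summary(ratios: pd.Series, tail_threshold: float = 1.0) -> dict:
    """Histogram-style summary: central location and heavy-tail mass."""
    r = np.asarray(ratios, dtype=float)
    hist, edges = np.histogram(r, bins=81)
    mode_bin = int(np.argmax(hist))
    return {
        "median": float(np.median(r)),
        "mode": float(0.5 * (edges[mode_bin] + edges[mode_bin + 1])),
        "tail_mass": float(np.mean(np.abs(r) > tail_threshold)),
    }


# ---------------------------------------------------- distances & Ward


def sample_distance_matrix(matrix, pseudocount: float = 1.0) -> pd.DataFrame:
    """Euclidean distances between sample columns of the log2(v + pc) matrix."""
    df = _as_df(matrix)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    logv = np.log2(df.to_numpy(dtype=float) + pseudocount)
    d = squareform(pdist(logv.T, metric="euclidean"))
    return pd.DataFrame(d, index=df.columns, columns=df.columns)


@dataclass
class Dendrogram:
    """Binary merge tree over samples in scipy linkage-matrix form.

    ``linkage`` rows are (cluster_a, cluster_b, height, size); leaves are
    numbered 0..n-1 in ``labels`` order, merged clusters n, n+1, ...
    """

    linkage: np.ndarray
    labels: list

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def leaf_sets(self) -> list[frozenset]:
        """Leaf-label set of every cluster ever formed, in merge order."""
        n = len(self.labels)
        members: list[frozenset] = [frozenset([lab]) for lab in self.labels]
        for a, b, _, _ in self.linkage:
            members.append(members[int(a)] | members[int(b)])
        return members[n:]

    def to_newick(self) -> str:
        """Serialize with branch lengths = parent height - child height."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        for step, (a, b, h, _) in enumerate(self.linkage):
            heights[n + step] = float(h)

        def render(node: int, parent_height: float) -> str:
            if node < n:
                return f"{self.labels[node]}:{parent_height - 0.0:.10g}"
            a, b, h, _ = self.linkage[node - n]
            inner = f"({render(int(a), h)},{render(int(b), h)})"
            return f"{inner}:{parent_height - h:.10g}"

        a, b, h, _ = self.linkage[-1]
        return f"({render(int(a), h)},{render(int(b), h)});"


def ward_cluster(distances: pd.DataFrame) -> Dendrogram:
    """Agglomerative Ward clustering in the "ward.D2" convention.

    The Lance-Williams update runs on *squared* Euclidean distances,

        D2(k, i+j) = ((n_i + n_k) D2(k, i) + (n_j + n_k) D2(k, j)
                      - n_k D2(i, j)) / (n_i + n_j + n_k),

    and merge heights are reported on the non-squared scale (sqrt of the
    minimized quantity), matching hclust's ward.D2 on a Euclidean distance
    matrix. Ties are broken toward the lexicographically smallest cluster
    index pair, so the merge order is deterministic.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if (d < 0).any():
        raise ValueError("distance matrix must be non-negative")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    labels = list(distances.columns) if isinstance(distances, pd.DataFrame) else list(range(len(d)))
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")

    d2 = d * d
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    cur: dict[tuple[int, int], float] = {
        (i, j): d2[i, j] for i in range(n) for j in range(i + 1, n)
    }
    linkage = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        (i, j), best = min(cur.items(), key=lambda kv: (kv[1], kv[0]))
        ni, nj = active[i], active[j]
        linkage[step] = (i, j, np.sqrt(best), ni + nj)
        del active[i], active[j]
        updated = {}
        for k, nk in active.items():
            dki = cur[(min(i, k), max(i, k))]
            dkj = cur[(min(j, k), max(j, k))]
            updated[k] = ((ni + nk) * dki + (nj + nk) * dkj - nk * best) / (
                ni + nj + nk
            )
        cur = {
            (a, b): v
            for (a, b), v in cur.items()
            if a not in (i, j) and b not in (i, j)
        }
        for k, v in updated.items():
            cur[(min(k, next_id), max(k, next_id))] = v
        active[next_id] = ni + nj
        next_id += 1
    return Dendrogram(linkage, labels)


def monophyletic_conditions(
    tree: Dendrogram, condition_of_sample: dict
) -> dict[str, bool]:
    """Which conditions' samples form an exact clade of the dendrogram."""
    clades = set(tree.leaf_sets()) | {frozenset([lab]) for lab in tree.labels}
    groups: dict[str, set] = {}
    for sample, cond in condition_of_sample.items():
        if sample in tree.labels:
            groups.setdefault(cond, set()).add(sample)
    return {cond: frozenset(members) in clades for cond, members in groups.items()}


# -------------------------------------------------------- correlations


def gene_correlation_matrix(matrix, gene_ids) -> pd.DataFrame:
    """Pairwise Pearson correlation of the listed genes across samples.

    Genes are ordered by mean abundance (ascending). A zero-variance gene
    gets NaN in its row/column, with a warning.
    """
    df = _as_df(matrix)
    gene_ids = list(gene_ids)
    missing = [g for g in gene_ids if g not in df.index]
    if missing:
        raise ValueError(f"gene(s) not in matrix: {missing[:5]}")
    if df.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    sub = df.loc[gene_ids]
    order = sub.mean(axis=1).sort_values(kind="stable").index
    sub = sub.loc[order]
    values = sub.to_numpy(dtype=float)
    sd = values.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"zero-variance gene(s) in correlation request: {list(order[flat])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values)
    corr[flat, :] = np.nan
    corr[:, flat] = np.nan
    return pd.DataFrame(corr, index=order, columns=order)
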