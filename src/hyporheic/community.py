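"""Diversity, Bray-Curtis dissimilarity, ANOSIM and boundary delineation.

The benthic and hyporheic assemblages are delineated from abundance data
alone: Bray-Curtis dissimilarities between replicate samples of adjacent
5-cm sediment layers are tested with a permutation ANOSIM, scanning from
the surface downward; the shallowest adjacent layer pair whose assemblages
differ significantly marks the boundary between benthos and hyporheos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.stats import rankdata

__all__ = [
    "AnosimResult",
    "PairTest",
    "BoundaryResult",
    "shannon",
    "bray_curtis",
    "dissimilarity_matrix",
    "anosim",
    "delineate_boundary",
    "cluster_layers",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class AnosimResult:
    r_statistic: float
    p_value: float
    n_permutations: int
    n_samples: int
    seed: int | None


@dataclass(frozen=True)
class PairTest:
    """ANOSIM of one adjacent layer pair (shallow layer k vs layer k+1)."""

    upper_layer: int
    lower_layer: int
    boundary_depth_cm: float  # the shared edge of the two strata
    result: AnosimResult
    mean_between_similarity: float
    n_upper: int
    n_lower: int


@dataclass(frozen=True)
class BoundaryResult:
    condition: str
    boundary_interval: tuple[int, int] | None  # (layer k, layer k+1)
    boundary_depth_cm: float | None
    boundary_similarity: float | None
    pair_tests: tuple[PairTest, ...]
    alpha: float
    mode: str


def shannon(abundances) -> float:
    """Shannon-Wiener index H' = -sum p_i ln p_i over taxa with p_i > 0.

    Returns NaN for an all-zero assemblage (diversity undefined; such rows
    are excluded from downstream models).
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be >= 0")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x[x > 0] / total
    p = p[p > 0]  # guard against underflow of very small proportions
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2 sum(min) / sum(x + y) in [0, 1].

    Undefined (NaN) when both vectors are entirely zero — such a pair
    carries no compositional information.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must be aligned on the same taxa")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be >= 0")
    denom = (x + y).sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


def dissimilarity_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray-Curtis matrix from a samples-by-taxa abundance table.

    Zero diagonal; both-zero sample pairs give NaN entries.
    """
    X = table.to_numpy(dtype=float)
    if np.any(X < 0):
        raise ValueError("abundances must be >= 0")
    sums = X.sum(axis=1)
    denom = sums[:, None] + sums[None, :]
    # sum of element-wise minima for all pairs
    mins = np.array([[np.minimum(a, b).sum() for b in X] for a in X])
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - 2.0 * mins / denom
    d[denom == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=table.index, columns=table.index)


def anosim(
    dissim: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AnosimResult:
    """Analysis of similarities with a permutation test.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
    with ranks (average on ties) over all off-diagonal dissimilarities.
    The one-sided p-value uses the (1 + exceedances)/(1 + n_permutations)
    estimator over random relabellings of the samples.
    """
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("dissimilarity matrix must be square")
    if np.isnan(d[np.triu_indices(n, k=1)]).any():
        raise ValueError("undefined (NaN) dissimilarities; drop empty samples first")
    labels = np.asarray(groups)
    if labels.shape != (n,):
        raise ValueError("groups must label every sample")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 members")

    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu, ju])  # average ranks on ties
    denom = n * (n - 1) / 4.0

    codes = np.searchsorted(uniq, labels)

    def r_stat(code_vec: np.ndarray) -> float:
        within = code_vec[iu] == code_vec[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    observed = r_stat(codes)
    if rng is None:
        rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if r_stat(rng.permutation(codes)) >= observed:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return AnosimResult(
        r_statistic=float(observed),
        p_value=float(p),
        n_permutations=int(n_permutations),
        n_samples=int(n),
        seed=seed,
    )


def delineate_boundary(
    table: pd.DataFrame,
    condition: str = "",
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int | None = None,
    mode: str = "adjacent",
    holm: bool = False,
    layer_thickness_cm: float = 5.0,
) -> BoundaryResult:
    """Locate the benthos/hyporheos boundary for one hydrodynamic condition.

    ``table`` is a samples-by-taxa abundance table whose index carries a
    ``layer`` level; replicate samples (site x date) within each layer are
    the ANOSIM group members.  For each adjacent layer pair (k, k+1) —
    or, in ``mode="cumulative"``, layers 0..k pooled against layer k+1 —
    an ANOSIM compares the two strata; the boundary is the shallowest pair
    with p < alpha.  All-zero replicate samples are dropped (their
    Bray-Curtis against another empty sample is undefined); a layer left
    with fewer than two informative replicates truncates the scan.

    With ``holm=True`` the p-values of the scanned pairs are Holm-adjusted
    before the threshold is applied.
    """
    if mode not in ("adjacent", "cumulative"):
        raise ValueError(f"unknown mode {mode!r}")
    layers = table.index.get_level_values("layer").to_numpy()
    order = np.unique(layers)
    rng = np.random.default_rng(seed)
    tests: list[PairTest] = []
    scanned: list[int] = []
    for idx in range(len(order) - 1):
        upper, lower = order[idx], order[idx + 1]
        if mode == "adjacent":
            upper_mask = layers == upper
        else:
            upper_mask = np.isin(layers, order[: idx + 1])
        lower_mask = layers == lower
        sub = table.loc[upper_mask | lower_mask]
        nonzero = sub.sum(axis=1) > 0
        if not nonzero.all():
            sub = sub.loc[nonzero]
        sub_layers = sub.index.get_level_values("layer").to_numpy()
        grp = np.where(sub_layers == lower, "lower", "upper")
        n_upper = int((grp == "upper").sum())
        n_lower = int((grp == "lower").sum())
        if n_upper < 2 or n_lower < 2:
            warnings.warn(
                f"layer pair ({upper}, {lower}): fewer than 2 informative "
                "replicates per stratum; scan truncated",
                stacklevel=2,
            )
            break
        d = dissimilarity_matrix(sub)
        res = anosim(d, grp, n_permutations=n_permutations, rng=rng, seed=seed)
        between = d.to_numpy()[np.ix_(grp == "upper", grp == "lower")]
        tests.append(
            PairTest(
                upper_layer=int(upper),
                lower_layer=int(lower),
                boundary_depth_cm=float(lower) * layer_thickness_cm,
                result=res,
                mean_between_similarity=float(1.0 - np.nanmean(between)),
                n_upper=n_upper,
                n_lower=n_lower,
            )
        )
        scanned.append(idx)

    pvals = np.array([t.result.p_value for t in tests])
    if holm and len(pvals):
        order_p = np.argsort(pvals)
        adj = np.empty_like(pvals)
        m = len(pvals)
        running = 0.0
        for rank, j in enumerate(order_p):
            running = max(running, (m - rank) * pvals[j])
            adj[j] = min(1.0, running)
        pvals = adj

    boundary = None
    depth = None
    similarity = None
    for t, p in zip(tests, pvals):
        if p < alpha:
            boundary = (t.upper_layer, t.lower_layer)
            depth = t.boundary_depth_cm
            similarity = t.mean_between_similarity
            break
    return BoundaryResult(
        condition=condition,
        boundary_interval=boundary,
        boundary_depth_cm=depth,
        boundary_similarity=similarity,
        pair_tests=tuple(tests),
        alpha=alpha,
        mode=mode,
    )


def cluster_layers(dissim: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Average-linkage (UPGMA) agglomerative clustering of the labels.

    Returns the scipy linkage matrix and the label order.  NaN entries are
    refused rather than imputed.
    """
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need >= 3 labels to cluster")
    iu = np.triu_indices(n, k=1)
    condensed = d[iu]
    if np.isnan(condensed).any():
        raise ValueError("undefined dissimilarities; cannot cluster")
    Z = linkage(condensed, method="average")
    labels = [str(label) for label in dissim.index]
    return Z, labels


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = walk(tree, tree.dist)
    # strip the root's zero-length branch
    return body.rsplit(":", 1)[0] + ";"
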