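"""Clustering of repeat weight matrices by cyclic distance.

Two repeat matrices describing the same consensus may be phase-shifted: the
rows of one are a cyclic rotation of the other.  The distance between two
n x 25 matrices is therefore the minimum over all n row rotations of the
Euclidean distance (B_min).  Matrices of a fixed n are agglomerated by
complete linkage on the pairwise B_min matrix; the cut level B0 is chosen
where the mean class size of the real matrices separates from that of
element-shuffled twins by more than 10 standard errors,

    Z_n(B) = (X_n(B) - Y_n(B)) / sqrt(D(X)/r1 + D(Y)/r2),

with X/Y the mean class sizes and r1/r2 the class counts at cut B.  Each
class is summarized by a consensus matrix: members are rotated to the phase
best matching the class's central member (minimal total within-class
distance) and averaged cell-wise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import squareform

from ._rng import STREAM_CLASSIFY, substream


@dataclass(frozen=True)
class CyclicDistance:
    value: float       # B_min
    best_shift: int    # row rotation of the second matrix achieving it


def _as_array(m) -> np.ndarray:
    return np.asarray(m.matrix if hasattr(m, "matrix") else m, dtype=np.float64)


def cyclic_matrix_distance(a, b) -> CyclicDistance:
    """Minimum Euclidean distance between two n x 25 matrices over all
    cyclic row rotations of the second."""
    A = _as_array(a)
    B = _as_array(b)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    n = A.shape[0]
    dists = np.empty(n)
    for shift in range(n):
        dists[shift] = np.sqrt(((A - np.roll(B, shift, axis=0)) ** 2).sum())
    best = int(np.argmin(dists))
    return CyclicDistance(value=float(dists[best]), best_shift=best)


def pairwise_cyclic_distances(matrices) -> np.ndarray:
    """Symmetric matrix of pairwise B_min values."""
    arrays = [_as_array(m) for m in matrices]
    m = len(arrays)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = cyclic_matrix_distance(arrays[i], arrays[j]).value
    return D


@dataclass(frozen=True)
class ClassPartition:
    linkage_matrix: np.ndarray
    cut: float
    classes: tuple[tuple[int, ...], ...]  # disjoint member index lists


def cluster_matrices(matrices, cut: float, distances: np.ndarray | None = None) -> ClassPartition:
    """Complete-linkage agglomeration on pairwise B_min, cut at height ``cut``."""
    if len(matrices) < 2:
        raise ValueError("need at least 2 matrices to cluster")
    if distances is None:
        distances = pairwise_cyclic_distances(matrices)
    Z = linkage(squareform(distances, checks=False), method="complete")
    labels = fcluster(Z, t=cut, criterion="distance")
    classes: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        classes.setdefault(int(lab), []).append(idx)
    ordered = tuple(tuple(v) for _, v in sorted(classes.items()))
    return ClassPartition(linkage_matrix=Z, cut=cut, classes=ordered)


def shuffle_matrix_elements(m, seed: int = 0, tag: int = 0) -> np.ndarray:
    """Uniform random permutation of all cells (multiset of values preserved)."""
    A = _as_array(m)
    rng = substream(seed, STREAM_CLASSIFY, tag)
    flat = rng.permutation(A.ravel())
    return flat.reshape(A.shape)


@dataclass(frozen=True)
class CutSignificance:
    b_grid: np.ndarray
    x: np.ndarray          # mean class size, real matrices
    y: np.ndarray          # mean class size, shuffled twins
    var_x: np.ndarray
    var_y: np.ndarray
    r1: np.ndarray         # class counts, real
    r2: np.ndarray         # class counts, shuffled
    z: np.ndarray
    recommended_b0: float | None  # smallest grid level with Z > 10


def _class_size_stats(distances: np.ndarray, grid: np.ndarray):
    Z = linkage(squareform(distances, checks=False), method="complete")
    means = np.empty(len(grid))
    variances = np.empty(len(grid))
    counts = np.empty(len(grid))
    for gi, b in enumerate(grid):
        labels = fcluster(Z, t=b, criterion="distance")
        sizes = np.bincount(labels)[1:]
        sizes = sizes[sizes > 0]
        means[gi] = sizes.mean()
        variances[gi] = sizes.var()  # population variance across classes
        counts[gi] = len(sizes)
    return means, variances, counts


def cut_significance(real, seed: int = 0, b_grid=None) -> CutSignificance:
    """Compare real-matrix clustering against element-shuffled twins.

    The twin set contains one shuffled matrix per real matrix.  The default
    grid is 40 evenly spaced levels between the 1st and 99th percentile of
    the real pairwise distances.
    """
    if len(real) < 10:
        raise ValueError("need at least 10 matrices")
    d_real = pairwise_cyclic_distances(real)
    twins = [shuffle_matrix_elements(m, seed=seed, tag=i) for i, m in enumerate(real)]
    d_twin = pairwise_cyclic_distances(twins)
    if b_grid is None:
        tri = squareform(d_real, checks=False)
        lo, hi = np.percentile(tri, [1, 99])
        b_grid = np.linspace(lo, hi, 40)
    else:
        b_grid = np.asarray(b_grid, dtype=np.float64)
    if len(b_grid) < 1 or np.any(np.diff(b_grid) < 0):
        raise ValueError("degenerate B grid")
    x, var_x, r1 = _class_size_stats(d_real, b_grid)
    y, var_y, r2 = _class_size_stats(d_twin, b_grid)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.sqrt(var_x / r1 + var_y / r2)
        z = np.where(denom > 0, (x - y) / denom, np.inf * np.sign(x - y))
    above = np.nonzero(z > 10.0)[0]
    b0 = float(b_grid[above[0]]) if len(above) else None
    return CutSignificance(
        b_grid=b_grid, x=x, y=y, var_x=var_x, var_y=var_y,
        r1=r1, r2=r2, z=z, recommended_b0=b0,
    )


@dataclass(frozen=True)
class ClassMatrix:
    central_member: int
    matrix: np.ndarray  # phase-aligned cell-wise mean


def class_consensus_matrix(members, distances: np.ndarray | None = None) -> ClassMatrix:
    """Phase-aligned average of a class of matrices.

    The central member minimizes the summed B_min to the others (ties to the
    smallest index); every other member is rotated to its best phase against
    the central matrix before averaging.
    """
    arrays = [_as_array(m) for m in members]
    if not arrays:
        raise ValueError("empty class")
    if len(arrays) == 1:
        return ClassMatrix(central_member=0, matrix=arrays[0].copy())
    if distances is None:
        distances = pairwise_cyclic_distances(arrays)
    central = int(np.argmin(distances.sum(axis=1)))
    aligned = []
    for i, A in enumerate(arrays):
        if i == central:
            aligned.append(A)
        else:
            shift = cyclic_matrix_distance(arrays[central], A).best_shift
            aligned.append(np.roll(A, shift, axis=0))
    return ClassMatrix(central_member=central, matrix=np.mean(aligned, axis=0))


def linkage_to_newick(Z: np.ndarray, labels: list[str] | None = None) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = to_tree(Z)

    def render(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            name = labels[node.id] if labels else str(node.id)
            return f"{name}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"
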