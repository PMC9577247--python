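"""Agglomerative clustering of samples and characterisation metrics.

Implements Lance-Williams agglomeration with a documented deterministic
tie-break (the pair whose smallest leaf labels sort first merges first), so
dendrograms are bit-reproducible regardless of input order.  Default
pipelines follow field practice: metrics are clustered on correlation
distance with average linkage; samples on euclidean distance of
z-standardised metrics with Ward linkage.  Trees export to Newick.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_data import MetricMatrix, ValidationError

AXES = ("samples", "metrics")
MEASURES = ("euclidean", "correlation")
LINKAGES = ("single", "complete", "average", "ward")


def standardize(matrix: MetricMatrix, axis: str = "metrics") -> MetricMatrix:
    """Z-score along the chosen axis (sample sd, ddof=1).

    Zero-spread vectors are mapped to all-zero and recorded in the result's
    ``zero_spread`` attribute rather than raising.
    """
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {AXES}")
    df = matrix.data
    if axis == "metrics":
        mean, sd = df.mean(axis=0), df.std(axis=0, ddof=1)
        flagged = tuple(sd.index[(sd == 0) | sd.isna()])
        safe = sd.replace(0, np.nan)
        out = ((df - mean) / safe).fillna(0.0) if flagged else (df - mean) / safe
    else:
        mean, sd = df.mean(axis=1), df.std(axis=1, ddof=1)
        flagged = tuple(df.index[(sd == 0) | sd.isna()])
        safe = sd.replace(0, np.nan)
        out = df.sub(mean, axis=0).div(safe, axis=0)
        if flagged:
            out = out.fillna(0.0)
    return MetricMatrix(out, directions=matrix.directions, zero_spread=flagged)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {vals.shape} != ({n}, {n})")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValidationError("distance matrix not symmetric within 1e-12")
        if np.abs(np.diag(vals)).max(initial=0.0) > 1e-12:
            raise ValidationError("distance matrix diagonal not zero")
        if vals.min(initial=0.0) < -1e-12:
            raise ValidationError("negative distances")
        vals = np.clip((vals + vals.T) / 2.0, 0.0, None)
        np.fill_diagonal(vals, 0.0)
        object.__setattr__(self, "values", vals)


def distance(matrix: MetricMatrix, axis: str = "metrics",
             measure: str = "correlation") -> DistanceMatrix:
    """Pairwise distances between rows (samples) or columns (metrics).

    ``euclidean`` is plain L2 on the vectors as given (standardise first for
    the default sample pipeline); ``correlation`` is 1 - Pearson r.
    """
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {AXES}")
    if measure not in MEASURES:
        raise ValidationError(f"measure must be one of {MEASURES}")
    data = matrix.data if axis == "samples" else matrix.data.T
    labels = tuple(str(x) for x in data.index)
    if len(labels) < 2:
        raise ValidationError(f"need at least 2 {axis} to compute distances")
    X = data.to_numpy()
    if not np.isfinite(X).all():
        raise ValidationError("missing/non-finite entries; aggregate or impute first")
    if measure == "euclidean":
        D = squareform(pdist(X, metric="euclidean"))
    else:
        sd = X.std(axis=1, ddof=1)
        bad = [labels[i] for i in np.flatnonzero(sd == 0)]
        if bad:
            raise ValidationError(
                f"correlation distance undefined for zero-spread items: {bad}")
        D = 1.0 - np.corrcoef(X)
        D = np.clip((D + D.T) / 2.0, 0.0, None)
        np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels, D)


@dataclass(frozen=True)
class Merge:
    left: int      # node id (leaves are 0..n-1, internal nodes n, n+1, ...)
    right: int
    height: float
    size: int      # leaves under the new node


@dataclass(frozen=True)
class Dendrogram:
    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        n = len(self.leaves)
        if len(set(self.leaves)) != n:
            raise ValidationError("duplicate leaf labels")
        if len(self.merges) != max(n - 1, 0):
            raise ValidationError(
                f"{n} leaves require {n - 1} merges, got {len(self.merges)}")

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]

    def to_linkage(self) -> np.ndarray:
        """SciPy-style (n-1) x 4 linkage matrix."""
        return np.array([[m.left, m.right, m.height, m.size]
                         for m in self.merges], dtype=float)


def _lance_williams(linkage: str, d_ki: float, d_kj: float, d_ij: float,
                    n_i: int, n_j: int, n_k: int) -> float:
    if linkage == "single":
        return min(d_ki, d_kj)
    if linkage == "complete":
        return max(d_ki, d_kj)
    if linkage == "average":
        return (n_i * d_ki + n_j * d_kj) / (n_i + n_j)
    # ward
    tot = n_i + n_j + n_k
    return np.sqrt(((n_i + n_k) * d_ki**2 + (n_j + n_k) * d_kj**2
                    - n_k * d_ij**2) / tot)


def agglomerate(dist: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Hierarchical agglomeration with deterministic tie-breaking.

    At every step the closest active pair merges; exact ties go to the pair
    whose (smallest-leaf-label, smallest-leaf-label) pair sorts first.
    Merge heights are the inter-cluster distances at merge time, which are
    non-decreasing for the supported monotone linkages.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    n = len(dist.labels)
    if n == 1:
        return Dendrogram(dist.labels, ())
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = float(dist.values[i, j])
    size = {i: 1 for i in range(n)}
    minleaf = {i: dist.labels[i] for i in range(n)}
    active = set(range(n))
    merges: list[Merge] = []
    for step in range(n - 1):
        best_key = None
        best_pair = None
        for (i, j), d in D.items():
            tie = tuple(sorted((minleaf[i], minleaf[j])))
            key = (d, tie)
            if best_key is None or key < best_key:
                best_key, best_pair = key, (i, j)
        i, j = best_pair
        d_ij = D.pop((i, j))
        new = n + step
        # order children so the clade with the smaller leaf label sits left
        left, right = (i, j) if minleaf[i] <= minleaf[j] else (j, i)
        merges.append(Merge(left, right, d_ij, size[i] + size[j]))
        for k in list(active):
            if k in (i, j):
                continue
            d_ki = D.pop(tuple(sorted((k, i))))
            d_kj = D.pop(tuple(sorted((k, j))))
            D[(k, new)] = float(_lance_williams(linkage, d_ki, d_kj, d_ij,
                                                size[i], size[j], size[k]))
        active -= {i, j}
        active.add(new)
        size[new] = size[i] + size[j]
        minleaf[new] = min(minleaf[i], minleaf[j])
    return Dendrogram(dist.labels, tuple(merges))


def cut(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cluster labels from removing the k-1 last (highest) merges.

    Groups are numbered deterministically: the group holding the
    lexicographically smallest leaf is 1, and so on ascending.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValidationError(f"k must be in [1, {n}], got {k}")
    members: dict[int, list[str]] = {i: [lab] for i, lab in
                                     enumerate(dendrogram.leaves)}
    for step, m in enumerate(dendrogram.merges[: n - k]):
        members[n + step] = members.pop(m.left) + members.pop(m.right)
    groups = sorted(members.values(), key=min)
    out: dict[str, int] = {}
    for g, leaves in enumerate(groups, start=1):
        for leaf in leaves:
            out[leaf] = g
    return pd.Series({lab: out[lab] for lab in dendrogram.leaves},
                     name="cluster", dtype=int)


def _newick_label(label: str) -> str:
    if any(c in label for c in "(),:;'\t\n ") or label == "":
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string; branch lengths are parent height minus child height."""
    n = dendrogram.n_leaves
    if n == 1:
        return _newick_label(dendrogram.leaves[0]) + ";"
    height = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for step, m in enumerate(dendrogram.merges):
        node = n + step
        height[node] = m.height
        children[node] = (m.left, m.right)

    def render(node: int, parent_height: float | None) -> str:
        if node < n:
            body = _newick_label(dendrogram.leaves[node])
        else:
            left, right = children[node]
            body = "(" + render(left, height[node]) + "," \
                   + render(right, height[node]) + ")"
        if parent_height is None:
            return body
        return body + ":" + format(parent_height - height[node], ".10g")

    return render(n + len(dendrogram.merges) - 1, None) + ";"


def cluster_metrics(matrix: MetricMatrix, linkage: str = "average",
                    measure: str = "correlation") -> Dendrogram:
    """Default metric pipeline: z-standardise, correlation distance, average
    linkage (standardisation leaves correlations unchanged but normalises any
    euclidean fallback)."""
    z = standardize(matrix, axis="metrics")
    return agglomerate(distance(z, axis="metrics", measure=measure), linkage)


def cluster_samples(matrix: MetricMatrix, linkage: str = "ward",
                    measure: str = "euclidean") -> Dendrogram:
    """Default sample pipeline: z-standardise metrics, euclidean, Ward."""
    z = standardize(matrix, axis="metrics")
    return agglomerate(distance(z, axis="samples", measure=measure), linkage)
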