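"""Cost matrices for transport problems.

Builds the across-space cost ``C`` and the within-space costs ``C^X``/``C^Y``
from a declarative :class:`CostSpec`: squared Euclidean, cosine, the elastic
L1 cost ``h(z) = 0.5*||z||^2 + gamma*||z||_1`` and graph-geodesic distances on
a symmetrized k-nearest-neighbour graph. Multimodal inputs are merged by
variance-normalized concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, shortest_path
from scipy.spatial.distance import cdist

from .container import AnnotatedMatrix

__all__ = [
    "CostSpec",
    "CostMatrix",
    "build_cost",
    "multimodal_concat",
    "geodesic_cost",
]

_KINDS = ("sq_euclidean", "cosine", "elastic_l1", "geodesic")
_SCALINGS = ("mean", "max", "none")


@dataclass
class CostSpec:
    """How a pairwise cost matrix is realized.

    ``scaling="mean"`` (the default practice) divides the realized matrix by
    its mean so epsilon is comparable across problems; ``geodesic_k`` only
    applies to ``kind="geodesic"``, ``elastic_gamma`` only to
    ``kind="elastic_l1"``.
    """

    kind: str = "sq_euclidean"
    representation: str = "features"
    scaling: str = "mean"
    geodesic_k: int = 30
    elastic_gamma: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown cost kind {self.kind!r}; one of {_KINDS}")
        if self.scaling not in _SCALINGS:
            raise ValueError(
                f"unknown scaling {self.scaling!r}; one of {_SCALINGS}"
            )
        if self.geodesic_k < 1:
            raise ValueError("geodesic_k must be >= 1")
        if self.elastic_gamma < 0:
            raise ValueError("elastic_gamma must be non-negative")


@dataclass
class CostMatrix:
    """A realized non-negative cost matrix with its provenance."""

    values: np.ndarray
    row_ids: list[str] = field(default_factory=list)
    col_ids: list[str] = field(default_factory=list)
    spec: CostSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cost matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("cost matrix contains negative entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _apply_scaling(values: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "none":
        return values
    denom = values.mean() if scaling == "mean" else values.max()
    if not denom > 0:
        if np.all(values == 0):  # degenerate (e.g. single point): identity
            return values
        raise ValueError(f"cannot {scaling}-scale a cost matrix with {scaling} 0")
    return values / denom


def _pairwise(x: np.ndarray, y: np.ndarray, spec: CostSpec, row_ids, col_ids):
    if spec.kind == "sq_euclidean":
        return cdist(x, y, metric="sqeuclidean")
    if spec.kind == "cosine":
        norms_x = np.linalg.norm(x, axis=1)
        norms_y = np.linalg.norm(y, axis=1)
        for norms, ids, side in ((norms_x, row_ids, "row"), (norms_y, col_ids, "col")):
            bad = np.flatnonzero(norms == 0)
            if bad.size:
                name = ids[bad[0]] if ids else str(bad[0])
                raise ValueError(
                    f"zero-norm vector under cosine cost at {side} observation {name}"
                )
        return np.clip(cdist(x, y, metric="cosine"), 0.0, 2.0)
    if spec.kind == "elastic_l1":
        return 0.5 * cdist(x, y, metric="sqeuclidean") + spec.elastic_gamma * cdist(
            x, y, metric="cityblock"
        )
    raise AssertionError(spec.kind)


def build_cost(
    source: AnnotatedMatrix,
    target: AnnotatedMatrix,
    spec: CostSpec,
) -> CostMatrix:
    """Realize the cost matrix between two datasets under ``spec``.

    For ``kind="geodesic"`` source and target must be the same point set
    (a within-space cost); shortest-path distances are computed on the
    symmetrized k-NN graph with Euclidean edge weights.
    """
    x = source.get_representation(spec.representation)
    y = target.get_representation(spec.representation)
    if x.shape[1] != y.shape[1]:
        raise ValueError(
            f"representation {spec.representation!r} has dimensionality "
            f"{x.shape[1]} in source vs {y.shape[1]} in target"
        )
    if spec.kind == "geodesic":
        if source.obs_ids != target.obs_ids:
            raise ValueError(
                "geodesic cost is a within-space cost: source and target must "
                "be the same point set"
            )
        return geodesic_cost(x, spec.geodesic_k, ids=source.obs_ids, scaling=spec.scaling)
    values = _pairwise(x, y, spec, source.obs_ids, target.obs_ids)
    values = _apply_scaling(values, spec.scaling)
    return CostMatrix(values, list(source.obs_ids), list(target.obs_ids), spec)


def multimodal_concat(
    parts: Sequence[np.ndarray],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Merge modality representations into one space.

    Each part is rescaled to unit total variance (sum of per-dimension
    variances equals one) so no modality dominates distances, then the parts
    are concatenated column-wise. Optional weights multiply parts after
    rescaling.
    """
    if len(parts) < 2:
        raise ValueError("need at least two parts to concatenate")
    n = parts[0].shape[0]
    if any(p.shape[0] != n for p in parts):
        raise ValueError("parts must have aligned observations")
    if weights is None:
        weights = [1.0] * len(parts)
    if len(weights) != len(parts):
        raise ValueError("one weight per part required")
    scaled = []
    for i, (p, w) in enumerate(zip(parts, weights)):
        p = np.asarray(p, dtype=float)
        total_var = p.var(axis=0, ddof=0).sum()
        if total_var <= 0:
            raise ValueError(f"part {i} has zero variance")
        scaled.append(w * p / np.sqrt(total_var))
    return np.concatenate(scaled, axis=1)


def geodesic_cost(
    points: np.ndarray,
    k: int,
    ids: Sequence[str] | None = None,
    scaling: str = "none",
) -> CostMatrix:
    """All-pairs shortest-path distances on the symmetrized k-NN graph.

    Edges carry Euclidean lengths; the directed k-NN graph is symmetrized by
    taking the union of edges (i->j or j->i). Neighbour ties are broken by
    observation index and a point is never its own neighbour.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} points, got {n}")
    # full pairwise distances with a stable argsort: neighbour ties break by
    # observation index, self excluded
    dmat = cdist(points, points)
    np.fill_diagonal(dmat, np.inf)
    order = np.argsort(dmat, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = order.ravel()
    vals = dmat[rows, cols]
    graph = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    graph = graph.maximum(graph.T)  # union symmetrization
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels).tolist()
        raise ValueError(
            f"k-NN graph with k={k} is disconnected; component sizes {sizes} "
            "(raise k)"
        )
    values = shortest_path(graph, method="D", directed=False)
    np.fill_diagonal(values, 0.0)
    values = _apply_scaling(values, scaling)
    ids = list(ids) if ids is not None else [str(i) for i in range(n)]
    spec = CostSpec(kind="geodesic", scaling=scaling, geodesic_k=k)
    return CostMatrix(values, ids, ids, spec)
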