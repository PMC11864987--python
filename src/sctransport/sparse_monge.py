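"""Entropic Monge maps with elastic-net sparsity.

From a converged Sinkhorn solve between two cell populations, the dual
potential over targets defines a deterministic map: each source point moves
to a softmax-weighted combination of target points. Replacing the squared
Euclidean cost with the elastic L1 cost ``h(z) = 0.5 ||z||^2 + gamma ||z||_1``
and applying the soft-threshold operator to the displacement zeroes out
coordinates that barely move, so each cell acquires a sparse set of
"important" features — the genes its transport actually uses. Neighborhood
dissimilarity of those sets highlights cells in heterogeneous fate
neighborhoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .container import AnnotatedMatrix
from .solvers import Marginals, sinkhorn

__all__ = [
    "EntropicMap",
    "fit_entropic_map",
    "soft_threshold",
    "elastic_map_apply",
    "important_features",
    "neighborhood_dissimilarity",
]


def _h_cost(x: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    """Translation-invariant cost h(x - y) for the elastic L1 family.

    ``gamma = 0`` is the plain 0.5 * squared Euclidean cost.
    """
    c = 0.5 * cdist(x, y, metric="sqeuclidean")
    if gamma > 0:
        c = c + gamma * cdist(x, y, metric="cityblock")
    return c


@dataclass
class EntropicMap:
    """A fitted entropic transport map."""

    target_points: np.ndarray
    potential: np.ndarray  # dual potential g over targets
    epsilon: float
    gamma: float = 0.0  # 0 => squared Euclidean cost

    def __post_init__(self) -> None:
        if self.potential.shape[0] != self.target_points.shape[0]:
            raise ValueError("potential length must equal number of targets")

    def weights(self, x: np.ndarray) -> np.ndarray:
        """Softmax weights p^j(x) over targets for source points x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        logits = (self.potential[None, :] - _h_cost(x, self.target_points, self.gamma)) / self.epsilon
        logits = logits - logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        return w / w.sum(axis=1, keepdims=True)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the map; squared-Euclidean form (gamma is handled by
        :func:`elastic_map_apply`)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        w = self.weights(x)
        out = w @ self.target_points
        return out[0] if single else out


def fit_entropic_map(
    src: AnnotatedMatrix,
    tgt: AnnotatedMatrix,
    eps: float,
    gamma: float = 0.0,
    max_iter: int = 100_000,
    tol: float = 1e-4,
) -> EntropicMap:
    """Fit the dual potential by a balanced Sinkhorn solve.

    Uniform weights on both sides; the target-side potential is read off the
    converged log-domain scalings. Raises if Sinkhorn did not converge.
    """
    x = src.values
    y = tgt.values
    if x.shape[1] != y.shape[1]:
        raise ValueError("source and target must share a feature space")
    C = _h_cost(x, y, gamma)
    m = Marginals.uniform(x.shape[0], y.shape[0])
    c = sinkhorn(C, m, eps, max_iter=max_iter, tol=tol)
    if not c.converged:
        raise RuntimeError(
            f"Sinkhorn did not converge (marginal error {c.marginal_error:.2e})"
        )
    _, g = c.potentials
    # potentials of the 1/m-weighted problem -> potential per target point in
    # the uniform-weight softmax convention of the map estimator
    g = g + eps * np.log(y.shape[0])
    return EntropicMap(target_points=y, potential=g, epsilon=eps, gamma=gamma)


def soft_threshold(z: np.ndarray, gamma: float) -> np.ndarray:
    """ST_gamma(z) = (1 - gamma/|z|)_+ * z, elementwise; 0 where |z| <= gamma."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    z = np.asarray(z, dtype=float)
    if gamma == 0:
        return z.copy()
    mag = np.abs(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        shrink = np.where(mag > gamma, 1.0 - gamma / mag, 0.0)
    return shrink * z


def elastic_map_apply(emap: EntropicMap, x: np.ndarray, gamma: float) -> np.ndarray:
    """Evaluate the elastic entropic map at source points.

    ``T(x) = x - ST_gamma(x - sum_j p^j(x) (y_j + gamma sign(x - y_j)))``
    with the softmax weights of the fitted potential. Coordinates whose
    displacement the soft threshold zeroes out are left exactly unchanged.
    ``gamma`` must match the cost the map was fitted with.
    """
    if gamma != emap.gamma:
        raise ValueError(
            f"gamma mismatch: map fitted with {emap.gamma}, apply got {gamma}"
        )
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x2 = np.atleast_2d(x)
    w = emap.weights(x2)  # (n, m)
    y = emap.target_points  # (m, d)
    if gamma == 0:
        out = w @ y
        return out[0] if single else out
    # anchor_i = sum_j w_ij (y_j + gamma * sign(x_i - y_j))
    sign_part = np.empty_like(x2)
    for i in range(x2.shape[0]):
        sign_part[i] = w[i] @ np.sign(x2[i][None, :] - y)
    anchor = w @ y + gamma * sign_part
    out = x2 - soft_threshold(x2 - anchor, gamma)
    return out[0] if single else out


def important_features(
    src: AnnotatedMatrix,
    emap: EntropicMap,
    gamma: float,
    threshold: float = 1e-6,
) -> tuple[list[set], pd.DataFrame | None]:
    """Per-cell sets of features with non-negligible transport displacement.

    A feature belongs to a cell's important set when the absolute
    displacement ``|x - T(x)|`` in that coordinate exceeds ``threshold``.
    If the source carries annotations, per-annotation relevance is the
    fraction of that annotation's cells having each feature in their set.
    """
    mapped = elastic_map_apply(emap, src.values, gamma)
    disp = np.abs(src.values - mapped)
    hits = disp > threshold
    sets = [set(np.flatnonzero(row)) for row in hits]
    ann = src.annotation
    relevance = None
    if ann is not None:
        rows = {}
        for cat in sorted(set(ann)):
            members = hits[np.asarray(ann == cat)]
            rows[cat] = members.mean(axis=0)
        relevance = pd.DataFrame.from_dict(
            rows, orient="index", columns=src.feature_ids
        )
    return sets, relevance


def _jaccard(s1: set, s2: set) -> float:
    if not s1 and not s2:
        return 1.0
    union = len(s1 | s2)
    return len(s1 & s2) / union


def neighborhood_dissimilarity(
    sets: Sequence[set],
    representation: np.ndarray,
    k: int = 50,
    mode: str = "mean_pairwise",
) -> np.ndarray:
    """1 minus the Jaccard similarity of a cell's set to its neighborhood.

    ``mean_pairwise`` (default) averages Jaccard(own, neighbour) over the k
    nearest neighbours; ``union`` compares the own set against the union of
    neighbour sets. Cells with an empty own set get dissimilarity 1.
    """
    if mode not in ("mean_pairwise", "union"):
        raise ValueError(f"unknown mode {mode!r}")
    representation = np.asarray(representation, dtype=float)
    n = representation.shape[0]
    if len(sets) != n:
        raise ValueError("one set per observation required")
    if not (0 < k < n):
        raise ValueError("k must satisfy 0 < k < n")
    d = cdist(representation, representation)
    np.fill_diagonal(d, np.inf)
    nbrs = np.argsort(d, axis=1, kind="stable")[:, :k]
    out = np.empty(n)
    for i in range(n):
        if not sets[i]:
            out[i] = 1.0
            continue
        if mode == "mean_pairwise":
            sim = np.mean([_jaccard(sets[i], sets[j]) for j in nbrs[i]])
        else:
            union: set = set()
            for j in nbrs[i]:
                union |= sets[j]
            sim = _jaccard(sets[i], union)
        out[i] = 1.0 - sim
    return out
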