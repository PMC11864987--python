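"""Map a dissociated single-cell reference onto spatial coordinates.

A fused GW problem couples reference cells to spatial units: the linear (W)
term compares expression of genes shared by both datasets, the quadratic
(GW) term enforces correspondence between molecular similarity among
reference cells and physical proximity among spatial units. The solved plan
imputes unmeasured features into the spatial domain and transfers
annotations as likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .container import AnnotatedMatrix
from .geometry import CostSpec, build_cost
from .solvers import Coupling, Marginals, ProblemSpec, fused_gw

__all__ = [
    "MappingResult",
    "solve_mapping",
    "impute_features",
    "transfer_annotations",
    "spatial_correspondence",
]


@dataclass
class MappingResult:
    coupling: Coupling
    imputed: AnnotatedMatrix | None = None
    annotation_likelihoods: pd.DataFrame | None = None


def solve_mapping(
    ref: AnnotatedMatrix,
    spatial: AnnotatedMatrix,
    shared_cost: CostSpec,
    ref_cost: CostSpec,
    spatial_cost: CostSpec,
    spec: ProblemSpec,
) -> Coupling:
    """Solve the reference-to-space fused GW problem.

    ``shared_cost`` builds the across-space term on features measured in
    both datasets; ``ref_cost`` the within-reference molecular similarity;
    ``spatial_cost`` the within-space physical similarity (squared Euclidean
    on coordinates by default, or a spatial-graph geodesic).
    """
    if spec.alpha is None:
        raise ValueError("mapping requires an FGW alpha in the problem spec")
    shared = [f for f in ref.feature_ids if f in set(spatial.feature_ids)]
    if shared_cost.representation == "features" and not shared:
        raise ValueError("no shared features between reference and spatial data")
    if shared_cost.representation == "features":
        ref_shared = AnnotatedMatrix(
            ref.values[:, ref.feature_index(shared)], ref.obs_ids, shared
        )
        sp_shared = AnnotatedMatrix(
            spatial.values[:, spatial.feature_index(shared)],
            spatial.obs_ids,
            shared,
        )
        C = build_cost(ref_shared, sp_shared, shared_cost)
    else:
        C = build_cost(ref, spatial, shared_cost)
    Cx = build_cost(ref, ref, ref_cost)
    Cy = build_cost(spatial, spatial, spatial_cost)
    m = Marginals.uniform(ref.n_obs, spatial.n_obs)
    return fused_gw(
        C, Cx, Cy, m,
        eps=spec.epsilon,
        alpha=spec.alpha,
        tau_a=spec.tau_a,
        tau_b=spec.tau_b,
        max_iter=spec.max_iter,
        tol=spec.tol,
        inner_max_iter=spec.inner_max_iter,
        inner_tol=spec.inner_tol,
    )


def _column_normalized(P: np.ndarray) -> np.ndarray:
    sums = P.sum(axis=0, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("plan has zero-mass columns; cannot project")
    return P / sums


def impute_features(
    c: Coupling,
    ref: AnnotatedMatrix,
    features: Sequence[str],
) -> AnnotatedMatrix:
    """Barycentric projection of reference features into the spatial domain.

    Each spatial unit receives the plan-weighted average of the requested
    reference features (the plan is column-normalized first so every imputed
    value is a convex combination of reference values). Applies unchanged to
    any modality carried by the reference (genes, proteins, peaks).
    """
    idx = ref.feature_index(features)
    P_hat = _column_normalized(c.dense())
    imputed = P_hat.T @ ref.values[:, idx]
    return AnnotatedMatrix(imputed, c.col_ids, list(features))


def transfer_annotations(
    c: Coupling,
    labels: Sequence,
) -> tuple[pd.DataFrame, list]:
    """Map reference annotations to spatial units.

    One-hot reference labels are projected through the column-normalized
    plan; each spatial unit's row is its annotation likelihood (sums to 1).
    Hard labels take the most likely annotation, ties broken by lowest
    label index in sorted order.
    """
    labels = list(labels)
    if len(labels) != c.shape[0]:
        raise ValueError("labels must align with the reference side of the plan")
    cats = sorted(set(labels))
    onehot = np.zeros((len(labels), len(cats)))
    cat_idx = {lab: i for i, lab in enumerate(cats)}
    for i, lab in enumerate(labels):
        onehot[i, cat_idx[lab]] = 1.0
    P_hat = _column_normalized(c.dense())
    G = P_hat.T @ onehot
    likelihood = pd.DataFrame(G, index=c.col_ids, columns=cats)
    hard = [cats[j] for j in np.argmax(G, axis=1)]
    return likelihood, hard


def spatial_correspondence(spatial: AnnotatedMatrix, n_thresholds: int = 10) -> float:
    """Correlation between expression similarity and spatial proximity.

    ``n_thresholds`` increasing spatial-distance thresholds (equally spaced
    quantiles of the pairwise spatial distances) discretize spatial
    proximity: every pair of spatial units is assigned the smallest
    threshold covering its spatial distance, and the returned value is the
    Pearson correlation between pairwise expression distance and the
    assigned threshold over all pairs. Positive values indicate that nearby
    units have similar expression and justify the structural-correspondence
    assumption of the GW term; under expression with no spatial structure
    the correlation concentrates near zero.
    """
    if n_thresholds < 3:
        raise ValueError("need at least 3 thresholds")
    coords = spatial.spatial
    if coords is None:
        raise ValueError("no spatial coordinates present")
    d_space = pdist(coords)
    d_expr = pdist(spatial.values)
    if np.all(d_expr == 0):
        raise ValueError(
            "expression distances are all zero (constant expression); "
            "correlation undefined"
        )
    qs = np.linspace(0, 1, n_thresholds + 1)[1:]
    thresholds = np.quantile(d_space, qs)
    # smallest threshold covering each pair's spatial distance
    bins = np.searchsorted(thresholds, d_space, side="left")
    bins = np.minimum(bins, n_thresholds - 1)
    x = thresholds[bins]
    usable = np.unique(x).size
    if usable < 3:
        raise ValueError("fewer than 3 usable thresholds")
    if x.std() == 0 or d_expr.std() == 0:
        raise ValueError("degenerate threshold assignment; correlation undefined")
    return float(np.corrcoef(x, d_expr)[0, 1])
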