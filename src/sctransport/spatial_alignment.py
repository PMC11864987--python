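"""Align spatial slides into a common coordinate frame.

Slide pairs are coupled by fused GW (expression in the linear term, spatial
structure in the quadratic terms) under a sequential policy (consecutive
pairs) or a star policy (every query against one reference). Coordinates
move between frames either by the nonlinear warp (plan-weighted barycenters
of the partner slide) or by a weighted least-squares affine map extracted
from the coupling; a subsequent W-type solve on the aligned coordinates can
sharpen low-rank alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .container import AnnotatedMatrix
from .geometry import CostSpec, build_cost
from .solvers import Coupling, Marginals, ProblemSpec, fused_gw, sinkhorn

__all__ = [
    "PolicySpec",
    "AlignmentResult",
    "solve_alignment",
    "warp_coordinates",
    "affine_from_coupling",
    "refine_on_coordinates",
    "refine_affine",
    "project_to_ccf",
]


@dataclass
class PolicySpec:
    """Which slide pairs get coupled."""

    kind: str = "sequential"
    reference_id: str | None = None
    slide_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("sequential", "star", "explicit"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind == "sequential" and len(self.slide_ids) < 2:
            raise ValueError("sequential policy requires at least 2 slides")
        if self.kind == "star":
            if self.reference_id is None:
                raise ValueError("star policy requires a reference_id")
            if self.reference_id not in self.slide_ids:
                raise ValueError(
                    f"reference {self.reference_id!r} not among slides "
                    f"{self.slide_ids}"
                )

    def edges(self) -> list[tuple[str, str]]:
        if self.kind == "sequential":
            return list(zip(self.slide_ids[:-1], self.slide_ids[1:]))
        if self.kind == "star":
            return [
                (self.reference_id, s)
                for s in self.slide_ids
                if s != self.reference_id
            ]
        raise ValueError("explicit policies carry their own edge list")


@dataclass
class AlignmentResult:
    couplings: dict
    transformed: dict
    transform_kind: dict


def _normalize_coords(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Center and scale to unit median pairwise distance; return transform."""
    center = coords.mean(axis=0)
    shifted = coords - center
    from scipy.spatial.distance import pdist

    med = np.median(pdist(shifted))
    if med == 0:
        med = 1.0
    return shifted / med, center, med


def solve_alignment(
    slides: dict,
    policy: PolicySpec,
    shared_cost: CostSpec,
    spec: ProblemSpec,
) -> dict:
    """One fused GW coupling per policy edge.

    The quadratic terms use squared Euclidean distances on coordinates that
    are centered and scaled to unit median pairwise distance per slide, so
    slides of different physical extent compare sensibly; the linear term
    follows ``shared_cost``.
    """
    if spec.alpha is None:
        raise ValueError("alignment requires an FGW alpha in the problem spec")
    for sid in policy.slide_ids:
        if sid not in slides:
            raise ValueError(f"slide {sid!r} missing from input")
        if slides[sid].spatial is None:
            raise ValueError(f"slide {sid!r} has no spatial coordinates")
    couplings: dict = {}
    coord_spec = CostSpec(kind="sq_euclidean", representation="features", scaling="mean")
    for left_id, right_id in policy.edges():
        left, right = slides[left_id], slides[right_id]
        C = build_cost(left, right, shared_cost)
        left_norm, _, _ = _normalize_coords(left.spatial)
        right_norm, _, _ = _normalize_coords(right.spatial)
        left_view = AnnotatedMatrix(
            left_norm, left.obs_ids, [f"c{i}" for i in range(left_norm.shape[1])]
        )
        right_view = AnnotatedMatrix(
            right_norm, right.obs_ids, [f"c{i}" for i in range(right_norm.shape[1])]
        )
        Cx = build_cost(left_view, left_view, coord_spec)
        Cy = build_cost(right_view, right_view, coord_spec)
        m = Marginals.uniform(left.n_obs, right.n_obs)
        couplings[(left_id, right_id)] = fused_gw(
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
    return couplings


def _row_normalized(P: np.ndarray, ids) -> np.ndarray:
    sums = P.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        bad = [ids[i] for i in np.flatnonzero(sums[:, 0] == 0)]
        raise ValueError(f"zero-mass rows for observations {bad[:10]}")
    return P / sums


def warp_coordinates(c: Coupling, target_coords: np.ndarray) -> np.ndarray:
    """Nonlinear warp of target coordinates into the source frame.

    Each source point lands at the plan-weighted barycenter of its matched
    target points (rows normalized to sum one), so warped coordinates lie in
    the convex hull of the target slide.
    """
    target_coords = np.asarray(target_coords, dtype=float)
    if target_coords.shape[0] != c.shape[1]:
        raise ValueError("target coordinates must align with plan columns")
    P_hat = _row_normalized(c.dense(), c.row_ids)
    return P_hat @ target_coords


def affine_from_coupling(
    c: Coupling,
    source_coords: np.ndarray,
    target_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted least-squares affine map from target to source frame.

    Minimizes ``sum_ij P_ij ||A z_j + t - z_i||^2`` over the matrix ``A``
    and translation ``t``; with an exact matching of a rigidly moved copy it
    recovers the inverse rigid motion.
    """
    P = c.dense()
    Z_s = np.asarray(source_coords, dtype=float)
    Z_t = np.asarray(target_coords, dtype=float)
    if Z_s.shape[0] != P.shape[0] or Z_t.shape[0] != P.shape[1]:
        raise ValueError("coordinate row counts must match the plan shape")
    mass = P.sum()
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    mu_s = (p_row @ Z_s) / mass
    mu_t = (p_col @ Z_t) / mass
    Xs = Z_s - mu_s
    Xt = Z_t - mu_t
    cross = Xs.T @ P @ Xt  # d_s x d_t weighted cross-covariance
    tgt_cov = (Xt * p_col[:, None]).T @ Xt
    d = Z_t.shape[1]
    if np.linalg.matrix_rank(tgt_cov) < d:
        raise ValueError(
            "rank-deficient weighted target covariance (degenerate, e.g. "
            "collinear, coordinates); affine map undetermined"
        )
    A = cross @ np.linalg.inv(tgt_cov)
    t = mu_s - A @ mu_t
    return A, t


def refine_on_coordinates(
    aligned_source: np.ndarray,
    aligned_target: np.ndarray,
    eps: float,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> Coupling:
    """Sharpen an alignment by a W-type solve on coordinates in one frame.

    Intended as a second pass after warp/affine transformation (useful for
    low-rank first passes): a balanced entropic problem on the mean-scaled
    squared Euclidean coordinate cost.
    """
    from scipy.spatial.distance import cdist

    aligned_source = np.asarray(aligned_source, dtype=float)
    aligned_target = np.asarray(aligned_target, dtype=float)
    C = cdist(aligned_source, aligned_target, metric="sqeuclidean")
    mean = C.mean()
    if mean > 0:
        C = C / mean
    m = Marginals.uniform(aligned_source.shape[0], aligned_target.shape[0])
    return sinkhorn(C, m, eps, max_iter=max_iter, tol=tol)


def _weighted_procrustes(P: np.ndarray, Z_s: np.ndarray, Z_t: np.ndarray):
    """Best rotation + translation (no scale) under plan weights.

    SVD of the weighted cross-covariance, reflection-corrected; immune to
    the scale attenuation a free least-squares fit suffers on blurred
    couplings.
    """
    mass = P.sum()
    p_row = P.sum(axis=1)
    p_col = P.sum(axis=0)
    mu_s = (p_row @ Z_s) / mass
    mu_t = (p_col @ Z_t) / mass
    M = (Z_s - mu_s).T @ P @ (Z_t - mu_t)
    U, S, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0] * (len(S) - 1) + [d])
    R = U @ D @ Vt
    return R, mu_s - R @ mu_t


def refine_affine(
    c: Coupling,
    source_coords: np.ndarray,
    target_coords: np.ndarray,
    n_iter: int = 3,
    tau_a: float = 0.5,
    eps: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, Coupling]:
    """Polish an affine alignment by alternating W solves and refits.

    Internal rounds use the weighted orthogonal Procrustes rotation (a
    least-squares affine fit of a blurred coupling shrinks toward the
    centroid, which corrupts the neighbour matching of the next round):
    transform the target by the current rotation, solve an unbalanced
    W-type problem on the coordinates, refit. The left marginal is relaxed
    (``tau_a < 1``) so source points without a true partner — e.g. when the
    partner slide is subsampled — shed mass instead of distorting the fit.
    The returned map is the full weighted least-squares affine extracted
    from the final (sharp) coupling, with its translation and the coupling
    itself.
    """
    from scipy.spatial.distance import cdist

    from .solvers import sinkhorn_unbalanced

    source_coords = np.asarray(source_coords, dtype=float)
    target_coords = np.asarray(target_coords, dtype=float)
    A, t = _weighted_procrustes(c.dense(), source_coords, target_coords)
    m = Marginals.uniform(source_coords.shape[0], target_coords.shape[0])
    refined = c
    for _ in range(n_iter):
        moved = target_coords @ A.T + t
        C = cdist(source_coords, moved, metric="sqeuclidean")
        mean = C.mean()
        if mean > 0:
            C = C / mean
        refined = sinkhorn_unbalanced(C, m, eps, tau_a=tau_a, tau_b=1.0)
        A, t = _weighted_procrustes(refined.plan, source_coords, target_coords)
    A, t = affine_from_coupling(refined, source_coords, target_coords)
    return A, t, refined


def project_to_ccf(c: Coupling, query: AnnotatedMatrix) -> AnnotatedMatrix:
    """Project query expression onto the reference support of a star edge.

    The row-normalized plan (reference rows x query columns) averages query
    profiles per reference unit, enabling joint analysis of all queries in
    common-coordinate-framework positions.
    """
    if query.n_obs != c.shape[1]:
        raise ValueError("query must align with plan columns")
    P_hat = _row_normalized(c.dense(), c.row_ids)
    projected = P_hat @ query.values
    return AnnotatedMatrix(projected, c.row_ids, query.feature_ids)
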