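"""Entropic optimal-transport solvers.

The transport core shared by every problem class: balanced and unbalanced
Sinkhorn in the log domain, a low-rank factored Sinkhorn, entropic
Gromov-Wasserstein and fused GW via mirror descent, and the debiased
Sinkhorn divergence.

Conventions
-----------
A coupling ``P`` distributes the source mass ``a`` over the target mass
``b``. The entropic objective is ``<C, P> - eps * H(P)`` with
``H(P) = -sum P (log P - 1)``. Unbalanced problems replace the hard marginal
constraints with KL penalties weighted by ``rho = eps * tau / (1 - tau)``;
``tau = 1`` is the exact balanced constraint. Low-rank plans are stored as
``P = Q diag(1/g) R^T`` with ``Q 1_r = a`` and ``R 1_r = b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import CostMatrix


def logsumexp(x: np.ndarray, axis: int) -> np.ndarray:
    """Stable log-sum-exp along one axis (lean hot-loop variant)."""
    m = np.max(x, axis=axis, keepdims=True)
    out = m + np.log(np.sum(np.exp(x - m), axis=axis, keepdims=True))
    return np.squeeze(out, axis=axis)

__all__ = [
    "ProblemSpec",
    "Marginals",
    "Coupling",
    "sinkhorn",
    "sinkhorn_unbalanced",
    "sinkhorn_low_rank",
    "gromov_wasserstein",
    "fused_gw",
    "sinkhorn_divergence",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class ProblemSpec:
    """Full specification of one transport problem."""

    problem_type: str = "W"
    epsilon: float = 1e-2
    tau_a: float = 1.0
    tau_b: float = 1.0
    alpha: float | None = None
    rank: int | str = "full"
    lr_gamma: float = 100.0
    max_iter: int = 10_000
    tol: float = 1e-6
    inner_max_iter: int = 10_000
    inner_tol: float = 1e-8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.problem_type not in ("W", "GW", "FGW"):
            raise ValueError(f"unknown problem_type {self.problem_type!r}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        for tau in (self.tau_a, self.tau_b):
            if not (0 < tau <= 1):
                raise ValueError("tau_a, tau_b must lie in (0, 1]")
        if self.problem_type == "FGW":
            if self.alpha is None:
                raise ValueError("alpha is required for FGW problems")
            if not (0 <= self.alpha <= 1):
                raise ValueError("alpha must lie in [0, 1]")
        if self.rank != "full" and int(self.rank) < 1:
            raise ValueError("rank must be >= 1 or 'full'")


class Marginals:
    """Prescribed row/column mass totals of a coupling.

    Entries must be strictly positive; balanced problems require equal
    total mass (enforced by renormalization of ``b`` with a warning).
    """

    def __init__(self, a: np.ndarray, b: np.ndarray) -> None:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("marginal entries must be strictly positive")
        self.a = a
        self.b = b

    @classmethod
    def uniform(cls, n: int, m: int) -> "Marginals":
        return cls(np.full(n, 1.0 / n), np.full(m, 1.0 / m))

    def balanced(self) -> "Marginals":
        """Return marginals with equal total mass, warning if renormalized."""
        sa, sb = self.a.sum(), self.b.sum()
        if abs(sa - sb) <= 1e-9:
            return self
        warnings.warn(
            f"marginal sums differ ({sa:.6g} vs {sb:.6g}); renormalizing b "
            "to match a for the balanced problem",
            stacklevel=3,
        )
        return Marginals(self.a, self.b * (sa / sb))


@dataclass
class Coupling:
    """A solved transport plan, dense or low-rank factored."""

    plan: np.ndarray | None
    row_ids: list[str]
    col_ids: list[str]
    spec: ProblemSpec
    objective: float
    converged: bool
    n_iter: int
    marginal_error: float
    factors: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    potentials: tuple[np.ndarray, np.ndarray] | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.plan is None) == (self.factors is None):
            raise ValueError("exactly one of plan / factors must be set")

    @property
    def is_low_rank(self) -> bool:
        return self.factors is not None

    @property
    def shape(self) -> tuple[int, int]:
        if self.plan is not None:
            return self.plan.shape
        q, r, _ = self.factors
        return (q.shape[0], r.shape[0])

    def dense(self) -> np.ndarray:
        """Materialize the plan as a dense array."""
        if self.plan is not None:
            return self.plan
        q, r, g = self.factors
        return (q / g) @ r.T

    def row_sums(self) -> np.ndarray:
        if self.plan is not None:
            return self.plan.sum(axis=1)
        return self.factors[0].sum(axis=1)

    def col_sums(self) -> np.ndarray:
        if self.plan is not None:
            return self.plan.sum(axis=0)
        return self.factors[1].sum(axis=1)


# ----------------------------------------------------------------------
# helpers
# ----------------------------------------------------------------------
def _cost_values(C) -> np.ndarray:
    values = C.values if isinstance(C, CostMatrix) else np.asarray(C, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("cost matrix contains non-finite entries")
    return values


def _cost_ids(C, n: int, m: int) -> tuple[list[str], list[str]]:
    if isinstance(C, CostMatrix) and C.row_ids and C.col_ids:
        return list(C.row_ids), list(C.col_ids)
    return [str(i) for i in range(n)], [str(j) for j in range(m)]


def entropy(P: np.ndarray) -> float:
    """H(P) = -sum P (log P - 1), with 0 log 0 = 0."""
    mask = P > 0
    return float(-(P[mask] * (np.log(P[mask]) - 1.0)).sum())


def _kl(x: np.ndarray, y: np.ndarray) -> float:
    mask = x > 0
    return float((x[mask] * np.log(x[mask] / y[mask])).sum() - x.sum() + y.sum())


def transport_cost(C, coupling: Coupling) -> float:
    """<C, P> without materializing a low-rank plan unnecessarily."""
    values = _cost_values(C)
    if coupling.plan is not None:
        return float((values * coupling.plan).sum())
    q, r, g = coupling.factors
    return float(np.einsum("il,ij,jl->", q / g, values, r))


# ----------------------------------------------------------------------
# balanced / unbalanced Sinkhorn
# ----------------------------------------------------------------------
def sinkhorn(
    C,
    m: Marginals,
    eps: float,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> Coupling:
    """Balanced entropic OT by log-domain Sinkhorn iterations.

    Returns a coupling with ``P_ij = exp((f_i + g_j - C_ij) / eps)`` where
    ``f, g`` are the converged dual potentials; convergence is declared when
    the L1 marginal deviation drops below ``tol``. ``init`` warm-starts the
    potentials (used by the mirror-descent outer loops).
    """
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    values = _cost_values(C)
    n_rows, n_cols = values.shape
    m = m.balanced()
    a, b = m.a, m.b
    log_a, log_b = np.log(a), np.log(b)
    if init is not None:
        f, g = init[0].copy(), init[1].copy()
    else:
        f = np.zeros(n_rows)
        g = np.zeros(n_cols)
    err = np.inf
    it = 0
    check_every = 5
    for it in range(1, max_iter + 1):
        f = eps * (log_a - logsumexp((g[None, :] - values) / eps, axis=1))
        g = eps * (log_b - logsumexp((f[:, None] - values) / eps, axis=0))
        if it % check_every and it != max_iter:
            continue
        # after the g update column sums match b exactly; check rows
        P = np.exp((f[:, None] + g[None, :] - values) / eps)
        err = float(np.abs(P.sum(axis=1) - a).sum() + np.abs(P.sum(axis=0) - b).sum())
        if err <= tol:
            break
    else:
        P = np.exp((f[:, None] + g[None, :] - values) / eps)
    objective = float((values * P).sum()) - eps * entropy(P)
    row_ids, col_ids = _cost_ids(C, n_rows, n_cols)
    spec = ProblemSpec(problem_type="W", epsilon=eps, max_iter=max_iter, tol=tol)
    return Coupling(
        plan=P,
        row_ids=row_ids,
        col_ids=col_ids,
        spec=spec,
        objective=objective,
        converged=err <= tol,
        n_iter=it,
        marginal_error=err,
        potentials=(f, g),
    )


def sinkhorn_unbalanced(
    C,
    m: Marginals,
    eps: float,
    tau_a: float = 1.0,
    tau_b: float = 1.0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> Coupling:
    """Unbalanced entropic OT with KL-relaxed marginals.

    The marginal constraints are replaced by KL penalties with weight
    ``rho = eps * tau / (1 - tau)`` per side; the generalized Sinkhorn
    iteration raises the scalings to the power ``rho / (rho + eps)``.
    ``tau = 1`` on both sides reproduces the exact balanced solution.
    Convergence is declared on the fixed point of the potentials; the
    realized marginal deviation is reported, not enforced.
    """
    for tau in (tau_a, tau_b):
        if not (0 < tau <= 1):
            raise ValueError("tau_a, tau_b must lie in (0, 1]")
    if tau_a == 1.0 and tau_b == 1.0:
        c = sinkhorn(C, m, eps, max_iter=max_iter, tol=tol, init=init)
        c.spec.tau_a = c.spec.tau_b = 1.0
        return c
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    values = _cost_values(C)
    n_rows, n_cols = values.shape
    a, b = m.a, m.b
    log_a, log_b = np.log(a), np.log(b)
    # exponent rho / (rho + eps) with rho = eps * tau / (1 - tau)
    # simplifies to tau (balanced side: exponent 1)
    exp_a = 1.0 if tau_a == 1.0 else tau_a
    exp_b = 1.0 if tau_b == 1.0 else tau_b
    if init is not None:
        f, g = init[0].copy(), init[1].copy()
    else:
        f = np.zeros(n_rows)
        g = np.zeros(n_cols)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        f_prev = f
        f = exp_a * eps * (log_a - logsumexp((g[None, :] - values) / eps, axis=1))
        g = exp_b * eps * (log_b - logsumexp((f[:, None] - values) / eps, axis=0))
        if np.abs(f - f_prev).max() <= tol:
            converged = True
            break
    P = np.exp((f[:, None] + g[None, :] - values) / eps)
    marg_err = float(np.abs(P.sum(axis=1) - a).sum() + np.abs(P.sum(axis=0) - b).sum())
    objective = float((values * P).sum()) - eps * entropy(P)
    if tau_a < 1.0:
        objective += eps * tau_a / (1.0 - tau_a) * _kl(P.sum(axis=1), a)
    if tau_b < 1.0:
        objective += eps * tau_b / (1.0 - tau_b) * _kl(P.sum(axis=0), b)
    row_ids, col_ids = _cost_ids(C, n_rows, n_cols)
    spec = ProblemSpec(
        problem_type="W", epsilon=eps, tau_a=tau_a, tau_b=tau_b,
        max_iter=max_iter, tol=tol,
    )
    return Coupling(
        plan=P,
        row_ids=row_ids,
        col_ids=col_ids,
        spec=spec,
        objective=objective,
        converged=converged,
        n_iter=it,
        marginal_error=marg_err,
        potentials=(f, g),
    )


# ----------------------------------------------------------------------
# low-rank Sinkhorn
# ----------------------------------------------------------------------
def _lr_objective(values: np.ndarray, q: np.ndarray, r: np.ndarray, g: np.ndarray) -> float:
    return float(np.einsum("il,ij,jl->", q / g, values, r))


_LR_G_FLOOR = np.log(1e-10)  # lower bound on inner weights, guards collapse


def _lr_dykstra(
    lk1: np.ndarray,
    lk2: np.ndarray,
    lk3: np.ndarray,
    log_a: np.ndarray,
    log_b: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """KL-project log-kernels onto the factored coupling constraints.

    Finds ``(Q, R, g)`` closest in KL to ``exp(lk1), exp(lk2), exp(lk3)``
    subject to ``Q 1 = a``, ``R 1 = b`` and ``Q^T 1 = R^T 1 = g``. The shared
    inner weight solves ``g^3 = K3 (K1^T u1)(K2^T u2)`` elementwise, giving
    the cube-root update; everything runs in the log domain.
    """
    rank = lk3.shape[0]
    lv1 = np.zeros(rank)
    lv2 = np.zeros(rank)
    lu1 = np.zeros(log_a.shape[0])
    lu2 = np.zeros(log_b.shape[0])
    lg = lk3
    for _ in range(max_iter):
        lu1 = log_a - logsumexp(lk1 + lv1[None, :], axis=1)
        lu2 = log_b - logsumexp(lk2 + lv2[None, :], axis=1)
        c1 = logsumexp(lk1 + lu1[:, None], axis=0)
        c2 = logsumexp(lk2 + lu2[:, None], axis=0)
        lg = np.maximum((lk3 + c1 + c2) / 3.0, _LR_G_FLOOR)
        lv1_new = lg - c1
        lv2_new = lg - c2
        delta = max(np.abs(lv1_new - lv1).max(), np.abs(lv2_new - lv2).max())
        lv1, lv2 = lv1_new, lv2_new
        if delta <= tol:
            break
    # end on the u-updates so the outer marginals a, b hold exactly
    lu1 = log_a - logsumexp(lk1 + lv1[None, :], axis=1)
    lu2 = log_b - logsumexp(lk2 + lv2[None, :], axis=1)
    q = np.exp(lu1[:, None] + lk1 + lv1[None, :])
    r = np.exp(lu2[:, None] + lk2 + lv2[None, :])
    return q, r, np.exp(lg)


def sinkhorn_low_rank(
    C,
    m: Marginals,
    eps: float = 1e-4,
    rank: int = 2,
    lr_gamma: float = 100.0,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-9,
    n_init: int = 4,
    inner_max_iter: int = 500,
    inner_tol: float = 1e-9,
) -> Coupling:
    """Low-rank factored transport ``P = Q diag(1/g) R^T``.

    Mirror descent on the factors: at each outer step the gradients of the
    transport cost with respect to ``(Q, R, g)`` are exponentiated into KL
    kernels with adaptive step size ``lr_gamma / ||grad||_inf`` and the
    triple is re-projected onto the factored coupling constraints by an
    alternating-Sinkhorn (Dykstra-style) inner loop. ``eps > 0`` adds
    entropic damping of the kernels. The iterate with the best objective is
    returned, so the objective over accepted (best-so-far) iterates is
    non-increasing. Several restarts — one deterministic (equivalent to the
    independence plan) plus Dirichlet initializations drawn from ``seed`` —
    guard against poor local optima; the best is kept.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if eps <= 0:
        raise ValueError("epsilon must be positive")
    values = _cost_values(C)
    n_rows, n_cols = values.shape
    if rank > min(n_rows, n_cols):
        raise ValueError(
            f"rank {rank} exceeds min(n, m) = {min(n_rows, n_cols)}"
        )
    m = m.balanced()
    a, b = m.a / m.a.sum(), m.b / m.b.sum()  # factored form assumes unit mass
    total_mass = m.a.sum()
    log_a, log_b = np.log(a), np.log(b)
    rng = np.random.default_rng(seed)
    tiny = 1e-300

    def run(init: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
        g = np.full(rank, 1.0 / rank)
        if init == "deterministic":
            q = np.outer(a, g)
            r = np.outer(b, g)
        else:
            q = a[:, None] * rng.dirichlet(np.ones(rank), size=n_rows)
            r = b[:, None] * rng.dirichlet(np.ones(rank), size=n_cols)
            g = 0.5 * (q.sum(axis=0) + r.sum(axis=0))
            g = g / g.sum()
        obj = _lr_objective(values, q, r, g)
        best = (q, r, g, obj)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            grad_q = values @ (r / g)
            grad_r = values.T @ (q / g)
            grad_g = -np.einsum("il,ij,jl->l", q, values, r) / g**2
            scale = max(
                np.abs(grad_q).max(), np.abs(grad_r).max(), np.abs(grad_g).max()
            )
            step = lr_gamma / max(scale, 1e-12)
            damp = 1.0 + step * eps
            lk1 = (np.log(np.maximum(q, tiny)) - step * grad_q) / damp
            lk2 = (np.log(np.maximum(r, tiny)) - step * grad_r) / damp
            lk3 = np.maximum(
                (np.log(np.maximum(g, tiny)) - step * grad_g) / damp, _LR_G_FLOOR
            )
            q, r, g = _lr_dykstra(
                lk1, lk2, lk3, log_a, log_b, inner_max_iter, inner_tol
            )
            obj_new = _lr_objective(values, q, r, g)
            if obj_new < best[3]:
                best = (q, r, g, obj_new)
            if abs(obj - obj_new) <= tol * max(1.0, abs(obj_new)):
                converged = True
                obj = obj_new
                break
            obj = obj_new
        q, r, g, obj = best
        return q, r, g, obj, it, converged

    best = None
    inits = ["deterministic"] + ["dirichlet"] * max(0, n_init - 1)
    for init in inits:
        result = run(init)
        if best is None or result[3] < best[3]:
            best = result
    q, r, g, obj, it, converged = best
    # final pure projection (zero gradient step) cleans up the factor marginals
    q, r, g = _lr_dykstra(
        np.log(np.maximum(q, tiny)),
        np.log(np.maximum(r, tiny)),
        np.maximum(np.log(np.maximum(g, tiny)), _LR_G_FLOOR),
        log_a, log_b, inner_max_iter, min(inner_tol, 1e-12),
    )
    obj = _lr_objective(values, q, r, g)
    q = q * total_mass
    r = r * total_mass
    g = g * total_mass
    marg_err = float(
        np.abs(q.sum(axis=1) - m.a).sum() + np.abs(r.sum(axis=1) - m.b).sum()
    )
    row_ids, col_ids = _cost_ids(C, n_rows, n_cols)
    spec = ProblemSpec(
        problem_type="W", epsilon=eps, rank=rank, lr_gamma=lr_gamma,
        max_iter=max_iter, tol=tol, seed=seed,
    )
    return Coupling(
        plan=None,
        row_ids=row_ids,
        col_ids=col_ids,
        spec=spec,
        objective=obj * total_mass,
        converged=converged,
        n_iter=it,
        marginal_error=marg_err,
        factors=(q, r, g),
    )


# ----------------------------------------------------------------------
# Gromov-Wasserstein and fused GW
# ----------------------------------------------------------------------
def _gw_linearization(Cx: np.ndarray, Cy: np.ndarray, P: np.ndarray,
                      a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gradient of the GW objective at P for the element-wise squared loss.

    Uses the decomposition L(u, v) = u^2 + v^2 - 2uv, so each evaluation
    costs two matrix products.
    """
    const = np.outer((Cx**2) @ a, np.ones_like(b)) + np.outer(
        np.ones_like(a), (Cy**2) @ b
    )
    return 2.0 * (const - 2.0 * Cx @ P @ Cy)


def _gw_objective(Cx: np.ndarray, Cy: np.ndarray, P: np.ndarray) -> float:
    p, q = P.sum(axis=1), P.sum(axis=0)
    const = np.outer((Cx**2) @ p, np.ones_like(q)) + np.outer(
        np.ones_like(p), (Cy**2) @ q
    )
    return float(((const - 2.0 * Cx @ P @ Cy) * P).sum())


def gromov_wasserstein(
    Cx,
    Cy,
    m: Marginals,
    eps: float,
    max_iter: int = 200,
    tol: float = 1e-6,
    inner_max_iter: int = 10_000,
    inner_tol: float = 1e-8,
    anneal: bool = True,
) -> Coupling:
    """Entropic GW between two within-space geometries by mirror descent.

    At each outer iterate the squared-loss GW gradient is linearized into a
    cost matrix and an entropic W problem is solved; iteration stops when
    the plan change drops below ``tol``. With ``anneal`` (default) the
    regularization starts high and decays geometrically to ``eps``, which
    avoids the shallow local optima the non-convex objective exhibits at
    small ``eps``.
    """
    X = _cost_values(Cx)
    Y = _cost_values(Cy)
    if X.shape[0] != X.shape[1] or Y.shape[0] != Y.shape[1]:
        raise ValueError(
            f"within-space costs must be square, got {X.shape} and {Y.shape}"
        )
    m = m.balanced()
    a, b = m.a, m.b
    P = np.outer(a, b) / a.sum()
    it = 0
    converged = False
    last = None
    pots = None
    eps_start = eps
    if anneal:
        lin0 = _gw_linearization(X, Y, P, a, b)
        eps_start = max(eps, 0.05 * float(np.abs(lin0).mean()))
    for it in range(1, max_iter + 1):
        cur_eps = max(eps, eps_start * 0.5 ** (it - 1))
        lin = _gw_linearization(X, Y, P, a, b)
        last = sinkhorn(lin, m, cur_eps, max_iter=inner_max_iter, tol=inner_tol, init=pots)
        pots = last.potentials
        P_new = last.plan
        change = float(np.abs(P_new - P).sum())
        P = P_new
        if change <= tol and cur_eps == eps:
            converged = True
            break
    objective = _gw_objective(X, Y, P)
    row_ids = _cost_ids(Cx, X.shape[0], X.shape[0])[0]
    col_ids = _cost_ids(Cy, Y.shape[0], Y.shape[0])[0]
    spec = ProblemSpec(
        problem_type="GW", epsilon=eps, max_iter=max_iter, tol=tol,
        inner_max_iter=inner_max_iter, inner_tol=inner_tol,
    )
    return Coupling(
        plan=P,
        row_ids=row_ids,
        col_ids=col_ids,
        spec=spec,
        objective=objective,
        converged=converged,
        n_iter=it,
        marginal_error=last.marginal_error if last is not None else np.inf,
    )


def fused_gw(
    C,
    Cx,
    Cy,
    m: Marginals,
    eps: float,
    alpha: float,
    tau_a: float = 1.0,
    tau_b: float = 1.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    inner_max_iter: int = 10_000,
    inner_tol: float = 1e-8,
    anneal: bool = True,
) -> Coupling:
    """Fused GW: convex blend of a feature (W) and a structural (GW) term.

    The mirror-descent linearized cost is ``(1 - alpha) * C`` plus ``alpha``
    times the GW gradient; unbalancedness, when requested, is applied in the
    inner W solves. ``alpha = 0`` reduces to ``sinkhorn(C)``; ``alpha = 1``
    to ``gromov_wasserstein(Cx, Cy)``. Annealing of the regularization (on
    by default, active only when the GW term participates) guards against
    shallow local optima at small ``eps``.
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    lin_C = _cost_values(C)
    X = _cost_values(Cx)
    Y = _cost_values(Cy)
    if X.shape[0] != X.shape[1] or Y.shape[0] != Y.shape[1]:
        raise ValueError(
            f"within-space costs must be square, got {X.shape} and {Y.shape}"
        )
    if lin_C.shape != (X.shape[0], Y.shape[0]):
        raise ValueError(
            f"across-space cost shape {lin_C.shape} does not match "
            f"({X.shape[0]}, {Y.shape[0]})"
        )
    balanced = tau_a == 1.0 and tau_b == 1.0
    if balanced:
        m = m.balanced()
    a, b = m.a, m.b
    P = np.outer(a, b) / a.sum()
    it = 0
    converged = False
    last = None
    pots = None
    eps_start = eps
    if anneal and alpha > 0:
        lin0 = (1.0 - alpha) * lin_C + alpha * _gw_linearization(X, Y, P, a, b)
        eps_start = max(eps, 0.05 * float(np.abs(lin0).mean()))
    for it in range(1, max_iter + 1):
        cur_eps = max(eps, eps_start * 0.5 ** (it - 1))
        cost = (1.0 - alpha) * lin_C
        if alpha > 0:
            cost = cost + alpha * _gw_linearization(X, Y, P, a, b)
        if balanced:
            last = sinkhorn(cost, m, cur_eps, max_iter=inner_max_iter, tol=inner_tol, init=pots)
        else:
            last = sinkhorn_unbalanced(
                cost, m, cur_eps, tau_a=tau_a, tau_b=tau_b,
                max_iter=inner_max_iter, tol=inner_tol, init=pots,
            )
        pots = last.potentials
        P_new = last.plan
        change = float(np.abs(P_new - P).sum())
        P = P_new
        if change <= tol and cur_eps == eps:
            converged = True
            break
    gw_obj = _gw_objective(X, Y, P)
    lin_cost = float((lin_C * P).sum())
    objective = alpha * gw_obj + (1.0 - alpha) * lin_cost - eps * entropy(P)
    row_ids, col_ids = _cost_ids(C, lin_C.shape[0], lin_C.shape[1])
    spec = ProblemSpec(
        problem_type="FGW", epsilon=eps, alpha=alpha, tau_a=tau_a, tau_b=tau_b,
        max_iter=max_iter, tol=tol,
        inner_max_iter=inner_max_iter, inner_tol=inner_tol,
    )
    return Coupling(
        plan=P,
        row_ids=row_ids,
        col_ids=col_ids,
        spec=spec,
        objective=objective,
        converged=converged,
        n_iter=it,
        marginal_error=last.marginal_error if last is not None else np.inf,
        extras={"gw_objective": gw_obj, "linear_cost": lin_cost},
    )


# ----------------------------------------------------------------------
# Sinkhorn divergence
# ----------------------------------------------------------------------
def _ot_eps(mu: np.ndarray, nu: np.ndarray, values: np.ndarray, eps: float) -> float:
    c = sinkhorn(values, Marginals(mu, nu), eps, max_iter=50_000, tol=1e-12)
    P = c.plan
    return float((values * P).sum()) + eps * _kl(P, np.outer(mu, nu) / mu.sum())


def sinkhorn_divergence(mu: np.ndarray, nu: np.ndarray, C, eps: float) -> float:
    """Debiased entropic OT distance between two histograms on one support.

    ``S_eps(mu, nu) = OT_eps(mu, nu) - 0.5 OT_eps(mu, mu) - 0.5 OT_eps(nu, nu)``
    where each OT value is the transport cost plus ``eps`` times the KL
    divergence of the plan from the product measure. Zero when the
    histograms coincide; symmetric; non-negative up to solver tolerance.
    """
    mu = np.asarray(mu, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(mu < 0) or np.any(nu < 0):
        raise ValueError("negative mass in input histograms")
    values = _cost_values(C)
    if values.shape[0] != values.shape[1]:
        raise ValueError("the support cost must be square")
    # zero-mass bins break strict-positivity of the solver; lift both
    # histograms off zero on the shared support
    tiny = 1e-12
    mu = mu + tiny
    nu = nu + tiny
    mu = mu / mu.sum()
    nu = nu / nu.sum()
    ot_xy = _ot_eps(mu, nu, values, eps)
    ot_xx = _ot_eps(mu, mu, values, eps)
    ot_yy = _ot_eps(nu, nu, values, eps)
    return ot_xy - 0.5 * ot_xx - 0.5 * ot_yy
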