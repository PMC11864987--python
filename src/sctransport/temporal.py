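"""Temporal couplings: growth-aware trajectory mapping between time points.

A source population at t1 is coupled to a target population at t2 by
entropic OT on a phenotypic cost. The left marginal encodes prior knowledge
of proliferation and death: a cell expected to divide distributes more
probability mass forward, a dying cell less. Couplings chain across time
points under a Markov assumption; push/pull operations yield descendant and
ancestor distributions, which aggregate to annotation-level transition
tables, correlate with gene expression to nominate driver/target genes, and
assemble into an absorbing Markov chain for fate probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .container import AnnotatedMatrix
from .geometry import CostSpec, build_cost
from .solvers import (
    Coupling,
    Marginals,
    ProblemSpec,
    sinkhorn,
    sinkhorn_low_rank,
    sinkhorn_unbalanced,
)

__all__ = [
    "GrowthConfig",
    "TransitionTable",
    "growth_marginals",
    "solve_temporal",
    "chain_couplings",
    "push",
    "pull",
    "cell_transition",
    "correlate_with_distribution",
    "scaled_growth_and_apoptosis",
    "fate_probabilities",
]


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass
class GrowthConfig:
    """How the left (source) marginal encodes growth and death.

    ``birth_death`` uses the expected value of a birth-death process,
    ``g(x) = exp(beta(x) - delta(x))``, raised to the elapsed time:
    ``a_i = g(x_i)^dt / sum_j g(x_j)^dt``. ``score_diff`` uses proliferation
    and apoptosis scores directly, ``a_i ∝ exp((p_i - q_i) / c)`` with scale
    ``c`` (renormalized to a probability vector before use). ``uniform``
    assigns ``1/N``.
    """

    mode: str = "uniform"
    delta_t: float = 1.0
    scale_c: float | None = None
    proliferation_scores: np.ndarray | None = None
    apoptosis_scores: np.ndarray | None = None
    beta: np.ndarray | None = None
    delta: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("birth_death", "score_diff", "uniform"):
            raise ValueError(f"unknown growth mode {self.mode!r}")
        if self.delta_t <= 0 and self.mode == "birth_death":
            if self.delta_t < 0:
                raise ValueError("delta_t must be non-negative")


@dataclass
class TransitionTable:
    """A coupling aggregated to annotation level."""

    values: np.ndarray
    source_labels: list
    target_labels: list
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.source_labels), len(self.target_labels)):
            raise ValueError("table shape does not match label counts")
        if np.any(self.values < 0):
            raise ValueError("transition mass must be non-negative")
        if self.normalization not in ("row", "col", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.source_labels, columns=self.target_labels
        )


# ----------------------------------------------------------------------
# growth marginals
# ----------------------------------------------------------------------
def growth_marginals(src: AnnotatedMatrix, cfg: GrowthConfig) -> np.ndarray:
    """Left marginal over source cells under the chosen growth model.

    Always returns a probability vector. The score-difference formula is
    unnormalized as written; it is renormalized here because a marginal must
    carry fixed total mass.
    """
    n = src.n_obs
    if cfg.mode == "uniform":
        return np.full(n, 1.0 / n)
    if cfg.mode == "birth_death":
        if cfg.beta is None or cfg.delta is None:
            raise ValueError("birth_death mode requires beta and delta rate vectors")
        beta = np.asarray(cfg.beta, dtype=float)
        delta = np.asarray(cfg.delta, dtype=float)
        if beta.shape != (n,) or delta.shape != (n,):
            raise ValueError("rate vectors must be obs-aligned")
        g = np.exp(beta - delta)
        powered = g**cfg.delta_t
        return powered / powered.sum()
    # score_diff
    if cfg.scale_c is None or cfg.scale_c <= 0:
        raise ValueError("score_diff mode requires a positive scale_c")
    if cfg.proliferation_scores is None or cfg.apoptosis_scores is None:
        raise ValueError("score_diff mode requires proliferation and apoptosis scores")
    p = np.asarray(cfg.proliferation_scores, dtype=float)
    q = np.asarray(cfg.apoptosis_scores, dtype=float)
    if p.shape != (n,) or q.shape != (n,):
        raise ValueError("score vectors must be obs-aligned")
    a = np.exp((p - q) / cfg.scale_c)
    return a / a.sum()


# ----------------------------------------------------------------------
# solving
# ----------------------------------------------------------------------
def solve_temporal(
    src: AnnotatedMatrix,
    tgt: AnnotatedMatrix,
    cost: CostSpec,
    spec: ProblemSpec,
    growth: GrowthConfig | None = None,
) -> Coupling:
    """Couple two time points with a growth-adjusted W-type problem.

    The left marginal comes from :func:`growth_marginals`; the right marginal
    is uniform (every target cell receives the same sampling weight).
    Unbalancedness and low rank are chosen through ``spec``.
    """
    growth = growth or GrowthConfig()
    a = growth_marginals(src, growth)
    b = np.full(tgt.n_obs, 1.0 / tgt.n_obs)
    C = build_cost(src, tgt, cost)
    m = Marginals(a, b)
    if spec.rank != "full":
        c = sinkhorn_low_rank(
            C, m, eps=spec.epsilon, rank=int(spec.rank), lr_gamma=spec.lr_gamma,
            seed=spec.seed, max_iter=spec.max_iter, tol=spec.tol,
        )
    elif spec.tau_a == 1.0 and spec.tau_b == 1.0:
        c = sinkhorn(C, m, spec.epsilon, max_iter=spec.max_iter, tol=spec.tol)
    else:
        c = sinkhorn_unbalanced(
            C, m, spec.epsilon, tau_a=spec.tau_a, tau_b=spec.tau_b,
            max_iter=spec.max_iter, tol=spec.tol,
        )
    return c


def chain_couplings(couplings: Sequence[Coupling]) -> Coupling:
    """Compose time-consecutive couplings by matrix multiplication.

    Under the Markov assumption the composite ``P(1) P(2) ... P(R-1)`` links
    the first time point to the last.
    """
    if not couplings:
        raise ValueError("need at least one coupling")
    result = couplings[0].dense()
    row_ids = couplings[0].row_ids
    col_ids = couplings[0].col_ids
    for k, c in enumerate(couplings[1:], start=1):
        if col_ids != c.row_ids:
            raise ValueError(
                f"id mismatch at junction {k}: cols of link {k - 1} do not "
                f"match rows of link {k}"
            )
        result = result @ c.dense()
        col_ids = c.col_ids
    first = couplings[0]
    return Coupling(
        plan=result,
        row_ids=list(row_ids),
        col_ids=list(col_ids),
        spec=first.spec,
        objective=float("nan"),
        converged=all(c.converged for c in couplings),
        n_iter=sum(c.n_iter for c in couplings),
        marginal_error=float("nan"),
    )


# ----------------------------------------------------------------------
# push / pull and aggregation
# ----------------------------------------------------------------------
def indicator_weights(labels: Sequence, members: set) -> np.ndarray:
    """Normalized indicator ``1/|S|`` over observations whose label is in S."""
    mask = np.array([lab in members for lab in labels], dtype=float)
    if mask.sum() == 0:
        raise ValueError(f"no observations labelled in {sorted(members)}")
    return mask / mask.sum()


def push(c: Coupling, p: np.ndarray) -> np.ndarray:
    """Push a source weight vector forward: ``P^T p`` (descendants)."""
    p = np.asarray(p, dtype=float)
    if np.all(p == 0):
        raise ValueError("all-zero weight vector")
    if p.shape[0] != c.shape[0]:
        raise ValueError(f"weights have length {p.shape[0]}, plan has {c.shape[0]} rows")
    return c.dense().T @ p


def pull(c: Coupling, q: np.ndarray) -> np.ndarray:
    """Pull a target weight vector back: ``P q`` (ancestors)."""
    q = np.asarray(q, dtype=float)
    if np.all(q == 0):
        raise ValueError("all-zero weight vector")
    if q.shape[0] != c.shape[1]:
        raise ValueError(f"weights have length {q.shape[0]}, plan has {c.shape[1]} cols")
    return c.dense() @ q


def cell_transition(
    c: Coupling,
    src_ann: Sequence,
    tgt_ann: Sequence,
    normalization: str = "row",
    source_order: Sequence | None = None,
    target_order: Sequence | None = None,
) -> TransitionTable:
    """Aggregate a coupling to annotation level.

    Entry ``(s, t)`` sums the plan mass from source cells labelled ``s`` to
    target cells labelled ``t``. Row normalization turns rows into
    descendancy distributions; column normalization turns columns into
    ancestry distributions. Zero-mass rows/columns stay zero.
    """
    P = c.dense()
    src_ann = list(src_ann)
    tgt_ann = list(tgt_ann)
    if len(src_ann) != P.shape[0] or len(tgt_ann) != P.shape[1]:
        raise ValueError(
            f"label vector lengths ({len(src_ann)}, {len(tgt_ann)}) do not "
            f"match plan shape {P.shape}"
        )
    s_labels = list(source_order) if source_order is not None else sorted(set(src_ann))
    t_labels = list(target_order) if target_order is not None else sorted(set(tgt_ann))
    s_idx = {lab: i for i, lab in enumerate(s_labels)}
    t_idx = {lab: i for i, lab in enumerate(t_labels)}
    rows = np.array([s_idx[lab] for lab in src_ann])
    cols = np.array([t_idx[lab] for lab in tgt_ann])
    table = np.zeros((len(s_labels), len(t_labels)))
    np.add.at(table, (rows[:, None], cols[None, :]), P)
    if normalization == "row":
        sums = table.sum(axis=1, keepdims=True)
        table = np.divide(table, sums, out=np.zeros_like(table), where=sums > 0)
    elif normalization == "col":
        sums = table.sum(axis=0, keepdims=True)
        table = np.divide(table, sums, out=np.zeros_like(table), where=sums > 0)
    return TransitionTable(table, s_labels, t_labels, normalization)


def correlate_with_distribution(
    weights: np.ndarray,
    features: AnnotatedMatrix,
    method: str = "pearson",
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Correlate each feature with a pull/push density over observations.

    High positive correlation with a pull-back density marks putative driver
    genes of the pulled state; with a push-forward density, putative targets.
    An optional boolean mask restricts the computation (e.g. to known
    progenitor populations). Zero-variance features get NaN and are excluded
    from the ranking.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    weights = np.asarray(weights, dtype=float)
    if weights.shape[0] != features.n_obs:
        raise ValueError("weights must align with observations")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        weights = weights[mask]
        values = features.values[mask]
    else:
        values = features.values
    if weights.shape[0] < 3:
        raise ValueError("need at least 3 observations after masking")
    if method == "spearman":
        w = stats.rankdata(weights)
        v = np.apply_along_axis(stats.rankdata, 0, values)
    else:
        w = weights
        v = values
    w = w - w.mean()
    v = v - v.mean(axis=0)
    w_norm = np.sqrt((w**2).sum())
    v_norm = np.sqrt((v**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (v.T @ w) / (v_norm * w_norm)
    corr[v_norm == 0] = np.nan
    out = pd.DataFrame({"correlation": corr}, index=features.feature_ids)
    out["rank"] = (-out["correlation"]).rank(method="average")
    return out.sort_values("correlation", ascending=False)


def scaled_growth_and_apoptosis(
    a: np.ndarray,
    n_cells: int,
    s: float,
) -> tuple[np.ndarray, float]:
    """Convert realized coupling marginals into biological growth rates.

    ``g_i = N * a_i * s`` rescales the per-cell mass share by the average
    ancestor count ``s`` (the population-size change between the time
    points). Cells with ``g_i < 1`` contribute ``1 - g_i`` expected deaths;
    the apoptosis rate is the summed contribution divided by ``N``.
    """
    if s <= 0:
        raise ValueError("population scaling s must be positive")
    a = np.asarray(a, dtype=float)
    g = n_cells * a * s
    deficit = np.clip(1.0 - g, 0.0, None)
    apoptosis_rate = float(deficit.sum() / n_cells)
    return g, apoptosis_rate


# ----------------------------------------------------------------------
# fate probabilities
# ----------------------------------------------------------------------
def fate_probabilities(
    couplings: Sequence[Coupling],
    within_sim: Sequence[np.ndarray],
    labels: Sequence[Sequence],
    terminal_sets: dict,
    w_ot: float = 0.9,
) -> pd.DataFrame:
    """Absorption probabilities on the coupled multi-time-point Markov chain.

    A block transition matrix is assembled over all observations of all time
    points: row-normalized couplings occupy the superdiagonal blocks with
    weight ``w_ot`` and within-time similarity matrices the diagonal blocks
    with weight ``1 - w_ot`` (the last time point, having no outgoing
    coupling, keeps its within-time block at full weight). After row
    normalization, observations belonging to a terminal set are made
    absorbing and the absorption probability into each terminal group is
    computed by the exact linear solve ``(I - T) B = R``.

    Parameters
    ----------
    couplings
        Time-ordered couplings, one per consecutive pair.
    within_sim
        Row-stochastic within-time similarity matrices, one per time point.
    labels
        Per-time-point annotation vectors aligned with the couplings.
    terminal_sets
        Mapping from terminal-state name to the set of labels (at the last
        time point) forming that state.
    """
    n_times = len(within_sim)
    if len(couplings) != n_times - 1:
        raise ValueError("need one coupling per consecutive time-point pair")
    if not (0 <= w_ot <= 1):
        raise ValueError("w_ot must lie in [0, 1]")
    sizes = [w.shape[0] for w in within_sim]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    total = offsets[-1]
    K = np.zeros((total, total))
    for t, W in enumerate(within_sim):
        W = np.asarray(W, dtype=float)
        if W.shape != (sizes[t], sizes[t]):
            raise ValueError(f"within-time matrix {t} has shape {W.shape}")
        weight = 1.0 - w_ot if t < n_times - 1 else 1.0
        K[offsets[t]:offsets[t + 1], offsets[t]:offsets[t + 1]] = weight * W
    for t, c in enumerate(couplings):
        P = c.dense()
        rows = P.sum(axis=1, keepdims=True)
        if np.any(rows == 0):
            bad = [c.row_ids[i] for i in np.flatnonzero(rows[:, 0] == 0)]
            raise ValueError(f"observations with zero outgoing mass: {bad[:10]}")
        K[offsets[t]:offsets[t + 1], offsets[t + 1]:offsets[t + 2]] = (
            w_ot * P / rows
        )
    row_sums = K.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("states with zero outgoing mass in the assembled chain")
    K = K / row_sums
    # terminal membership: labels at the last time point
    last_labels = list(labels[-1])
    if len(last_labels) != sizes[-1]:
        raise ValueError("last label vector does not match last time point size")
    terminal_names = list(terminal_sets)
    absorbing = np.zeros(total, dtype=bool)
    group = np.full(total, -1, dtype=int)
    for gi, name in enumerate(terminal_names):
        members = terminal_sets[name]
        for i, lab in enumerate(last_labels):
            if lab in members:
                absorbing[offsets[-2] + i] = True
                group[offsets[-2] + i] = gi
    if not absorbing.any():
        raise ValueError("no observation belongs to any terminal set")
    transient = ~absorbing
    T = K[np.ix_(transient, transient)]
    R = np.zeros((transient.sum(), len(terminal_names)))
    K_ta = K[np.ix_(transient, absorbing)]
    for gi in range(len(terminal_names)):
        cols = group[absorbing] == gi
        R[:, gi] = K_ta[:, cols].sum(axis=1)
    B = np.linalg.solve(np.eye(T.shape[0]) - T, R)
    out = np.zeros((total, len(terminal_names)))
    out[transient] = B
    for gi in range(len(terminal_names)):
        out[absorbing & (group == gi), gi] = 1.0
    ids: list[str] = []
    for t, c in enumerate(couplings):
        ids.extend(c.row_ids)
    ids.extend(couplings[-1].col_ids if couplings else [str(i) for i in range(total)])
    return pd.DataFrame(out, index=ids, columns=terminal_names)
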