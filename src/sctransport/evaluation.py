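"""Evaluation metrics for couplings and alignments.

Transition-accuracy scores against curated allowed-transition sets, a
cell-level kNN coupling baseline (clTOME-style), a cyclic direction score
for cell-cycle phase transitions with a permutation test, the 1-D L1
Wasserstein distance, and gene-consistency diagnostics for aligned slides.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import wasserstein_distance

from .container import AnnotatedMatrix
from .solvers import Coupling, ProblemSpec
from .temporal import TransitionTable

__all__ = [
    "transition_accuracy",
    "cltome_coupling",
    "cell_cycle_direction_score",
    "wasserstein_1d",
    "alignment_consistency",
]

#: canonical cyclic ordering of cell-cycle phases
CYCLE_PHASES = ("G1S", "S", "G2M", "M", "MG1")


def transition_accuracy(
    table: TransitionTable,
    allowed: set,
    edge_threshold: float = 0.05,
) -> float:
    """Mass-weighted fraction of retained transitions that are allowed.

    Edges with weight below ``edge_threshold`` are excluded; the score is
    the weight sum over allowed retained edges divided by the weight sum
    over all retained edges. For a germ-layer variant, map the labels to
    layer ids first and put any curated exceptions (e.g. the neural-crest
    transition) into ``allowed``.
    """
    if table.normalization != "row":
        raise ValueError("transition table must be row-normalized")
    values = table.values
    retained = values >= edge_threshold
    total = values[retained].sum()
    if total == 0:
        raise ValueError("no transitions retained at this edge threshold")
    good = 0.0
    for i, s in enumerate(table.source_labels):
        for j, t in enumerate(table.target_labels):
            if retained[i, j] and (s, t) in allowed:
                good += values[i, j]
    return float(good / total)


def cltome_coupling(
    src: AnnotatedMatrix,
    tgt: AnnotatedMatrix,
    representation: str = "features",
    k: int = 5,
    n_subsamples: int = 500,
    frac: float = 0.8,
    seed: int | None = None,
) -> Coupling:
    """Cell-level kNN coupling baseline aggregated over random subsamples.

    In each subsample (a fraction ``frac`` of both time points) every target
    cell contributes ``1/k`` mass to each of its k nearest source cells in
    the shared representation. Accumulated over subsamples, the matrix is
    column-normalized so every target cell receives unit incoming mass.
    """
    x = src.get_representation(representation)
    y = tgt.get_representation(representation)
    n, m = x.shape[0], y.shape[0]
    rng = np.random.default_rng(seed)
    plan = np.zeros((n, m))
    for _ in range(n_subsamples):
        src_idx = np.sort(rng.choice(n, size=max(1, int(round(frac * n))), replace=False))
        tgt_idx = np.sort(rng.choice(m, size=max(1, int(round(frac * m))), replace=False))
        if k > src_idx.size:
            raise ValueError(
                f"k={k} exceeds the {src_idx.size} source cells in a subsample"
            )
        d = cdist(y[tgt_idx], x[src_idx])
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        for row, j in enumerate(tgt_idx):
            plan[src_idx[nn[row]], j] += 1.0 / k
    col_sums = plan.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        plan = np.divide(plan, col_sums, out=np.zeros_like(plan), where=col_sums > 0)
    spec = ProblemSpec(problem_type="W", epsilon=1.0, seed=seed)
    return Coupling(
        plan=plan,
        row_ids=list(src.obs_ids),
        col_ids=list(tgt.obs_ids),
        spec=spec,
        objective=float("nan"),
        converged=True,
        n_iter=n_subsamples,
        marginal_error=float("nan"),
    )


def _cycle_score(values: np.ndarray) -> float:
    k = values.shape[0]
    fwd = sum(values[i, (i + 1) % k] for i in range(k))
    bwd = sum(values[i, (i - 1) % k] for i in range(k))
    return float(fwd - bwd)


def cell_cycle_direction_score(
    table: TransitionTable,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Directionality of phase transitions around the cell cycle.

    ``score = sum_i (A[i, i+1] - A[i, i-1])`` with cyclic indices over the
    ordered phases G1S, S, G2M, M, MG1. The null permutes the 20
    off-diagonal entries uniformly among off-diagonal positions; the
    one-sided p-value uses add-one smoothing:
    ``(#{perm >= observed} + 1) / (n_perm + 1)``.
    """
    A = table.values
    if A.shape != (5, 5):
        raise ValueError(f"phase table must be 5x5, got {A.shape}")
    observed = _cycle_score(A)
    off_mask = ~np.eye(5, dtype=bool)
    off_vals = A[off_mask]
    rng = np.random.default_rng(seed)
    # vectorized null: permute off-diagonal values among off-diagonal slots
    perm_idx = np.argsort(rng.random((n_perm, off_vals.size)), axis=1)
    permuted = off_vals[perm_idx]  # (n_perm, 20)
    null_tables = np.zeros((n_perm, 5, 5))
    null_tables[:, off_mask] = permuted
    # diagonal does not enter the score
    k = 5
    fwd_idx = [(i, (i + 1) % k) for i in range(k)]
    bwd_idx = [(i, (i - 1) % k) for i in range(k)]
    fwd = sum(null_tables[:, i, j] for i, j in fwd_idx)
    bwd = sum(null_tables[:, i, j] for i, j in bwd_idx)
    null_scores = fwd - bwd
    p = (np.sum(null_scores >= observed) + 1) / (n_perm + 1)
    return observed, float(p)


def wasserstein_1d(
    x_samples: np.ndarray,
    y_samples: np.ndarray,
    x_weights: np.ndarray | None = None,
    y_weights: np.ndarray | None = None,
) -> float:
    """L1 optimal-transport distance between two 1-D sample sets."""
    x_samples = np.asarray(x_samples, dtype=float)
    y_samples = np.asarray(y_samples, dtype=float)
    if x_samples.size == 0 or y_samples.size == 0:
        raise ValueError("empty sample set")
    return float(
        wasserstein_distance(x_samples, y_samples, x_weights, y_weights)
    )


def alignment_consistency(
    ref: AnnotatedMatrix,
    queries: Sequence[AnnotatedMatrix],
    aligned_coords: Sequence[np.ndarray],
    k: int = 30,
) -> pd.DataFrame:
    """Gene-consistency of aligned slides via neighbourhood W1 distances.

    All slides must be in the reference frame: ``aligned_coords`` holds the
    reference coordinates first, then one aligned coordinate array per
    query. Per gene (skipping cells with zero expression), each reference
    cell gathers its k nearest query cells in aligned space; the reported
    value is the W1 distance between those query-neighbour expression values
    and the reference expression values. The correlation of distance with
    per-gene mean expression is attached as a robustness diagnostic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(aligned_coords) != len(queries) + 1:
        raise ValueError("need reference coordinates plus one array per query")
    ref_coords = np.asarray(aligned_coords[0], dtype=float)
    records = []
    for qi, (query, q_coords) in enumerate(zip(queries, aligned_coords[1:])):
        q_coords = np.asarray(q_coords, dtype=float)
        d = cdist(ref_coords, q_coords)
        nn = np.argsort(d, axis=1, kind="stable")[:, :k]
        shared = [g for g in ref.feature_ids if g in set(query.feature_ids)]
        q_idx = query.feature_index(shared)
        r_idx = ref.feature_index(shared)
        for g_pos, gene in enumerate(shared):
            r_expr = ref.values[:, r_idx[g_pos]]
            q_expr = query.values[:, q_idx[g_pos]]
            r_mask = r_expr > 0
            if not r_mask.any():
                continue  # gene with no expressing reference cells
            neighbour_vals = q_expr[nn[r_mask]].ravel()
            neighbour_vals = neighbour_vals[neighbour_vals > 0]
            if neighbour_vals.size == 0:
                continue
            dist = wasserstein_1d(neighbour_vals, r_expr[r_mask])
            records.append(
                {
                    "query": qi,
                    "gene": gene,
                    "w1_distance": dist,
                    "mean_expression": float(r_expr[r_mask].mean()),
                }
            )
    out = pd.DataFrame.from_records(
        records, columns=["query", "gene", "w1_distance", "mean_expression"]
    )
    if len(out) >= 3 and out["w1_distance"].std() > 0 and out["mean_expression"].std() > 0:
        rho = float(
            np.corrcoef(out["w1_distance"], out["mean_expression"])[0, 1]
        )
    else:
        rho = float("nan")
    out.attrs["expression_correlation"] = rho
    return out
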