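"""Trajectory inference that respects tissue organization.

Couples consecutive time points of spatially resolved data with a fused GW
problem: the linear term compares expression, the quadratic terms compare
spatial arrangements within each time point, and the left marginal carries
growth/death priors exactly as in the purely temporal model. At ``alpha = 0``
the problem reduces to the temporal W-type coupling. Annotations available
only at the latest time point propagate backward through the chain of
couplings.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .container import AnnotatedMatrix
from .geometry import CostSpec, build_cost
from .solvers import Coupling, Marginals, ProblemSpec, fused_gw
from .temporal import GrowthConfig, growth_marginals

__all__ = ["solve_spatiotemporal", "propagate_annotations_backward"]


def solve_spatiotemporal(
    src: AnnotatedMatrix,
    tgt: AnnotatedMatrix,
    shared_cost: CostSpec,
    src_spatial_cost: CostSpec,
    tgt_spatial_cost: CostSpec,
    spec: ProblemSpec,
    growth: GrowthConfig | None = None,
) -> Coupling:
    """Fused GW coupling of two time points with spatial quadratic terms.

    The left marginal comes from the growth model, the right is uniform;
    ``alpha`` interpolates between pure expression matching (0) and pure
    spatial-structure matching (1).
    """
    if spec.alpha is None:
        raise ValueError("spatiotemporal problems require an FGW alpha")
    growth = growth or GrowthConfig()
    a = growth_marginals(src, growth)
    b = np.full(tgt.n_obs, 1.0 / tgt.n_obs)
    C = build_cost(src, tgt, shared_cost)
    Cx = build_cost(src, src, src_spatial_cost)
    Cy = build_cost(tgt, tgt, tgt_spatial_cost)
    return fused_gw(
        C, Cx, Cy, Marginals(a, b),
        eps=spec.epsilon,
        alpha=spec.alpha,
        tau_a=spec.tau_a,
        tau_b=spec.tau_b,
        max_iter=spec.max_iter,
        tol=spec.tol,
        inner_max_iter=spec.inner_max_iter,
        inner_tol=spec.inner_tol,
    )


def propagate_annotations_backward(
    couplings: Sequence[Coupling],
    labels_at_last: Sequence,
) -> list[list]:
    """Walk annotations from the latest time point back to the earliest.

    For each coupling, starting from the last pair, the plan is aggregated
    over the (current) target annotations and row-normalized; every earlier
    observation takes the argmax annotation of its row. Ties break by larger
    pre-normalization mass, then by lower label index. Newly assigned labels
    feed the next-earlier step. Returns label vectors for every time point,
    earliest first (the last entry is the input).
    """
    labels_at_last = list(labels_at_last)
    if couplings and len(labels_at_last) != couplings[-1].shape[1]:
        raise ValueError("labels must align with the last coupling's columns")
    out: list[list] = [labels_at_last]
    current = labels_at_last
    for c in reversed(list(couplings)):
        cats = sorted(set(current))
        # per-observation aggregation: plan mass into each target category;
        # argmax is invariant to the row normalization, so ties resolve by
        # pre-normalization mass then by lowest label index
        P = c.dense()
        onehot = np.zeros((c.shape[1], len(cats)))
        cat_idx = {lab: i for i, lab in enumerate(cats)}
        for j, lab in enumerate(current):
            onehot[j, cat_idx[lab]] = 1.0
        mass = P @ onehot  # n_src x n_cats, pre-normalization masses
        empty = mass.sum(axis=0) == 0
        if empty.any():
            dropped = [cats[i] for i in np.flatnonzero(empty)]
            warnings.warn(
                f"annotation categories with no incoming mass dropped: {dropped}",
                stacklevel=2,
            )
        assigned = [cats[j] for j in np.argmax(mass, axis=1)]
        out.append(assigned)
        current = assigned
    out.reverse()
    return out
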