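"""Synthetic fixtures with the statistical structure the models assume.

Every generator is a pure function of its arguments including the seed and
stores the planted ground truth needed by recovery metrics:

* temporal Gaussian mixtures with planted cluster transitions and growth,
* grid-arranged spatial expression (i.i.d. or coordinate-coupled),
* rigidly moved slide pairs with known correspondence,
* multimodal blocks sharing one latent space,
* cell-cycle phase chains with a controllable forward bias.

Cluster centres of the temporal mixture sit equispaced on a line. On a line
the squared-Euclidean transport optimum between cluster-level masses is the
unique monotone rearrangement, so forward-chain transition matrices planted
by the generator are identifiable from the coupling — with equidistant
centre configurations they would not be.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .container import AnnotatedMatrix

__all__ = [
    "make_temporal_mixture",
    "make_spatial_grid",
    "make_slide_pair",
    "make_multimodal",
    "make_cycle_chain",
]


def _mat(values, prefix, meta=None, reps=None, t=None) -> AnnotatedMatrix:
    n, d = values.shape
    obs = [f"{prefix}_{i}" for i in range(n)]
    feats = [f"g{j}" for j in range(d)]
    if meta is not None:
        meta = meta.copy()
        meta.index = obs
    am = AnnotatedMatrix(values, obs, feats, meta, reps)
    return am


def make_temporal_mixture(
    n_per_time: int = 200,
    n_clusters: int = 4,
    transition: np.ndarray | None = None,
    growth: np.ndarray | None = None,
    n_time: int = 2,
    d: int = 5,
    sep: float = 6.0,
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> list[AnnotatedMatrix]:
    """Gaussian-blob time series with planted cluster transitions.

    Cluster ``k`` sits at ``k * sep`` along the first axis (isotropic noise
    ``noise_sd``). Cluster sizes at time t+1 follow a multinomial draw with
    probabilities proportional to ``sizes_t * diag(growth) * transition``.
    The planted transition matrix, per-cluster growth and true labels are
    stored in ``obs_meta`` / ``attrs`` for recovery tests.
    """
    if sep <= 0:
        raise ValueError("cluster separation must be positive")
    if transition is None:
        # default: forward developmental chain, 70% stay / 30% advance
        transition = np.eye(n_clusters) * 0.7
        for k in range(n_clusters - 1):
            transition[k, k + 1] = 0.3
        transition[-1, -1] = 1.0
    transition = np.asarray(transition, dtype=float)
    if transition.shape != (n_clusters, n_clusters):
        raise ValueError("transition must be n_clusters x n_clusters")
    if not np.allclose(transition.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("transition rows must sum to 1")
    if growth is None:
        growth = np.ones(n_clusters)
    growth = np.asarray(growth, dtype=float)
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, d))
    centers[:, 0] = np.arange(n_clusters) * sep

    sizes = rng.multinomial(n_per_time, np.full(n_clusters, 1.0 / n_clusters))
    out: list[AnnotatedMatrix] = []
    for t in range(n_time):
        labels = np.repeat(np.arange(n_clusters), sizes)
        points = centers[labels] + rng.normal(0, noise_sd, size=(n_per_time, d))
        meta = pd.DataFrame(
            {
                "time": t,
                "annotation": [f"c{c}" for c in labels],
            }
        )
        am = _mat(points, f"t{t}", meta)
        am.obs_meta.attrs["transition"] = transition
        am.obs_meta.attrs["growth"] = growth
        out.append(am)
        if t < n_time - 1:
            flow = sizes * growth  # expected outgoing mass per cluster
            probs = flow @ transition
            probs = probs / probs.sum()
            sizes = rng.multinomial(n_per_time, probs)
    return out


def make_spatial_grid(
    side: int = 10,
    n_genes: int = 20,
    structure: str = "coord_coupled",
    subsample_frac: float = 1.0,
    noise_sd: float = 0.05,
    seed: int | None = None,
) -> tuple[AnnotatedMatrix, AnnotatedMatrix]:
    """A (reference, spatial) pair on a regular grid.

    ``random_normal`` draws i.i.d. expression (no spatial structure);
    ``coord_coupled`` makes each gene a smooth sinusoidal/linear function of
    the coordinates plus noise, giving positive spatial correspondence. The
    spatial member keeps coordinates and is subsampled at
    ``subsample_frac``; ground-truth matching indices are stored in its
    ``obs_meta["true_index"]``.
    """
    if structure not in ("random_normal", "coord_coupled"):
        raise ValueError(f"unknown structure {structure!r}")
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(side, dtype=float), np.arange(side, dtype=float))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    n = coords.shape[0]
    if structure == "random_normal":
        expr = rng.normal(size=(n, n_genes))
    else:
        # smooth, predominantly monotone spatial gradients: linear readouts
        # of the coordinates plus a gentle curvature term and noise, so
        # expression distance grows with spatial distance
        scaled = coords / max(side - 1, 1)
        # isometric linear readout (orthonormal loadings): expression
        # distance tracks spatial distance exactly up to curvature + noise
        basis, _ = np.linalg.qr(rng.normal(size=(n_genes, 2)))
        loadings = basis.T * np.sqrt(n_genes)
        curvature = rng.uniform(0.05, 0.15, size=n_genes)
        phases = rng.uniform(0, np.pi, size=n_genes)
        expr = scaled @ loadings
        expr += curvature * np.sin(np.pi * scaled.sum(axis=1)[:, None] + phases)
        expr += rng.normal(0, noise_sd, size=(n, n_genes))
    reference = _mat(expr, "ref")
    keep = np.sort(
        rng.choice(n, size=max(1, int(round(subsample_frac * n))), replace=False)
    )
    meta = pd.DataFrame(
        {
            "spatial_0": coords[keep, 0],
            "spatial_1": coords[keep, 1],
            "true_index": keep,
        }
    )
    spatial = _mat(expr[keep], "sp", meta)
    return reference, spatial


def make_slide_pair(
    n: int = 100,
    d_genes: int = 20,
    rotation_deg: float = 30.0,
    translation: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    subsample_frac: float = 1.0,
    seed: int | None = None,
) -> tuple[AnnotatedMatrix, AnnotatedMatrix]:
    """Two slides related by a rigid motion with known correspondence.

    Slide 2 is a (possibly subsampled) copy of slide 1 with coordinates
    rotated by ``rotation_deg`` and translated, and expression perturbed by
    Gaussian noise of ``noise_sd``. The index of each slide-2 point in
    slide 1 is stored in ``obs_meta["true_index"]``.
    """
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 10, size=(n, 2))
    expr = rng.normal(size=(n, d_genes)) + coords @ rng.normal(size=(2, d_genes))
    meta1 = pd.DataFrame({"spatial_0": coords[:, 0], "spatial_1": coords[:, 1]})
    slide1 = _mat(expr, "s1", meta1)
    theta = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    keep = np.sort(
        rng.choice(n, size=max(2, int(round(subsample_frac * n))), replace=False)
    )
    coords2 = coords[keep] @ R.T + np.asarray(translation)
    expr2 = expr[keep] + rng.normal(0, noise_sd, size=(keep.size, d_genes))
    meta2 = pd.DataFrame(
        {
            "spatial_0": coords2[:, 0],
            "spatial_1": coords2[:, 1],
            "true_index": keep,
        }
    )
    slide2 = _mat(expr2, "s2", meta2)
    return slide1, slide2


def make_multimodal(
    n: int = 100,
    d1: int = 20,
    d2: int = 15,
    shared_latent_dim: int = 3,
    noise: float = 0.3,
    seed: int | None = None,
) -> AnnotatedMatrix:
    """One population with two modality representations of a shared latent.

    Both representation slots (``mod1``, ``mod2``) are linear readouts of a
    common latent factor matrix plus independent noise; the latent itself is
    stored as representation ``latent`` for validating that concatenation
    recovers shared structure.
    """
    rng = np.random.default_rng(seed)
    latent = rng.normal(size=(n, shared_latent_dim))
    W1 = rng.normal(size=(shared_latent_dim, d1))
    W2 = rng.normal(size=(shared_latent_dim, d2))
    mod1 = latent @ W1 + rng.normal(0, noise, size=(n, d1))
    mod2 = latent @ W2 + rng.normal(0, noise, size=(n, d2))
    am = _mat(mod1, "mm")
    am.add_representation("mod1", mod1)
    am.add_representation("mod2", mod2)
    am.add_representation("latent", latent)
    return am


def make_cycle_chain(
    n_per_phase: int = 40,
    forward_bias: float = 0.9,
    noise_sd: float = 0.1,
    seed: int | None = None,
) -> tuple[AnnotatedMatrix, AnnotatedMatrix]:
    """Two time points of cells on the cell-cycle circle.

    Time-1 cells carry the five ordered phase labels placed on a circle;
    each time-2 cell advances one phase with probability ``forward_bias``
    and stays otherwise. The identity correspondence (cell i at time 2
    descends from cell i at time 1) is stored in
    ``obs_meta["true_index"]``, so the ground-truth phase-transition table
    is computable in closed form.
    """
    from .evaluation import CYCLE_PHASES

    if not (0 <= forward_bias <= 1):
        raise ValueError("forward_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    k = len(CYCLE_PHASES)
    n = n_per_phase * k
    phase1 = np.repeat(np.arange(k), n_per_phase)
    angles1 = 2 * np.pi * phase1 / k
    coords1 = np.column_stack([np.cos(angles1), np.sin(angles1)])
    coords1 += rng.normal(0, noise_sd, size=coords1.shape)
    meta1 = pd.DataFrame({"annotation": [CYCLE_PHASES[p] for p in phase1]})
    t1 = _mat(coords1, "p1", meta1)

    advance = rng.random(n) < forward_bias
    phase2 = (phase1 + advance.astype(int)) % k
    angles2 = 2 * np.pi * phase2 / k
    coords2 = np.column_stack([np.cos(angles2), np.sin(angles2)])
    coords2 += rng.normal(0, noise_sd, size=coords2.shape)
    meta2 = pd.DataFrame(
        {
            "annotation": [CYCLE_PHASES[p] for p in phase2],
            "true_index": np.arange(n),
        }
    )
    t2 = _mat(coords2, "p2", meta2)
    return t1, t2
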