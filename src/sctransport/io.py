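"""Reading and writing the on-disk formats.

Dense matrices and metadata travel as tab-delimited UTF-8 tables; sparse
matrices as Matrix Market with obs/feature id sidecar files; couplings as
TSV with a key-value header block (or three factor files for low-rank
plans); run configuration as schema-validated YAML; run reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread

from .container import AnnotatedMatrix
from .geometry import CostSpec
from .solvers import Coupling, ProblemSpec
from .temporal import GrowthConfig, TransitionTable

__all__ = [
    "read_annotated_matrix",
    "write_annotated_matrix",
    "write_coupling",
    "read_coupling",
    "RunConfig",
    "load_config",
    "write_report",
]

_FLOAT_FMT = "%.17g"


# ----------------------------------------------------------------------
# AnnotatedMatrix
# ----------------------------------------------------------------------
def read_annotated_matrix(
    values_path: str | Path,
    obs_meta_path: str | Path | None = None,
    format: str = "dense_delim",
) -> AnnotatedMatrix:
    """Load a values matrix plus optional metadata, joined strictly by id.

    ``dense_delim``: TSV whose first column holds obs ids and whose header
    holds feature ids. ``mtx``: Matrix Market file with companion sidecars
    ``<stem>.obs_ids.txt`` and ``<stem>.feature_ids.txt`` (one id per line).
    """
    values_path = Path(values_path)
    if not values_path.exists():
        raise FileNotFoundError(values_path)
    if format == "dense_delim":
        frame = pd.read_csv(values_path, sep="\t", index_col=0)
        values = frame.to_numpy(dtype=float)
        obs_ids = [str(i) for i in frame.index]
        feature_ids = [str(c) for c in frame.columns]
    elif format == "mtx":
        values = np.asarray(mmread(values_path).todense(), dtype=float)
        stem = values_path.with_suffix("")
        obs_file = Path(f"{stem}.obs_ids.txt")
        feat_file = Path(f"{stem}.feature_ids.txt")
        for p in (obs_file, feat_file):
            if not p.exists():
                raise FileNotFoundError(f"missing id sidecar {p}")
        obs_ids = obs_file.read_text().split()
        feature_ids = feat_file.read_text().split()
    else:
        raise ValueError(f"unknown format {format!r}")
    obs_meta = None
    if obs_meta_path is not None:
        obs_meta_path = Path(obs_meta_path)
        if not obs_meta_path.exists():
            raise FileNotFoundError(obs_meta_path)
        obs_meta = pd.read_csv(obs_meta_path, sep="\t", index_col=0)
        if len(obs_meta) != len(obs_ids):
            raise ValueError(
                f"dimension mismatch: metadata has {len(obs_meta)} rows vs "
                f"matrix with {len(obs_ids)}"
            )
    return AnnotatedMatrix(values, obs_ids, feature_ids, obs_meta)


def write_annotated_matrix(am: AnnotatedMatrix, values_path: str | Path,
                           obs_meta_path: str | Path | None = None) -> None:
    values_path = Path(values_path)
    frame = pd.DataFrame(am.values, index=am.obs_ids, columns=am.feature_ids)
    frame.index.name = "obs_id"
    frame.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    if obs_meta_path is not None and len(am.obs_meta.columns) > 0:
        meta = am.obs_meta.copy()
        meta.index.name = "obs_id"
        meta.to_csv(Path(obs_meta_path), sep="\t", float_format=_FLOAT_FMT)


# ----------------------------------------------------------------------
# couplings
# ----------------------------------------------------------------------
def _header_lines(c: Coupling, seed) -> list[str]:
    spec = c.spec
    fields = {
        "problem_type": spec.problem_type,
        "epsilon": spec.epsilon,
        "tau_a": spec.tau_a,
        "tau_b": spec.tau_b,
        "alpha": spec.alpha,
        "rank": spec.rank,
        "objective": c.objective,
        "converged": c.converged,
        "n_iter": c.n_iter,
        "marginal_error": c.marginal_error,
        "seed": seed if seed is not None else spec.seed,
    }
    return [f"# {k}={v}" for k, v in fields.items()]


def write_coupling(
    c: Coupling,
    path: str | Path,
    format: str = "dense_delim",
    seed: int | None = None,
) -> Path:
    """Serialize a coupling with its solver settings.

    ``dense_delim`` stores the full plan (any coupling). ``factored`` stores
    the Q, R, g factors of a low-rank plan in three sibling files and fails
    for dense plans.
    """
    path = Path(path)
    if format == "dense_delim":
        lines = _header_lines(c, seed)
        frame = pd.DataFrame(c.dense(), index=c.row_ids, columns=c.col_ids)
        frame.index.name = "obs_id"
        body = frame.to_csv(sep="\t", float_format=_FLOAT_FMT)
        path.write_text("\n".join(lines) + "\n" + body)
        return path
    if format == "factored":
        if not c.is_low_rank:
            raise ValueError("factored format requires a low-rank plan")
        q, r, g = c.factors
        stem = path.with_suffix("")
        q_frame = pd.DataFrame(q, index=c.row_ids)
        q_frame.index.name = "obs_id"
        q_path = Path(f"{stem}.Q.tsv")
        q_path.write_text(
            "\n".join(_header_lines(c, seed)) + "\n"
            + q_frame.to_csv(sep="\t", float_format=_FLOAT_FMT)
        )
        r_frame = pd.DataFrame(r, index=c.col_ids)
        r_frame.index.name = "obs_id"
        r_frame.to_csv(Path(f"{stem}.R.tsv"), sep="\t", float_format=_FLOAT_FMT)
        np.savetxt(Path(f"{stem}.g.tsv"), g, fmt=_FLOAT_FMT, delimiter="\t")
        return q_path
    raise ValueError(f"unknown format {format!r}")


def _parse_header(lines: list[str]) -> dict:
    out = {}
    for line in lines:
        key, _, value = line[1:].strip().partition("=")
        out[key.strip()] = value.strip()
    return out


def read_coupling(path: str | Path, format: str = "dense_delim") -> Coupling:
    """Read back a serialized coupling (inverse of :func:`write_coupling`)."""
    path = Path(path)
    text = path.read_text().splitlines()
    header = [ln for ln in text if ln.startswith("#")]
    meta = _parse_header(header)
    body = "\n".join(ln for ln in text if not ln.startswith("#"))
    from io import StringIO

    def build_spec() -> ProblemSpec:
        alpha = meta.get("alpha", "None")
        rank = meta.get("rank", "full")
        return ProblemSpec(
            problem_type=meta.get("problem_type", "W"),
            epsilon=float(meta.get("epsilon", 1e-2)),
            tau_a=float(meta.get("tau_a", 1.0)),
            tau_b=float(meta.get("tau_b", 1.0)),
            alpha=None if alpha == "None" else float(alpha),
            rank="full" if rank == "full" else int(rank),
            seed=None if meta.get("seed", "None") == "None" else int(meta["seed"]),
        )

    common = dict(
        spec=build_spec(),
        objective=float(meta.get("objective", "nan")),
        converged=meta.get("converged", "False") == "True",
        n_iter=int(meta.get("n_iter", 0)),
        marginal_error=float(meta.get("marginal_error", "nan")),
    )
    if format == "dense_delim":
        frame = pd.read_csv(StringIO(body), sep="\t", index_col=0)
        return Coupling(
            plan=frame.to_numpy(dtype=float),
            row_ids=[str(i) for i in frame.index],
            col_ids=[str(c) for c in frame.columns],
            **common,
        )
    if format == "factored":
        stem = Path(str(path)[: -len(".Q.tsv")]) if str(path).endswith(".Q.tsv") else path.with_suffix("")
        q_frame = pd.read_csv(StringIO(body), sep="\t", index_col=0)
        r_frame = pd.read_csv(Path(f"{stem}.R.tsv"), sep="\t", index_col=0)
        g = np.loadtxt(Path(f"{stem}.g.tsv"), delimiter="\t", ndmin=1)
        return Coupling(
            plan=None,
            factors=(
                q_frame.to_numpy(dtype=float),
                r_frame.to_numpy(dtype=float),
                g,
            ),
            row_ids=[str(i) for i in q_frame.index],
            col_ids=[str(i) for i in r_frame.index],
            **common,
        )
    raise ValueError(f"unknown format {format!r}")


# ----------------------------------------------------------------------
# configuration and reports
# ----------------------------------------------------------------------
_PROBLEM_KEYS = {
    "problem_type", "epsilon", "tau_a", "tau_b", "alpha", "rank", "lr_gamma",
    "max_iter", "tol", "inner_max_iter", "inner_tol", "seed",
}
_COST_KEYS = {"kind", "representation", "scaling", "geodesic_k", "elastic_gamma"}
_GROWTH_KEYS = {"mode", "delta_t", "scale_c"}
_TOP_KEYS = {
    "problem", "cost", "growth", "inputs", "output_dir", "seed", "log_level",
    "alpha_grid", "policy", "reference",
}


@dataclass
class RunConfig:
    """A validated run configuration; unknown keys are an error."""

    problem: ProblemSpec
    cost: CostSpec
    growth: GrowthConfig
    inputs: dict
    output_dir: str
    seed: int = 0
    log_level: str = "INFO"
    extras: dict = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def sub(section: str, allowed: set) -> dict:
        block = raw.get(section) or {}
        bad = set(block) - allowed
        if bad:
            raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
        return block

    problem = ProblemSpec(**sub("problem", _PROBLEM_KEYS))
    cost = CostSpec(**sub("cost", _COST_KEYS))
    growth = GrowthConfig(**sub("growth", _GROWTH_KEYS))
    seed = int(raw.get("seed", 0))
    if problem.seed is None:
        problem.seed = seed
    extras = {
        k: raw[k] for k in ("alpha_grid", "policy", "reference") if k in raw
    }
    return RunConfig(
        problem=problem,
        cost=cost,
        growth=growth,
        inputs=raw.get("inputs") or {},
        output_dir=str(raw.get("output_dir", ".")),
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        extras=extras,
    )


def write_report(path: str | Path, config: RunConfig, coupling: Coupling,
                 extra: dict | None = None) -> None:
    """Machine-readable JSON record of settings and outcome."""
    spec = coupling.spec
    report = {
        "seed": config.seed,
        "problem": {k: v for k, v in asdict(spec).items()},
        "cost": asdict(config.cost),
        "objective": coupling.objective,
        "converged": bool(coupling.converged),
        "n_iter": int(coupling.n_iter),
        "marginal_error": coupling.marginal_error,
    }
    if extra:
        report.update(extra)
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    frame = table.to_frame()
    frame.index.name = "source"
    frame.to_csv(Path(path), sep="\t", float_format=_FLOAT_FMT)
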