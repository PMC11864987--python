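"""Universal observation-by-feature container used by every problem class.

An :class:`AnnotatedMatrix` holds a state matrix (cells/spots/bins by
genes/peaks/features), per-observation metadata (time label, annotation,
spatial coordinates) and any number of named low-dimensional representations,
all aligned on unique observation ids.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["AnnotatedMatrix"]

#: reserved obs_meta column names with special meaning
TIME_COL = "time"
ANNOTATION_COL = "annotation"
SPATIAL_COLS = ("spatial_0", "spatial_1", "spatial_2")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {what}: {dups}")
    return ids


class AnnotatedMatrix:
    """Observations x features matrix with aligned metadata and representations.

    Parameters
    ----------
    values
        Dense ``(n_obs, n_features)`` array of expression/accessibility values.
    obs_ids, feature_ids
        Unique string identifiers for rows and columns.
    obs_meta
        Optional table indexed by (or joinable on) ``obs_ids``. Recognized
        columns: ``time`` (ordered label), ``annotation`` (categorical),
        ``spatial_0 .. spatial_2`` (coordinates, all present up to the
        dimensionality used).
    representations
        Named map of obs-aligned real matrices ``(n_obs, d)``, e.g. a PCA
        or joint latent space used to build cost matrices.
    """

    def __init__(
        self,
        values: np.ndarray,
        obs_ids: Sequence[str],
        feature_ids: Sequence[str],
        obs_meta: pd.DataFrame | None = None,
        representations: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        self.values = values
        self.obs_ids = _check_unique(obs_ids, "obs ids")
        self.feature_ids = _check_unique(feature_ids, "feature ids")
        n_obs, n_feat = values.shape
        if len(self.obs_ids) != n_obs:
            raise ValueError(
                f"matrix has {n_obs} rows but {len(self.obs_ids)} obs ids"
            )
        if len(self.feature_ids) != n_feat:
            raise ValueError(
                f"matrix has {n_feat} columns but {len(self.feature_ids)} feature ids"
            )
        if obs_meta is None:
            obs_meta = pd.DataFrame(index=pd.Index(self.obs_ids, name="obs_id"))
        else:
            obs_meta = obs_meta.copy()
            obs_meta.index = obs_meta.index.astype(str)
            if len(obs_meta) != n_obs:
                raise ValueError(
                    f"metadata has {len(obs_meta)} rows vs matrix with {n_obs}"
                )
            missing = set(self.obs_ids) - set(obs_meta.index)
            if missing:
                raise ValueError(
                    f"metadata is missing obs ids: {sorted(missing)[:10]}"
                )
            # join strictly by id, never by row order
            obs_meta = obs_meta.loc[self.obs_ids]
        self.obs_meta = obs_meta
        self.representations: dict[str, np.ndarray] = {}
        for name, rep in (representations or {}).items():
            self.add_representation(name, rep)
        self._check_spatial()

    # ------------------------------------------------------------------
    def _check_spatial(self) -> None:
        present = [c for c in SPATIAL_COLS if c in self.obs_meta.columns]
        if not present:
            return
        expected = list(SPATIAL_COLS[: len(present)])
        if present != expected:
            raise ValueError(
                f"spatial columns must be contiguous from spatial_0, got {present}"
            )
        if self.obs_meta[present].isna().any().any():
            raise ValueError("spatial coordinates contain missing values")

    # ------------------------------------------------------------------
    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def spatial(self) -> np.ndarray | None:
        """Spatial coordinates ``(n_obs, 2 or 3)`` or None if absent."""
        cols = [c for c in SPATIAL_COLS if c in self.obs_meta.columns]
        if not cols:
            return None
        return self.obs_meta[cols].to_numpy(dtype=float)

    @property
    def time(self) -> pd.Series | None:
        return self.obs_meta[TIME_COL] if TIME_COL in self.obs_meta.columns else None

    @property
    def annotation(self) -> pd.Series | None:
        col = ANNOTATION_COL
        return self.obs_meta[col] if col in self.obs_meta.columns else None

    # ------------------------------------------------------------------
    def add_representation(self, name: str, rep: np.ndarray) -> None:
        rep = np.asarray(rep, dtype=float)
        if rep.ndim != 2 or rep.shape[0] != self.n_obs:
            raise ValueError(
                f"representation {name!r} has shape {rep.shape}, "
                f"expected ({self.n_obs}, d)"
            )
        self.representations[name] = rep

    def get_representation(self, name: str) -> np.ndarray:
        """Return the named representation; ``"features"`` is the raw matrix."""
        if name == "features":
            return self.values
        if name == "spatial":
            coords = self.spatial
            if coords is None:
                raise KeyError("no spatial coordinates present")
            return coords
        try:
            return self.representations[name]
        except KeyError:
            raise KeyError(
                f"unknown representation {name!r}; available: "
                f"{['features'] + sorted(self.representations)}"
            ) from None

    def feature_index(self, features: Sequence[str]) -> np.ndarray:
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        unknown = [f for f in features if f not in lookup]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        return np.array([lookup[f] for f in features], dtype=int)

    def subset_obs(self, mask_or_ids) -> "AnnotatedMatrix":
        """Row-subset by boolean mask or id list, keeping alignment."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            lookup = {o: i for i, o in enumerate(self.obs_ids)}
            idx = np.array([lookup[str(o)] for o in mask_or_ids], dtype=int)
        return AnnotatedMatrix(
            self.values[idx],
            [self.obs_ids[i] for i in idx],
            self.feature_ids,
            self.obs_meta.iloc[idx],
            {k: v[idx] for k, v in self.representations.items()},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        reps = sorted(self.representations)
        return (
            f"AnnotatedMatrix(n_obs={self.n_obs}, n_features={self.n_features}, "
            f"meta={list(self.obs_meta.columns)}, representations={reps})"
        )
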