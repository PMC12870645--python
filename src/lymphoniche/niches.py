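"""Spatial-niche discovery: K-means over neighborhood-composition vectors.

Each cell is described by the raw counts of neighboring cells per cluster
label within the analysis radius; K-means over these vectors groups cells into
recurring local microenvironments ("niches").  The within-cluster sum of
squares (WCSS) curve over a grid of k supports elbow-style model selection.

The raw count matrix is clustered unscaled by default; a fraction-normalized
variant is available but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "NicheModel",
    "fit_niches",
    "wcss_curve",
    "elbow_k",
    "niche_profiles",
    "map_niche_roles",
    "DEFAULT_K",
]

DEFAULT_K = 50


@dataclass
class NicheModel:
    """Fitted niche model: centroids in composition space plus profiles.

    Niche labels run 1..k.  ``niche_profiles`` rows give, for each niche, the
    fraction of member cells carrying each cell-cluster label (the members'
    *own* labels, not their neighbors'); rows of non-empty niches sum to 1.
    """

    k: int
    centroids: np.ndarray
    columns: list[str]
    seed: int
    wcss: float
    niche_profiles: pd.DataFrame | None = None
    n_restarts: int = 10
    empty_niches: list[int] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "wcss": self.wcss,
            "n_restarts": self.n_restarts,
            "columns": self.columns,
            "centroids": self.centroids.tolist(),
            "niche_profiles": None
            if self.niche_profiles is None
            else self.niche_profiles.to_dict(orient="index"),
            "empty_niches": self.empty_niches,
        }


def _as_matrix(nbhd: pd.DataFrame, use_fractions: bool) -> np.ndarray:
    X = nbhd.to_numpy(dtype=float)
    if use_fractions:
        rows = X.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1.0
        X = X / rows
    return X


def fit_niches(
    nbhd: pd.DataFrame,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 10,
    use_fractions: bool = False,
) -> tuple[NicheModel, np.ndarray]:
    """Cluster neighborhood-composition vectors into ``k`` spatial niches.

    Deterministic given ``seed``; k-means++ initialization with
    ``n_restarts`` restarts and Lloyd iterations to 1e-4 relative tolerance.
    Returns the model and per-cell niche labels in 1..k.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = _as_matrix(nbhd, use_fractions)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct composition rows")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, tol=1e-4)
    labels0 = km.fit_predict(X)
    labels = labels0 + 1  # niches are 1-based
    model = NicheModel(
        k=k,
        centroids=km.cluster_centers_,
        columns=list(nbhd.columns),
        seed=seed,
        wcss=float(km.inertia_),
        n_restarts=n_restarts,
    )
    model.empty_niches = sorted(set(range(1, k + 1)) - set(labels.tolist()))
    return model, labels


def wcss_curve(
    nbhd: pd.DataFrame,
    k_grid: list[int],
    seed: int = 0,
    n_restarts: int = 10,
    use_fractions: bool = False,
) -> pd.DataFrame:
    """WCSS at each k of an ascending grid, for elbow-based selection of k."""
    if list(k_grid) != sorted(k_grid):
        raise ValueError("k_grid must be ascending")
    rows = []
    for k in k_grid:
        model, _ = fit_niches(nbhd, k=k, seed=seed, n_restarts=n_restarts, use_fractions=use_fractions)
        rows.append({"k": k, "wcss": model.wcss})
    return pd.DataFrame(rows)


def elbow_k(curve: pd.DataFrame) -> int:
    """k with the largest second difference of WCSS (interior grid points)."""
    if len(curve) < 3:
        return int(curve["k"].iloc[-1])
    w = curve["wcss"].to_numpy()
    second = w[:-2] - 2 * w[1:-1] + w[2:]
    return int(curve["k"].iloc[1 + int(np.argmax(second))])


def niche_profiles(
    cells: pd.DataFrame,
    niche_labels: np.ndarray,
    label_column: str = "cluster",
    k: int | None = None,
) -> pd.DataFrame:
    """Per-niche composition: fraction of member cells per cell-cluster label.

    Empty niches get an all-zero row (flagged by the zero row sum) rather
    than an error.
    """
    niche_labels = np.asarray(niche_labels)
    if len(niche_labels) != len(cells):
        raise ValueError("niche label vector length differs from cell table")
    if cells[label_column].isna().any():
        raise ValueError("every cell needs a cluster label")
    if k is None:
        k = int(niche_labels.max()) if len(niche_labels) else 0
    vocab = sorted(map(str, cells[label_column].unique()))
    counts = (
        pd.crosstab(pd.Series(niche_labels, index=cells.index, name="niche"),
                    cells[label_column].astype(str))
        .reindex(index=range(1, k + 1), columns=vocab, fill_value=0)
    )
    totals = counts.sum(axis=1)
    profiles = counts.div(totals.where(totals > 0, 1), axis=0)
    profiles.index.name = "niche"
    return profiles


def map_niche_roles(
    profiles: pd.DataFrame,
    gc_labels: set[str],
    mz_labels: set[str],
    majority: float = 0.5,
) -> dict[int, str]:
    """Assign each niche a microanatomical role from its member composition.

    A niche is a "GC" niche when more than ``majority`` of its member cells
    carry a germinal-center cell label, "MZ" when mantle labels dominate, and
    "other" otherwise.  Used to connect data-driven niche ids to the
    GC/mantle niche sets that follicle detection expects.
    """
    roles: dict[int, str] = {}
    gc_cols = [c for c in profiles.columns if c in gc_labels]
    mz_cols = [c for c in profiles.columns if c in mz_labels]
    for niche, row in profiles.iterrows():
        gc_frac = float(row[gc_cols].sum()) if gc_cols else 0.0
        mz_frac = float(row[mz_cols].sum()) if mz_cols else 0.0
        if gc_frac > majority:
            roles[int(niche)] = "GC"
        elif mz_frac > majority:
            roles[int(niche)] = "MZ"
        else:
            roles[int(niche)] = "other"
    return roles
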