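"""Fuzzy c-means clustering of standardized temporal expression profiles.

Profiles are standardized gene-wise to mean 0 / SD 1 so that clustering in
Euclidean space groups genes by profile shape rather than absolute level.
The clusterer is the classic Bezdek fuzzy c-means iteration with fuzzifier
m (default 1.75) and c clusters (default 6); a gene belongs to a cluster
"core" when its membership in that cluster reaches 0.90.
"""

from __future__ import annotations

import dataclasses
import warnings
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


def standardize_profiles(sm: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardization to mean 0, SD 1 (population SD).

    Zero-variance (flat) profiles cannot be standardized; they are dropped
    with a warning. Standardization is invariant to positive affine
    transforms of a profile.
    """
    x = sm.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.all():
        raise ValueError("all profiles have zero variance")
    if flat.any():
        warnings.warn(
            f"dropping {int(flat.sum())} zero-variance profiles", stacklevel=2
        )
    keep = ~flat
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    return pd.DataFrame(z, index=sm.index[keep], columns=sm.columns)


@dataclasses.dataclass
class FuzzyClusteringResult:
    """Membership matrix U (genes x clusters), cluster centres and run metadata."""

    memberships: pd.DataFrame
    centers: pd.DataFrame
    m: float
    c: int
    n_iter: int
    objective: float
    objective_history: list[float]
    seed: int

    def hard_labels(self) -> pd.Series:
        """Cluster of maximal membership per gene."""
        return self.memberships.idxmax(axis=1)


def _memberships_from_distances(d2: np.ndarray, m: float) -> np.ndarray:
    """u_ij = 1 / sum_k (d_ij / d_kj)^(2/(m-1)); membership 1 on exact hits."""
    u = np.zeros_like(d2)
    zero_rows = (d2 == 0).any(axis=1)
    if zero_rows.any():
        hits = d2[zero_rows] == 0
        u[zero_rows] = hits / hits.sum(axis=1, keepdims=True)
    nz = ~zero_rows
    if nz.any():
        # normalise by the row minimum so the exponentiation stays bounded
        # even for m close to 1 (large exponent)
        d2n = d2[nz] / d2[nz].min(axis=1, keepdims=True)
        inv = d2n ** (-1.0 / (m - 1.0))
        u[nz] = inv / inv.sum(axis=1, keepdims=True)
    return u


def fuzzy_cmeans(
    profiles: pd.DataFrame,
    c: int = 6,
    m: float = 1.75,
    tol: float = 1e-6,
    max_iter: int = 1000,
    seed: int = 0,
) -> FuzzyClusteringResult:
    """Bezdek fuzzy c-means on gene profiles (rows = genes, columns = stages).

    Memberships are initialized from a symmetric Dirichlet under ``seed``;
    each iteration recomputes centres c_i = sum_j u_ij^m x_j / sum_j u_ij^m
    and memberships from squared Euclidean distances, until the largest
    membership change falls below ``tol``. The objective
    J = sum_ij u_ij^m d_ij^2 is recorded each iteration and is
    non-increasing. Cluster labels are canonicalized by the stage at which
    each centre peaks, so runs are comparable.
    """
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    x = profiles.to_numpy(dtype=float)
    n = x.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} genes, got {n}")
    # per-gene Dirichlet init keyed on (seed, gene id) so that permuting the
    # input rows permutes the result rows identically
    u = np.stack(
        [
            np.random.default_rng(
                [seed, zlib.crc32(str(g).encode())]
            ).dirichlet(np.ones(c))
            for g in profiles.index
        ]
    )
    history: list[float] = []
    centers = np.zeros((c, x.shape[1]))
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = cdist(x, centers, metric="sqeuclidean")
        u_new = _memberships_from_distances(d2, m)
        history.append(float(((u_new**m) * d2).sum()))
        delta = float(np.abs(u_new - u).max())
        u = u_new
        if delta < tol:
            break

    # canonical cluster order: by peak stage, then by descending peak height
    order = sorted(
        range(c), key=lambda i: (int(centers[i].argmax()), -centers[i].max())
    )
    labels = [f"cluster_{k+1}" for k in range(c)]
    memberships = pd.DataFrame(u[:, order], index=profiles.index, columns=labels)
    centers_df = pd.DataFrame(centers[order], index=labels, columns=profiles.columns)
    return FuzzyClusteringResult(
        memberships=memberships,
        centers=centers_df,
        m=m,
        c=c,
        n_iter=n_iter,
        objective=history[-1],
        objective_history=history,
        seed=seed,
    )


@dataclasses.dataclass
class ClusterCores:
    """Per-cluster gene lists at membership >= the core threshold."""

    cores: dict[str, list[str]]
    threshold: float


def cluster_cores(
    res: FuzzyClusteringResult, core_threshold: float = 0.90
) -> ClusterCores:
    """Genes with membership >= ``core_threshold`` in a cluster.

    With threshold > 0.5 a gene can belong to at most one core.
    """
    if not 0.5 < core_threshold <= 1:
        raise ValueError("core_threshold must be in (0.5, 1]")
    cores = {
        col: list(res.memberships.index[res.memberships[col] >= core_threshold])
        for col in res.memberships.columns
    }
    return ClusterCores(cores=cores, threshold=core_threshold)


def write_memberships(
    res: FuzzyClusteringResult, cores: ClusterCores, path: str | Path
) -> None:
    out = res.memberships.copy()
    out["hard_label"] = res.hard_labels()
    core_of: dict[str, str] = {}
    for label, genes in cores.cores.items():
        for g in genes:
            core_of[g] = label
    out["core"] = [core_of.get(g, ".") for g in out.index]
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6f")


def write_centers(res: FuzzyClusteringResult, path: str | Path) -> None:
    out = res.centers.copy()
    out.index.name = "cluster"
    out.to_csv(path, sep="\t", float_format="%.6f")
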