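"""Systematic categorical-space design for ligand libraries.

A library of several hundred candidate phosphine ligands, each described by
tens of computed molecular descriptors, is reduced to a diverse experimental
panel: z-score the descriptors, project onto the leading principal
components, k-means the scores into regions of chemical space, and pick the
ligand nearest each cluster centroid (subject to caller-supplied exclusions
for availability, price or stability).  A synthetic descriptor generator
with planted cluster structure stands in for the public descriptor set so
the design pipeline is testable offline.

k-means is run as explicit Lloyd iterations (k-means++ seeding, best of
several restarts by inertia) so that the per-iteration monotone decrease of
inertia can be asserted; PCA and seeding reuse scikit-learn primitives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import kmeans_plusplus
from sklearn.decomposition import PCA

__all__ = [
    "DescriptorTable",
    "ClusterModel",
    "standardize",
    "pca_project",
    "cluster_kmeans",
    "select_representatives",
    "synthesize_descriptor_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DescriptorTable:
    """Ligand × descriptor matrix with row/column labels."""

    ligand_ids: tuple[str, ...]
    matrix: np.ndarray
    descriptor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ligand_ids", tuple(self.ligand_ids))
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.shape != (len(self.ligand_ids), len(self.descriptor_names)):
            raise ValueError("matrix shape does not match labels")
        if len(self.ligand_ids) < 2:
            raise ValueError("need at least 2 ligands")
        if np.isnan(m).any():
            raise ValueError("missing values present; use from_dataframe to drop them")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DescriptorTable":
        """Build from a DataFrame (index = ligand ids); rows with missing
        values are dropped with a logged count."""
        n0 = len(df)
        df = df.dropna(axis=0)
        dropped = n0 - len(df)
        if dropped:
            logger.info("dropped %d ligand rows with missing descriptors", dropped)
        return cls(ligand_ids=tuple(str(i) for i in df.index),
                   matrix=df.to_numpy(dtype=float),
                   descriptor_names=tuple(str(c) for c in df.columns))

    @classmethod
    def read_csv(cls, path: str | Path) -> "DescriptorTable":
        return cls.from_dataframe(pd.read_csv(path, index_col=0))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ligand_ids),
                            columns=list(self.descriptor_names))


@dataclass(frozen=True)
class ClusterModel:
    """PCA + k-means decomposition of a descriptor table."""

    pc_loadings: np.ndarray          # descriptors × n_pc
    pc_scores: np.ndarray            # ligands × n_pc
    explained_variance: np.ndarray   # fractions, descending
    labels: dict[str, int]           # ligand id → cluster
    centroids: np.ndarray            # k × n_pc
    inertia: float
    representatives: dict[int, str | None] | None = None

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def standardize(table: DescriptorTable) -> DescriptorTable:
    """Z-score every descriptor column (population sd); drop zero-variance
    columns with a log entry.  Idempotent on already-standardized input."""
    X = table.matrix
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all descriptor columns have zero variance")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d zero-variance descriptor columns", n_drop)
    Xk = X[:, keep]
    Z = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0, ddof=0)
    return DescriptorTable(
        ligand_ids=table.ligand_ids,
        matrix=Z,
        descriptor_names=tuple(np.array(table.descriptor_names)[keep]),
    )


def pca_project(table: DescriptorTable, n_pc: int = 4,
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Project onto the leading principal components.

    Returns (scores ligands×n_pc, loadings descriptors×n_pc, explained
    variance fractions).  Sign convention: each loading vector's
    largest-magnitude entry is made positive, so projections are
    reproducible across linear-algebra backends.
    """
    n, p = table.matrix.shape
    if n_pc > min(n - 1, p):
        raise ValueError(f"n_pc={n_pc} exceeds min(rows-1, cols)={min(n - 1, p)}")
    pca = PCA(n_components=n_pc, svd_solver="full")
    scores = pca.fit_transform(table.matrix)
    loadings = pca.components_.T.copy()  # p × n_pc
    for j in range(n_pc):
        i = int(np.abs(loadings[:, j]).argmax())
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return scores, loadings, pca.explained_variance_ratio_.copy()


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300,
           tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, float]:
    """Lloyd iterations from given centers; inertia is checked nonincreasing."""
    prev_inertia = np.inf
    labels = np.zeros(X.shape[0], dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = float(d2[np.arange(X.shape[0]), labels].sum())
        assert inertia <= prev_inertia + 1e-9, "k-means inertia increased"
        new_centers = centers.copy()
        for c in range(centers.shape[0]):
            mask = labels == c
            if mask.any():
                new_centers[c] = X[mask].mean(axis=0)
        if prev_inertia - inertia <= tol:
            centers = new_centers
            break
        centers, prev_inertia = new_centers, inertia
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centers, inertia


def cluster_kmeans(scores: np.ndarray, k: int = 24, seed: int = 0,
                   restarts: int = 20) -> tuple[np.ndarray, np.ndarray, float]:
    """k-means on PC scores: k-means++ seeding, Lloyd iterations, best of
    ``restarts`` by inertia.  Deterministic under a fixed seed."""
    X = np.asarray(scores, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        centers, _ = kmeans_plusplus(X, n_clusters=k, random_state=rs)
        labels, centers, inertia = _lloyd(X, centers)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    return best


def fit_cluster_model(table: DescriptorTable, n_pc: int = 4, k: int = 24,
                      seed: int = 0, restarts: int = 20) -> ClusterModel:
    """Standardize → PCA → k-means, returning the full decomposition."""
    std = standardize(table)
    scores, loadings, evr = pca_project(std, n_pc=n_pc)
    labels, centroids, inertia = cluster_kmeans(scores, k=k, seed=seed,
                                                restarts=restarts)
    return ClusterModel(
        pc_loadings=loadings, pc_scores=scores, explained_variance=evr,
        labels={lig: int(c) for lig, c in zip(std.ligand_ids, labels)},
        centroids=centroids, inertia=inertia,
    )


def select_representatives(model: ClusterModel, table: DescriptorTable,
                           exclusions: Iterable[str | int] = (),
                           ) -> dict[int, str | None]:
    """One ligand per cluster: the non-excluded member closest to its
    centroid in PC space (ties → lexicographically smallest id).

    ``exclusions`` may contain ligand ids or whole cluster ids; a wholly
    excluded cluster maps to ``None``.
    """
    excl = set(exclusions)
    excluded_clusters = {e for e in excl if isinstance(e, int)}
    excluded_ligands = {e for e in excl if isinstance(e, str)}
    ids = list(table.ligand_ids)
    reps: dict[int, str | None] = {}
    for c in range(model.k):
        if c in excluded_clusters:
            reps[c] = None
            continue
        members = [(lig, i) for i, lig in enumerate(ids)
                   if model.labels.get(lig) == c and lig not in excluded_ligands]
        if not members:
            reps[c] = None
            continue
        dists = {lig: float(np.linalg.norm(model.pc_scores[i] - model.centroids[c]))
                 for lig, i in members}
        best = min(dists.values())
        candidates = sorted(lig for lig, d in dists.items()
                            if abs(d - best) <= 1e-12)
        reps[c] = candidates[0]
    return reps


def synthesize_descriptor_table(n_ligands: int = 365, n_descriptors: int = 30,
                                n_clusters: int = 24, seed: int = 0,
                                latent_dim: int = 4,
                                center_scale: float = 4.0,
                                within_scale: float = 0.35,
                                noise_scale: float = 0.15,
                                ) -> tuple[DescriptorTable, np.ndarray]:
    """Synthetic ligand descriptor table with planted cluster structure.

    Emulates the shape of a public phosphine descriptor library: several
    hundred ligands, tens of correlated numeric descriptors.  Cluster
    centers are drawn in a ``latent_dim``-dimensional latent space, each
    ligand sits near its cluster center, and the latent coordinates are
    lifted to ``n_descriptors`` observed descriptors through a random linear
    map with heterogeneous per-descriptor scales/offsets plus independent
    noise.  Returns the table and the planted ground-truth labels for
    recovery tests.
    """
    if n_clusters > n_ligands:
        raise ValueError("n_clusters must not exceed n_ligands")
    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, center_scale, size=(n_clusters, latent_dim))
    labels = np.sort(rng.integers(0, n_clusters, size=n_ligands))
    # guarantee every cluster is populated
    labels[:n_clusters] = np.arange(n_clusters)
    latent = centers[labels] + rng.normal(0.0, within_scale,
                                          size=(n_ligands, latent_dim))
    lift = rng.normal(0.0, 1.0, size=(latent_dim, n_descriptors))
    col_scale = rng.lognormal(0.0, 1.0, size=n_descriptors)
    col_offset = rng.normal(0.0, 10.0, size=n_descriptors)
    X = latent @ lift
    X = X * col_scale + col_offset
    X = X + rng.normal(0.0, noise_scale, size=X.shape) * col_scale
    table = DescriptorTable(
        ligand_ids=tuple(f"P{i + 1}" for i in range(n_ligands)),
        matrix=X,
        descriptor_names=tuple(f"desc_{j + 1}" for j in range(n_descriptors)),
    )
    return table, labels


def assignments_frame(model: ClusterModel, table: DescriptorTable,
                      representatives: Mapping[int, str | None] | None = None,
                      ) -> pd.DataFrame:
    """Cluster-assignment table (ligand, cluster, pc1..pc_n, is_representative)."""
    reps = set()
    if representatives:
        reps = {r for r in representatives.values() if r is not None}
    n_pc = model.pc_scores.shape[1]
    rows = []
    for i, lig in enumerate(table.ligand_ids):
        row = {"ligand_id": lig, "cluster": model.labels[lig]}
        for j in range(n_pc):
            row[f"pc{j + 1}"] = model.pc_scores[i, j]
        row["is_representative"] = lig in reps
        rows.append(row)
    return pd.DataFrame(rows)
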