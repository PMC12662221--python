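"""Resampled nearest-neighbor similarity between query and reference cell
clusters on a joint PCA embedding.

For a reference cluster Y, the neighbor set is the ``N = 2 |Y|`` non-Y
cells closest (Euclidean) to Y's centroid in the embedding; the similarity
of a query cluster X to Y is the fraction of X's cells found in that
neighbor set.  The statistic is averaged over resampling iterations in
which each query cluster is subsampled and the joint embedding recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


@dataclass
class EmbeddedCellSet:
    """Cells with dataset-of-origin and cluster labels in a shared
    low-dimensional embedding."""

    coords: pd.DataFrame     # cells x components
    dataset: pd.Series       # "query" | "reference" per cell
    cluster: pd.Series       # cluster label per cell

    def __post_init__(self) -> None:
        if not np.isfinite(self.coords.to_numpy()).all():
            raise ValueError("embedding coordinates must be finite")
        if not (self.coords.index.equals(self.dataset.index) and self.coords.index.equals(self.cluster.index)):
            raise ValueError("coords, dataset and cluster must share the same cell index")

    def cells_of(self, dataset: str, cluster: str) -> pd.Index:
        return self.coords.index[(self.dataset == dataset) & (self.cluster == cluster)]


@dataclass
class SimilarityMatrix:
    """Mean query x reference cluster similarity, with per-iteration values."""

    mean: pd.DataFrame                   # query cluster x reference cluster
    per_iteration: pd.DataFrame          # long: iteration, query, reference, similarity

    def to_tsv(self, path) -> None:
        self.mean.to_csv(path, sep="\t", index_label="query_cluster")


def joint_pca(
    expr_query: pd.DataFrame,
    expr_ref: pd.DataFrame,
    labels: pd.DataFrame,
    n_pcs: int = 15,
) -> EmbeddedCellSet:
    """Project both datasets onto a shared PCA space.

    Both matrices (cells x genes) are restricted to common genes,
    log1p-transformed, per-gene centered and unit-scaled on the
    concatenated matrix, and projected onto the top ``n_pcs`` principal
    axes of the concatenation.  Component signs follow a deterministic
    convention: the largest-magnitude loading of each component is made
    positive.  ``labels`` maps every cell to its dataset ("query" or
    "reference") and cluster.
    """
    common = expr_query.columns.intersection(expr_ref.columns)
    if len(common) == 0:
        raise ValueError("no common genes between the datasets")
    if len(expr_query) < 2 or len(expr_ref) < 2:
        raise ValueError("each dataset needs at least two cells")
    n_pcs = min(n_pcs, len(common), len(expr_query) + len(expr_ref) - 1)
    concat = pd.concat([expr_query[common], expr_ref[common]], axis=0)
    logged = np.log1p(concat.to_numpy(dtype=float))
    mu = logged.mean(axis=0)
    sd = logged.std(axis=0)
    sd[sd == 0] = 1.0
    scaled = (logged - mu) / sd
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(scaled)
    # sign convention: largest-|loading| entry positive per component
    for j in range(n_pcs):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] = -coords[:, j]
    coords_df = pd.DataFrame(
        coords, index=concat.index, columns=[f"PC{j+1}" for j in range(n_pcs)]
    )
    lab = labels.loc[concat.index]
    return EmbeddedCellSet(coords_df, lab["dataset"], lab["cluster"])


def cluster_similarity(
    embedding: EmbeddedCellSet,
    query_cluster: str,
    ref_cluster: str,
    neighbor_mode: str = "centroid",
) -> float:
    """Similarity of query cluster X to reference cluster Y in [0, 1].

    With ``neighbor_mode="centroid"`` (default), ``N = 2 |Y|`` and the
    neighbor set of Y is the N non-Y cells with the smallest Euclidean
    distance to Y's centroid (all non-Y cells if fewer than N), ties
    broken by cell order.  With ``neighbor_mode="per_cell"`` the neighbor
    set is instead the union of each Y cell's 2 nearest non-Y cells (the
    same total budget of 2 |Y| neighbor slots, found per cell).  The
    similarity is ``|X & neighbors(Y)| / |X|``.
    """
    x_cells = embedding.cells_of("query", query_cluster)
    y_cells = embedding.cells_of("reference", ref_cluster)
    if len(x_cells) == 0:
        raise ValueError(f"query cluster {query_cluster!r} is empty")
    if len(y_cells) == 0:
        raise ValueError(f"reference cluster {ref_cluster!r} is empty")
    coords = embedding.coords
    non_y = coords.index[~coords.index.isin(y_cells)]
    non_y_arr = coords.loc[non_y].to_numpy()
    if neighbor_mode == "centroid":
        centroid = coords.loc[y_cells].mean(axis=0).to_numpy()
        d = np.linalg.norm(non_y_arr - centroid, axis=1)
        n_neighbors = min(2 * len(y_cells), len(non_y))
        order = np.argsort(d, kind="stable")[:n_neighbors]
        neighbor_set = set(non_y[order])
    elif neighbor_mode == "per_cell":
        neighbor_set = set()
        k = min(2, len(non_y))
        for y in y_cells:
            d = np.linalg.norm(non_y_arr - coords.loc[y].to_numpy(), axis=1)
            order = np.argsort(d, kind="stable")[:k]
            neighbor_set.update(non_y[order])
    else:
        raise ValueError(f"unknown neighbor_mode {neighbor_mode!r}")
    return len(set(x_cells) & neighbor_set) / len(x_cells)


def similarity_all_pairs(embedding: EmbeddedCellSet) -> pd.DataFrame:
    """Query x reference cluster similarity matrix for one embedding."""
    q_clusters = sorted(embedding.cluster[embedding.dataset == "query"].unique())
    r_clusters = sorted(embedding.cluster[embedding.dataset == "reference"].unique())
    out = pd.DataFrame(index=q_clusters, columns=r_clusters, dtype=float)
    for qc in q_clusters:
        for rc in r_clusters:
            out.loc[qc, rc] = cluster_similarity(embedding, qc, rc)
    return out


def resampled_similarity(
    expr_query: pd.DataFrame,
    expr_ref: pd.DataFrame,
    labels: pd.DataFrame,
    n_iter: int = 10,
    sample_per_cluster: int = 50,
    n_pcs: int = 15,
    *,
    seed: int,
) -> SimilarityMatrix:
    """Resampled similarity between all query and reference cluster pairs.

    Each iteration subsamples every query cluster to
    ``min(sample_per_cluster, size)`` cells without replacement, recomputes
    the joint PCA with the full reference, and evaluates
    :func:`cluster_similarity` for every pair; the mean over iterations and
    the per-iteration values are both returned.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if seed is None:
        raise ValueError("a seed is mandatory")
    rng = np.random.default_rng(int(seed))
    q_labels = labels.loc[expr_query.index]
    long_rows = []
    mats = []
    for it in range(n_iter):
        chosen: list[str] = []
        for cluster, members in q_labels.groupby("cluster", sort=True):
            cells = list(members.index)
            k = min(sample_per_cluster, len(cells))
            pick = rng.choice(len(cells), size=k, replace=False)
            chosen.extend(cells[i] for i in sorted(pick))
        sub_q = expr_query.loc[chosen]
        emb = joint_pca(sub_q, expr_ref, labels, n_pcs=n_pcs)
        mat = similarity_all_pairs(emb)
        mats.append(mat)
        for qc in mat.index:
            for rc in mat.columns:
                long_rows.append(
                    {"iteration": it, "query_cluster": qc, "reference_cluster": rc,
                     "similarity": float(mat.loc[qc, rc])}
                )
    mean = sum(mats) / len(mats)
    return SimilarityMatrix(mean, pd.DataFrame(long_rows))
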