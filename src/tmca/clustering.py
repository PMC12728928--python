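"""Unsupervised conformational-state discovery.

The pipeline featurizes each frame as the flattened inter-residue distance
matrices between backbone beads (BB, or Cα at atomistic resolution) spaced
every five residues along the receptor helix and each adaptor chain
(computed per chain, then concatenated), embeds the feature matrix in 2D
with UMAP, and clusters the embedding with HDBSCAN. Outputs are per-frame
state labels (−1 = noise), cluster populations, label-vs-time series and a
medoid representative frame per cluster.

`ConformationalStates` wraps the embed+cluster stages as a scikit-learn
style estimator so the pipeline composes with sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN

from .io_model import Selection, Topology, Trajectory, pairwise_min_image_distance

__all__ = [
    "FeatureMatrix",
    "ConformationalStates",
    "extract_features",
    "embed",
    "cluster",
    "populations_and_timeseries",
    "representative_frame",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """n_frames × n_features inter-bead distances (Å) with provenance."""
    values: np.ndarray
    index: list  # (receptor_residue, adaptor_chain, adaptor_residue) per column
    residue_stride: int


def _helix_beads(top: Topology, sel: Selection, stride: int) -> np.ndarray:
    """One bead per residue (BB or Cα) along a helix selection, subsampled
    every ``stride`` residues starting from the first."""
    idx = np.asarray(sel.indices)
    keep = np.isin(top.atom_names[idx], ("BB", "CA"))
    beads = idx[keep] if keep.any() else idx
    order = np.argsort(top.residue_ids[beads], kind="stable")
    beads = beads[order]
    n_res = len(beads)
    if n_res < stride:
        raise ValueError(f"helix has {n_res} residues, fewer than stride {stride}")
    return beads[::stride]


def extract_features(
    traj: Trajectory, top: Topology,
    receptor_helix: Selection,
    adaptor_helices: tuple[Selection, Selection],
    residue_stride: int = 5,
) -> FeatureMatrix:
    """Flattened receptor×adaptor bead distance matrices, one row per frame,
    adaptor chains computed independently and concatenated."""
    rec = _helix_beads(top, receptor_helix, residue_stride)
    ads = [_helix_beads(top, s, residue_stride) for s in adaptor_helices]
    index = []
    for k, ad in enumerate(ads):
        for i in rec:
            for j in ad:
                index.append((int(top.residue_ids[i]),
                              str(top.chain_ids[j]), int(top.residue_ids[j])))
    rows = np.empty((traj.n_frames, len(index)))
    for t in range(traj.n_frames):
        parts = [
            pairwise_min_image_distance(traj.coordinates[t][rec],
                                        traj.coordinates[t][ad],
                                        traj.box[t]).ravel()
            for ad in ads
        ]
        rows[t] = np.concatenate(parts)
    return FeatureMatrix(values=rows, index=index, residue_stride=residue_stride)


class ConformationalStates(BaseEstimator, ClusterMixin):
    """UMAP embedding followed by HDBSCAN clustering of frame features.

    Parameters
    ----------
    n_neighbors : UMAP neighborhood size (50 for slowly interconverting
        systems, 10 for faster/smaller ones).
    min_dist : UMAP minimum embedding distance.
    min_cluster_size : HDBSCAN minimum cluster membership.
    cluster_selection_epsilon : HDBSCAN flat-cut distance in embedding units.
    random_state : seed; fixing it makes the full pipeline deterministic.

    Attributes (after ``fit``)
    --------------------------
    embedding_ : (n_frames, 2) UMAP coordinates.
    labels_ : per-frame integer state labels, −1 for noise.
    populations_ : dict label -> fraction of frames (noise included).
    representative_frames_ : dict label -> medoid frame index.
    """

    def __init__(self, n_neighbors: int = 50, min_dist: float = 0.1,
                 min_cluster_size: int = 50,
                 cluster_selection_epsilon: float = 2.0,
                 allow_single_cluster: bool = True,
                 random_state: int = 42):
        self.n_neighbors = n_neighbors
        self.min_dist = min_dist
        self.min_cluster_size = min_cluster_size
        self.cluster_selection_epsilon = cluster_selection_epsilon
        self.allow_single_cluster = allow_single_cluster
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X.values if isinstance(X, FeatureMatrix) else X, dtype=float)
        if X.ndim != 2:
            raise ValueError("feature matrix must be 2-D (frames × features)")
        if X.shape[0] <= self.n_neighbors:
            raise ValueError(
                f"need more than n_neighbors={self.n_neighbors} frames, "
                f"got {X.shape[0]}")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains non-finite entries")
        import umap  # deferred: numba compilation is slow at import

        reducer = umap.UMAP(n_components=2, n_neighbors=self.n_neighbors,
                            min_dist=self.min_dist, n_jobs=1,
                            random_state=self.random_state)
        self.embedding_ = np.asarray(reducer.fit_transform(X), dtype=float)
        clusterer = HDBSCAN(min_cluster_size=self.min_cluster_size,
                            cluster_selection_epsilon=self.cluster_selection_epsilon,
                            allow_single_cluster=self.allow_single_cluster,
                            copy=True)
        self.labels_ = clusterer.fit_predict(self.embedding_)
        self.populations_ = populations_and_timeseries(self.labels_)[0]
        self.representative_frames_ = {
            int(lab): representative_frame(self.labels_, self.embedding_, int(lab))
            for lab in np.unique(self.labels_) if lab != -1
        }
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def embed(fm: FeatureMatrix, n_neighbors: int = 50, seed: int = 42,
          min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP embedding of a feature matrix (deterministic given seed)."""
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    if X.shape[0] <= n_neighbors:
        raise ValueError("too few frames for the requested n_neighbors")
    import umap

    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, n_jobs=1, random_state=seed)
    return np.asarray(reducer.fit_transform(X), dtype=float)


def cluster(embedding: np.ndarray, min_cluster_size: int = 50,
            cluster_selection_epsilon: float = 2.0,
            allow_single_cluster: bool = True) -> np.ndarray:
    """HDBSCAN labels on an embedding; −1 marks noise frames.

    ``allow_single_cluster`` lets the hierarchy root be returned, so a
    system sampling one conformational state yields one cluster rather
    than all-noise.
    """
    emb = np.asarray(embedding, dtype=float)
    if not np.all(np.isfinite(emb)):
        raise ValueError("embedding contains non-finite values")
    return HDBSCAN(min_cluster_size=min_cluster_size,
                   cluster_selection_epsilon=cluster_selection_epsilon,
                   allow_single_cluster=allow_single_cluster,
                   copy=True).fit_predict(emb)


def populations_and_timeseries(labels: np.ndarray, times: np.ndarray | None = None
                               ) -> tuple[dict[int, float], np.ndarray]:
    """Cluster population fractions (noise included under label −1) and the
    label-vs-time series in frame order."""
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    pops = {int(u): float(c) / len(labels) for u, c in zip(uniq, counts)}
    series = labels if times is None else np.column_stack([times, labels])
    return pops, series


def representative_frame(labels: np.ndarray, embedding: np.ndarray,
                         label: int | None = None):
    """Medoid frame per cluster: the member minimizing the summed
    embedding-space distance to its co-members (ties → earliest frame)."""
    labels = np.asarray(labels)
    emb = np.asarray(embedding)
    targets = [label] if label is not None else \
        [int(l) for l in np.unique(labels) if l != -1]
    if not targets:
        raise ValueError("no non-noise clusters present")
    out = {}
    for lab in targets:
        members = np.where(labels == lab)[0]
        if len(members) == 0:
            raise ValueError(f"cluster {lab} has no members")
        pts = emb[members]
        dist = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        out[lab] = int(members[np.argmin(dist.sum(axis=1))])
    return out[label] if label is not None else out
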