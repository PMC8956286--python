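"""Clustering of inhibitory response time courses.

Inhibitory input to an On parasol cell mixes a feedforward component
(On-pathway, increment-driven, fast and onset-locked) and a crossover
component (Off-pathway, decrement-driven, larger and delayed).  Responses
to flashed stimuli are separated by their time course alone: traces are
centered on the mean trace, projected onto their first three principal
components, and partitioned with k-means (k = 3).  Cluster indices are then
relabeled deterministically from the reconstructed centroid time courses --
the earliest-peaking centroid is tagged ``feedforward``, the larger of the
remaining two ``crossover``, and the last ``mixed``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = ["ClusterModel", "fit_clusters", "assign", "LABELS"]

LABELS = ("feedforward", "mixed", "crossover")


@dataclass
class ClusterModel:
    """PCA basis + k-means centroids over inhibitory time courses.

    ``pca_basis`` is (n_components, n_time) with orthonormal rows;
    ``centroids`` is (k, n_components) in PC space, ordered so that index i
    carries ``labels[i]``.
    """

    pca_basis: np.ndarray
    pca_mean: np.ndarray
    centroids: np.ndarray
    labels: tuple = LABELS

    @property
    def n_time(self) -> int:
        return self.pca_basis.shape[1]

    def centroid_traces(self) -> np.ndarray:
        """Centroids mapped back to the time domain (k, n_time)."""
        return self.pca_mean + self.centroids @ self.pca_basis

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "pca_basis": self.pca_basis.tolist(),
                "pca_mean": self.pca_mean.tolist(),
                "centroids": self.centroids.tolist(),
                "labels": list(self.labels),
            }, fh)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(np.array(d["pca_basis"]), np.array(d["pca_mean"]),
                   np.array(d["centroids"]), tuple(d["labels"]))


def _relabel_order(centroid_traces: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Deterministic cluster ordering: feedforward, mixed, crossover.

    Feedforward = earliest peak of the reconstructed centroid; of the
    remaining two, crossover = larger peak amplitude, mixed = the other.
    """
    peak_t = np.argmax(centroid_traces, axis=1)
    peak_a = np.max(centroid_traces, axis=1)
    ff = int(np.argmin(peak_t))
    rest = [i for i in range(len(centroid_traces)) if i != ff]
    rest.sort(key=lambda i: peak_a[i])  # smaller -> mixed
    return np.array([ff, rest[0], rest[-1]])


def fit_clusters(
    traces: np.ndarray,
    k: int = 3,
    seed: int = 0,
    restarts: int = 20,
    n_components: int = 3,
) -> tuple:
    """Fit the PCA + k-means model; returns (ClusterModel, assignments).

    ``traces`` is (n_traces, n_time); the input is only the response time
    courses -- no stimulus information enters the clustering.  The best of
    ``restarts`` seeded k-means++ initializations (by within-cluster sum of
    squares) is kept.  Assignments are indices into ``model.labels``.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise ValueError("traces must be (n_traces, n_time)")
    n = len(traces)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of traces ({n})")
    rank = np.linalg.matrix_rank(traces - traces.mean(axis=0))
    n_comp = min(n_components, rank)
    if n_comp < n_components:
        logger.warning("degenerate PCA: rank %d < %d; using %d components",
                       rank, n_components, n_comp)
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(traces)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    raw = km.fit_predict(scores)
    model = ClusterModel(pca_basis=pca.components_, pca_mean=pca.mean_,
                         centroids=km.cluster_centers_)
    if k == 3:
        order = _relabel_order(model.centroid_traces())
        model.centroids = model.centroids[order]
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        raw = remap[raw]
    return model, raw


def assign(model: ClusterModel, new_traces: np.ndarray) -> np.ndarray:
    """Assign held-out traces to the stored clusters (nearest centroid in PC space)."""
    new_traces = np.asarray(new_traces, dtype=float)
    if new_traces.ndim == 1:
        new_traces = new_traces[None, :]
    if new_traces.shape[1] != model.n_time:
        raise ValueError(
            f"trace length {new_traces.shape[1]} does not match training time base {model.n_time}")
    scores = (new_traces - model.pca_mean) @ model.pca_basis.T
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
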