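"""Ensemble-based conformational clustering.

Reference harvesting at a Cα-RMSD cutoff ``r``: (i) a reference frame
is drawn uniformly at random from the remaining conformations and every
conformation within ``r`` of it (including itself) is removed; this is
repeated until the pool is empty, yielding references that are pairwise
at least ``r`` apart; (ii) every analysed frame is assigned to the
reference of minimal RMSD (ties to the lower reference index).

The RNG protocol is fixed so an independent implementation can replay
it: ``numpy.random.default_rng(seed)`` and one ``integers(len(pool))``
draw per harvested reference, in harvesting order.  RMSDs are plain
coordinate RMSDs — the ensemble is expected to be superposed first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ensembles import (AtomSelection, ConformationEnsemble, EnsembleError,
                        write_table)


@dataclass
class ClusterAssignment:
    """Result of one clustering run (cutoff, seed and stride recorded)."""

    reference_frames: np.ndarray        # analysed-frame indices of references
    labels: np.ndarray                  # per analysed frame, cluster id
    rmsd_to_reference: np.ndarray       # per analysed frame, Å
    frame_indices: np.ndarray           # analysed (strided) original frame ids
    reference_coordinates: np.ndarray   # (n_refs, n_sel_atoms, 3)
    r: float
    seed: int
    stride: int = 1

    @property
    def n_clusters(self) -> int:
        return int(self.reference_frames.size)

    @property
    def populations(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters)

    def write(self, path) -> None:
        write_table(pd.DataFrame({
            "frame": self.frame_indices,
            "cluster_id": self.labels,
            "rmsd_to_reference": self.rmsd_to_reference}), path)


def _pairwise_rmsd_to(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean(np.sum((coords - ref) ** 2, axis=2), axis=1))


class EnsembleClustering(BaseEstimator):
    """Scikit-learn style estimator for reference-harvesting clustering.

    Parameters
    ----------
    r : float
        RMSD cutoff in Å (references end up pairwise ≥ r apart).
    stride : int
        Analyse every ``stride``-th frame (the conventional choice is a
        100 ps-equivalent spacing).
    random_state : int
        Seed of the documented RNG protocol.
    selection : AtomSelection or None
        Atoms used for RMSD; default Cα.

    Attributes (after ``fit``)
    --------------------------
    reference_indices_, labels_, rmsd_, populations_, n_clusters_,
    assignment_ (the full :class:`ClusterAssignment`).
    """

    def __init__(self, r: float = 4.0, stride: int = 1, random_state: int = 0,
                 selection: AtomSelection | None = None):
        self.r = r
        self.stride = stride
        self.random_state = random_state
        self.selection = selection

    def _coords(self, X) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(X, ConformationEnsemble):
            sel = self.selection if self.selection is not None \
                else X.topology.ca_selection()
            coords = X.coordinates[:, sel.indices, :]
        else:
            coords = np.asarray(X, dtype=float)
            if coords.ndim != 3:
                raise EnsembleError("expected ensemble or (frames, atoms, 3) array")
        frame_idx = np.arange(0, coords.shape[0], self.stride)
        return coords[frame_idx], frame_idx

    def fit(self, X, y=None) -> "EnsembleClustering":
        if self.r <= 0:
            raise EnsembleError("cutoff r must be > 0")
        coords, frame_idx = self._coords(X)
        n = coords.shape[0]
        if n == 0:
            raise EnsembleError("no frames to cluster")
        rng = np.random.default_rng(self.random_state)
        pool = list(range(n))
        references: list[int] = []
        while pool:
            pick = int(rng.integers(len(pool)))
            ref = pool[pick]
            references.append(ref)
            d = _pairwise_rmsd_to(coords[pool], coords[ref])
            pool = [p for p, dist in zip(pool, d) if dist >= self.r]
        refs = np.array(references)
        d_all = np.stack([_pairwise_rmsd_to(coords, coords[ref]) for ref in refs],
                         axis=1)
        labels = np.argmin(d_all, axis=1)       # argmin ties → lower index
        self.assignment_ = ClusterAssignment(
            reference_frames=refs,
            labels=labels,
            rmsd_to_reference=d_all[np.arange(n), labels],
            frame_indices=frame_idx,
            reference_coordinates=coords[refs].copy(),
            r=float(self.r), seed=int(self.random_state), stride=int(self.stride))
        self.reference_indices_ = refs
        self.labels_ = labels
        self.rmsd_ = self.assignment_.rmsd_to_reference
        self.populations_ = self.assignment_.populations
        self.n_clusters_ = self.assignment_.n_clusters
        return self

    def predict(self, X) -> np.ndarray:
        """Assign new frames (same selection) to the fitted references."""
        coords, _ = self._coords(X)
        d = np.stack([_pairwise_rmsd_to(coords, ref)
                      for ref in self.assignment_.reference_coordinates], axis=1)
        return np.argmin(d, axis=1)

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def cluster_ensemble(ensemble, r: float, seed: int = 0, stride: int = 1,
                     selection: AtomSelection | None = None) -> ClusterAssignment:
    """Functional wrapper over :class:`EnsembleClustering`."""
    est = EnsembleClustering(r=r, stride=stride, random_state=seed,
                             selection=selection)
    return est.fit(ensemble).assignment_


def compare_clusterings(a: ClusterAssignment, b: ClusterAssignment) -> dict:
    """Overlap summary of two assignments.

    Returns cluster counts, the minimal cross-assignment reference RMSD
    matrix, and — when both assignments cover the same frames — the
    co-membership agreement (Rand index, as a percentage).
    """
    if a.reference_coordinates.shape[1:] != b.reference_coordinates.shape[1:]:
        raise EnsembleError("assignments built on different atom selections")
    cross = np.zeros((a.n_clusters, b.n_clusters))
    for i, ra in enumerate(a.reference_coordinates):
        cross[i] = _pairwise_rmsd_to(b.reference_coordinates, ra)
    out = {
        "n_clusters_a": a.n_clusters,
        "n_clusters_b": b.n_clusters,
        "min_cross_reference_rmsd": cross,
    }
    if a.labels.size == b.labels.size and np.array_equal(a.frame_indices,
                                                         b.frame_indices):
        la, lb = a.labels, b.labels
        same_a = la[:, None] == la[None, :]
        same_b = lb[:, None] == lb[None, :]
        n = la.size
        iu = np.triu_indices(n, 1)
        agree = np.mean(same_a[iu] == same_b[iu]) if n > 1 else 1.0
        out["overlap_percent"] = 100.0 * float(agree)
    return out
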