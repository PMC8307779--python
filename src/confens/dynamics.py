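"""Per-residue Markov modelling of secondary-structure dynamics and
information-geometric comparison of replicas.

Each residue's frame-to-frame 8-state sequence is summarised by an
8×8 row-stochastic transition matrix (rows smoothed with a pseudo-count
so rarely-visited states stay well defined).  Two replicas are compared
with the Fisher–Rao geodesic distance between corresponding transition
rows — for categorical distributions d(p, q) = 2·arccos Σ√(pₛqₛ), the
Bhattacharyya angle — aggregated occupancy-weighted over rows and
uniformly over residues.  Classical (Torgerson) multidimensional
scaling embeds the replica distance matrix in the plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .ensembles import EnsembleError, write_table
from .secondary_structure import SS_STATES, SecondaryStructureTrack

N_STATES = len(SS_STATES)


@dataclass
class TransitionMatrixSet:
    """One 8×8 row-stochastic matrix per residue (state order H,G,I,E,B,T,S,C)."""

    matrices: np.ndarray       # (n_res, 8, 8)
    occupancy: np.ndarray      # (n_res, 8) source-state counts (unsmoothed)
    label: str = ""
    alpha: float = 0.5
    lag: int = 1

    def __post_init__(self):
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1:] != (N_STATES, N_STATES):
            raise EnsembleError("matrices must have shape (n_res, 8, 8)")
        rowsum = m.sum(axis=2)
        if np.any(np.abs(rowsum - 1.0) > 1e-9) or np.any(m < 0):
            raise EnsembleError("transition rows must be stochastic")
        self.matrices = m
        self.occupancy = np.asarray(self.occupancy, dtype=float)

    @property
    def n_residues(self) -> int:
        return int(self.matrices.shape[0])


@dataclass
class ReplicaDistanceMatrix:
    """Symmetric Fisher–Rao distances between replicas."""

    distances: np.ndarray
    labels: list[str]
    groups: list[str] | None = None

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise EnsembleError("distance matrix must be square")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
            raise EnsembleError("distance matrix must be symmetric, "
                                "non-negative, zero-diagonal")
        self.distances = d

    def write(self, path) -> None:
        df = pd.DataFrame(self.distances, columns=self.labels)
        df.insert(0, "replica", self.labels)
        write_table(df, path)


class TransitionMatrixEstimator(BaseEstimator):
    """Estimate per-residue transition matrices from a state track.

    Consecutive-frame (or ``lag``-separated) state pairs are counted per
    residue; ``alpha`` (default 0.5, the Jeffreys pseudo-count) is added
    to every cell before row normalisation, so never-visited source
    states yield uniform rows instead of divisions by zero.
    """

    def __init__(self, alpha: float = 0.5, lag: int = 1):
        self.alpha = alpha
        self.lag = lag

    def fit(self, X: SecondaryStructureTrack, y=None) -> "TransitionMatrixEstimator":
        if X.n_frames < self.lag + 1:
            raise EnsembleError("need at least lag+1 frames to count transitions")
        codes = X.state_codes()
        src = codes[:-self.lag]
        dst = codes[self.lag:]
        n_res = X.n_residues
        counts = np.zeros((n_res, N_STATES, N_STATES))
        flat = src.astype(np.int64) * N_STATES + dst
        for r in range(n_res):
            counts[r] = np.bincount(flat[:, r], minlength=N_STATES ** 2
                                    ).reshape(N_STATES, N_STATES)
        occupancy = counts.sum(axis=2)
        smoothed = counts + self.alpha
        rowsum = smoothed.sum(axis=2, keepdims=True)
        if self.alpha == 0:
            # unsmoothed: unoccupied rows fall back to the identity row
            with np.errstate(invalid="ignore", divide="ignore"):
                mat = smoothed / rowsum
            for r in range(n_res):
                for s in range(N_STATES):
                    if occupancy[r, s] == 0:
                        mat[r, s] = 0.0
                        mat[r, s, s] = 1.0
        else:
            mat = smoothed / rowsum
        self.set_ = TransitionMatrixSet(mat, occupancy, label=X.label,
                                        alpha=self.alpha, lag=self.lag)
        self.matrices_ = self.set_.matrices
        self.occupancy_ = self.set_.occupancy
        return self


def transition_matrices(track: SecondaryStructureTrack, alpha: float = 0.5,
                        lag: int = 1) -> TransitionMatrixSet:
    """Functional wrapper over :class:`TransitionMatrixEstimator`."""
    return TransitionMatrixEstimator(alpha=alpha, lag=lag).fit(track).set_


def _row_fisher_rao(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Fisher–Rao geodesic between categorical rows: 2·arccos Σ√(pq).

    Identical rows are snapped to exactly 0 (arccos would otherwise
    leave ~1e-8 floating-point residue on the unit Bhattacharyya
    coefficient).
    """
    bc = np.sum(np.sqrt(p * q), axis=-1)
    d = 2.0 * np.arccos(np.clip(bc, -1.0, 1.0))
    d[np.all(p == q, axis=-1)] = 0.0
    return d


def fisher_rao_distance(a: TransitionMatrixSet, b: TransitionMatrixSet) -> float:
    """Aggregate Fisher–Rao distance between two replicas' Markov models.

    Row geodesics are averaged per residue weighted by the combined row
    occupancy (rarely-visited source states carry little information),
    then uniformly over residues.  Symmetric; 0 for identical sets;
    each row distance — and hence the aggregate — is bounded by π.
    """
    if a.n_residues != b.n_residues:
        raise EnsembleError(
            f"residue-count mismatch: {a.n_residues} vs {b.n_residues}")
    d_rows = _row_fisher_rao(a.matrices, b.matrices)      # (n_res, 8)
    w = a.occupancy + b.occupancy
    per_res = np.zeros(a.n_residues)
    wsum = w.sum(axis=1)
    active = wsum > 0
    per_res[active] = np.sum(d_rows * w, axis=1)[active] / wsum[active]
    return float(per_res.mean())


def replica_distance_matrix(sets: list[TransitionMatrixSet],
                            groups: list[str] | None = None
                            ) -> ReplicaDistanceMatrix:
    """Pairwise Fisher–Rao distances between all replicas."""
    if len(sets) < 2:
        raise EnsembleError("need at least 2 replicas")
    n = len(sets)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fisher_rao_distance(sets[i], sets[j])
    labels = [s.label or f"replica{i + 1}" for i, s in enumerate(sets)]
    return ReplicaDistanceMatrix(D, labels, groups)


class ClassicalMDS(BaseEstimator):
    """Classical (Torgerson) metric multidimensional scaling.

    Double-centers the squared distance matrix, B = −½·J·D²·J, and
    embeds with the top eigenpairs; negative eigenvalues (non-Euclidean
    residue of the distances) are clipped to zero.  Deterministic and
    eigen-based — an 'as isometric as possible' planar layout.

    Attributes: ``embedding_`` (n, dims), ``eigenvalues_`` (descending),
    ``stress_`` (relative Frobenius distance-reconstruction error).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, D, y=None) -> "ClassicalMDS":
        if isinstance(D, ReplicaDistanceMatrix):
            self.labels_ = D.labels
            D = D.distances
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise EnsembleError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise EnsembleError("distance matrix must be symmetric")
        n = D.shape[0]
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        evals, evecs = np.linalg.eigh(B)
        order = np.argsort(evals)[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        dims = min(self.n_components, n)
        lam = np.clip(evals[:dims], 0.0, None)
        self.embedding_ = evecs[:, :dims] * np.sqrt(lam)
        self.eigenvalues_ = evals
        diff = self.embedding_[:, None, :] - self.embedding_[None, :, :]
        D_hat = np.linalg.norm(diff, axis=2)
        denom = np.linalg.norm(D)
        self.stress_ = float(np.linalg.norm(D_hat - D) / denom) if denom > 0 else 0.0
        return self

    def fit_transform(self, D, y=None) -> np.ndarray:
        return self.fit(D).embedding_


def classical_mds(d: ReplicaDistanceMatrix | np.ndarray, dims: int = 2
                  ) -> ClassicalMDS:
    """Functional wrapper over :class:`ClassicalMDS`."""
    return ClassicalMDS(n_components=dims).fit(d)
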