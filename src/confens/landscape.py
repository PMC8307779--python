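"""First-principles free-energy landscapes over reaction-coordinate pairs.

The relative Gibbs free energy of the sampled canonical ensemble is
ΔG(R1, R2) = −kB·T·ln(P(R1, R2) / Pmax), with the probability density P
estimated by a k-nearest-neighbour scheme in the per-axis standardised
(z-scored) plane: density_i = k / (N · π · d_{i,k}²).  Standardisation
makes the estimate well-behaved when the two coordinates have
incommensurate units (Å, %, Å²); ΔG differences are invariant under any
affine rescaling of either raw coordinate.

Wells (metastable conformational states) are local minima of the grid
under 8-neighbour connectivity; shallow minima are merged into deeper
neighbours when the barrier between them is below a persistence
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator

from .ensembles import EnsembleError, write_table

#: Boltzmann constant in kcal mol⁻¹ K⁻¹.
KB_KCAL = 0.0019872041


@dataclass
class ReactionCoordinatePair:
    """Two per-frame reaction coordinates in native units."""

    names: tuple[str, str]
    values: np.ndarray            # (n_frames, 2)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise EnsembleError("reaction coordinates must have shape (frames, 2)")
        if not np.all(np.isfinite(v)):
            raise EnsembleError("reaction coordinates must be finite")
        self.values = v


@dataclass
class Well:
    """A free-energy minimum; rank 1 is the global well (depth 0)."""

    rank: int
    location: tuple[float, float]        # native units
    location_std: tuple[float, float]
    depth: float                         # kcal/mol above the global minimum
    grid_cell: tuple[int, int]
    basin_id: int
    population: int = 0


def knn_density(points: np.ndarray, k: int) -> np.ndarray:
    """kNN density of each sample point among its peers.

    ``density_i = k / (N · π · d_{i,k}²)`` with ``d_{i,k}`` the distance
    to the k-th nearest *other* point.  Points are used as given (they
    should already be standardised).  Duplicate points with a zero k-th
    neighbour distance get a capped density and trigger a warning.
    """
    pts = np.asarray(points, dtype=float)
    n = pts.shape[0]
    if k < 1 or k >= n:
        raise EnsembleError(f"k must be in [1, N-1], got k={k}, N={n}")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k + 1)
    dk = d[:, k]
    zero = dk <= 0
    if np.any(zero):
        warnings.warn(f"{int(zero.sum())} duplicate points: density capped")
        positive = dk[~zero]
        dk = dk.copy()
        dk[zero] = positive.min() if positive.size else 1e-12
    return k / (n * np.pi * dk ** 2)


class FreeEnergyLandscape(BaseEstimator):
    """kNN-density free-energy landscape over a 2D reaction-coordinate pair.

    Parameters
    ----------
    temperature : float
        Simulation temperature in K (default 310 K).
    k : int or None
        Neighbour count for the density estimate; default ⌈√N⌉.
    grid_size : (int, int)
        Landscape grid resolution over the data bounding box.
    pad : float
        Fractional bounding-box padding per axis.
    min_well_depth : float
        Persistence threshold (kcal/mol) below which a shallow minimum
        is merged into its deeper neighbour.

    Attributes (after ``fit``)
    --------------------------
    delta_g_ : (ny, nx) grid, NaN where unsampled; delta_g_full_ the
    same without the support mask; wells_ ranked by depth; basins_ the
    per-cell basin label; grid_x_/grid_y_ native axes.
    """

    def __init__(self, temperature: float = 310.0, k: int | None = None,
                 grid_size: tuple[int, int] = (100, 100), pad: float = 0.05,
                 min_well_depth: float = 0.5, kB: float = KB_KCAL):
        self.temperature = temperature
        self.k = k
        self.grid_size = grid_size
        self.pad = pad
        self.min_well_depth = min_well_depth
        self.kB = kB

    # -- helpers ----------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.std_

    def _density_at(self, Z: np.ndarray) -> np.ndarray:
        d, _ = self.tree_.query(Z, k=self.k_)
        dk = d[:, -1] if d.ndim > 1 else d
        dk = np.maximum(dk, 1e-12)
        return self.k_ / (self.n_samples_ * np.pi * dk ** 2)

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None) -> "FreeEnergyLandscape":
        if isinstance(X, ReactionCoordinatePair):
            self.names_ = X.names
            X = X.values
        else:
            self.names_ = ("R1", "R2")
        X = np.asarray(X, dtype=float)
        if self.temperature <= 0:
            raise EnsembleError("temperature must be > 0")
        n = X.shape[0]
        k = int(np.ceil(np.sqrt(n))) if self.k is None else int(self.k)
        if k >= n:
            raise EnsembleError(f"k={k} must be < N={n}")
        self.n_samples_ = n
        self.k_ = k
        self.X_ = X
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0)
        self.std_[self.std_ == 0] = 1.0
        Z = self._standardize(X)
        self.Z_ = Z
        self.tree_ = cKDTree(Z)

        nx, ny = self.grid_size
        lo = Z.min(axis=0)
        hi = Z.max(axis=0)
        span = hi - lo
        lo = lo - self.pad * span
        hi = hi + self.pad * span
        gx = np.linspace(lo[0], hi[0], nx)
        gy = np.linspace(lo[1], hi[1], ny)
        self.grid_x_std_, self.grid_y_std_ = gx, gy
        self.grid_x_ = gx * self.std_[0] + self.mean_[0]
        self.grid_y_ = gy * self.std_[1] + self.mean_[1]
        GX, GY = np.meshgrid(gx, gy)               # (ny, nx)
        nodes = np.column_stack([GX.ravel(), GY.ravel()])
        dens = self._density_at(nodes).reshape(ny, nx)
        self.p_max_ = float(dens.max())
        kBT = self.kB * self.temperature
        self.kBT_ = kBT
        dg = -kBT * np.log(dens / self.p_max_)
        self.delta_g_full_ = dg

        # support: cells that actually contain samples
        ix = np.clip(np.searchsorted(gx, Z[:, 0]) - 1, 0, nx - 2)
        iy = np.clip(np.searchsorted(gy, Z[:, 1]) - 1, 0, ny - 2)
        support = np.zeros((ny, nx), dtype=bool)
        support[iy, ix] = True
        support[iy + 1, ix] = True
        support[iy, ix + 1] = True
        support[iy + 1, ix + 1] = True
        self.support_ = support
        dg_masked = dg.copy()
        dg_masked[~support] = np.nan
        self.delta_g_ = dg_masked

        self.basins_, self.wells_ = self._find_wells(dg, self.min_well_depth)
        self.frame_cells_ = (iy, ix)
        self._assign_populations()
        return self

    def _find_wells(self, dg: np.ndarray, min_depth: float):
        """Persistence watershed over the full grid (8-connectivity)."""
        ny, nx = dg.shape
        order = np.argsort(dg, axis=None)
        basin = -np.ones(dg.size, dtype=int)
        parent: list[int] = []
        basin_min: list[float] = []
        basin_argmin: list[int] = []

        def find(b):
            while parent[b] != b:
                parent[b] = parent[parent[b]]
                b = parent[b]
            return b

        neigh_off = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]
        for flat in order:
            iy, ix = divmod(int(flat), nx)
            roots = set()
            for dy, dx in neigh_off:
                y2, x2 = iy + dy, ix + dx
                if 0 <= y2 < ny and 0 <= x2 < nx and basin[y2 * nx + x2] >= 0:
                    roots.add(find(basin[y2 * nx + x2]))
            if not roots:
                b = len(parent)
                parent.append(b)
                basin_min.append(float(dg[iy, ix]))
                basin_argmin.append(int(flat))
                basin[flat] = b
                continue
            deepest = min(roots, key=lambda b: basin_min[b])
            basin[flat] = deepest
            for b in roots:
                if b == deepest:
                    continue
                persistence = float(dg[iy, ix]) - basin_min[b]
                if persistence < min_depth:
                    parent[b] = deepest
        # resolve final labels
        final = np.array([find(b) for b in basin]).reshape(ny, nx)
        roots = sorted(set(final.ravel().tolist()), key=lambda b: basin_min[b])
        relabel = {b: i for i, b in enumerate(roots)}
        basins = np.vectorize(relabel.get)(final)
        wells = []
        for rank, b in enumerate(roots, start=1):
            flat = basin_argmin[b]
            iy, ix = divmod(flat, nx)
            wells.append(Well(
                rank=rank,
                location=(float(self.grid_x_[ix]), float(self.grid_y_[iy])),
                location_std=(float(self.grid_x_std_[ix]),
                              float(self.grid_y_std_[iy])),
                depth=basin_min[b] - basin_min[roots[0]],
                grid_cell=(int(iy), int(ix)),
                basin_id=relabel[b]))
        return basins, wells

    def _assign_populations(self) -> None:
        iy, ix = self.frame_cells_
        labels = self.basins_[iy, ix]
        self.frame_basins_ = labels
        for w in self.wells_:
            w.population = int(np.sum(labels == w.basin_id))

    # -- queries ----------------------------------------------------------

    def delta_g_at(self, points) -> np.ndarray:
        """ΔG (kcal/mol) of arbitrary native-unit coordinate pairs."""
        Z = self._standardize(np.atleast_2d(np.asarray(points, dtype=float)))
        dens = self._density_at(Z)
        return -self.kBT_ * np.log(dens / self.p_max_)

    def well_members(self, well: Well | None = None) -> np.ndarray:
        """Indices of fitted frames falling in a well's basin (default:
        the global well)."""
        if well is None:
            well = self.wells_[0]
        return np.flatnonzero(self.frame_basins_ == well.basin_id)

    def representative_frame(self, well: Well | None = None) -> int:
        """Fitted frame nearest the well minimum in standardised space."""
        if well is None:
            well = self.wells_[0]
        members = self.well_members(well)
        if members.size == 0:
            raise EnsembleError("well basin contains no frames")
        target = np.array(well.location_std)
        d = np.linalg.norm(self.Z_[members] - target, axis=1)
        return int(members[np.argmin(d)])

    def write(self, path) -> None:
        ny, nx = self.delta_g_.shape
        rows = []
        for iy in range(ny):
            for ix in range(nx):
                v = self.delta_g_[iy, ix]
                if np.isfinite(v):
                    rows.append((self.grid_x_[ix], self.grid_y_[iy], v))
        write_table(pd.DataFrame(rows, columns=[self.names_[0], self.names_[1],
                                                "delta_g"]), path)

    def write_wells(self, path) -> None:
        write_table(pd.DataFrame(
            [(w.rank, w.location[0], w.location[1], w.depth, w.population)
             for w in self.wells_],
            columns=["rank", self.names_[0], self.names_[1], "depth",
                     "population"]), path)


def free_energy_landscape(rc, temperature: float = 310.0, k: int | None = None,
                          grid_resolution: tuple[int, int] = (100, 100),
                          min_well_depth: float = 0.5) -> FreeEnergyLandscape:
    """Functional wrapper: fit a landscape on a reaction-coordinate pair."""
    fel = FreeEnergyLandscape(temperature=temperature, k=k,
                              grid_size=grid_resolution,
                              min_well_depth=min_well_depth)
    return fel.fit(rc)


def find_wells(fel: FreeEnergyLandscape, min_depth: float | None = None
               ) -> list[Well]:
    """Wells of a fitted landscape, optionally at a different persistence
    threshold (recomputed without re-estimating densities)."""
    if min_depth is None or min_depth == fel.min_well_depth:
        return fel.wells_
    basins, wells = fel._find_wells(fel.delta_g_full_, min_depth)
    fel.basins_ = basins
    fel.wells_ = wells
    fel._assign_populations()
    return wells


def deepest_well_members(fel: FreeEnergyLandscape, ensemble=None
                         ) -> tuple[np.ndarray, int]:
    """Frames in the global well's basin and the representative frame
    (nearest the minimum in standardised coordinates)."""
    members = fel.well_members()
    if members.size == 0:
        raise EnsembleError("empty basin for the global well")
    rep = fel.representative_frame()
    return members, rep
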