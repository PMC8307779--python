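"""Per-frame and per-residue structural descriptors.

These are the reaction-coordinate building blocks of the ensemble
analysis: RMSD/RMSF against the initial conformation, radius of
gyration (mass-weighted or Cα-unweighted), solvent-accessible surface
area by sphere sampling, phosphosite distance geometry, compactness
classes and normalised probability distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensembles import (AtomSelection, ConformationEnsemble, EnsembleError,
                        write_table)

#: van der Waals radii (Å) used for surface-area sampling.
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}


@dataclass
class DescriptorSeries:
    """One scalar per frame (Å for RMSD/Rg, Å² for SASA, % for Hfp)."""

    name: str
    values: np.ndarray
    units: str = ""
    label: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise EnsembleError(f"{self.name}: non-finite descriptor values")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frame": np.arange(self.values.size),
                             self.name: self.values})

    def write(self, path) -> None:
        write_table(self.to_frame(), path)


@dataclass
class ResidueProfile:
    """One non-negative value per residue (e.g. RMSF in Å)."""

    name: str
    residue_numbers: np.ndarray
    values: np.ndarray
    warning: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if self.values.size != self.residue_numbers.size:
            raise EnsembleError("profile length must equal residue count")
        if np.any(self.values < -1e-12):
            raise EnsembleError("profile values must be >= 0")

    def write(self, path) -> None:
        write_table(pd.DataFrame({"residue_number": self.residue_numbers,
                                  self.name: self.values}), path)


@dataclass
class DistanceGeometry:
    """Per-frame pairwise Cα distances between a small set of node residues.

    Edge order is lexicographic by residue-number pair, so a 4-node
    tyrosine tetrahedron yields 6 edge series.
    """

    node_residues: np.ndarray
    edges: list[tuple[int, int]]
    distances: np.ndarray          # (n_frames, n_edges), Å

    def write(self, path) -> None:
        cols = {f"d_{i}_{j}": self.distances[:, k]
                for k, (i, j) in enumerate(self.edges)}
        df = pd.DataFrame({"frame": np.arange(self.distances.shape[0]), **cols})
        write_table(df, path)


@dataclass
class Histogram:
    """Normalised histogram: contiguous bins, probabilities summing to 1."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise EnsembleError("histogram probabilities must sum to 1")
        self.probabilities = p
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peaks(self) -> list[tuple[float, float]]:
        """Local maxima as (location, probability), ordered by mass."""
        p = self.probabilities
        c = self.bin_centers
        out = []
        for i in range(p.size):
            left = p[i - 1] if i > 0 else -np.inf
            right = p[i + 1] if i < p.size - 1 else -np.inf
            if p[i] > 0 and p[i] >= left and p[i] > right:
                out.append((float(c[i]), float(p[i])))
        out.sort(key=lambda t: -t[1])
        return out

    def write(self, path) -> None:
        write_table(pd.DataFrame({"bin_left": self.bin_edges[:-1],
                                  "bin_right": self.bin_edges[1:],
                                  "probability": self.probabilities}), path)


# ---------------------------------------------------------------------------


def _resolve_selection(ensemble, selection) -> AtomSelection:
    sel = ensemble.topology.ca_selection() if selection is None else selection
    if len(sel) == 0:
        raise EnsembleError("empty atom selection")
    return sel


def rmsd_series(ensemble: ConformationEnsemble, reference_frame: int = 0,
                selection: AtomSelection | None = None) -> DescriptorSeries:
    """Per-frame RMSD (Å) of the selection to a reference frame.

    No re-fitting is performed here: the ensemble is expected to be
    superposed already, matching the convention of computing RMSD after
    least-squares fitting on the initial conformation.
    """
    sel = _resolve_selection(ensemble, selection)
    xyz = ensemble.coordinates[:, sel.indices, :]
    ref = ensemble.coordinates[reference_frame, sel.indices, :]
    d2 = np.sum((xyz - ref) ** 2, axis=2)
    return DescriptorSeries("rmsd", np.sqrt(d2.mean(axis=1)), "A", ensemble.label)


def rmsf_per_residue(ensemble: ConformationEnsemble,
                     selection: AtomSelection | None = None,
                     mode: str = "about_mean",
                     reference_frame: int = 0) -> ResidueProfile:
    """Per-residue Cα fluctuation (Å).

    ``about_mean`` (the conventional RMSF) measures fluctuation about
    the time-averaged position; ``about_reference`` measures it about a
    fixed reference frame.
    """
    if mode not in ("about_mean", "about_reference"):
        raise EnsembleError(f"unknown RMSF mode {mode!r}")
    sel = _resolve_selection(ensemble, selection)
    xyz = ensemble.coordinates[:, sel.indices, :]
    warning = None
    if mode == "about_mean":
        if ensemble.n_frames < 2:
            warning = "single-frame ensemble: RMSF about the mean is identically zero"
        center = xyz.mean(axis=0)
    else:
        center = ensemble.coordinates[reference_frame, sel.indices, :]
    msf_atom = np.mean(np.sum((xyz - center) ** 2, axis=2), axis=0)
    res_of_atom = ensemble.topology.atom_residue_index[sel.indices]
    res_ids = np.unique(res_of_atom)
    msf_res = np.array([msf_atom[res_of_atom == r].mean() for r in res_ids])
    return ResidueProfile("rmsf", ensemble.topology.residue_numbers[res_ids],
                          np.sqrt(msf_res), warning=warning)


def radius_of_gyration(ensemble: ConformationEnsemble,
                       selection: AtomSelection | None = None,
                       mass_weighted: bool = False) -> DescriptorSeries:
    """Per-frame radius of gyration Rg = sqrt(Σ mᵢ rᵢ² / Σ mᵢ) in Å.

    rᵢ is each selected atom's distance from the selection's centre of
    mass.  The unweighted mode (mᵢ = 1, the default) matches the
    Cα-only convention used for landscape reaction coordinates; the
    mass-weighted mode implements the textbook definition.
    """
    sel = _resolve_selection(ensemble, selection)
    xyz = ensemble.coordinates[:, sel.indices, :]
    m = ensemble.topology.masses[sel.indices] if mass_weighted else np.ones(len(sel))
    M = m.sum()
    if M <= 0:
        raise EnsembleError("zero total mass in selection")
    com = np.einsum("fas,a->fs", xyz, m) / M
    r2 = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt(np.einsum("fa,a->f", r2, m) / M)
    return DescriptorSeries("rg", rg, "A", ensemble.label)


def _sphere_points(n: int) -> np.ndarray:
    """Fibonacci-spiral quasi-uniform points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(ensemble: ConformationEnsemble, probe_radius: float = 1.4,
         n_sphere_points: int = 960, radii: dict | None = None,
         selection: AtomSelection | None = None) -> DescriptorSeries:
    """Per-frame total solvent-accessible surface area (Å²).

    Shrake–Rupley sphere sampling: each atom's solvent-expanded sphere
    (vdW radius + probe) carries ``n_sphere_points`` quasi-uniform test
    points; the accessible area is the fraction of points not buried
    inside any neighbour's expanded sphere.
    """
    radii = dict(VDW_RADII if radii is None else radii)
    if selection is None:
        selection = ensemble.topology.select()        # all atoms
    idx = selection.indices
    elements = np.char.upper(ensemble.topology.elements[idx])
    missing = sorted(set(elements) - {e.upper() for e in radii})
    if missing:
        bad = np.flatnonzero(np.isin(elements, missing))[0]
        raise EnsembleError(
            f"no vdW radius configured for element {elements[bad]!r} "
            f"(atom {ensemble.topology.atom_names[idx[bad]]})")
    rad = np.array([radii[e.upper()] for e in elements]) + probe_radius
    unit = _sphere_points(n_sphere_points)
    areas = np.empty(ensemble.n_frames)
    for f in range(ensemble.n_frames):
        xyz = ensemble.coordinates[f, idx, :]
        tree = cKDTree(xyz)
        max_reach = 2.0 * rad.max()
        total = 0.0
        for a in range(xyz.shape[0]):
            pts = xyz[a] + rad[a] * unit
            nb = tree.query_ball_point(xyz[a], rad[a] + rad.max())
            nb = [j for j in nb if j != a
                  and np.linalg.norm(xyz[j] - xyz[a]) < rad[a] + rad[j]]
            if nb:
                d = np.linalg.norm(pts[:, None, :] - xyz[nb][None, :, :], axis=2)
                exposed = np.all(d >= rad[nb][None, :], axis=1)
                frac = exposed.mean()
            else:
                frac = 1.0
            total += frac * 4.0 * np.pi * rad[a] ** 2
        areas[f] = total
    return DescriptorSeries("sasa", areas, "A^2", ensemble.label)


#: Rg compactness classes (Å), closed intervals as reported for ensemble
#: mean values; values falling in the print gaps are assigned to the
#: nearest bin by midpoint so every in-range Rg gets a label.
COMPACTNESS_BINS = {
    "compact": (11.2, 11.6),
    "semi-compact": (11.7, 12.2),
    "loose": (12.3, 12.8),
}


def classify_compactness(rg: float, bins: dict | None = None) -> str:
    """Compactness class for an Rg value (Å): compact / semi-compact /
    loose, or ``out-of-range`` beyond the configured bins."""
    if rg < 0:
        raise EnsembleError("Rg must be >= 0")
    bins = COMPACTNESS_BINS if bins is None else bins
    items = sorted(bins.items(), key=lambda kv: kv[1][0])
    lo_all, hi_all = items[0][1][0], items[-1][1][1]
    if rg < lo_all or rg > hi_all:
        return "out-of-range"
    for label, (lo, hi) in items:
        if lo <= rg <= hi:
            return label
    # gap between printed bins: nearest bin by midpoint of the gap
    for (l1, (lo1, hi1)), (l2, (lo2, hi2)) in zip(items, items[1:]):
        if hi1 < rg < lo2:
            return l1 if (rg - hi1) <= (lo2 - rg) else l2
    return "out-of-range"


def distance_geometry(ensemble: ConformationEnsemble,
                      node_residues) -> DistanceGeometry:
    """Per-frame Cα–Cα distances between node residues (Å).

    Used for the phosphotyrosine tetrahedron (Y703/Y721/Y730/Y747) and
    the rigid-residue triangle; n nodes yield n(n−1)/2 edge series in
    lexicographic residue-pair order.
    """
    nodes = np.asarray(sorted(np.atleast_1d(node_residues).tolist()), dtype=int)
    idx = [ensemble.topology.atom_index(r, "CA") for r in nodes]
    xyz = ensemble.coordinates[:, idx, :]
    edges = list(combinations(range(nodes.size), 2))
    d = np.stack([np.linalg.norm(xyz[:, i] - xyz[:, j], axis=1)
                  for i, j in edges], axis=1)
    return DistanceGeometry(nodes, [(int(nodes[i]), int(nodes[j])) for i, j in edges], d)


def probability_distribution(series: DescriptorSeries,
                             bin_width: float) -> Histogram:
    """Normalised histogram of a descriptor series with fixed bin width."""
    if bin_width <= 0:
        raise EnsembleError("bin width must be positive")
    v = series.values
    if v.size == 0:
        raise EnsembleError("empty series")
    lo = np.floor(v.min() / bin_width) * bin_width
    n_bins = max(1, int(np.ceil((v.max() - lo) / bin_width + 1e-12)))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] <= v.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(v, bins=edges)
    return Histogram(edges, counts / counts.sum())
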