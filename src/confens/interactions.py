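"""Dynamic contact maps and non-covalent interaction statistics.

Criteria follow the conventional MD-analysis thresholds: a residue
contact is a Cα–Cα distance strictly below 10 Å; a hydrogen bond needs
a donor/acceptor heavy-atom (N, O, S) distance ≤ 3.6 Å and a D–H⋯A
angle ≥ 120°; a hydrophobic contact is a side-chain heavy-atom minimum
distance ≤ 4 Å between hydrophobic residues.  All statistics are
occurrence fractions normalised over frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensembles import (ConformationEnsemble, EnsembleError, THREE_TO_ONE,
                        write_table)
from .secondary_structure import reconstruct_amide_hydrogens

HYDROPHOBIC_RESIDUES = frozenset("AVLIPFMW")
_POLAR_ELEMENTS = ("N", "O", "S")
_BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT", "H", "HA"}


@dataclass
class ContactMap:
    """Residue × residue contact frequencies in [0, 1].

    Cells on the diagonal band |i−j| ≤ ``neighbour_exclusion`` are NaN
    (trivial sequence neighbours), keeping the occurrence statistics
    informative; set the exclusion to 0 for the strict full map.
    """

    frequencies: np.ndarray
    residue_numbers: np.ndarray
    cutoff: float
    neighbour_exclusion: int = 2

    def write(self, path) -> None:
        rn = self.residue_numbers
        rows = [(int(rn[i]), int(rn[j]), self.frequencies[i, j])
                for i in range(rn.size) for j in range(i + 1, rn.size)
                if np.isfinite(self.frequencies[i, j])]
        write_table(pd.DataFrame(rows, columns=["res_i", "res_j", "frequency"]), path)


@dataclass
class InteractionRecord:
    """One detected interaction with its occurrence over frames."""

    kind: str                      # "hbond" | "hydrophobic" | "contact"
    res_i: int
    res_j: int
    atom_i: str | None = None      # donor atom for hbond
    atom_j: str | None = None      # acceptor atom for hbond
    occurrence: float = 0.0
    geometry_inferred: bool = False  # True when the H was reconstructed

    def __post_init__(self):
        if not 0.0 <= self.occurrence <= 1.0:
            raise EnsembleError("occurrence must be within [0, 1]")


def records_table(records: list[InteractionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.kind, r.res_i, r.atom_i or "", r.res_j, r.atom_j or "", r.occurrence)
         for r in records],
        columns=["kind", "res_i", "atom_i", "res_j", "atom_j", "occurrence"])


# ---------------------------------------------------------------------------


def contact_map(ensemble: ConformationEnsemble, cutoff: float = 10.0,
                neighbour_exclusion: int = 2) -> ContactMap:
    """Dynamic Cα–Cα contact map: frequency of frames with distance
    strictly below ``cutoff`` (Å), normalised over the frame count."""
    topo = ensemble.topology
    try:
        ca = [topo.atom_index(r, "CA") for r in topo.residue_numbers]
    except EnsembleError as exc:
        raise EnsembleError(f"contact map needs Cα for every residue: {exc}") from exc
    xyz = ensemble.coordinates[:, ca, :]
    diff = xyz[:, :, None, :] - xyz[:, None, :, :]
    d = np.linalg.norm(diff, axis=3)
    freq = np.mean(d < cutoff, axis=0)
    n = topo.n_residues
    ii, jj = np.indices((n, n))
    freq[np.abs(ii - jj) <= neighbour_exclusion] = np.nan
    return ContactMap(freq, topo.residue_numbers, cutoff, neighbour_exclusion)


def _covalent_graph(ensemble: ConformationEnsemble) -> set[tuple[int, int]]:
    """1-2 and 1-3 heavy-atom pairs, bonds inferred from frame-0 distances."""
    topo = ensemble.topology
    xyz = ensemble.coordinates[0]
    heavy = np.flatnonzero(np.char.upper(topo.elements) != "H")
    tree = cKDTree(xyz[heavy])
    bonds: dict[int, set[int]] = {int(a): set() for a in heavy}
    for ia, ib in tree.query_pairs(1.9):
        a, b = int(heavy[ia]), int(heavy[ib])
        bonds[a].add(b)
        bonds[b].add(a)
    excluded = set()
    for a, nbs in bonds.items():
        for b in nbs:
            excluded.add((min(a, b), max(a, b)))
            for c in bonds[b]:
                if c != a:
                    excluded.add((min(a, c), max(a, c)))
    return excluded


def hydrogen_bonds(ensemble: ConformationEnsemble, dist_cutoff: float = 3.6,
                   angle_cutoff: float = 120.0, min_occurrence: float = 0.0
                   ) -> list[InteractionRecord]:
    """Hydrogen bonds (incl. salt bridges) with occurrence statistics.

    Donors/acceptors are N, O and S heavy atoms.  A bond requires the
    heavy-atom distance ≤ ``dist_cutoff`` and the D–H⋯A angle (at the
    hydrogen) ≥ ``angle_cutoff``.  Explicit hydrogens are used when
    present; backbone amide hydrogens are otherwise reconstructed and
    the records flagged ``geometry_inferred``.  Covalent 1-2/1-3 and
    intra-residue pairs are excluded.
    """
    topo = ensemble.topology
    elements = np.char.upper(topo.elements)
    polar = np.flatnonzero(np.isin(elements, _POLAR_ELEMENTS))
    if polar.size == 0:
        warnings.warn("no polar (N/O/S) atoms in topology; no H-bonds possible")
        return []
    xyz = ensemble.coordinates
    n_frames = ensemble.n_frames

    # attach hydrogens: explicit (bonded by distance in frame 0), else
    # reconstructed amide H on backbone N
    h_atoms = np.flatnonzero(elements == "H")
    donors: list[tuple[int, object, bool]] = []   # (heavy idx, H source, inferred)
    if h_atoms.size:
        tree_h = cKDTree(xyz[0, h_atoms])
        for d in polar:
            near = tree_h.query_ball_point(xyz[0, d], 1.25)
            for k in near:
                donors.append((int(d), int(h_atoms[k]), False))
    have_explicit = {d for d, _, _ in donors}
    amide_h = None
    for ri, rnum in enumerate(topo.residue_numbers):
        try:
            n_idx = topo.atom_index(rnum, "N")
        except EnsembleError:
            continue
        if n_idx in have_explicit or topo.residue_names[ri] == "PRO" or ri == 0:
            continue
        if amide_h is None:
            amide_h = reconstruct_amide_hydrogens(ensemble)
        donors.append((n_idx, ("amide", ri), True))

    excluded = _covalent_graph(ensemble)
    res_of = topo.atom_residue_index
    counts: dict[tuple[int, int], int] = {}
    inferred_flag: dict[tuple[int, int], bool] = {}
    for f in range(n_frames):
        tree_a = cKDTree(xyz[f, polar])
        for d_idx, h_src, inferred in donors:
            if inferred:
                h_pos = amide_h[f, h_src[1]]
                if not np.all(np.isfinite(h_pos)):
                    continue
            else:
                h_pos = xyz[f, h_src]
            for k in tree_a.query_ball_point(xyz[f, d_idx], dist_cutoff):
                a_idx = int(polar[k])
                if a_idx == d_idx or res_of[a_idx] == res_of[d_idx]:
                    continue
                if (min(d_idx, a_idx), max(d_idx, a_idx)) in excluded:
                    continue
                u = xyz[f, d_idx] - h_pos
                v = xyz[f, a_idx] - h_pos
                cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
                ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                if ang >= angle_cutoff:
                    key = (d_idx, a_idx)
                    counts[key] = counts.get(key, 0) + 1
                    inferred_flag[key] = inferred_flag.get(key, False) or inferred
    records = []
    for (d_idx, a_idx), c in sorted(counts.items()):
        occ = c / n_frames
        if occ < min_occurrence or occ == 0:
            continue
        records.append(InteractionRecord(
            "hbond",
            int(topo.residue_numbers[res_of[d_idx]]), int(topo.residue_numbers[res_of[a_idx]]),
            str(topo.atom_names[d_idx]), str(topo.atom_names[a_idx]),
            occ, inferred_flag[(d_idx, a_idx)]))
    records.sort(key=lambda r: -r.occurrence)
    return records


def hydrophobic_contacts(ensemble: ConformationEnsemble, cutoff: float = 4.0,
                         min_occurrence: float = 0.0,
                         hydrophobic=HYDROPHOBIC_RESIDUES
                         ) -> list[InteractionRecord]:
    """Hydrophobic residue pairs whose side-chain heavy atoms come
    within ``cutoff`` Å, with occurrence over frames."""
    topo = ensemble.topology
    elements = np.char.upper(topo.elements)
    side = {}
    for ri in range(topo.n_residues):
        one = THREE_TO_ONE.get(str(topo.residue_names[ri]), "X")
        if one not in hydrophobic:
            continue
        atoms = np.flatnonzero(
            (topo.atom_residue_index == ri)
            & (elements != "H")
            & ~np.isin(topo.atom_names, list(_BACKBONE_NAMES)))
        if atoms.size == 0:
            raise EnsembleError(
                f"residue {topo.residue_numbers[ri]} ({topo.residue_names[ri]}) "
                "is in the hydrophobic set but has no side-chain heavy atoms")
        side[ri] = atoms
    keys = sorted(side)
    records = []
    for a_pos in range(len(keys)):
        for b_pos in range(a_pos + 1, len(keys)):
            ri, rj = keys[a_pos], keys[b_pos]
            xi = ensemble.coordinates[:, side[ri], :]
            xj = ensemble.coordinates[:, side[rj], :]
            d = np.linalg.norm(xi[:, :, None, :] - xj[:, None, :, :], axis=3)
            occ = float(np.mean(d.min(axis=(1, 2)) <= cutoff))
            if occ > 0 and occ >= min_occurrence:
                records.append(InteractionRecord(
                    "hydrophobic",
                    int(topo.residue_numbers[ri]), int(topo.residue_numbers[rj]),
                    occurrence=occ))
    records.sort(key=lambda r: -r.occurrence)
    return records


def segment_contacts(records_or_map, segments: list[tuple[int, int]],
                     min_occurrence: float = 0.80) -> list[InteractionRecord]:
    """Interactions anchored on origin segments (residue-number spans),
    kept only above the occurrence threshold (strictly greater).

    Accepts a record list or a ContactMap (converted to per-pair
    contact records first).
    """
    if not segments:
        raise EnsembleError("empty segment list")
    if isinstance(records_or_map, ContactMap):
        cm = records_or_map
        rn = cm.residue_numbers
        records = [InteractionRecord("contact", int(rn[i]), int(rn[j]),
                                     occurrence=float(cm.frequencies[i, j]))
                   for i in range(rn.size) for j in range(i + 1, rn.size)
                   if np.isfinite(cm.frequencies[i, j]) and cm.frequencies[i, j] > 0]
    else:
        records = list(records_or_map)

    def in_segments(res: int) -> bool:
        return any(lo <= res <= hi for lo, hi in segments)

    return [r for r in records
            if r.occurrence > min_occurrence
            and (in_segments(r.res_i) or in_segments(r.res_j))]
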