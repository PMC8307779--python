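"""Per-frame, per-residue secondary structure and helix statistics.

States follow the 8-letter DSSP alphabet: H (α-helix), G (3₁₀-helix),
I (π-helix), E (strand), B (bridge), T (turn), S (bend), C (coil; '-'
is accepted as an alias on input).  Assignment is backbone H-bond
based; the Kabsch–Sander electrostatic H-bond energy is exposed so the
assignment can be audited against the raw i→i+3 / i→i+4 bond patterns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import mdtraj as md
from mdtraj.core import element as md_element

from .ensembles import ConformationEnsemble, EnsembleError
from .descriptors import DescriptorSeries

SS_STATES = ("H", "G", "I", "E", "B", "T", "S", "C")
_STATE_INDEX = {s: i for i, s in enumerate(SS_STATES)}

#: Kabsch–Sander H-bond energy threshold (kcal/mol).
HBOND_ENERGY_CUTOFF = -0.5


@dataclass
class SecondaryStructureTrack:
    """frames × residues matrix of 8-state fold codes."""

    states: np.ndarray                 # (n_frames, n_res) of 'U1'
    residue_numbers: np.ndarray
    label: str = ""

    def __post_init__(self):
        s = np.asarray(self.states, dtype="U1")
        s[s == "-"] = "C"
        s[s == " "] = "C"
        bad = set(np.unique(s)) - set(SS_STATES)
        if bad:
            raise EnsembleError(f"unknown secondary-structure states: {sorted(bad)}")
        self.states = s
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        if s.shape[1] != self.residue_numbers.size:
            raise EnsembleError("track width must equal residue count")

    @property
    def n_frames(self) -> int:
        return int(self.states.shape[0])

    @property
    def n_residues(self) -> int:
        return int(self.states.shape[1])

    def state_codes(self) -> np.ndarray:
        """Integer codes 0..7 in the canonical state order."""
        codes = np.empty(self.states.shape, dtype=np.int8)
        for s, i in _STATE_INDEX.items():
            codes[self.states == s] = i
        return codes

    def write(self, path) -> None:
        df = pd.DataFrame(self.states, columns=[str(r) for r in self.residue_numbers])
        df.insert(0, "frame", np.arange(self.n_frames))
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path, label: str = "") -> "SecondaryStructureTrack":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = [c for c in df.columns if c != "frame"]
        states = df[cols].to_numpy(dtype="U1")
        return cls(states, np.array([int(c) for c in cols]), label=label)


@dataclass
class HelixSegment:
    """A persistent helical stretch (states H/G) merged across frames."""

    label: str
    start_residue: int
    end_residue: int
    lifetime: float          # fraction of frames present with >= min_length
    alpha_fraction: float    # H among helical cells
    three10_fraction: float  # G among helical cells


# ---------------------------------------------------------------------------
# DSSP assignment
# ---------------------------------------------------------------------------

_BACKBONE = ("N", "CA", "C", "O")


def _to_mdtraj(ensemble: ConformationEnsemble) -> md.Trajectory:
    topo = ensemble.topology
    for ri in range(topo.n_residues):
        names = set(topo.atom_names[topo.atom_residue_index == ri])
        missing = [n for n in _BACKBONE if n not in names]
        if missing:
            raise EnsembleError(
                f"residue {topo.residue_numbers[ri]} missing backbone atom(s) "
                f"{missing}")
    mtop = md.Topology()
    chain = mtop.add_chain()
    residues = []
    for ri in range(topo.n_residues):
        residues.append(mtop.add_residue(str(topo.residue_names[ri]), chain,
                                         resSeq=int(topo.residue_numbers[ri])))
    for ai in range(topo.n_atoms):
        el = md_element.get_by_symbol(str(topo.elements[ai]).capitalize())
        mtop.add_atom(str(topo.atom_names[ai]), el, residues[topo.atom_residue_index[ai]])
    return md.Trajectory(ensemble.coordinates / 10.0, mtop)   # Å → nm


def assign_dssp(ensemble: ConformationEnsemble) -> SecondaryStructureTrack:
    """8-state DSSP assignment for every frame.

    Backbone N/Cα/C/O must be present for every residue (the amide
    hydrogen is reconstructed internally, so H-less ensembles are
    fine).  Chain breaks act as segment boundaries.
    """
    traj = _to_mdtraj(ensemble)
    codes = md.compute_dssp(traj, simplified=False)
    codes = np.char.replace(np.char.replace(codes.astype("U1"), " ", "C"), "~", "C")
    return SecondaryStructureTrack(codes, ensemble.topology.residue_numbers,
                                   label=ensemble.label)


def reconstruct_amide_hydrogens(ensemble: ConformationEnsemble) -> np.ndarray:
    """Amide H positions (frames × residues × 3, Å); NaN where undefined.

    H sits 1.01 Å from N along the outward bisector of the
    C(prev)–N–Cα angle.  The first residue (no preceding carbonyl) and
    prolines (no amide H) are NaN.
    """
    topo = ensemble.topology
    n_idx = [topo.atom_index(r, "N") for r in topo.residue_numbers]
    ca_idx = [topo.atom_index(r, "CA") for r in topo.residue_numbers]
    c_idx = [topo.atom_index(r, "C") for r in topo.residue_numbers]
    xyz = ensemble.coordinates
    out = np.full((ensemble.n_frames, topo.n_residues, 3), np.nan)
    for ri in range(1, topo.n_residues):
        if topo.residue_names[ri] == "PRO":
            continue
        N = xyz[:, n_idx[ri]]
        u = xyz[:, c_idx[ri - 1]] - N
        v = xyz[:, ca_idx[ri]] - N
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        b = u + v
        b = b / np.linalg.norm(b, axis=1, keepdims=True)
        out[:, ri] = N - 1.01 * b
    return out


def kabsch_sander_energies(ensemble: ConformationEnsemble,
                           frame: int) -> np.ndarray:
    """Backbone H-bond energies E[donor, acceptor] (kcal/mol) for one frame.

    E = 0.084 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) · 332 with the
    donor's amide N–H and the acceptor's carbonyl C=O; a bond is
    assigned where E < −0.5 kcal/mol.  Entries are +inf where the
    geometry is undefined (first residue, prolines, |i−j| < 2).
    """
    topo = ensemble.topology
    nres = topo.n_residues
    n_pos = np.array([ensemble.coordinates[frame, topo.atom_index(r, "N")]
                      for r in topo.residue_numbers])
    c_pos = np.array([ensemble.coordinates[frame, topo.atom_index(r, "C")]
                      for r in topo.residue_numbers])
    o_pos = np.array([ensemble.coordinates[frame, topo.atom_index(r, "O")]
                      for r in topo.residue_numbers])
    h_pos = reconstruct_amide_hydrogens(ensemble)[frame]
    E = np.full((nres, nres), np.inf)
    for i in range(nres):                      # donor
        if not np.all(np.isfinite(h_pos[i])):
            continue
        for j in range(nres):                  # acceptor
            if abs(i - j) < 2:
                continue
            r_on = np.linalg.norm(o_pos[j] - n_pos[i])
            r_ch = np.linalg.norm(c_pos[j] - h_pos[i])
            r_oh = np.linalg.norm(o_pos[j] - h_pos[i])
            r_cn = np.linalg.norm(c_pos[j] - n_pos[i])
            if min(r_on, r_ch, r_oh, r_cn) < 1e-6:
                continue
            E[i, j] = 0.084 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn) * 332.0
    return E


# ---------------------------------------------------------------------------
# Helical statistics
# ---------------------------------------------------------------------------

def helical_fraction(track: SecondaryStructureTrack,
                     states=("H", "G")) -> DescriptorSeries:
    """Helical folding order parameter Hfp: per-frame % of residues in
    the given states (α + 3₁₀ by default; π excluded)."""
    if not states:
        raise EnsembleError("empty state set")
    if track.n_frames == 0:
        raise EnsembleError("empty track")
    mask = np.isin(track.states, list(states))
    return DescriptorSeries("hfp", 100.0 * mask.mean(axis=1), "%", track.label)


def _frame_runs(row: np.ndarray, min_length: int) -> list[tuple[int, int]]:
    """Maximal helical runs [start, end] (inclusive, residue indices)."""
    helical = np.isin(row, ("H", "G"))
    runs = []
    start = None
    for i, h in enumerate(helical):
        if h and start is None:
            start = i
        elif not h and start is not None:
            if i - start >= min_length:
                runs.append((start, i - 1))
            start = None
    if start is not None and helical.size - start >= min_length:
        runs.append((start, helical.size - 1))
    return runs


def helix_segments(track: SecondaryStructureTrack, min_length: int = 3,
                   min_lifetime: float = 0.0) -> list[HelixSegment]:
    """Persistent helices: per-frame H/G runs merged across frames by
    residue-span overlap (≥1 shared residue), labelled H1…Hn from the
    N-terminus by mean position.

    Lifetime is the fraction of frames in which the merged segment
    appears with at least ``min_length`` residues.
    """
    all_runs = []                      # (frame, start, end)
    for f in range(track.n_frames):
        for s, e in _frame_runs(track.states[f], min_length):
            all_runs.append((f, s, e))
    if not all_runs:
        return []
    parent = list(range(len(all_runs)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    # sweep by residue interval overlap
    order = sorted(range(len(all_runs)), key=lambda k: all_runs[k][1])
    active: list[int] = []
    for k in order:
        _, s, e = all_runs[k]
        active = [a for a in active if all_runs[a][2] >= s]
        for a in active:
            union(a, k)
        active.append(k)
    groups: dict[int, list[int]] = {}
    for k in range(len(all_runs)):
        groups.setdefault(find(k), []).append(k)

    segments = []
    for members in groups.values():
        frames = {all_runs[k][0] for k in members}
        start = min(all_runs[k][1] for k in members)
        end = max(all_runs[k][2] for k in members)
        lifetime = len(frames) / track.n_frames
        if lifetime < min_lifetime:
            continue
        cells_h = cells_g = 0
        for k in members:
            f, s, e = all_runs[k]
            row = track.states[f, s:e + 1]
            cells_h += int(np.sum(row == "H"))
            cells_g += int(np.sum(row == "G"))
        total = max(cells_h + cells_g, 1)
        segments.append((start, end, lifetime, cells_h / total, cells_g / total))
    segments.sort(key=lambda t: 0.5 * (t[0] + t[1]))
    rn = track.residue_numbers
    return [HelixSegment(f"H{i + 1}", int(rn[s]), int(rn[e]), lt, fa, fg)
            for i, (s, e, lt, fa, fg) in enumerate(segments)]
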