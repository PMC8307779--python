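"""Conformational ensembles over a fixed topology.

An ensemble is the in-memory surrogate of an MD trajectory: an ordered
stack of frames (frames × atoms × 3, Å) over one residue-level topology.
Multi-model PDB is the interchange format (MODEL/ENDMDL delimited);
binary trajectory formats are deliberately out of scope.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
import biotite.structure.io.pdb as bst_pdb

from ._geometry import kabsch_rotation, is_collinear

# Standard atomic masses (amu) for the elements this package handles.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971,
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class EnsembleError(ValueError):
    """Raised on malformed ensemble input or invariant violations."""


@dataclass(frozen=True)
class Topology:
    """Residue-level topology: who the atoms are, not where they sit.

    ``residue_numbers`` keeps the author numbering verbatim (e.g.
    689–768 for the KIT kinase-insert domain); it is never renumbered.
    """

    residue_numbers: np.ndarray          # (n_res,) int, strictly increasing
    residue_names: np.ndarray            # (n_res,) 3-letter codes
    atom_names: np.ndarray               # (n_atoms,) str
    elements: np.ndarray                 # (n_atoms,) str
    atom_residue_index: np.ndarray       # (n_atoms,) int into residues
    masses: np.ndarray = field(default=None)  # (n_atoms,) amu
    chain_id: str = "A"

    def __post_init__(self):
        rn = np.asarray(self.residue_numbers, dtype=int)
        object.__setattr__(self, "residue_numbers", rn)
        object.__setattr__(self, "residue_names", np.asarray(self.residue_names, dtype="U3"))
        object.__setattr__(self, "atom_names", np.asarray(self.atom_names, dtype="U6"))
        object.__setattr__(self, "elements", np.asarray(self.elements, dtype="U2"))
        ari = np.asarray(self.atom_residue_index, dtype=int)
        object.__setattr__(self, "atom_residue_index", ari)
        if np.any(np.diff(rn) <= 0):
            raise EnsembleError("residue numbers must be strictly increasing")
        if ari.min(initial=0) < 0 or (ari.size and ari.max() >= rn.size):
            raise EnsembleError("atom_residue_index out of residue range")
        if self.masses is None:
            try:
                m = np.array([ATOMIC_MASSES[e.upper()] for e in self.elements])
            except KeyError as exc:
                raise EnsembleError(f"no mass for element {exc}") from exc
            object.__setattr__(self, "masses", m)
        else:
            object.__setattr__(self, "masses", np.asarray(self.masses, dtype=float))
        if np.any(self.masses <= 0):
            raise EnsembleError("atomic masses must be positive")

    @property
    def n_residues(self) -> int:
        return int(self.residue_numbers.size)

    @property
    def n_atoms(self) -> int:
        return int(self.atom_names.size)

    def select(self, atom_names=None, residue_numbers=None, elements=None) -> "AtomSelection":
        """Select atom indices by name / residue number / element."""
        mask = np.ones(self.n_atoms, dtype=bool)
        desc = []
        if atom_names is not None:
            names = set(np.atleast_1d(atom_names).tolist())
            mask &= np.isin(self.atom_names, list(names))
            desc.append(f"atoms {sorted(names)}")
        if residue_numbers is not None:
            wanted = set(np.atleast_1d(residue_numbers).tolist())
            res_mask = np.isin(self.residue_numbers, list(wanted))
            mask &= res_mask[self.atom_residue_index]
            desc.append(f"residues {min(wanted)}-{max(wanted)}")
        if elements is not None:
            els = set(e.upper() for e in np.atleast_1d(elements).tolist())
            mask &= np.isin(np.char.upper(self.elements), list(els))
            desc.append(f"elements {sorted(els)}")
        return AtomSelection(np.flatnonzero(mask), "; ".join(desc) or "all atoms")

    def ca_selection(self) -> "AtomSelection":
        sel = self.select(atom_names="CA")
        return AtomSelection(sel.indices, f"Cα of residues "
                             f"{self.residue_numbers[0]}-{self.residue_numbers[-1]}")

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        ri = np.flatnonzero(self.residue_numbers == residue_number)
        if ri.size == 0:
            raise EnsembleError(f"residue {residue_number} not in topology")
        hits = np.flatnonzero(
            (self.atom_residue_index == ri[0]) & (self.atom_names == atom_name)
        )
        if hits.size == 0:
            raise EnsembleError(f"residue {residue_number} has no atom {atom_name}")
        return int(hits[0])

    def sequence(self) -> str:
        return "".join(THREE_TO_ONE.get(n, "X") for n in self.residue_names)


@dataclass(frozen=True)
class AtomSelection:
    """A set of 0-based atom indices into an ensemble, with a label."""

    indices: np.ndarray
    description: str = ""

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise EnsembleError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return int(self.indices.size)


@dataclass
class ConformationEnsemble:
    """Frames × atoms × 3 coordinate stack (Å) over one topology."""

    topology: Topology
    coordinates: np.ndarray
    frame_times: np.ndarray | None = None   # ps, optional
    label: str = ""

    def __post_init__(self):
        xyz = np.asarray(self.coordinates, dtype=float)
        if xyz.ndim != 3 or xyz.shape[2] != 3:
            raise EnsembleError("coordinates must have shape (frames, atoms, 3)")
        if xyz.shape[1] != self.topology.n_atoms:
            raise EnsembleError(
                f"coordinate atom count {xyz.shape[1]} != topology atom count "
                f"{self.topology.n_atoms}")
        if not np.all(np.isfinite(xyz)):
            raise EnsembleError("coordinates must be finite")
        self.coordinates = xyz
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if t.size != xyz.shape[0]:
                raise EnsembleError("frame_times length must equal frame count")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return int(self.coordinates.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coordinates.shape[1])

    def strided(self, stride: int) -> "ConformationEnsemble":
        """Every ``stride``-th frame (analysis subsampling)."""
        if stride < 1:
            raise EnsembleError("stride must be >= 1")
        t = None if self.frame_times is None else self.frame_times[::stride]
        return ConformationEnsemble(self.topology, self.coordinates[::stride].copy(),
                                    t, self.label)


# ---------------------------------------------------------------------------
# Multi-model PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _prescan_pdb(lines: list[str]) -> None:
    """Cheap structural sanity pass over PDB text.

    Checks coordinate fields parse and that every MODEL carries the same
    atom count, raising errors that name the offending line or model.
    """
    model_counts: list[int] = []
    current = 0
    in_model = False
    n_atoms_flat = 0
    for i, line in enumerate(lines, start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model = True
            current = 0
        elif rec.startswith("ENDMDL"):
            model_counts.append(current)
            in_model = False
        elif rec in ("ATOM  ", "HETATM"):
            if len(line.rstrip("\n")) < 54:
                raise EnsembleError(f"PDB parse error at line {i}: truncated ATOM record")
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except ValueError:
                raise EnsembleError(f"PDB parse error at line {i}: bad coordinate field")
            if in_model:
                current += 1
            else:
                n_atoms_flat += 1
    if in_model:
        model_counts.append(current)
    if model_counts:
        first = model_counts[0]
        for m, cnt in enumerate(model_counts, start=1):
            if cnt != first:
                raise EnsembleError(
                    f"model {m} has {cnt} atoms, expected {first} (as in model 1)")
        if first == 0:
            raise EnsembleError("PDB file contains MODEL records but no atoms")
    elif n_atoms_flat == 0:
        raise EnsembleError("PDB file contains no models / atoms")


def _topology_from_atom_array(arr) -> Topology:
    starts = np.concatenate(([0], np.flatnonzero(np.diff(arr.res_id)) + 1))
    res_ids = arr.res_id[starts]
    res_names = arr.res_name[starts]
    res_index = np.searchsorted(res_ids, arr.res_id)
    chain = str(arr.chain_id[0]) if arr.array_length() else "A"
    return Topology(
        residue_numbers=res_ids,
        residue_names=res_names,
        atom_names=arr.atom_name,
        elements=arr.element,
        atom_residue_index=res_index,
        chain_id=chain,
    )


def read_ensemble(path, fmt: str = "pdb_multimodel", stride: int = 1,
                  label: str | None = None) -> ConformationEnsemble:
    """Read a conformational ensemble from a multi-model PDB file.

    One frame per MODEL record (a single-model file yields a one-frame
    ensemble); the topology is taken from the first model.  Occupancy
    and B-factor columns are ignored.
    """
    if fmt != "pdb_multimodel":
        raise EnsembleError(f"unsupported format: {fmt}")
    path = Path(path)
    text = path.read_text()
    _prescan_pdb(text.splitlines())
    pdb = bst_pdb.PDBFile.read(_io.StringIO(text))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, bst.AtomArray):            # single model
        stack = bst.stack([stack])
    arr0 = stack[0]
    topo = _topology_from_atom_array(arr0)
    ens = ConformationEnsemble(topo, np.asarray(stack.coord, dtype=float),
                               label=label if label is not None else path.stem)
    return ens.strided(stride) if stride > 1 else ens


def write_ensemble(ensemble: ConformationEnsemble, path) -> None:
    """Write as multi-model PDB (MODEL/ENDMDL; occupancy 1.00, B 0.00)."""
    topo = ensemble.topology
    n = topo.n_atoms
    arr = bst.AtomArrayStack(ensemble.n_frames, n)
    arr.coord = ensemble.coordinates
    arr.chain_id = np.full(n, topo.chain_id)
    arr.res_id = topo.residue_numbers[topo.atom_residue_index]
    arr.res_name = topo.residue_names[topo.atom_residue_index]
    arr.atom_name = topo.atom_names
    arr.element = topo.elements
    arr.hetero = np.zeros(n, dtype=bool)
    arr.set_annotation("occupancy", np.ones(n))
    arr.set_annotation("b_factor", np.zeros(n))
    pdb = bst_pdb.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_table(df: pd.DataFrame, path) -> None:
    """TSV writer used for every exported table ('.' decimal, header row)."""
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Ensemble operations
# ---------------------------------------------------------------------------

def superpose(ensemble: ConformationEnsemble, reference_frame: int = 0,
              selection: AtomSelection | None = None) -> ConformationEnsemble:
    """Remove rigid-body motion by least-squares fitting every frame.

    Each frame is rigidly transformed (Kabsch optimal rotation +
    translation, proper rotations only) to minimise the RMSD of the
    fitting selection to the reference frame.  Intra-frame geometry is
    untouched.  Default selection: all Cα atoms; default reference:
    frame 0 (the initial conformation).
    """
    if selection is None:
        selection = ensemble.topology.ca_selection()
    idx = selection.indices
    if idx.size and (idx.min() < 0 or idx.max() >= ensemble.n_atoms):
        raise EnsembleError("selection indices out of range")
    if idx.size < 3:
        raise EnsembleError("superposition needs >= 3 selected atoms")
    ref = ensemble.coordinates[reference_frame][idx]
    if is_collinear(ref):
        raise EnsembleError("degenerate fit: selected reference atoms are collinear")
    out = np.empty_like(ensemble.coordinates)
    for f in range(ensemble.n_frames):
        R, t, _ = kabsch_rotation(ensemble.coordinates[f][idx], ref)
        out[f] = ensemble.coordinates[f] @ R.T + t
    return ConformationEnsemble(ensemble.topology, out,
                                ensemble.frame_times, ensemble.label)


def drop_equilibration(ensemble: ConformationEnsemble, n_frames: int) -> ConformationEnsemble:
    """Discard the first ``n_frames`` (non-equilibrated) frames."""
    if not 0 <= n_frames < ensemble.n_frames:
        raise EnsembleError(
            f"n_frames must be in [0, {ensemble.n_frames}), got {n_frames}")
    t = None if ensemble.frame_times is None else ensemble.frame_times[n_frames:]
    return ConformationEnsemble(ensemble.topology,
                                ensemble.coordinates[n_frames:].copy(),
                                t, ensemble.label)


def concatenate(ensembles: list[ConformationEnsemble],
                label: str = "merged") -> ConformationEnsemble:
    """Merge replicas frame-wise; topologies must match atom-for-atom."""
    if not ensembles:
        raise EnsembleError("nothing to concatenate")
    topo = ensembles[0].topology
    for e in ensembles[1:]:
        t = e.topology
        if t.n_atoms != topo.n_atoms:
            raise EnsembleError(
                f"topology mismatch: {t.n_atoms} atoms vs {topo.n_atoms}")
        diff = np.flatnonzero(
            (t.atom_names != topo.atom_names)
            | (t.atom_residue_index != topo.atom_residue_index))
        if diff.size:
            a = diff[0]
            raise EnsembleError(
                f"topology mismatch at atom {a}: "
                f"{t.atom_names[a]} vs {topo.atom_names[a]}")
    coords = np.concatenate([e.coordinates for e in ensembles], axis=0)
    times = None
    if all(e.frame_times is not None for e in ensembles):
        times = np.concatenate([e.frame_times for e in ensembles])
    return ConformationEnsemble(topo, coords, times, label)
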