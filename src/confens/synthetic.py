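"""Synthetic test-data generators.

The MD trajectories this package is meant for are too large to archive,
so every analysis stage is exercised on synthetic inputs that emulate
their statistical structure: 80-residue chains (numbered 689–768, the
KIT kinase-insert domain convention), 8-state secondary-structure
sequences evolving under per-residue Markov chains, ideal-geometry
peptide ensembles realising those states, Gaussian-mixture reaction
coordinates, and multi-basin coordinate ensembles with bimodal RMSD
structure.  Every generator is a pure function of its spec and seed,
and ground-truth labels are always returned alongside the data.

Per-residue chains are intentionally independent (no spatial coupling):
this suffices to test the estimators; emulating cooperative folding is
out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._geometry import place_atom
from .ensembles import (ConformationEnsemble, EnsembleError, ONE_TO_THREE,
                        Topology)
from .landscape import ReactionCoordinatePair
from .secondary_structure import SS_STATES, SecondaryStructureTrack

_DEG = np.pi / 180.0

#: Ideal backbone dihedrals per helical state (φ, ψ in degrees).
HELIX_DIHEDRALS = {"H": (-57.0, -47.0), "G": (-49.0, -26.0), "I": (-57.0, -70.0)}
#: Broad coil basin for every non-helical state (mean, sd in degrees).
COIL_PHI = (-120.0, 30.0)
COIL_PSI = (130.0, 30.0)


@dataclass
class ChainSpec:
    """Ground-truth per-residue Markov chains for state simulation."""

    matrices: np.ndarray              # (n_res, 8, 8) row-stochastic
    initial: np.ndarray               # (n_res, 8) initial distributions
    n_frames: int
    seed: int
    residue_numbers: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim == 2:
            m = np.broadcast_to(m, (1,) + m.shape).copy()
        if m.shape[1:] != (8, 8):
            raise EnsembleError("chain matrices must be (n_res, 8, 8)")
        if np.any(m < 0) or np.any(np.abs(m.sum(axis=2) - 1.0) > 1e-9):
            raise EnsembleError("chain rows must be stochastic")
        self.matrices = m
        init = np.asarray(self.initial, dtype=float)
        if init.ndim == 1:
            init = np.broadcast_to(init, (m.shape[0], 8)).copy()
        if np.any(np.abs(init.sum(axis=1) - 1.0) > 1e-9):
            raise EnsembleError("initial distributions must be stochastic")
        self.initial = init
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(689, 689 + m.shape[0])
        else:
            self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)


def simulate_ss_chain(spec: ChainSpec, label: str = "") -> SecondaryStructureTrack:
    """Simulate independent per-residue 8-state Markov trajectories."""
    rng = np.random.default_rng(spec.seed)
    n_res = spec.matrices.shape[0]
    cum_init = np.cumsum(spec.initial, axis=1)
    cum = np.cumsum(spec.matrices, axis=2)          # (n_res, 8, 8)
    states = np.empty((spec.n_frames, n_res), dtype=np.int8)
    u0 = rng.random(n_res)
    states[0] = (u0[:, None] < cum_init).argmax(axis=1)
    ar = np.arange(n_res)
    for t in range(1, spec.n_frames):
        rows = cum[ar, states[t - 1]]               # (n_res, 8)
        u = rng.random(n_res)
        states[t] = (u[:, None] < rows).argmax(axis=1)
    letters = np.array(SS_STATES, dtype="U1")[states]
    return SecondaryStructureTrack(letters, spec.residue_numbers, label=label)


# ---------------------------------------------------------------------------
# Ideal-geometry peptide builder
# ---------------------------------------------------------------------------

_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.53, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2 * _DEG, 116.2 * _DEG, 121.7 * _DEG
_A_CA_C_O, _A_N_CA_CB = 120.5 * _DEG, 110.5 * _DEG


def build_peptide_ensemble(sequence: str, track: SecondaryStructureTrack,
                           jitter_sigma: float = 0.0, seed: int = 0,
                           label: str = "") -> ConformationEnsemble:
    """Realise a state track as backbone coordinates, frame by frame.

    The chain is grown by internal-coordinate (NeRF) extension with
    standard bond lengths/angles; helical states get their ideal (φ, ψ)
    and all other states draw from a broad coil basin.  Cβ and the
    amide hydrogen are placed by ideal geometry, then isotropic
    Gaussian jitter of ``jitter_sigma`` Å is added per coordinate.
    """
    sequence = sequence.upper()
    if len(sequence) != track.n_residues:
        raise EnsembleError("sequence length must equal track residue count")
    bad = [c for c in sequence if c not in ONE_TO_THREE]
    if bad:
        raise EnsembleError(f"invalid residue letter(s): {sorted(set(bad))}")
    rng = np.random.default_rng(seed)
    F, R = track.n_frames, track.n_residues

    phi = rng.normal(COIL_PHI[0], COIL_PHI[1], size=(F, R)) * _DEG
    psi = rng.normal(COIL_PSI[0], COIL_PSI[1], size=(F, R)) * _DEG
    for state, (p, s) in HELIX_DIHEDRALS.items():
        mask = track.states == state
        phi[mask] = p * _DEG
        psi[mask] = s * _DEG

    N = np.zeros((F, R, 3))
    CA = np.zeros((F, R, 3))
    C = np.zeros((F, R, 3))
    N[:, 0] = [0.0, 0.0, 0.0]
    CA[:, 0] = [_B_N_CA, 0.0, 0.0]
    dummy = np.broadcast_to(np.array([0.0, -1.0, 0.0]), (F, 3))
    C[:, 0] = place_atom(dummy, N[:, 0], CA[:, 0], _B_CA_C, _A_N_CA_C, phi[:, 0])
    for i in range(1, R):
        N[:, i] = place_atom(N[:, i - 1], CA[:, i - 1], C[:, i - 1],
                             _B_C_N, _A_CA_C_N, psi[:, i - 1])
        CA[:, i] = place_atom(CA[:, i - 1], C[:, i - 1], N[:, i],
                              _B_N_CA, _A_C_N_CA, np.pi)        # ω = 180°
        C[:, i] = place_atom(C[:, i - 1], N[:, i], CA[:, i],
                             _B_CA_C, _A_N_CA_C, phi[:, i])

    O = np.zeros((F, R, 3))
    for i in range(R - 1):
        O[:, i] = place_atom(N[:, i + 1], CA[:, i], C[:, i],
                             _B_C_O, _A_CA_C_O, np.pi)
    O[:, R - 1] = place_atom(N[:, R - 1], CA[:, R - 1], C[:, R - 1],
                             _B_C_O, _A_CA_C_O, psi[:, R - 1] - np.pi)

    CB = {}
    for i, aa in enumerate(sequence):
        if aa == "G":
            continue
        CB[i] = place_atom(C[:, i], N[:, i], CA[:, i],
                           _B_CA_CB, _A_N_CA_CB, -122.6 * _DEG)
    H = {}
    for i, aa in enumerate(sequence):
        if i == 0 or aa == "P":
            continue
        u = C[:, i - 1] - N[:, i]
        v = CA[:, i] - N[:, i]
        u = u / np.linalg.norm(u, axis=1, keepdims=True)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        b = u + v
        b = b / np.linalg.norm(b, axis=1, keepdims=True)
        H[i] = N[:, i] - _B_N_H * b

    atom_names, elements, res_index, coords = [], [], [], []
    for i, aa in enumerate(sequence):
        per_res = [("N", "N", N[:, i]), ("CA", "C", CA[:, i]), ("C", "C", C[:, i]),
                   ("O", "O", O[:, i])]
        if i in CB:
            per_res.append(("CB", "C", CB[i]))
        if i in H:
            per_res.append(("H", "H", H[i]))
        for name, el, pos in per_res:
            atom_names.append(name)
            elements.append(el)
            res_index.append(i)
            coords.append(pos)
    xyz = np.stack(coords, axis=1)                  # (F, n_atoms, 3)
    if jitter_sigma > 0:
        xyz = xyz + rng.normal(0.0, jitter_sigma, size=xyz.shape)
    topo = Topology(
        residue_numbers=track.residue_numbers,
        residue_names=[ONE_TO_THREE[c] for c in sequence],
        atom_names=atom_names, elements=elements, atom_residue_index=res_index)
    return ConformationEnsemble(topo, xyz, label=label or track.label)


# ---------------------------------------------------------------------------
# Reaction-coordinate and multi-basin fixtures
# ---------------------------------------------------------------------------

@dataclass
class MixtureSample:
    """2D Gaussian-mixture sample with ground-truth component labels."""

    rc: ReactionCoordinatePair
    labels: np.ndarray
    means: np.ndarray
    sigmas: np.ndarray
    weights: np.ndarray


def gaussian_mixture_samples(means, sigmas, weights, n: int, seed: int = 0,
                             names: tuple[str, str] = ("R1", "R2")
                             ) -> MixtureSample:
    """Draw n iid samples from a 2D isotropic Gaussian mixture."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    sigmas = np.broadcast_to(np.asarray(sigmas, dtype=float), (means.shape[0],))
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9 or np.any(weights < 0):
        raise EnsembleError("mixture weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    labels = rng.choice(means.shape[0], size=n, p=weights)
    pts = means[labels] + rng.normal(size=(n, 2)) * sigmas[labels][:, None]
    return MixtureSample(ReactionCoordinatePair(names, pts), labels,
                         means, np.asarray(sigmas), weights)


@dataclass
class BasinSpec:
    """Multi-basin ensemble spec: template conformations + jitter."""

    templates: np.ndarray             # (n_basins, n_atoms, 3)
    topology: Topology
    weights: np.ndarray
    sigmas: np.ndarray                # per-basin jitter σ (Å)
    n_frames: int
    seed: int

    def __post_init__(self):
        t = np.asarray(self.templates, dtype=float)
        if t.ndim != 3 or t.shape[1] != self.topology.n_atoms:
            raise EnsembleError("templates must share the topology's atom count")
        self.templates = t
        w = np.asarray(self.weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise EnsembleError("basin weights must sum to 1")
        self.weights = w
        s = np.broadcast_to(np.asarray(self.sigmas, dtype=float), (t.shape[0],))
        if np.any(s < 0):
            raise EnsembleError("jitter sigma must be >= 0")
        self.sigmas = s


def multi_basin_ensemble(spec: BasinSpec, label: str = ""
                         ) -> tuple[ConformationEnsemble, np.ndarray]:
    """Each frame = a weight-chosen template plus isotropic jitter.

    Returns the ensemble and the ground-truth basin label per frame.
    Emulates trajectories hopping between groups of highly different
    conformations (bimodal RMSD distributions with peaks 1–3 Å apart or
    more, depending on template separation).
    """
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(spec.templates.shape[0], size=spec.n_frames,
                        p=spec.weights)
    xyz = spec.templates[labels] + rng.normal(
        size=(spec.n_frames, spec.topology.n_atoms, 3)
    ) * spec.sigmas[labels][:, None, None]
    return ConformationEnsemble(spec.topology, xyz, label=label), labels


# ---------------------------------------------------------------------------
# The domain-like default fixture (80 residues, replicas in groups 4+2+2)
# ---------------------------------------------------------------------------

def kid_like_sequence() -> str:
    """80-residue poly-Ala with the domain's anchor residues substituted:
    F689 and D768 at the termini, tyrosines at 703/721/730/747."""
    seq = list("A" * 80)
    seq[0] = "F"
    seq[79] = "D"
    for rnum in (703, 721, 730, 747):
        seq[rnum - 689] = "Y"
    return "".join(seq)


def helix_coil_chain_spec(helix_prob, n_frames: int, seed: int,
                          switch_rate: float = 0.05,
                          residue_numbers=None) -> ChainSpec:
    """Per-residue chains with a prescribed stationary helix fraction.

    Each residue follows a sticky helix/coil chain with stationary
    helical probability ``helix_prob[r]`` and switching rate
    ``switch_rate``; within the helical set 10% of the stay mass goes
    to G (α ↔ 3₁₀ interconversion), within the coil set 10% / 5% go to
    turns / bends.
    """
    p = np.atleast_1d(np.asarray(helix_prob, dtype=float))
    n_res = p.size
    iH, iG, iT, iS, iC = (SS_STATES.index(s) for s in "HGTSC")
    mats = np.zeros((n_res, 8, 8))
    init = np.zeros((n_res, 8))
    for r in range(n_res):
        leave_h = switch_rate * (1.0 - p[r])
        leave_c = switch_rate * p[r]
        stay_h = 1.0 - leave_h
        stay_c = 1.0 - leave_c
        row_helical = np.zeros(8)
        row_helical[iH] = 0.9 * stay_h
        row_helical[iG] = 0.1 * stay_h
        row_helical[iC] = leave_h
        row_coil = np.zeros(8)
        row_coil[iC] = 0.85 * stay_c
        row_coil[iT] = 0.10 * stay_c
        row_coil[iS] = 0.05 * stay_c
        row_coil[iH] = leave_c
        for s in range(8):
            mats[r, s] = row_helical if s in (iH, iG) else row_coil
        init[r, iH] = p[r]
        init[r, iC] = 1.0 - p[r]
    return ChainSpec(mats, init, n_frames, seed, residue_numbers=residue_numbers)


def _helix_profile(segments: list[tuple[int, int]], p_in: float,
                   p_out: float = 0.02, n_res: int = 80,
                   first: int = 689) -> np.ndarray:
    prof = np.full(n_res, p_out)
    for lo, hi in segments:
        prof[lo - first:hi - first + 1] = p_in
    return prof


#: Helical-segment layouts per replica group, chosen so the groups have
#: distinct folding dynamics and stationary helicities spanning the
#: 25–56% range seen in disordered-domain ensembles.
KID_GROUP_PROFILES = {
    "C": dict(segments=[(692, 703), (707, 714), (719, 727), (733, 741),
                        (746, 753), (757, 765)], p_in=0.75),   # helix-rich
    "D": dict(segments=[(692, 703), (719, 727), (746, 752)], p_in=0.70),
    "CR": dict(segments=[(692, 703), (707, 716), (733, 741), (757, 764)],
               p_in=0.80),
}

#: Replica layout mirroring four + two + two independent trajectories.
KID_REPLICA_GROUPS = ("C", "C", "C", "C", "D", "D", "CR", "CR")


def kid_like_replicas(n_frames: int = 2000, seed: int = 0,
                      build_coordinates: bool = False,
                      coordinate_frames: int | None = None,
                      jitter_sigma: float = 0.15) -> list[dict]:
    """The default 8-replica fixture in groups 4+2+2.

    Returns one dict per replica with keys ``label``, ``group``,
    ``track``, ``spec`` and (optionally) ``ensemble``.  Coordinate
    building realises a (possibly shorter) prefix of the track.
    """
    residue_numbers = np.arange(689, 769)
    seq = kid_like_sequence()
    out = []
    for i, group in enumerate(KID_REPLICA_GROUPS):
        prof = KID_GROUP_PROFILES[group]
        profile = _helix_profile(prof["segments"], prof["p_in"])
        spec = helix_coil_chain_spec(profile, n_frames, seed * 1000 + i,
                                     residue_numbers=residue_numbers)
        label = f"KID{group}_{i + 1}"
        track = simulate_ss_chain(spec, label=label)
        rec = {"label": label, "group": group, "track": track, "spec": spec}
        if build_coordinates:
            nf = coordinate_frames or n_frames
            sub = SecondaryStructureTrack(track.states[:nf], residue_numbers,
                                          label=label)
            rec["ensemble"] = build_peptide_ensemble(
                seq, sub, jitter_sigma=jitter_sigma, seed=seed * 1000 + 500 + i,
                label=label)
        out.append(rec)
    return out
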