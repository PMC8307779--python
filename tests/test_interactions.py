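"""Contact maps, H-bond and hydrophobic-contact criteria."""

import numpy as np
import pytest

from confens.ensembles import ConformationEnsemble, EnsembleError, Topology
from confens.interactions import (ContactMap, InteractionRecord, contact_map,
                                  hydrogen_bonds, hydrophobic_contacts,
                                  segment_contacts)

from conftest import make_ca_ensemble


def pair_ensemble(distance, n_frames=4, n_pad=4):
    """Cα chain where residues 0 and last sit exactly `distance` apart
    and padding residues keep them sequence-distant."""
    n = n_pad + 2
    coords = np.zeros((n_frames, n, 3))
    for k in range(1, n_pad + 1):
        coords[:, k] = [0, 40.0 * k, 0]     # park the padding far away
    coords[:, n - 1] = [distance, 0, 0]
    return make_ca_ensemble(coords)


# ---------------------------------------------------------------------------
# Contact maps


@pytest.mark.parametrize("d,freq", [(8.0, 1.0), (10.1, 0.0), (10.0, 0.0)])
def test_contact_threshold_is_strict(d, freq):
    cm = contact_map(pair_ensemble(d))
    assert cm.frequencies[0, -1] == freq


def test_contact_half_frames():
    ens = pair_ensemble(8.0, n_frames=4)
    ens.coordinates[2:, -1] = [30.0, 0, 0]
    assert contact_map(ens).frequencies[0, -1] == 0.5


def test_contact_map_symmetric_and_band_excluded(rng):
    ens = make_ca_ensemble(rng.normal(scale=6, size=(10, 12, 3)))
    cm = contact_map(ens)
    f = cm.frequencies
    np.testing.assert_array_equal(np.isnan(f), np.isnan(f.T))
    m = np.where(np.isnan(f), -1.0, f)
    np.testing.assert_array_equal(m, m.T)
    n = f.shape[0]
    for i in range(n):
        for j in range(max(0, i - 2), min(n, i + 3)):
            assert np.isnan(f[i, j])


def test_contact_map_matches_bruteforce_oracle(rng):
    coords = rng.normal(scale=8, size=(100, 20, 3))
    ens = make_ca_ensemble(coords)
    cm = contact_map(ens, cutoff=10.0, neighbour_exclusion=0)
    for i in range(20):
        for j in range(20):
            if i == j:
                continue
            count = sum(
                np.linalg.norm(coords[f, i] - coords[f, j]) < 10.0
                for f in range(100))
            assert cm.frequencies[i, j] == count / 100


def test_contact_frequency_monotone_in_cutoff(rng):
    ens = make_ca_ensemble(rng.normal(scale=8, size=(30, 8, 3)))
    prev = None
    for cutoff in (6.0, 8.0, 10.0, 14.0):
        f = contact_map(ens, cutoff=cutoff).frequencies
        if prev is not None:
            mask = np.isfinite(f)
            assert np.all(f[mask] >= prev[mask] - 1e-12)
        prev = f


# ---------------------------------------------------------------------------
# Hydrogen bonds


def hbond_fixture(d_no, angle_deg, n_frames=3):
    """Two 'residues': donor N–H and acceptor backbone-like O, with the
    D–H⋯A angle set by placing the acceptor around the hydrogen."""
    # donor N at origin; H along +x at 1.0 Å
    N = np.array([0.0, 0.0, 0.0])
    H = np.array([1.0, 0.0, 0.0])
    # acceptor placed so that |N-O| = d_no with the requested D-H...A angle:
    # solve for O on the plane, angle at H between H->N (-x) and H->O
    theta = np.radians(angle_deg)
    direction = np.array([-np.cos(theta), np.sin(theta), 0.0])
    # find t with |N - (H + t·direction)| = d_no
    a = 1.0
    b = 2 * direction @ (H - N)
    c = (H - N) @ (H - N) - d_no ** 2
    t = (-b + np.sqrt(b * b - 4 * a * c)) / 2
    O = H + t * direction
    topo = Topology(
        residue_numbers=[689, 695],
        residue_names=["ALA", "ALA"],
        atom_names=["N", "H", "O"],
        elements=["N", "H", "O"],
        atom_residue_index=[0, 0, 1],
    )
    coords = np.repeat(np.stack([N, H, O])[None], n_frames, axis=0)
    return ConformationEnsemble(topo, coords)


def test_hbond_detected_within_criteria():
    recs = hydrogen_bonds(hbond_fixture(3.5, 150.0))
    assert len(recs) == 1
    assert recs[0].occurrence == 1.0
    assert recs[0].kind == "hbond"
    assert not recs[0].geometry_inferred


def test_hbond_distance_fail():
    assert hydrogen_bonds(hbond_fixture(3.7, 150.0)) == []


def test_hbond_angle_fail():
    assert hydrogen_bonds(hbond_fixture(3.0, 100.0)) == []


def test_hbond_no_polar_atoms_warns():
    ens = make_ca_ensemble(np.zeros((1, 2, 3)) + [[0, 0, 0], [3, 0, 0]])
    with pytest.warns(UserWarning, match="polar"):
        assert hydrogen_bonds(ens) == []


def test_hbond_occurrence_counts_frames():
    ens = hbond_fixture(3.5, 150.0, n_frames=4)
    ens.coordinates[2:, 2] += [5.0, 0, 0]          # move acceptor away
    recs = hydrogen_bonds(ens)
    assert len(recs) == 1
    assert recs[0].occurrence == 0.5


def test_hbond_reconstructed_amide_flagged():
    # helix backbone without explicit hydrogens: i→i+4 bonds found and
    # flagged as geometry-inferred
    from confens.synthetic import build_peptide_ensemble
    from confens.secondary_structure import SecondaryStructureTrack
    track = SecondaryStructureTrack(np.full((1, 12), "H"), np.arange(689, 701))
    ens = build_peptide_ensemble("A" * 12, track, 0.0, seed=0)
    keep = ens.topology.atom_names != "H"
    topo = ens.topology
    sub = Topology(topo.residue_numbers, topo.residue_names,
                   topo.atom_names[keep], topo.elements[keep],
                   topo.atom_residue_index[keep])
    ens_noH = ConformationEnsemble(sub, ens.coordinates[:, keep, :])
    recs = hydrogen_bonds(ens_noH)
    backbone = [r for r in recs if r.atom_i == "N" and r.atom_j == "O"]
    assert backbone and all(r.geometry_inferred for r in backbone)
    assert any(r.res_i - r.res_j == 4 for r in backbone)


# ---------------------------------------------------------------------------
# Hydrophobic contacts


def sidechain_pair(d, res_names=("LEU", "LEU")):
    topo = Topology(
        residue_numbers=[700, 710],
        residue_names=list(res_names),
        atom_names=["CA", "CB", "CA", "CB"],
        elements=["C", "C", "C", "C"],
        atom_residue_index=[0, 0, 1, 1],
    )
    coords = np.zeros((2, 4, 3))
    coords[:, 1] = [1.5, 0, 0]
    coords[:, 2] = [1.5 + d + 1.5, 0, 0]
    coords[:, 3] = [1.5 + d, 0, 0]       # CB–CB distance d
    return ConformationEnsemble(topo, coords)


def test_hydrophobic_within_cutoff():
    recs = hydrophobic_contacts(sidechain_pair(3.8))
    assert len(recs) == 1
    assert recs[0].occurrence == 1.0


def test_hydrophobic_beyond_cutoff():
    assert hydrophobic_contacts(sidechain_pair(4.2)) == []


def test_hydrophobic_requires_set_membership():
    assert hydrophobic_contacts(sidechain_pair(3.0, ("LEU", "SER"))) == []


def test_glycine_in_hydrophobic_set_errors():
    ens = sidechain_pair(3.0, ("GLY", "LEU"))
    # strip GLY side chain to reproduce the degenerate case
    keep = ~((ens.topology.atom_residue_index == 0)
             & (ens.topology.atom_names == "CB"))
    topo = ens.topology
    sub = Topology(topo.residue_numbers, topo.residue_names,
                   topo.atom_names[keep], topo.elements[keep],
                   topo.atom_residue_index[keep])
    ens2 = ConformationEnsemble(sub, ens.coordinates[:, keep, :])
    with pytest.raises(EnsembleError, match="side-chain"):
        hydrophobic_contacts(ens2, hydrophobic=frozenset("GL"))


# ---------------------------------------------------------------------------
# Segment filtering


def test_segment_filter_thresholds():
    recs = [
        InteractionRecord("hbond", 700, 720, occurrence=0.85),
        InteractionRecord("hbond", 700, 720, occurrence=0.79),
        InteractionRecord("hbond", 670, 680, occurrence=0.95),
    ]
    kept = segment_contacts(recs, [(699, 709), (754, 764)])
    assert len(kept) == 1
    assert kept[0].occurrence == 0.85


def test_segment_filter_on_contact_map(rng):
    ens = pair_ensemble(8.0)
    cm = contact_map(ens)
    kept = segment_contacts(cm, [(689, 689)], min_occurrence=0.5)
    assert len(kept) == 1
    assert kept[0].kind == "contact"


def test_segment_filter_empty_segments_errors():
    with pytest.raises(EnsembleError):
        segment_contacts([], [])
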